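"""Unfolded 2D coordinate frame for EC, DG, and CA3 populations.

The hippocampus is treated as a flattened sheet per subfield.  The
longitudinal (septotemporal) axis runs from 0 mm at the temporal pole
toward the septal pole; the transverse (proximodistal) axis runs from
0 mm at the proximal edge (the CA3c border with the dentate gyrus)
increasing distally.  CA3 is partitioned into CA3c/CA3b/CA3a along the
transverse axis and into overlapping septal/middle/temporal windows
along the longitudinal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Set, Tuple

import numpy as np

__all__ = [
    "SheetExtent",
    "UnfoldedPosition",
    "PopulationConfig",
    "PopulationLayout",
    "SectionGrid",
    "build_layout",
    "assign_section",
    "DEFAULT_EXTENTS",
    "TRANSVERSE_COLUMNS",
    "LONGITUDINAL_ROWS",
]

TRANSVERSE_COLUMNS = ("CA3c", "CA3b", "CA3a")  # proximal -> distal
LONGITUDINAL_ROWS = ("septal", "middle", "temporal")

BLADE_NONE = -1
BLADE_SUPRA = 0
BLADE_INFRA = 1
_BLADE_NAMES = {BLADE_NONE: "none", BLADE_SUPRA: "suprapyramidal", BLADE_INFRA: "infrapyramidal"}


class ConfigurationError(ValueError):
    """Raised for invalid geometry / population configuration."""


@dataclass(frozen=True)
class SheetExtent:
    """Rectangular extent of one unfolded subfield sheet, in mm."""

    longitudinal: float
    transverse: float

    def __post_init__(self):
        if self.longitudinal <= 0 or self.transverse <= 0:
            raise ConfigurationError("sheet extents must be positive")


# The source anatomy never states flattened sheet dimensions numerically;
# these defaults are documented modelling assumptions (see docs/methods.md).
DEFAULT_EXTENTS: Dict[str, SheetExtent] = {
    "EC": SheetExtent(10.0, 3.0),
    "DG": SheetExtent(10.0, 2.0),
    "CA3": SheetExtent(10.0, 3.0),
}

FULL_SCALE_SIZES: Dict[str, int] = {"EC": 112_000, "DG": 120_000, "CA3": 25_000}


@dataclass(frozen=True)
class UnfoldedPosition:
    """A single neuron position on an unfolded subfield sheet."""

    longitudinal: float
    transverse: float
    subfield: str
    blade: str = "none"

    def __post_init__(self):
        if self.subfield not in ("EC", "DG", "CA3"):
            raise ConfigurationError(f"unknown subfield {self.subfield!r}")
        if self.blade != "none" and self.subfield != "DG":
            raise ConfigurationError("blade labels are valid only for DG positions")


@dataclass(frozen=True)
class PopulationConfig:
    """Population sizes, sheet extents, and DG blade split."""

    sizes: Dict[str, int] = field(default_factory=lambda: dict(FULL_SCALE_SIZES))
    extents: Dict[str, SheetExtent] = field(default_factory=lambda: dict(DEFAULT_EXTENTS))
    infrapyramidal_fraction: float = 0.5

    def __post_init__(self):
        for pop, n in self.sizes.items():
            if n < 0:
                raise ConfigurationError(f"negative population size for {pop}: {n}")
        if not 0.0 <= self.infrapyramidal_fraction <= 1.0:
            raise ConfigurationError("infrapyramidal_fraction must lie in [0, 1]")

    @classmethod
    def scaled(cls, fraction: float, **kwargs) -> "PopulationConfig":
        """Population counts scaled to ``fraction`` of full scale (geometry unchanged)."""
        if not 0 < fraction <= 1:
            raise ConfigurationError("scale fraction must lie in (0, 1]")
        sizes = {pop: int(round(n * fraction)) for pop, n in FULL_SCALE_SIZES.items()}
        return cls(sizes=sizes, **kwargs)


class PopulationLayout:
    """Neuron ids and unfolded positions for each population.

    Per population, neuron ids are dense 0..N-1 and index the position
    arrays directly.  ``blade`` is meaningful only for DG (-1 elsewhere).
    """

    def __init__(self, config: PopulationConfig, seed: int,
                 positions: Dict[str, np.ndarray], blades: Dict[str, np.ndarray]):
        self.config = config
        self.seed = seed
        self._positions = positions  # pop -> (N, 2) float64 [longitudinal, transverse]
        self._blades = blades        # pop -> (N,) int8

    @property
    def populations(self) -> Tuple[str, ...]:
        return tuple(self._positions)

    def size(self, pop: str) -> int:
        return len(self._positions[pop])

    def positions(self, pop: str) -> np.ndarray:
        """(N, 2) array of [longitudinal_mm, transverse_mm]."""
        return self._positions[pop]

    def blades(self, pop: str) -> np.ndarray:
        return self._blades[pop]

    def position(self, pop: str, neuron_id: int) -> UnfoldedPosition:
        lon, tra = self._positions[pop][neuron_id]
        blade = _BLADE_NAMES[int(self._blades[pop][neuron_id])]
        return UnfoldedPosition(float(lon), float(tra), pop, blade)

    def to_dataframe(self):
        import pandas as pd

        frames = []
        for pop in self.populations:
            pos = self._positions[pop]
            frames.append(pd.DataFrame({
                "population": pop,
                "id": np.arange(len(pos)),
                "longitudinal_mm": pos[:, 0],
                "transverse_mm": pos[:, 1],
                "blade": [_BLADE_NAMES[int(b)] for b in self._blades[pop]],
            }))
        return pd.concat(frames, ignore_index=True)

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def save_npz(self, path) -> None:
        arrays = {"seed": np.asarray(self.seed)}
        for pop in self.populations:
            arrays[f"{pop}_positions"] = self._positions[pop]
            arrays[f"{pop}_blades"] = self._blades[pop]
        np.savez(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "PopulationLayout":
        with np.load(path) as data:
            pops = sorted({k.split("_")[0] for k in data.files if k.endswith("_positions")})
            positions = {p: data[f"{p}_positions"] for p in pops}
            blades = {p: data[f"{p}_blades"] for p in pops}
            seed = int(data["seed"])
        sizes = {p: len(positions[p]) for p in pops}
        config = PopulationConfig(sizes=sizes)
        return cls(config, seed, positions, blades)


def build_layout(config: Optional[PopulationConfig] = None, seed: int = 0,
                 density_profile=None) -> PopulationLayout:
    """Place neurons uniformly at random on each subfield sheet.

    Parameters
    ----------
    config : population sizes and sheet extents.
    seed : RNG seed; layouts are bit-reproducible per seed.
    density_profile : optional ``{pop: callable(rng, n, extent) -> (n, 2)}``
        hook replacing uniform placement for selected populations.

    DG granule cells are additionally labeled supra-/infrapyramidal with
    the configured split.
    """
    if config is None:
        config = PopulationConfig()
    rng = np.random.default_rng(seed)
    positions: Dict[str, np.ndarray] = {}
    blades: Dict[str, np.ndarray] = {}
    for pop in ("EC", "DG", "CA3"):
        n = int(config.sizes.get(pop, 0))
        extent = config.extents[pop]
        if density_profile and pop in density_profile:
            pos = np.asarray(density_profile[pop](rng, n, extent), dtype=float)
            if pos.shape != (n, 2):
                raise ConfigurationError("density profile returned wrong shape")
        else:
            pos = np.empty((n, 2))
            pos[:, 0] = rng.uniform(0.0, extent.longitudinal, size=n)
            pos[:, 1] = rng.uniform(0.0, extent.transverse, size=n)
        positions[pop] = pos
        if pop == "DG":
            blades[pop] = np.where(
                rng.random(n) < config.infrapyramidal_fraction, BLADE_INFRA, BLADE_SUPRA
            ).astype(np.int8)
        else:
            blades[pop] = np.full(n, BLADE_NONE, dtype=np.int8)
    return PopulationLayout(config, seed, positions, blades)


@dataclass(frozen=True)
class SectionGrid:
    """3x3 partition of CA3 into longitudinal windows x transverse thirds.

    Longitudinal windows overlap (default centers 7.5/5.0/2.5 mm with a
    2.5 mm half-width) and use closed membership |center - y| <= hw, so
    a position exactly between two windows belongs to both.  Transverse
    columns partition the axis with half-open intervals, lower edge
    inclusive, so a boundary position falls in the distal-side column.
    """

    transverse_edges: Tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    window_centers: Tuple[float, ...] = (7.5, 5.0, 2.5)  # septal, middle, temporal
    half_width: float = 2.5

    def __post_init__(self):
        if self.half_width <= 0:
            raise ConfigurationError("longitudinal window half-width must be > 0")
        edges = np.asarray(self.transverse_edges)
        if len(edges) != 4 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("transverse_edges must be 4 increasing values")

    @classmethod
    def for_extent(cls, extent: SheetExtent, window_centers=(7.5, 5.0, 2.5),
                   half_width: float = 2.5) -> "SectionGrid":
        e = extent.transverse
        return cls(transverse_edges=(0.0, e / 3, 2 * e / 3, e),
                   window_centers=tuple(window_centers), half_width=half_width)

    def transverse_column(self, transverse: float) -> str:
        edges = self.transverse_edges
        idx = int(np.searchsorted(edges, transverse, side="right")) - 1
        if idx < 0 or transverse >= edges[-1]:
            # positions at or beyond the distal edge belong to the last column
            idx = min(max(idx, 0), 2)
        idx = min(idx, 2)
        return TRANSVERSE_COLUMNS[idx]

    def longitudinal_rows(self, longitudinal: float) -> Tuple[str, ...]:
        rows = []
        for name, c in zip(LONGITUDINAL_ROWS, self.window_centers):
            if abs(longitudinal - c) <= self.half_width:
                rows.append(name)
        return tuple(rows)

    def column_index_array(self, transverse: np.ndarray) -> np.ndarray:
        """Vectorized transverse column index (0=CA3c, 1=CA3b, 2=CA3a)."""
        idx = np.searchsorted(self.transverse_edges, transverse, side="right") - 1
        return np.clip(idx, 0, 2)

    def row_mask_array(self, longitudinal: np.ndarray) -> np.ndarray:
        """(N, 3) boolean membership in the septal/middle/temporal windows."""
        lon = np.asarray(longitudinal)[:, None]
        c = np.asarray(self.window_centers)[None, :]
        return np.abs(lon - c) <= self.half_width


def assign_section(position: UnfoldedPosition, grid: SectionGrid) -> Set[Tuple[str, str]]:
    """All (longitudinal row, transverse column) sections containing a CA3 position.

    The transverse column is unique; overlapping longitudinal windows can
    place one neuron in several rows.
    """
    if position.subfield != "CA3":
        raise ValueError("section assignment is defined for CA3 positions only")
    col = grid.transverse_column(position.transverse)
    return {(row, col) for row in grid.longitudinal_rows(position.longitudinal)}
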