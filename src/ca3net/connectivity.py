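"""Anatomically-constrained stochastic connectome generation.

Four excitatory pathways are generated:

* lateral / medial perforant path (LPP / MPP): entorhinal axons carry a
  Gaussian terminal field along the CA3 longitudinal axis, centered at
  the position given by the entorhinal->CA3 topographic map, with the
  1-1.5 mm reported field extent read as a +/-2 sd span.  Budgeted
  postsynaptically from layer synapse counts (density x dendritic
  length), which rise from zero proximally to their distal maxima.
* mossy fibers (MF): each granule cell sends a single thin fiber across
  the CA3 transverse axis at its longitudinal level, deviating toward
  the temporal pole within CA3a.  Synapses are placed along the fiber by
  a Poisson process whose mean spacing is region dependent (162 um in
  CA3c, 223 um in CA3b, 345 um in CA3a); each synapse captures one CA3
  cell within 30 um, or is dropped.  Infrapyramidal-origin fibers
  contact the proximal stratum oriens while in CA3c, stratum lucidum
  elsewhere.
* associational (ASSOC): recurrent CA3->CA3 projection whose axon field
  is a 2D skew-Gaussian with parameters interpolated over a 3x3
  injection grid; budgeted postsynaptically for strata radiatum and
  oriens.

Edges carry conduction delays (path length / pathway conduction
velocity: 0.32, 0.27, 0.39 m/s for PP, MF, ASSOC).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree
from scipy.stats import norm, skewnorm

from .geometry import PopulationLayout, SheetExtent, UnfoldedPosition, BLADE_INFRA

__all__ = [
    "GaussianField", "SkewFieldParams", "MossyFiberPath", "SynapseBudget",
    "Connectome", "ConnectivityConfig",
    "pp_field_for", "synapse_budget", "sample_inputs_postsynaptic",
    "mf_trajectory", "mf_place_synapses", "mf_assign_post",
    "assoc_field_for", "skew_gaussian_density", "compute_delay",
    "build_connectome",
    "CONDUCTION_VELOCITY", "MF_REGION_MEANS_UM", "TABLE1",
]

PATHWAYS = ("LPP", "MPP", "MF", "ASSOC")

# conduction velocities, m/s == mm/ms
CONDUCTION_VELOCITY = {"LPP": 0.32, "MPP": 0.32, "PP": 0.32, "MF": 0.27, "ASSOC": 0.39}

# mean inter-synapse distance of mossy fibers per transverse region (um)
MF_REGION_MEANS_UM = {"CA3c": 162.0, "CA3b": 223.0, "CA3a": 345.0}

# layer synapse budgets: synaptic density (synapses/um) and the input
# counts at the proximal and distal transverse extremes
TABLE1 = {
    #                 density  proximal  distal
    "lacunosum_distal":   (0.63,     0,  1658),   # LEC / LPP
    "lacunosum_proximal": (0.63,     0,  1105),   # MEC / MPP
    "radiatum":           (3.61, 11241, 11281),   # associational
    "oriens":             (3.15,  7147, 17893),   # associational
}

LAYER_COMP = {
    "lacunosum_distal": 0,
    "lacunosum_proximal": 1,
    "radiatum": 3,
    "lucidum": 4,
    "oriens_proximal": 6,
    "oriens_distal": 7,
}


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# perforant-path terminal fields

@dataclass(frozen=True)
class GaussianField:
    """Longitudinal Gaussian axon terminal field over the CA3 sheet.

    Uniform across the transverse span; truncated to [0, domain] and
    renormalized along the longitudinal axis.
    """

    center: float        # mm, CA3 longitudinal
    sd: float            # mm
    domain: float        # CA3 longitudinal extent, mm

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("field sd must be > 0")

    @property
    def truncated_mass(self) -> float:
        return float(norm.cdf((self.domain - self.center) / self.sd)
                     - norm.cdf((0.0 - self.center) / self.sd))

    def density(self, longitudinal) -> np.ndarray:
        """Renormalized density over the truncated domain (integrates to 1)."""
        y = np.asarray(longitudinal, dtype=float)
        d = norm.pdf(y, loc=self.center, scale=self.sd) / self.truncated_mass
        d = np.where((y >= 0) & (y <= self.domain), d, 0.0)
        return d

    def weight_at(self, longitudinal) -> np.ndarray:
        """Unnormalized connection probability weight at CA3 positions."""
        y = np.asarray(longitudinal, dtype=float)
        return np.exp(-0.5 * ((y - self.center) / self.sd) ** 2)


def pp_field_for(ec_position: UnfoldedPosition, topo_map: Callable[[float], float],
                 extent_mm: float = 1.25, ca3_longitudinal_extent: float = 10.0,
                 ) -> GaussianField:
    """Terminal field of one entorhinal cell over CA3.

    ``topo_map`` maps EC longitudinal position (mm) to the CA3
    longitudinal center (monotone; identity on the normalized axis by
    default).  The reported 1-1.5 mm terminal-field extent is read as a
    +/-2 sd span, so sd = extent / 4.
    """
    if ec_position.subfield != "EC":
        raise ConfigurationError("pp_field_for expects an EC position")
    if extent_mm <= 0:
        raise ConfigurationError("field extent must be > 0")
    center = float(topo_map(ec_position.longitudinal))
    return GaussianField(center=center, sd=extent_mm / 4.0,
                         domain=ca3_longitudinal_extent)


def identity_topo_map(src_extent: float, dst_extent: float) -> Callable[[float], float]:
    """Default topographic map: identity on normalized longitudinal position."""
    return lambda y: y / src_extent * dst_extent


# --------------------------------------------------------------------------
# synapse budgets (postsynaptic method)

@dataclass(frozen=True)
class SynapseBudget:
    """Per-layer input counts for one CA3 pyramidal cell."""

    lacunosum_distal: int
    lacunosum_proximal: int
    radiatum: int
    oriens: int

    def __post_init__(self):
        for v in (self.lacunosum_distal, self.lacunosum_proximal,
                  self.radiatum, self.oriens):
            if v < 0:
                raise ConfigurationError("budgets must be >= 0")


def _implied_lengths() -> Dict[str, Tuple[float, float]]:
    """Proximal/distal dendritic lengths (um) implied by count / density."""
    return {layer: (prox / dens, dist / dens)
            for layer, (dens, prox, dist) in TABLE1.items()}


def synapse_budget(transverse_fraction: float,
                   densities: Optional[Dict[str, float]] = None,
                   lengths: Optional[Dict[str, float]] = None) -> SynapseBudget:
    """Layer input counts at a relative transverse position in [0, 1].

    count = round(density x dendritic length); default lengths
    interpolate linearly between the proximal and distal values implied
    by the layer count table.  Proximal cells receive no
    lacunosum-moleculare (perforant path) inputs.
    """
    if not 0.0 <= transverse_fraction <= 1.0:
        raise ConfigurationError("transverse_fraction must lie in [0, 1]")
    dens = {layer: TABLE1[layer][0] for layer in TABLE1}
    if densities:
        dens.update(densities)
    if any(d < 0 for d in dens.values()):
        raise ConfigurationError("densities must be >= 0")
    if lengths is None:
        implied = _implied_lengths()
        lengths = {layer: (1 - transverse_fraction) * lo + transverse_fraction * hi
                   for layer, (lo, hi) in implied.items()}
    if any(l < 0 for l in lengths.values()):
        raise ConfigurationError("lengths must be >= 0")
    counts = {layer: int(round(dens[layer] * lengths[layer])) for layer in dens}
    return SynapseBudget(
        lacunosum_distal=counts["lacunosum_distal"],
        lacunosum_proximal=counts["lacunosum_proximal"],
        radiatum=counts["radiatum"],
        oriens=counts["oriens"],
    )


def sample_inputs_postsynaptic(probabilities: np.ndarray, budget: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Presynaptic partner indices for one cell, drawn with replacement.

    Probabilities are renormalized over the candidates; repeated draws
    represent multi-synapse contacts and are kept as separate edges.
    """
    p = np.asarray(probabilities, dtype=float)
    if budget < 0:
        raise ConfigurationError("budget must be >= 0")
    if budget == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(p < 0):
        raise GenerationError("negative connection probability")
    total = p.sum()
    if total <= 0:
        raise GenerationError("no candidate with positive probability")
    # inverse-CDF draw (faster than rng.choice for large budgets)
    cdf = np.cumsum(p)
    u = rng.random(budget) * cdf[-1]
    return np.searchsorted(cdf, u, side="right")


# --------------------------------------------------------------------------
# mossy fibers

@dataclass
class MossyFiberPath:
    """Polyline trajectory of one mossy fiber in CA3 sheet coordinates."""

    origin_longitudinal: float
    blade: str                      # suprapyramidal / infrapyramidal
    vertices: np.ndarray            # (n, 2) [longitudinal, transverse] mm
    arc: np.ndarray                 # (n,) cumulative arc length, mm

    @property
    def length_mm(self) -> float:
        return float(self.arc[-1]) if len(self.arc) else 0.0

    def point_at(self, s) -> np.ndarray:
        """Interpolated sheet position(s) at arc length(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        lon = np.interp(s, self.arc, self.vertices[:, 0])
        tra = np.interp(s, self.arc, self.vertices[:, 1])
        return np.column_stack([lon, tra])


def default_mf_deviation_spline(transverse_extent: float = 3.0,
                                temporal_turn_mm: float = 1.5):
    """Cubic spline of longitudinal deviation vs transverse position.

    Zero deviation through CA3c and CA3b, then a smooth turn toward the
    temporal pole (negative deviation in the septal-positive convention)
    within CA3a.
    """
    x = np.array([0.0, transverse_extent / 3, 2 * transverse_extent / 3,
                  transverse_extent])
    d = np.array([0.0, 0.0, 0.0, -abs(temporal_turn_mm)])
    return make_interp_spline(x, d, k=3)


def mf_trajectory(origin: UnfoldedPosition, trajectory_spline=None,
                  noise_sd: float = 0.05, seed=0,
                  ca3_extent: SheetExtent = SheetExtent(10.0, 3.0),
                  n_vertices: int = 25) -> MossyFiberPath:
    """One mossy-fiber trajectory entering CA3 at the origin's longitudinal level.

    The fiber runs transversely with the spline's longitudinal deviation;
    Gaussian jitter of ``noise_sd`` is added vertex-wise to the
    longitudinal coordinate and the path is clipped to the CA3 sheet.
    """
    if origin.subfield != "DG":
        raise ConfigurationError("mossy fibers originate in the DG")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if trajectory_spline is None:
        trajectory_spline = default_mf_deviation_spline(ca3_extent.transverse)
    x = np.linspace(0.0, ca3_extent.transverse, n_vertices)
    lon = origin.longitudinal + np.asarray(trajectory_spline(x), dtype=float)
    if noise_sd > 0:
        lon = lon + rng.normal(0.0, noise_sd, size=n_vertices)
    lon = np.clip(lon, 0.0, ca3_extent.longitudinal)
    vertices = np.column_stack([lon, x])
    seglen = np.hypot(np.diff(lon), np.diff(x))
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    return MossyFiberPath(origin.longitudinal, origin.blade, vertices, arc)


def mf_place_synapses(path: MossyFiberPath,
                      region_means_um: Dict[str, float] = MF_REGION_MEANS_UM,
                      seed=0,
                      transverse_edges: Tuple[float, ...] = (0.0, 1.0, 2.0, 3.0),
                      ) -> np.ndarray:
    """Synapse arc-length positions along a fiber (inhomogeneous Poisson).

    The local rate is 1/mean inter-synapse distance of the region the
    fiber currently traverses (region by transverse coordinate,
    piecewise-constant per polyline segment).  Returns sorted arc
    positions in mm.
    """
    for v in region_means_um.values():
        if v <= 0:
            raise ConfigurationError("region means must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if path.length_mm == 0:
        return np.empty(0)
    edges = np.asarray(transverse_edges)
    names = ("CA3c", "CA3b", "CA3a")
    means_mm = np.array([region_means_um[n] / 1000.0 for n in names])
    mid_tra = 0.5 * (path.vertices[:-1, 1] + path.vertices[1:, 1])
    region = np.clip(np.searchsorted(edges, mid_tra, side="right") - 1, 0, 2)
    seg_len = np.diff(path.arc)
    rate = 1.0 / means_mm[region]            # synapses per mm, per segment
    counts = rng.poisson(rate * seg_len)
    out = []
    for i in np.nonzero(counts)[0]:
        out.append(path.arc[i] + rng.random(counts[i]) * seg_len[i])
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def mf_assign_post(synapse_xy: np.ndarray, ca3_positions: np.ndarray,
                   capture_radius_mm: float = 0.03, seed=0,
                   tree: Optional[cKDTree] = None, max_neighbors: int = 16,
                   ) -> Tuple[np.ndarray, int]:
    """Choose one CA3 cell within the capture radius of each synapse.

    Returns (post ids, n_dropped); dropped synapses (no cell in range)
    get post id -1.
    """
    if capture_radius_mm <= 0:
        raise ConfigurationError("capture radius must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(synapse_xy) == 0:
        return np.empty(0, dtype=np.int64), 0
    if tree is None:
        tree = cKDTree(ca3_positions)
    k = min(max_neighbors, len(ca3_positions))
    dist, idx = tree.query(synapse_xy, k=k, distance_upper_bound=capture_radius_mm)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    valid = np.isfinite(dist)
    counts = valid.sum(axis=1)
    post = np.full(len(synapse_xy), -1, dtype=np.int64)
    has = counts > 0
    # uniform choice among in-radius neighbors
    pick = np.floor(rng.random(has.sum()) * counts[has]).astype(np.int64)
    rows = np.nonzero(has)[0]
    post[rows] = idx[rows, pick]
    return post, int((~has).sum())


# --------------------------------------------------------------------------
# associational skew-Gaussian fields

@dataclass(frozen=True)
class SkewFieldParams:
    """2D skew-Gaussian axon field: per-axis location, scale, skew."""

    loc_long: float
    scale_long: float
    alpha_long: float
    loc_trans: float
    scale_trans: float
    alpha_trans: float
    amplitude: float = 1.0

    def __post_init__(self):
        if self.scale_long <= 0 or self.scale_trans <= 0:
            raise ConfigurationError("skew-field scales must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.loc_long, self.scale_long, self.alpha_long,
                         self.loc_trans, self.scale_trans, self.alpha_trans,
                         self.amplitude])


def skew_gaussian_density(u_long, u_trans, params: SkewFieldParams) -> np.ndarray:
    """Product of two 1D skew-normal densities at sheet offsets (mm).

    Each axis uses f(z) = 2 phi(z) Phi(alpha z) with z standardized by
    the axis location and scale; integrates to 1 over the plane before
    truncation.
    """
    p = params
    d = (skewnorm.pdf(u_long, p.alpha_long, loc=p.loc_long, scale=p.scale_long)
         * skewnorm.pdf(u_trans, p.alpha_trans, loc=p.loc_trans, scale=p.scale_trans))
    return p.amplitude * d


def default_assoc_param_grid(ca3_extent: SheetExtent = SheetExtent(10.0, 3.0),
                             ) -> Dict[Tuple[int, int], SkewFieldParams]:
    """Shipped placeholder 3x3 injection-grid parameters.

    Qualitatively matches anterograde-tracing descriptions: fields are
    centered on the injection site, elongated along the longitudinal
    axis, and skewed away from the nearer pole / proximodistal border.
    The fitted values from the original tracer material are not
    published; these are configuration defaults.
    """
    lon_nodes = [0.75 * ca3_extent.longitudinal, 0.5 * ca3_extent.longitudinal,
                 0.25 * ca3_extent.longitudinal]     # septal, middle, temporal
    tra_nodes = [ca3_extent.transverse * f for f in (1 / 6, 3 / 6, 5 / 6)]
    alpha_lon = {0: -3.0, 1: 0.0, 2: 3.0}   # septal rows skew temporal-ward
    alpha_tra = {0: 2.0, 1: 0.0, 2: -2.0}   # CA3c columns skew distal-ward
    grid = {}
    for r, lon in enumerate(lon_nodes):
        for c, tra in enumerate(tra_nodes):
            grid[(r, c)] = SkewFieldParams(
                loc_long=lon, scale_long=2.0, alpha_long=alpha_lon[r],
                loc_trans=tra, scale_trans=1.0, alpha_trans=alpha_tra[c],
                amplitude=1.0,
            )
    return grid


def _grid_axes(param_grid) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    expected = {(r, c) for r in range(3) for c in range(3)}
    if set(param_grid) != expected:
        raise ConfigurationError("param_grid must cover a full 3x3 grid")
    arr = np.empty((3, 3, 7))
    for (r, c), p in param_grid.items():
        arr[r, c] = p.as_array()
    lon_nodes = arr[:, 0, 0]   # loc_long per row
    tra_nodes = arr[0, :, 3]   # loc_trans per column
    if not (np.all(np.diff(lon_nodes) < 0) or np.all(np.diff(lon_nodes) > 0)):
        raise ConfigurationError("grid longitudinal nodes must be monotone")
    return arr, lon_nodes, tra_nodes


def _interp1(nodes: np.ndarray, values: np.ndarray, x) -> np.ndarray:
    """Piecewise-linear interpolation with linear extrapolation.

    values has shape (3, ...) along the node axis; x may be an array.
    """
    order = np.argsort(nodes)
    n = nodes[order]
    v = values[order]
    x = np.asarray(x, dtype=float)
    idx = np.clip(np.searchsorted(n, x) - 1, 0, len(n) - 2)
    x0, x1 = n[idx], n[idx + 1]
    w = (x - x0) / (x1 - x0)
    wshape = w.reshape(w.shape + (1,) * (v.ndim - 1))
    return (1 - wshape) * v[idx] + wshape * v[idx + 1]


def assoc_field_params_at(longitudinal, transverse, param_grid) -> np.ndarray:
    """Bilinearly interpolated (extrapolated) skew-field parameter vectors.

    Returns an array of shape broadcast(long, trans) x 7.
    """
    arr, lon_nodes, tra_nodes = _grid_axes(param_grid)
    lon = np.atleast_1d(np.asarray(longitudinal, dtype=float))
    tra = np.atleast_1d(np.asarray(transverse, dtype=float))
    by_row = _interp1(lon_nodes, arr, lon)          # (n, 3, 7) over columns
    out = np.empty((len(lon), 7))
    for j in range(len(lon)):
        out[j] = _interp1(tra_nodes, by_row[j], tra[j])
    return out


def assoc_field_for(ca3_position: UnfoldedPosition, param_grid) -> SkewFieldParams:
    """Skew-Gaussian axon field of one CA3 cell, interpolated from the grid."""
    if ca3_position.subfield != "CA3":
        raise ConfigurationError("assoc_field_for expects a CA3 position")
    vec = assoc_field_params_at(ca3_position.longitudinal,
                                ca3_position.transverse, param_grid)[0]
    return SkewFieldParams(*vec)


# --------------------------------------------------------------------------
# delays

def compute_delay(path_length_mm: float, pathway: str) -> float:
    """Conduction delay (ms) = path length / pathway conduction velocity."""
    if path_length_mm < 0:
        raise ConfigurationError("path length must be >= 0")
    if pathway not in CONDUCTION_VELOCITY:
        raise ConfigurationError(f"unknown pathway {pathway!r}")
    return path_length_mm / CONDUCTION_VELOCITY[pathway]


# --------------------------------------------------------------------------
# connectome container and orchestration

@dataclass
class PathwayEdges:
    """Columnar edge list of one pathway."""

    pre_pop: str
    pre: np.ndarray       # int32
    post: np.ndarray      # int32
    comp: np.ndarray      # int8, target compartment
    delay_ms: np.ndarray  # float32
    weight: np.ndarray    # float32, relative to the calibrated unitary weight

    def __len__(self):
        return len(self.pre)


@dataclass
class Connectome:
    edges: Dict[str, PathwayEdges]
    seed: int
    config_hash: str
    mf_dropped: int = 0

    def n_edges(self, pathway: Optional[str] = None) -> int:
        if pathway is not None:
            return len(self.edges[pathway]) if pathway in self.edges else 0
        return sum(len(e) for e in self.edges.values())

    def in_degree(self, pathway: str, n_post: int) -> np.ndarray:
        if pathway not in self.edges:
            return np.zeros(n_post, dtype=np.int64)
        return np.bincount(self.edges[pathway].post, minlength=n_post)

    def scale_weights(self, pathway: str, factor: float) -> "Connectome":
        """Copy with one pathway's weights multiplied; the original is untouched."""
        if pathway not in PATHWAYS:
            raise ConfigurationError(f"unknown pathway {pathway!r}")
        if factor < 0:
            raise ConfigurationError("scale factor must be >= 0")
        new_edges = {}
        for name, e in self.edges.items():
            w = e.weight * factor if name == pathway else e.weight.copy()
            new_edges[name] = PathwayEdges(e.pre_pop, e.pre.copy(), e.post.copy(),
                                           e.comp.copy(), e.delay_ms.copy(),
                                           w.astype(np.float32))
        return Connectome(new_edges, self.seed, self.config_hash, self.mf_dropped)

    def summary(self) -> Dict[str, Dict[str, float]]:
        out = {}
        for name, e in self.edges.items():
            deg = np.bincount(e.post) if len(e) else np.zeros(1)
            out[name] = {
                "n_edges": len(e),
                "mean_in_degree": float(deg[deg > 0].mean()) if (deg > 0).any() else 0.0,
                "mean_delay_ms": float(e.delay_ms.mean()) if len(e) else 0.0,
            }
        return out

    def save_tsv(self, path) -> None:
        import pandas as pd

        frames = []
        for name, e in self.edges.items():
            frames.append(pd.DataFrame({
                "pre_pop": e.pre_pop, "pre_id": e.pre, "post_id": e.post,
                "pathway": name, "compartment": e.comp,
                "delay_ms": e.delay_ms, "weight": e.weight,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    def save_npz(self, path) -> None:
        arrays = {"seed": np.asarray(self.seed),
                  "config_hash": np.asarray(self.config_hash),
                  "mf_dropped": np.asarray(self.mf_dropped)}
        for name, e in self.edges.items():
            for col in ("pre", "post", "comp", "delay_ms", "weight"):
                arrays[f"{name}_{col}"] = getattr(e, col)
            arrays[f"{name}_prepop"] = np.asarray(e.pre_pop)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "Connectome":
        with np.load(path) as d:
            names = {k.rsplit("_", 1)[0] for k in d.files if k.endswith("_pre")}
            edges = {}
            for name in names:
                edges[name] = PathwayEdges(
                    str(d[f"{name}_prepop"]), d[f"{name}_pre"], d[f"{name}_post"],
                    d[f"{name}_comp"], d[f"{name}_delay_ms"], d[f"{name}_weight"])
            return cls(edges, int(d["seed"]), str(d["config_hash"]),
                       int(d["mf_dropped"]))


@dataclass
class ConnectivityConfig:
    """Generation parameters for all pathways."""

    pathways: Tuple[str, ...] = PATHWAYS
    pp_extent_mm: float = 1.25
    lateral_fraction: float = 0.5       # EC cells labeled lateral vs medial
    mf_noise_sd: float = 0.05
    mf_temporal_turn_mm: float = 1.5
    mf_capture_radius_mm: float = 0.03
    mf_vertices: int = 25
    budget_scale: float = 1.0           # optional scaling of Table-1 budgets
    assoc_param_grid: Optional[dict] = None
    topo_map: Optional[Callable[[float], float]] = None

    def hash(self) -> str:
        parts = (self.pathways, self.pp_extent_mm, self.lateral_fraction,
                 self.mf_noise_sd, self.mf_temporal_turn_mm,
                 self.mf_capture_radius_mm, self.mf_vertices, self.budget_scale)
        return hashlib.md5(repr(parts).encode()).hexdigest()[:12]


def _scaled_budget(frac: float, scale: float) -> SynapseBudget:
    b = synapse_budget(frac)
    if scale == 1.0:
        return b
    return SynapseBudget(*(int(round(v * scale)) for v in
                           (b.lacunosum_distal, b.lacunosum_proximal,
                            b.radiatum, b.oriens)))


def _pp_edges(layout: PopulationLayout, config: ConnectivityConfig,
              which: str, ec_mask: np.ndarray, rng: np.random.Generator,
              ) -> PathwayEdges:
    """Budgeted postsynaptic sampling for one perforant-path division."""
    ec_pos = layout.positions("EC")
    ca3_pos = layout.positions("CA3")
    ca3_extent = layout.config.extents["CA3"]
    ec_extent = layout.config.extents["EC"]
    topo = config.topo_map or identity_topo_map(ec_extent.longitudinal,
                                                ca3_extent.longitudinal)
    cand = np.nonzero(ec_mask)[0]
    centers = np.asarray([topo(y) for y in ec_pos[cand, 0]])
    sd = config.pp_extent_mm / 4.0
    layer = "lacunosum_distal" if which == "LPP" else "lacunosum_proximal"
    comp = LAYER_COMP[layer]
    pre_l, post_l, delay_l = [], [], []
    for i in range(len(ca3_pos)):
        frac = ca3_pos[i, 1] / ca3_extent.transverse
        b = _scaled_budget(frac, config.budget_scale)
        budget = getattr(b, layer)
        if budget == 0:
            continue
        w = np.exp(-0.5 * ((ca3_pos[i, 0] - centers) / sd) ** 2)
        draws = sample_inputs_postsynaptic(w, budget, rng)
        pre_ids = cand[draws]
        # axons enter at the proximal edge at their mapped longitudinal level
        dist = np.hypot(centers[draws] - ca3_pos[i, 0], ca3_pos[i, 1])
        pre_l.append(pre_ids)
        post_l.append(np.full(budget, i, dtype=np.int64))
        delay_l.append(dist / CONDUCTION_VELOCITY["PP"])
    if not pre_l:
        z = np.empty(0)
        return PathwayEdges("EC", z.astype(np.int32), z.astype(np.int32),
                            z.astype(np.int8), z.astype(np.float32),
                            z.astype(np.float32))
    pre = np.concatenate(pre_l).astype(np.int32)
    post = np.concatenate(post_l).astype(np.int32)
    delay = np.concatenate(delay_l).astype(np.float32)
    return PathwayEdges("EC", pre, post,
                        np.full(len(pre), comp, dtype=np.int8), delay,
                        np.ones(len(pre), dtype=np.float32))


def _mf_edges(layout: PopulationLayout, config: ConnectivityConfig,
              rng: np.random.Generator) -> Tuple[PathwayEdges, int]:
    dg_pos = layout.positions("DG")
    dg_blade = layout.blades("DG")
    ca3_pos = layout.positions("CA3")
    ca3_extent = layout.config.extents["CA3"]
    edges_t = (0.0, ca3_extent.transverse / 3, 2 * ca3_extent.transverse / 3,
               ca3_extent.transverse)
    spline = default_mf_deviation_spline(ca3_extent.transverse,
                                         config.mf_temporal_turn_mm)
    tree = cKDTree(ca3_pos) if len(ca3_pos) else None
    xy_l, pre_l, arc_l, comp_l = [], [], [], []
    for j in range(len(dg_pos)):
        origin = UnfoldedPosition(dg_pos[j, 0], dg_pos[j, 1], "DG",
                                  "infrapyramidal" if dg_blade[j] == BLADE_INFRA
                                  else "suprapyramidal")
        path = mf_trajectory(origin, spline, config.mf_noise_sd, rng,
                             ca3_extent, config.mf_vertices)
        s = mf_place_synapses(path, MF_REGION_MEANS_UM, rng, edges_t)
        if len(s) == 0:
            continue
        xy = path.point_at(s)
        infra = dg_blade[j] == BLADE_INFRA
        in_ca3c = xy[:, 1] < edges_t[1]
        comp = np.where(infra & in_ca3c, LAYER_COMP["oriens_proximal"],
                        LAYER_COMP["lucidum"]).astype(np.int8)
        xy_l.append(xy)
        arc_l.append(s)
        pre_l.append(np.full(len(s), j, dtype=np.int32))
        comp_l.append(comp)
    if not xy_l or tree is None:
        z = np.empty(0)
        return PathwayEdges("DG", z.astype(np.int32), z.astype(np.int32),
                            z.astype(np.int8), z.astype(np.float32),
                            z.astype(np.float32)), 0
    xy = np.concatenate(xy_l)
    arc = np.concatenate(arc_l)
    pre = np.concatenate(pre_l)
    comp = np.concatenate(comp_l)
    post, dropped = mf_assign_post(xy, ca3_pos, config.mf_capture_radius_mm,
                                   rng, tree=tree)
    keep = post >= 0
    delay = (arc[keep] / CONDUCTION_VELOCITY["MF"]).astype(np.float32)
    return PathwayEdges("DG", pre[keep], post[keep].astype(np.int32),
                        comp[keep], delay,
                        np.ones(keep.sum(), dtype=np.float32)), dropped


def _assoc_edges(layout: PopulationLayout, config: ConnectivityConfig,
                 rng: np.random.Generator) -> PathwayEdges:
    ca3_pos = layout.positions("CA3")
    n = len(ca3_pos)
    ca3_extent = layout.config.extents["CA3"]
    grid = config.assoc_param_grid or default_assoc_param_grid(ca3_extent)
    # axon-field parameters of every presynaptic cell
    params = assoc_field_params_at(ca3_pos[:, 0], ca3_pos[:, 1], grid)  # (n, 7)
    pre_l, post_l, comp_l, delay_l = [], [], [], []
    # density of every pre field at every post position, built post-by-post
    for i in range(n):
        frac = ca3_pos[i, 1] / ca3_extent.transverse
        b = _scaled_budget(frac, config.budget_scale)
        w = (skewnorm.pdf(ca3_pos[i, 0], params[:, 2], loc=params[:, 0],
                          scale=params[:, 1])
             * skewnorm.pdf(ca3_pos[i, 1], params[:, 5], loc=params[:, 3],
                            scale=params[:, 4]) * params[:, 6])
        w[i] = 0.0  # no self-connections
        for layer, budget in (("radiatum", b.radiatum), ("oriens", b.oriens)):
            if budget == 0:
                continue
            draws = sample_inputs_postsynaptic(w, budget, rng)
            dist = np.hypot(ca3_pos[draws, 0] - ca3_pos[i, 0],
                            ca3_pos[draws, 1] - ca3_pos[i, 1])
            comp = LAYER_COMP["radiatum"] if layer == "radiatum" \
                else LAYER_COMP["oriens_distal"]
            pre_l.append(draws.astype(np.int32))
            post_l.append(np.full(budget, i, dtype=np.int32))
            comp_l.append(np.full(budget, comp, dtype=np.int8))
            delay_l.append((dist / CONDUCTION_VELOCITY["ASSOC"]).astype(np.float32))
    if not pre_l:
        z = np.empty(0)
        return PathwayEdges("CA3", z.astype(np.int32), z.astype(np.int32),
                            z.astype(np.int8), z.astype(np.float32),
                            z.astype(np.float32))
    pre = np.concatenate(pre_l)
    return PathwayEdges("CA3", pre, np.concatenate(post_l),
                        np.concatenate(comp_l), np.concatenate(delay_l),
                        np.ones(len(pre), dtype=np.float32))


def build_connectome(layout: PopulationLayout,
                     config: Optional[ConnectivityConfig] = None,
                     seed: int = 0) -> Connectome:
    """Generate all enabled pathways for a layout.

    LPP/MPP/ASSOC are budgeted postsynaptically (in-degree equals the
    layer budget exactly); MF is generated presynaptically from fiber
    trajectories.  Bit-reproducible per seed.
    """
    if config is None:
        config = ConnectivityConfig()
    edges: Dict[str, PathwayEdges] = {}
    dropped = 0
    if any(p in config.pathways for p in ("LPP", "MPP")):
        ec_n = layout.size("EC")
        lateral = np.random.default_rng((seed, 101)).random(ec_n) < config.lateral_fraction
        if "LPP" in config.pathways:
            edges["LPP"] = _pp_edges(layout, config, "LPP", lateral,
                                     np.random.default_rng((seed, 1)))
        if "MPP" in config.pathways:
            edges["MPP"] = _pp_edges(layout, config, "MPP", ~lateral,
                                     np.random.default_rng((seed, 2)))
    if "MF" in config.pathways:
        edges["MF"], dropped = _mf_edges(layout, config,
                                         np.random.default_rng((seed, 3)))
    if "ASSOC" in config.pathways:
        edges["ASSOC"] = _assoc_edges(layout, config,
                                      np.random.default_rng((seed, 4)))
    return Connectome(edges, seed, config.hash(), dropped)
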