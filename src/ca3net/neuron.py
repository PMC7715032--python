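"""Reduced eight-compartment conductance-based neuron models.

Each cell is a chain of eight compartments, one per dendritic layer plus
the soma, so every afferent pathway targets exactly one compartment:

    0 lacunosum_distal   (lateral perforant path)
    1 lacunosum_proximal (medial perforant path)
    2 radiatum_distal
    3 radiatum_proximal  (associational, stratum radiatum)
    4 lucidum            (mossy fibers)
    5 soma
    6 oriens_proximal    (mossy fibers from infrapyramidal CA3c / associational)
    7 oriens_distal      (associational, stratum oriens)

Channel dynamics follow the classical two-variable Hodgkin-Huxley
formalism used in reduced hippocampal models (fast Na and delayed
rectifier at the soma, high-threshold Ca with Ca-activated K and a slow
AHP conductance in the dendrites, plus an M-type slow K current for
adaptation).  Three CA3 presets reproduce the qualitative firing
taxonomy of CA3 pyramidal cells (bursting, strongly adapting, weakly
adapting); a granule preset reuses the same machinery for the dentate.
Quantitative trace matching to detailed reconstructions is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = [
    "NCOMP", "SOMA", "LAYER_COMPARTMENT", "CellParams",
    "ca3_pyramidal", "granule_cell", "PRESETS",
]

NCOMP = 8
SOMA = 5

LAYER_COMPARTMENT: Dict[str, int] = {
    "lacunosum_distal": 0,
    "lacunosum_proximal": 1,
    "radiatum_distal": 2,
    "radiatum": 3,
    "radiatum_proximal": 3,
    "lucidum": 4,
    "soma": 5,
    "oriens_proximal": 6,
    "oriens_distal": 7,
}

# Reversal potentials (mV)
E_NA = 60.0
E_K = -75.0
E_CA = 80.0


@dataclass
class CellParams:
    """Per-compartment biophysical parameters of one cell preset.

    Conductance densities are mS/cm^2; areas cm^2; axial couplings uS
    between adjacent compartments in the chain.
    """

    label: str
    area: np.ndarray            # (8,) cm^2
    cm: float                   # uF/cm^2
    g_leak: np.ndarray          # (8,) mS/cm^2
    e_leak: float               # mV
    g_na: np.ndarray
    g_kdr: np.ndarray
    g_ca: np.ndarray
    g_kc: np.ndarray
    g_kahp: np.ndarray
    g_km: np.ndarray
    tau_km: float               # ms
    g_axial: np.ndarray         # (7,) uS, link i connects comps i and i+1
    v_rest: float = -65.0

    @property
    def cap_nF(self) -> np.ndarray:
        return self.cm * self.area * 1e3  # uF/cm^2 * cm^2 -> uF, *1e3 -> nF

    def abs_uS(self, density: np.ndarray) -> np.ndarray:
        return density * self.area * 1e3  # mS/cm^2 * cm^2 -> mS, *1e3 -> uS

    @property
    def input_resistance_MOhm(self) -> float:
        return 1.0 / self.abs_uS(self.g_leak).sum()


def _base_arrays():
    return {k: np.zeros(NCOMP) for k in
            ("g_na", "g_kdr", "g_ca", "g_kc", "g_kahp", "g_km")}


def ca3_pyramidal(firing_type: str = "weakly_adapting") -> CellParams:
    """Reduced CA3 pyramidal cell preset for one of the three firing types.

    Total membrane area 6e-4 cm^2 (Rin ~ 17 MOhm at 0.1 mS/cm^2 leak),
    half somatic.  The adapting presets differ in M-current strength;
    the bursting preset concentrates dendritic area and high-threshold
    Ca / Ca-activated K on the two compartments flanking the soma, which
    produces a ping-pong somatodendritic burst at onset (three spikes
    with < 10 ms intervals at 1.25x rheobase).
    """
    area = np.full(NCOMP, 3.0e-4 / 7)
    area[SOMA] = 3.0e-4
    ch = _base_arrays()
    ch["g_na"][SOMA] = 30.0
    ch["g_kdr"][SOMA] = 18.0
    g_axial = np.full(NCOMP - 1, 0.6)  # uS
    tau_km = 120.0
    cm = 1.0  # uF/cm^2; the bursting preset uses the higher value its
    #            somatodendritic loop was tuned with
    if firing_type == "weakly_adapting":
        ch["g_km"][SOMA] = 0.15
    elif firing_type == "strongly_adapting":
        ch["g_km"][SOMA] = 10.0
        tau_km = 200.0
    elif firing_type == "bursting":
        area = np.full(NCOMP, 0.6e-4 / 5)
        area[SOMA] = 3.0e-4
        area[4] = area[6] = 1.2e-4
        ch["g_kdr"][SOMA] = 15.0
        for comp in (4, 6):
            ch["g_ca"][comp] = 10.0
            ch["g_kc"][comp] = 15.0
            ch["g_kahp"][comp] = 2.0
        g_axial = np.full(NCOMP - 1, 0.3)
        g_axial[4] = g_axial[5] = 0.63  # soma links carry the burst loop
        cm = 3.0
    else:
        raise ValueError(f"unknown CA3 firing type {firing_type!r}")
    return CellParams(
        label=f"ca3_{firing_type}",
        area=area, cm=cm,
        g_leak=np.full(NCOMP, 0.1), e_leak=-65.0,
        tau_km=tau_km, g_axial=g_axial, **ch,
    )


def granule_cell() -> CellParams:
    """Dentate granule cell preset: small, compact, weakly adapting.

    Granule cells are electrotonically compact with a high input
    resistance and fire sparsely; only the two molecular-layer
    compartments receive (perforant-path) input.
    """
    area = np.full(NCOMP, 0.5e-4 / 7)
    area[SOMA] = 0.5e-4
    ch = _base_arrays()
    ch["g_na"][SOMA] = 30.0
    ch["g_kdr"][SOMA] = 20.0
    ch["g_km"][SOMA] = 0.8
    return CellParams(
        label="granule",
        area=area, cm=1.0,
        g_leak=np.full(NCOMP, 0.1), e_leak=-70.0,
        tau_km=80.0, g_axial=np.full(NCOMP - 1, 0.3), v_rest=-70.0, **ch,
    )


PRESETS = {
    "bursting": lambda: ca3_pyramidal("bursting"),
    "strongly_adapting": lambda: ca3_pyramidal("strongly_adapting"),
    "weakly_adapting": lambda: ca3_pyramidal("weakly_adapting"),
    "granule": granule_cell,
}
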