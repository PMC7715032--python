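"""Network simulation API: cells + calibrated synapses + connectome -> raster.

Wraps the fixed-step integration kernel.  Presynaptic spikes come from
feedforward spike sources (EC/DG rasters) or from recurrent cells;
every edge's calibrated conductance is scaled by its pathway's weight
factor before delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Sequence

import numpy as np

from . import engine
from .connectivity import Connectome
from .neuron import NCOMP, SOMA, LAYER_COMPARTMENT, CellParams, PRESETS
from .sources import SpikeRaster
from .synapses import (AMPAParams, NMDAParams, DEFAULT_NMDA, VoltageTrace,
                       CalibratedSynapse, calibrate_all, nmda_peak_normalizer)

__all__ = [
    "SimConfig", "PathwayScale", "CompartmentKinetics", "SingleCell",
    "reference_cell", "calibrated_kinetics", "simulate_network",
    "scale_weights", "classify_firing_type", "firing_response",
    "adaptation_index",
]

# pathway -> target layer name is fixed by the anatomy; the compartment
# index is resolved through LAYER_COMPARTMENT.
PATHWAY_LAYERS = {
    "LPP": "lacunosum_distal",
    "MPP": "lacunosum_proximal",
    "MF": "lucidum",            # infrapyramidal CA3c contacts use oriens_proximal
    "ASSOC": "radiatum",        # oriens contacts use oriens_distal
}


class WiringError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


class ClassificationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation step, duration, spike detection, and weight scaling."""

    dt_ms: float = 0.025
    duration_ms: float = 5000.0
    v_threshold_mV: float = -10.0
    lockout_ms: float = 2.0
    seed: int = 0
    record_cell: int = -1

    def __post_init__(self):
        if self.dt_ms <= 0 or self.duration_ms < 0:
            raise ValueError("dt must be > 0 and duration >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt_ms))


@dataclass(frozen=True)
class PathwayScale:
    """Synaptic weight multipliers per pathway (1.0 = calibrated strength)."""

    LPP: float = 1.0
    MPP: float = 1.0
    MF: float = 1.0
    ASSOC: float = 1.0

    def __post_init__(self):
        for p in ("LPP", "MPP", "MF", "ASSOC"):
            if getattr(self, p) < 0:
                raise ValueError("pathway scale factors must be >= 0")

    def get(self, pathway: str) -> float:
        return getattr(self, pathway)


class CompartmentKinetics:
    """Per-compartment synapse kinetics and unitary weights for one cell type."""

    def __init__(self, calibrations: Dict[str, CalibratedSynapse]):
        self.calibrations = calibrations
        self.dA1 = np.ones(NCOMP)
        self.dA2 = np.ones(NCOMP)
        self.dN1 = np.ones(NCOMP)
        self.dN2 = np.ones(NCOMP)
        self.dN3 = np.ones(NCOMP)
        self.wN = np.zeros(NCOMP)
        self.pfA = np.ones(NCOMP)
        self.pfN = np.ones(NCOMP)
        self.unitary_uS = np.zeros(NCOMP)
        self.unitary_nmda_uS = np.zeros(NCOMP)
        self.has_syn = np.zeros(NCOMP, dtype=np.uint8)
        self.mg_mM = DEFAULT_NMDA.mg_mM
        self._tauA = {}
        for layer, cal in calibrations.items():
            k = LAYER_COMPARTMENT[layer]
            self.has_syn[k] = 1
            self._tauA[k] = (cal.ampa.tau1, cal.ampa.tau2)
            self.pfA[k] = cal.ampa.peak_factor
            self.pfN[k] = nmda_peak_normalizer(cal.nmda)
            self.wN[k] = cal.nmda.w
            self.unitary_uS[k] = cal.ampa.weight
            self.unitary_nmda_uS[k] = cal.nmda.weight
            self.mg_mM = cal.nmda.mg_mM
            self._nmda_taus = (cal.nmda.tau1, cal.nmda.tau2, cal.nmda.tau3)

    def decay_factors(self, dt_ms: float) -> None:
        for k, (t1, t2) in self._tauA.items():
            self.dA1[k] = np.exp(-dt_ms / t1)
            self.dA2[k] = np.exp(-dt_ms / t2)
            cal = None
            for layer, c in self.calibrations.items():
                if LAYER_COMPARTMENT[layer] == k:
                    cal = c
                    break
            self.dN1[k] = np.exp(-dt_ms / cal.nmda.tau1)
            self.dN2[k] = np.exp(-dt_ms / cal.nmda.tau2)
            self.dN3[k] = np.exp(-dt_ms / cal.nmda.tau3)


def _empty_csr(n_src: int):
    return (np.zeros(n_src + 1, dtype=np.int64),
            np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int8),
            np.empty(0, dtype=np.int32),
            np.empty(0, dtype=np.float64), np.empty(0, dtype=np.float64))


def _build_csr(n_src, pre, tcell, tcomp, delay_steps, wa, wn):
    """Adjacency sorted by source id, CSR indptr over 0..n_src."""
    if len(pre) == 0:
        return _empty_csr(n_src)
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    counts = np.bincount(pre, minlength=n_src)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return (indptr, tcell[order].astype(np.int32), tcomp[order].astype(np.int8),
            delay_steps[order].astype(np.int32),
            wa[order].astype(np.float64), wn[order].astype(np.float64))


class SingleCell:
    """One isolated compartmental cell; used for calibration and protocols."""

    def __init__(self, params: CellParams, dt_ms: float = 0.025):
        self.params = params
        self.dt_ms = dt_ms

    def _run(self, duration_ms, inj_amp=0.0, inj_window=(0.0, 0.0),
             deliveries=(), kin: Optional[CompartmentKinetics] = None,
             record=True):
        p = self.params
        nsteps = int(round(duration_ms / self.dt_ms))
        if kin is None:
            kin = CompartmentKinetics({})
        kin.decay_factors(self.dt_ms)
        # deliveries: sequence of (time_ms, comp, w_ampa_uS, w_nmda_uS)
        if deliveries:
            steps = np.array([max(1, int(round(t / self.dt_ms))) for t, *_ in deliveries],
                             dtype=np.int64)
            order = np.argsort(steps)
            src_step = steps[order] - 1  # schedule one step early, delay 1
            src_id = np.arange(len(deliveries), dtype=np.int32)[order]
            n_src = len(deliveries)
            tcell = np.zeros(n_src, dtype=np.int32)
            tcomp = np.array([d[1] for d in deliveries], dtype=np.int8)
            wa = np.array([d[2] / kin.pfA[d[1]] for d in deliveries])
            wn = np.array([d[3] / kin.pfN[d[1]] for d in deliveries])
            delay = np.ones(n_src, dtype=np.int32)
            indptr = np.arange(n_src + 1, dtype=np.int64)
            src = (src_step, src_id, indptr, tcell, tcomp, delay, wa, wn)
        else:
            indptr, tcell, tcomp, delay, wa, wn = _empty_csr(1)
            src = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32),
                   indptr, tcell, tcomp, delay, wa, wn)
        rec_csr = _empty_csr(1)
        inj = np.full(1, inj_amp)
        i0 = int(round(inj_window[0] / self.dt_ms))
        i1 = int(round(inj_window[1] / self.dt_ms))
        spk_cell, spk_step, nspk, vrec = engine.run_network(
            self.dt_ms, nsteps,
            p.cap_nF, p.abs_uS(p.g_leak), p.e_leak, p.abs_uS(p.g_na),
            p.abs_uS(p.g_kdr), p.abs_uS(p.g_ca), p.abs_uS(p.g_kc),
            p.abs_uS(p.g_kahp), p.abs_uS(p.g_km), p.tau_km, p.g_axial,
            p.g_ca,
            p.v_rest, 1,
            kin.dA1, kin.dA2, kin.pfA, kin.dN1, kin.dN2, kin.dN3, kin.wN,
            kin.pfN, kin.mg_mM, kin.has_syn,
            *src,
            *rec_csr,
            max(2, int(delay.max()) + 2 if len(delay) else 2),
            inj, i0, i1,
            -10.0, int(round(2.0 / self.dt_ms)),
            100000, 0 if record else -1,
        )
        if nspk < 0:
            raise IntegrationError("single-cell integration diverged")
        times = spk_step[:nspk] * self.dt_ms
        return times, vrec

    def epsp_trace(self, layer: str, ampa: AMPAParams,
                   nmda: NMDAParams = DEFAULT_NMDA,
                   onset_ms: float = 100.0, window_ms: float = 900.0,
                   ) -> VoltageTrace:
        """Somatic voltage response to one synaptic event on ``layer``."""
        comp = LAYER_COMPARTMENT[layer]
        kin = CompartmentKinetics({layer: CalibratedSynapse(ampa, nmda, 0, 0)})
        _, vrec = self._run(onset_ms + window_ms,
                            deliveries=[(onset_ms, comp, ampa.weight, nmda.weight)],
                            kin=kin)
        # drop the pre-onset settling transient; keep a short baseline segment
        i_base = int(round(onset_ms / self.dt_ms)) - 2
        i0 = max(0, i_base - int(round(10.0 / self.dt_ms)))
        t = np.arange(len(vrec)) * self.dt_ms
        return VoltageTrace(t_ms=t[i0:], v_mV=vrec[i0:],
                            baseline_mV=float(vrec[i_base]))

    def step_response(self, amp_nA: float, onset_ms: float = 100.0,
                      dur_ms: float = 1000.0, tail_ms: float = 100.0):
        """Spike times and somatic trace under a somatic step current."""
        times, vrec = self._run(onset_ms + dur_ms + tail_ms, inj_amp=amp_nA,
                                inj_window=(onset_ms, onset_ms + dur_ms))
        return times, vrec


def reference_cell(dt_ms: float = 0.025) -> SingleCell:
    """The reference reduced CA3 pyramidal cell used for EPSP calibration."""
    return SingleCell(PRESETS["weakly_adapting"](), dt_ms)


@lru_cache(maxsize=8)
def calibrated_kinetics(cell_type: str = "ca3") -> CompartmentKinetics:
    """EPSP-constrained synapse kinetics for a cell type (cached).

    CA3 pyramidal cells are calibrated against the six unitary-EPSP
    targets; granule cells against a perforant-path target of 0.2 mV /
    40 ms on both molecular-layer compartments (the granule-specific
    constraints are not tabulated; see docs/methods.md).
    """
    if cell_type == "ca3":
        cals = calibrate_all(reference_cell())
    elif cell_type == "granule":
        cell = SingleCell(PRESETS["granule"]())
        from .synapses import calibrate_synapse
        cals = {layer: calibrate_synapse(cell, layer, 0.2, 40.0)
                for layer in ("lacunosum_distal", "lacunosum_proximal")}
    else:
        raise ValueError(f"unknown cell type {cell_type!r}")
    return CompartmentKinetics(cals)


def scale_weights(connectome: Connectome, pathway: str, factor: float) -> Connectome:
    """Copy of the connectome with one pathway's weights multiplied."""
    return connectome.scale_weights(pathway, factor)


def simulate_network(connectome: Connectome, sources: Dict[str, SpikeRaster],
                     cell_params: CellParams, kinetics: CompartmentKinetics,
                     config: SimConfig, n_cells: int,
                     scale: PathwayScale = PathwayScale(),
                     gains: Optional[Dict[str, float]] = None) -> SpikeRaster:
    """Integrate the postsynaptic population and return its spike raster.

    ``sources`` maps input population name (EC, DG) to its raster;
    recurrent (ASSOC) edges are delivered event-driven during the run.
    ``gains`` are per-pathway drive multipliers on top of ``scale``.
    Deterministic given connectome, sources, and config.
    """
    gains = gains or {}
    dt = config.dt_ms
    nsteps = config.n_steps
    kinetics.decay_factors(dt)

    # --- virtual feedforward source index space
    pops = sorted(sources)
    offsets = {}
    off = 0
    for pop in pops:
        offsets[pop] = off
        off += sources[pop].n_neurons
    n_src = off

    ff_pre, ff_cell, ff_comp, ff_delay, ff_wa, ff_wn = [], [], [], [], [], []
    rec_pre, rec_cell, rec_comp, rec_delay, rec_wa, rec_wn = [], [], [], [], [], []
    max_delay_steps = 1
    for name, e in connectome.edges.items():
        if len(e) == 0:
            continue
        s = scale.get(name) * gains.get(name, 1.0)
        # unitary NMDA weight already carries the calibration's NMDA:AMPA ratio
        w = e.weight.astype(np.float64) * kinetics.unitary_uS[e.comp] * s
        wn = e.weight.astype(np.float64) * kinetics.unitary_nmda_uS[e.comp] * s
        wa_n = w / kinetics.pfA[e.comp]
        wn_n = wn / kinetics.pfN[e.comp]
        dsteps = np.maximum(1, np.round(e.delay_ms / dt)).astype(np.int32)
        max_delay_steps = max(max_delay_steps, int(dsteps.max()))
        if name == "ASSOC":
            if e.pre_pop != "CA3":
                raise WiringError("ASSOC edges must originate in CA3")
            rec_pre.append(e.pre)
            rec_cell.append(e.post)
            rec_comp.append(e.comp)
            rec_delay.append(dsteps)
            rec_wa.append(wa_n)
            rec_wn.append(wn_n)
        else:
            if e.pre_pop not in offsets:
                raise WiringError(f"no source raster for population {e.pre_pop!r} "
                                  f"needed by pathway {name}")
            if e.pre.max() >= sources[e.pre_pop].n_neurons:
                raise WiringError(f"edge references source id beyond raster size "
                                  f"({name})")
            ff_pre.append(e.pre.astype(np.int64) + offsets[e.pre_pop])
            ff_cell.append(e.post)
            ff_comp.append(e.comp)
            ff_delay.append(dsteps)
            ff_wa.append(wa_n)
            ff_wn.append(wn_n)

    if ff_pre:
        src_csr = _build_csr(n_src, np.concatenate(ff_pre),
                             np.concatenate(ff_cell), np.concatenate(ff_comp),
                             np.concatenate(ff_delay), np.concatenate(ff_wa),
                             np.concatenate(ff_wn))
    else:
        src_csr = _empty_csr(max(n_src, 1))
    if rec_pre:
        rec_csr = _build_csr(n_cells, np.concatenate(rec_pre).astype(np.int64),
                             np.concatenate(rec_cell), np.concatenate(rec_comp),
                             np.concatenate(rec_delay), np.concatenate(rec_wa),
                             np.concatenate(rec_wn))
    else:
        rec_csr = _empty_csr(n_cells)

    # --- source spike list sorted by step
    steps_l, ids_l = [], []
    for pop in pops:
        for i, train in enumerate(sources[pop].trains):
            if len(train):
                steps_l.append(np.round(train / dt).astype(np.int64))
                ids_l.append(np.full(len(train), offsets[pop] + i, dtype=np.int32))
    if steps_l:
        steps = np.concatenate(steps_l)
        ids = np.concatenate(ids_l)
        order = np.argsort(steps, kind="stable")
        src_step, src_id = steps[order], ids[order]
        keep = src_step < nsteps
        src_step, src_id = src_step[keep], src_id[keep]
    else:
        src_step = np.empty(0, dtype=np.int64)
        src_id = np.empty(0, dtype=np.int32)

    p = cell_params
    horizon = max_delay_steps + 2
    spike_cap = int(n_cells * (config.duration_ms / 1000.0) * 300) + 1000
    spk_cell, spk_step, nspk, _ = engine.run_network(
        dt, nsteps,
        p.cap_nF, p.abs_uS(p.g_leak), p.e_leak, p.abs_uS(p.g_na),
        p.abs_uS(p.g_kdr), p.abs_uS(p.g_ca), p.abs_uS(p.g_kc),
        p.abs_uS(p.g_kahp), p.abs_uS(p.g_km), p.tau_km, p.g_axial,
        p.g_ca,
        p.v_rest, n_cells,
        kinetics.dA1, kinetics.dA2, kinetics.pfA, kinetics.dN1, kinetics.dN2,
        kinetics.dN3, kinetics.wN, kinetics.pfN, kinetics.mg_mM, kinetics.has_syn,
        src_step, src_id, *src_csr,
        *rec_csr,
        horizon,
        np.zeros(n_cells), 0, 0,
        config.v_threshold_mV, int(round(config.lockout_ms / dt)),
        spike_cap, config.record_cell,
    )
    if nspk == -1000000000:
        raise IntegrationError("spike capacity exceeded (runaway network?)")
    if nspk < 0:
        raise IntegrationError(f"integration diverged in cell {-nspk - 1}")
    trains = [np.empty(0)] * n_cells
    cells = spk_cell[:nspk]
    times = spk_step[:nspk] * dt
    order = np.argsort(cells, kind="stable")
    cells, times = cells[order], times[order]
    bounds = np.searchsorted(cells, np.arange(n_cells + 1))
    for i in range(n_cells):
        trains[i] = times[bounds[i]:bounds[i + 1]]
    return SpikeRaster(trains, config.duration_ms, population="sim")


# --------------------------------------------------------------------------
# firing-type classification

def adaptation_index(spike_times_ms: Sequence[float]) -> float:
    """AI = (ISI_last - ISI_first) / (ISI_last + ISI_first)."""
    t = np.asarray(spike_times_ms, dtype=float)
    if len(t) < 2:
        raise ClassificationError("need >= 2 spikes for an adaptation index")
    isis = np.diff(t)
    return float((isis[-1] - isis[0]) / (isis[-1] + isis[0]))


def classify_firing_type(spike_times_ms: Sequence[float],
                         burst_isi_ms: float = 10.0,
                         strong_ai: float = 0.3) -> str:
    """Label a step-protocol response as bursting / strongly / weakly adapting.

    Bursting: at least three spikes with inter-spike intervals below
    10 ms at response onset.  Otherwise the adaptation index decides:
    AI > 0.3 is strongly adapting, else weakly adapting.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    if len(t) < 2:
        raise ClassificationError("protocol produced fewer than 2 spikes")
    isis = np.diff(t)
    if len(t) >= 3 and isis[0] < burst_isi_ms and isis[1] < burst_isi_ms:
        return "bursting"
    return "strongly adapting" if adaptation_index(t) > strong_ai else "weakly adapting"


def rheobase(cell: SingleCell, lo_nA: float = 0.05, step_nA: float = 0.05,
             hi_nA: float = 3.0, dur_ms: float = 1000.0) -> float:
    """Smallest step current (coarse grid) evoking at least two spikes."""
    amp = lo_nA
    while amp <= hi_nA:
        times, _ = cell.step_response(amp, dur_ms=dur_ms)
        if len(times) >= 2:
            return amp
        amp += step_nA
    raise ClassificationError("no amplitude up to the scan limit evoked 2 spikes")


def firing_response(preset: str, amp_nA: Optional[float] = None,
                    dur_ms: float = 1000.0, dt_ms: float = 0.025):
    """Spike times of a preset under the standard somatic step protocol.

    The standard protocol is a 1 s step at 1.25x rheobase (rheobase
    found by a coarse upward scan), the conventional regime for
    assessing firing-type taxonomy near threshold.  An explicit
    ``amp_nA`` overrides it.
    """
    cell = SingleCell(PRESETS[preset](), dt_ms)
    if amp_nA is None:
        amp_nA = 1.25 * rheobase(cell, dur_ms=dur_ms)
    times, _ = cell.step_response(amp_nA, dur_ms=dur_ms)
    return times
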