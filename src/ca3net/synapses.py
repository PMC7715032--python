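"""AMPA/NMDA conductance waveforms, EPSP measurement, and calibration.

AMPA conductance is a peak-normalized double exponential,
``g(t) = w * (exp(-t/tau2) - exp(-t/tau1)) / peak`` with tau2 > tau1.
NMDA conductance is a peak-normalized triple exponential,
``w3*exp(-t/tau3) + (1-w3)*exp(-t/tau2) - exp(-t/tau1)`` with
tau3 > tau2 > tau1, multiplied by the sigmoidal magnesium block
``1 / (1 + exp(-0.062 v) [Mg]/3.57)``.

Synaptic weights and AMPA time constants are calibrated so that the
somatic unitary EPSP of each pathway matches its experimental peak and
half-height-width target on the reference reduced CA3 cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AMPAParams",
    "NMDAParams",
    "VoltageTrace",
    "EPSPMeasurement",
    "ampa_peak_time",
    "ampa_g",
    "nmda_peak_normalizer",
    "mg_block",
    "nmda_g",
    "measure_epsp",
    "calibrate_synapse",
    "EPSP_TARGETS",
    "DEFAULT_NMDA",
]


class MeasurementError(RuntimeError):
    pass


class SynapseCalibrationError(RuntimeError):
    pass


# Experimentally reported unitary somatic EPSP targets per pathway/layer:
# (peak mV, half-height width ms).
EPSP_TARGETS: Dict[str, Tuple[float, float]] = {
    "lacunosum_distal": (0.30, 46.1),    # lateral perforant path
    "lacunosum_proximal": (0.30, 46.1),  # medial perforant path
    "radiatum": (0.30, 40.9),            # associational
    "lucidum": (3.2, 135.0),             # mossy fiber
    "oriens_proximal": (3.2, 135.0),     # mossy fiber (infrapyramidal, CA3c)
    "oriens_distal": (0.30, 38.0),       # associational
}


@dataclass(frozen=True)
class AMPAParams:
    """Double-exponential AMPA conductance; weight is the peak conductance (uS)."""

    tau1: float
    tau2: float
    weight: float = 1.0

    def __post_init__(self):
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require tau2 > tau1 > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def peak_factor(self) -> float:
        """Unnormalized waveform maximum (attained at the analytic peak time)."""
        t = ampa_peak_time(self.tau1, self.tau2)
        return np.exp(-t / self.tau2) - np.exp(-t / self.tau1)


@dataclass(frozen=True)
class NMDAParams:
    """Triple-exponential NMDA conductance with sigmoidal Mg block."""

    tau1: float = 5.0
    tau2: float = 50.0
    tau3: float = 150.0
    w: float = 0.5
    mg_mM: float = 1.0
    weight: float = 0.0

    def __post_init__(self):
        if not 0 < self.tau1 < self.tau2 < self.tau3:
            raise ValueError("require tau3 > tau2 > tau1 > 0")
        if not 0 < self.w < 1:
            raise ValueError("w must lie in (0, 1)")
        if self.mg_mM < 0:
            raise ValueError("Mg concentration must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def peak_factor(self) -> float:
        return nmda_peak_normalizer(self)


# NMDA kinetics are not constrained by the unitary-EPSP data used here;
# defaults are documented assumptions (slow decay, equal component split).
DEFAULT_NMDA = NMDAParams()


def ampa_peak_time(tau1: float, tau2: float) -> float:
    """Closed-form peak time tau1*tau2/(tau2-tau1)*ln(tau2/tau1)."""
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def ampa_g(t, params: AMPAParams):
    """Peak-normalized AMPA conductance at time(s) t (ms since onset)."""
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0,
                 np.exp(-t / params.tau2) - np.exp(-t / params.tau1), 0.0)
    out = params.weight * g / params.peak_factor
    return out if out.ndim else float(out)


def _nmda_numerator(t, p: NMDAParams):
    return (p.w * np.exp(-t / p.tau3) + (1.0 - p.w) * np.exp(-t / p.tau2)
            - np.exp(-t / p.tau1))


def nmda_peak_normalizer(params: NMDAParams) -> float:
    """Maximum of the unblocked triple-exponential, via bracketed root-finding.

    The derivative has a single sign change between the rise (dominated
    by tau1) and the decay; the bracket is expanded over (0, 20*tau3).
    """
    p = params

    def deriv(t):
        return (-p.w / p.tau3 * np.exp(-t / p.tau3)
                - (1 - p.w) / p.tau2 * np.exp(-t / p.tau2)
                + 1.0 / p.tau1 * np.exp(-t / p.tau1))

    lo = 1e-9
    if deriv(lo) <= 0:
        raise SynapseCalibrationError("NMDA waveform derivative not positive at onset")
    hi = p.tau1
    upper = 20.0 * p.tau3
    while deriv(hi) > 0:
        hi *= 2.0
        if hi > upper:
            raise SynapseCalibrationError("NMDA peak not bracketed in (0, 20*tau3)")
    t_peak = brentq(deriv, lo, hi, xtol=1e-12, rtol=1e-14)
    peak = _nmda_numerator(t_peak, p)
    if peak <= 0:
        raise SynapseCalibrationError("non-positive NMDA peak")
    return float(peak)


def mg_block(v, mg_mM: float = 1.0):
    """Voltage-dependent magnesium unblock factor 1/(1 + exp(-0.062 v) [Mg]/3.57)."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-0.062 * v) * mg_mM / 3.57)
    return out if out.ndim else float(out)


def nmda_g(t, v, params: NMDAParams):
    """Peak-normalized, Mg-blocked NMDA conductance at time t and voltage v."""
    t = np.asarray(t, dtype=float)
    num = np.where(t >= 0, _nmda_numerator(np.maximum(t, 0.0), params), 0.0)
    out = params.weight * num / params.peak_factor * mg_block(v, params.mg_mM)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled somatic voltage (mV) with a pre-stimulus baseline."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    baseline_mV: float

    def __post_init__(self):
        if len(self.t_ms) != len(self.v_mV):
            raise ValueError("time and voltage arrays must match")
        if not np.all(np.isfinite(self.v_mV)):
            raise ValueError("voltage trace contains non-finite values")


@dataclass(frozen=True)
class EPSPMeasurement:
    peak_mV: float
    hhw_ms: float


def measure_epsp(trace: VoltageTrace) -> EPSPMeasurement:
    """Peak amplitude above baseline and half-height width of an EPSP.

    Half-height crossings are located by linear interpolation between
    samples; a flat trace or one that never falls back below half peak
    is a measurement error.
    """
    v = trace.v_mV - trace.baseline_mV
    t = trace.t_ms
    i_peak = int(np.argmax(v))
    peak = float(v[i_peak])
    if peak <= 0:
        raise MeasurementError("flat or non-depolarizing trace")
    half = peak / 2.0

    # rising crossing: last sample before the peak below half
    below = np.nonzero(v[: i_peak + 1] < half)[0]
    if len(below) == 0:
        raise MeasurementError("no rising half-height crossing")
    i0 = below[-1]
    t_rise = t[i0] + (half - v[i0]) * (t[i0 + 1] - t[i0]) / (v[i0 + 1] - v[i0])

    # falling crossing: first sample after the peak below half
    after = np.nonzero(v[i_peak:] < half)[0]
    if len(after) == 0:
        raise MeasurementError("no falling half-height crossing (monotone trace)")
    i1 = i_peak + after[0]
    t_fall = t[i1 - 1] + (half - v[i1 - 1]) * (t[i1] - t[i1 - 1]) / (v[i1] - v[i1 - 1])

    return EPSPMeasurement(peak_mV=peak, hhw_ms=float(t_fall - t_rise))


@dataclass(frozen=True)
class CalibratedSynapse:
    ampa: AMPAParams
    nmda: NMDAParams
    measured_peak_mV: float
    measured_hhw_ms: float


def calibrate_synapse(cell, layer: str, target_peak_mV: float, target_hhw_ms: float,
                      nmda_ratio: float = 0.1, tau_ratio: float = 5.0,
                      tau1_max_ms: float = 3.0,
                      tol: float = 0.01, probe_weight: float = 1e-3,
                      nmda: NMDAParams = DEFAULT_NMDA) -> CalibratedSynapse:
    """Two-stage unitary-EPSP calibration on a reference cell.

    Stage 1 bisects on the AMPA decay constant tau2 until the somatic
    half-height width matches the target within ``tol``; stage 2 bisects
    on the synaptic weight until the somatic peak matches.  The rise
    constant is slaved to the decay (tau1 = tau2 / tau_ratio) to keep
    the shape search one-dimensional, but capped at ``tau1_max_ms``:
    AMPA-receptor rise times are on the millisecond scale even for
    synapses whose somatic EPSPs are very broad (e.g. mossy fibers).
    NMDA is co-activated at ``nmda_ratio`` times the AMPA peak
    conductance throughout (at rest the Mg block makes its contribution
    small, so the result is robust to the ratio).

    ``cell`` must provide ``epsp_trace(layer, ampa, nmda) -> VoltageTrace``.
    """
    if target_peak_mV < 0 or target_hhw_ms <= 0:
        raise ValueError("targets must be positive")
    if target_peak_mV == 0:
        ampa = AMPAParams(1.0, tau_ratio, 0.0)
        return CalibratedSynapse(ampa, replace(nmda, weight=0.0), 0.0, 0.0)

    def tau1_of(tau2: float) -> float:
        return min(tau2 / tau_ratio, tau1_max_ms)

    def hhw_for(tau2: float, pw: float) -> float:
        ampa = AMPAParams(tau1_of(tau2), tau2, pw)
        nm = replace(nmda, weight=pw * nmda_ratio)
        return measure_epsp(cell.epsp_trace(layer, ampa, nm)).hhw_ms

    def stage1_tau2(pw: float) -> float:
        # HHW(tau2) is U-shaped: for very fast AMPA decay the slow NMDA
        # tail dominates the (tiny) EPSP, so scan a geometric grid for the
        # last below-target point on the rising branch before bisecting.
        grid = 0.3 * 2.0 ** np.arange(15)
        lo = hi = None
        seen_below = False
        f_min = np.inf
        for tau in grid:
            f = hhw_for(tau, pw)
            f_min = min(f_min, f)
            if f < target_hhw_ms:
                seen_below = True
                lo = tau
            elif seen_below:
                hi = tau
                break
        if not seen_below:
            raise SynapseCalibrationError(
                f"HHW target {target_hhw_ms} ms below the membrane floor "
                f"(minimum attainable {f_min:.1f} ms)")
        if hi is None:
            raise SynapseCalibrationError(
                f"HHW target {target_hhw_ms} ms not reachable (bracket exhausted)")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f_mid = hhw_for(mid, pw)
            if abs(f_mid - target_hhw_ms) / target_hhw_ms < tol * 0.25:
                return mid
            if f_mid < target_hhw_ms:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def stage2_weight(tau2: float) -> float:
        def peak_for(w: float) -> float:
            ampa = AMPAParams(tau1_of(tau2), tau2, w)
            nm = replace(nmda, weight=w * nmda_ratio)
            return measure_epsp(cell.epsp_trace(layer, ampa, nm)).peak_mV

        w_lo, w_hi = 0.0, probe_weight
        p_hi = peak_for(w_hi)
        while p_hi < target_peak_mV:
            w_lo, w_hi = w_hi, w_hi * 2.0
            if w_hi > 10.0:
                raise SynapseCalibrationError(
                    "peak target not reachable (weight bracket exhausted)")
            p_hi = peak_for(w_hi)
        for _ in range(60):
            w_mid = 0.5 * (w_lo + w_hi)
            p_mid = peak_for(w_mid)
            if abs(p_mid - target_peak_mV) / target_peak_mV < tol * 0.25:
                return w_mid
            if p_mid < target_peak_mV:
                w_lo = w_mid
            else:
                w_hi = w_mid
        return 0.5 * (w_lo + w_hi)

    # two passes: the second re-solves the shape stage at the calibrated
    # weight, where large-amplitude EPSPs respond mildly nonlinearly
    pw = probe_weight
    for _ in range(2):
        tau2 = stage1_tau2(pw)
        weight = stage2_weight(tau2)
        pw = weight

    ampa = AMPAParams(tau1_of(tau2), tau2, weight)
    nm = replace(nmda, weight=weight * nmda_ratio)
    meas = measure_epsp(cell.epsp_trace(layer, ampa, nm))
    return CalibratedSynapse(ampa, nm, meas.peak_mV, meas.hhw_ms)


def calibrate_all(cell, targets: Dict[str, Tuple[float, float]] = EPSP_TARGETS,
                  **kwargs) -> Dict[str, CalibratedSynapse]:
    """Calibrate every pathway/layer in ``targets`` on the same cell."""
    return {layer: calibrate_synapse(cell, layer, pk, hhw, **kwargs)
            for layer, (pk, hhw) in targets.items()}
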