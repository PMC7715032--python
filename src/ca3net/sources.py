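"""Renewal-process spike sources and the spike-raster container.

Entorhinal inputs are modelled as a homogeneous Poisson process with an
exponentially recovering refractory period: after each spike the hazard
is lambda(t) = base_rate * (1 - exp(-(t - t_last)/tau)).  The base rate
is calibrated semi-analytically so the *realized* mean rate matches the
requested target (5 Hz for entorhinal sources, 0.62 Hz for the random
dentate surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "RenewalParams",
    "SpikeRaster",
    "BinnedSpikeMatrix",
    "calibrate_base_rate",
    "renewal_mean_rate",
    "generate_renewal_train",
    "generate_population_trains",
    "bin_spikes",
    "EC_RATE_HZ",
    "DG_SURROGATE_RATE_HZ",
    "REFRACTORY_TAU_MS",
]

EC_RATE_HZ = 5.0
DG_SURROGATE_RATE_HZ = 0.62
REFRACTORY_TAU_MS = 35.0


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RenewalParams:
    """Refractory renewal-process parameters.

    target_rate : realized mean rate in Hz.
    refractory_tau : recovery time constant in ms (default 35).
    base_rate : internal hazard ceiling in Hz; calibrated lazily when None.
    """

    target_rate: float
    refractory_tau: float = REFRACTORY_TAU_MS
    base_rate: Optional[float] = None

    def __post_init__(self):
        if self.target_rate < 0:
            raise ValueError("target_rate must be >= 0")
        if self.refractory_tau <= 0:
            raise ValueError("refractory_tau must be > 0")

    def calibrated(self) -> "RenewalParams":
        if self.base_rate is not None:
            return self
        base = calibrate_base_rate(self.target_rate, self.refractory_tau)
        return RenewalParams(self.target_rate, self.refractory_tau, base)


def _mean_isi_ms(base_rate_hz: float, tau_ms: float) -> float:
    """Mean inter-spike interval (ms) of the refractory renewal process.

    With hazard h(d) = lam0*(1 - exp(-d/tau)) (lam0 in 1/ms), the
    survival function is S(d) = exp(-lam0*(d - tau*(1 - exp(-d/tau))))
    and the mean ISI is the integral of S.
    """
    lam0 = base_rate_hz / 1000.0  # spikes per ms
    if lam0 <= 0:
        return np.inf
    tau = tau_ms

    def survival(d):
        return np.exp(-lam0 * (d - tau * (1.0 - np.exp(-d / tau))))

    # integrate to where survival is negligible
    upper = tau + 60.0 / lam0
    val, _ = quad(survival, 0.0, upper, limit=200)
    return val


def renewal_mean_rate(base_rate_hz: float, tau_ms: float) -> float:
    """Realized mean rate (Hz) for a given hazard ceiling."""
    if base_rate_hz <= 0:
        return 0.0
    return 1000.0 / _mean_isi_ms(base_rate_hz, tau_ms)


def calibrate_base_rate(target_rate: float, refractory_tau: float = REFRACTORY_TAU_MS) -> float:
    """Hazard ceiling (Hz) whose realized mean rate equals ``target_rate``.

    Root-finds on the semi-analytic mean-rate map.  Returns 0 for a zero
    target.  Raises CalibrationError when the target exceeds the
    refractory-limited ceiling.
    """
    if target_rate < 0:
        raise ValueError("target_rate must be >= 0")
    if target_rate == 0:
        return 0.0
    if refractory_tau <= 0:
        raise ValueError("refractory_tau must be > 0")
    # Mean ISI > integral of exp(-lam0 d)(stuff) ... hard ceiling: even an
    # infinite hazard cannot beat the recovery; cap the search and verify.
    lo, hi = target_rate, target_rate
    for _ in range(200):
        hi *= 2.0
        if renewal_mean_rate(hi, refractory_tau) >= target_rate:
            break
    else:
        raise CalibrationError(
            f"target rate {target_rate} Hz unattainable with tau={refractory_tau} ms")
    if renewal_mean_rate(hi, refractory_tau) < target_rate:
        raise CalibrationError(
            f"target rate {target_rate} Hz unattainable with tau={refractory_tau} ms")
    f = lambda b: renewal_mean_rate(b, refractory_tau) - target_rate
    if f(lo) >= 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def generate_renewal_train(params: RenewalParams, duration_ms: float,
                           seed=0) -> np.ndarray:
    """One spike train (sorted times in ms) from the refractory renewal process.

    Sampling is by thinning: candidate events from a Poisson process at
    the hazard ceiling are accepted with probability 1 - exp(-dt/tau).
    Exact for this bounded hazard.  ``seed`` may be an int or a Generator.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    p = params.calibrated()
    if p.target_rate == 0 or p.base_rate == 0:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam0 = p.base_rate / 1000.0  # per ms
    tau = p.refractory_tau
    t = 0.0
    t_last = -np.inf
    out: List[float] = []
    # draw exponentials in blocks for speed
    while t < duration_ms:
        gaps = rng.exponential(1.0 / lam0, size=256)
        us = rng.random(256)
        for gap, u in zip(gaps, us):
            t += gap
            if t >= duration_ms:
                break
            if u < 1.0 - np.exp(-(t - t_last) / tau):
                out.append(t)
                t_last = t
    return np.asarray(out)


def generate_population_trains(n: int, params: RenewalParams, duration_ms: float,
                               seed: int = 0) -> List[np.ndarray]:
    """Independent trains with per-neuron substreams derived from (seed, id)."""
    p = params.calibrated()
    return [
        generate_renewal_train(p, duration_ms, np.random.default_rng((seed, i)))
        for i in range(n)
    ]


class SpikeRaster:
    """Per-neuron sorted spike-time lists (ms) over a fixed duration."""

    def __init__(self, trains: Sequence[np.ndarray], duration_ms: float,
                 population: str = ""):
        if duration_ms <= 0:
            raise ValueError("duration must be > 0")
        self.duration_ms = float(duration_ms)
        self.population = population
        self.trains = [np.sort(np.asarray(t, dtype=float)) for t in trains]
        for t in self.trains:
            if len(t) and (t[0] < 0 or t[-1] >= duration_ms):
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains])

    def mean_rate_hz(self) -> float:
        total = sum(len(t) for t in self.trains)
        return 1000.0 * total / (self.n_neurons * self.duration_ms) if self.n_neurons else 0.0

    def save_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# population={self.population} duration_ms={self.duration_ms} "
                     f"n_neurons={self.n_neurons}\n")
            for i, train in enumerate(self.trains):
                for t in train:
                    fh.write(f"{i}\t{t:.6f}\n")

    @classmethod
    def load_text(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(item.split("=") for item in header.lstrip("# ").split())
            duration = float(meta["duration_ms"])
            n = int(meta["n_neurons"])
            trains: Dict[int, List[float]] = {i: [] for i in range(n)}
            for line in fh:
                idx, t = line.split("\t")
                trains[int(idx)].append(float(t))
        return cls([np.asarray(trains[i]) for i in range(n)], duration,
                   meta.get("population", ""))

    def save_npz(self, path) -> None:
        lengths = np.array([len(t) for t in self.trains])
        flat = np.concatenate(self.trains) if self.trains else np.empty(0)
        np.savez(path, lengths=lengths, times=flat,
                 duration_ms=np.asarray(self.duration_ms),
                 population=np.asarray(self.population))

    @classmethod
    def load_npz(cls, path) -> "SpikeRaster":
        with np.load(path) as data:
            lengths = data["lengths"]
            flat = data["times"]
            duration = float(data["duration_ms"])
            population = str(data["population"])
        trains = np.split(flat, np.cumsum(lengths)[:-1]) if len(lengths) else []
        return cls(list(trains), duration, population)


@dataclass
class BinnedSpikeMatrix:
    """Binary spike matrix x[neuron, bin] with per-train mean and std.

    Bins are half-open [b*dt, (b+1)*dt); a bin is 1 if at least one
    spike fell in it (counts clipped to 1).  mu/sigma are population
    statistics over all N bins of each train.
    """

    x: np.ndarray
    bin_ms: float
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.x.shape[1]


def bin_spikes(raster: SpikeRaster, bin_ms: float = 1.0) -> BinnedSpikeMatrix:
    """Binarize a raster at the given bin width (default 1 ms)."""
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(np.ceil(raster.duration_ms / bin_ms))
    x = np.zeros((raster.n_neurons, n_bins), dtype=np.uint8)
    for i, train in enumerate(raster.trains):
        if len(train):
            idx = np.floor_divide(train, bin_ms).astype(np.int64)
            x[i, idx] = 1
    mu = x.mean(axis=1) if n_bins else np.zeros(raster.n_neurons)
    sigma = x.std(axis=1) if n_bins else np.zeros(raster.n_neurons)
    return BinnedSpikeMatrix(x=x, bin_ms=float(bin_ms), mu=mu, sigma=sigma)
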