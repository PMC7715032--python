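"""Synthetic rasters and toy networks with known ground truth.

Cluster fixtures emulate spatially and temporally dense regions of
co-activation ("clusters") on top of independent renewal background:
at each planted event, neurons near the cluster center receive an extra
spike with Gaussian spatial participation and Gaussian temporal jitter.
They exercise the full correlation pipeline without any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .connectivity import (Connectome, PathwayEdges, compute_delay,
                           CONDUCTION_VELOCITY)
from .geometry import PopulationConfig, PopulationLayout, SheetExtent, build_layout
from .sources import RenewalParams, SpikeRaster, generate_renewal_train

__all__ = ["ClusterFixtureSpec", "make_cluster_raster", "make_toy_network"]


@dataclass(frozen=True)
class ClusterFixtureSpec:
    """Planted-cluster raster specification.

    Cluster centers default to uniform random positions on the sheet.
    ``events_hz`` is the rate of planted events per cluster.
    """

    n_clusters: int = 1
    centers: Optional[Tuple[Tuple[float, float], ...]] = None
    spatial_sd_mm: float = 0.5
    jitter_sd_ms: float = 2.0
    participation: float = 0.3
    background_rate_hz: float = 0.5
    events_hz: float = 2.0
    duration_ms: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if self.spatial_sd_mm <= 0 or self.jitter_sd_ms < 0:
            raise ValueError("spatial sd must be > 0 and jitter >= 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must lie in [0, 1]")
        if self.background_rate_hz < 0 or self.events_hz < 0:
            raise ValueError("rates must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


def make_cluster_raster(spec: ClusterFixtureSpec, positions: np.ndarray,
                        extent: SheetExtent = SheetExtent(10.0, 2.0),
                        refractory_tau_ms: float = 35.0,
                        ) -> Tuple[SpikeRaster, pd.DataFrame]:
    """Background renewal spikes plus planted cluster events.

    For every event of cluster k (Poisson in time at ``events_hz``),
    each neuron participates with probability
    ``participation * exp(-d^2 / (2 sd^2))`` where d is its sheet
    distance to the cluster center, spiking at the event time plus
    Gaussian jitter.  Returns the raster and the ground-truth event
    table (cluster, time, center coordinates).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(positions)
    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float)
        if len(centers) != spec.n_clusters:
            raise ValueError("centers must match n_clusters")
    else:
        centers = np.column_stack([
            rng.uniform(0, extent.longitudinal, spec.n_clusters),
            rng.uniform(0, extent.transverse, spec.n_clusters)])

    trains: List[List[float]] = [[] for _ in range(n)]
    if spec.background_rate_hz > 0:
        params = RenewalParams(spec.background_rate_hz, refractory_tau_ms).calibrated()
        for i in range(n):
            t = generate_renewal_train(params, spec.duration_ms,
                                       np.random.default_rng((spec.seed, 7, i)))
            trains[i].extend(t.tolist())

    records = []
    for k in range(spec.n_clusters):
        n_events = rng.poisson(spec.events_hz * spec.duration_ms / 1000.0)
        times = np.sort(rng.uniform(0, spec.duration_ms, n_events))
        d2 = ((positions - centers[k]) ** 2).sum(axis=1)
        p = spec.participation * np.exp(-d2 / (2 * spec.spatial_sd_mm ** 2))
        for t0 in times:
            part = rng.random(n) < p
            idx = np.nonzero(part)[0]
            jit = rng.normal(0.0, spec.jitter_sd_ms, len(idx)) if spec.jitter_sd_ms > 0 \
                else np.zeros(len(idx))
            for i, dt in zip(idx, jit):
                t = t0 + dt
                if 0 <= t < spec.duration_ms:
                    trains[i].append(t)
            records.append({"cluster": k, "time_ms": t0,
                            "center_long_mm": centers[k, 0],
                            "center_trans_mm": centers[k, 1],
                            "n_participants": len(idx)})
    raster = SpikeRaster([np.unique(np.asarray(t)) for t in trains],
                         spec.duration_ms, population="fixture")
    events = pd.DataFrame.from_records(
        records, columns=["cluster", "time_ms", "center_long_mm",
                          "center_trans_mm", "n_participants"])
    return raster, events


def make_toy_network(n_pre: int, n_post: int, pathway: str = "MF",
                     wiring: str = "single_edge", seed: int = 0,
                     ) -> Tuple[PopulationLayout, Connectome]:
    """Minimal layouts + connectomes for engine and calibration tests.

    wiring rules: 'single_edge' pairs pre i with post i; 'fan' connects
    every pre to every post; 'chain' connects pre i -> post i and post
    i -> post i+1 is not modelled (feedforward only).  Delays use the
    straight-line sheet distance at the pathway's conduction velocity
    (for MF this doubles as the arc length of a straight fiber).
    """
    if n_pre < 0 or n_post < 0:
        raise ValueError("sizes must be >= 0")
    pre_pop = {"LPP": "EC", "MPP": "EC", "MF": "DG", "ASSOC": "CA3"}[pathway]
    comp = {"LPP": 0, "MPP": 1, "MF": 4, "ASSOC": 3}[pathway]
    sizes = {"EC": 0, "DG": 0, "CA3": n_post}
    sizes[pre_pop] = n_pre if pre_pop != "CA3" else n_post
    layout = build_layout(PopulationConfig(sizes=sizes), seed=seed)

    pre_pos = layout.positions(pre_pop)
    post_pos = layout.positions("CA3")
    pre_l, post_l = [], []
    if wiring == "single_edge":
        for i in range(min(n_pre, n_post)):
            pre_l.append(i)
            post_l.append(i)
    elif wiring == "fan":
        for i in range(n_pre):
            for j in range(n_post):
                pre_l.append(i)
                post_l.append(j)
    else:
        raise ValueError(f"unknown wiring rule {wiring!r}")
    pre = np.asarray(pre_l, dtype=np.int32)
    post = np.asarray(post_l, dtype=np.int32)
    if len(pre):
        dist = np.hypot(pre_pos[pre, 0] - post_pos[post, 0],
                        pre_pos[pre, 1] - post_pos[post, 1])
        delay = np.array([compute_delay(d, pathway) for d in dist],
                         dtype=np.float32)
    else:
        delay = np.empty(0, dtype=np.float32)
    edges = {pathway: PathwayEdges(
        pre_pop, pre, post, np.full(len(pre), comp, dtype=np.int8), delay,
        np.ones(len(pre), dtype=np.float32))}
    return layout, Connectome(edges, seed, "toy")
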