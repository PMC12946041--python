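"""Mass-univariate paired testing and spatiotemporal cluster-based permutation
inference for sensor x time ERP data.

The statistic is the cluster mass: the sum of pointwise paired t values over
a spatiotemporally connected set of same-sign suprathreshold
(electrode, sample) points.  Connectivity combines the sensor neighbor graph
(same sample) with temporal adjacency (same sensor, adjacent samples);
diagonal neighbor-channel-and-adjacent-time links are not connected.
Family-wise error is controlled with the max-|mass| permutation null: each
permutation flips the sign of whole subject difference maps (condition
labels exchanged within participants), the largest absolute cluster mass is
recorded, and an observed cluster's corrected p is
(1 + #{null >= |mass|}) / (n_perm + 1).

``exhaustive_null`` enumerates all 2^n sign assignments and serves as the
exact oracle for the Monte Carlo engine on small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .epoching import SubjectERP, average_conditions
from .montage import NeighborGraph
from .synthetic_data import EpochSet

__all__ = [
    "TMap",
    "ClusterResult",
    "ClusterGeometry",
    "pointwise_paired_t",
    "form_clusters",
    "permutation_test",
    "permutation_test_trial_level",
    "exhaustive_null",
]

EXHAUSTIVE_MAX_N = 16


@dataclass(frozen=True)
class TMap:
    """Pointwise paired t statistics on the channel x sample grid."""

    t: np.ndarray  # (C, S)
    df: int
    channels: tuple[str, ...]
    times_ms: np.ndarray

    def critical_value(self, alpha_forming: float = 0.05) -> float:
        return float(t_dist.ppf(1.0 - alpha_forming / 2.0, self.df))


@dataclass
class ClusterResult:
    """One signed spatiotemporal cluster and (after permutation) its corrected p."""

    chan_idx: np.ndarray
    samp_idx: np.ndarray
    sign: int
    mass: float
    time_window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    max_spatial_extent: tuple[float, float]  # (time_ms, n_electrodes)
    p_corrected: float | None = None

    @property
    def size(self) -> int:
        return len(self.chan_idx)

    def to_dict(self, include_members: bool = False) -> dict:
        out = {
            "sign": self.sign,
            "mass": self.mass,
            "p": self.p_corrected,
            "window_ms": list(self.time_window_ms),
            "electrodes": list(self.electrodes),
            "max_extent": {
                "time_ms": self.max_spatial_extent[0],
                "n_electrodes": int(self.max_spatial_extent[1]),
            },
            "n_samples": self.size,
        }
        if include_members:
            out["members"] = [
                [int(c), int(s)] for c, s in zip(self.chan_idx, self.samp_idx)
            ]
        return out


class ClusterGeometry:
    """Sparse spatiotemporal adjacency over the flattened (channel, sample) grid."""

    def __init__(self, channels: tuple[str, ...], n_samples: int, graph: NeighborGraph):
        self.channels = tuple(channels)
        self.n_channels = len(channels)
        self.n_samples = int(n_samples)
        index = {l: i for i, l in enumerate(self.channels)}
        rows, cols = [], []
        s = np.arange(self.n_samples)
        for a, nbrs in graph.adjacency.items():
            if a not in index:
                continue
            ia = index[a]
            for b in nbrs:
                if b not in index:
                    continue
                ib = index[b]
                rows.append(ia * self.n_samples + s)
                cols.append(ib * self.n_samples + s)
        for c in range(self.n_channels):
            base = c * self.n_samples
            rows.append(base + s[:-1])
            cols.append(base + s[1:])
            rows.append(base + s[1:])
            cols.append(base + s[:-1])
        n = self.n_channels * self.n_samples
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            data = np.ones(r.size, dtype=np.int8)
            self.adjacency = sparse.csr_matrix((data, (r, c)), shape=(n, n))
        else:
            self.adjacency = sparse.csr_matrix((n, n), dtype=np.int8)

    def components(self, flat_mask: np.ndarray) -> list[np.ndarray]:
        """Connected components among masked nodes; each as flat-index array."""
        idx = np.flatnonzero(flat_mask)
        if idx.size == 0:
            return []
        sub = self.adjacency[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        return [idx[labels == k] for k in range(n_comp)]

    def max_abs_mass(self, t_flat: np.ndarray, threshold: float) -> float:
        """Largest |cluster mass| across both signs for one statistic map."""
        best = 0.0
        for mask in (t_flat > threshold, t_flat < -threshold):
            for comp in self.components(mask):
                best = max(best, abs(float(t_flat[comp].sum())))
        return best


def _paired_t(diffs2d: np.ndarray) -> np.ndarray:
    """One-sample t of per-subject differences against 0; zero variance -> 0."""
    n = diffs2d.shape[0]
    mean = diffs2d.mean(axis=0)
    sd = diffs2d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    np.divide(mean * np.sqrt(n), sd, out=t, where=sd > 0)
    return t


def pointwise_paired_t(erps: SubjectERP) -> TMap:
    """Paired t map of the per-subject S - A differences at every point."""
    diffs = erps.difference()
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("paired t needs >= 2 participants")
    flat = diffs.reshape(n, -1)
    sd = flat.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} point(s) with zero variance; t set to 0",
            stacklevel=2,
        )
    t = _paired_t(flat).reshape(diffs.shape[1:])
    return TMap(t=t, df=n - 1, channels=erps.channels, times_ms=erps.times_ms.copy())


def form_clusters(
    tmap: TMap,
    graph: NeighborGraph,
    alpha_forming: float = 0.05,
    geometry: ClusterGeometry | None = None,
) -> list[ClusterResult]:
    """Partition suprathreshold points into signed connected clusters.

    Clusters are sorted by |mass| descending; p values are unset until a
    permutation test fills them in.
    """
    n_chan, n_samp = tmap.t.shape
    if geometry is None:
        geometry = ClusterGeometry(tmap.channels, n_samp, graph)
    threshold = tmap.critical_value(alpha_forming)
    t_flat = tmap.t.ravel()
    clusters: list[ClusterResult] = []
    for sign, mask in ((1, t_flat > threshold), (-1, t_flat < -threshold)):
        for comp in geometry.components(mask):
            chan_idx, samp_idx = np.divmod(comp, n_samp)
            times = tmap.times_ms[samp_idx]
            extent_samples, extent_counts = np.unique(samp_idx, return_counts=True)
            k = int(np.argmax(extent_counts))  # earliest time on ties (sorted)
            clusters.append(
                ClusterResult(
                    chan_idx=chan_idx,
                    samp_idx=samp_idx,
                    sign=sign,
                    mass=float(t_flat[comp].sum()),
                    time_window_ms=(float(times.min()), float(times.max())),
                    electrodes=tuple(
                        sorted({tmap.channels[c] for c in chan_idx})
                    ),
                    max_spatial_extent=(
                        float(tmap.times_ms[extent_samples[k]]),
                        float(extent_counts[k]),
                    ),
                )
            )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return clusters


def _as_diffs(subject_diffs) -> tuple[np.ndarray, tuple[str, ...], np.ndarray]:
    if isinstance(subject_diffs, SubjectERP):
        return (
            subject_diffs.difference(),
            subject_diffs.channels,
            subject_diffs.times_ms,
        )
    raise TypeError(
        "pass a SubjectERP, or use permutation_test(..., channels=..., times_ms=...) "
        "with a raw (participants, channels, samples) array"
    )


def permutation_test(
    subject_diffs,
    graph: NeighborGraph,
    n_perm: int = 5000,
    alpha: float = 0.05,
    alpha_forming: float = 0.05,
    seed: int | None = None,
    channels: tuple[str, ...] | None = None,
    times_ms: np.ndarray | None = None,
    chunk: int = 200,
) -> list[ClusterResult]:
    """Cluster-based permutation test on per-subject S - A difference maps.

    Each of ``n_perm`` permutations multiplies every subject's difference map
    by an independent random sign (the within-subject label exchange for a
    paired design) and records the maximal absolute cluster mass.  Observed
    clusters receive p = (1 + #{null >= |mass|}) / (n_perm + 1), two-sided by
    construction of the max-|mass| null; significance is p <= alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if channels is None or times_ms is None:
        diffs, channels, times_ms = _as_diffs(subject_diffs)
    else:
        diffs = np.asarray(subject_diffs, dtype=float)
    n, n_chan, n_samp = diffs.shape
    tmap = TMap(
        t=_paired_t(diffs.reshape(n, -1)).reshape(n_chan, n_samp),
        df=n - 1,
        channels=tuple(channels),
        times_ms=np.asarray(times_ms, dtype=float),
    )
    geometry = ClusterGeometry(tmap.channels, n_samp, graph)
    clusters = form_clusters(tmap, graph, alpha_forming, geometry=geometry)
    threshold = tmap.critical_value(alpha_forming)

    flat = diffs.reshape(n, -1)
    ss = (flat**2).sum(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        signs = rng.choice((-1.0, 1.0), size=(b, n))
        mean = signs @ flat / n
        var = (ss - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = np.where(var > 0, mean * np.sqrt(n) / np.sqrt(var), 0.0)
        for j in range(b):
            null[done + j] = geometry.max_abs_mass(t_perm[j], threshold)
        done += b
    for cl in clusters:
        cl.p_corrected = float(
            (1 + np.count_nonzero(null >= abs(cl.mass))) / (n_perm + 1)
        )
    return clusters


def exhaustive_null(
    subject_diffs,
    graph: NeighborGraph,
    alpha_forming: float = 0.05,
    channels: tuple[str, ...] | None = None,
    times_ms: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Exact cluster p values by enumerating all 2^n sign assignments.

    The observed (all +1) assignment is part of the enumeration, so
    p = #{assignments with max |mass| >= |observed mass|} / 2^n is never 0.
    Refuses cohorts larger than 16 subjects.
    """
    if channels is None or times_ms is None:
        diffs, channels, times_ms = _as_diffs(subject_diffs)
    else:
        diffs = np.asarray(subject_diffs, dtype=float)
    n, n_chan, n_samp = diffs.shape
    if n > EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive enumeration limited to n <= {EXHAUSTIVE_MAX_N}")
    tmap = TMap(
        t=_paired_t(diffs.reshape(n, -1)).reshape(n_chan, n_samp),
        df=n - 1,
        channels=tuple(channels),
        times_ms=np.asarray(times_ms, dtype=float),
    )
    geometry = ClusterGeometry(tmap.channels, n_samp, graph)
    clusters = form_clusters(tmap, graph, alpha_forming, geometry=geometry)
    threshold = tmap.critical_value(alpha_forming)

    flat = diffs.reshape(n, -1)
    ss = (flat**2).sum(axis=0)
    total = 2**n
    null = np.empty(total)
    codes = np.arange(total)
    signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n)[None, :]) & 1)
    for start in range(0, total, 512):
        block = signs[start : start + 512]
        mean = block @ flat / n
        var = np.maximum((ss - n * mean**2) / (n - 1), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = np.where(var > 0, mean * np.sqrt(n) / np.sqrt(var), 0.0)
        for j in range(block.shape[0]):
            null[start + j] = geometry.max_abs_mass(t_perm[j], threshold)
    for cl in clusters:
        cl.p_corrected = float(np.count_nonzero(null >= abs(cl.mass)) / total)
    return clusters


def permutation_test_trial_level(
    epochs: EpochSet,
    graph: NeighborGraph,
    n_perm: int = 1000,
    alpha: float = 0.05,
    alpha_forming: float = 0.05,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Trial-level label-shuffle variant of the permutation test.

    Condition labels are re-drawn without replacement among each
    participant's retained trials before re-averaging; otherwise identical
    to :func:`permutation_test`.  Considerably slower; not the default
    exchange scheme.
    """
    erps = average_conditions(epochs)
    geometry = ClusterGeometry(erps.channels, erps.times_ms.size, graph)
    tmap = pointwise_paired_t(erps)
    clusters = form_clusters(tmap, graph, alpha_forming, geometry=geometry)
    threshold = tmap.critical_value(alpha_forming)

    rng = np.random.default_rng(seed)
    kept = [i for i, p in enumerate(epochs.participants) if p in erps.participants]
    null = np.empty(n_perm)
    for b in range(n_perm):
        diffs = []
        for i in kept:
            sel = np.flatnonzero(epochs.retained[i])
            labels = epochs.conditions[i, sel]
            perm = rng.permutation(labels)
            d = epochs.data[i, sel].astype(np.float64)
            diffs.append(d[perm == "S"].mean(axis=0) - d[perm == "A"].mean(axis=0))
        t_perm = _paired_t(np.stack(diffs).reshape(len(diffs), -1))
        null[b] = geometry.max_abs_mass(t_perm, threshold)
    for cl in clusters:
        cl.p_corrected = float(
            (1 + np.count_nonzero(null >= abs(cl.mass))) / (n_perm + 1)
        )
    return clusters
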