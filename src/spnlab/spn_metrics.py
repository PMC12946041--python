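"""SPN quantification and derived statistics.

The sustained posterior negativity (SPN) is the symmetric-minus-asymmetric
(S - A) ERP difference averaged over a posterior region of interest and a
time window.  Two ROI definitions are supported: the canonical
literature-based posterior set (O1, O2, Oz, PO3, PO4, PO7, PO8; 250-600 ms)
and a cluster-derived ROI taken from the significant cluster of the
permutation test (union of its electrodes, its time window).

Per participant the quantification order is: window mean per electrode per
condition -> electrode-wise S - A difference -> mean across ROI electrodes.
All steps are linear, so the order is a reporting convention rather than a
numerical one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, pearsonr

from .cluster_perm import ClusterResult
from .epoching import SubjectERP

__all__ = [
    "ROISpec",
    "SPNEstimate",
    "CANONICAL_ROI_SPEC",
    "cluster_roi",
    "spn_amplitude",
    "peak_latency",
    "split_hemispheres",
    "lateralization_spn",
    "lateralization_condition",
    "dz_from_t",
    "correlate_spn_behavior",
]


@dataclass(frozen=True)
class ROISpec:
    """Electrode set + time window over which SPN amplitudes are averaged."""

    electrodes: tuple[str, ...]
    window_ms: tuple[float, float]
    origin: str = "canonical"  # or "cluster-derived"

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ValueError("ROI must contain at least one electrode")
        if not self.window_ms[0] < self.window_ms[1]:
            raise ValueError("ROI window must have start < end")


CANONICAL_ROI_SPEC = ROISpec(
    electrodes=("O1", "O2", "Oz", "PO3", "PO4", "PO7", "PO8"),
    window_ms=(250.0, 600.0),
    origin="canonical",
)


@dataclass(frozen=True)
class SPNEstimate:
    """Per-participant SPN amplitudes (uV, S - A) for one ROI."""

    amplitudes: np.ndarray  # (P,)
    participants: tuple[int, ...]
    roi: ROISpec

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def mean(self) -> float:
        return float(self.amplitudes.mean())


def cluster_roi(cluster: ClusterResult) -> ROISpec:
    """ROI spanned by a significant cluster: union of electrodes, its window."""
    return ROISpec(
        electrodes=cluster.electrodes,
        window_ms=cluster.time_window_ms,
        origin="cluster-derived",
    )


def _roi_indices(erps: SubjectERP, roi: ROISpec) -> list[int]:
    missing = [e for e in roi.electrodes if e not in erps.channels]
    if missing:
        raise ValueError(f"ROI electrode(s) absent from data: {missing}")
    return [erps.channels.index(e) for e in roi.electrodes]


def spn_amplitude(erps: SubjectERP, roi: ROISpec) -> SPNEstimate:
    """Per-participant SPN: ROI/window mean of the S - A difference (uV)."""
    idx = _roi_indices(erps, roi)
    mask = erps.window_mask(roi.window_ms)
    i_s = erps.condition_order.index("S")
    i_a = erps.condition_order.index("A")
    # window mean per electrode per condition, then electrode-wise difference
    win_mean = erps.erp[:, :, idx][..., mask].mean(axis=-1)  # (P, 2, E)
    per_electrode_diff = win_mean[:, i_s] - win_mean[:, i_a]  # (P, E)
    return SPNEstimate(
        amplitudes=per_electrode_diff.mean(axis=1),
        participants=erps.participants,
        roi=roi,
    )


def peak_latency(
    erps: SubjectERP, roi: ROISpec
) -> tuple[float, float]:
    """Time and amplitude of maximal negativity of the group ROI difference.

    The S - A difference is averaged over participants and ROI electrodes;
    the minimizing sample within the window is returned (earliest on ties).
    """
    idx = _roi_indices(erps, roi)
    mask = erps.window_mask(roi.window_ms)
    trace = erps.difference()[:, idx].mean(axis=(0, 1))  # (S,)
    times = erps.times_ms[mask]
    windowed = trace[mask]
    k = int(np.argmin(windowed))  # argmin returns first minimum: earliest tie
    return float(times[k]), float(windowed[k])


def split_hemispheres(electrodes) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Left/right electrode subsets by 10-20 numeric suffix (odd/even; z excluded)."""
    left, right = [], []
    for e in electrodes:
        digits = "".join(ch for ch in e if ch.isdigit())
        if not digits:
            continue  # midline (z suffix)
        (left if int(digits) % 2 else right).append(e)
    return tuple(left), tuple(right)


def _li(right: np.ndarray, left: np.ndarray) -> np.ndarray:
    """(R - L) / (|L| + |R|); nan where the denominator is 0."""
    denom = np.abs(left) + np.abs(right)
    out = np.full_like(denom, np.nan, dtype=float)
    np.divide(right - left, denom, out=out, where=denom > 0)
    return out


def lateralization_spn(spn_left: SPNEstimate, spn_right: SPNEstimate) -> np.ndarray:
    """SPN-based lateralization index per participant, in [-1, 1] when defined."""
    if spn_left.participants != spn_right.participants:
        raise ValueError("hemispheric SPN estimates cover different participants")
    if spn_left.roi.window_ms != spn_right.roi.window_ms:
        raise ValueError("hemispheric SPNs must share the same window")
    return _li(spn_right.amplitudes, spn_left.amplitudes)


def lateralization_condition(
    erps: SubjectERP,
    left_set,
    right_set,
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Condition-based lateralization index, shape (P, 2) ordered like the ERPs.

    Per condition: ROI/window mean on each hemisphere, then
    (R - L) / (|L| + |R|).
    """
    li = np.empty((erps.n_participants, 2))
    mask = erps.window_mask(window_ms)
    idx_l = _roi_indices(erps, ROISpec(tuple(left_set), window_ms))
    idx_r = _roi_indices(erps, ROISpec(tuple(right_set), window_ms))
    mean_l = erps.erp[:, :, idx_l][..., mask].mean(axis=(-2, -1))  # (P, 2)
    mean_r = erps.erp[:, :, idx_r][..., mask].mean(axis=(-2, -1))
    li[:] = _li(mean_r, mean_l)
    return li


def dz_from_t(t_value: float, n: int) -> float:
    """Within-subject standardized effect size d_z = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t_value / np.sqrt(n))


def correlate_spn_behavior(
    spn: SPNEstimate | np.ndarray, metric: np.ndarray, conf: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Pearson r between SPN amplitude and a per-participant scalar.

    Returns (r, Fisher-z confidence interval, two-sided p).  The CI uses the
    atanh transform with standard error 1/sqrt(n - 3).
    """
    x = spn.amplitudes if isinstance(spn, SPNEstimate) else np.asarray(spn, float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 participants")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors; r undefined")
    r, p = pearsonr(x, y)
    zcrit = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return float(r), ci, float(p)
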