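"""Epoch conditioning: baseline correction, common-average reference,
automated quality screening, correct-trial filtering, condition averaging.

The screening stage reproduces a fully automated epoch-quality pass on
scalp channels: an epoch is removed when any channel (a) exceeds +-120 uV
within -200..600 ms, (b) shows a linear trend whose fitted change across
the epoch exceeds 75 uV with R^2 > 0.50, or (c) has excess kurtosis more
than 7 SD from the participant's epoch distribution, at either the
single-channel ("local") or channel-mean ("global") level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kurtosis as _excess_kurtosis

from .synthetic_data import EpochSet

__all__ = [
    "ScreenReport",
    "SubjectERP",
    "AlignmentError",
    "baseline_correct",
    "rereference_average",
    "screen_epochs",
    "filter_correct",
    "average_conditions",
]

CONDITION_ORDER = ("S", "A")


class AlignmentError(ValueError):
    """Raised when a behavior table does not align with the epochs."""


@dataclass
class ScreenReport:
    """Per-epoch screening flags and the removal bookkeeping.

    ``flags`` has one row per epoch that entered the screen, with boolean
    columns amplitude / trend / kurtosis_local / kurtosis_global and the
    final ``removed`` decision (any flag set).
    """

    flags: pd.DataFrame
    thresholds: dict

    @property
    def n_input(self) -> int:
        return len(self.flags)

    @property
    def n_removed(self) -> int:
        return int(self.flags["removed"].sum())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def removed_per_participant(self) -> pd.Series:
        return self.flags.groupby("participant")["removed"].sum()

    def retained_per_condition(self) -> pd.DataFrame:
        kept = self.flags[~self.flags["removed"]]
        return kept.groupby(["participant", "condition"]).size().unstack(fill_value=0)

    def to_tsv(self, path) -> None:
        self.flags.to_csv(path, sep="\t", index=False)


@dataclass
class SubjectERP:
    """Per participant x condition mean waveforms (uV) with trial counts."""

    erp: np.ndarray  # (P, 2, C, S); axis 1 ordered like condition_order
    counts: np.ndarray  # (P, 2) contributing trials
    condition_order: tuple[str, str]
    participants: tuple[int, ...]
    channels: tuple[str, ...]
    times_ms: np.ndarray
    fs_hz: float

    @property
    def n_participants(self) -> int:
        return self.erp.shape[0]

    def difference(self) -> np.ndarray:
        """Per-subject S - A difference waves, shape (P, C, S)."""
        i_s = self.condition_order.index("S")
        i_a = self.condition_order.index("A")
        return self.erp[:, i_s] - self.erp[:, i_a]

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        eps = 1e-6
        mask = (self.times_ms >= lo - eps) & (self.times_ms <= hi + eps)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each epoch's per-channel mean over ``window_ms`` (idempotent)."""
    mask = epochs.window_mask(window_ms)
    out = epochs.copy()
    base = out.data[..., mask].mean(axis=-1, keepdims=True)
    out.data = (out.data - base).astype(out.data.dtype)
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-express every sample relative to the mean across scalp channels."""
    if epochs.shape[2] < 2:
        raise ValueError("common-average reference needs >= 2 channels")
    out = epochs.copy()
    mean = out.data.mean(axis=2, keepdims=True)
    out.data = (out.data - mean).astype(out.data.dtype)
    return out


def _linear_trend(data: np.ndarray, times_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted change (uV over the epoch) and R^2 of the per-channel OLS line.

    ``data`` is (..., S); closed-form simple regression on the time axis.
    """
    t = times_ms - times_ms.mean()
    sxx = (t**2).sum()
    mean = data.mean(axis=-1, keepdims=True)
    slope = ((data - mean) * t).sum(axis=-1) / sxx
    sst = ((data - mean) ** 2).sum(axis=-1)
    ssr = slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 0.0)
    change = np.abs(slope) * (times_ms[-1] - times_ms[0])
    return change, r2


def screen_epochs(
    epochs: EpochSet,
    amp_limit_uv: float = 120.0,
    amp_window_ms: tuple[float, float] = (-200.0, 600.0),
    trend_delta_uv: float = 75.0,
    trend_r2: float = 0.50,
    kurt_z: float = 7.0,
) -> tuple[EpochSet, ScreenReport]:
    """Automated epoch-quality screen; flagged epochs are dropped from ``retained``.

    Only epochs retained at entry are screened; the kurtosis z-scores are
    computed across each participant's entering epochs.
    """
    for name, v in (("amp_limit_uv", amp_limit_uv), ("trend_delta_uv", trend_delta_uv),
                    ("trend_r2", trend_r2), ("kurt_z", kurt_z)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    out = epochs.copy()
    amp_mask = out.window_mask(amp_window_ms)
    rows = []
    for i, pid in enumerate(out.participants):
        trials = np.flatnonzero(out.retained[i])
        if trials.size == 0:
            continue
        d = out.data[i, trials].astype(np.float64)  # (t, C, S)
        amp_flag = (np.abs(d[..., amp_mask]) > amp_limit_uv).any(axis=(1, 2))
        change, r2 = _linear_trend(d, out.times_ms)
        trend_flag = ((change > trend_delta_uv) & (r2 > trend_r2)).any(axis=1)
        kurt = _excess_kurtosis(d, axis=-1, fisher=True, bias=True)  # (t, C)
        mu, sd = kurt.mean(axis=0), kurt.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z_local = np.where(sd > 0, (kurt - mu) / sd, 0.0)
        local_flag = (np.abs(z_local) > kurt_z).any(axis=1)
        gk = kurt.mean(axis=1)
        gsd = gk.std()
        z_global = (gk - gk.mean()) / gsd if gsd > 0 else np.zeros_like(gk)
        global_flag = np.abs(z_global) > kurt_z
        removed = amp_flag | trend_flag | local_flag | global_flag
        out.retained[i, trials[removed]] = False
        for k, t in enumerate(trials):
            rows.append(
                (pid, int(t), out.conditions[i, t], bool(amp_flag[k]),
                 bool(trend_flag[k]), bool(local_flag[k]), bool(global_flag[k]),
                 bool(removed[k]))
            )
    flags = pd.DataFrame(
        rows,
        columns=["participant", "trial", "condition", "amplitude", "trend",
                 "kurtosis_local", "kurtosis_global", "removed"],
    )
    report = ScreenReport(
        flags=flags,
        thresholds=dict(
            amp_limit_uv=amp_limit_uv, amp_window_ms=amp_window_ms,
            trend_delta_uv=trend_delta_uv, trend_r2=trend_r2, kurt_z=kurt_z,
        ),
    )
    return out, report


def filter_correct(epochs: EpochSet, behavior: pd.DataFrame) -> EpochSet:
    """Retain only epochs whose trial is marked correct in the behavior table."""
    out = epochs.copy()
    P, T = out.retained.shape
    for i, pid in enumerate(out.participants):
        sub = behavior[behavior["participant"] == pid]
        if len(sub) != T or not np.array_equal(
            np.sort(sub["trial"].to_numpy()), np.arange(T)
        ):
            raise AlignmentError(
                f"behavior rows for participant {pid} do not align with {T} epochs"
            )
        sub = sub.sort_values("trial")
        if not np.array_equal(sub["condition"].to_numpy(), out.conditions[i]):
            raise AlignmentError(
                f"behavior condition labels disagree with epochs for participant {pid}"
            )
        out.retained[i] &= sub["correct"].to_numpy()
    if not out.retained.any():
        warnings.warn("no correct trials remain after filtering", stacklevel=2)
    return out


def average_conditions(epochs: EpochSet) -> SubjectERP:
    """Per-participant, per-condition mean waveforms over retained epochs.

    Participants lacking retained trials in either condition are excluded
    with a warning.
    """
    P, T, C, S = epochs.shape
    keep, erps, counts = [], [], []
    for i, pid in enumerate(epochs.participants):
        row_erp = np.empty((2, C, S))
        row_n = np.empty(2, dtype=int)
        ok = True
        for j, cond in enumerate(CONDITION_ORDER):
            sel = epochs.retained[i] & (epochs.conditions[i] == cond)
            row_n[j] = int(sel.sum())
            if row_n[j] == 0:
                ok = False
                break
            row_erp[j] = epochs.data[i, sel].astype(np.float64).mean(axis=0)
        if not ok:
            warnings.warn(
                f"participant {pid} has no retained '{cond}' trials; excluded",
                stacklevel=2,
            )
            continue
        keep.append(pid)
        erps.append(row_erp)
        counts.append(row_n)
    if not keep:
        raise ValueError("no participant has retained trials in both conditions")
    return SubjectERP(
        erp=np.stack(erps),
        counts=np.stack(counts),
        condition_order=CONDITION_ORDER,
        participants=tuple(keep),
        channels=epochs.channels,
        times_ms=epochs.times_ms.copy(),
        fs_hz=epochs.fs_hz,
    )
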