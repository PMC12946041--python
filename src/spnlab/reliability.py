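"""Fixed-cohort trial-subsampling reliability, exact binomial intervals, and
analytic correlation power.

The subsampling procedure asks how many epochs per condition are minimally
sufficient for reliable SPN detection in a given cohort.  For each candidate
count m and each of ``n_perm`` permutations, every participant contributes m
symmetric and m asymmetric epochs sampled without replacement; the
participant's SPN is mean(S) - mean(A) of the epoch-level ROI/window means,
and the across-participant mean is tested against zero with a one-tailed
one-sample t-test (H1: SPN < 0).  Reliability at m is the proportion of
permutations with p < 0.05, with an exact Clopper-Pearson interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, norm, t as t_dist

from .spn_metrics import ROISpec
from .synthetic_data import EpochSet

__all__ = [
    "ReliabilityCurve",
    "trial_roi_means",
    "subsample_reliability",
    "clopper_pearson",
    "correlation_power",
]

_NS_SUBSAMPLE = 7  # substream namespace for subsampling draws


@dataclass(frozen=True)
class ReliabilityCurve:
    """Reliability and SPN summaries per tested epoch count m."""

    m_values: tuple[int, ...]
    reliability: np.ndarray  # proportion of permutations with p < .05
    ci: np.ndarray  # (len(m), 2) exact 95% Clopper-Pearson
    mean_spn: np.ndarray  # mean across permutations of the group-mean SPN
    band: np.ndarray  # (len(m), 2) 2.5-97.5% permutation percentiles
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.m_values,
                "reliability": self.reliability,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
                "mean_spn": self.mean_spn,
                "band_low": self.band[:, 0],
                "band_high": self.band[:, 1],
            }
        )


def trial_roi_means(epochs: EpochSet, roi: ROISpec) -> pd.DataFrame:
    """Epoch-level ROI/window mean (uV) for every retained epoch.

    Computed once and reused across permutations: averaging epoch-level
    scalars is identical to re-averaging the epochs themselves.
    """
    missing = [e for e in roi.electrodes if e not in epochs.channels]
    if missing:
        raise ValueError(f"ROI electrode(s) absent from data: {missing}")
    idx = [epochs.channels.index(e) for e in roi.electrodes]
    mask = epochs.window_mask(roi.window_ms)
    rows = []
    for i, pid in enumerate(epochs.participants):
        sel = np.flatnonzero(epochs.retained[i])
        vals = epochs.data[i][sel][:, idx][..., mask].astype(np.float64).mean(axis=(1, 2))
        for t, v in zip(sel, vals):
            rows.append((pid, int(t), epochs.conditions[i, t], float(v)))
    return pd.DataFrame(rows, columns=["participant", "trial", "condition", "value"])


def subsample_reliability(
    trial_means: pd.DataFrame,
    m_values=(5, 10, 15, 20, 25),
    n_perm: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ReliabilityCurve:
    """Fixed-cohort balanced subsampling of epoch-level ROI means.

    Every participant must have at least max(m_values) epochs per condition;
    otherwise a cohort error names the offenders (the procedure caps m at
    the minimum balanced count rather than dropping participants).
    Deterministic under ``seed``: draws use independent substreams per
    (m, permutation, participant).
    """
    m_values = tuple(int(m) for m in m_values)
    if min(m_values) < 1:
        raise ValueError("m values must be positive")
    pids = sorted(trial_means["participant"].unique())
    per_cond: dict[int, dict[str, np.ndarray]] = {}
    offenders = []
    m_max = max(m_values)
    for pid in pids:
        sub = trial_means[trial_means["participant"] == pid]
        vals = {
            c: sub.loc[sub["condition"] == c, "value"].to_numpy()
            for c in ("S", "A")
        }
        if min(len(vals["S"]), len(vals["A"])) < m_max:
            offenders.append(int(pid))
        per_cond[pid] = vals
    if offenders:
        raise ValueError(
            f"participants below the balanced cap m={m_max}: {offenders}"
        )

    n_sub = len(pids)
    reliability = np.empty(len(m_values))
    ci = np.empty((len(m_values), 2))
    mean_spn = np.empty(len(m_values))
    band = np.empty((len(m_values), 2))
    for mi, m in enumerate(m_values):
        group_means = np.empty(n_perm)
        pvals = np.empty(n_perm)
        spn = np.empty(n_sub)
        for b in range(n_perm):
            for k, pid in enumerate(pids):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(_NS_SUBSAMPLE, mi, b, k))
                )
                v = per_cond[pid]
                s = rng.choice(v["S"], size=m, replace=False)
                a = rng.choice(v["A"], size=m, replace=False)
                spn[k] = s.mean() - a.mean()
            group_means[b] = spn.mean()
            sd = spn.std(ddof=1)
            if sd == 0:
                pvals[b] = 0.5 if spn.mean() == 0 else (0.0 if spn.mean() < 0 else 1.0)
            else:
                t = spn.mean() / (sd / np.sqrt(n_sub))
                pvals[b] = t_dist.cdf(t, n_sub - 1)  # H1: SPN < 0
        k_sig = int(np.count_nonzero(pvals < alpha))
        reliability[mi] = k_sig / n_perm
        ci[mi] = clopper_pearson(k_sig, n_perm)
        mean_spn[mi] = group_means.mean()
        band[mi] = np.percentile(group_means, [2.5, 97.5])
    return ReliabilityCurve(
        m_values=m_values,
        reliability=reliability,
        ci=ci,
        mean_spn=mean_spn,
        band=band,
        n_perm=n_perm,
    )


def clopper_pearson(
    successes: int, n: int, conf: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    a = 1.0 - conf
    lower = 0.0 if successes == 0 else float(beta.ppf(a / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - a / 2, successes + 1, n - successes))
    return (lower, upper)


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power to detect a correlation, by the Fisher-z approximation.

    power = Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2}) with
    lambda = atanh(rho) * sqrt(n - 3).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    lam = np.arctanh(rho) * np.sqrt(n - 3)
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(lam - zcrit) + norm.cdf(-lam - zcrit))
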