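"""Behavioral statistics: chance-level gate, equal-variance SDT metrics,
one-sample tests, and logit-scale summary arithmetic.

Conventions follow the equal-variance Gaussian signal-detection model with
"symmetric" as the signal class: d' = z(H) - z(FA) and
c = -(z(H) + z(FA)) / 2, where H is the probability of responding
"symmetric" on symmetric trials and FA on asymmetric trials.  Negative c is
a liberal bias toward reporting "symmetric".  Rates are clamped to
[1/(2N), 1 - 1/(2N)] per class before the inverse-normal transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, norm, t as t_dist

__all__ = [
    "SDTSummary",
    "chance_criterion",
    "sdt_metrics",
    "sdt_from_table",
    "expected_accuracy",
    "one_sample_t",
    "logit_summary",
]


@dataclass(frozen=True)
class SDTSummary:
    """Clamped hit/false-alarm rates and the derived d' and criterion."""

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_signal: int
    n_noise: int


def chance_criterion(
    n_trials: int, alpha: float = 0.05, convention: str = "quantile"
) -> tuple[int, float]:
    """Minimum correct count to clear chance by a one-tailed binomial test.

    ``convention="quantile"`` (default) returns the (1 - alpha) quantile of
    Binomial(n, 1/2): the smallest k with P(X <= k) >= 1 - alpha.
    ``convention="tail"`` returns the smallest k with P(X >= k) < alpha
    (the strict rejection threshold), which can differ by one.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if convention == "quantile":
        k = int(binom.ppf(1.0 - alpha, n_trials, 0.5))
    elif convention == "tail":
        # P(X >= k) = sf(k - 1); find smallest k with sf(k - 1) < alpha
        ks = np.arange(n_trials + 2)
        tail = binom.sf(ks - 1, n_trials, 0.5)
        k = int(ks[np.argmax(tail < alpha)])
    else:
        raise ValueError("convention must be 'quantile' or 'tail'")
    return k, k / n_trials


def sdt_metrics(hits: int, misses: int, fas: int, crs: int) -> SDTSummary:
    """Equal-variance d' and criterion from a 2x2 response table."""
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal < 1 or n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    h = np.clip(hits / n_signal, 1 / (2 * n_signal), 1 - 1 / (2 * n_signal))
    fa = np.clip(fas / n_noise, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise))
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return SDTSummary(
        hit_rate=float(h),
        fa_rate=float(fa),
        dprime=float(zh - zfa),
        criterion=float(-(zh + zfa) / 2.0),
        n_signal=int(n_signal),
        n_noise=int(n_noise),
    )


def sdt_from_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SDT metrics from a trial-level behavior table.

    "Symmetric" is the signal class: a hit is responding "S" on an "S"
    trial, a false alarm responding "S" on an "A" trial.
    """
    rows = []
    for pid, sub in behavior.groupby("participant"):
        sig = sub[sub["condition"] == "S"]
        noi = sub[sub["condition"] == "A"]
        s = sdt_metrics(
            hits=int((sig["response"] == "S").sum()),
            misses=int((sig["response"] != "S").sum()),
            fas=int((noi["response"] == "S").sum()),
            crs=int((noi["response"] != "S").sum()),
        )
        rows.append(
            (pid, s.hit_rate, s.fa_rate, s.dprime, s.criterion,
             float(sub["correct"].mean()), int(sub["correct"].sum()), len(sub))
        )
    return pd.DataFrame(
        rows,
        columns=["participant", "hit_rate", "fa_rate", "dprime", "criterion",
                 "accuracy", "n_correct", "n_trials"],
    )


def expected_accuracy(dprime: float, criterion: float, p_signal: float = 0.5) -> float:
    """Closed-form accuracy under the equal-variance model at fixed (d', c)."""
    acc_signal = norm.cdf(dprime / 2.0 - criterion)
    acc_noise = norm.cdf(dprime / 2.0 + criterion)
    return float(p_signal * acc_signal + (1.0 - p_signal) * acc_noise)


def one_sample_t(
    values,
    mu: float = 0.0,
    alternative: str = "two-sided",
    conf: float = 0.95,
) -> dict:
    """One-sample t-test with matching (one- or two-sided) confidence interval.

    ``alternative``: "two-sided", "less" (H1: mean < mu) or "greater".
    One-sided CIs are half-lines: (-inf, upper] for "less", [lower, inf)
    for "greater".
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t undefined")
    mean = x.mean()
    se = sd / np.sqrt(n)
    t = (mean - mu) / se
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * t_dist.sf(abs(t), df)
        tcrit = t_dist.ppf(1.0 - (1.0 - conf) / 2.0, df)
        ci = (mean - tcrit * se, mean + tcrit * se)
    elif alternative == "less":
        p = t_dist.cdf(t, df)
        tcrit = t_dist.ppf(conf, df)
        ci = (-np.inf, mean + tcrit * se)
    elif alternative == "greater":
        p = t_dist.sf(t, df)
        tcrit = t_dist.ppf(conf, df)
        ci = (mean - tcrit * se, np.inf)
    else:
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    return {
        "t": float(t), "df": int(df), "p": float(p), "mean": float(mean),
        "se": float(se), "ci": (float(ci[0]), float(ci[1])),
    }


def logit_summary(
    intercept: float, se: float, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Inverse-logit of an intercept estimate with a Wald CI on the probability scale."""
    if se < 0:
        raise ValueError("se must be >= 0")
    z = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    inv = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    return float(inv(intercept)), (
        float(inv(intercept - z * se)),
        float(inv(intercept + z * se)),
    )
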