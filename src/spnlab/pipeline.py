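"""End-to-end pipeline: simulate (optional) -> screen -> cluster -> SPN ->
behavior -> lateralization -> reliability, with a machine-readable summary.

The summary JSON only collects numbers computed by the stage modules; it
never derives statistics of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .behavior_stats import one_sample_t, sdt_from_table
from .cluster_perm import permutation_test
from .epoching import (
    average_conditions,
    baseline_correct,
    filter_correct,
    rereference_average,
    screen_epochs,
)
from .montage import build_neighbor_graph, load_montage, packaged_montage
from .reliability import subsample_reliability, trial_roi_means
from .spn_metrics import (
    CANONICAL_ROI_SPEC,
    cluster_roi,
    correlate_spn_behavior,
    dz_from_t,
    lateralization_spn,
    peak_latency,
    spn_amplitude,
    split_hemispheres,
)
from .synthetic_data import (
    SimulationConfig,
    read_behavior,
    read_epochs,
    simulate_behavior,
    simulate_epochs,
)

log = logging.getLogger("spnlab")

DEFAULTS = {
    "neighbor_mm": 35.0,
    "baseline_ms": (-200.0, 0.0),
    "n_perm": 5000,
    "alpha": 0.05,
    "alpha_forming": 0.05,
    "reliability_m": (5, 10, 15, 20, 25),
    "reliability_perm": 1000,
}


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis described by ``config`` and return the summary.

    ``config`` keys (all optional except the data source): ``simulate`` (dict
    of :class:`SimulationConfig` overrides) or ``epochs``/``behavior`` paths;
    ``montage`` path (defaults to the packaged 64-channel fixture); stage
    parameters from :data:`DEFAULTS`; ``seed``; ``out`` for the JSON summary.
    """
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    seed = int(config.get("seed", 0))
    hashed = {k: v for k, v in config.items() if k != "out"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    log.info("pipeline start: seed=%d config_hash=%s version=%s", seed, cfg_hash, __version__)

    montage = (
        load_montage(config["montage"]) if config.get("montage") else packaged_montage()
    )
    graph = build_neighbor_graph(montage, params["neighbor_mm"])
    log.info(
        "montage: %d sensors, mean neighbors %.2f, isolated %s",
        len(montage), graph.mean_neighbor_count, list(graph.isolated),
    )

    stage = "simulate"
    try:
        if "epochs" in config:
            epochs = read_epochs(config["epochs"])
            behavior = read_behavior(config["behavior"])
            sim_cfg = None
        else:
            sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seed})
            behavior = simulate_behavior(sim_cfg)
            epochs = simulate_epochs(sim_cfg, montage, behavior)

        stage = "screen"
        epochs = baseline_correct(epochs, params["baseline_ms"])
        epochs = rereference_average(epochs)
        epochs = filter_correct(epochs, behavior)
        epochs, screen_report = screen_epochs(epochs)

        stage = "cluster"
        erps = average_conditions(epochs)
        clusters = permutation_test(
            erps, graph,
            n_perm=params["n_perm"], alpha=params["alpha"],
            alpha_forming=params["alpha_forming"], seed=seed,
        )
        significant = [c for c in clusters if c.p_corrected <= params["alpha"]]
        neg_sig = [c for c in significant if c.sign < 0]

        stage = "spn"
        spn_canon = spn_amplitude(erps, CANONICAL_ROI_SPEC)
        t_canon = one_sample_t(spn_canon.amplitudes, alternative="less")
        peak_t, peak_uv = peak_latency(erps, CANONICAL_ROI_SPEC)
        spn_summary = {
            "canonical": {
                "roi": list(CANONICAL_ROI_SPEC.electrodes),
                "window_ms": list(CANONICAL_ROI_SPEC.window_ms),
                "mean_uv": spn_canon.mean,
                "t": t_canon["t"], "p": t_canon["p"],
                "ci_upper_uv": t_canon["ci"][1],
                "dz": dz_from_t(t_canon["t"], spn_canon.n_participants),
                "peak_ms": peak_t, "peak_uv": peak_uv,
            }
        }
        lat_summary = None
        if neg_sig:
            roi = cluster_roi(neg_sig[0])
            spn_clust = spn_amplitude(erps, roi)
            t_clust = one_sample_t(spn_clust.amplitudes, alternative="less")
            spn_summary["cluster"] = {
                "roi": list(roi.electrodes),
                "window_ms": list(roi.window_ms),
                "mean_uv": spn_clust.mean,
                "t": t_clust["t"], "p": t_clust["p"],
                "dz": dz_from_t(t_clust["t"], spn_clust.n_participants),
            }
            stage = "lateralization"
            left, right = split_hemispheres(roi.electrodes)
            if left and right:
                li = lateralization_spn(
                    spn_amplitude(erps, type(roi)(left, roi.window_ms, roi.origin)),
                    spn_amplitude(erps, type(roi)(right, roi.window_ms, roi.origin)),
                )
                defined = li[~np.isnan(li)]
                t_li = one_sample_t(defined) if defined.size >= 2 and defined.std() > 0 else None
                lat_summary = {
                    "n_defined": int(defined.size),
                    "mean": float(defined.mean()) if defined.size else None,
                    "t": t_li["t"] if t_li else None,
                    "p": t_li["p"] if t_li else None,
                }

        stage = "behavior"
        sdt = sdt_from_table(behavior)
        t_dprime = one_sample_t(sdt["dprime"], alternative="two-sided")
        t_crit = one_sample_t(sdt["criterion"], alternative="two-sided")
        r_dprime, ci_r, p_r = correlate_spn_behavior(
            spn_canon, sdt.set_index("participant").loc[
                list(spn_canon.participants), "dprime"
            ].to_numpy()
        )
        behavior_summary = {
            "dprime_mean": float(sdt["dprime"].mean()),
            "dprime_sd": float(sdt["dprime"].std(ddof=1)),
            "criterion_mean": float(sdt["criterion"].mean()),
            "criterion_sd": float(sdt["criterion"].std(ddof=1)),
            "dprime_t": t_dprime["t"], "criterion_t": t_crit["t"],
            "accuracy_mean": float(sdt["accuracy"].mean()),
            "spn_dprime_r": r_dprime, "spn_dprime_ci": list(ci_r), "spn_dprime_p": p_r,
        }

        stage = "reliability"
        reliability_summary = None
        trials = trial_roi_means(epochs, CANONICAL_ROI_SPEC)
        counts = trials.groupby(["participant", "condition"]).size()
        m_max = max(params["reliability_m"])
        if counts.groupby("participant").min().min() >= m_max:
            curve = subsample_reliability(
                trials, m_values=params["reliability_m"],
                n_perm=params["reliability_perm"], seed=seed,
            )
            reliability_summary = {
                "m": list(curve.m_values),
                "reliability": curve.reliability.tolist(),
                "ci": curve.ci.tolist(),
                "mean_spn": curve.mean_spn.tolist(),
            }
        else:
            log.warning("cohort below balanced cap m=%d; reliability skipped", m_max)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    summary = _round({
        "version": __version__,
        "seed": seed,
        "config_hash": cfg_hash,
        "montage": {
            "n_sensors": len(montage),
            "mean_neighbors": graph.mean_neighbor_count,
            "isolated": list(graph.isolated),
        },
        "screening": {
            "n_input": screen_report.n_input,
            "n_removed": screen_report.n_removed,
        },
        "clusters": [c.to_dict() for c in clusters[:10]],
        "n_significant_clusters": len(significant),
        "spn": spn_summary,
        "lateralization": lat_summary,
        "behavior": behavior_summary,
        "reliability": reliability_summary,
    })
    if config.get("out"):
        Path(config["out"]).write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
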