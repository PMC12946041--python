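"""Synthetic behavior tables and epoched EEG with the structure the pipeline assumes.

The generator emulates a two-alternative symmetry-discrimination EEG study:
23 participants x 120 trials, ~50/50 symmetric/asymmetric, responses from an
equal-variance Gaussian signal-detection model (population d' ~ N(1.88, 0.65)
truncated at 0, criterion c ~ N(-0.14, 0.23)), and 64-channel epochs from
-500 to +1000 ms at 256 Hz containing

* 1/f-type background noise, independent per channel and trial,
* condition-common P1/N1-like deflections with a posterior topography, and
* on symmetric trials only, a subject-specific sustained posterior
  negativity (SPN): amplitude A_i ~ N(spn_amp_mean, spn_amp_sd), a Gaussian
  spatial profile centred on the occipito-parietal ROI, and a raised-cosine
  temporal profile spanning ``spn_window_ms``.

Amplitude convention: the injected spatiotemporal profile is normalised so
that the *average-referenced* mean of the effect over the ROI electrodes and
the SPN window equals A_i exactly.  ``spn_amp_mean`` is therefore directly
the group SPN that a correct downstream pipeline should recover.

Randomness is organised in named substreams derived from the master seed
(counter-style spawn keys), so e.g. participant 7's epochs are reproducible
regardless of how many other participants are simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.stats import norm

from .montage import ElectrodeMontage

__all__ = [
    "SimulationConfig",
    "EpochSet",
    "EpochFormatError",
    "simulate_behavior",
    "simulate_epochs",
    "write_epochs",
    "read_epochs",
    "write_behavior",
    "read_behavior",
]

CANONICAL_ROI = ("O1", "O2", "Oz", "PO3", "PO4", "PO7", "PO8")

# substream namespaces for the counter-based seeding scheme
_NS_BEHAVIOR, _NS_NOISE, _NS_AMPLITUDE, _NS_ERP = 0, 1, 2, 3


class EpochFormatError(ValueError):
    """Raised when an epoch file or container violates the documented layout."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters of the synthetic cohort.

    Defaults are the conditions of the emulated study; amplitudes in uV,
    latencies in ms.
    """

    n_participants: int = 23
    n_trials: int = 120
    p_symmetric: float = 0.5
    # equal-variance Gaussian SDT population
    dprime_mean: float = 1.88
    dprime_sd: float = 0.65
    criterion_mean: float = -0.14
    criterion_sd: float = 0.23
    # symmetry effect (SPN)
    spn_amp_mean: float = -0.45
    spn_amp_sd: float = 0.63
    spn_window_ms: tuple[float, float] = (250.0, 600.0)
    spn_peak_ms: float = 390.0
    roi_center_labels: tuple[str, ...] = CANONICAL_ROI
    spatial_sigma_mm: float = 45.0
    temporal_profile: str = "raised_cosine"  # or "boxcar"
    inject_correct_only: bool = False
    # condition-common early deflections
    p1_amp_uv: float = 2.5
    p1_latency_ms: float = 100.0
    p1_sigma_ms: float = 20.0
    n1_amp_uv: float = -3.0
    n1_latency_ms: float = 170.0
    n1_sigma_ms: float = 25.0
    # background noise
    noise_sd_uv: float = 10.0
    noise_exponent: float = 1.0
    # sampling grid
    fs_hz: float = 256.0
    epoch_span_ms: tuple[float, float] = (-500.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not 0 < self.p_symmetric < 1:
            raise ValueError("p_symmetric must lie in (0, 1)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        lo, hi = self.spn_window_ms
        span_lo, span_hi = self.epoch_span_ms
        if not (span_lo <= lo < hi <= span_hi):
            raise ValueError("spn_window_ms must be ordered and inside epoch_span_ms")
        if self.temporal_profile not in ("raised_cosine", "boxcar"):
            raise ValueError("temporal_profile must be 'raised_cosine' or 'boxcar'")
        if not lo <= self.spn_peak_ms <= hi:
            raise ValueError("spn_peak_ms must lie inside spn_window_ms")

    @property
    def times_ms(self) -> np.ndarray:
        lo, hi = self.epoch_span_ms
        n = int(round((hi - lo) * self.fs_hz / 1000.0)) + 1
        return lo + np.arange(n) * 1000.0 / self.fs_hz

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EpochSet:
    """Epoched multi-channel EEG: participants x trials x channels x samples (uV).

    ``retained`` marks epochs still in the analysis; screening and the
    correct-trial filter clear entries rather than reshaping the array, so
    the container stays rectangular.
    """

    data: np.ndarray  # (P, T, C, S) float32
    times_ms: np.ndarray  # (S,)
    fs_hz: float
    channels: tuple[str, ...]
    participants: tuple[int, ...]
    conditions: np.ndarray  # (P, T) of "S"/"A"
    correct: np.ndarray  # (P, T) bool
    retained: np.ndarray = field(default=None)  # (P, T) bool

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.data.shape[:2], dtype=bool)
        P, T, C, S = self.data.shape
        if self.times_ms.shape != (S,):
            raise EpochFormatError("times_ms length does not match data samples")
        if len(self.channels) != C:
            raise EpochFormatError("channel list does not match data channels")
        if len(self.participants) != P:
            raise EpochFormatError("participant list does not match data")
        for name, arr in (("conditions", self.conditions),
                          ("correct", self.correct),
                          ("retained", self.retained)):
            if np.asarray(arr).shape != (P, T):
                raise EpochFormatError(f"{name} shape does not match (participants, trials)")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            fs_hz=self.fs_hz,
            channels=self.channels,
            participants=self.participants,
            conditions=self.conditions.copy(),
            correct=self.correct.copy(),
            retained=self.retained.copy(),
        )

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask: samples at or inside both bounds (1e-6 ms slack)."""
        lo, hi = window_ms
        eps = 1e-6
        mask = (self.times_ms >= lo - eps) & (self.times_ms <= hi + eps)
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
        return mask


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_behavior(cfg: SimulationConfig) -> pd.DataFrame:
    """Trial-level behavior from the equal-variance Gaussian SDT model.

    Per participant, (d'_i, c_i) are drawn from the population normals
    (d' truncated at 0); on symmetric trials the probability of responding
    "symmetric" is Phi(d'_i/2 - c_i), on asymmetric trials Phi(-d'_i/2 - c_i).

    Returns a table with columns participant, trial, condition ("S"/"A"),
    response ("S"/"A"), correct (bool), dprime_true, criterion_true.
    """
    rows = []
    for pid in range(cfg.n_participants):
        rng = _substream(cfg.seed, _NS_BEHAVIOR, pid)
        dprime = rng.normal(cfg.dprime_mean, cfg.dprime_sd)
        while dprime < 0:  # truncated population
            dprime = rng.normal(cfg.dprime_mean, cfg.dprime_sd)
        crit = rng.normal(cfg.criterion_mean, cfg.criterion_sd)
        is_sym = rng.random(cfg.n_trials) < cfg.p_symmetric
        p_respond_sym = np.where(
            is_sym, norm.cdf(dprime / 2.0 - crit), norm.cdf(-dprime / 2.0 - crit)
        )
        respond_sym = rng.random(cfg.n_trials) < p_respond_sym
        for t in range(cfg.n_trials):
            cond = "S" if is_sym[t] else "A"
            resp = "S" if respond_sym[t] else "A"
            rows.append(
                (pid, t, cond, resp, cond == resp, dprime, crit)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "trial", "condition", "response", "correct",
            "dprime_true", "criterion_true",
        ],
    )


def _onef_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                fs_hz: float, sd_uv: float, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit-calibrated to sd_uv per sample."""
    if sd_uv == 0:
        return np.zeros(shape + (n_samples,), dtype=np.float64)
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    re = rng.standard_normal(shape + (n_freq,))
    im = rng.standard_normal(shape + (n_freq,))
    coeff = (re + 1j * im) / np.sqrt(2.0) * amp
    coeff[..., 0] = 0.0
    if n_samples % 2 == 0:
        coeff[..., -1] = re[..., -1] * amp[-1]
    x = np.fft.irfft(coeff, n=n_samples, axis=-1)
    # analytic per-sample variance of the synthesised process
    w = np.full(n_freq, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    var = (w * amp**2).sum() / n_samples**2
    return x * (sd_uv / np.sqrt(var))


def _gaussian_bump(times_ms: np.ndarray, latency: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - latency) / sigma) ** 2)


def spn_temporal_profile(cfg: SimulationConfig, times_ms: np.ndarray) -> np.ndarray:
    """Unit-peak temporal profile of the injected SPN (zero outside the window)."""
    lo, hi = cfg.spn_window_ms
    h = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms <= hi)
    if cfg.temporal_profile == "boxcar":
        h[inside] = 1.0
        return h
    peak = cfg.spn_peak_ms
    t = times_ms[inside]
    left = np.maximum(peak - lo, 1e-9)
    right = np.maximum(hi - peak, 1e-9)
    half = np.where(t <= peak, left, right)
    h[inside] = 0.5 * (1.0 + np.cos(np.pi * (t - peak) / half))
    return h


def spn_spatial_profile(cfg: SimulationConfig, montage: ElectrodeMontage) -> np.ndarray:
    """Average-referenced Gaussian spatial profile over sensors (unitless)."""
    missing = [l for l in cfg.roi_center_labels if l not in montage.labels]
    if missing:
        raise ValueError(f"ROI label(s) not in montage: {missing}")
    centroid = montage.subset_coords(cfg.roi_center_labels).mean(axis=0)
    d = np.linalg.norm(montage.coords - centroid, axis=1)
    g = np.exp(-0.5 * (d / cfg.spatial_sigma_mm) ** 2)
    return g - g.mean()


def simulate_epochs(
    cfg: SimulationConfig,
    montage: ElectrodeMontage,
    behavior: pd.DataFrame,
) -> EpochSet:
    """Generate the epoched EEG implied by ``cfg`` for the given behavior table."""
    times = cfg.times_ms
    n_samples = times.size
    channels = montage.labels
    n_chan = len(channels)
    pids = sorted(behavior["participant"].unique())
    n_trials = cfg.n_trials

    g_car = spn_spatial_profile(cfg, montage)  # (C,), zero channel mean
    h = spn_temporal_profile(cfg, times)  # (S,)
    roi_idx = [montage.index(l) for l in cfg.roi_center_labels]
    win = (times >= cfg.spn_window_ms[0] - 1e-6) & (times <= cfg.spn_window_ms[1] + 1e-6)
    # normalisation: ROI x window mean of the average-referenced profile is 1
    z = g_car[roi_idx].mean() * h[win].mean()
    if abs(z) < 1e-12:
        raise ValueError("degenerate SPN profile normalisation")
    effect_profile = np.outer(g_car, h) / z  # (C, S)

    # condition-common early deflections share the (un-referenced) posterior kernel
    centroid = montage.subset_coords(cfg.roi_center_labels).mean(axis=0)
    d = np.linalg.norm(montage.coords - centroid, axis=1)
    g_raw = np.exp(-0.5 * (d / cfg.spatial_sigma_mm) ** 2)
    common = np.outer(
        g_raw,
        cfg.p1_amp_uv * _gaussian_bump(times, cfg.p1_latency_ms, cfg.p1_sigma_ms)
        + cfg.n1_amp_uv * _gaussian_bump(times, cfg.n1_latency_ms, cfg.n1_sigma_ms),
    )

    data = np.empty((len(pids), n_trials, n_chan, n_samples), dtype=np.float32)
    conditions = np.empty((len(pids), n_trials), dtype="<U1")
    correct = np.zeros((len(pids), n_trials), dtype=bool)

    for i, pid in enumerate(pids):
        sub = behavior[behavior["participant"] == pid].sort_values("trial")
        if len(sub) != n_trials:
            raise ValueError(f"participant {pid}: expected {n_trials} trials, got {len(sub)}")
        conditions[i] = sub["condition"].to_numpy()
        correct[i] = sub["correct"].to_numpy()

        rng_noise = _substream(cfg.seed, _NS_NOISE, int(pid))
        noise = _onef_noise(
            rng_noise, (n_trials, n_chan), n_samples,
            cfg.fs_hz, cfg.noise_sd_uv, cfg.noise_exponent,
        )
        epochs = noise + common[None, :, :]

        rng_amp = _substream(cfg.seed, _NS_AMPLITUDE, int(pid))
        amp = rng_amp.normal(cfg.spn_amp_mean, cfg.spn_amp_sd)
        inject = conditions[i] == "S"
        if cfg.inject_correct_only:
            inject &= correct[i]
        epochs[inject] += amp * effect_profile[None, :, :]
        data[i] = epochs.astype(np.float32)

    return EpochSet(
        data=data,
        times_ms=times,
        fs_hz=cfg.fs_hz,
        channels=channels,
        participants=tuple(int(p) for p in pids),
        conditions=conditions,
        correct=correct,
    )


# ---------------------------------------------------------------------------
# persistence

_H5_FIELDS = ("data", "times_ms", "channels", "participants")
_TRIAL_FIELDS = ("participant", "trial", "condition", "correct", "retained")


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write the documented HDF5 layout (lossless round-trip)."""
    P, T, _, _ = epochs.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset(
            "channels", data=np.array([c.encode() for c in epochs.channels])
        )
        f.create_dataset("participants", data=np.asarray(epochs.participants))
        f.attrs["fs_hz"] = epochs.fs_hz
        grp = f.create_group("trial_table")
        pid_grid = np.repeat(np.asarray(epochs.participants), T)
        grp.create_dataset("participant", data=pid_grid)
        grp.create_dataset("trial", data=np.tile(np.arange(T), P))
        grp.create_dataset(
            "condition",
            data=np.array([c.encode() for c in epochs.conditions.ravel()]),
        )
        grp.create_dataset("correct", data=epochs.correct.ravel())
        grp.create_dataset("retained", data=epochs.retained.ravel())


def read_epochs(path: str | Path) -> EpochSet:
    """Read the HDF5 layout written by :func:`write_epochs`, validating it."""
    with h5py.File(path, "r") as f:
        for name in _H5_FIELDS:
            if name not in f:
                raise EpochFormatError(f"{Path(path).name}: missing dataset '/{name}'")
        if "trial_table" not in f:
            raise EpochFormatError(f"{Path(path).name}: missing group '/trial_table'")
        grp = f["trial_table"]
        for name in _TRIAL_FIELDS:
            if name not in grp:
                raise EpochFormatError(
                    f"{Path(path).name}: missing dataset '/trial_table/{name}'"
                )
        data = f["data"][()]
        if data.ndim != 4:
            raise EpochFormatError(f"{Path(path).name}: '/data' must be 4-D")
        P, T, C, S = data.shape
        times = f["times_ms"][()]
        channels = tuple(c.decode() for c in f["channels"][()])
        participants = tuple(int(p) for p in f["participants"][()])
        cond = np.array([c.decode() for c in grp["condition"][()]])
        if cond.size != P * T:
            raise EpochFormatError(
                f"{Path(path).name}: trial_table length {cond.size} does not "
                f"match data shape ({P} x {T} epochs)"
            )
        try:
            return EpochSet(
                data=data,
                times_ms=times,
                fs_hz=float(f.attrs.get("fs_hz", 0.0)),
                channels=channels,
                participants=participants,
                conditions=cond.reshape(P, T),
                correct=grp["correct"][()].astype(bool).reshape(P, T),
                retained=grp["retained"][()].astype(bool).reshape(P, T),
            )
        except (ValueError, EpochFormatError) as exc:
            raise EpochFormatError(f"{Path(path).name}: {exc}") from exc


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"participant", "trial", "condition", "response", "correct"}
    missing = required - set(table.columns)
    if missing:
        raise EpochFormatError(f"{Path(path).name}: missing column(s) {sorted(missing)}")
    table["correct"] = table["correct"].astype(bool)
    return table
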