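"""Synthetic EEG + behavior generator with known ground truth.

The generator emulates the structure of a product-evaluation EEG study:
participants view product images and answer Yes/No questions on three
dimensions (appealing, curiosity, wanting) while 64-channel EEG is
recorded, then rate the same images on a 0-100 scale.  A single latent
"appeal" variable per participant x image drives (a) the amplitude of a
spatially patterned ERP component injected into ongoing-noise epochs,
(b) the Yes/No responses per dimension, and (c) the 0-100 ratings — so
neural signal, choices and ratings are mutually consistent by construction
and every downstream decoding stage has a known recovery target.

Noise model: spatially correlated 1/f^alpha ("pink") noise mixed across
channels plus white sensor noise, scaled to a target per-channel SD in μV.
Two signal components are injected by default: a weak early one (100-300 ms)
and a strong late one (440-860 ms), both amplitude-modulated by the latent
appeal and windowed with a half-cosine envelope to avoid edge artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

from ._seeds import derive_seed, rng_for
from .channels import BIOSEMI_64, DEFAULT_SIGNAL_CHANNELS, spatial_pattern
from .epochs import DIMENSIONS, EpochedDataset, TrialInfo, times_axis

GROUPS = ("never", "current", "past")


@dataclass
class GroupBehavior:
    """Latent-appeal mean/SD for one vaping-status group.

    Defaults are calibrated so that, through the default rating transform,
    group mean ratings land near the observed real-data pattern
    (current ≈ 48 > past ≈ 22 > never ≈ 10 on the 0-100 scale).
    """

    mean: float
    sd: float = 0.5


DEFAULT_BEHAVIOR_PARAMS: dict[str, GroupBehavior] = {
    "never": GroupBehavior(-0.9),
    "current": GroupBehavior(0.8),
    "past": GroupBehavior(-0.4),
}

#: Per-dimension Yes thresholds on the latent scale.  Wanting is hardest to
#: endorse and curiosity easiest, mirroring the ordering of Yes counts and
#: decoding-eligible sample sizes in this kind of study.
DIMENSION_THRESHOLDS: dict[str, float] = {
    "appealing": 0.25,
    "curiosity": 0.0,
    "wanting": 0.5,
}


@dataclass
class SimConfig:
    """Study-design constants and generator knobs."""

    n_participants: int = 38
    group_sizes: tuple[int, int, int] = (12, 16, 10)  # never, current, past
    n_images: int = 120
    n_channels: int = 64
    sampling_rate: float = 512.0  # Hz
    epoch_span: tuple[float, float] = (-100.0, 1000.0)  # ms
    signal_window: tuple[float, float] = (440.0, 860.0)  # ms, late component
    early_window: tuple[float, float] = (100.0, 300.0)  # ms, weak component
    signal_amplitude: float = 1.5  # μV per unit of standardized latent appeal
    early_amplitude: float | None = None  # defaults to 0.4 x signal_amplitude
    spatial_pattern: np.ndarray | None = None  # unit-norm channel weights
    noise_sd: float = 10.0  # μV per channel
    pink_exponent: float = 1.0
    pink_fraction: float = 0.8  # variance share of the correlated pink part
    spatial_rho: float = 0.5  # inter-channel correlation decay of the pink part
    envelope: str = "halfcos"  # boxcar | halfcos
    behavior_params: dict[str, GroupBehavior] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_PARAMS)
    )
    image_sd: float = 0.5  # SD of shared per-image appeal
    idio_sd: float = 0.5  # SD of participant x image idiosyncrasy
    dimension_noise_sd: float = 0.4  # per-dimension latent jitter
    response_temperature: float = 0.6  # logistic scale for Yes/No
    rating_intercept: float = 30.0
    rating_slope: float = 22.0
    rating_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_images < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if sum(self.group_sizes) != self.n_participants:
            raise ValueError("group_sizes must sum to n_participants")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.epoch_span
        for name in ("signal_window", "early_window"):
            w0, w1 = getattr(self, name)
            if not (lo <= w0 < w1 <= hi):
                raise ValueError(f"{name} must lie within epoch_span")
        if self.early_amplitude is None:
            self.early_amplitude = 0.4 * self.signal_amplitude
        if self.spatial_pattern is None:
            if self.n_channels == 64:
                self.spatial_pattern = spatial_pattern()
            else:
                # concentrate on the last ~12% of channels (>= 1)
                k = max(1, self.n_channels // 8)
                w = np.zeros(self.n_channels)
                w[-k:] = 1.0
                self.spatial_pattern = w / np.linalg.norm(w)
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float)
        if self.spatial_pattern.shape != (self.n_channels,):
            raise ValueError("spatial_pattern length must equal n_channels")
        if not np.isclose(np.linalg.norm(self.spatial_pattern), 1.0):
            raise ValueError("spatial_pattern must have unit Euclidean norm")
        if self.envelope not in ("boxcar", "halfcos"):
            raise ValueError("envelope must be 'boxcar' or 'halfcos'")
        if set(self.behavior_params) != set(GROUPS):
            raise ValueError(f"behavior_params must have keys {GROUPS}")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == 64:
            return BIOSEMI_64
        return tuple(f"CH{i:02d}" for i in range(self.n_channels))

    @property
    def signal_channels(self) -> tuple[str, ...]:
        labels = self.channel_labels
        return tuple(
            labels[i] for i in np.flatnonzero(self.spatial_pattern > 1e-12)
        )

    @property
    def participant_groups(self) -> list[str]:
        out: list[str] = []
        for g, n in zip(GROUPS, self.group_sizes):
            out.extend([g] * n)
        return out

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spatial_pattern"] = [float(x) for x in self.spatial_pattern]
        d["behavior_params"] = {
            g: {"mean": p.mean, "sd": p.sd} for g, p in self.behavior_params.items()
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "behavior_params" in d:
            d["behavior_params"] = {
                g: GroupBehavior(**p) for g, p in d["behavior_params"].items()
            }
        if d.get("spatial_pattern") is not None:
            d["spatial_pattern"] = np.asarray(d["spatial_pattern"], dtype=float)
        for key in ("group_sizes", "epoch_span", "signal_window", "early_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery checks."""

    latent_appeal: np.ndarray  # (n_participants, n_images), ~standardized
    late_amplitude: np.ndarray  # (n_participants, n_images), μV
    early_amplitude: np.ndarray  # (n_participants, n_images), μV
    signal_channels: tuple[str, ...]
    spatial_pattern: np.ndarray


# ---------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------

def _pink_spectrum(n_fft: int, sampling_rate: float, exponent: float) -> np.ndarray:
    """rfft-domain amplitude shaping for 1/f^exponent power.

    Scaled so that complex-normal spectral coefficients with these
    amplitudes synthesise (via irfft) a time series of unit variance.
    """
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    # time-domain variance of irfft of coefficients X_k with E|X_k|^2 =
    # 2*shape_k^2: (1/n^2) * sum over the full symmetric spectrum
    weights = np.full(n_fft // 2 + 1, 2.0)
    weights[0] = 1.0
    if n_fft % 2 == 0:
        weights[-1] = 1.0
    var = 2.0 * float(np.sum(weights * shape**2)) / n_fft**2
    return shape / np.sqrt(var)


def simulate_noise_epochs(
    n_trials: int, config: SimConfig, seed: int
) -> np.ndarray:
    """Ongoing-EEG surrogate: correlated pink + white noise epochs.

    Pink (1/f^exponent) noise is synthesised directly in the frequency
    domain — complex-normal coefficients shaped by the target spectrum —
    at a fast FFT length and truncated to the epoch, then mixed across
    channels with corr(i, j) = rho^|i-j|; white sensor noise is added on
    top.  The result is a ``(n_trials, n_channels, n_samples)`` array whose
    per-channel SD is ``config.noise_sd`` μV in expectation.
    ``noise_sd = 0`` yields an all-zeros array.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = times_axis(config.epoch_span, config.sampling_rate)
    n_samples = times.size
    shape = (n_trials, config.n_channels, n_samples)
    if config.noise_sd == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    n_fft = int(scipy.fft.next_fast_len(n_samples))
    n_rfft = n_fft // 2 + 1
    filt = _pink_spectrum(n_fft, config.sampling_rate, config.pink_exponent)
    flat = (n_trials * config.n_channels, n_rfft)
    spec = rng.standard_normal(flat) + 1j * rng.standard_normal(flat)
    spec *= filt
    pink = scipy.fft.irfft(spec, n=n_fft, axis=-1)[:, :n_samples]
    pink = pink.reshape(shape)
    # channel mixing with corr(i, j) = rho^|i-j| (unit variance per channel)
    idx = np.arange(config.n_channels)
    cov = config.spatial_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(cov)
    pink = (pink.transpose(0, 2, 1) @ chol.T).transpose(0, 2, 1)
    sensor = rng.standard_normal(shape)
    out = (
        np.sqrt(config.pink_fraction) * pink
        + np.sqrt(1.0 - config.pink_fraction) * sensor
    )
    out *= config.noise_sd
    return out


# ---------------------------------------------------------------------
# signal injection
# ---------------------------------------------------------------------

def _envelope(n: int, kind: str) -> np.ndarray:
    if kind == "boxcar":
        return np.ones(n)
    if kind == "halfcos":
        u = (np.arange(n) + 0.5) / n
        return np.sin(np.pi * u)
    raise ValueError(f"unknown envelope {kind!r}")


def inject_signal(
    epochs: np.ndarray,
    amplitudes: np.ndarray,
    pattern: np.ndarray,
    window_ms: tuple[float, float],
    times: np.ndarray,
    envelope: str = "halfcos",
) -> np.ndarray:
    """Add ``amplitude x pattern x envelope`` to the epochs inside a window.

    ``amplitudes`` is per-trial (μV), ``pattern`` per-channel; samples with
    ``window_ms[0] <= t < window_ms[1]`` are modified, all others returned
    unchanged.
    """
    epochs = np.asarray(epochs, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (epochs.shape[0],):
        raise ValueError("amplitudes length must equal n_trials")
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (epochs.shape[1],):
        raise ValueError("pattern length must equal n_channels")
    lo, hi = window_ms
    if lo < times[0] - 1e-9 or hi > times[-1] + (times[1] - times[0]) + 1e-9:
        raise ValueError("window outside epoch span")
    mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("window contains no samples")
    env = _envelope(idx.size, envelope)
    out = epochs.copy()
    out[:, :, idx] += (
        amplitudes[:, None, None] * pattern[None, :, None] * env[None, None, :]
    )
    return out


# ---------------------------------------------------------------------
# latent appeal + behavior
# ---------------------------------------------------------------------

def draw_ground_truth(config: SimConfig, seed: int) -> GroundTruth:
    """Latent appeal per participant x image and the injected amplitudes."""
    rng = np.random.default_rng(seed)
    groups = config.participant_groups
    person = np.array(
        [
            rng.normal(config.behavior_params[g].mean, config.behavior_params[g].sd)
            for g in groups
        ]
    )
    image = rng.normal(0.0, config.image_sd, size=config.n_images)
    idio = rng.normal(0.0, config.idio_sd, size=(config.n_participants, config.n_images))
    latent = person[:, None] + image[None, :] + idio
    return GroundTruth(
        latent_appeal=latent,
        late_amplitude=config.signal_amplitude * latent,
        early_amplitude=float(config.early_amplitude) * latent,
        signal_channels=config.signal_channels,
        spatial_pattern=config.spatial_pattern.copy(),
    )


def simulate_behavior(
    config: SimConfig, truth: GroundTruth, seed: int
) -> dict:
    """Yes/No responses and 0-100 ratings driven by the latent appeal.

    Yes/No per dimension: logistic thresholding of the latent appeal plus
    per-dimension jitter.  Ratings: affine transform of the same per-dimension
    latent plus noise, rounded and clipped to [0, 100].

    Returns ``{"yes": bool (P, I, D), "rating": int (P, I, D), "table": df}``
    where the table holds per participant x dimension Yes/No counts, mean
    rating and group membership.
    """
    if truth.latent_appeal.shape != (config.n_participants, config.n_images):
        raise ValueError("ground truth inconsistent with config")
    rng = np.random.default_rng(seed)
    P, I, D = config.n_participants, config.n_images, len(DIMENSIONS)
    latent_dim = (
        truth.latent_appeal[:, :, None]
        + rng.normal(0.0, config.dimension_noise_sd, size=(P, I, D))
    )
    thresholds = np.array([DIMENSION_THRESHOLDS[d] for d in DIMENSIONS])
    p_yes = 1.0 / (
        1.0
        + np.exp(-(latent_dim - thresholds[None, None, :]) / config.response_temperature)
    )
    yes = rng.random(size=(P, I, D)) < p_yes
    raw = (
        config.rating_intercept
        + config.rating_slope * latent_dim
        + rng.normal(0.0, config.rating_noise_sd, size=(P, I, D))
    )
    rating = np.clip(np.round(raw), 0, 100).astype(int)
    groups = config.participant_groups
    rows = []
    for p in range(P):
        for d, dim in enumerate(DIMENSIONS):
            n_yes = int(yes[p, :, d].sum())
            rows.append(
                {
                    "participant_id": f"sub-{p + 1:02d}",
                    "group": groups[p],
                    "dimension": dim,
                    "yes_count": n_yes,
                    "no_count": I - n_yes,
                    "n_missing": 0,
                    "mean_rating": float(rating[p, :, d].mean()),
                }
            )
    return {"yes": yes, "rating": rating, "table": pd.DataFrame(rows)}


# ---------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------

def generate_participant(
    config: SimConfig,
    participant_index: int,
    truth: GroundTruth,
    behavior: dict,
    seed: int,
) -> EpochedDataset:
    """EEG epochs + metadata for one participant (n_images x 3 trials)."""
    p = participant_index
    rng = rng_for(seed, "participant", p)
    times = times_axis(config.epoch_span, config.sampling_rate)
    n_trials = config.n_images * len(DIMENSIONS)
    # trial order: shuffled image x dimension pairs
    pairs = [(i, d) for i in range(config.n_images) for d in range(len(DIMENSIONS))]
    order = rng.permutation(len(pairs))
    pairs = [pairs[k] for k in order]
    epochs = simulate_noise_epochs(
        n_trials, config, derive_seed(seed, "noise", p)
    )
    img_idx = np.array([i for i, _ in pairs])
    late_amp = truth.late_amplitude[p, img_idx]
    early_amp = truth.early_amplitude[p, img_idx]
    if config.signal_amplitude != 0:
        epochs = inject_signal(
            epochs, late_amp, config.spatial_pattern, config.signal_window,
            times, config.envelope,
        )
    if config.early_amplitude:
        epochs = inject_signal(
            epochs, early_amp, config.spatial_pattern, config.early_window,
            times, config.envelope,
        )
    sides = rng.random(n_trials) < 0.5
    trials = [
        TrialInfo(
            image_id=f"img-{i + 1:03d}",
            dimension=DIMENSIONS[d],
            response="yes" if behavior["yes"][p, i, d] else "no",
            rating=int(behavior["rating"][p, i, d]),
            response_side="left" if sides[k] else "right",
        )
        for k, (i, d) in enumerate(pairs)
    ]
    return EpochedDataset(
        participant_id=f"sub-{p + 1:02d}",
        voltages=epochs,
        times=times,
        channel_labels=config.channel_labels,
        sampling_rate=config.sampling_rate,
        trials=trials,
        group=config.participant_groups[p],
    )


def generate_study(
    config: SimConfig, seed: int | None = None
) -> tuple[list[EpochedDataset], pd.DataFrame, GroundTruth]:
    """Full synthetic study: one EpochedDataset per participant.

    Deterministic given (config, seed).  The EEG signal amplitude and the
    behavioral responses are driven by the same latent appeal, so trials
    answered Yes carry larger injected amplitudes whenever
    ``signal_amplitude > 0``.
    """
    if seed is None:
        seed = config.seed
    truth = draw_ground_truth(config, derive_seed(seed, "truth"))
    behavior = simulate_behavior(config, truth, derive_seed(seed, "behavior"))
    datasets = [
        generate_participant(config, p, truth, behavior, seed)
        for p in range(config.n_participants)
    ]
    return datasets, behavior["table"], truth


def iter_study(config: SimConfig, seed: int | None = None):
    """Memory-lean variant of :func:`generate_study`.

    Yields ``(dataset, table, truth)`` one participant at a time so large
    studies can be processed without holding every participant's voltages.
    The per-participant datasets are identical to :func:`generate_study`'s.
    """
    if seed is None:
        seed = config.seed
    truth = draw_ground_truth(config, derive_seed(seed, "truth"))
    behavior = simulate_behavior(config, truth, derive_seed(seed, "behavior"))
    for p in range(config.n_participants):
        yield generate_participant(config, p, truth, behavior, seed), behavior["table"], truth
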