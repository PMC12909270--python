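"""Chance-level and familywise-error calibration on signal-free studies.

Decoding pipelines earn trust by what they do NOT find: on data with no
class information, shuffled-label SVM accuracy must average 50%, shuffled-
rating SVR Fisher-Z must average 0, and the corrected group pipeline must
declare a significant cluster in at most the nominal fraction of null
studies.  This module runs those checks end-to-end through the same code
paths used for real analyses, on reduced grids so they complete at desk
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .group import cluster_permutation_test
from .mvpa import WindowGrid, build_windows, null_run, _svm_one_pass
from .simulate import SimConfig, simulate_noise_epochs
from .epochs import times_axis


def _null_config(config: SimConfig | None) -> SimConfig:
    if config is not None:
        return config
    # single-participant frame: only channel/sampling geometry is used here
    return SimConfig(
        n_participants=1, group_sizes=(1, 0, 0), signal_amplitude=0.0
    )


def reduced_grid(config: SimConfig, n_windows: int, window_ms: float = 10.0) -> WindowGrid:
    """``n_windows`` evenly spaced windows of the full moving-window grid."""
    times = times_axis(config.epoch_span, config.sampling_rate)
    grid = build_windows(times, config.sampling_rate, window_ms)
    idx = np.unique(np.linspace(0, grid.n_windows - 1, n_windows).astype(int))
    return grid.subgrid(idx)


def _balanced_labels(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    if n_trials % 2:
        raise ValueError("balanced labels need an even trial count")
    y = np.array(["no", "yes"]).repeat(n_trials // 2)
    return y[rng.permutation(n_trials)]


def _null_ratings(n_trials: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ratings drawn from the generator's rating model, independent of any EEG."""
    latent = rng.standard_normal(n_trials)
    raw = (
        config.rating_intercept
        + config.rating_slope * latent
        + rng.normal(0.0, config.rating_noise_sd, size=n_trials)
    )
    return np.clip(np.round(raw), 0, 100).astype(float)


def shuffled_label_accuracy_study(
    n_participants: int = 20,
    n_trials: int = 120,
    n_windows: int = 30,
    folds: int = 3,
    repetitions: int = 1,
    cost: float = 1.0,
    config: SimConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-participant x window shuffled-label SVM accuracy (%) on noise epochs.

    Emulates one question dimension of a signal-free study with balanced
    Yes/No labels; the grand mean over the returned matrix estimates the
    empirical chance level (50% when calibrated).
    """
    config = _null_config(config)
    grid = reduced_grid(config, n_windows)
    out = np.empty((n_participants, grid.n_windows))
    for p in range(n_participants):
        epochs = simulate_noise_epochs(
            n_trials, config, derive_seed(seed, "noise", p)
        )
        rng = np.random.default_rng(derive_seed(seed, "labels", p))
        y = _balanced_labels(n_trials, rng)
        for w, (a, b) in enumerate(grid.windows):
            X = epochs[:, :, a:b].reshape(n_trials, -1)
            out[p, w] = null_run(
                X, y, "svm", folds, repetitions, cost,
                seed=derive_seed(seed, "null", p, a),
            )
    return out


def shuffled_rating_fisherz_study(
    n_participants: int = 20,
    n_trials: int = 120,
    n_windows: int = 30,
    folds: int = 3,
    repetitions: int = 1,
    cost: float = 1.0,
    config: SimConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-participant x window shuffled-rating SVR Fisher-Z on noise epochs."""
    config = _null_config(config)
    grid = reduced_grid(config, n_windows)
    out = np.empty((n_participants, grid.n_windows))
    for p in range(n_participants):
        epochs = simulate_noise_epochs(
            n_trials, config, derive_seed(seed, "noise", p)
        )
        rng = np.random.default_rng(derive_seed(seed, "ratings", p))
        ratings = _null_ratings(n_trials, config, rng)
        for w, (a, b) in enumerate(grid.windows):
            X = epochs[:, :, a:b].reshape(n_trials, -1)
            out[p, w] = null_run(
                X, ratings, "svr", folds, repetitions, cost,
                seed=derive_seed(seed, "null", p, a),
            )
    return out


def grand_mean_and_se(values: np.ndarray) -> tuple[float, float]:
    """Grand mean and its Monte-Carlo standard error.

    Participants are the independent replication unit (windows share
    trials), so the SE is the SD of participant means over sqrt(P).
    """
    per_participant = values.mean(axis=1)
    se = per_participant.std(ddof=1) / np.sqrt(len(per_participant))
    return float(values.mean()), float(se)


@dataclass
class FwerResult:
    """Outcome of a familywise-error simulation over null studies."""

    fwer: float  # fraction of studies declaring any corrected cluster
    n_studies: int
    flags: np.ndarray  # per-study any-significant indicator
    binomial_se: float


def familywise_error_rate(
    n_studies: int = 100,
    n_participants: int = 20,
    n_trials: int = 60,
    n_windows: int = 30,
    folds: int = 3,
    repetitions: int = 1,
    cost: float = 1.0,
    n_permutations: int = 500,
    alpha_forming: float = 0.05,
    alpha_cluster: float = 0.05,
    config: SimConfig | None = None,
    seed: int = 0,
) -> FwerResult:
    """Fraction of independent signal-free studies with any corrected cluster.

    Each study runs the full pipeline: per participant, true-label and
    shuffled-label moving-window SVM decoding on pure-noise epochs with
    balanced labels; then per-window one-tailed paired t of the true-null
    differences and cluster-mass permutation correction.  Under the global
    null the declared fraction should not exceed ``alpha_cluster`` beyond
    binomial error.
    """
    config = _null_config(config)
    grid = reduced_grid(config, n_windows)
    flags = np.zeros(n_studies, dtype=bool)
    for s in range(n_studies):
        diffs = np.empty((n_participants, grid.n_windows))
        for p in range(n_participants):
            epochs = simulate_noise_epochs(
                n_trials, config, derive_seed(seed, "noise", s, p)
            )
            rng = np.random.default_rng(derive_seed(seed, "labels", s, p))
            y = _balanced_labels(n_trials, rng)
            for w, (a, b) in enumerate(grid.windows):
                X = epochs[:, :, a:b].reshape(n_trials, -1)
                acc_true = 100.0 * np.mean(
                    [
                        _svm_one_pass(
                            X, y, folds, cost,
                            derive_seed(seed, "true", s, p, a, r),
                        )
                        for r in range(repetitions)
                    ]
                )
                acc_null = null_run(
                    X, y, "svm", folds, repetitions, cost,
                    seed=derive_seed(seed, "null", s, p, a),
                )
                diffs[p, w] = acc_true - acc_null
        res = cluster_permutation_test(
            diffs,
            times_ms=grid.times_ms,
            n_permutations=n_permutations,
            alpha_forming=alpha_forming,
            alpha_cluster=alpha_cluster,
            seed=derive_seed(seed, "perm", s),
        )
        flags[s] = bool(res.significant_mask.any())
    fwer = float(flags.mean())
    se = float(np.sqrt(alpha_cluster * (1 - alpha_cluster) / n_studies))
    return FwerResult(fwer=fwer, n_studies=n_studies, flags=flags, binomial_se=se)
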