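"""Group-level inference over moving-window decoding results.

Per analysis window, a one-tailed paired-samples t-test compares each
participant's true-label score against their shuffled-label (empirical
null) score.  Familywise error across the many windows is controlled with a
cluster-based permutation test: clusters are maximal runs of contiguous
windows with uncorrected p below the cluster-forming threshold (and
positive t), scored by cluster mass (the sum of t over member windows), and
referred to the permutation distribution of the maximum cluster mass
obtained by randomly sign-flipping each participant's difference series.

Feature-weight topographies summarise which channels drive the prediction
inside a significant cluster: the linear model is refit on all eligible
(balanced) trials per participant and window, absolute weights are averaged
over within-window samples, z-standardised across channels, averaged over
the cluster's windows, and tested against zero across participants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC, SVR

from ._seeds import derive_seed
from .epochs import EpochedDataset
from .mvpa import (
    DecodeParams,
    WindowGrid,
    prepare_decoding_trials,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------

@dataclass
class PairedT:
    t: float
    p: float
    degenerate: bool = False


def paired_t_onetailed(
    values_true: np.ndarray, values_null: np.ndarray
) -> PairedT:
    """One-tailed paired-samples t-test of H1: true > null.

    ``t`` is computed on the differences d = true - null with n-1 degrees of
    freedom; ``p`` is the upper-tail Student-t probability.  Zero-variance
    differences are degenerate: p = 0 if the (constant) difference is
    positive, else 1.
    """
    d = np.asarray(values_true, dtype=float) - np.asarray(values_null, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need n >= 2 paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedT(
            t=np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0),
            p=0.0 if d.mean() > 0 else 1.0,
            degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    return PairedT(t=float(t), p=float(stats.t.sf(t, df=n - 1)))


def _t_series(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-window one-tailed paired t over a participants x windows matrix."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.sign(mean) * np.inf)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = stats.t.sf(t, df=n - 1)
    p = np.where(np.isposinf(t), 0.0, np.where(np.isneginf(t), 1.0, p))
    return t, p


# ---------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------

@dataclass
class Cluster:
    start: int  # first member window index
    stop: int  # one past the last member window index
    mass: float  # sum of t over member windows
    p_value: float | None = None

    @property
    def windows(self) -> list[int]:
        return list(range(self.start, self.stop))


def find_clusters(
    p_uncorrected: np.ndarray, t: np.ndarray, alpha_forming: float = 0.05
) -> list[Cluster]:
    """Maximal contiguous runs with p < alpha_forming and t > 0, scored by mass."""
    p = np.asarray(p_uncorrected, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError("p and t series must be aligned")
    supra = (p < alpha_forming) & (t > 0)
    clusters: list[Cluster] = []
    i = 0
    n = supra.size
    while i < n:
        if supra[i]:
            j = i
            while j < n and supra[j]:
                j += 1
            clusters.append(Cluster(start=i, stop=j, mass=float(t[i:j].sum())))
            i = j
        else:
            i += 1
    return clusters


@dataclass
class GroupStatResult:
    """Per-window group statistics with cluster-corrected significance."""

    times_ms: np.ndarray
    t: np.ndarray
    p_uncorrected: np.ndarray
    clusters: list[Cluster]
    null_max_mass: np.ndarray  # permutation distribution of max cluster mass
    significant_mask: np.ndarray  # corrected, per window
    n_participants: int
    n_cluster_permutations: int
    alpha_forming: float
    alpha_cluster: float
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        cluster_id = np.full(self.t.size, -1)
        cluster_p = np.full(self.t.size, np.nan)
        for k, c in enumerate(self.clusters):
            cluster_id[c.start:c.stop] = k
            cluster_p[c.start:c.stop] = c.p_value
        return pd.DataFrame(
            {
                "window_time_ms": self.times_ms,
                "t": self.t,
                "p_uncorrected": self.p_uncorrected,
                "cluster_id": cluster_id,
                "cluster_p": cluster_p,
                "significant": self.significant_mask,
            }
        )


def _max_cluster_mass(t: np.ndarray, p: np.ndarray, alpha_forming: float) -> float:
    clusters = find_clusters(p, t, alpha_forming)
    return max((c.mass for c in clusters), default=0.0)


def cluster_permutation_test(
    diffs: np.ndarray,
    times_ms: np.ndarray | None = None,
    n_permutations: int = 1000,
    alpha_forming: float = 0.05,
    alpha_cluster: float = 0.05,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> GroupStatResult:
    """Cluster-mass permutation correction for a participants x windows design.

    The observed clusters come from the per-window one-tailed paired t
    series of ``diffs`` (true - null scores).  The null distribution of the
    maximum cluster mass is built by randomly flipping the sign of each
    participant's whole difference series (exchangeable under H0: no
    difference between true and shuffled-label decoding) and recomputing the
    t series and clusters.  Cluster p-values use the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.

    With ``exhaustive=True`` all 2^n sign assignments are enumerated (only
    sensible for small n); the p-value denominator is then the full count.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2:
        raise ValueError("diffs must be participants x windows")
    n_p, n_w = diffs.shape
    if n_p < 2:
        raise ValueError("need >= 2 participants")
    if times_ms is None:
        times_ms = np.arange(n_w, dtype=float)
    t_obs, p_obs = _t_series(diffs)
    clusters = find_clusters(p_obs, t_obs, alpha_forming)

    if exhaustive:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n_p)] for m in range(2**n_p)],
            dtype=float,
        )
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if n_permutations < 100:
            warnings.warn(
                f"n_permutations = {n_permutations} gives a coarse null; "
                "consider >= 1000",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_p))

    null_max = np.empty(signs.shape[0])
    for k in range(signs.shape[0]):
        t_k, p_k = _t_series(signs[k][:, None] * diffs)
        null_max[k] = _max_cluster_mass(t_k, p_k, alpha_forming)

    denom = signs.shape[0] if exhaustive else signs.shape[0] + 1
    for c in clusters:
        exceed = int(np.sum(null_max >= c.mass - 1e-12))
        c.p_value = (exceed if exhaustive else exceed + 1) / denom

    mask = np.zeros(n_w, dtype=bool)
    for c in clusters:
        if c.p_value is not None and c.p_value < alpha_cluster:
            mask[c.start:c.stop] = True

    return GroupStatResult(
        times_ms=np.asarray(times_ms, dtype=float),
        t=t_obs,
        p_uncorrected=p_obs,
        clusters=clusters,
        null_max_mass=null_max,
        significant_mask=mask,
        n_participants=n_p,
        n_cluster_permutations=signs.shape[0],
        alpha_forming=alpha_forming,
        alpha_cluster=alpha_cluster,
        seed=seed,
    )


def group_inference(
    results: list,
    times_ms: np.ndarray | None = None,
    **kwargs,
) -> GroupStatResult:
    """Convenience wrapper: stack ParticipantDecodingResults and run the test."""
    diffs = np.vstack([r.values_true - r.values_null for r in results])
    if times_ms is None:
        times_ms = results[0].times_ms
    return cluster_permutation_test(diffs, times_ms=times_ms, **kwargs)


# ---------------------------------------------------------------------
# feature-weight topographies
# ---------------------------------------------------------------------

@dataclass
class FeatureWeightMap:
    """Channel-wise standardized absolute weights for a cluster of windows."""

    window_range_ms: tuple[float, float]
    channel_labels: tuple[str, ...]
    mean_z: np.ndarray  # group mean of standardized |weight| per channel
    t: np.ndarray
    p: np.ndarray  # one-tailed, per channel, uncorrected
    significant: np.ndarray  # p < alpha
    n_participants: int
    per_participant_z: np.ndarray = field(repr=False, default=None)

    @property
    def significant_channels(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.channel_labels)[self.significant])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.channel_labels),
                "mean_z": self.mean_z,
                "t": self.t,
                "p": self.p,
                "significant": self.significant,
            }
        )


def _participant_channel_weights(
    ds: EpochedDataset,
    dimension: str,
    mode: str,
    windows: list[tuple[int, int]],
    params: DecodeParams,
    seed: int,
) -> np.ndarray | None:
    """Standardized per-channel |weight| averaged over a cluster's windows."""
    prepared = prepare_decoding_trials(ds, dimension, mode, params, seed)
    if prepared is None:
        return None
    view, targets = prepared
    n_ch = view.n_channels
    zs = np.zeros(n_ch)
    for a, b in windows:
        X = view.voltages[:, :, a:b].reshape(view.n_trials, -1)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd
        if mode == "svm":
            model = SVC(kernel="linear", C=params.cost)
        else:
            model = SVR(kernel="linear", C=params.cost)
        model.fit(Xz, targets)
        w = np.abs(model.coef_.ravel()).reshape(n_ch, b - a).mean(axis=1)
        w_sd = w.std()
        zs += (w - w.mean()) / w_sd if w_sd > 0 else np.zeros(n_ch)
    return zs / len(windows)


def feature_weight_map(
    datasets: list[EpochedDataset],
    dimension: str,
    grid: WindowGrid,
    cluster: Cluster | list[int],
    mode: str = "svm",
    params: DecodeParams | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> FeatureWeightMap:
    """Group topography of channel importance within a (significant) cluster.

    Per participant and cluster window the linear model is refit on all
    eligible balanced trials; absolute weights are averaged over the
    window's samples per channel, z-standardised across channels (mean 0,
    SD 1 within participant), and averaged across the cluster's windows.
    Channels are then tested across participants with a one-tailed
    one-sample t against 0 and flagged at ``p < alpha`` (uncorrected).
    """
    params = params or DecodeParams()
    win_idx = cluster.windows if isinstance(cluster, Cluster) else list(cluster)
    if not win_idx:
        logger.warning("empty cluster: returning empty feature-weight map")
        win_idx = []
    windows = [grid.windows[i] for i in win_idx]
    labels = datasets[0].channel_labels if datasets else ()
    rows = []
    for i, ds in enumerate(datasets if windows else []):
        z = _participant_channel_weights(
            ds, dimension, mode, windows, params,
            derive_seed(seed, "weights", i),
        )
        if z is not None:
            rows.append(z)
    if not rows or not windows:
        n_ch = len(labels)
        return FeatureWeightMap(
            window_range_ms=(np.nan, np.nan),
            channel_labels=labels,
            mean_z=np.zeros(n_ch),
            t=np.zeros(n_ch),
            p=np.ones(n_ch),
            significant=np.zeros(n_ch, dtype=bool),
            n_participants=0,
            per_participant_z=np.zeros((0, n_ch)),
        )
    Z = np.vstack(rows)
    res = stats.ttest_1samp(Z, 0.0, axis=0, alternative="greater")
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    lo = grid.times_ms[win_idx[0]] - grid.window_ms / 2
    hi = grid.times_ms[win_idx[-1]] + grid.window_ms / 2
    return FeatureWeightMap(
        window_range_ms=(float(lo), float(hi)),
        channel_labels=labels,
        mean_z=Z.mean(axis=0),
        t=t,
        p=p,
        significant=p < alpha,
        n_participants=Z.shape[0],
        per_participant_z=Z,
    )
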