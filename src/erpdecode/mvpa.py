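"""Per-participant moving-window decoding.

The epoch is tiled with short consecutive analysis windows (10 ms by
default).  Within each window, the spatiotemporal voltage pattern (all
channels x all samples in the window) is used to

* classify binary Yes/No responses with a linear soft-margin SVM, scored as
  mean held-out accuracy over stratified k-fold cross-validation repeated
  several times with re-randomised folds, and
* predict 0-100 ratings with a linear SVR, scored as the Fisher-Z
  transformed Pearson correlation between pooled held-out predictions and
  the true ratings, averaged over repetitions.

An empirical null is obtained by re-running the identical machinery after
randomly shuffling the labels (one shuffle per repetition), giving each
participant a per-window chance series to pair against the true series at
the group level.

The models are deliberately not tuned: the point is to establish the
presence of predictive information via significance testing against the
shuffled-label null, not to maximise accuracy.  The regularization constant
is therefore fixed (default C = 1) and no inner selection loop exists.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from ._seeds import derive_seed, rng_for
from .epochs import EpochedDataset, select_trials

logger = logging.getLogger(__name__)

RESPONSE_ORDER = ("no", "yes")  # fixed class ordering; ties resolve to "no"


# ---------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------

@dataclass
class WindowGrid:
    """Non-overlapping analysis windows tiling the epoch, in sample indices."""

    window_ms: float
    windows: list[tuple[int, int]]  # (start, stop), stop exclusive
    times_ms: np.ndarray  # representative (centre) time per window

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def subgrid(self, indices: np.ndarray | list[int]) -> "WindowGrid":
        """A reduced grid keeping only the given window indices (in order)."""
        indices = list(indices)
        return WindowGrid(
            window_ms=self.window_ms,
            windows=[self.windows[i] for i in indices],
            times_ms=self.times_ms[indices],
        )

    def restrict(self, lo_ms: float, hi_ms: float) -> "WindowGrid":
        """Windows whose centre lies in [lo_ms, hi_ms]."""
        keep = np.flatnonzero((self.times_ms >= lo_ms) & (self.times_ms <= hi_ms))
        return self.subgrid(keep)


def build_windows(
    times: np.ndarray, sampling_rate: float, window_ms: float = 10.0
) -> WindowGrid:
    """Tile the epoch with consecutive windows of ``window_ms`` duration.

    Each window spans ``floor(window_ms * fs / 1000)`` samples (5 at 512 Hz
    for 10-ms windows); a trailing partial window is dropped.  The grid
    covers the prestimulus baseline as well as the post-stimulus epoch.
    """
    n_samples = len(times)
    spw = int(np.floor(window_ms * sampling_rate / 1000.0))
    if spw < 1:
        raise ValueError("window_ms must cover at least one sample period")
    if spw > n_samples:
        raise ValueError("window longer than epoch")
    n_windows = n_samples // spw
    windows = [(i * spw, (i + 1) * spw) for i in range(n_windows)]
    centres = np.array([times[a:b].mean() for a, b in windows])
    return WindowGrid(window_ms=window_ms, windows=windows, times_ms=centres)


# ---------------------------------------------------------------------
# features + eligibility
# ---------------------------------------------------------------------

def extract_features(
    ds: EpochedDataset, window: tuple[int, int], feature_mode: str = "spatiotemporal"
) -> np.ndarray:
    """Trials x features matrix for one window.

    ``spatiotemporal`` (default): all channels x samples in the window,
    channel-major then sample (64 channels x 5 samples -> 320 features).
    ``channel_mean``: per-channel mean over the window's samples.
    """
    a, b = window
    if not (0 <= a < b <= ds.n_samples):
        raise ValueError("window outside epoch")
    for t in ds.trials:
        if t.rejected or t.response == "none":
            raise ValueError(
                "rejected/missing-response trials must be excluded before "
                "feature extraction"
            )
    block = ds.voltages[:, :, a:b]
    if feature_mode == "spatiotemporal":
        return block.reshape(ds.n_trials, -1)
    if feature_mode == "channel_mean":
        return block.mean(axis=2)
    raise ValueError(f"unknown feature_mode {feature_mode!r}")


def eligibility_classification(labels: np.ndarray, min_per_class: int = 20) -> bool:
    """Participants need >= ``min_per_class`` trials of BOTH classes.

    Mirrors the exclusion of participants who answered Yes to fewer than 20
    images: too few trials to train the classifier for both classes.
    """
    labels = np.asarray(labels)
    n_yes = int(np.sum(labels == "yes") if labels.dtype.kind in "US" else labels.sum())
    n_no = len(labels) - n_yes
    return n_yes >= min_per_class and n_no >= min_per_class


def eligibility_regression(
    ratings: np.ndarray, min_unique: int = 5, min_sd: float = 1.0
) -> bool:
    """Ratings must be sufficiently variable to fit the regression model."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size < 2:
        return False
    return (
        float(np.std(ratings, ddof=1)) >= min_sd
        and np.unique(ratings).size >= min_unique
    )


def balance_classes(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices retaining all minority-class trials and a random majority subsample.

    Keeps the chance level at 50% regardless of the Yes/No split.  Returned
    indices are sorted (original trial order preserved).  Deterministic
    given ``seed``; balanced input is returned unchanged.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    n = min(idx0.size, idx1.size)
    if n == 0:
        raise ValueError("a class is absent")
    rng = np.random.default_rng(seed)
    take0 = idx0 if idx0.size == n else np.sort(rng.choice(idx0, size=n, replace=False))
    take1 = idx1 if idx1.size == n else np.sort(rng.choice(idx1, size=n, replace=False))
    return np.sort(np.concatenate([take0, take1]))


# ---------------------------------------------------------------------
# cross-validated models
# ---------------------------------------------------------------------

def _scale_train_test(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scoring with training-fold statistics only."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _svm_one_pass(
    X: np.ndarray, y: np.ndarray, folds: int, cost: float, fold_seed: int
) -> float:
    """One stratified k-fold pass; returns fraction correct over held-out folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    correct = 0
    for train, test in skf.split(X, y):
        Xtr, Xte = _scale_train_test(X[train], X[test])
        clf = SVC(kernel="linear", C=cost)
        clf.fit(Xtr, y[train])
        correct += int(np.sum(clf.predict(Xte) == y[test]))
    return correct / len(y)


def svm_cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    repetitions: int = 10,
    cost: float = 1.0,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy (%) of a linear SVM over repeated stratified CV.

    Fold assignment is re-randomised each repetition.  Expects balanced
    classes (apply :func:`balance_classes` first) and at least ``folds``
    trials per class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.size != 2:
        raise ValueError("binary labels required")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} trials per class for {folds}-fold CV")
    accs = [
        _svm_one_pass(X, y, folds, cost, derive_seed(seed, "rep", r))
        for r in range(repetitions)
    ]
    return 100.0 * float(np.mean(accs))


def _fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)))


def _svr_one_pass(
    X: np.ndarray, y: np.ndarray, folds: int, cost: float, fold_seed: int
) -> float:
    """One k-fold pass; Fisher-Z of r(pooled held-out predictions, truth)."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    pred = np.empty_like(y, dtype=float)
    for train, test in kf.split(X):
        Xtr, Xte = _scale_train_test(X[train], X[test])
        reg = SVR(kernel="linear", C=cost)
        reg.fit(Xtr, y[train])
        pred[test] = reg.predict(Xte)
    if np.std(pred) == 0 or np.std(y) == 0:
        logger.warning("zero-variance predictions or targets; returning Z = 0")
        return 0.0
    r = float(np.corrcoef(pred, y)[0, 1])
    return _fisher_z(r)


def svr_cv_fisherz(
    features: np.ndarray,
    ratings: np.ndarray,
    folds: int = 10,
    repetitions: int = 10,
    cost: float = 1.0,
    seed: int = 0,
) -> float:
    """Mean Fisher-Z correlation between SVR-predicted and true ratings.

    Per repetition, held-out predictions are pooled across the k folds, the
    Pearson correlation with the true ratings is computed, and
    ``z = atanh(r)`` is taken; the mean over repetitions is returned.
    Targets are used on their native 0-100 scale and predictions are not
    clipped before correlating.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if len(y) < folds:
        raise ValueError("fewer trials than folds")
    zs = [
        _svr_one_pass(X, y, folds, cost, derive_seed(seed, "rep", r))
        for r in range(repetitions)
    ]
    return float(np.mean(zs))


def null_run(
    features: np.ndarray,
    targets: np.ndarray,
    mode: str,
    folds: int = 10,
    repetitions: int = 10,
    cost: float = 1.0,
    n_shuffles_per_repetition: int = 1,
    seed: int = 0,
) -> float:
    """Shuffled-label empirical null for the same CV machinery.

    Labels (or ratings) are permuted uniformly at random across trials —
    ``n_shuffles_per_repetition`` times per CV repetition — and the identical
    cross-validation is run on each shuffle; the mean score is returned
    (accuracy % for ``mode='svm'``, Fisher-Z for ``mode='svr'``).
    """
    if mode not in ("svm", "svr"):
        raise ValueError("mode must be 'svm' or 'svr'")
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    scores = []
    for r in range(repetitions):
        for s in range(n_shuffles_per_repetition):
            rng = rng_for(seed, "shuffle", r, s)
            y_perm = y[rng.permutation(len(y))]
            fold_seed = derive_seed(seed, "rep", r, s)
            if mode == "svm":
                scores.append(
                    100.0 * _svm_one_pass(X, y_perm, folds, cost, fold_seed)
                )
            else:
                scores.append(
                    _svr_one_pass(X, y_perm.astype(float), folds, cost, fold_seed)
                )
    return float(np.mean(scores))


# ---------------------------------------------------------------------
# per-participant orchestration
# ---------------------------------------------------------------------

@dataclass
class DecodeParams:
    """Knobs of the moving-window decoding stage."""

    window_ms: float = 10.0
    folds: int = 10
    repetitions: int = 10
    cost: float = 1.0
    min_per_class: int = 20
    min_unique: int = 5
    min_sd: float = 1.0
    feature_mode: str = "spatiotemporal"  # or "channel_mean"
    n_shuffles_per_repetition: int = 1


@dataclass
class ParticipantDecodingResult:
    """Per-window true and shuffled-label scores for one participant x dimension."""

    participant_id: str
    dimension: str
    mode: str  # svm | svr
    times_ms: np.ndarray
    values_true: np.ndarray  # accuracy % (svm) or Fisher-Z (svr)
    values_null: np.ndarray
    n_trials: int  # per-class count x2 for svm; rated trials for svr
    cv_folds: int
    cv_repetitions: int
    seed: int

    def __post_init__(self) -> None:
        if not (
            len(self.values_true) == len(self.values_null) == len(self.times_ms)
        ):
            raise ValueError("true/null/time series must have equal length")
        if self.mode == "svm" and not (
            np.all(self.values_true >= 0) and np.all(self.values_true <= 100)
        ):
            raise ValueError("accuracies must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "dimension": self.dimension,
                "mode": self.mode,
                "window_time_ms": self.times_ms,
                "value_true": self.values_true,
                "value_null": self.values_null,
            }
        )


def prepare_decoding_trials(
    ds: EpochedDataset, dimension: str, mode: str, params: DecodeParams, seed: int
) -> tuple[EpochedDataset, np.ndarray] | None:
    """Select, eligibility-check and (for SVM) balance one participant's trials.

    Returns ``(view, targets)`` or ``None`` when the participant is
    ineligible for this mode x dimension (logged, not raised).
    """
    view = select_trials(ds, dimension, drop_rejected=True)
    if mode == "svm":
        labels = np.array([t.response for t in view.trials])
        if not eligibility_classification(labels, params.min_per_class):
            logger.info(
                "%s/%s ineligible for svm: yes=%d no=%d (< %d per class)",
                ds.participant_id, dimension,
                int(np.sum(labels == "yes")), int(np.sum(labels == "no")),
                params.min_per_class,
            )
            return None
        keep = balance_classes(labels, derive_seed(seed, "balance"))
        view = dataclasses.replace(
            view, voltages=view.voltages[keep], trials=[view.trials[i] for i in keep]
        )
        return view, np.array([t.response for t in view.trials])
    if mode == "svr":
        has_rating = [i for i, t in enumerate(view.trials) if t.rating is not None]
        view = dataclasses.replace(
            view,
            voltages=view.voltages[has_rating],
            trials=[view.trials[i] for i in has_rating],
        )
        ratings = np.array([t.rating for t in view.trials], dtype=float)
        if not eligibility_regression(ratings, params.min_unique, params.min_sd):
            logger.info(
                "%s/%s ineligible for svr: insufficient rating variability",
                ds.participant_id, dimension,
            )
            return None
        return view, ratings
    raise ValueError("mode must be 'svm' or 'svr'")


def run_participant(
    ds: EpochedDataset,
    dimension: str,
    mode: str,
    grid: WindowGrid,
    params: DecodeParams | None = None,
    seed: int = 0,
) -> ParticipantDecodingResult | None:
    """Moving-window true + shuffled-label decoding for one participant.

    Per-window seeds are derived deterministically from ``seed`` and the
    window's position, so windows may be evaluated in any order (or in
    parallel) with results identical to serial execution.  Returns ``None``
    for ineligible participants.
    """
    params = params or DecodeParams()
    prepared = prepare_decoding_trials(ds, dimension, mode, params, seed)
    if prepared is None:
        return None
    view, targets = prepared
    vals_true = np.empty(grid.n_windows)
    vals_null = np.empty(grid.n_windows)
    for w, window in enumerate(grid.windows):
        X = extract_features(view, window, params.feature_mode)
        wkey = window[0]  # identity of the window, robust to subgrids
        if mode == "svm":
            vals_true[w] = svm_cv_accuracy(
                X, targets, params.folds, params.repetitions, params.cost,
                seed=derive_seed(seed, "true", wkey),
            )
        else:
            vals_true[w] = svr_cv_fisherz(
                X, targets, params.folds, params.repetitions, params.cost,
                seed=derive_seed(seed, "true", wkey),
            )
        vals_null[w] = null_run(
            X, targets, mode, params.folds, params.repetitions, params.cost,
            params.n_shuffles_per_repetition,
            seed=derive_seed(seed, "null", wkey),
        )
    return ParticipantDecodingResult(
        participant_id=ds.participant_id,
        dimension=dimension,
        mode=mode,
        times_ms=grid.times_ms.copy(),
        values_true=vals_true,
        values_null=vals_null,
        n_trials=view.n_trials,
        cv_folds=params.folds,
        cv_repetitions=params.repetitions,
        seed=seed,
    )


def results_to_frame(results: list[ParticipantDecodingResult]) -> pd.DataFrame:
    """Tidy long table over participants (participant, dimension, mode, window...)."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
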