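"""Behavioral arm: descriptives, one-way ANOVA with Bonferroni post hocs,
and image-level response-rating correlations.

The behavioral table (one row per participant x dimension) carries Yes/No
counts from the choice phase, the mean 0-100 rating from the post-session
phase, and the participant's vaping-status group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("never", "current", "past")


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group (and full-sample) summary per dimension.

    Yes/No counts are summarised as median/min/max, ratings as mean (SD) —
    the shape of the study's descriptive table.  Empty groups yield NaN rows.
    """
    if table.empty:
        raise ValueError("empty behavioral table")
    blocks = []
    scopes = [("full_sample", table)] + [
        (g, table[table["group"] == g]) for g in GROUP_ORDER
    ]
    for name, sub in scopes:
        for dim, dsub in sub.groupby("dimension", sort=True):
            blocks.append(
                {
                    "scope": name,
                    "dimension": dim,
                    "n": dsub["participant_id"].nunique(),
                    "yes_mdn": dsub["yes_count"].median(),
                    "yes_min": dsub["yes_count"].min(),
                    "yes_max": dsub["yes_count"].max(),
                    "no_mdn": dsub["no_count"].median(),
                    "no_min": dsub["no_count"].min(),
                    "no_max": dsub["no_count"].max(),
                    "rating_mean": dsub["mean_rating"].mean(),
                    "rating_sd": dsub["mean_rating"].std(ddof=1),
                }
            )
        if sub.empty:
            warnings.warn(f"group {name!r} is empty", stacklevel=2)
    return pd.DataFrame(blocks)


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    posthoc: pd.DataFrame  # pair, t, p_raw, p_bonferroni, significant


def oneway_anova_bonferroni(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA over group labels plus Bonferroni-corrected post hocs.

    Post hocs are classical equal-variance two-sample t-tests for every
    group pair, with p multiplied by the number of pairs (capped at 1).
    Groups with fewer than 2 members are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples, names = [], []
    for g in pd.unique(groups):
        v = values[groups == g]
        if v.size < 2:
            warnings.warn(f"group {g!r} has < 2 members; excluded", stacklevel=2)
            continue
        samples.append(v)
        names.append(g)
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f, p = stats.f_oneway(*samples)
    if np.isnan(f):  # all observations identical -> no variance anywhere
        f, p = 0.0, 1.0
    n_pairs = len(samples) * (len(samples) - 1) // 2
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t_ij, p_ij = stats.ttest_ind(samples[i], samples[j], equal_var=True)
            if np.isnan(t_ij):
                t_ij, p_ij = 0.0, 1.0
            p_adj = min(1.0, n_pairs * float(p_ij))
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "t": float(t_ij),
                    "p_raw": float(p_ij),
                    "p_bonferroni": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    n_total = sum(len(s) for s in samples)
    return AnovaResult(
        f=float(f),
        p=float(p),
        df_between=len(samples) - 1,
        df_within=n_total - len(samples),
        posthoc=pd.DataFrame(rows),
    )


def anova_by_dimension(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA series per dimension for each dependent variable.

    Runs the group comparison separately with Yes counts, No counts and
    mean ratings as the dependent variable, labelling each series.
    """
    rows = []
    for dim, sub in table.groupby("dimension", sort=True):
        for dv in ("yes_count", "no_count", "mean_rating"):
            res = oneway_anova_bonferroni(
                sub[dv].to_numpy(), sub["group"].to_numpy(), alpha
            )
            base = {"dimension": dim, "dependent": dv, "F": res.f, "p": res.p}
            for _, ph in res.posthoc.iterrows():
                rows.append(
                    base
                    | {
                        "pair": f"{ph.group_a}-{ph.group_b}",
                        "t": ph.t,
                        "p_raw": ph.p_raw,
                        "p_bonferroni": ph.p_bonferroni,
                        "significant": ph.significant,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ImageCorrelation:
    dimension: str
    r_yes: float
    p_yes: float
    r_no: float
    p_no: float
    n_images: int
    degenerate: bool = False


def image_level_correlation(
    trials: pd.DataFrame, dimension: str
) -> ImageCorrelation:
    """Pearson r between per-image Yes (and No) counts and mean ratings.

    Per image, counts Yes/No responses across participants and averages
    the ratings, then correlates across images.  Zero variance in either
    variable yields NaN correlations with ``degenerate=True``.
    """
    sub = trials[(trials["dimension"] == dimension) & (trials["response"] != "none")]
    agg = sub.groupby("image_id").agg(
        yes_count=("response", lambda s: int((s == "yes").sum())),
        no_count=("response", lambda s: int((s == "no").sum())),
        mean_rating=("rating", "mean"),
    )
    if len(agg) < 3:
        raise ValueError("need >= 3 images")
    if agg["mean_rating"].std() == 0 or agg["yes_count"].std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return ImageCorrelation(
            dimension, np.nan, np.nan, np.nan, np.nan, len(agg), degenerate=True
        )
    r_yes, p_yes = stats.pearsonr(agg["yes_count"], agg["mean_rating"])
    r_no, p_no = stats.pearsonr(agg["no_count"], agg["mean_rating"])
    return ImageCorrelation(
        dimension, float(r_yes), float(p_yes), float(r_no), float(p_no), len(agg)
    )
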