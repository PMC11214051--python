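"""Rating screening, inter-rater agreement, mean ratings and behavioral RDMs.

Raters who gave the same response on more than 80% of trials for a scale are
excluded for that scale; inter-rater agreement is quantified with the
two-way random-effects intraclass correlation for the mean of k raters,
ICC(2,k); scales with poor agreement are dropped from all downstream
analyses.  The behavioral RDM of a characteristic is the absolute difference
in mean rating between every pair of stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RDM
from .factors import PCASolution, pca_oblimin

__all__ = [
    "RaterScreenReport",
    "MeanRatings",
    "screen_raters",
    "icc2k",
    "mean_ratings",
    "characteristic_correlations",
    "rating_rdm",
    "behavioral_rdms",
    "pca_oblimin",
]

RATING_COLUMNS = ("rater_id", "stimulus_id", "characteristic", "rating")


def _validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    vals = ratings["rating"]
    bad = ratings[(vals < 1) | (vals > 9) | (vals != vals.round())]
    if len(bad):
        raise ValueError(
            f"ratings must be integers in [1, 9]; offending rows:\n{bad.head()}"
        )
    return ratings


@dataclass
class RaterScreenReport:
    excluded: list[tuple[str, str]]  # (rater_id, characteristic)
    max_same_fraction: pd.DataFrame  # rater x characteristic
    icc2k: dict[str, float]  # per characteristic, after exclusions
    dropped_characteristics: list[str]
    threshold: float = 0.8
    icc_threshold: float = 0.5


def screen_raters(ratings: pd.DataFrame, max_same_fraction: float = 0.8) -> pd.DataFrame:
    """Modal-response fraction per (rater, characteristic).

    Returns a rater x characteristic frame of the fraction of trials on
    which the rater gave their most frequent response; pairs strictly above
    ``max_same_fraction`` are to be excluded (a fraction of exactly 0.8 is
    retained).
    """
    _validate_ratings(ratings)

    def modal_frac(x: pd.Series) -> float:
        return x.value_counts().iloc[0] / len(x)

    return (
        ratings.groupby(["rater_id", "characteristic"])["rating"]
        .apply(modal_frac)
        .unstack("characteristic")
    )


def icc2k(table: np.ndarray) -> float:
    """ICC(2,k): two-way random-effects reliability of the k-rater mean.

    ``table`` is items x raters with no missing cells.  From the two-way
    ANOVA mean squares (items, raters, error):

        ICC(2,k) = (MS_items - MS_err) / (MS_items + (MS_raters - MS_err) / n_items)

    A table with zero variance anywhere it matters returns NaN with a
    warning rather than raising.
    """
    x = np.asarray(table, dtype=np.float64)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters")
    grand = x.mean()
    item_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_items = k * np.sum((item_means - grand) ** 2)
    ss_raters = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_items - ss_raters
    ms_items = ss_items / (n - 1)
    ms_raters = ss_raters / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_items + (ms_raters - ms_err) / n
    if denom == 0:
        warnings.warn("ICC(2,k) undefined: zero denominator (degenerate table)")
        return float("nan")
    return float((ms_items - ms_err) / denom)


def rater_agreement(
    ratings: pd.DataFrame,
    max_same_fraction: float = 0.8,
    icc_threshold: float = 0.5,
) -> RaterScreenReport:
    """Apply the response screen, then ICC(2,k) per characteristic.

    Raters with any missing stimulus on a scale are dropped listwise for the
    ICC of that scale.  Characteristics whose ICC falls below
    ``icc_threshold`` are marked dropped.
    """
    fracs = screen_raters(ratings, max_same_fraction)
    excluded = [
        (r, c)
        for (r, c) in fracs.stack().index
        if fracs.loc[r, c] > max_same_fraction
    ]
    excl_set = set(excluded)
    iccs: dict[str, float] = {}
    dropped: list[str] = []
    for char, grp in ratings.groupby("characteristic"):
        grp = grp[~grp["rater_id"].map(lambda r: (r, char) in excl_set)]
        wide = grp.pivot(index="stimulus_id", columns="rater_id", values="rating")
        wide = wide.dropna(axis=1)  # listwise deletion of incomplete raters
        if wide.shape[1] < 2:
            iccs[str(char)] = float("nan")
            dropped.append(str(char))
            continue
        iccs[str(char)] = icc2k(wide.to_numpy())
        if not (iccs[str(char)] >= icc_threshold):
            dropped.append(str(char))
    return RaterScreenReport(
        excluded=excluded,
        max_same_fraction=fracs,
        icc2k=iccs,
        dropped_characteristics=dropped,
        threshold=max_same_fraction,
        icc_threshold=icc_threshold,
    )


@dataclass
class MeanRatings:
    """Stimulus x characteristic mean ratings over retained raters."""

    values: pd.DataFrame  # index stimulus_id, columns characteristics
    n_raters_used: dict[str, int]

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def characteristics(self) -> list[str]:
        return list(self.values.columns)


def mean_ratings(ratings: pd.DataFrame, screen: RaterScreenReport) -> MeanRatings:
    """Per-stimulus means over retained raters; dropped characteristics are
    excluded entirely (exclusions are scale-specific)."""
    _validate_ratings(ratings)
    excl = set(screen.excluded)
    keep_chars = [
        c
        for c in ratings["characteristic"].unique()
        if c not in screen.dropped_characteristics
    ]
    cols = {}
    n_used = {}
    for char in keep_chars:
        grp = ratings[ratings["characteristic"] == char]
        grp = grp[~grp["rater_id"].map(lambda r: (r, char) in excl)]
        if grp["rater_id"].nunique() == 0:
            raise ValueError(f"no raters retained for characteristic {char!r}")
        cols[char] = grp.groupby("stimulus_id")["rating"].mean()
        n_used[char] = int(grp["rater_id"].nunique())
    values = pd.DataFrame(cols)
    return MeanRatings(values=values, n_raters_used=n_used)


def characteristic_correlations(means: MeanRatings) -> pd.DataFrame:
    """Pairwise Spearman correlations between mean-rating profiles.

    Constant columns yield NaN entries (flagged with a warning)."""
    from scipy.stats import spearmanr

    df = means.values
    if len(df) < 3:
        raise ValueError("need at least 3 stimuli")
    consts = [c for c in df.columns if df[c].nunique() == 1]
    if consts:
        warnings.warn(f"constant characteristic columns, correlations undefined: {consts}")
    rho = spearmanr(df.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=df.columns, columns=df.columns)
    for c in consts:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
        out.loc[c, c] = 1.0
    return out


def rating_rdm(means: MeanRatings, characteristic: str) -> RDM:
    """Absolute mean-rating distance between every stimulus pair."""
    if characteristic not in means.values.columns:
        raise KeyError(f"characteristic {characteristic!r} not retained")
    m = means.values[characteristic].to_numpy()
    vals = np.abs(m[:, None] - m[None, :])
    return RDM(
        values=vals, items=means.stimulus_ids, kind="abs_rating_diff", name=characteristic
    )


def behavioral_rdms(means: MeanRatings) -> dict[str, RDM]:
    return {c: rating_rdm(means, c) for c in means.characteristics}
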