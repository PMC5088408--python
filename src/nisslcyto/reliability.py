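"""Inter-rater reliability: coincidence matrix, Krippendorff's alpha,
pairwise percent agreement and disagreement ranking.

For ``N`` units (cells) and ``m`` raters there are ``N * m * (m - 1)``
possible ordered pairs of ratings; pairs are permutations, so every
unordered combination of two ratings of the same unit is counted twice.
The coincidence matrix ``o`` accumulates those ordered pairs per category
pair: two raters agreeing that a cell is a neuron add 2 to the
neuron-neuron diagonal entry, a neuron/astrocyte split adds 1 to each of
the two symmetric off-diagonal entries.  Units rated by fewer than two
raters carry no pairable values and are excluded.

With ``n`` the total pair count and ``n_c`` the category marginals, the
nominal-metric alpha is

    alpha = 1 - (n - 1) * sum_{c != k} o_ck / (n^2 - sum_c n_c^2)
          = 1 - D_o / D_e

with observed disagreement ``D_o = (1/n) sum_{c != k} o_ck`` and expected
chance disagreement ``D_e = (1/(n(n-1))) sum_{c != k} n_c n_k``.  Alpha is 1
for perfect agreement, about 0 for chance-level rating, and can go negative
for systematic disagreement.  When every rating falls in one category
``D_e = 0`` and alpha is undefined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import RATING_LABELS

logger = logging.getLogger(__name__)


class EmptyDataError(ValueError):
    """No pairable data after filtering."""


class UndefinedAlphaError(ZeroDivisionError):
    """Expected disagreement is zero (all ratings in a single category)."""


@dataclass
class RatingsTable:
    """Units x raters categorical ratings with missing entries allowed.

    ``values`` is a DataFrame indexed by unit (cell) id with one column per
    rater; missing ratings are NaN.  ``rater_experience`` maps rater id to
    ``"experienced"``/``"inexperienced"``; ``unit_test`` maps unit id to the
    test it belonged to (``"test1"``/``"test2"``).
    """

    values: pd.DataFrame
    rater_experience: dict = field(default_factory=dict)
    unit_test: dict = field(default_factory=dict)
    categories: tuple = RATING_LABELS

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate unit ids: {list(dupes)}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate rater ids")
        stacked = self.values.stack()
        bad = stacked[~stacked.isin(self.categories)]
        if len(bad):
            unit, rater = bad.index[0]
            raise ValueError(
                f"unknown rating token {bad.iloc[0]!r} "
                f"(unit {unit!r}, rater {rater!r})"
            )

    @property
    def units(self) -> list:
        return list(self.values.index)

    @property
    def raters(self) -> list:
        return list(self.values.columns)

    def select(
        self,
        raters=None,
        experience: str | None = None,
        test: str | None = None,
    ) -> "RatingsTable":
        """Restrict to a rater subset and/or one test's units."""
        df = self.values
        if experience is not None and experience != "all":
            keep = [
                r
                for r in df.columns
                if self.rater_experience.get(r) == experience
            ]
            df = df[keep]
        if raters is not None:
            df = df[[r for r in df.columns if r in set(raters)]]
        if test is not None and test != "all":
            keep_u = [u for u in df.index if self.unit_test.get(u) == test]
            df = df.loc[keep_u]
        return RatingsTable(
            values=df.copy(),
            rater_experience=self.rater_experience,
            unit_test=self.unit_test,
            categories=self.categories,
        )


@dataclass
class CoincidenceMatrix:
    """K x K symmetric count table of pairwise rater categorizations."""

    categories: tuple
    counts: np.ndarray  # float array, K x K
    n_excluded_units: int = 0

    @property
    def n(self) -> float:
        """Total pairable-pair count: sum_u m_u * (m_u - 1)."""
        return float(self.counts.sum())

    @property
    def marginals(self) -> np.ndarray:
        """Per-category marginal pair counts ``n_c``."""
        return self.counts.sum(axis=1)

    @property
    def off_diagonal_total(self) -> float:
        return float(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.categories)
        )


def build_coincidence_matrix(
    ratings: RatingsTable,
    raters=None,
    experience: str | None = None,
    test: str | None = None,
) -> CoincidenceMatrix:
    """Accumulate ordered label pairs of distinct raters per unit.

    For each unit with ``m_u >= 2`` non-missing ratings, every ordered pair
    of distinct raters' labels ``(c, k)`` adds 1 to ``o_ck``; units with
    fewer than two ratings are excluded (and counted in a log line).
    """
    if raters is not None or experience is not None or test is not None:
        ratings = ratings.select(raters=raters, experience=experience, test=test)
    cats = list(ratings.categories)
    K = len(cats)
    code = {c: i for i, c in enumerate(cats)}

    counts = np.zeros((K, K), dtype=float)
    excluded = 0
    for _, row in ratings.values.iterrows():
        vals = row.dropna()
        if len(vals) < 2:
            excluded += 1
            continue
        v = np.zeros(K, dtype=float)
        for lab in vals:
            v[code[lab]] += 1
        counts += np.outer(v, v)
        counts[np.diag_indices(K)] -= v
    if excluded:
        logger.info("excluded %d unit(s) with fewer than 2 ratings", excluded)
    if counts.sum() == 0:
        raise EmptyDataError("no unit with >= 2 pairable ratings after filtering")
    return CoincidenceMatrix(
        categories=tuple(cats), counts=counts, n_excluded_units=excluded
    )


@dataclass
class ReliabilityReport:
    alpha: float
    D_o: float
    D_e: float
    n: float
    coincidence: CoincidenceMatrix
    percent_agreement_mean: float | None = None
    percent_agreement_sem: float | None = None
    disagreement_ranking: list = field(default_factory=list)

    def to_dict(self) -> dict:
        cm = self.coincidence
        return {
            "schema_version": "1",
            "alpha": self.alpha,
            "D_o": self.D_o,
            "D_e": self.D_e,
            "n": self.n,
            "categories": list(cm.categories),
            "coincidence_matrix": cm.counts.tolist(),
            "marginals": cm.marginals.tolist(),
            "excluded_units": cm.n_excluded_units,
            "percent_agreement": {
                "mean": self.percent_agreement_mean,
                "sem": self.percent_agreement_sem,
            },
            "disagreement_ranking": [
                [a, b, count] for (a, b), count in self.disagreement_ranking
            ],
        }


def krippendorff_alpha(coincidence: CoincidenceMatrix) -> ReliabilityReport:
    """Nominal-metric alpha from a coincidence matrix.

    Raises :class:`UndefinedAlphaError` when the expected disagreement is
    zero (fewer than two categories carry marginal mass).
    """
    n = coincidence.n
    if n < 2:
        raise EmptyDataError("need at least one pairable pair (n >= 2)")
    off = coincidence.off_diagonal_total
    n_c = coincidence.marginals
    denom = n * n - float((n_c**2).sum())  # = sum_{c != k} n_c n_k
    D_o = off / n
    D_e = denom / (n * (n - 1.0))
    if D_e <= 0:
        raise UndefinedAlphaError(
            "expected disagreement is zero: all ratings fall in one category"
        )
    alpha = 1.0 - (n - 1.0) * off / denom
    return ReliabilityReport(
        alpha=alpha, D_o=D_o, D_e=D_e, n=n, coincidence=coincidence
    )


def alpha_from_ratings(
    ratings: RatingsTable,
    raters=None,
    experience: str | None = None,
    test: str | None = None,
) -> ReliabilityReport:
    """Coincidence-matrix construction and alpha in one step."""
    cm = build_coincidence_matrix(
        ratings, raters=raters, experience=experience, test=test
    )
    return krippendorff_alpha(cm)


def pairwise_percent_agreement(ratings: RatingsTable) -> tuple[float, float]:
    """Mean and SEM of percent agreement across unordered rater pairs.

    For each rater pair, agreement is the share of co-rated units on which
    both gave the same label (in percent).  Pairs with no co-rated unit are
    skipped; if no pair shares a unit an :class:`EmptyDataError` is raised.
    The SEM is taken across rater pairs and is 0 for a single pair.
    """
    df = ratings.values
    agreements = []
    for a, b in itertools.combinations(df.columns, 2):
        both = df[[a, b]].dropna()
        if len(both) == 0:
            continue
        agreements.append(100.0 * float((both[a] == both[b]).mean()))
    if not agreements:
        raise EmptyDataError("no rater pair shares a co-rated unit")
    arr = np.asarray(agreements, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, sem


def disagreement_ranking(
    coincidence: CoincidenceMatrix, half_counts: bool = False
) -> list[tuple[tuple[str, str], float]]:
    """Off-diagonal unordered category pairs ranked by pair count.

    Each unordered pair is reported with count ``o_ck + o_kc`` (both
    permutations), or ``o_ck`` with ``half_counts=True``, matching the
    convention of quoting each unordered disagreement once.  Zero-count
    pairs are dropped; ties break by canonical category order.
    """
    cats = coincidence.categories
    out = []
    for i, j in itertools.combinations(range(len(cats)), 2):
        count = float(coincidence.counts[i, j] + coincidence.counts[j, i])
        if half_counts:
            count /= 2.0
        if count > 0:
            out.append(((cats[i], cats[j]), count))
    out.sort(key=lambda item: (-item[1], cats.index(item[0][0]), cats.index(item[0][1])))
    return out


def reliability_report(
    ratings: RatingsTable,
    raters=None,
    experience: str | None = None,
    test: str | None = None,
    half_counts: bool = False,
) -> ReliabilityReport:
    """Full report: alpha, percent agreement and disagreement ranking."""
    subset = ratings.select(raters=raters, experience=experience, test=test)
    report = alpha_from_ratings(subset)
    mean, sem = pairwise_percent_agreement(subset)
    report.percent_agreement_mean = mean
    report.percent_agreement_sem = sem
    report.disagreement_ranking = disagreement_ranking(
        report.coincidence, half_counts=half_counts
    )
    return report
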