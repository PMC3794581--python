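"""Best/worst-matching protein cohorts and external score comparison.

From a per-pair correlation set, the top cohort collects the fraction of
proteins with the most negative R (strongest compositional matching, since
preference is a pseudo-energy) and the bottom cohort the most positive.
Externally supplied per-protein scalar scores (e.g. mean predicted disorder)
are then compared between a cohort and the background with a rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .profiles import CorrelationSet


@dataclass(frozen=True)
class Cohort:
    label: str
    side: str  # "top" (best matching, most negative R) | "bottom"
    members: tuple[str, ...]
    fraction: float


@dataclass
class ScoreComparison:
    cohort_mean: float
    cohort_sd: float
    background_mean: float
    background_sd: float
    statistic: float
    p_value: float
    test: str
    n_cohort: int
    n_background: int
    missing_scores: tuple[str, ...] = ()


def extract_cohorts(
    correlations: CorrelationSet | pd.Series,
    fraction: float = 0.10,
    label: str = "",
) -> tuple[Cohort, Cohort]:
    """Deterministic top/bottom cohorts of size floor(fraction * n).

    Pairs are sorted by (R, id); the id tie-break makes membership a pure
    function of the correlation table. Top and bottom are disjoint for any
    fraction <= 0.5.
    """
    r = correlations.r if isinstance(correlations, CorrelationSet) else correlations
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    n = len(r)
    size = math.floor(fraction * n)
    if size < 1:
        raise ValueError(f"{n} pairs is too few for fraction {fraction}")
    order = r.to_frame("R").reset_index(names="id").sort_values(["R", "id"])
    ids = order["id"].tolist()
    top = Cohort(label, "top", tuple(ids[:size]), fraction)
    bottom = Cohort(label, "bottom", tuple(ids[-size:]), fraction)
    return top, bottom


def compare_scores(
    cohort: Cohort,
    scores: Mapping[str, float] | pd.Series,
    test: str = "ranksum",
) -> ScoreComparison:
    """Compare cohort scores against the background of all scored proteins.

    ``ranksum`` runs the two-sided Mann-Whitney rank-sum test of cohort
    versus non-cohort scores; ``signedrank`` runs the one-sample Wilcoxon
    signed-rank test of cohort scores against the background mean. Cohort
    members without a score are logged, never silently dropped.
    """
    if test not in ("ranksum", "signedrank"):
        raise ValueError("test must be 'ranksum' or 'signedrank'")
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    scores = scores.astype(float)
    member_set = set(cohort.members)
    missing = tuple(sorted(member_set - set(scores.index)))
    cohort_scores = scores.reindex([m for m in cohort.members if m in scores.index])
    if len(cohort_scores) < 2:
        raise ValueError("fewer than two scored cohort members")
    background = scores  # the entire scored set, cohort included
    rest = scores.drop(index=cohort_scores.index)
    if len(rest) == 0:
        raise ValueError("cohort covers every scored protein; no comparison possible")

    if test == "ranksum":
        statistic, p = stats.mannwhitneyu(
            cohort_scores, rest, alternative="two-sided"
        )
    else:
        diffs = cohort_scores - background.mean()
        statistic, p = stats.wilcoxon(diffs)

    return ScoreComparison(
        cohort_mean=float(cohort_scores.mean()),
        cohort_sd=float(cohort_scores.std(ddof=0)),
        background_mean=float(background.mean()),
        background_sd=float(background.std(ddof=0)),
        statistic=float(statistic),
        p_value=float(p),
        test=test,
        n_cohort=len(cohort_scores),
        n_background=len(background),
        missing_scores=missing,
    )


def load_scores_tsv(path) -> pd.Series:
    """Read an (id, score) two-column TSV into a Series."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError("scores TSV needs at least two columns: id, score")
    return frame.set_index(frame.columns[0])[frame.columns[1]].astype(float)
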