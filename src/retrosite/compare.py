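"""Pairwise two-sided Fisher's exact tests between datasets.

Every comparison is a 2x2 table: sites in-category vs not, for each of two
datasets. The two-sided p-value is the sum of point probabilities of all
tables (with the observed margins) no more likely than the observed one —
the standard convention. Significance defaults to p < 0.01, with no
multiple-testing correction (an optional Bonferroni flag is provided).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 test: (a, b) = dataset-1 in/out of category, (c, d) = dataset-2."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    significant: bool


def fisher_two_sided(a: int, b: int, c: int, d: int, alpha: float = 0.01) -> ContingencyResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The sample odds ratio (a*d)/(b*c) is reported, with 0 and inf for
    tables containing zeros (nan when doubly degenerate). Both margins
    must be positive.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ValueError("zero margin: each dataset needs at least one site")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=odds,
        p_two_sided=float(p),
        significant=bool(p < alpha),
    )


def compare_proportions(
    count1: int, total1: int, count2: int, total2: int, alpha: float = 0.01
) -> ContingencyResult:
    """Fisher test of count1/total1 vs count2/total2."""
    return fisher_two_sided(
        count1, total1 - count1, count2, total2 - count2, alpha=alpha
    )


def counts_from_percent(percent: float, total: int) -> int:
    """Reconstruct an integer count from a printed percentage of a total."""
    return round(percent * total / 100.0)


def compare_categories(
    datasets: Mapping[str, Mapping[str, int]],
    categories: Sequence[str],
    totals: Mapping[str, int],
    alpha: float = 0.01,
    bonferroni: bool = False,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """All pairwise Fisher tests per category between dataset summaries.

    ``datasets`` maps label -> {category: count}; ``totals`` gives each
    dataset's size. A star column marks p below alpha (Bonferroni-divided
    across performed tests when requested). Categories missing from a
    dataset produce no row (logged).
    """
    labels = list(datasets)
    if pairs is None:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    rows = []
    for d1, d2 in pairs:
        for cat in categories:
            if cat not in datasets[d1] or cat not in datasets[d2]:
                logger.warning("category %r missing for pair (%s, %s)", cat, d1, d2)
                continue
            res = compare_proportions(
                datasets[d1][cat], totals[d1], datasets[d2][cat], totals[d2], alpha
            )
            rows.append(
                {
                    "dataset_1": d1,
                    "dataset_2": d2,
                    "category": cat,
                    "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_two_sided,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        threshold = alpha / len(df) if bonferroni else alpha
        df["star"] = df["p"] < threshold
    return df
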