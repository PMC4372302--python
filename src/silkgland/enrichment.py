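"""Chi-square GO-term enrichment of a target gene set vs a background.

For each term, a 2x2 Pearson chi-square (no continuity correction) on
(annotated, not annotated) x (target, background). The background must
exclude target genes: the comparison is between two disjoint lists.
No multiple-testing correction is applied by default (raw chi-square
p-values, the classical two-list comparison); a BH option is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from silkgland.family_expression import bh_fdr


@dataclass
class EnrichmentRow:
    term: str
    count_target: int
    size_target: int
    count_background: int
    size_background: int
    chi2: float
    p: float
    low_expected: bool = False
    term_class: str | None = None


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Pearson chi-square for the table [[a, b], [c, d]], 1 df.

    Returns (statistic, p, low-expected flag); degenerate margins give
    (0, 1).
    """
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    return float(stat), float(stats.chi2.sf(stat, 1)), expected_min < 5


def chisq_enrichment(
    target: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    term_classes: dict[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Per-term enrichment of ``target`` against a disjoint
    ``background``; rows sorted by ascending p (ties by term id).

    ``annotations`` maps gene -> set of term ids; genes without
    annotation simply count as unannotated for every term.
    """
    if not target or not background:
        raise ValueError("both gene sets must be non-empty")
    overlap = target & background
    if overlap:
        raise ValueError(
            f"target and background overlap ({len(overlap)} genes); "
            "sets must be disjoint"
        )
    terms: set[str] = set()
    for gene in target | background:
        terms |= annotations.get(gene, set())
    size_t, size_b = len(target), len(background)
    rows: list[EnrichmentRow] = []
    for term in sorted(terms):
        count_t = sum(1 for g in target if term in annotations.get(g, ()))
        count_b = sum(1 for g in background if term in annotations.get(g, ()))
        stat, p, low = pearson_chi2_2x2(
            count_t, size_t - count_t, count_b, size_b - count_b
        )
        rows.append(
            EnrichmentRow(
                term=term,
                count_target=count_t,
                size_target=size_t,
                count_background=count_b,
                size_background=size_b,
                chi2=stat,
                p=p,
                low_expected=low,
                term_class=(term_classes or {}).get(term),
            )
        )
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def enrichment_report(
    rows: list[EnrichmentRow],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Tabulate enrichment rows at significance level ``alpha``.

    With ``adjust=True`` the filter applies to BH-adjusted p-values
    (added as an ``fdr`` column). Rows are grouped by term class when
    class metadata is present.
    """
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "class", "count_target", "size_target",
                "count_background", "size_background", "chi2", "p",
                "low_expected",
            ]
        )
    frame = pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "class": [r.term_class or "" for r in rows],
            "count_target": [r.count_target for r in rows],
            "size_target": [r.size_target for r in rows],
            "count_background": [r.count_background for r in rows],
            "size_background": [r.size_background for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p": [r.p for r in rows],
            "low_expected": [r.low_expected for r in rows],
        }
    )
    if adjust:
        frame["fdr"] = bh_fdr(frame["p"].to_numpy())
        frame = frame[frame["fdr"] < alpha]
    else:
        frame = frame[frame["p"] < alpha]
    return frame.sort_values(["class", "p", "term"]).reset_index(drop=True)
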