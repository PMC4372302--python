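"""Family-level expression comparison between cocoon-color groups.

Transcript and gene-family RPKM, group-specific family calls,
phylogenetic trait filtering via independent contrasts, and a negative-
binomial exact test for differential family expression with common
dispersion estimated by conditional maximum likelihood and BH FDR
control. Species act as replicates within each group: the study design
has one silk-gland library per species and no biological replicates,
so group membership is the only replication available (a documented
caveat, not a statistical free lunch).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from silkgland.phylo_tools import pic_correlation


@dataclass
class DEResult:
    family: str
    log2_fold_change: float
    p: float
    fdr: float


def transcript_rpkm(reads: float, length: float, library: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length <= 0 or library <= 0:
        raise ValueError("length and library size must be positive")
    return reads / ((length / 1000.0) * (library / 1e6))


def family_rpkm(
    member_reads: np.ndarray | list[float],
    member_lengths: np.ndarray | list[float],
    library: float,
) -> float:
    """Family RPKM: total member reads per kilobase of total member
    transcript length per million mapped reads; 0 with no members."""
    reads = np.asarray(member_reads, dtype=float)
    lengths = np.asarray(member_lengths, dtype=float)
    if reads.size == 0:
        return 0.0
    if library <= 0 or np.any(lengths <= 0):
        raise ValueError("lengths and library size must be positive")
    return float(reads.sum() / ((lengths.sum() / 1000.0) * (library / 1e6)))


def family_expression_matrix(
    families: pd.DataFrame, expr: pd.DataFrame
) -> pd.DataFrame:
    """Family x species RPKM matrix.

    ``families`` has columns (family, species, transcript); ``expr``
    has (transcript, species, length, reads, library_size). Families
    with no members in a species get RPKM 0.
    """
    merged = families.merge(expr, on=["transcript", "species"], how="left")
    if merged["reads"].isna().any():
        missing = merged.loc[merged["reads"].isna(), "transcript"].tolist()[:5]
        raise ValueError(f"transcripts missing from expression table: {missing}")
    libs = expr.drop_duplicates("species").set_index("species")["library_size"]
    species = sorted(expr["species"].unique())
    fam_ids = list(dict.fromkeys(families["family"]))
    out = pd.DataFrame(0.0, index=fam_ids, columns=species)
    for (fam, sp), grp in merged.groupby(["family", "species"], sort=False):
        out.loc[fam, sp] = family_rpkm(
            grp["reads"].to_numpy(), grp["length"].to_numpy(), float(libs[sp])
        )
    out.index.name = "family"
    return out


def family_count_matrix(families: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Family x species total read counts (for the exact test)."""
    merged = families.merge(expr, on=["transcript", "species"], how="left")
    counts = (
        merged.pivot_table(
            index="family", columns="species", values="reads",
            aggfunc="sum", fill_value=0,
        )
        .astype(float)
    )
    counts.index.name = "family"
    return counts


def group_specific_families(
    famexpr: pd.DataFrame,
    groups: dict[str, str],
    presence_min: float = 1.0,
) -> dict[str, set[str]]:
    """Families expressed in every species of one group and in none of
    the other (RPKM threshold ``presence_min``)."""
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    members = {g: [s for s, gg in groups.items() if gg == g] for g in names}
    if any(not m for m in members.values()):
        raise ValueError("both groups must be non-empty")
    out: dict[str, set[str]] = {g: set() for g in names}
    for fam, row in famexpr.iterrows():
        for g in names:
            other = names[1 - names.index(g)]
            if all(row[s] >= presence_min for s in members[g]) and all(
                row[s] < presence_min for s in members[other]
            ):
                out[g].add(fam)
    return out


def trait_filter(
    famexpr: pd.DataFrame,
    tree: dendropy.Tree,
    trait: dict[str, float],
    alpha: float = 0.05,
    families: set[str] | None = None,
    positive_only: bool = False,
) -> tuple[set[str], set[str]]:
    """Phylogenetic filter: keep families whose per-species RPKM shows a
    significant PIC correlation with the trait.

    Returns (retained, excluded). Families with constant RPKM produce
    zero contrasts and are excluded (flagged internally with p = 1).
    With ``positive_only``, negative correlations are excluded too.
    """
    candidates = set(famexpr.index) if families is None else set(families)
    retained: set[str] = set()
    excluded: set[str] = set()
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    for fam in sorted(candidates):
        rpkm = {s: float(famexpr.loc[fam, s]) for s in famexpr.columns if s in leaf_labels}
        result = pic_correlation(tree, rpkm, trait)
        keep = result.p < alpha and not result.zero_variance
        if positive_only and result.r < 0:
            keep = False
        (retained if keep else excluded).add(fam)
    return retained, excluded


def _log_nb_conditional(counts: np.ndarray, r_per_rep: float) -> float:
    """Log conditional likelihood of NB replicate counts given their sum
    (equal effective library sizes), dispersion 1/r_per_rep."""
    n = counts.size
    s = counts.sum()
    return float(
        special.gammaln(counts + r_per_rep).sum()
        - n * special.gammaln(r_per_rep)
        + special.gammaln(n * r_per_rep)
        - special.gammaln(s + n * r_per_rep)
        + special.gammaln(s + 1)
        - special.gammaln(counts + 1).sum()
    )


def estimate_common_dispersion(
    counts: pd.DataFrame | np.ndarray,
    groups: dict[str, str] | list[str],
    phi_max: float = 5.0,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Sums, over families and over both groups, the likelihood of the
    replicate counts conditional on the group total (which does not
    depend on the mean when effective library sizes are equal), then
    maximizes over phi on a log grid refined by bounded scalar search.
    """
    if isinstance(counts, pd.DataFrame):
        cols = list(counts.columns)
        mat = counts.to_numpy(dtype=float)
        labels = [groups[c] for c in cols] if isinstance(groups, dict) else list(groups)
    else:
        mat = np.asarray(counts, dtype=float)
        labels = list(groups)
    names = sorted(set(labels))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    group_cols = {g: [i for i, l in enumerate(labels) if l == g] for g in names}
    if any(len(ix) < 2 for ix in group_cols.values()):
        raise ValueError("need >= 2 replicates (species) per group")
    mat = np.round(mat)
    if np.allclose(mat, mat[:, :1]):
        return 0.0

    def neg_cl(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for g in names:
            sub = mat[:, group_cols[g]]
            n = sub.shape[1]
            total += (
                special.gammaln(sub + r).sum()
                - sub.shape[0] * n * special.gammaln(r)
                + sub.shape[0] * special.gammaln(n * r)
                - special.gammaln(sub.sum(axis=1) + n * r).sum()
            )
        return -total

    grid = np.log(np.geomspace(1e-4, phi_max, 40))
    values = [neg_cl(x) for x in grid]
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_cl, bounds=(lo, hi), method="bounded")
    phi_hat = float(np.exp(res.x))
    # if the likelihood is still rising at the smallest grid value the
    # data are effectively Poisson
    if best == 0 and values[0] <= min(values[1:]):
        return float(np.exp(grid[0]))
    return phi_hat


def nb_exact_test(
    counts_a: np.ndarray | list[float],
    counts_b: np.ndarray | list[float],
    dispersion: float,
) -> float:
    """Two-sided exact test of equal means for two NB count groups.

    Group sums are NB with shape n_g/phi and a common success
    probability under the null, so the sum of group A conditional on
    the grand total follows a negative hypergeometric law free of the
    unknown mean. The two-sided p doubles the smaller tail (observed
    value included), capped at 1. With phi = 0 the conditional law is
    binomial (Poisson counts). Expects library-size-normalized
    pseudo-counts.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ya, yb = float(np.round(a.sum())), float(np.round(b.sum()))
    s = int(ya + yb)
    if s == 0:
        return 1.0
    na, nb_ = a.size, b.size
    support = np.arange(s + 1)
    if dispersion == 0:
        logpmf = stats.binom.logpmf(support, s, na / (na + nb_))
    else:
        ra, rb = na / dispersion, nb_ / dispersion
        logpmf = (
            special.gammaln(support + ra)
            - special.gammaln(support + 1)
            - special.gammaln(ra)
            + special.gammaln(s - support + rb)
            - special.gammaln(s - support + 1)
            - special.gammaln(rb)
        )
        logpmf -= special.logsumexp(logpmf)
    pmf = np.exp(logpmf - special.logsumexp(logpmf))
    k = int(ya)
    lower = pmf[: k + 1].sum()
    upper = pmf[k:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def normalize_counts(counts: pd.DataFrame, library_sizes: dict[str, float]) -> pd.DataFrame:
    """Scale species columns to the geometric-mean library size."""
    libs = np.array([library_sizes[c] for c in counts.columns], dtype=float)
    ref = float(np.exp(np.mean(np.log(libs))))
    return counts * (ref / libs)


def de_families(
    counts: pd.DataFrame,
    groups: dict[str, str],
    library_sizes: dict[str, float] | None = None,
    alpha_fdr: float = 0.05,
    dispersion: float | None = None,
) -> list[DEResult]:
    """Differential family expression between the two groups.

    Library-normalizes family counts, estimates a common dispersion by
    conditional ML unless supplied, applies the NB exact test per
    family, and BH-adjusts. Families with ``fdr < alpha_fdr`` are the
    significant set; log2 fold changes use a 0.5 pseudo-count.
    """
    if library_sizes is not None:
        counts = normalize_counts(counts, library_sizes)
    names = sorted(set(groups.values()))
    cols = {g: [c for c in counts.columns if groups.get(c) == g] for g in names}
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, groups)
    pvals = []
    lfc = []
    fams = list(counts.index)
    for fam in fams:
        row = counts.loc[fam]
        a = row[cols[names[0]]].to_numpy(dtype=float)
        b = row[cols[names[1]]].to_numpy(dtype=float)
        pvals.append(nb_exact_test(a, b, dispersion))
        lfc.append(float(np.log2((a.mean() + 0.5) / (b.mean() + 0.5))))
    fdr = bh_fdr(pvals)
    results = [
        DEResult(family=f, log2_fold_change=l, p=p, fdr=q)
        for f, l, p, q in zip(fams, lfc, pvals, fdr)
    ]
    return results


def significant_families(results: list[DEResult], alpha_fdr: float = 0.05) -> set[str]:
    return {r.family for r in results if r.fdr < alpha_fdr}
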