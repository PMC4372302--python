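"""Codon-level molecular evolution: NG86 counting and codon-model ML.

Implements the Nei-Gojobori (1986) pairwise dN/dS estimator with
Jukes-Cantor correction, and maximum-likelihood fitting of a
Goldman-Yang-style codon substitution model on a fixed tree under either
a single dN/dS ratio shared by all branches ("one-ratio") or one ratio
per branch ("free-ratio"), compared by a likelihood-ratio test.

The rate matrix acts on the 61 sense codons of the standard genetic
code: substitutions changing more than one position have rate zero, and
a single-position change i->j has rate

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

scaled so branch lengths are expected substitutions per codon. Codon
frequencies ``pi`` are uniform over the 61 sense codons or F3x4
(empirical positional nucleotide frequencies) computed from the
alignment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("silkgland.codon_evol")

NUCS = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard genetic code, codon -> one-letter amino acid ('*' = stop).
_BASES_BY_INDEX = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = dict(zip(_BASES_BY_INDEX, _AA_ORDER))
SENSE_CODONS = tuple(c for c in _BASES_BY_INDEX if GENETIC_CODE[c] != "*")
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


class CodonAlignmentError(ValueError):
    """The supplied sequences are not a valid in-frame codon alignment."""


@dataclass
class CodonAlignment:
    """An in-frame multi-taxon coding-nucleotide alignment.

    Gaps, when present, must occupy whole codons; internal stop codons
    are rejected. Column-wise complete deletion of gapped codon sites is
    applied by :meth:`without_gaps` before likelihood work.
    """

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise CodonAlignmentError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise CodonAlignmentError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise CodonAlignmentError("rows have unequal lengths")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise CodonAlignmentError("alignment length not divisible by 3")
        for taxon, row in zip(self.taxa, self.rows):
            for i in range(0, length, 3):
                codon = row[i : i + 3]
                if "-" in codon:
                    if codon != "---":
                        raise CodonAlignmentError(
                            f"{taxon}: partial-codon gap at nucleotide {i}"
                        )
                elif GENETIC_CODE.get(codon) == "*":
                    raise CodonAlignmentError(
                        f"{taxon}: internal stop codon {codon} at nucleotide {i}"
                    )
                elif codon not in GENETIC_CODE:
                    raise CodonAlignmentError(
                        f"{taxon}: unrecognized codon {codon!r} at nucleotide {i}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_column(self, site: int) -> list[str]:
        return [row[3 * site : 3 * site + 3] for row in self.rows]

    def without_gaps(self) -> "CodonAlignment":
        """Drop every codon column containing a gap in any row."""
        keep = [
            s for s in range(self.n_codons)
            if all("-" not in codon for codon in self.codon_column(s))
        ]
        rows = [
            "".join(row[3 * s : 3 * s + 3] for s in keep) for row in self.rows
        ]
        return CodonAlignment(taxa=list(self.taxa), rows=rows)

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_sites) array of sense-codon indices (gap-free only)."""
        out = np.empty((len(self.rows), self.n_codons), dtype=np.int64)
        for i, row in enumerate(self.rows):
            for s in range(self.n_codons):
                codon = row[3 * s : 3 * s + 3]
                if codon not in CODON_INDEX:
                    raise CodonAlignmentError(f"gap or stop codon at row {i}, site {s}")
                out[i, s] = CODON_INDEX[codon]
        return out


@dataclass
class CodonEvolResult:
    omega: float
    kappa: float
    branch_lengths: dict[str, float]
    lnL: float
    per_branch_omega: dict[str, float] | None = None
    converged: bool = True
    n_sites: int = 0


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# NG86 pairwise counting
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three single-base changes at ``pos`` that are
    synonymous; changes creating stop codons are excluded from the
    numerator and denominator (position still counts as one site)."""
    aa = GENETIC_CODE[codon]
    syn = 0
    total = 0
    for nuc in NUCS:
        if nuc == codon[pos]:
            continue
        alt = codon[:pos] + nuc + codon[pos + 1 :]
        if GENETIC_CODE[alt] == "*":
            continue
        total += 1
        if GENETIC_CODE[alt] == aa:
            syn += 1
    if total == 0:
        return 0.0
    return syn / total


def syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (NG86 convention; the
    three positions contribute one site each)."""
    return sum(_syn_fraction(codon, pos) for pos in range(3))


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous differences between two codons,
    averaged over all minimal mutational pathways not passing through a
    stop codon (all pathways if every one is blocked)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else paths).append((sd, nd))
    pool = paths or blocked
    sd = float(np.mean([p[0] for p in pool]))
    nd = float(np.mean([p[1] for p in pool]))
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differences."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: distance saturated")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(codons_a: str, codons_b: str) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) pairwise dN, dS and their ratio.

    Site counts are averaged over the two sequences; multi-hit codons
    average over all minimal mutational pathways; Jukes-Cantor corrects
    for multiple substitutions. ``omega`` is ``None`` when dS = 0.
    """
    if len(codons_a) != len(codons_b):
        raise CodonAlignmentError("sequences differ in length")
    if len(codons_a) % 3 != 0:
        raise CodonAlignmentError("length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(codons_a), 3):
        ca, cb = codons_a[i : i + 3], codons_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        for codon in (ca, cb):
            if GENETIC_CODE.get(codon, "*") == "*":
                raise CodonAlignmentError(f"stop or invalid codon {codon!r}")
        s_here = 0.5 * (syn_sites(ca) + syn_sites(cb))
        S += s_here
        N += 3.0 - s_here
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS > 0 else None
    return dN, dS, omega


# ---------------------------------------------------------------------------
# Goldman-Yang one-ratio machinery
# ---------------------------------------------------------------------------

def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies: product of positional nucleotide
    frequencies, renormalized over sense codons."""
    pos_counts = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(NUCS)}
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if "-" in codon:
                continue
            for pos in range(3):
                pos_counts[pos, nuc_index[codon[pos]]] += 1
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, nuc_index[c[0]]]
            * pos_freqs[1, nuc_index[c[1]]]
            * pos_freqs[2, nuc_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise CodonAlignmentError("degenerate F3x4 frequencies")
    return freqs / total


def _single_change_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61, 61) masks: single-position change, transition,
    nonsynonymous. Computed once at import."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            k = diffs[0]
            ts[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return single, ts, nonsyn


_SINGLE, _TS, _NONSYN = _single_change_masks()


def gy94_rate_matrix(
    omega: float, kappa: float, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Scaled one-ratio codon rate matrix (rows sum to zero, mean rate 1)."""
    if omega <= 0 or kappa <= 0:
        raise ValueError("omega and kappa must be positive")
    pi = uniform_codon_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_SINGLE] = 1.0
    Q[_TS] *= kappa
    Q[_NONSYN] *= omega
    Q *= pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


class _CodonModel:
    """Eigendecomposition cache for one (omega-vector, kappa, pi).

    The GY94 matrix is reversible, so D^{1/2} Q D^{-1/2} is symmetric
    and P(t) for every branch comes from a single ``eigh`` call.
    """

    def __init__(self, omega: float, kappa: float, pi: np.ndarray):
        Q = gy94_rate_matrix(omega, kappa, pi)
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((S + S.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None] * 1.0  # D^{-1/2} V
        self._right = (evecs * sqrt_pi[:, None]).T  # V^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def _compress_patterns(codon_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns; returns (patterns, weights)."""
    cols, counts = np.unique(codon_idx.T, axis=0, return_counts=True)
    return cols.T, counts.astype(float)


def _edge_key(node: dendropy.Node) -> str:
    """Stable branch identifier: sorted leaf set below the node."""
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "|".join(leaves)


def _tree_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Non-root nodes in a stable postorder (each owns its parent edge)."""
    return [n for n in tree.postorder_node_iter() if n.parent_node is not None]


def _pruning_loglik(
    tree: dendropy.Tree,
    patterns: np.ndarray,
    weights: np.ndarray,
    taxon_row: dict[str, int],
    pi: np.ndarray,
    P_by_node: dict[int, np.ndarray],
) -> float:
    """Felsenstein pruning over the 61-codon state space."""
    n_sites = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = taxon_row[node.taxon.label]
            part = np.zeros((n_sites, N_CODONS))
            part[np.arange(n_sites), patterns[row]] = 1.0
        else:
            part = np.ones((n_sites, N_CODONS))
            for child in node.child_nodes():
                P = P_by_node[id(child)]
                part *= partials.pop(id(child)) @ P.T
            # rescale per site to avoid underflow on deep trees
            mx = part.max(axis=1, keepdims=True)
            if np.any(mx == 0):
                return -np.inf
            part /= mx
            logscale += np.log(mx[:, 0])
        partials[id(node)] = part
    site_lik = partials[id(tree.seed_node)] @ pi
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.sum(weights * (np.log(site_lik) + logscale)))


def m0_loglik(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    omega: float,
    kappa: float,
    freqs: np.ndarray | None = None,
    branch_lengths: dict[str, float] | None = None,
) -> float:
    """One-ratio log-likelihood at given parameters on a fixed tree.

    Branch lengths are taken from the tree unless overridden via
    ``branch_lengths`` keyed by :func:`_edge_key`.
    """
    aln = aln.without_gaps()
    pi = uniform_codon_freqs() if freqs is None else np.asarray(freqs, float)
    taxa = set(aln.taxa)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if taxa != leaves:
        raise ValueError(f"tree leaves {sorted(leaves)} != alignment taxa {sorted(taxa)}")
    model = _CodonModel(omega, kappa, pi)
    edges = _tree_edges(tree)
    P_by_node = {}
    for node in edges:
        key = _edge_key(node)
        if branch_lengths is not None:
            t = branch_lengths[key]
        else:
            t = node.edge.length
            if t is None:
                raise ValueError(f"branch {key} has no length")
        P_by_node[id(node)] = model.transition_matrix(max(t, 0.0))
    patterns, weights = _compress_patterns(aln.codon_indices())
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    return _pruning_loglik(tree, patterns, weights, taxon_row, pi, P_by_node)


def _initial_branch_lengths(
    aln: CodonAlignment, tree: dendropy.Tree
) -> dict[str, float]:
    """Least-squares branch lengths from NG86-derived pairwise distances."""
    taxa = aln.taxa
    seq = dict(zip(aln.taxa, aln.rows))
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    dist = np.zeros(len(pairs))
    for k, (i, j) in enumerate(pairs):
        try:
            dN, dS, _ = ng86_pair(seq[taxa[i]], seq[taxa[j]])
            # total divergence in substitutions/codon, roughly 3 * per-site
            dist[k] = 3.0 * (0.25 * dS + 0.75 * dN)
        except ValueError:
            dist[k] = 1.0
    edges = _tree_edges(tree)
    # indicator matrix: which branches lie on the path between each leaf pair
    leaf_sets = {id(n): {l.taxon.label for l in n.leaf_iter()} for n in edges}
    A = np.zeros((len(pairs), len(edges)))
    for k, (i, j) in enumerate(pairs):
        for e, node in enumerate(edges):
            below = leaf_sets[id(node)]
            if (taxa[i] in below) != (taxa[j] in below):
                A[k, e] = 1.0
    lengths, _ = optimize.nnls(A, dist)
    return {
        _edge_key(node): max(float(b), 1e-4) for node, b in zip(edges, lengths)
    }


@dataclass
class _FitSetup:
    aln: CodonAlignment
    tree: dendropy.Tree
    pi: np.ndarray
    edges: list
    edge_keys: list[str]
    patterns: np.ndarray
    weights: np.ndarray
    taxon_row: dict[str, int]


def _prepare_fit(aln, tree, freqs) -> _FitSetup:
    aln = aln.without_gaps()
    if len(aln.taxa) < 2:
        raise ValueError("need at least two taxa")
    if freqs is None:
        pi = f3x4_frequencies(aln)
    elif isinstance(freqs, str) and freqs == "uniform":
        pi = uniform_codon_freqs()
    else:
        pi = np.asarray(freqs, float)
    edges = _tree_edges(tree)
    patterns, weights = _compress_patterns(aln.codon_indices())
    return _FitSetup(
        aln=aln,
        tree=tree,
        pi=pi,
        edges=edges,
        edge_keys=[_edge_key(n) for n in edges],
        patterns=patterns,
        weights=weights,
        taxon_row={t: i for i, t in enumerate(aln.taxa)},
    )


_OMEGA_BOUNDS = (1e-4, 10.0)
_KAPPA_BOUNDS = (1e-2, 50.0)
_BRANCH_BOUNDS = (1e-6, 20.0)


def fit_one_ratio(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    freqs: np.ndarray | str | None = None,
    max_iter: int = 500,
) -> CodonEvolResult:
    """Maximize the one-ratio likelihood over (omega, kappa, branch lengths).

    Deterministic bounded L-BFGS-B from fixed initials (omega 0.4,
    kappa 2, branch lengths from NG86 least squares). ``freqs`` may be
    an explicit vector, ``"uniform"``, or None for F3x4 from the data.
    """
    setup = _prepare_fit(aln, tree, freqs)
    b0 = _initial_branch_lengths(setup.aln, tree)
    x0 = np.concatenate([[0.4, 2.0], [b0[k] for k in setup.edge_keys]])
    bounds = [_OMEGA_BOUNDS, _KAPPA_BOUNDS] + [_BRANCH_BOUNDS] * len(setup.edges)

    def negloglik(x: np.ndarray) -> float:
        model = _CodonModel(x[0], x[1], setup.pi)
        P_by_node = {
            id(node): model.transition_matrix(t)
            for node, t in zip(setup.edges, x[2:])
        }
        ll = _pruning_loglik(
            setup.tree, setup.patterns, setup.weights, setup.taxon_row,
            setup.pi, P_by_node,
        )
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter},
    )
    result = CodonEvolResult(
        omega=float(res.x[0]),
        kappa=float(res.x[1]),
        branch_lengths=dict(zip(setup.edge_keys, map(float, res.x[2:]))),
        lnL=float(-res.fun),
        converged=bool(res.success),
        n_sites=setup.aln.n_codons,
    )
    if not res.success and res.nit >= max_iter:
        exc = RuntimeError(f"one-ratio fit did not converge: {res.message}")
        exc.best_so_far = result  # type: ignore[attr-defined]
        raise exc
    return result


def fit_free_ratio(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    freqs: np.ndarray | str | None = None,
    max_iter: int = 1000,
) -> CodonEvolResult:
    """Per-branch-omega fit; otherwise as :func:`fit_one_ratio`."""
    setup = _prepare_fit(aln, tree, freqs)
    b0 = _initial_branch_lengths(setup.aln, tree)
    nb = len(setup.edges)
    x0 = np.concatenate([[2.0], [b0[k] for k in setup.edge_keys], [0.4] * nb])
    bounds = [_KAPPA_BOUNDS] + [_BRANCH_BOUNDS] * nb + [_OMEGA_BOUNDS] * nb

    def negloglik(x: np.ndarray) -> float:
        kappa = x[0]
        lengths = x[1 : 1 + nb]
        omegas = x[1 + nb :]
        models: dict[float, _CodonModel] = {}
        P_by_node = {}
        for node, t, w in zip(setup.edges, lengths, omegas):
            key = float(w)
            if key not in models:
                models[key] = _CodonModel(key, kappa, setup.pi)
            P_by_node[id(node)] = models[key].transition_matrix(t)
        ll = _pruning_loglik(
            setup.tree, setup.patterns, setup.weights, setup.taxon_row,
            setup.pi, P_by_node,
        )
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter},
    )
    omegas = dict(zip(setup.edge_keys, map(float, res.x[1 + nb :])))
    result = CodonEvolResult(
        omega=float(np.mean(res.x[1 + nb :])),
        kappa=float(res.x[0]),
        branch_lengths=dict(zip(setup.edge_keys, map(float, res.x[1 : 1 + nb]))),
        lnL=float(-res.fun),
        per_branch_omega=omegas,
        converged=bool(res.success),
        n_sites=setup.aln.n_codons,
    )
    if not res.success and res.nit >= max_iter:
        exc = RuntimeError(f"free-ratio fit did not converge: {res.message}")
        exc.best_so_far = result  # type: ignore[attr-defined]
        raise exc
    return result


def lrt(lnL0: float, lnL1: float, df: int) -> LRTResult:
    """Likelihood-ratio test of nested models (chi-square upper tail)."""
    if df <= 0:
        raise ValueError("df must be positive")
    if lnL1 < lnL0 - 1e-6:
        raise ValueError("alternative log-likelihood below null beyond tolerance")
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return LRTResult(stat=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def lrt_free_vs_one(
    aln: CodonAlignment, tree: dendropy.Tree, freqs=None
) -> tuple[CodonEvolResult, CodonEvolResult, LRTResult]:
    """Fit both branch models and test them; df = (#branches - 1)."""
    one = fit_one_ratio(aln, tree, freqs=freqs)
    free = fit_free_ratio(aln, tree, freqs=freqs)
    df = len(_tree_edges(tree)) - 1
    return one, free, lrt(one.lnL, free.lnL, df)
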