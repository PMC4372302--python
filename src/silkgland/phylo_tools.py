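"""Tree construction and tree-aware statistics.

Neighbor-joining from Tajima-Nei or p-distances, Felsenstein's
phylogenetically independent contrasts (PIC) with origin-constrained
correlation, and parsimony gene-tree/species-tree reconciliation by LCA
mapping with per-node duplication and loss counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from silkgland.io_formats import SequenceSet


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")


@dataclass
class ContrastResult:
    contrasts: list[float]
    r: float = float("nan")
    p: float = float("nan")
    node_values: list[float] = field(default_factory=list)
    zero_variance: bool = False


@dataclass
class ReconciliationSummary:
    """Per species-tree node duplication/loss counts plus the LCA map."""

    duplications: dict[str, int]
    losses: dict[str, int]
    mapping: dict[str, str]  # gene node key -> species node key

    @property
    def total_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_GAPS = frozenset("-NX?")


def _ungapped_pair(a: str, b: str) -> tuple[str, str]:
    keep = [(x, y) for x, y in zip(a, b) if x not in _GAPS and y not in _GAPS]
    if not keep:
        raise ValueError("no comparable sites after gap removal")
    return "".join(x for x, _ in keep), "".join(y for _, y in keep)


def p_distance(a: str, b: str) -> float:
    a, b = _ungapped_pair(a, b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


def tajima_nei_distance(a: str, b: str) -> float:
    """Tajima-Nei (1984) distance for unequal base frequencies.

    d = -b ln(1 - p/b) with b = (1 - sum g_i^2 + p^2/h)/2 and
    h = sum_{i<j} x_ij^2 / (2 g_i g_j), where g are mean nucleotide
    frequencies over both sequences and x_ij the fraction of sites
    pairing nucleotide i with j.
    """
    a, b_seq = _ungapped_pair(a, b)
    n = len(a)
    nucs = "ACGT"
    counts = {nuc: (a.count(nuc) + b_seq.count(nuc)) / (2 * n) for nuc in nucs}
    p = sum(x != y for x, y in zip(a, b_seq)) / n
    if p == 0:
        return 0.0
    h = 0.0
    for i, j in itertools.combinations(nucs, 2):
        x_ij = sum(
            1 for x, y in zip(a, b_seq) if {x, y} == {i, j}
        ) / n
        gi, gj = counts[i], counts[j]
        if x_ij > 0 and (gi == 0 or gj == 0):
            raise ValueError("inconsistent frequencies")
        if gi > 0 and gj > 0:
            h += x_ij**2 / (2.0 * gi * gj)
    if h <= 0:
        raise ValueError("degenerate pair: h = 0 with p > 0")
    b_coef = 0.5 * (1.0 - sum(g**2 for g in counts.values()) + p**2 / h)
    if p >= b_coef:
        raise ValueError(f"saturated pair (p={p:.4f} >= b={b_coef:.4f})")
    return -b_coef * np.log(1.0 - p / b_coef)


def distance_matrix(aln: SequenceSet, model: str = "tajima_nei") -> DistanceMatrix:
    """Pairwise distance matrix from an aligned SequenceSet.

    ``model`` is ``"p"`` or ``"tajima_nei"``; gap columns are removed
    per pair (complete pairwise deletion). A saturated pair raises an
    error naming it.
    """
    funcs = {"p": p_distance, "tajima_nei": tajima_nei_distance}
    if model not in funcs:
        raise ValueError(f"unknown model {model!r}")
    lengths = {len(s) for _, s in aln.records}
    if len(lengths) > 1:
        raise ValueError("sequences not aligned (unequal lengths)")
    taxa = aln.ids()
    n = len(taxa)
    mat = np.zeros((n, n))
    seqs = aln.to_dict()
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = funcs[model](seqs[taxa[i]], seqs[taxa[j]])
        except ValueError as exc:
            raise ValueError(f"pair ({taxa[i]}, {taxa[j]}): {exc}") from exc
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=mat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou-Nei with the Q criterion).

    Deterministic: ties in Q broken by the lexicographically smallest
    (label_i, label_j) pair. Negative branch lengths are clamped to
    zero with the deficit moved to the sibling branch. Returns an
    unrooted tree (trifurcating seed node for >3 taxa).
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxon_ns = dendropy.TaxonNamespace(d.taxa)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    labels: list[str] = list(d.taxa)
    for label in d.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    mat = d.matrix.copy()

    def sort_key(i: int, j: int) -> tuple[str, str]:
        return tuple(sorted((labels[i], labels[j])))

    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * mat[i, j] - r[i] - r[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and sort_key(i, j) < sort_key(*best)
                ):
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_d = 0.5 * (mat[i] + mat[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = new_d[keep]
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(sort_key(i, j))]

    # join the last three nodes at an unrooted central node
    (d01, d02, d12) = (mat[0, 1], mat[0, 2], mat[1, 2])
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    center = dendropy.Node()
    for node, length in zip(nodes, (l0, l1, l2)):
        center.add_child(node)
        node.edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies arbitrarily (by leaf-label order) with
    zero-length branches; returns a modified copy."""
    tree = tree.clone(depth=1)
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            ordered = sorted(
                children,
                key=lambda c: min(l.taxon.label for l in c.leaf_iter()),
            )
            a, b = ordered[0], ordered[1]
            node.remove_child(a)
            node.remove_child(b)
            merged = dendropy.Node()
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
            merged.edge.length = 0.0
            children = node.child_nodes()
    return tree


def pic(tree: dendropy.Tree, trait: dict[str, float]) -> ContrastResult:
    """Felsenstein's phylogenetically independent contrasts.

    Requires a rooted, fully bifurcating tree with positive branch
    lengths and a trait value at every leaf. Contrasts are returned in
    postorder; each is (x_left - x_right)/sqrt(v_left + v_right) with
    the usual extended-branch-length recursion.
    """
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    node_values: list[float] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"missing trait value for leaf {label!r}")
            values[id(node)] = float(trait[label])
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError(f"leaf {label!r} needs a positive branch length")
            lengths[id(node)] = float(node.edge.length)
        else:
            children = node.child_nodes()
            if len(children) != 2:
                raise ValueError(
                    "polytomy encountered; resolve with resolve_polytomies() first"
                )
            a, b = children
            va, vb = lengths[id(a)], lengths[id(b)]
            xa, xb = values[id(a)], values[id(b)]
            contrasts.append((xa - xb) / np.sqrt(va + vb))
            x = (xa / va + xb / vb) / (1.0 / va + 1.0 / vb)
            node_values.append(x)
            values[id(node)] = x
            extra = va * vb / (va + vb)
            edge = node.edge.length
            if node.parent_node is None:
                edge = 0.0
            elif edge is None or edge < 0:
                # zero is allowed: polytomy resolutions insert zero-length
                # branches and the recursion stays well defined
                raise ValueError("internal branch needs a nonnegative length")
            lengths[id(node)] = float(edge) + extra
    return ContrastResult(contrasts=contrasts, node_values=node_values)


def pic_correlation(
    tree: dendropy.Tree,
    trait_x: dict[str, float],
    trait_y: dict[str, float],
) -> ContrastResult:
    """Correlation through the origin of two traits' contrasts.

    r = sum(uv)/sqrt(sum u^2 sum v^2); two-sided p from a
    t-distribution with (n_contrasts - 1) degrees of freedom. When
    either trait's contrasts are all ~zero the result is flagged and
    p = 1.
    """
    cx = pic(tree, trait_x).contrasts
    cy = pic(tree, trait_y).contrasts
    u = np.asarray(cx)
    v = np.asarray(cy)
    su, sv = np.sum(u * u), np.sum(v * v)
    if su < 1e-300 or sv < 1e-300:
        return ContrastResult(contrasts=cx, r=0.0, p=1.0, zero_variance=True)
    r = float(np.sum(u * v) / np.sqrt(su * sv))
    r = max(-1.0, min(1.0, r))
    df = len(u) - 1
    if df <= 0:
        return ContrastResult(contrasts=cx, r=r, p=1.0, zero_variance=True)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return ContrastResult(contrasts=cx, r=r, p=p)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


def default_leaf_map(gene_tree: dendropy.Tree, sep: str = "|") -> dict[str, str]:
    """Gene leaf -> species from labels of the form ``fam|species|copy``."""
    mapping = {}
    for leaf in gene_tree.leaf_node_iter():
        parts = leaf.taxon.label.split(sep)
        if len(parts) < 2:
            raise ValueError(f"cannot infer species from leaf {leaf.taxon.label!r}")
        mapping[leaf.taxon.label] = parts[1]
    return mapping


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: dict[str, str],
) -> ReconciliationSummary:
    """Parsimony duplication-loss reconciliation by LCA mapping.

    Each gene node maps to the LCA (in the species tree) of the species
    of its leaves. A gene node is a duplication iff it maps to the same
    species node as one of its children. Losses along a gene edge are
    the species-tree edges skipped on the path between the parent's and
    child's images (one fewer at speciations); each loss is attributed
    to the species node whose lineage disappeared.
    """
    sp_nodes = {_node_key(n): n for n in species_tree.preorder_node_iter()}
    sp_parent = {
        id(n): n.parent_node for n in species_tree.preorder_node_iter()
    }
    sp_depth: dict[int, int] = {}
    for node in species_tree.preorder_node_iter():
        parent = sp_parent[id(node)]
        sp_depth[id(node)] = 0 if parent is None else sp_depth[id(parent)] + 1
    leaf_by_species = {
        n.taxon.label: n for n in species_tree.leaf_node_iter()
    }

    def species_lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if sp_depth[id(a)] >= sp_depth[id(b)]:
                a = sp_parent[id(a)]
            else:
                b = sp_parent[id(b)]
        return a

    mapping: dict[int, dendropy.Node] = {}
    is_dup: dict[int, bool] = {}
    mapping_out: dict[str, str] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_map:
                raise ValueError(f"gene leaf {label!r} has no species mapping")
            species = leaf_map[label]
            if species not in leaf_by_species:
                raise ValueError(f"species {species!r} absent from species tree")
            mapping[id(node)] = leaf_by_species[species]
            is_dup[id(node)] = False
        else:
            image = None
            for child in node.child_nodes():
                image = (
                    mapping[id(child)]
                    if image is None
                    else species_lca(image, mapping[id(child)])
                )
            mapping[id(node)] = image
            is_dup[id(node)] = any(
                mapping[id(child)] is image for child in node.child_nodes()
            )
        key = node.taxon.label if node.is_leaf() else _node_key(node)
        mapping_out[key] = _node_key(mapping[id(node)])

    duplications: dict[str, int] = {}
    losses: dict[str, int] = {}
    for node in gene_tree.preorder_node_iter():
        if not node.is_leaf() and is_dup[id(node)]:
            key = _node_key(mapping[id(node)])
            duplications[key] = duplications.get(key, 0) + 1
        for child in node.child_nodes():
            top = mapping[id(node)]
            bottom = mapping[id(child)]
            # species nodes strictly between bottom and top, plus top
            # itself when the parent gene node is a duplication: at each,
            # the lineage fails to reach the off-path child.
            path: list[dendropy.Node] = []
            cur = bottom
            while cur is not top:
                cur = sp_parent[id(cur)]
                if cur is None:
                    raise ValueError("gene-tree image not ancestral to child image")
                path.append(cur)
            # path = internal stops (excluding bottom), ending at top
            loss_points = path[:-1] if path else []
            if is_dup[id(node)] and path:
                loss_points = path  # include top: dup lineage does not split there
            prev = bottom
            for sp in loss_points:
                for sp_child in sp.child_nodes():
                    if sp_child is not prev:
                        key = _node_key(sp_child)
                        losses[key] = losses.get(key, 0) + 1
                prev = sp
    return ReconciliationSummary(
        duplications=duplications, losses=losses, mapping=mapping_out
    )
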