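"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates the fixed seven-taxon wild-silkmoth species tree, gene
families evolving by a per-branch duplication-loss process, negative-
binomial transcript counts with group-level fold changes, codon
alignments under the one-ratio substitution process, fibroin-like
proteins (conserved 14-residue head, variable N terminus, alternating
poly-alanine / glycine-rich spacer repeat blocks), serine-rich
sericin-like proteins, and GO annotation tables with planted term
enrichment. Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from silkgland.codon_evol import (
    SENSE_CODONS,
    CodonAlignment,
    _CodonModel,
    uniform_codon_freqs,
)
from silkgland.io_formats import SequenceSet, parse_newick, write_newick

SPECIES = (
    "A.pernyi",
    "A.yamamai",
    "A.assama",
    "Ac.selene",
    "R.newara",
    "S.cynthia",
    "B.mori",
)

# Cocoon-color groups among the six Saturniidae (B. mori excluded):
# stable coloration = 1, unstable = 0.
COLORED_GROUP = ("A.yamamai", "R.newara", "A.assama")
NONCOLORED_GROUP = ("A.pernyi", "Ac.selene", "S.cynthia")
DEFAULT_GROUPS = {
    **{s: "colored" for s in COLORED_GROUP},
    **{s: "noncolored" for s in NONCOLORED_GROUP},
}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Planted parameters recorded by the generators."""

    species_tree_newick: str | None = None
    family_events: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    family_membership: dict[str, dict[str, int]] = field(default_factory=dict)
    de_families: dict[str, float] = field(default_factory=dict)
    baseline_means: dict[str, float] = field(default_factory=dict)
    omega_true: float | None = None
    kappa_true: float | None = None
    enriched_terms: dict[str, float] = field(default_factory=dict)
    silk_records: list[dict] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def make_species_tree(branch_length: float = 0.1) -> dendropy.Tree:
    """The fixed rooted seven-taxon topology used throughout.

    The Saturniidae clade nests (((A.pernyi, A.yamamai), A.assama),
    Ac.selene), then R.newara, with S.cynthia the deepest split;
    B.mori is the outgroup sister to the whole clade. All branch
    lengths equal ``branch_length``.
    """
    b = branch_length
    newick = (
        f"((((((A.pernyi:{b},A.yamamai:{b}):{b},A.assama:{b}):{b},"
        f"Ac.selene:{b}):{b},R.newara:{b}):{b},S.cynthia:{b}):{b},"
        f"B.mori:{b});"
    )
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# Gene families by duplication-loss
# ---------------------------------------------------------------------------

def _species_postorder_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def simulate_families(
    tree: dendropy.Tree,
    n_families: int,
    dup_rate: float,
    loss_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, list[dendropy.Tree], SyntheticTruth]:
    """Evolve ``n_families`` single-copy ancestors down the species tree.

    On each species-tree edge every surviving gene lineage is lost with
    probability ``loss_rate``, else duplicated with probability
    ``dup_rate`` (interpreted as per-branch event probabilities; at
    most one event per lineage per branch). Returns the family
    membership table (columns family, species, transcript), one gene
    tree per surviving family, and the planted truth (events keyed by
    the species node at the bottom of the edge they occurred on).

    Families losing every lineage are emitted with empty membership and
    recorded in the events list; they get no gene tree.
    """
    if dup_rate < 0 or loss_rate < 0 or dup_rate + loss_rate > 1:
        raise ValueError("rates must be nonnegative with sum <= 1")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        species_tree_newick=write_newick(tree), seeds={"families": seed}
    )
    rows: list[dict] = []
    gene_trees: list[dendropy.Tree] = []
    counter = {"transcript": 0}

    def node_label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))

    for fam_i in range(n_families):
        fam = f"fam{fam_i:04d}"
        events: list[tuple[str, str]] = []
        membership: dict[str, int] = {}
        leaf_names: list[str] = []

        def evolve(species_node: dendropy.Node) -> dict | None:
            """Evolve one gene lineage from the top of the edge leading
            into ``species_node``; returns a nested gene-subtree dict or
            None if the lineage goes extinct below here."""
            u = rng.random()
            if u < loss_rate:
                events.append((node_label(species_node), "loss"))
                return None
            if u < loss_rate + dup_rate:
                events.append((node_label(species_node), "duplication"))
                left = continue_from(species_node)
                right = continue_from(species_node)
                kids = [k for k in (left, right) if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                return {"children": kids}
            return continue_from(species_node)

        def continue_from(species_node: dendropy.Node) -> dict | None:
            if species_node.is_leaf():
                sp = species_node.taxon.label
                counter["transcript"] += 1
                tid = f"{sp}_t{counter['transcript']:05d}"
                name = f"{fam}|{sp}|{tid}"
                membership[sp] = membership.get(sp, 0) + 1
                leaf_names.append(name)
                rows.append({"family": fam, "species": sp, "transcript": tid})
                return {"leaf": name}
            kids = [evolve(child) for child in species_node.child_nodes()]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return {"children": kids}

        # the root lineage starts above the root node; allow root-edge events
        shape = evolve(tree.seed_node)
        truth.family_events[fam] = events
        truth.family_membership[fam] = membership
        if shape is None:
            continue

        def to_newick(node: dict) -> str:
            if "leaf" in node:
                return node["leaf"]
            return "(" + ",".join(to_newick(c) for c in node["children"]) + ")"

        text = to_newick(shape)
        if "children" not in shape:  # single surviving leaf: still a valid tree
            text = f"({text})"
        gtree = parse_newick(text + ";")
        for edge in gtree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = 1.0
        gtree.label = fam
        gene_trees.append(gtree)

    table = pd.DataFrame(rows, columns=["family", "species", "transcript"])
    return table, gene_trees, truth


def membership_from_events(
    tree: dendropy.Tree, events: list[tuple[str, str]]
) -> dict[str, int]:
    """Replay per-edge event counts to per-species gene copy numbers.

    Independent of the gene-tree construction: lineage counts entering
    each node are propagated top-down, adding duplications and
    subtracting losses recorded on the edge above that node.
    """
    dup = {}
    loss = {}
    for label, kind in events:
        d = dup if kind == "duplication" else loss
        d[label] = d.get(label, 0) + 1

    def node_label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))

    counts: dict[str, int] = {}
    entering: dict[int, int] = {}

    for node in tree.preorder_node_iter():
        parent = node.parent_node
        incoming = 1 if parent is None else entering[id(parent)]
        label = node_label(node)
        n = incoming - loss.get(label, 0) + dup.get(label, 0)
        n = max(n, 0)
        entering[id(node)] = n
        if node.is_leaf():
            counts[label] = n
    return counts


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    families: pd.DataFrame,
    groups: dict[str, str] | None = None,
    n_de: int = 50,
    fold_change: float = 8.0,
    nb_dispersion: float = 0.2,
    libsizes: dict[str, float] | None = None,
    seed: int = 0,
    mean_expression: float = 100.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Negative-binomial transcript counts with planted family-level DE.

    Each family draws a log-normal baseline mean (median
    ``mean_expression`` reads at the reference library size); the first
    ``n_de`` families get the colored-group mean multiplied by
    ``fold_change``. Family means are split evenly among a species'
    member transcripts; counts are NB with variance mu + phi*mu^2.
    Transcript lengths are log-normal(6.5, 0.5) truncated at 200 bp.

    Returns a long-format table (transcript, species, length, reads,
    library_size) and the truth with the planted DE set.
    """
    groups = dict(DEFAULT_GROUPS) if groups is None else groups
    group_names = set(groups.values())
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    for g in group_names:
        if not any(v == g for v in groups.values()):
            raise ValueError(f"empty group {g}")
    if fold_change <= 0 or nb_dispersion < 0:
        raise ValueError("fold_change must be > 0 and dispersion >= 0")
    species = [s for s in SPECIES if s in groups] or sorted(groups)
    if libsizes is None:
        libsizes = {s: 2e7 for s in species}
    rng = np.random.default_rng(seed)
    fam_ids = list(dict.fromkeys(families["family"]))
    de_set = fam_ids[:n_de]
    truth = SyntheticTruth(seeds={"counts": seed})
    truth.de_families = {f: fold_change for f in de_set}

    members: dict[str, dict[str, list[str]]] = {}
    for row in families.itertuples():
        members.setdefault(row.family, {}).setdefault(row.species, []).append(
            row.transcript
        )

    rows: list[dict] = []
    ref_lib = float(np.exp(np.mean(np.log([libsizes[s] for s in species]))))
    for fam in fam_ids:
        base = float(rng.lognormal(mean=np.log(mean_expression), sigma=0.8))
        truth.baseline_means[fam] = base
        for sp in species:
            tids = members.get(fam, {}).get(sp, [])
            if not tids:
                continue
            mean_sp = base
            if fam in truth.de_families and groups[sp] == "colored":
                mean_sp *= fold_change
            mean_sp *= libsizes[sp] / ref_lib
            per_transcript = mean_sp / len(tids)
            for tid in tids:
                length = max(200, int(rng.lognormal(6.5, 0.5)))
                reads = int(_nb_draw(rng, np.array(per_transcript), nb_dispersion))
                rows.append(
                    {
                        "transcript": tid,
                        "species": sp,
                        "length": length,
                        "reads": reads,
                        "library_size": libsizes[sp],
                    }
                )
    matrix = pd.DataFrame(
        rows, columns=["transcript", "species", "length", "reads", "library_size"]
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: dendropy.Tree,
    n_codons: int,
    omega: float,
    kappa: float,
    seed: int,
    freqs: np.ndarray | None = None,
) -> CodonAlignment:
    """Evolve a gap-free codon alignment under the one-ratio process.

    Root codons are drawn from the equilibrium frequencies (uniform
    over the 61 sense codons by default) and propagated along each
    branch with the exact transition matrix, so no stop codon can ever
    appear.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    pi = uniform_codon_freqs() if freqs is None else np.asarray(freqs, float)
    rng = np.random.default_rng(seed)
    model = _CodonModel(omega, kappa, pi)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(len(SENSE_CODONS), size=n_codons, p=pi)
    taxa: list[str] = []
    rows: list[str] = []
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length
            if t is None:
                raise ValueError("tree branch without length")
            P = model.transition_matrix(float(t))
            parent_states = states[id(node.parent_node)]
            child = np.empty_like(parent_states)
            # draw child states grouped by parent state for vectorized sampling
            for s in np.unique(parent_states):
                mask = parent_states == s
                child[mask] = rng.choice(len(SENSE_CODONS), size=mask.sum(), p=P[s])
            states[id(node)] = child
        if node.is_leaf():
            codons = states[id(node)]
            taxa.append(node.taxon.label)
            rows.append("".join(SENSE_CODONS[s] for s in codons))
    return CodonAlignment(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# Silk-like proteins
# ---------------------------------------------------------------------------

@dataclass
class SilkTemplate:
    """Generative grammar for a fibroin-like protein.

    The protein is a conserved 14-residue head, a variable-tail
    N terminus of ``nterm_length`` residues total, then
    ``n_repeat_units`` repeats of (poly-alanine run, glycine-rich
    spacer). The spacer concatenates GGGX/GGX/GX motifs drawn by
    ``spacer_grammar`` weights, with X drawn from ``x_weights``.
    """

    head: str = "MRVTTFVILCCALQ"
    nterm_length_range: tuple[int, int] = (87, 103)
    n_repeat_units: int = 10
    polyA_run_range: tuple[int, int] = (5, 12)
    spacer_motifs_per_unit: int = 6
    spacer_grammar: dict[str, float] = field(
        default_factory=lambda: {"GGGX": 1.0, "GGX": 2.0, "GX": 1.0}
    )
    x_weights: dict[str, float] = field(
        default_factory=lambda: {"S": 0.35, "Y": 0.2, "D": 0.15, "R": 0.1, "V": 0.1, "W": 0.1}
    )

    def __post_init__(self) -> None:
        if len(self.head) != 14:
            raise ValueError("head must be exactly 14 residues")
        if self.nterm_length_range[0] < 14:
            raise ValueError("N terminus cannot be shorter than the head")
        if any(w < 0 for w in self.spacer_grammar.values()) or sum(
            self.spacer_grammar.values()
        ) <= 0:
            raise ValueError("spacer grammar weights must be nonnegative, sum > 0")
        if "G" in self.x_weights or "A" in self.x_weights:
            raise ValueError("X residues must exclude G (motif definition) and A")


# residues used for N-terminus tails: no alanine, so planted poly-A runs
# are the only ones and region detection has an unambiguous truth
_TAIL_AA = "CDEFGHIKLMNPQRSTVWY"


@dataclass
class SilkProteinTruth:
    sequences: SequenceSet
    boundaries: dict[str, int]  # species -> repeat-region start
    polyA_positions: dict[str, list[int]]  # planted poly-A residue indices


def generate_silk_proteins(
    template: SilkTemplate | None = None,
    per_species_divergence: float = 0.05,
    seed: int = 0,
    species: tuple[str, ...] = SPECIES,
) -> SilkProteinTruth:
    """One fibroin-like protein per species, with recorded truth spans.

    The 14-residue head is held identical across species; the rest of
    the N terminus descends from one ancestral tail with per-site
    substitution probability ``per_species_divergence`` (substitutions
    never create alanine, keeping planted poly-A runs unambiguous).
    The repeat region alternates poly-A runs with glycine-rich spacers
    drawn independently per species from the grammar.
    """
    template = template or SilkTemplate()
    rng = np.random.default_rng(seed)
    lo, hi = template.nterm_length_range
    nterm_len = int(rng.integers(lo, hi + 1))
    tail_len = nterm_len - 14
    ancestral_tail = "".join(rng.choice(list(_TAIL_AA), size=tail_len))
    x_res = list(template.x_weights)
    x_p = np.array([template.x_weights[r] for r in x_res], float)
    x_p /= x_p.sum()
    motifs = list(template.spacer_grammar)
    motif_p = np.array([template.spacer_grammar[m] for m in motifs], float)
    motif_p /= motif_p.sum()

    records: list[tuple[str, str]] = []
    boundaries: dict[str, int] = {}
    polyA: dict[str, list[int]] = {}
    for sp in species:
        tail = list(ancestral_tail)
        for i in range(tail_len):
            if rng.random() < per_species_divergence:
                tail[i] = rng.choice(list(_TAIL_AA))
        parts = [template.head, "".join(tail)]
        boundary = nterm_len
        pos = nterm_len
        pa_positions: list[int] = []
        for _ in range(template.n_repeat_units):
            run = int(rng.integers(*template.polyA_run_range))
            parts.append("A" * run)
            pa_positions.extend(range(pos, pos + run))
            pos += run
            spacer = []
            for _ in range(template.spacer_motifs_per_unit):
                motif = motifs[int(rng.choice(len(motifs), p=motif_p))]
                x = x_res[int(rng.choice(len(x_res), p=x_p))]
                spacer.append("G" * (len(motif) - 1) + x)
            spacer_seq = "".join(spacer)
            parts.append(spacer_seq)
            pos += len(spacer_seq)
        records.append((sp, "".join(parts)))
        boundaries[sp] = boundary
        polyA[sp] = pa_positions
    seqs = SequenceSet(records=records, alphabet="protein")
    return SilkProteinTruth(sequences=seqs, boundaries=boundaries, polyA_positions=polyA)


def generate_sericin_proteins(
    n: int = 6,
    length: int = 400,
    serine_fraction: float = 0.33,
    seed: int = 0,
) -> SequenceSet:
    """Serine-rich sericin-like proteins: i.i.d. residues with an
    elevated serine weight, remaining mass spread over G, A, T, D, N
    and the other residues."""
    rng = np.random.default_rng(seed)
    other = [a for a in STANDARD_AA if a != "S"]
    base = np.ones(len(other))
    for favored in "GATDN":
        base[other.index(favored)] = 3.0
    base = base / base.sum() * (1.0 - serine_fraction)
    residues = ["S"] + other
    probs = np.concatenate([[serine_fraction], base])
    records = [
        (f"sericin{i}", "".join(rng.choice(residues, size=length, p=probs)))
        for i in range(n)
    ]
    return SequenceSet(records=records, alphabet="protein")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def generate_go_annotations(
    genes: list[str],
    n_terms: int,
    enriched_terms: dict[str, float] | None,
    target_set: set[str],
    seed: int,
    base_prob: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-gene GO term assignments with planted enrichment.

    Terms are ``GO:0000000`` .. sequentially; each gene carries term t
    with probability ``base_prob``, multiplied by the enrichment factor
    for genes in ``target_set`` when t is enriched. ``enriched_terms``
    maps term ids (or bare indices via ``term{i}``) to factors.
    """
    if not target_set <= set(genes):
        raise ValueError("target_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    factors = {t: 1.0 for t in terms}
    for key, factor in (enriched_terms or {}).items():
        factors[key] = factor
    truth = SyntheticTruth(
        enriched_terms={t: f for t, f in factors.items() if f != 1.0},
        seeds={"go": seed},
    )
    rows = []
    target = set(target_set)
    for t in terms:
        p_bg = base_prob
        p_target = min(1.0, base_prob * factors[t])
        for gene in genes:
            p = p_target if gene in target else p_bg
            if rng.random() < p:
                rows.append({"gene": gene, "term": t})
    return pd.DataFrame(rows, columns=["gene", "term"]), truth
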