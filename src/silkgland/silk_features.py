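"""Silk-protein sequence characterization.

Isoelectric point by Henderson-Hasselbalch bisection, Kyte-Doolittle
hydropathy profiles, reference-anchored global alignment restricted to
mutually ungapped columns, poly-alanine/spacer decomposition of repeat
regions, GGGX/GGX/GX motif inventories, and amino-acid composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from silkgland.io_formats import STANDARD_AA


# Electrophoresis-calibrated pKa values; override via the pka_set argument.
DEFAULT_PKA = {
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
    "N_term": 8.6,
    "C_term": 3.6,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")

# Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class SilkProteinRecord:
    """A protein with annotated N-terminus and repeat-region spans
    (0-based, half-open)."""

    id: str
    species: str
    sequence: str
    nterm_span: tuple[int, int] | None = None
    repeat_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, span in (("nterm_span", self.nterm_span), ("repeat_span", self.repeat_span)):
            if span is None:
                continue
            lo, hi = span
            if not (0 <= lo <= hi <= n):
                raise ValueError(f"{name} {span} outside sequence bounds [0, {n})")
        if self.nterm_span and self.repeat_span:
            if self.nterm_span[1] > self.repeat_span[0]:
                raise ValueError("nterm_span must precede repeat_span without overlap")


@dataclass
class ProteinFeatureResult:
    pI: float
    composition: dict[str, float]
    length: int


@dataclass
class HydropathyProfile:
    window: int
    positions: np.ndarray  # window-center indices
    scores: np.ndarray


@dataclass
class RepeatDecomposition:
    """Ordered (kind, span, subsequence) blocks tiling the repeat region."""

    blocks: list[tuple[str, tuple[int, int], str]]

    def polyA_residues(self) -> set[int]:
        out: set[int] = set()
        for kind, (lo, hi), _ in self.blocks:
            if kind == "polyA":
                out.update(range(lo, hi))
        return out

    def spacer_sequences(self) -> list[str]:
        return [seq for kind, _, seq in self.blocks if kind == "spacer"]


@dataclass
class MotifInventory:
    counts: dict[str, int]
    x_composition: dict[str, dict[str, float]]
    unparsed_fraction: float
    total_residues: int = 0


def net_charge(seq: str, pH: float, pka: dict[str, float] | None = None) -> float:
    """Net protein charge at a pH: termini plus ionizable side chains;
    'X' residues carry no charge."""
    pka = pka or DEFAULT_PKA
    charge = 1.0 / (1.0 + 10 ** (pH - pka["N_term"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["C_term"] - pH))
    for res in seq:
        if res in _BASIC:
            charge += 1.0 / (1.0 + 10 ** (pH - pka[res]))
        elif res in _ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (pka[res] - pH))
    return charge


def compute_pI(
    seq: str, pka_set: dict[str, float] | None = None, tol: float = 1e-4
) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    converges unconditionally; iteration stops at |delta pH| < tol.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(STANDARD_AA) - {"X"}
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydropathy_profile(
    seq: str,
    window: int = 9,
    scale: dict[str, float] | None = None,
    hydrophilicity: bool = False,
) -> HydropathyProfile:
    """Sliding-window mean of a residue hydropathy scale.

    ``window`` must be odd and no longer than the sequence. With
    ``hydrophilicity=True`` the Kyte-Doolittle values are sign-flipped,
    so peaks mark hydrophilic stretches.
    """
    scale = scale or KYTE_DOOLITTLE
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = np.array([scale[res] for res in seq], dtype=float)
    if hydrophilicity:
        values = -values
    kernel = np.full(window, 1.0 / window)
    scores = np.convolve(values, kernel, mode="valid")
    half = window // 2
    positions = np.arange(half, half + len(scores))
    return HydropathyProfile(window=window, positions=positions, scores=scores)


@dataclass
class AlignmentConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


def align_to_reference(
    ref: str, query: str, params: AlignmentConfig | None = None
) -> tuple[float, list[tuple[int, int]]]:
    """Global pairwise alignment anchored on a reference sequence.

    Returns (score, aligned column pairs): 0-based index pairs
    (ref_pos, query_pos) for every column where neither sequence is
    gapped. End gaps are penalized (true global alignment); the first
    gap position costs ``gap_open`` and each further position
    ``gap_extend``.
    """
    if not ref or not query:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    alignment = aligner.align(ref, query)[0]
    pairs: list[tuple[int, int]] = []
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        pairs.extend(zip(range(r0, r1), range(q0, q1)))
    return float(alignment.score), pairs


def aligned_identity(ref: str, query: str, pairs: list[tuple[int, int]]) -> float:
    if not pairs:
        return 0.0
    return sum(ref[i] == query[j] for i, j in pairs) / len(pairs)


def decompose_repeats(record: SilkProteinRecord, min_run: int = 3) -> RepeatDecomposition:
    """Tile the repeat region into poly-alanine runs and spacers.

    Maximal runs of 'A' of length >= ``min_run`` become polyA blocks;
    everything between consecutive runs is a spacer block.
    """
    if record.repeat_span is None:
        raise ValueError("repeat_span not set; annotate or run detect_regions first")
    lo, hi = record.repeat_span
    region = record.sequence[lo:hi]
    blocks: list[tuple[str, tuple[int, int], str]] = []
    cursor = 0
    for match in re.finditer(f"A{{{min_run},}}", region):
        if match.start() > cursor:
            sub = region[cursor : match.start()]
            blocks.append(("spacer", (lo + cursor, lo + match.start()), sub))
        blocks.append(("polyA", (lo + match.start(), lo + match.end()), match.group()))
        cursor = match.end()
    if cursor < len(region):
        blocks.append(("spacer", (lo + cursor, hi), region[cursor:]))
    return RepeatDecomposition(blocks=blocks)


def motif_inventory(spacer_seqs: list[str]) -> MotifInventory:
    """Greedy left-to-right motif scan of spacer sequences.

    At each position try GGGX, then GGX, then GX, where X is any
    non-glycine residue; a match consumes its residues and records X,
    otherwise the scan advances one residue and counts it unparsed.
    Scans never cross spacer boundaries.
    """
    counts = {"GGGX": 0, "GGX": 0, "GX": 0}
    x_counts: dict[str, dict[str, int]] = {k: {} for k in counts}
    unparsed = 0
    total = 0
    for seq in spacer_seqs:
        total += len(seq)
        i = 0
        while i < len(seq):
            matched = False
            for motif, g in (("GGGX", 3), ("GGX", 2), ("GX", 1)):
                if (
                    i + g < len(seq)
                    and seq[i : i + g] == "G" * g
                    and seq[i + g] != "G"
                ):
                    counts[motif] += 1
                    x = seq[i + g]
                    x_counts[motif][x] = x_counts[motif].get(x, 0) + 1
                    i += g + 1
                    matched = True
                    break
            if not matched:
                unparsed += 1
                i += 1
    x_composition = {
        motif: {
            res: n / counts[motif] for res, n in sorted(x_counts[motif].items())
        }
        if counts[motif]
        else {}
        for motif in counts
    }
    return MotifInventory(
        counts=counts,
        x_composition=x_composition,
        unparsed_fraction=unparsed / total if total else 0.0,
        total_residues=total,
    )


def aa_composition(seq: str) -> dict[str, float]:
    """Residue fractions over the 20 standard amino acids; 'X' is
    excluded from the denominator."""
    filtered = [res for res in seq if res in STANDARD_AA]
    if not filtered:
        raise ValueError("no standard residues in input")
    n = len(filtered)
    return {res: filtered.count(res) / n for res in sorted(set(filtered))}


class RegionDetectionError(ValueError):
    """No poly-alanine run found; enter spans manually."""


def detect_regions(
    seq: str,
    head_length: int = 14,
    nterm_max: int = 110,
    min_run: int = 3,
    record_id: str = "",
    species: str = "",
) -> SilkProteinRecord:
    """Split a fibroin-like protein into N terminus and repeat region.

    The boundary is the start of the first poly-alanine run of length
    >= ``min_run`` at or after ``head_length``, capped at
    ``nterm_max``; the N terminus is [0, boundary) and the repeat
    region [boundary, end).
    """
    if len(seq) <= nterm_max:
        raise ValueError("sequence shorter than nterm_max; nothing to split")
    match = re.search(f"A{{{min_run},}}", seq[head_length:])
    if match is None:
        raise RegionDetectionError(
            "no poly-alanine run found after the head; set spans manually"
        )
    boundary = min(head_length + match.start(), nterm_max)
    boundary = max(boundary, head_length)
    return SilkProteinRecord(
        id=record_id or "query",
        species=species,
        sequence=seq,
        nterm_span=(0, boundary),
        repeat_span=(boundary, len(seq)),
    )


def protein_features(
    seq: str, pka_set: dict[str, float] | None = None
) -> ProteinFeatureResult:
    return ProteinFeatureResult(
        pI=compute_pI(seq, pka_set),
        composition=aa_composition(seq),
        length=len(seq),
    )
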