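"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and tab-separated tables are handled with explicit line-level
validation so that malformed inputs fail with the offending line number;
Newick trees are backed by :mod:`dendropy`, and tables by
:class:`pandas.DataFrame` (referred to throughout as ``TableFrame``).

Coordinate convention: all sequence intervals in this package are 0-based
and half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("silkgland")

# IUPAC alphabets; '-' permitted so aligned inputs pass validation unchanged.
DNA_CHARS = frozenset("ACGTURYSWKMBDHVN-")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*-")
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A file violated the expected format (message names the line)."""


class SchemaError(ValueError):
    """A table did not match the required column schema."""


@dataclass
class SequenceSet:
    """An ordered collection of named sequences over one alphabet.

    ``records`` holds ``(identifier, sequence)`` pairs in file order;
    ``descriptions`` keeps any FASTA header text after the first
    whitespace, keyed by identifier.
    """

    records: list[tuple[str, str]]
    alphabet: str  # "protein" | "dna"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seen: set[str] = set()
        allowed = PROTEIN_CHARS if self.alphabet == "protein" else DNA_CHARS
        for ident, seq in self.records:
            if not ident:
                raise FormatError("empty sequence identifier")
            if ident in seen:
                raise FormatError(f"duplicate sequence identifier {ident!r}")
            seen.add(ident)
            if not seq:
                raise FormatError(f"empty sequence for record {ident!r}")
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"illegal {self.alphabet} character(s) {sorted(bad)} in record {ident!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [ident for ident, _ in self.records]

    def to_dict(self) -> dict[str, str]:
        return dict(self.records)


def read_fasta(path: str | Path, alphabet: str) -> SequenceSet:
    """Parse a FASTA file.

    The identifier is the header text up to the first whitespace; the
    remainder is kept as the description. Sequences are upper-cased and
    whitespace-stripped. Malformed input raises :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    ident: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if ident is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {ident!r} has no sequence")
        records.append((ident, seq))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = header.split(None, 1)
                ident = parts[0]
                if ident in descriptions or any(i == ident for i, _ in records):
                    raise FormatError(f"{path}:{lineno}: duplicate header {ident!r}")
                descriptions[ident] = parts[1] if len(parts) > 1 else ""
                chunks = []
                header_line = lineno
            else:
                if ident is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before first header")
                chunk = "".join(line.split()).upper()
                allowed = PROTEIN_CHARS if alphabet == "protein" else DNA_CHARS
                bad = set(chunk) - allowed
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal {alphabet} character(s) {sorted(bad)}"
                    )
                chunks.append(chunk)
    flush()
    return SequenceSet(records=records, alphabet=alphabet, descriptions=descriptions)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write a SequenceSet as FASTA with fixed-width line wrapping."""
    path = Path(path)
    with open(path, "w") as handle:
        for ident, seq in seqs.records:
            desc = seqs.descriptions.get(ident, "")
            header = f">{ident} {desc}".rstrip()
            handle.write(header + "\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted :class:`dendropy.Tree`.

    Missing branch lengths stay ``None`` (never coerced to zero). Quoted
    labels and duplicate leaf labels are rejected.
    """
    if "'" in text or '"' in text:
        raise FormatError("quoted Newick labels are not supported")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a TSV with a header row; ``#``-prefixed lines are comments.

    ``schema`` maps required column names to scalar types (``int``,
    ``float`` or ``str``); extra columns pass through untouched.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty table") from exc
    if schema:
        missing = [col for col in schema if col not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for col, typ in schema.items():
            if typ is str:
                continue
            try:
                frame[col] = frame[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: column {col!r} is not coercible to {typ.__name__}"
                ) from exc
    if frame.columns.duplicated().any():
        raise SchemaError(f"{path}: duplicate column names")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a TableFrame as TSV with header, no index."""
    frame.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key=value`` config file; '#' lines are comments."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config


def setup_logging(level: str = "info") -> None:
    numeric = {"debug": logging.DEBUG, "info": logging.INFO, "warn": logging.WARNING}[level]
    logging.basicConfig(
        level=numeric,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
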