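"""Readers and writers for RNA alignments, dot-bracket structures and trees.

All coordinates are 0-based alignment-column indices; ranges are half-open.
Sequences are held in the RNA alphabet internally: ``T`` on input is converted
to ``U`` once, with a single logged warning per file (mitogenome extracts are
usually deposited as DNA). Ambiguity codes (N, R, Y, ...) are preserved here;
their resolution is the recoding stage's job.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pairphy")

#: IUPAC nucleotide ambiguity codes accepted in alignments (besides ACGU-).
AMBIGUITY_CODES = frozenset("NRYSWKMBDHV")
RNA_BASES = frozenset("ACGU")
GAP = "-"

Pathish = Union[str, "io.IOBase", TextIO]


class PairphyError(Exception):
    """Base class for all pairphy data errors."""


class FormatError(PairphyError):
    """Malformed input file or record."""


class StructureError(PairphyError):
    """Dot-bracket string violates bracket matching."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class RnaAlignment:
    """A multiple sequence alignment over {A, C, G, U, -, ambiguity codes}.

    Invariants (enforced on construction): all rows have equal length, names
    are unique, and every character is a legal alignment symbol.
    """

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise FormatError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise FormatError(f"duplicate sequence names: {dup}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        allowed = RNA_BASES | AMBIGUITY_CODES | {GAP}
        for name, row in zip(self.names, self.rows):
            bad = set(row) - allowed
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in sequence {name!r}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def select_columns(self, columns: Sequence[int]) -> "RnaAlignment":
        """Sub-alignment restricted to the given columns, in the given order."""
        rows = ["".join(row[j] for j in columns) for row in self.rows]
        return RnaAlignment(list(self.names), rows)

    def select_taxa(self, names: Iterable[str]) -> "RnaAlignment":
        wanted = list(names)
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in wanted if n not in index]
        if missing:
            raise FormatError(f"taxa not in alignment: {missing}")
        return RnaAlignment(wanted, [self.rows[index[n]] for n in wanted])


def _normalize_rna(seq: str, source: str, warned: list[bool]) -> str:
    seq = seq.upper()
    if "T" in seq:
        if not warned[0]:
            logger.warning("T found in %s: converting T to U (DNA input assumed)", source)
            warned[0] = True
        seq = seq.replace("T", "U")
    return seq


def read_alignment(path: Pathish) -> RnaAlignment:
    """Read an aligned FASTA file into an :class:`RnaAlignment`."""
    handle = open(path) if isinstance(path, str) else path
    warned = [False]
    names, rows = [], []
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            names.append(rec.id)
            rows.append(_normalize_rna(str(rec.seq), rec.id, warned))
    finally:
        if isinstance(path, str):
            handle.close()
    return RnaAlignment(names, rows)


def write_alignment(aln: RnaAlignment, path: Pathish) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if isinstance(path, str):
            handle.close()


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

_OPEN = {"(": ")", "[": "]"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass
class SecondaryStructure:
    """A general secondary structure as a pair table over alignment columns.

    ``pairs`` holds (i, j) with i < j; ``unpaired`` is the set of dot columns.
    One extra bracket tier ``[]`` is accepted for a pseudoknot layer; every
    column belongs to exactly one of {5' partner, 3' partner, unpaired}.
    """

    dotbracket: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    unpaired: set[int] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def paired_columns(self) -> set[int]:
        return {i for p in self.pairs for i in p}


def parse_structure(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string by per-tier stack matching.

    Allowed characters: ``(``, ``)``, ``.`` and one pseudoknot tier ``[``/``]``.
    Raises :class:`StructureError` on unbalanced brackets (naming the column)
    and :class:`FormatError` on any other character.
    """
    if not text:
        raise FormatError("empty dot-bracket string")
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    pairs: list[tuple[int, int]] = []
    unpaired: set[int] = set()
    for col, ch in enumerate(text):
        if ch == ".":
            unpaired.add(col)
        elif ch in _OPEN:
            stacks[ch].append(col)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise StructureError(f"unmatched {ch!r} at column {col}")
            pairs.append((stacks[opener].pop(), col))
        else:
            raise FormatError(f"illegal structure character {ch!r} at column {col}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(f"unclosed {opener!r} at column {stack[-1]}")
    pairs.sort()
    return SecondaryStructure(text, pairs, unpaired)


def render_structure(ss: SecondaryStructure) -> str:
    """Inverse of :func:`parse_structure` (uses ``()`` for the first nested
    tier and ``[]`` for pairs that cross it)."""
    chars = ["."] * ss.length
    nested: list[tuple[int, int]] = []
    for i, j in sorted(ss.pairs):
        crossing = any(a < i < b < j or i < a < j < b for a, b in nested)
        if crossing:
            chars[i], chars[j] = "[", "]"
        else:
            chars[i], chars[j] = "(", ")"
            nested.append((i, j))
    return "".join(chars)


def read_structure(path: Pathish) -> SecondaryStructure:
    """Read a plain-text dot-bracket file: first non-comment line is the
    structure; ``#`` starts a comment."""
    handle = open(path) if isinstance(path, str) else path
    try:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                return parse_structure(line)
    finally:
        if isinstance(path, str):
            handle.close()
    raise FormatError("no structure line found")


def write_structure(ss: SecondaryStructure, path: Pathish) -> None:
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write(ss.dotbracket + "\n")
    finally:
        if isinstance(path, str):
            handle.close()


# ---------------------------------------------------------------------------
# Three-row dialect: name / sequence / dot-bracket per record
# ---------------------------------------------------------------------------

def read_threerow(path: Pathish) -> list[tuple[str, str, SecondaryStructure]]:
    """Read the three-row alignment dialect (name, sequence, dot-bracket).

    Returns one ``(name, sequence_row, structure)`` tuple per record; the
    sequence row is T->U normalized. A sequence/structure length mismatch is a
    :class:`FormatError` naming the record.
    """
    handle = open(path) if isinstance(path, str) else path
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if isinstance(path, str):
            handle.close()
    if len(lines) % 3 != 0:
        raise FormatError(
            f"three-row file has {len(lines)} non-empty lines, not a multiple of 3"
        )
    warned = [False]
    out = []
    for k in range(0, len(lines), 3):
        name = lines[k].lstrip(">").strip()
        seq = _normalize_rna(lines[k + 1].strip(), name, warned)
        ss = parse_structure(lines[k + 2].strip())
        if len(seq) != ss.length:
            raise FormatError(
                f"record {name!r}: sequence length {len(seq)} != "
                f"structure length {ss.length}"
            )
        out.append((name, seq, ss))
    return out


def write_threerow(
    records: Iterable[tuple[str, str, SecondaryStructure]], path: Pathish
) -> None:
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        for name, seq, ss in records:
            handle.write(f">{name}\n{seq}\n{ss.dotbracket}\n")
    finally:
        if isinstance(path, str):
            handle.close()


# ---------------------------------------------------------------------------
# Trees (dendropy-backed)
# ---------------------------------------------------------------------------

Tree = dendropy.Tree


def read_tree(path: Pathish) -> Tree:
    """Read a Newick tree. Branch lengths must be non-negative."""
    if isinstance(path, str):
        tree = dendropy.Tree.get(path=path, schema="newick")
    else:
        tree = dendropy.Tree.get(data=path.read(), schema="newick")
    _validate_tree(tree)
    return tree


def tree_from_newick(newick: str) -> Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    _validate_tree(tree)
    return tree


def _validate_tree(tree: Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")


def write_tree(tree: Tree, path: Pathish) -> None:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write(text)
    finally:
        if isinstance(path, str):
            handle.close()
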