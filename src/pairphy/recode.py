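"""Pair-state recoding of RNA alignments under a general secondary structure.

Each structural pair (i, j) of the alignment is collapsed into ONE symbol
written at the 5' position; unpaired columns keep their nucleotide (U written
as T so coded files remain readable by protein-sequence software). Three
alphabets are supported:

* STATE16 — 4 unpaired bases + all 16 ordered base pairs (20 symbols);
* STATE7  — the 10 mismatch pairs collapsed to one symbol 'M' (11 symbols);
* STATE6  — 'M' replaced by '-' (missing), leaving the 6 WC/wobble pairs
  (10 symbols).

The pair-symbol table is a fixed bijection into the 20-letter amino-acid
alphabet; any fixed bijection preserves the method, this one keeps WC/wobble
letters distinct from mismatch letters and is used consistently everywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum

from .rnaio import (
    AMBIGUITY_CODES,
    GAP,
    FormatError,
    PairphyError,
    RnaAlignment,
    SecondaryStructure,
)


class ColumnKind(str, Enum):
    UNPAIRED = "U"
    PAIRED = "P"


#: Canonical (5' base, 3' base) -> coded symbol table.
PAIR_TO_SYMBOL: dict[tuple[str, str], str] = {
    ("A", "A"): "R", ("A", "C"): "N", ("A", "G"): "D", ("A", "U"): "Q",
    ("C", "A"): "E", ("C", "C"): "H", ("C", "G"): "I", ("C", "U"): "L",
    ("G", "A"): "K", ("G", "C"): "F", ("G", "G"): "M", ("G", "U"): "P",
    ("U", "A"): "S", ("U", "C"): "W", ("U", "G"): "Y", ("U", "U"): "V",
}
SYMBOL_TO_PAIR = {v: k for k, v in PAIR_TO_SYMBOL.items()}

#: Watson-Crick + wobble pairs and their coded letters.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
WC_SYMBOLS = "".join(sorted(PAIR_TO_SYMBOL[p] for p in WC_PAIRS))  # FIPQSY
MISMATCH_SYMBOLS = "".join(
    sorted(v for k, v in PAIR_TO_SYMBOL.items() if k not in WC_PAIRS)
)  # DEHKLMNRVW

UNPAIRED_SYMBOLS = "ACGT"  # unpaired U is written T
_UNPAIRED_MAP = {"A": "A", "C": "C", "G": "G", "U": "T"}
_UNPAIRED_INV = {v: k for k, v in _UNPAIRED_MAP.items()}

MISMATCH_COLLAPSED = "M"  # the STATE7 joint mismatch symbol


@dataclass(frozen=True)
class Alphabet:
    """A coded alphabet: 4 unpaired symbols followed by the pair symbols."""

    id: str
    unpaired_symbols: str
    pair_symbols: str
    pair_map: dict[tuple[str, str], str]

    @property
    def symbols(self) -> str:
        return self.unpaired_symbols + self.pair_symbols

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def n_unpaired(self) -> int:
        return len(self.unpaired_symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    @property
    def wc_set(self) -> frozenset[tuple[str, str]]:
        return WC_PAIRS


def _state7_map() -> dict[tuple[str, str], str]:
    return {
        p: (PAIR_TO_SYMBOL[p] if p in WC_PAIRS else MISMATCH_COLLAPSED)
        for p in PAIR_TO_SYMBOL
    }


def _state6_map() -> dict[tuple[str, str], str]:
    return {p: (PAIR_TO_SYMBOL[p] if p in WC_PAIRS else GAP) for p in PAIR_TO_SYMBOL}


STATE16 = Alphabet(
    "STATE16",
    UNPAIRED_SYMBOLS,
    "".join(sorted(PAIR_TO_SYMBOL.values())),
    dict(PAIR_TO_SYMBOL),
)
STATE7 = Alphabet("STATE7", UNPAIRED_SYMBOLS, WC_SYMBOLS + MISMATCH_COLLAPSED, _state7_map())
STATE6 = Alphabet("STATE6", UNPAIRED_SYMBOLS, WC_SYMBOLS, _state6_map())

ALPHABETS = {a.id: a for a in (STATE16, STATE7, STATE6)}

assert STATE16.size == 20 and STATE7.size == 11 and STATE6.size == 10


@dataclass
class CodedAlignment:
    """An alignment over a pair-state alphabet with per-column category.

    Invariant: non-gap symbols in an UNPAIRED column are unpaired symbols and
    those in a PAIRED column are pair symbols.
    """

    names: list[str]
    rows: list[str]
    column_kind: list[ColumnKind]
    alphabet: Alphabet
    structure_hash: str | None = None

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows} | {len(self.column_kind)}) > 1:
            raise FormatError("coded rows and column_kind lengths disagree")
        unp = set(self.alphabet.unpaired_symbols)
        par = set(self.alphabet.pair_symbols)
        for name, row in zip(self.names, self.rows):
            for j, ch in enumerate(row):
                if ch == GAP:
                    continue
                ok = unp if self.column_kind[j] is ColumnKind.UNPAIRED else par
                if ch not in ok:
                    raise FormatError(
                        f"symbol {ch!r} in {self.column_kind[j].name} column {j} "
                        f"of sequence {name!r} (alphabet {self.alphabet.id})"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def select_taxa(self, names: list[str]) -> "CodedAlignment":
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise FormatError(f"taxa not in coded alignment: {missing}")
        return CodedAlignment(
            list(names),
            [self.rows[index[n]] for n in names],
            list(self.column_kind),
            self.alphabet,
            self.structure_hash,
        )

    def select_columns(self, columns: list[int]) -> "CodedAlignment":
        return CodedAlignment(
            list(self.names),
            ["".join(row[j] for j in columns) for row in self.rows],
            [self.column_kind[j] for j in columns],
            self.alphabet,
            self.structure_hash,
        )


def structure_hash(ss: SecondaryStructure) -> str:
    return hashlib.sha1(ss.dotbracket.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Encoding / decoding
# ---------------------------------------------------------------------------

def encode16(aln: RnaAlignment, ss: SecondaryStructure) -> CodedAlignment:
    """Recode an RNA alignment into the 16-pair-state (20-symbol) alphabet.

    Each pair (i, j) emits one symbol at the 5' output position and drops
    column j; unpaired columns pass through (U written as T). If either pair
    partner is a gap or an ambiguity code the output is '-' (missing datum);
    unpaired ambiguity codes also become '-'.
    """
    if ss.length != aln.length:
        raise FormatError(
            f"structure length {ss.length} != alignment length {aln.length}"
        )
    pair_of = {i: j for i, j in ss.pairs}
    drop = {j for _, j in ss.pairs}
    out_cols = [c for c in range(aln.length) if c not in drop]
    kinds = [
        ColumnKind.PAIRED if c in pair_of else ColumnKind.UNPAIRED for c in out_cols
    ]
    rows = []
    for row in aln.rows:
        chars = []
        for c in out_cols:
            if c in pair_of:
                five, three = row[c], row[pair_of[c]]
                if five in AMBIGUITY_CODES or three in AMBIGUITY_CODES \
                        or GAP in (five, three):
                    chars.append(GAP)
                else:
                    chars.append(PAIR_TO_SYMBOL[(five, three)])
            else:
                b = row[c]
                chars.append(GAP if b in AMBIGUITY_CODES else _UNPAIRED_MAP.get(b, b))
        rows.append("".join(chars))
    return CodedAlignment(list(aln.names), rows, kinds, STATE16, structure_hash(ss))


def decode16(coded: CodedAlignment, ss: SecondaryStructure) -> RnaAlignment:
    """Inverse table expansion of :func:`encode16`: re-emits both pair
    partners at their structure positions. Gaps expand to gaps at both
    partner positions."""
    if coded.alphabet.id != "STATE16":
        raise PairphyError(f"decode16 needs STATE16, got {coded.alphabet.id}")
    pair_of = {i: j for i, j in ss.pairs}
    drop = {j for _, j in ss.pairs}
    out_cols = [c for c in range(ss.length) if c not in drop]
    rows = []
    for row in coded.rows:
        chars = [GAP] * ss.length
        for ch, c in zip(row, out_cols):
            if c in pair_of:
                if ch != GAP:
                    five, three = SYMBOL_TO_PAIR[ch]
                    chars[c], chars[pair_of[c]] = five, three
            else:
                chars[c] = _UNPAIRED_INV.get(ch, ch)
        rows.append("".join(chars))
    return RnaAlignment(list(coded.names), rows)


def collapse7(c16: CodedAlignment) -> CodedAlignment:
    """Collapse the 10 mismatch pair symbols to the joint symbol 'M'."""
    if c16.alphabet.id != "STATE16":
        raise PairphyError(f"collapse7 needs STATE16, got {c16.alphabet.id}")
    table = str.maketrans({s: MISMATCH_COLLAPSED for s in MISMATCH_SYMBOLS})
    rows = [row.translate(table) for row in c16.rows]
    return CodedAlignment(
        list(c16.names), rows, list(c16.column_kind), STATE7, c16.structure_hash
    )


def collapse6(c7: CodedAlignment) -> CodedAlignment:
    """Replace every mismatch symbol 'M' with '-' (missing data)."""
    if c7.alphabet.id != "STATE7":
        raise PairphyError(f"collapse6 needs STATE7, got {c7.alphabet.id}")
    rows = [row.replace(MISMATCH_COLLAPSED, GAP) for row in c7.rows]
    return CodedAlignment(
        list(c7.names), rows, list(c7.column_kind), STATE6, c7.structure_hash
    )


def composition(coded: CodedAlignment) -> dict[str, dict[str, float]]:
    """Relative symbol frequencies among non-gap characters, reported
    separately for UNPAIRED and PAIRED columns; each report sums to 1."""
    if not coded.rows or coded.length == 0:
        raise PairphyError("empty alignment")
    counts = {ColumnKind.UNPAIRED: {}, ColumnKind.PAIRED: {}}
    for row in coded.rows:
        for ch, kind in zip(row, coded.column_kind):
            if ch != GAP:
                counts[kind][ch] = counts[kind].get(ch, 0) + 1
    out = {}
    for kind, label in ((ColumnKind.UNPAIRED, "UNPAIRED"), (ColumnKind.PAIRED, "PAIRED")):
        total = sum(counts[kind].values())
        out[label] = {
            s: c / total for s, c in sorted(counts[kind].items())
        } if total else {}
    return out


# ---------------------------------------------------------------------------
# Coded-alignment FASTA I/O
# ---------------------------------------------------------------------------

def write_coded(coded: CodedAlignment, path) -> None:
    """Write a coded alignment as FASTA preceded by ``#`` header comments
    recording the alphabet, the source-structure hash and the column kinds."""
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write(f"# pairphy coded alignment alphabet={coded.alphabet.id}"
                     f" structure={coded.structure_hash or 'NA'}\n")
        kinds = "".join(k.value for k in coded.column_kind)
        handle.write(f"# column_kind={kinds}\n")
        for name, row in zip(coded.names, coded.rows):
            handle.write(f">{name}\n{row}\n")
    finally:
        if isinstance(path, str):
            handle.close()


def read_coded(path) -> CodedAlignment:
    handle = open(path) if isinstance(path, str) else path
    try:
        lines = [ln.rstrip("\n") for ln in handle]
    finally:
        if isinstance(path, str):
            handle.close()
    alphabet_id = shash = kinds = None
    names: list[str] = []
    rows: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            for token in ln[1:].split():
                if token.startswith("alphabet="):
                    alphabet_id = token.split("=", 1)[1]
                elif token.startswith("structure="):
                    shash = token.split("=", 1)[1]
                elif token.startswith("column_kind="):
                    kinds = token.split("=", 1)[1]
        elif ln.startswith(">"):
            names.append(ln[1:].strip())
            rows.append("")
        elif ln.strip():
            if not names:
                raise FormatError("sequence data before first FASTA header")
            rows[-1] += ln.strip()
    if alphabet_id not in ALPHABETS:
        raise FormatError(f"missing or unknown alphabet header: {alphabet_id!r}")
    if kinds is None:
        raise FormatError("missing column_kind header")
    return CodedAlignment(
        names,
        rows,
        [ColumnKind(c) for c in kinds],
        ALPHABETS[alphabet_id],
        None if shash in (None, "NA") else shash,
    )
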