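"""Partitioned conservation/selection statistics on stem vs loop columns.

An RNA gene alignment is split by its general secondary structure into the
paired (stem) and unpaired (loop) column sets; Tajima's D and the mean
pairwise identity (MPI) are computed on each side. D contrasts mean pairwise
diversity pi with the segregating-site estimator S/a1; negative values
indicate an excess of rare variants, the signature of purifying selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

from scipy.stats import beta as beta_dist

from .rnaio import AMBIGUITY_CODES, GAP, PairphyError, RnaAlignment, SecondaryStructure

logger = logging.getLogger("pairphy")


@dataclass
class PartitionMask:
    """Ordered column indices of the paired (both partners) and unpaired
    sides of a structure; disjoint, covering all annotated columns."""

    paired_columns: list[int]
    unpaired_columns: list[int]


def partition_mask(ss: SecondaryStructure) -> PartitionMask:
    paired = sorted({i for p in ss.pairs for i in p})
    unpaired = sorted(ss.unpaired)
    return PartitionMask(paired, unpaired)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None  # None iff S == 0
    p_class: str  # 'p>0.10', '0.10>p>0.05', 'p<0.05', or 'NA'


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def _beta_p_class(D: float, n: int, e2: float, a1: float) -> str:
    # Tajima's beta approximation: D is bounded; rescaled to (0,1) it is
    # treated as Beta(alpha, beta) with mean 0 and variance 1 on the D scale.
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    if n % 2 == 0:
        dmax = (n / (2.0 * (n - 1)) - 1.0 / a1) / math.sqrt(e2)
    else:
        dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    b = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    a = (1 + dmin * dmax) * dmin / (dmax - dmin)
    if a <= 0 or b <= 0:
        return "NA"
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = beta_dist.cdf(x, b, a)
    p = 2.0 * min(cdf, 1.0 - cdf)  # two-tailed
    if p < 0.05:
        return "p<0.05"
    if p < 0.10:
        return "0.10>p>0.05"
    return "p>0.10"


def tajimas_d(aln: RnaAlignment) -> TajimaResult:
    """Tajima's (1989) D on an alignment (complete deletion of columns
    containing any gap or ambiguity code before counting).

    Requires n >= 4 sequences. With no segregating site the statistic is
    undefined and ``D`` is None with p_class 'NA'; no exception is raised.
    """
    n = aln.n_sequences
    if n < 4:
        raise PairphyError(f"Tajima's D needs >= 4 sequences, got {n}")
    skip = AMBIGUITY_CODES | {GAP}
    cols = [
        j for j in range(aln.length)
        if not any(row[j] in skip for row in aln.rows)
    ]
    S = 0
    total_diffs = 0
    for j in cols:
        column = [row[j] for row in aln.rows]
        if len(set(column)) > 1:
            S += 1
            total_diffs += sum(
                1 for x, y in itertools.combinations(column, 2) if x != y
            )
    n_pairs = n * (n - 1) // 2
    pi = total_diffs / n_pairs
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_constants(n)
    if S == 0:
        return TajimaResult(n, 0, pi, a1, a2, b1, b2, c1, c2, e1, e2, None, "NA")
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaResult(
        n, S, pi, a1, a2, b1, b2, c1, c2, e1, e2, D, _beta_p_class(D, n, e2, a1)
    )


# ---------------------------------------------------------------------------
# Mean pairwise identity
# ---------------------------------------------------------------------------

@dataclass
class MpiResult:
    mpi: float
    n_pairs: int


def mpi(aln: RnaAlignment) -> MpiResult:
    """Mean pairwise identity over all unordered sequence pairs.

    Per pair: identical-residue columns / columns where neither sequence is
    gapped (gap-gap columns never count). A pair with zero comparable columns
    contributes identity 0, with a logged warning.
    """
    n = aln.n_sequences
    if n < 2:
        raise PairphyError(f"MPI needs >= 2 sequences, got {n}")
    identities = []
    for (na, a), (nb, b) in itertools.combinations(zip(aln.names, aln.rows), 2):
        comparable = matches = 0
        for x, y in zip(a, b):
            if x != GAP and y != GAP:
                comparable += 1
                if x == y:
                    matches += 1
        if comparable == 0:
            logger.warning("no comparable columns between %r and %r", na, nb)
            identities.append(0.0)
        else:
            identities.append(matches / comparable)
    return MpiResult(sum(identities) / len(identities), len(identities))


def partition_report(
    aln: RnaAlignment, ss: SecondaryStructure
) -> dict[str, dict[str, object]]:
    """Per-partition Tajima's D and MPI, mirroring a one-gene table row."""
    mask = partition_mask(ss)
    out: dict[str, dict[str, object]] = {}
    for label, cols in (("paired", mask.paired_columns), ("unpaired", mask.unpaired_columns)):
        if not cols:
            out[label] = {"D": None, "p_class": "NA", "mpi": None, "S": 0, "pi": 0.0}
            continue
        sub = aln.select_columns(cols)
        taj = tajimas_d(sub)
        out[label] = {
            "D": taj.D,
            "p_class": taj.p_class,
            "mpi": mpi(sub).mpi,
            "S": taj.S,
            "pi": taj.pi,
        }
    return out
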