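"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by direct enumeration or literal
formulas, deliberately sharing no code with the package implementation it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pairphy import CodedAlignment, ColumnKind
from pairphy.rnaio import GAP


# ---------------------------------------------------------------------------
# Likelihood by exhaustive interior-state enumeration
# ---------------------------------------------------------------------------

def enumeration_loglik(tree, coded: CodedAlignment, model) -> float:
    """Total lnL by summing over every assignment of states to internal
    nodes (and missing leaves). Exponential: only for tiny trees."""
    total = 0.0
    sym_index = {s: i for i, s in enumerate(model.alphabet.symbols)}
    nu = model.alphabet.n_unpaired
    for j in range(coded.length):
        paired = coded.column_kind[j] is ColumnKind.PAIRED
        lo, hi = (nu, model.alphabet.size) if paired else (0, nu)
        states = range(lo, hi)
        pi = model.pi[lo:hi] / model.pi[lo:hi].sum()

        nodes = list(tree.postorder_node_iter())
        fixed = {}
        free = []
        for nd in nodes:
            if nd.is_leaf():
                ch = coded.rows[coded.names.index(nd.taxon.label)][j]
                if ch == GAP or ch not in sym_index:
                    free.append(nd)
                else:
                    fixed[id(nd)] = sym_index[ch]
            else:
                free.append(nd)
        like = 0.0
        P = {
            id(nd): model.transition_matrix(nd.edge.length or 0.0)
            for nd in nodes if nd.parent_node is not None
        }
        for assign in itertools.product(states, repeat=len(free)):
            state = dict(fixed)
            for nd, s in zip(free, assign):
                state[id(nd)] = s
            prob = pi[state[id(tree.seed_node)] - lo]
            for nd in nodes:
                if nd.parent_node is not None:
                    prob *= P[id(nd)][state[id(nd.parent_node)], state[id(nd)]]
            like += prob
        total += math.log(like)
    return total


# ---------------------------------------------------------------------------
# Tajima's D by literal formulas
# ---------------------------------------------------------------------------

def literal_tajimas_d(rows: list[str]):
    """(S, pi, D) by direct pairwise counting and the 1989 constants;
    columns containing anything outside ACGU are dropped."""
    n = len(rows)
    keep = [
        j for j in range(len(rows[0]))
        if all(r[j] in "ACGU" for r in rows)
    ]
    S = sum(1 for j in keep if len({r[j] for r in rows}) > 1)
    diffs = 0
    for a, b in itertools.combinations(rows, 2):
        diffs += sum(1 for j in keep if a[j] != b[j])
    pi = diffs / (n * (n - 1) / 2)
    if S == 0:
        return S, pi, None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return S, pi, (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# Matching-split distance by enumerating all matchings
# ---------------------------------------------------------------------------

def enumeration_ms(splits1, splits2, leaves) -> float:
    """Minimum-cost perfect matching by trying every permutation."""
    n = len(leaves)
    all_set = frozenset(leaves)
    s1 = list(splits1)
    s2 = list(splits2)
    size = max(len(s1), len(s2))
    s1 += [None] * (size - len(s1))
    s2 += [None] * (size - len(s2))

    def cost(a, b):
        if a is None and b is None:
            return 0
        if a is None:
            return min(len(b), n - len(b))
        if b is None:
            return min(len(a), n - len(a))
        ac, bc = all_set - a, all_set - b
        return n - max(len(a & b) + len(ac & bc), len(a & bc) + len(ac & b))

    if size == 0:
        return 0.0
    best = math.inf
    for perm in itertools.permutations(range(size)):
        best = min(best, sum(cost(s1[i], s2[perm[i]]) for i in range(size)))
    return float(best)


# ---------------------------------------------------------------------------
# Random structures / alignments
# ---------------------------------------------------------------------------

def random_structure_string(rng: np.random.Generator, length: int,
                            pair_prob: float = 0.5) -> str:
    """Random nested dot-bracket by recursive bracket insertion."""
    chars = ["."] * length
    positions = list(range(length))

    def fill(lo: int, hi: int) -> None:
        i = lo
        while i < hi - 1:
            if rng.random() < pair_prob:
                span = int(rng.integers(2, min(hi - i, 12) + 1))
                chars[i], chars[i + span - 1] = "(", ")"
                fill(i + 1, i + span - 1)
                i += span
            else:
                i += 1

    fill(0, length)
    del positions
    return "".join(chars)


def random_rna_alignment(rng: np.random.Generator, n: int, length: int,
                         gap_prob: float = 0.0) -> list[str]:
    bases = np.array(list("ACGU"))
    rows = []
    for _ in range(n):
        row = bases[rng.integers(0, 4, size=length)]
        if gap_prob:
            mask = rng.random(length) < gap_prob
            row = np.where(mask, "-", row)
        rows.append("".join(row))
    return rows
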