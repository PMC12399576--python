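"""Simulation of coded-alignment evolution and synthetic RNA fixtures.

``simulate_coded`` evolves pair-state columns down a tree under a
block-diagonal model (root states drawn from the block-conditional
stationary frequencies, children via P(rate * t)). ``generate_fixture``
builds a complete synthetic study unit — an ultrametric Yule tree, a
stem/loop structure template, and the RNA alignment obtained by expanding
simulated stem pair-states into their two nucleotide partners — so every
downstream stage can be exercised without real data.

Stem columns are Watson-Crick/wobble-enriched with a tunable mismatch
frequency, and stem substitutions include direct pair-to-pair exchanges,
which is what compensatory (covarying) evolution looks like after recoding.
All randomness flows from explicit integer seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .recode import (
    PAIR_TO_SYMBOL,
    STATE16,
    WC_PAIRS,
    CodedAlignment,
    ColumnKind,
    decode16,
)
from .rnaio import PairphyError, RnaAlignment, SecondaryStructure, Tree, parse_structure
from .submodel import UNIFORM_RATES, RateModel, SubstitutionModel, build_model

#: a tRNA-like cloverleaf template: acceptor stem, three stem-loops
CLOVERLEAF = (
    "((((((("
    "..((((........))))."
    "(((((.......)))))"
    "....."
    "((((.......))))"
    ")))))))...."
)


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------

def yule_tree(n_taxa: int, seed: int, mean_root_to_tip: float = 0.5,
              birth_rate: float = 1.0) -> Tree:
    """Ultrametric equal-rate pure-birth tree, rescaled so the root-to-tip
    path equals ``mean_root_to_tip`` expected substitutions per site."""
    if n_taxa < 2:
        raise PairphyError("a Yule tree needs >= 2 taxa")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # forward simulation; the root splits at time 0 (no stem branch), then a
    # random lineage splits after each exponential waiting time
    first = (dendropy.Node(), dendropy.Node())
    for nd in first:
        tree.seed_node.add_child(nd)
    tips = [(nd, 0.0) for nd in first]  # (node, birth time)
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        idx = rng.integers(len(tips))
        node, born = tips.pop(idx)
        node.edge.length = t - born
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        tips.append((left, t))
        tips.append((right, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for i, (node, born) in enumerate(tips):
        node.edge.length = t_end - born
        node.taxon = taxa.get_taxon(f"t{i}")
    depth = t_end  # ultrametric: root-to-tip time
    scale = mean_root_to_tip / depth if depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Evolving coded columns along a tree
# ---------------------------------------------------------------------------

def simulate_coded(
    tree: Tree,
    model: SubstitutionModel,
    rate_model: RateModel = UNIFORM_RATES,
    n_columns: int = 100,
    column_kinds: list[ColumnKind] | None = None,
    seed: int = 0,
) -> CodedAlignment:
    """Simulate a coded alignment along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies conditional on
    each column's block; each branch applies P(rate_k * t) where rate_k is
    the column's rate category (0 with probability p_inv). Deterministic
    given the seed.
    """
    if n_columns < 1:
        raise PairphyError("n_columns must be >= 1")
    if column_kinds is None:
        column_kinds = [ColumnKind.PAIRED] * n_columns
    if len(column_kinds) != n_columns:
        raise PairphyError("column_kinds length must equal n_columns")
    nu = model.alphabet.n_unpaired
    has_pairs = model.alphabet.size > nu
    for kind in set(column_kinds):
        if kind is ColumnKind.PAIRED and not has_pairs:
            raise PairphyError("model has no paired block for PAIRED columns")

    rng = np.random.default_rng(seed)
    kinds_arr = np.array([k is ColumnKind.PAIRED for k in column_kinds])

    # per-column rate multipliers from the +I+G mixture
    rates = np.where(
        rng.random(n_columns) < rate_model.p_inv,
        0.0,
        rng.choice(rate_model.rates, size=n_columns, p=rate_model.weights),
    )

    def block_bounds(paired: bool) -> tuple[int, int]:
        return (nu, model.alphabet.size) if paired else (0, nu)

    states = np.empty(n_columns, dtype=np.int64)
    for paired in (False, True):
        cols = np.where(kinds_arr == paired)[0]
        if cols.size == 0:
            continue
        lo, hi = block_bounds(paired)
        p = model.pi[lo:hi] / model.pi[lo:hi].sum()
        states[cols] = lo + rng.choice(hi - lo, size=cols.size, p=p)

    rate_values = np.unique(rates)
    node_states: dict[int, np.ndarray] = {id(tree.seed_node): states}
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            t = node.edge.length or 0.0
            parent = node_states[id(node.parent_node)]
            child = parent.copy()
            for r in rate_values:
                if r == 0.0 or t == 0.0:
                    continue
                sel = np.where(rates == r)[0]
                if sel.size == 0:
                    continue
                P = model.transition_matrix(r * t)
                cum = P.cumsum(axis=1)
                cum /= cum[:, -1:]  # exact 1 in the last column despite clipping
                u = rng.random(sel.size)
                rows = cum[parent[sel]]
                child[sel] = (u[:, None] > rows).sum(axis=1)
            node_states[id(node)] = child
        if node.is_leaf():
            leaf_rows[node.taxon.label] = node_states[id(node)]

    symbols = model.alphabet.symbols
    names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    rows = ["".join(symbols[s] for s in leaf_rows[n]) for n in names]
    return CodedAlignment(names, rows, list(column_kinds), model.alphabet)


# ---------------------------------------------------------------------------
# Default stem/loop models for fixtures
# ---------------------------------------------------------------------------

def default_loop_frequencies() -> np.ndarray:
    # loop composition skewed A > U > G > C, as in mitochondrial RNA loops
    return np.array([0.45, 0.08, 0.12, 0.35])


def default_stem_model(mismatch_freq: float = 0.10,
                       compensatory_rate: float = 0.5) -> SubstitutionModel:
    """A STATE16 model for fixture generation.

    WC/wobble pairs carry 1 - mismatch_freq of the stem frequency mass
    (AU > UA > GC > CG > UG > GU, echoing real stem composition); the 10
    mismatches share ``mismatch_freq``. Exchangeabilities are 1 for
    single-base pair changes, ``compensatory_rate`` for double (compensatory)
    changes, doubled between WC pairs sharing no strand base to keep
    CBC-style exchanges visible.
    """
    if not 0 <= mismatch_freq < 1:
        raise PairphyError("mismatch_freq must be in [0, 1)")
    a = STATE16
    wc_weights = {
        ("A", "U"): 0.30, ("U", "A"): 0.27, ("G", "C"): 0.18,
        ("C", "G"): 0.11, ("U", "G"): 0.09, ("G", "U"): 0.05,
    }
    pi = np.zeros(a.size)
    pi[:4] = default_loop_frequencies() * 1e-9  # fixture columns are stems
    n_mm = 10
    for pair, sym in PAIR_TO_SYMBOL.items():
        i = a.index(sym)
        if pair in WC_PAIRS:
            pi[i] = (1 - mismatch_freq) * wc_weights[pair]
        else:
            pi[i] = mismatch_freq / n_mm
    S = np.zeros((a.size, a.size))
    pair_syms = [(p, PAIR_TO_SYMBOL[p]) for p in PAIR_TO_SYMBOL]
    for (pa, sa), (pb, sb) in (
        (x, y) for x in pair_syms for y in pair_syms if x[1] != y[1]
    ):
        shared = (pa[0] == pb[0]) + (pa[1] == pb[1])
        if shared == 1:
            rate = 1.0
        else:  # both partners differ: compensatory double change
            rate = compensatory_rate
            if pa in WC_PAIRS and pb in WC_PAIRS:
                rate *= 2.0
        S[a.index(sa), a.index(sb)] = rate
    S[:4, :4] = 1.0
    return build_model(a, pi, S)


def default_loop_model() -> SubstitutionModel:
    a = STATE16
    pi = np.zeros(a.size)
    pi[:4] = default_loop_frequencies()
    pi[4:] = 1e-9
    S = np.zeros((a.size, a.size))
    S[:4, :4] = 1.0
    S[4:, 4:] = 1.0
    return build_model(a, pi, S)


# ---------------------------------------------------------------------------
# Full fixture generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    n_taxa: int = 16
    structure: str = CLOVERLEAF
    stem_model: SubstitutionModel | None = None
    loop_model: SubstitutionModel | None = None
    rate_model: RateModel = field(default_factory=RateModel)
    mean_root_to_tip: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise PairphyError("fixtures need >= 4 taxa")
        parse_structure(self.structure)  # validates


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[RnaAlignment, SecondaryStructure, Tree]:
    """Simulate a Yule tree, evolve the structure's stem columns as
    pair-states and its loop columns as nucleotides, and expand the result
    into a gapless, structure-consistent RNA alignment."""
    ss = parse_structure(spec.structure)
    tree = yule_tree(spec.n_taxa, spec.seed, spec.mean_root_to_tip)
    stem_model = spec.stem_model or default_stem_model()
    loop_model = spec.loop_model or default_loop_model()

    drop = {j for _, j in ss.pairs}
    coded_cols = [c for c in range(ss.length) if c not in drop]
    kinds = [
        ColumnKind.PAIRED if c not in ss.unpaired else ColumnKind.UNPAIRED
        for c in coded_cols
    ]
    paired_idx = [i for i, k in enumerate(kinds) if k is ColumnKind.PAIRED]
    loop_idx = [i for i, k in enumerate(kinds) if k is ColumnKind.UNPAIRED]

    stem = simulate_coded(
        tree, stem_model, spec.rate_model, len(paired_idx),
        [ColumnKind.PAIRED] * len(paired_idx), seed=spec.seed + 1,
    ) if paired_idx else None
    loop = simulate_coded(
        tree, loop_model, spec.rate_model, len(loop_idx),
        [ColumnKind.UNPAIRED] * len(loop_idx), seed=spec.seed + 2,
    ) if loop_idx else None

    names = stem.names if stem else loop.names
    rows = []
    for ni, name in enumerate(names):
        chars = [""] * len(coded_cols)
        if stem is not None:
            srow = stem.rows[stem.names.index(name)]
            for ch, i in zip(srow, paired_idx):
                chars[i] = ch
        if loop is not None:
            lrow = loop.rows[loop.names.index(name)]
            for ch, i in zip(lrow, loop_idx):
                chars[i] = ch
        rows.append("".join(chars))
    coded = CodedAlignment(list(names), rows, kinds, STATE16)
    aln = decode16(coded, ss)
    return aln, ss, tree
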