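"""Empirical matrix estimation from coded training alignments.

The procedure mirrors the classic empirical-model pipelines for protein
matrices: split the taxa into tractable subsets (by a guide tree or at
random), then alternate between (a) re-deriving each subset's NJ topology and
branch lengths under the current model and (b) maximizing the pooled
log-likelihood over the within-block exchangeabilities with trees fixed.
Frequencies are count-based (+F style) and fixed at the smoothed observed
symbol counts; state pairs never co-observed in any column keep an
exchangeability of exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr, ttest_rel

from .phylik import PruningEngine, nj_tree, optimize_branch_lengths
from .recode import STATE7, STATE16, Alphabet, CodedAlignment, ColumnKind, WC_SYMBOLS
from .rnaio import GAP, PairphyError
from .submodel import SubstitutionModel, build_model

logger = logging.getLogger("pairphy")


class SplitMode(str, Enum):
    TREE_BASED = "tree"
    RANDOM = "random"


@dataclass
class SplitConfig:
    mode: SplitMode = SplitMode.TREE_BASED
    k: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise PairphyError(f"subset size k must be >= 4, got {self.k}")


@dataclass
class EstimationResult:
    model: SubstitutionModel
    iterations: int
    lnl_trace: list[float] = field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# Taxon splitting
# ---------------------------------------------------------------------------

def _chunk_with_merge(order: list[str], k: int) -> list[list[str]]:
    chunks = [order[i:i + k] for i in range(0, len(order), k)]
    if len(chunks) > 1 and len(chunks[-1]) < k:
        # trailing remainder folded into the previous subset
        chunks[-2].extend(chunks.pop())
    return chunks


def split_taxa(
    coded: CodedAlignment,
    config: SplitConfig,
    guide_model: SubstitutionModel | None = None,
) -> list[CodedAlignment]:
    """Partition the taxa into subsets of up to ~k for estimation.

    RANDOM: shuffle with the config seed and chunk by k (a trailing
    remainder is merged into the previous subset so no subset falls below 4
    taxa). TREE_BASED: build a guide NJ tree under ``guide_model``, root it
    at its longest internal edge and cut it top-down into complete clades of
    <= k leaves, so closely related taxa stay together.
    """
    n = coded.n_sequences
    if n < 4:
        raise PairphyError(f"need >= 4 taxa to split, got {n}")
    if n <= config.k:
        return [coded]
    if config.mode is SplitMode.RANDOM:
        rng = np.random.default_rng(config.seed)
        order = [coded.names[i] for i in rng.permutation(n)]
        groups = _chunk_with_merge(order, config.k)
    else:
        if guide_model is None:
            raise PairphyError("TREE_BASED splitting needs a guide model")
        tree = nj_tree(coded, guide_model)
        groups = _tree_cut(tree, config.k)
    merged: list[list[str]] = []
    for g in groups:
        if len(g) < 4 and merged:
            merged[-1].extend(g)
        else:
            merged.append(list(g))
    return [coded.select_taxa(g) for g in merged]


def _tree_cut(tree, k: int) -> list[list[str]]:
    """Cut the guide tree into complete clades of <= k leaves.

    The tree is first rooted at its longest internal edge (the deepest
    divergence), then clades are emitted top-down: a clade small enough is
    one group, a larger one recurses into its children. Distinct clades that
    each fit under k therefore never get split or mixed."""
    internal = [
        e for e in tree.preorder_edge_iter()
        if e.length is not None and e.tail_node is not None
        and not e.head_node.is_leaf()
    ]
    if internal:
        longest = max(internal, key=lambda e: e.length)
        tree.reroot_at_edge(longest, update_bipartitions=False)
    groups: list[list[str]] = []

    def emit(node) -> None:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if len(leaves) <= k:
            groups.append(leaves)
        else:
            for ch in node.child_nodes():
                emit(ch)

    emit(tree.seed_node)
    return groups


def holdout_split(
    coded: CodedAlignment, n_test: int, seed: int
) -> tuple[CodedAlignment, CodedAlignment]:
    """Random training/test taxon split (e.g. 263/29 at full scale)."""
    if not 0 < n_test < coded.n_sequences:
        raise PairphyError(f"n_test must be in (0, {coded.n_sequences})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(coded.n_sequences)
    test = sorted(order[:n_test])
    train = sorted(order[n_test:])
    return (
        coded.select_taxa([coded.names[i] for i in train]),
        coded.select_taxa([coded.names[i] for i in test]),
    )


# ---------------------------------------------------------------------------
# Initial models
# ---------------------------------------------------------------------------

def blosum62_init(alphabet: Alphabet) -> SubstitutionModel:
    """Symbol-wise reinterpretation of the Blosum62 log-odds over the coded
    alphabet: exchangeability 2^(score/2) for each within-block symbol pair,
    uniform frequencies. Only sensible as an optimization starting point."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    k = alphabet.size
    S = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            a, b = alphabet.symbols[i], alphabet.symbols[j]
            if a in blosum.alphabet and b in blosum.alphabet:
                S[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    S = (S + S.T) / 2.0
    return build_model(alphabet, np.full(k, 1.0 / k), S)


# ---------------------------------------------------------------------------
# Empirical matrix estimation
# ---------------------------------------------------------------------------

def observed_frequencies(subsets: list[CodedAlignment]) -> np.ndarray:
    alphabet = subsets[0].alphabet
    counts = np.zeros(alphabet.size)
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    for sub in subsets:
        for row in sub.rows:
            for ch in row:
                if ch in index:
                    counts[index[ch]] += 1
    if counts.sum() == 0:
        raise PairphyError("no observed symbols in subsets")
    return counts / counts.sum()


def _coobservation_mask(subsets: list[CodedAlignment]) -> np.ndarray:
    """Within-block state pairs observed together in at least one column."""
    alphabet = subsets[0].alphabet
    k, nu = alphabet.size, alphabet.n_unpaired
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    mask = np.zeros((k, k), dtype=bool)
    for sub in subsets:
        for j in range(sub.length):
            states = {index[row[j]] for row in sub.rows if row[j] in index}
            for a in states:
                for b in states:
                    if a != b:
                        mask[a, b] = True
    mask[:nu, nu:] = False
    mask[nu:, :nu] = False
    return mask


def estimate_empirical_model(
    subsets: list[CodedAlignment],
    initial_model: SubstitutionModel,
    tol: float = 0.1,
    max_iter: int = 10,
) -> EstimationResult:
    """Iterative tree/matrix maximum-likelihood estimation.

    Alternates NJ-topology + branch-length optimization per subset with a
    quasi-Newton maximization of the pooled lnL over log-exchangeabilities
    (frequencies fixed at smoothed observed counts; never-co-observed state
    pairs pinned at zero). Stops when the total lnL gain falls below ``tol``
    or after ``max_iter`` iterations. The lnL trace is non-decreasing.
    """
    alphabet = subsets[0].alphabet
    for sub in subsets:
        if sub.alphabet.id != alphabet.id:
            raise PairphyError("subsets use different alphabets")
        if all(r == sub.rows[0] for r in sub.rows):
            raise PairphyError(
                f"degenerate subset (all sequences identical): {sub.names[:3]}..."
            )
    if initial_model.alphabet.id != alphabet.id:
        raise PairphyError("initial model alphabet does not match the subsets")

    pi = observed_frequencies(subsets)
    mask = _coobservation_mask(subsets)
    iu = np.triu_indices(alphabet.size, 1)
    free = mask[iu]
    if not free.any():
        raise PairphyError("no co-observed state pairs; cannot estimate")

    s0 = initial_model.S[iu][free]
    x = np.log(np.maximum(s0, 1e-3))

    def model_from(xv: np.ndarray) -> SubstitutionModel:
        svec = np.zeros(len(iu[0]))
        svec[free] = np.exp(xv)
        S = np.zeros((alphabet.size, alphabet.size))
        S[iu] = svec
        S = S + S.T
        return build_model(alphabet, pi, S)

    model = model_from(x)
    trees: list = [None] * len(subsets)
    lengths: list = [None] * len(subsets)
    trace: list[float] = []
    converged = False
    iterations = 0

    for iteration in range(max_iter):
        iterations = iteration + 1
        # (a) topology + branch lengths per subset under the current model
        total_a = 0.0
        for si, sub in enumerate(subsets):
            proposal = nj_tree(sub, model)
            proposal, lnl_new = optimize_branch_lengths(proposal, sub, model)
            if trees[si] is not None:
                old, lnl_old = optimize_branch_lengths(trees[si], sub, model)
                if lnl_old >= lnl_new:
                    proposal, lnl_new = old, lnl_old
            trees[si] = proposal
            total_a += lnl_new

        # (b) exchangeabilities with trees fixed
        engines = [PruningEngine(t, sub) for t, sub in zip(trees, subsets)]

        def neg(xv: np.ndarray) -> float:
            m = model_from(xv)
            return -sum(e.total_loglik(m) for e in engines)

        res = minimize(neg, x, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-9})
        if -res.fun >= total_a:
            x = res.x
        model = model_from(x)
        total_b = -neg(x)
        logger.info("estimation iteration %d: lnL %.4f", iterations, total_b)
        if trace and total_b - trace[-1] < tol:
            trace.append(total_b)
            converged = True
            break
        trace.append(total_b)

    return EstimationResult(model, iterations, trace, converged)


# ---------------------------------------------------------------------------
# Parameter comparison between models
# ---------------------------------------------------------------------------

def _offdiag_exchangeabilities(model: SubstitutionModel) -> np.ndarray:
    """Upper-triangle within-block S entries, normalized to mean 1."""
    k, nu = model.alphabet.size, model.alphabet.n_unpaired
    iu = np.triu_indices(k, 1)
    within = ((iu[0] < nu) & (iu[1] < nu)) | ((iu[0] >= nu) & (iu[1] >= nu))
    vec = model.S[iu][within]
    return vec / vec.mean() if vec.mean() > 0 else vec


def compare_model_parameters(
    model_a: SubstitutionModel, model_b: SubstitutionModel
) -> dict[str, float]:
    """Pearson correlations of frequencies and exchangeabilities plus a
    paired-difference t test on the (mean-normalized) exchangeabilities."""
    if model_a.alphabet.id != model_b.alphabet.id:
        raise PairphyError("models use different alphabets")
    fa, fb = model_a.pi, model_b.pi
    sa, sb = _offdiag_exchangeabilities(model_a), _offdiag_exchangeabilities(model_b)
    freq_r, freq_p = pearsonr(fa, fb)
    exch_r, exch_p = pearsonr(sa, sb)
    if np.abs(sa - sb).max() < 1e-9 * max(1.0, np.abs(sa).max()):
        t_stat, t_p = 0.0, 1.0  # identical up to round-off
    else:
        t_stat, t_p = ttest_rel(sa, sb)
    return {
        "freq_r": float(freq_r),
        "freq_p": float(freq_p),
        "exch_r": float(exch_r),
        "exch_p": float(exch_p),
        "paired_t": float(t_stat),
        "paired_t_p": float(t_p),
    }


# ---------------------------------------------------------------------------
# Expanding a mismatch-collapsed model back onto the 16-pair alphabet
# ---------------------------------------------------------------------------

def expand_collapsed_model(
    model7: SubstitutionModel, mismatch_weights: np.ndarray | None = None
) -> SubstitutionModel:
    """Lift a STATE7 model onto STATE16 by tying all mismatch pairs.

    The joint mismatch frequency is shared among the 10 mismatch states
    (equally, or by ``mismatch_weights``); every mismatch state inherits the
    collapsed state's exchangeabilities, and mismatch-mismatch exchanges get
    their mean. Useful as the 'collapsed' competitor in model-fit contrasts.
    """
    if model7.alphabet.id != "STATE7":
        raise PairphyError("expand_collapsed_model needs a STATE7 model")
    a7, a16 = STATE7, STATE16
    m_idx7 = a7.index("M")
    mismatch16 = [i for i, s in enumerate(a16.symbols)
                  if i >= a16.n_unpaired and s not in WC_SYMBOLS]
    if mismatch_weights is None:
        mismatch_weights = np.full(len(mismatch16), 1.0 / len(mismatch16))
    mismatch_weights = np.asarray(mismatch_weights, float)
    mismatch_weights = mismatch_weights / mismatch_weights.sum()

    shared = [s for s in a16.symbols if s in a7.symbols and s != "M"]
    pi16 = np.zeros(a16.size)
    S16 = np.zeros((a16.size, a16.size))
    for s in shared:
        pi16[a16.index(s)] = model7.pi[a7.index(s)]
    for w, i in zip(mismatch_weights, mismatch16):
        pi16[i] = model7.pi[m_idx7] * w
    for s in shared:
        for t in shared:
            if s != t:
                S16[a16.index(s), a16.index(t)] = model7.S[a7.index(s), a7.index(t)]
    for i in mismatch16:
        for s in shared:
            S16[i, a16.index(s)] = S16[a16.index(s), i] = model7.S[m_idx7, a7.index(s)]
    wc_m = [model7.S[m_idx7, a7.index(s)] for s in shared if s in WC_SYMBOLS]
    mm = float(np.mean(wc_m)) if wc_m else 1.0
    for i in mismatch16:
        for j in mismatch16:
            if i != j:
                S16[i, j] = mm
    return build_model(a16, pi16, S16)
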