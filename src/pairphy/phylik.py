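"""Felsenstein pruning over coded alignments, +I+G4, AIC and model fit.

Columns are evaluated within their own block (loop or stem) of the
block-diagonal model: root frequencies are the stationary frequencies
conditional on the block, missing data ('-') is a uniform partial likelihood
over the block's states, and site patterns are compressed per block before
pruning. Per-node rescaling with logged scale factors keeps long alignments
from underflowing.

Parameter counting for AIC follows the convention for empirical models:
branch lengths plus the free rate-heterogeneity parameters (p_inv, alpha); a
fixed empirical exchangeability matrix and count-based frequencies add zero.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .recode import CodedAlignment, ColumnKind
from .rnaio import GAP, PairphyError, Tree
from .submodel import UNIFORM_RATES, RateModel, SubstitutionModel

_MIN_BRANCH = 1e-9
_MAX_BRANCH = 20.0


@dataclass
class ModelFitResult:
    site_lnl: np.ndarray
    total_lnl: float
    n_params: int
    n_sites: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.total_lnl


def aic(total_lnl: float, n_params: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    if n_params < 0:
        raise PairphyError("n_params must be >= 0")
    return 2.0 * n_params - 2.0 * total_lnl


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Precompiled pruning for one (tree topology, coded alignment) pair.

    The tree's topology and the alignment's site patterns are compiled once;
    branch lengths, the substitution model and the rate model can vary per
    likelihood call, which is what the optimizers need.
    """

    def __init__(self, tree: Tree, coded: CodedAlignment):
        leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = leaf_names - set(coded.names)
        if missing:
            raise PairphyError(f"tree leaves without sequences: {sorted(missing)}")
        self.tree = tree
        self.coded = coded
        self.alphabet = coded.alphabet

        # flatten the tree: postorder ids, child lists, edge lengths
        nodes = list(tree.postorder_node_iter())
        self._node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self._postorder = nodes
        self._children: list[list[tuple[int, int]]] = []  # (child_node_idx, edge_idx)
        self._edges: list[dendropy.Edge] = []
        self.edge_lengths: list[float] = []
        for nd in nodes:
            entry = []
            for ch in nd.child_nodes():
                eidx = len(self._edges)
                self._edges.append(ch.edge)
                self.edge_lengths.append(
                    ch.edge.length if ch.edge.length is not None else 0.0
                )
                entry.append((self._node_index[id(ch)], eidx))
            self._children.append(entry)
        self._root_idx = self._node_index[id(tree.seed_node)]
        self._leaf_rows = {
            self._node_index[id(lf)]: coded.names.index(lf.taxon.label)
            for lf in tree.leaf_node_iter()
        }

        self._compile_patterns()

    # -- pattern compilation ------------------------------------------------

    def _compile_patterns(self) -> None:
        coded = self.coded
        nu = self.alphabet.n_unpaired
        sym_index = {s: i for i, s in enumerate(self.alphabet.symbols)}
        self._blocks = {}
        for kind, offset, width in (
            (ColumnKind.UNPAIRED, 0, nu),
            (ColumnKind.PAIRED, nu, self.alphabet.size - nu),
        ):
            cols = [j for j, k in enumerate(coded.column_kind) if k is kind]
            if not cols:
                self._blocks[kind] = None
                continue
            leaf_ids = sorted(self._leaf_rows)
            mat = np.full((len(leaf_ids), len(cols)), -1, dtype=np.int16)
            for li, node_id in enumerate(leaf_ids):
                row = coded.rows[self._leaf_rows[node_id]]
                for cj, j in enumerate(cols):
                    ch = row[j]
                    if ch != GAP and ch in sym_index:
                        mat[li, cj] = sym_index[ch] - offset
            patterns, inverse, counts = np.unique(
                mat, axis=1, return_inverse=True, return_counts=True
            )
            self._blocks[kind] = {
                "cols": np.array(cols),
                "leaf_ids": leaf_ids,
                "patterns": patterns,  # (n_leaves, n_patterns), -1 = missing
                "inverse": inverse.ravel(),
                "counts": counts,
                "offset": offset,
                "width": width,
            }

    # -- likelihood ---------------------------------------------------------

    def _block_site_logliks(
        self, block, model: SubstitutionModel, rate: float, edge_lengths
    ) -> np.ndarray:
        """log-likelihood of each pattern of one block at one rate."""
        width, offset = block["width"], block["offset"]
        n_pat = block["patterns"].shape[1]
        pi_block = model.pi[offset:offset + width]
        pi_block = pi_block / pi_block.sum()

        P = {}  # edge idx -> block of P(rate * t)
        for eidx, t in enumerate(edge_lengths):
            P[eidx] = model.transition_matrix(rate * t)[
                offset:offset + width, offset:offset + width
            ]

        # leaf partials: indicator rows, ones for missing
        eye = np.vstack([np.eye(width), np.ones((1, width))])
        leaf_partial = {
            node_id: eye[block["patterns"][li]]
            for li, node_id in enumerate(block["leaf_ids"])
        }

        partial = [None] * len(self._postorder)
        log_scale = np.zeros(n_pat)
        for idx in range(len(self._postorder)):
            if not self._children[idx]:
                partial[idx] = leaf_partial[idx]
                continue
            acc = np.ones((n_pat, width))
            for child_idx, eidx in self._children[idx]:
                acc *= partial[child_idx] @ P[eidx].T
                partial[child_idx] = None  # free memory
            scale = acc.max(axis=1)
            scale[scale == 0.0] = 1.0
            acc /= scale[:, None]
            log_scale += np.log(scale)
            partial[idx] = acc
        root = partial[self._root_idx]
        like = root @ pi_block
        with np.errstate(divide="ignore"):
            return np.log(like) + log_scale

    def _block_invariant_logliks(self, block, model) -> np.ndarray:
        """Invariant-site likelihood per pattern: sum_s pi_s over states s
        compatible with every observed leaf (0 if the column varies)."""
        width, offset = block["width"], block["offset"]
        pi_block = model.pi[offset:offset + width]
        pi_block = pi_block / pi_block.sum()
        pats = block["patterns"]
        out = np.zeros(pats.shape[1])
        for p in range(pats.shape[1]):
            obs = set(pats[:, p]) - {-1}
            if not obs:
                out[p] = 1.0
            elif len(obs) == 1:
                out[p] = pi_block[obs.pop()]
        return out

    def site_logliks(
        self,
        model: SubstitutionModel,
        rate_model: RateModel = UNIFORM_RATES,
        edge_lengths: list[float] | None = None,
    ) -> np.ndarray:
        """Per-column log-likelihoods in original column order."""
        if model.alphabet.id != self.alphabet.id:
            raise PairphyError(
                f"model alphabet {model.alphabet.id} != data alphabet {self.alphabet.id}"
            )
        t = self.edge_lengths if edge_lengths is None else list(edge_lengths)
        out = np.zeros(self.coded.length)
        for kind in (ColumnKind.UNPAIRED, ColumnKind.PAIRED):
            block = self._blocks[kind]
            if block is None:
                continue
            per_cat = np.stack([
                self._block_site_logliks(block, model, r, t)
                for r in rate_model.rates
            ])  # (ncat, n_patterns)
            m = per_cat.max(axis=0)
            m = np.where(np.isfinite(m), m, 0.0)
            mix = (rate_model.weights[:, None] * np.exp(per_cat - m)).sum(axis=0)
            like_var = np.exp(m) * mix
            if rate_model.p_inv > 0:
                inv = self._block_invariant_logliks(block, model)
                like = rate_model.p_inv * inv + (1 - rate_model.p_inv) * like_var
            else:
                like = like_var
            with np.errstate(divide="ignore"):
                pattern_lnl = np.log(like)
            out[block["cols"]] = pattern_lnl[block["inverse"]]
        return out

    def total_loglik(self, model, rate_model=UNIFORM_RATES, edge_lengths=None) -> float:
        t = self.edge_lengths if edge_lengths is None else list(edge_lengths)
        total = 0.0
        for kind in (ColumnKind.UNPAIRED, ColumnKind.PAIRED):
            block = self._blocks[kind]
            if block is None:
                continue
            per_cat = np.stack([
                self._block_site_logliks(block, model, r, t)
                for r in rate_model.rates
            ])
            m = per_cat.max(axis=0)
            m = np.where(np.isfinite(m), m, 0.0)
            like_var = np.exp(m) * (
                rate_model.weights[:, None] * np.exp(per_cat - m)
            ).sum(axis=0)
            if rate_model.p_inv > 0:
                inv = self._block_invariant_logliks(block, model)
                like = rate_model.p_inv * inv + (1 - rate_model.p_inv) * like_var
            else:
                like = like_var
            with np.errstate(divide="ignore"):
                total += float(block["counts"] @ np.log(like))
        return total


def count_params(tree: Tree, rate_model: RateModel = UNIFORM_RATES) -> int:
    """Free parameters: branch lengths + p_inv/alpha if optimized."""
    n_branches = sum(1 for nd in tree.preorder_node_iter() if nd.parent_node)
    return n_branches + rate_model.n_free_params


def site_log_likelihoods(
    tree: Tree,
    coded: CodedAlignment,
    model: SubstitutionModel,
    rate_model: RateModel = UNIFORM_RATES,
) -> ModelFitResult:
    """Per-site log-likelihoods, total lnL and AIC for one (model, tree,
    alignment) triple."""
    engine = PruningEngine(tree, coded)
    site_lnl = engine.site_logliks(model, rate_model)
    return ModelFitResult(
        site_lnl=site_lnl,
        total_lnl=float(site_lnl.sum()),
        n_params=count_params(tree, rate_model),
        n_sites=coded.length,
    )


# ---------------------------------------------------------------------------
# Pairwise ML distances and NJ
# ---------------------------------------------------------------------------

def ml_pairwise_distance(
    coded: CodedAlignment, name_a: str, name_b: str, model: SubstitutionModel
) -> float:
    """Two-taxon ML distance: the branch length maximizing the closed
    two-sequence likelihood, found by bounded Brent search."""
    ia, ib = coded.names.index(name_a), coded.names.index(name_b)
    sym_index = {s: i for i, s in enumerate(model.alphabet.symbols)}
    pairs: dict[tuple[int, int], int] = {}
    n_mismatch = 0
    for ca, cb in zip(coded.rows[ia], coded.rows[ib]):
        if ca in sym_index and cb in sym_index:
            key = (sym_index[ca], sym_index[cb])
            pairs[key] = pairs.get(key, 0) + 1
            n_mismatch += ca != cb
    if not pairs:
        return 0.0
    keys = np.array(list(pairs.keys()))
    counts = np.array(list(pairs.values()), dtype=float)

    def neg_lnl(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(model.pi[keys[:, 0]] * P[keys[:, 0], keys[:, 1]],
                                   1e-300))
        return -float(counts @ lp)

    if n_mismatch == 0:
        return 0.0
    res = minimize_scalar(
        neg_lnl, bounds=(_MIN_BRANCH, _MAX_BRANCH), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def nj_tree(coded: CodedAlignment, model: SubstitutionModel) -> Tree:
    """Neighbor-joining on pairwise ML distances (dendropy's NJ); negative
    NJ branch lengths are clamped to 0."""
    n = coded.n_sequences
    if n < 3:
        raise PairphyError(f"NJ needs >= 3 sequences, got {n}")
    names = coded.names
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = ml_pairwise_distance(coded, names[i], names[j], model)
    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i in range(n):
        buf.write(names[i] + "," + ",".join(f"{D[i, j]:.10g}" for j in range(n)) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Branch-length and rate-model optimization
# ---------------------------------------------------------------------------

def optimize_branch_lengths(
    tree: Tree,
    coded: CodedAlignment,
    model: SubstitutionModel,
    rate_model: RateModel = UNIFORM_RATES,
    tol: float = 1e-3,
    max_sweeps: int = 10,
) -> tuple[Tree, float]:
    """Coordinate-wise Brent optimization of every branch length.

    Sweeps over all edges until the total lnL gain of a sweep drops below
    ``tol``. The likelihood never decreases: a proposed length is kept only
    if it improves the objective. Returns (tree, lnL); the input tree's edge
    lengths are updated in place.
    """
    engine = PruningEngine(tree, coded)
    lengths = list(engine.edge_lengths)
    current = engine.total_loglik(model, rate_model, lengths)
    for _ in range(max_sweeps):
        start = current
        for eidx in range(len(lengths)):
            def neg(t: float) -> float:
                trial = lengths.copy()
                trial[eidx] = t
                return -engine.total_loglik(model, rate_model, trial)

            res = minimize_scalar(
                neg, bounds=(0.0, _MAX_BRANCH), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > current:
                lengths[eidx] = float(res.x)
                current = -res.fun
        if current - start < tol:
            break
    for eidx, edge in enumerate(engine._edges):
        edge.length = lengths[eidx]
    return tree, current


def fit_rate_model(
    tree: Tree,
    coded: CodedAlignment,
    model: SubstitutionModel,
    optimize_pinv: bool = True,
    optimize_alpha: bool = True,
    ncat: int = 4,
    tol: float = 1e-6,
) -> tuple[RateModel, float]:
    """Nelder-Mead fit of (p_inv, alpha) on fixed tree and model."""
    engine = PruningEngine(tree, coded)

    def unpack(x):
        p_inv = 1.0 / (1.0 + np.exp(-x[0])) if optimize_pinv else 0.0
        alpha = float(np.exp(x[1])) if optimize_alpha else None
        return RateModel(p_inv=min(p_inv, 0.999), alpha=alpha, ncat=ncat)

    def neg(x):
        return -engine.total_loglik(model, unpack(x))

    x0 = np.array([np.log(0.1 / 0.9), 0.0])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"fatol": tol, "xatol": 1e-4})
    return unpack(res.x), -float(res.fun)


# ---------------------------------------------------------------------------
# Model-fit comparison
# ---------------------------------------------------------------------------

def compare_fit(
    models: list[tuple[str, SubstitutionModel, RateModel]],
    subsets: list[tuple[Tree, CodedAlignment]],
) -> pd.DataFrame:
    """Pairwise model comparison across shared test subsets.

    For each ordered model pair (A, B) and each subset, the per-site lnL and
    per-site AIC differences are averaged over subsets. Sign convention:
    ``mean_site_lnl_diff`` = mean(lnL_A - lnL_B)/sites, positive favoring A;
    ``mean_site_aic_diff`` = mean(AIC_A - AIC_B)/sites, negative favoring A.
    """
    if len(models) < 2:
        raise PairphyError("compare_fit needs at least two models")
    fits: dict[str, list[ModelFitResult]] = {}
    for name, model, rate_model in models:
        fits[name] = []
        for tree, coded in subsets:
            if model.alphabet.id != coded.alphabet.id:
                raise PairphyError(
                    f"model {name!r} alphabet {model.alphabet.id} does not match "
                    f"subset alphabet {coded.alphabet.id}"
                )
            fits[name].append(site_log_likelihoods(tree, coded, model, rate_model))
    rows = []
    for (na, _, _), (nb, _, _) in itertools.permutations(models, 2):
        dlnl, daic = [], []
        for fa, fb in zip(fits[na], fits[nb]):
            dlnl.append((fa.total_lnl - fb.total_lnl) / fa.n_sites)
            daic.append((fa.aic - fb.aic) / fa.n_sites)
        rows.append({
            "model_a": na,
            "model_b": nb,
            "mean_site_lnl_diff": float(np.mean(dlnl)),
            "mean_site_aic_diff": float(np.mean(daic)),
            "n_subsets": len(subsets),
        })
    return pd.DataFrame(rows)
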