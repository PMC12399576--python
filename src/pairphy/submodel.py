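"""Block-structured reversible substitution models over pair-state alphabets.

A model couples a coded alphabet with stationary frequencies pi and symmetric
exchangeabilities S. The rate matrix is Q_ij = S_ij * pi_j with the diagonal
set so rows sum to zero, normalized to one expected substitution per unit
branch length (-sum_i pi_i Q_ii = 1). Because a column is either a loop or a
stem site under one general structure, exchangeabilities between the
unpaired (first 4 states) and paired blocks are structurally zero, giving the
"4x4 + kxk" block-diagonal decomposition: one likelihood engine serves both
partitions.

Among-site rate heterogeneity follows the usual +I+G4 mixture: a proportion
p_inv of invariant sites plus a 4-category equal-weight discrete gamma whose
category rates are the conditional means of the quantile slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc, gammaincinv

from .recode import ALPHABETS, Alphabet
from .rnaio import PairphyError

#: pseudo-frequency given to unobserved states before renormalization
FREQ_FLOOR = 1e-6


@dataclass
class SubstitutionModel:
    alphabet: Alphabet
    pi: np.ndarray
    S: np.ndarray
    Q: np.ndarray = field(init=False)
    # eigendecomposition of the symmetrized generator, for fast P(t)
    _evals: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        k = self.alphabet.size
        self.pi = np.asarray(self.pi, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.pi.shape != (k,) or self.S.shape != (k, k):
            raise PairphyError(
                f"dimension mismatch: alphabet size {k}, pi {self.pi.shape}, "
                f"S {self.S.shape}"
            )
        if not np.allclose(self.S, self.S.T):
            raise PairphyError("exchangeability matrix S must be symmetric")
        if (self.S < 0).any():
            raise PairphyError("exchangeability matrix S must be nonnegative")
        pi = np.where(self.pi <= 0, FREQ_FLOOR, self.pi)
        self.pi = pi / pi.sum()

        S = self.S.copy()
        np.fill_diagonal(S, 0.0)
        nu = self.alphabet.n_unpaired
        S[:nu, nu:] = 0.0  # loop and stem states never interchange
        S[nu:, :nu] = 0.0
        self.S = S

        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(self.pi * np.diag(Q)).sum()
        if mean_rate <= 0:
            raise PairphyError("degenerate model: zero mean substitution rate")
        Q /= mean_rate
        self.Q = Q

        sqrt_pi = np.sqrt(self.pi)
        B = (Q * sqrt_pi[None, :].T) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # symmetric up to round-off
        evals, vecs = np.linalg.eigh(B)
        self._evals = evals
        self._right = vecs / sqrt_pi[:, None]
        self._left = vecs.T * sqrt_pi[None, :]

    @property
    def unpaired_slice(self) -> slice:
        return slice(0, self.alphabet.n_unpaired)

    @property
    def paired_slice(self) -> slice:
        return slice(self.alphabet.n_unpaired, self.alphabet.size)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition; falls back to
        scaling-and-squaring if the reconstruction is numerically defective."""
        if t < 0:
            raise PairphyError(f"negative branch length {t}")
        P = (self._right * np.exp(self._evals * t)) @ self._left
        if not np.all(np.isfinite(P)) or abs(P.sum(axis=1) - 1.0).max() > 1e-8:
            P = expm(self.Q * t)
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def rescaled(self, pi: np.ndarray | None = None, S: np.ndarray | None = None
                 ) -> "SubstitutionModel":
        return SubstitutionModel(
            self.alphabet,
            self.pi if pi is None else pi,
            self.S if S is None else S,
        )


def build_model(alphabet: Alphabet, pi, S) -> SubstitutionModel:
    """Construct a normalized block-diagonal reversible model.

    Zero frequencies are smoothed to ``FREQ_FLOOR`` before renormalization so
    Q stays non-singular for states never observed in training data;
    exchangeabilities may be exactly zero.
    """
    return SubstitutionModel(alphabet, np.asarray(pi, float), np.asarray(S, float))


def flat_model(alphabet: Alphabet) -> SubstitutionModel:
    """Uniform frequencies, equal within-block exchangeabilities."""
    k = alphabet.size
    return build_model(alphabet, np.full(k, 1.0 / k), np.ones((k, k)))


def jc_model(n_states: int = 4) -> SubstitutionModel:
    """Jukes-Cantor-like model on the unpaired block only (testing aid)."""
    alph = Alphabet("JC%d" % n_states, "ACGT"[:n_states], "", {})
    return build_model(alph, np.full(n_states, 1.0 / n_states), np.ones((n_states, n_states)))


# ---------------------------------------------------------------------------
# Rate heterogeneity (+I, +G4)
# ---------------------------------------------------------------------------

def gamma_categories(alpha: float, ncat: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discrete gamma (mean-per-slice rates).

    The mean-1 gamma (shape alpha, rate alpha) is cut at its k/ncat
    quantiles; each category rate is the conditional mean of its slice, so
    the weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise PairphyError(f"gamma shape must be positive, got {alpha}")
    probs = np.arange(1, ncat) / ncat
    # quantiles of Gamma(alpha, rate=alpha); gammaincinv works on shape alpha
    cuts = gammaincinv(alpha, probs) / alpha
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; X<x] for Gamma(alpha, alpha) equals P(alpha+1, alpha*x)
    upper = gammainc(alpha + 1, np.where(np.isinf(edges[1:]), np.inf, alpha * edges[1:]))
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = ncat * (upper - lower)
    weights = np.full(ncat, 1.0 / ncat)
    rates = rates / (weights @ rates)  # exact mean 1 despite round-off
    return rates, weights


@dataclass
class RateModel:
    """+I+G mixture: invariant fraction p_inv plus a discrete gamma."""

    p_inv: float = 0.0
    alpha: float | None = None
    ncat: int = 4
    rates: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inv < 1.0:
            raise PairphyError(f"p_inv must be in [0,1), got {self.p_inv}")
        if self.alpha is None:
            self.rates = np.array([1.0])
            self.weights = np.array([1.0])
        else:
            self.rates, self.weights = gamma_categories(self.alpha, self.ncat)

    @property
    def n_free_params(self) -> int:
        return int(self.p_inv > 0) + int(self.alpha is not None)


UNIFORM_RATES = RateModel()


# ---------------------------------------------------------------------------
# PAML-style model files
# ---------------------------------------------------------------------------

def write_model(model: SubstitutionModel, path) -> None:
    """Write the lower-triangle exchangeabilities followed by the frequency
    line (the interchange layout of empirical protein-model files), with a
    header comment naming the alphabet."""
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write(f"# pairphy model alphabet={model.alphabet.id}\n")
        k = model.alphabet.size
        for i in range(1, k):
            handle.write(" ".join(f"{model.S[i, j]:.6g}" for j in range(i)) + "\n")
        handle.write("\n")
        handle.write(" ".join(f"{f:.6g}" for f in model.pi) + "\n")
    finally:
        if isinstance(path, str):
            handle.close()


def read_model(path) -> SubstitutionModel:
    handle = open(path) if isinstance(path, str) else path
    try:
        lines = [ln.strip() for ln in handle]
    finally:
        if isinstance(path, str):
            handle.close()
    alphabet_id = None
    rows = []
    for ln in lines:
        if ln.startswith("#"):
            for token in ln[1:].split():
                if token.startswith("alphabet="):
                    alphabet_id = token.split("=", 1)[1]
        elif ln:
            rows.append([float(x) for x in ln.split()])
    if alphabet_id not in ALPHABETS:
        raise PairphyError(f"model file lacks a known alphabet header: {alphabet_id!r}")
    alphabet = ALPHABETS[alphabet_id]
    k = alphabet.size
    if len(rows) != k:
        raise PairphyError(f"expected {k - 1} triangle rows + 1 frequency row, got {len(rows)}")
    S = np.zeros((k, k))
    for i in range(1, k):
        if len(rows[i - 1]) != i:
            raise PairphyError(f"triangle row {i} has {len(rows[i - 1])} entries, expected {i}")
        S[i, :i] = rows[i - 1]
    S = S + S.T
    pi = np.array(rows[-1])
    if pi.shape != (k,):
        raise PairphyError(f"frequency row has {pi.size} entries, expected {k}")
    return build_model(alphabet, pi, S)
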