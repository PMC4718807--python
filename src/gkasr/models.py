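"""Reversible amino-acid substitution models with discrete-gamma rates.

A model is the pair (S, pi): a symmetric exchangeability matrix and stationary
frequencies, combined into the rate matrix Q = S·diag(pi) with the diagonal
set so rows sum to zero and the whole matrix rescaled so the expected rate
-sum_i pi_i Q_ii equals one substitution per site. Among-site rate variation
uses the discrete-gamma approximation: K equal-probability categories whose
rates are the conditional means of Gamma(alpha, alpha) in each quantile bin,
so the mean rate is exactly 1.

The WAG exchangeabilities and frequencies ship as a bundled PAML-style .dat
file; any matrix in that layout (LG, JTT, ...) loads the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import gammaincinv, gammainc

from .phyloio import AA_INDEX, AminoAcidAlignment

N_STATES = 20

#: floor applied to empirical frequencies so Q stays irreducible
FREQ_FLOOR = 1e-6


class ModelError(ValueError):
    pass


def load_exchangeabilities(source=None) -> tuple[np.ndarray, np.ndarray]:
    """Load (S, pi_model) from a PAML-style .dat file.

    The layout is 190 lower-triangle exchangeabilities (19 rows, row i giving
    entries against the first i states in ARNDCQEGHILKMFPSTWYV order) followed
    by 20 stationary frequencies. ``source=None`` loads the bundled WAG file.
    """
    if source is None:
        text = (
            resources.files("gkasr").joinpath("data/wag.dat").read_text("utf-8")
        )
    elif hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    numbers = []
    for tok in text.split():
        try:
            numbers.append(float(tok))
        except ValueError:
            break
    expected = 190 + N_STATES
    if len(numbers) < expected:
        raise ModelError(
            f"expected {expected} numbers (190 exchangeabilities + 20 "
            f"frequencies), found {len(numbers)}"
        )
    tri = numbers[:190]
    pi = np.array(numbers[190 : 190 + N_STATES])
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    if np.any(pi < 0):
        raise ModelError("negative stationary frequency in matrix file")
    return S, pi


def equal_exchangeabilities() -> np.ndarray:
    """All-ones exchangeabilities (Poisson/F81-style); handy as a test oracle."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return S


def empirical_frequencies(aln: AminoAcidAlignment) -> np.ndarray:
    """Observed residue frequencies, gaps/X excluded, floored and renormalized."""
    counts = np.zeros(N_STATES)
    for aa, idx in AA_INDEX.items():
        counts[idx] = np.count_nonzero(aln.states == aa)
    total = counts.sum()
    if total == 0:
        raise ModelError("alignment contains no non-gap residues")
    pi = counts / total
    pi = np.maximum(pi, FREQ_FLOOR)
    return pi / pi.sum()


@dataclass(frozen=True)
class RateCategories:
    """Discrete-gamma rate classes: K rates with uniform weights 1/K."""

    rates: np.ndarray
    weights: np.ndarray

    @property
    def k(self) -> int:
        return len(self.rates)


def discrete_gamma_rates(alpha: float, k: int) -> RateCategories:
    """Equal-probability discretization of Gamma(alpha, alpha) by category means.

    Category r is the mean of the distribution conditional on lying between
    the (r/K) and ((r+1)/K) quantiles; computed in closed form from the
    regularized incomplete gamma function, so sum(weights*rates) == 1.
    """
    if not (alpha > 0):
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ModelError(f"need at least one rate category, got {k}")
    if k == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs) / alpha
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X | a < X < b] * P(a < X < b) = I(alpha+1, rate*b) - I(alpha+1, rate*a)
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = (upper - lower) * k
    return RateCategories(rates, np.full(k, 1.0 / k))


@dataclass(frozen=True)
class SubstitutionModel:
    """Normalized reversible rate matrix plus optional gamma heterogeneity."""

    S: np.ndarray
    pi: np.ndarray
    Q: np.ndarray
    alpha: float | None
    n_categories: int
    freq_mode: str

    @property
    def rate_categories(self) -> RateCategories:
        if self.alpha is None or self.n_categories == 1:
            return RateCategories(np.array([1.0]), np.array([1.0]))
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(
            self.S, self.pi, self.Q, alpha, self.n_categories, self.freq_mode
        )

    # eigendecomposition cache for transition matrices
    def _eig(self):
        if not hasattr(self, "_eig_cache"):
            sqrt_pi = np.sqrt(self.pi)
            A = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            A = 0.5 * (A + A.T)  # symmetric up to roundoff for reversible Q
            w, U = np.linalg.eigh(A)
            object.__setattr__(self, "_eig_cache", (w, U, sqrt_pi))
        return self._eig_cache

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t·rate) = exp(Q·t·rate) via the symmetrized eigendecomposition."""
        if not np.isfinite(t) or t < 0:
            raise ModelError(f"branch length must be finite and >= 0, got {t}")
        if rate <= 0:
            raise ModelError(f"rate must be positive, got {rate}")
        w, U, sqrt_pi = self._eig()
        expw = np.exp(w * t * rate)
        P = (U * expw) @ U.T
        P = P / sqrt_pi[:, None] * sqrt_pi[None, :]
        # tiny negative entries are eigendecomposition roundoff
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def build_model(
    S: np.ndarray,
    pi: np.ndarray | None = None,
    alignment: AminoAcidAlignment | None = None,
    alpha: float | None = None,
    n_categories: int = 4,
) -> SubstitutionModel:
    """Assemble a normalized reversible model.

    Frequencies come either from ``pi`` (model frequencies, ``freq_mode='model'``)
    or from ``alignment`` (observed counts, ``freq_mode='empirical'``); exactly
    one must be given.
    """
    if (pi is None) == (alignment is None):
        raise ModelError("provide exactly one of pi or alignment")
    if alignment is not None:
        pi_vec = empirical_frequencies(alignment)
        freq_mode = "empirical"
    else:
        pi_vec = np.asarray(pi, dtype=float)
        if np.any(pi_vec < 0):
            raise ModelError("negative frequency")
        pi_vec = np.maximum(pi_vec, FREQ_FLOOR)
        pi_vec = pi_vec / pi_vec.sum()
        freq_mode = "model"
    if alpha is not None and alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if n_categories < 1:
        raise ModelError("n_categories must be >= 1")
    S = np.asarray(S, dtype=float)
    if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
        raise ModelError("S must be a symmetric 20x20 matrix")
    Q = S * pi_vec[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi_vec, np.diag(Q))
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    Q = Q / mu
    return SubstitutionModel(S, pi_vec, Q, alpha, n_categories, freq_mode)


def wag_model(
    alignment: AminoAcidAlignment | None = None,
    alpha: float | None = None,
    n_categories: int = 4,
) -> SubstitutionModel:
    """WAG with model frequencies, or empirical (+F) when an alignment is given."""
    S, pi_model = load_exchangeabilities()
    if alignment is not None:
        return build_model(
            S, alignment=alignment, alpha=alpha, n_categories=n_categories
        )
    return build_model(S, pi=pi_model, alpha=alpha, n_categories=n_categories)
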