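"""Amino-acid substitution models and discrete-gamma rate heterogeneity.

A general time-reversible model is assembled from a symmetric exchangeability
matrix S and equilibrium frequencies pi: Q_ij = S_ij * pi_j for i != j, the
diagonal set so rows sum to zero, and the whole matrix rescaled so that the
expected substitution rate at equilibrium, -sum_i pi_i Q_ii, equals one.
Branch lengths are then in expected substitutions per site.

Among-site rate variation uses Yang's (1994) discrete-gamma approximation:
K equal-probability categories whose rates are the conditional means of a
gamma(shape=alpha, rate=alpha) density over its K quantile bands, so the
mean rate is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .phylo import AMINO_ACIDS

N_STATES = 20


class ModelError(ValueError):
    pass


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalized reversible rate matrix from exchangeabilities and frequencies.

    Parameters
    ----------
    S : (20, 20) symmetric, non-negative off-diagonal, zero diagonal.
    pi : length-20, strictly positive, sums to one.

    Returns
    -------
    Q with zero row sums, detailed balance pi_i Q_ij = pi_j Q_ji, and
    -sum(pi * diag(Q)) == 1.
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ModelError(f"S must be {N_STATES}x{N_STATES}, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ModelError("exchangeability matrix S must be symmetric")
    if np.any(S < 0):
        raise ModelError("exchangeabilities must be non-negative")
    if pi.shape != (N_STATES,):
        raise ModelError(f"pi must have length {N_STATES}")
    if np.any(pi <= 0):
        raise ModelError("equilibrium frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ModelError(f"equilibrium frequencies must sum to 1, got {pi.sum():.10f}")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(pi * np.diag(Q))
    if scale <= 0:
        raise ModelError("degenerate model: zero substitution rate")
    return Q / scale


@dataclass
class SubstitutionModel:
    """Reversible substitution model with spectral transition probabilities.

    The symmetrized matrix B = D^{1/2} Q D^{-1/2} (D = diag(pi)) is real
    symmetric; its eigendecomposition gives P(t) = D^{-1/2} U e^{Lt} U' D^{1/2}
    cheaply for many branch lengths.
    """

    S: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    Q: np.ndarray = field(init=False)
    _evals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = build_rate_matrix(self.S, self.pi)
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize numerical noise
        evals, U = np.linalg.eigh(B)
        self._evals = evals
        self._right = U / sq[:, None]      # D^{-1/2} U
        self._left = (U * sq[:, None]).T   # U' D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped to [0, 1]."""
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        P = (self._right * np.exp(self._evals * t)) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        """Same exchangeabilities, different (e.g. empirical) frequencies."""
        return SubstitutionModel(S=self.S, pi=pi, name=f"{self.name}+F")


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Matrix exponential P(t) = exp(Qt) for an arbitrary valid rate matrix."""
    from scipy.linalg import expm

    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P / P.sum(axis=1, keepdims=True)


@dataclass
class GammaRates:
    """Discrete-gamma rate categories with equal weights 1/K."""

    alpha: float
    rates: np.ndarray

    @property
    def K(self) -> int:
        return len(self.rates)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.K, 1.0 / self.K)


def discrete_gamma(alpha: float, K: int = 4) -> GammaRates:
    """Equal-probability discrete-gamma categories with unit mean rate.

    Category k's rate is the mean of the gamma(alpha, rate alpha) density over
    its k-th K-quantile band, computed via the standard incomplete-gamma
    identity: the conditional mean over [a, b] is
    K * [F_{alpha+1}(b) - F_{alpha+1}(a)] where F_{alpha+1} is the CDF of
    gamma(alpha + 1, rate alpha).
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be > 0, got {alpha}")
    if K < 1:
        raise ModelError(f"need at least one rate category, got {K}")
    if K == 1:
        return GammaRates(alpha=alpha, rates=np.array([1.0]))
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper_cdf = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = K * np.diff(upper_cdf)
    rates = rates / rates.mean()  # remove residual quadrature error
    return GammaRates(alpha=alpha, rates=rates)


def _load_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.zeros((N_STATES, N_STATES))
    for i, line in enumerate(rows[: N_STATES - 1], start=1):
        vals = [float(x) for x in line.split()]
        if len(vals) != i:
            raise ModelError("malformed exchangeability triangle")
        S[i, :i] = vals
        S[:i, i] = vals
    pi = np.array([float(x) for x in rows[N_STATES - 1].split()])
    pi = pi / pi.sum()
    return S, pi


def lg_model(frequencies: str | np.ndarray = "model") -> SubstitutionModel:
    """The LG amino-acid replacement model.

    Parameters
    ----------
    frequencies : "model" for the published LG frequencies, or an explicit
        length-20 array (e.g. empirical alignment frequencies) in the order
        {order}.
    """
    text = resources.files("quatevol.data").joinpath("lg.dat").read_text()
    S, pi = _load_paml_dat(text)
    if isinstance(frequencies, str):
        if frequencies != "model":
            raise ModelError("frequencies must be 'model' or an explicit array")
    else:
        pi = np.asarray(frequencies, dtype=float)
    return SubstitutionModel(S=S, pi=pi, name="LG")


lg_model.__doc__ = lg_model.__doc__.format(order=AMINO_ACIDS)
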