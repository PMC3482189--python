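"""k-state continuous-time Markov substitution models.

All models here are time-reversible: a symmetric exchangeability matrix
``S`` combined with equilibrium frequencies ``π`` gives the rate matrix

    Q_ij = S_ij * π_j   (i ≠ j),   Q_ii = −Σ_{j≠i} Q_ij,

scaled so the expected number of substitutions per unit branch length is
one at equilibrium (−Σ_i π_i Q_ii = 1).  Transition matrices are computed
from the eigendecomposition of the symmetrised rate matrix, which is
numerically stable and makes repeated P(t) evaluations cheap.

Supported families: ``poisson`` (all exchangeabilities equal — the Mk /
Jukes–Cantor family for any k), ``fixed_exchangeability`` (an empirical
table such as LG, read from PAML-format text), and ``gtr`` (free
symmetric exchangeabilities).  Rate heterogeneity uses the standard
discrete-Γ approximation plus an optional invariant-site class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-slice discrete-Γ rate multipliers (mean 1).

    The Γ(α, α) distribution is cut into ``n_categories`` equal-probability
    slices; each category's rate is the conditional mean of its slice,
    computed in closed form from the Γ(α+1, α) CDF.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(n_categories + 1) / n_categories
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    bounds = _gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] for X~Gamma(alpha, alpha) equals CDF of Gamma(alpha+1, alpha)
    upper = _gamma_dist.cdf(bounds, a=alpha + 1, scale=1.0 / alpha)
    rates = n_categories * np.diff(upper)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized reversible k-state model with optional Γ+I rates."""

    k: int
    kind: str
    exchangeabilities: np.ndarray  # symmetric (k, k), zero diagonal
    frequencies: np.ndarray        # (k,), sums to 1
    gamma_alpha: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        if S.shape != (self.k, self.k):
            raise ValueError("exchangeability matrix has wrong shape")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if (S < 0).any():
            raise ValueError("negative exchangeability")
        if pi.shape != (self.k,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be a length-k simplex")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi / pi.sum())

    # -- rate matrix -----------------------------------------------------
    @property
    def rate_matrix(self) -> np.ndarray:
        S, pi = self.exchangeabilities, self.frequencies
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        return Q / mu

    def _eigensystem(self):
        cached = getattr(self, "_eig_cache", None)
        if cached is not None:
            return cached
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        pi = self.frequencies
        r = np.sqrt(np.clip(pi, 1e-300, None))
        B = (self.rate_matrix * r[:, None]) / r[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        # P(t) = diag(1/sqrt pi) V exp(wt) V^T diag(sqrt pi)
        result = (w, V / r[:, None], V.T * r[None, :])
        object.__setattr__(self, "_eig_cache", result)
        return result

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate·t) for one branch; rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        w, right, left = self._eigensystem()
        P = (right * np.exp(w * t * rate)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """P for every (branch, rate category): shape (n_branch, n_cat, k, k)."""
        w, right, left = self._eigensystem()
        scale = np.asarray(lengths)[:, None] * np.asarray(rates)[None, :]
        E = np.exp(w[None, None, :] * scale[:, :, None])
        P = (right[None, None, :, :] * E[:, :, None, :]) @ left
        return np.clip(P, 0.0, None)

    @property
    def rate_multipliers(self) -> np.ndarray:
        if self.gamma_alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_alpha, self.n_categories)

    def with_(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)


def read_paml_exchangeabilities(text: str, k: int = 20) -> tuple[np.ndarray, np.ndarray | None]:
    """Parse a PAML-style lower-triangle exchangeability table.

    The format is k−1 lower-triangle rows of rates followed, optionally,
    by a line of k equilibrium frequencies (the layout used for published
    empirical amino-acid models such as LG or WAG).
    """
    values = [float(tok) for tok in text.split()]
    n_tri = k * (k - 1) // 2
    if len(values) < n_tri:
        raise ValueError(f"expected at least {n_tri} exchangeabilities, got {len(values)}")
    S = np.zeros((k, k))
    it = iter(values[:n_tri])
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    freqs = None
    rest = values[n_tri:]
    if len(rest) >= k:
        freqs = np.asarray(rest[:k], float)
        freqs = freqs / freqs.sum()
    return S, freqs


def empirical_frequencies(codes: np.ndarray, k: int) -> np.ndarray:
    """Pooled state frequencies over a coded matrix, ignoring missing (−1).

    A small pseudo-count keeps unobserved states at positive frequency so
    that the rate matrix stays irreducible.
    """
    counts = np.bincount(codes[codes >= 0].ravel(), minlength=k).astype(float)
    counts += 0.5
    return counts / counts.sum()


def build_model(
    kind: str,
    k: int,
    frequencies: np.ndarray | str = "equal",
    data: np.ndarray | None = None,
    gamma_alpha: float | None = None,
    n_categories: int = 4,
    p_inv: float = 0.0,
    exchangeabilities: np.ndarray | None = None,
    exchangeability_text: str | None = None,
) -> SubstitutionModel:
    """Construct a normalized unit-mean-rate substitution model.

    ``frequencies`` may be ``"equal"``, ``"empirical"`` (counted from
    ``data``, missing symbols excluded) or an explicit simplex vector.
    ``fixed_exchangeability`` models take their rate table from
    ``exchangeability_text`` (PAML layout) or an explicit matrix.
    """
    if k < 2:
        raise ValueError("need at least two states")
    table_freqs = None
    if kind == "poisson":
        S = np.ones((k, k))
        np.fill_diagonal(S, 0.0)
    elif kind == "fixed_exchangeability":
        if exchangeability_text is not None:
            S, table_freqs = read_paml_exchangeabilities(exchangeability_text, k)
        elif exchangeabilities is not None:
            S = np.asarray(exchangeabilities, float)
        else:
            raise ValueError("fixed_exchangeability requires a rate table")
    elif kind == "gtr":
        if exchangeabilities is None:
            S = np.ones((k, k))
            np.fill_diagonal(S, 0.0)
        else:
            S = np.asarray(exchangeabilities, float)
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    if isinstance(frequencies, str):
        if frequencies == "equal":
            pi = np.full(k, 1.0 / k)
        elif frequencies == "empirical":
            if data is None:
                raise ValueError("empirical frequencies need data")
            pi = empirical_frequencies(np.asarray(data), k)
        elif frequencies == "model" and table_freqs is not None:
            pi = table_freqs
        else:
            raise ValueError(f"unknown frequency source {frequencies!r}")
    else:
        pi = np.asarray(frequencies, float)

    return SubstitutionModel(
        k=k, kind=kind, exchangeabilities=S, frequencies=pi,
        gamma_alpha=gamma_alpha, n_categories=n_categories, p_inv=p_inv,
    )
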