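"""Univariate association tests and univariate-based combination procedures.

Covers the single-trait OLS test, the family-wise minimum-p statistic, the
first-principal-component test (UV-PCA), sample-size-weighted Z meta-analysis
(the METAL "samplesize" scheme), Fisher's method, and the extended Simes
procedure (TATES).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import MonomorphicInputError

__all__ = [
    "UVResult",
    "uv_linear_test",
    "uv_table",
    "uv_min_p",
    "uv_pca_test",
    "meta_samplesize",
    "fisher_combine",
    "tates",
    "pvalue_correlation",
    "li_ji_meff",
]

#: Clamp for p-values at the edge of (0, 1) before inverse-normal transforms.
P_EPS = 1e-300


@dataclass(frozen=True)
class UVResult:
    """Per-trait univariate association summary."""

    p_values: np.ndarray  # (k,) two-sided
    directions: np.ndarray  # (k,) sign of slope
    slopes: np.ndarray  # (k,)
    standard_errors: np.ndarray  # (k,)
    n: int


def uv_linear_test(genotype, trait):
    """Two-sided t-test for the slope in ``trait ~ intercept + genotype``.

    Returns ``(p, direction, slope, se)``.  The p-value comes from the t
    distribution with n - 2 degrees of freedom.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = g.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    gc = g - g.mean()
    yc = y - y.mean()
    sgg = gc @ gc
    syy = yc @ yc
    if sgg == 0:
        raise MonomorphicInputError("genotype vector is constant")
    if syy == 0:
        raise MonomorphicInputError("trait vector is constant")
    slope = (gc @ yc) / sgg
    rss = syy - slope**2 * sgg
    rss = max(rss, 0.0)
    df = n - 2
    se = np.sqrt(rss / df / sgg)
    if se == 0:  # perfect fit
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(p, 1.0)), int(np.sign(slope)), float(slope), float(se)


def uv_table(genotype, traits) -> UVResult:
    """Univariate test of every trait column against the genotype."""
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] == np.asarray(genotype).shape[0]:
        cols = traits.T
    else:
        cols = traits
    out = [uv_linear_test(genotype, col) for col in cols]
    p, d, b, se = map(np.array, zip(*out))
    return UVResult(p, d, b, se, n=len(genotype))


def _pvalues(uv) -> np.ndarray:
    if isinstance(uv, UVResult):
        return uv.p_values
    return np.asarray(uv, dtype=float)


def uv_min_p(uv) -> float:
    """Minimum over traits of the univariate p-values.

    The statistic whose permutation null distribution defines the adjusted,
    family-wise univariate significance threshold.
    """
    p = _pvalues(uv)
    if p.size == 0:
        raise ValueError("need at least one trait")
    return float(p.min())


def uv_pca_test(genotype, traits):
    """Univariate test of the first principal component of the traits.

    The PC is covariance-based (the traits are standardized upstream, so this
    matches a correlation-based PCA of the raw traits).  Returns the same
    tuple as :func:`uv_linear_test`.
    """
    y = np.asarray(traits, dtype=float)
    if y.ndim == 1 or y.shape[1] == 1:
        return uv_linear_test(genotype, y.ravel())
    yc = y - y.mean(axis=0)
    cov = yc.T @ yc / (y.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    pc1 = yc @ v[:, -1]
    return uv_linear_test(genotype, pc1)


def _signed_z(p, directions):
    p = np.clip(_pvalues(p), P_EPS, 1 - 1e-16)
    return np.asarray(directions) * stats.norm.isf(p / 2.0)


def meta_samplesize(uv, n_per_trait=None):
    """Sample-size-weighted Z meta-analysis of the per-trait results.

    Z_j = direction_j * Phi^{-1}(1 - p_j / 2), weights w_j = sqrt(n_j),
    Z = sum(w_j Z_j) / sqrt(sum w_j^2), combined p = 2 Phi(-|Z|).  With equal
    sample sizes this is Z = sum(Z_j) / sqrt(k).

    Returns ``(combined_p, combined_z)``.
    """
    if isinstance(uv, UVResult):
        p, d = uv.p_values, uv.directions
        if n_per_trait is None:
            n_per_trait = np.full(p.shape, uv.n, dtype=float)
    else:
        p, d = uv
        if n_per_trait is None:
            raise ValueError("n_per_trait required with raw (p, direction) input")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at the boundary clamped for the Z transform")
    z = _signed_z(p, d)
    w = np.sqrt(np.asarray(n_per_trait, dtype=float))
    zc = (w @ z) / np.sqrt(w @ w)
    return float(2.0 * stats.norm.sf(abs(zc))), float(zc)


def fisher_combine(uv):
    """Fisher's method: X = -2 sum(ln p_j), p from chi^2 with 2k df."""
    p = np.clip(_pvalues(uv), P_EPS, 1.0)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# TATES (extended Simes)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _pvalue_corr_table(n_nodes: int = 48, n_grid: int = 201):
    """Tabulate corr(p1, p2) for two-sided p-values of bivariate-normal Zs.

    For (Z1, Z2) standard bivariate normal with correlation r, the p-values
    p_i = 2*Phi(-|Z_i|) are Uniform(0,1) marginally; their product moment
    E[p1 p2] is computed by 2-D Gauss-Hermite quadrature and converted to a
    correlation via var(p) = 1/12.  The map depends on |r| only (p is an even
    function of Z).
    """
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2 * np.pi)
    r = np.linspace(0.0, 1.0, n_grid)
    f1 = 2.0 * stats.norm.sf(np.abs(x))  # (H,)
    # z2 = r*z1 + sqrt(1-r^2)*x2
    z2 = r[:, None, None] * x[None, :, None] + np.sqrt(
        np.clip(1 - r**2, 0, 1)
    )[:, None, None] * x[None, None, :]
    f2 = 2.0 * stats.norm.sf(np.abs(z2))  # (G, H, H)
    ep1p2 = np.einsum("i,j,gij->g", w * f1, w, f2)
    rho = (ep1p2 - 0.25) * 12.0
    rho[0] = 0.0
    rho[-1] = 1.0
    return r, np.clip(rho, 0.0, 1.0)


def pvalue_correlation(r):
    """Correlation between two-sided p-values implied by a trait correlation.

    Deterministic quadrature mapping; vectorized over ``r``; depends on |r|.
    """
    grid, rho = _pvalue_corr_table()
    return np.interp(np.abs(np.asarray(r, dtype=float)), grid, rho)


def li_ji_meff(eigvals) -> float:
    """Li & Ji effective number of tests from correlation-matrix eigenvalues.

    m_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].

    The floor is evaluated with a small tolerance so that eigenvalues that
    are integers up to rounding error (e.g. the k of a perfectly correlated
    block) do not fall on the wrong side of the discontinuity.
    """
    lam = np.abs(np.asarray(eigvals, dtype=float))
    return float(
        np.sum((lam >= 1 - 1e-9).astype(float) + lam - np.floor(lam + 1e-9))
    )


def tates(
    p_values,
    trait_corr,
    mode: str = "quadrature",
    poly_coefficients=None,
    use_abs: bool = True,
) -> float:
    """Trait-based extended Simes combination of univariate p-values.

    Sort p_(1) <= ... <= p_(k); map the trait correlation matrix (reordered
    accordingly) to a p-value correlation matrix; for each j compute the
    Li-Ji effective number of tests m_e(j) among the top-j traits; return

        T = min_j  m_e(k) * p_(j) / m_e(j),   capped at 1.

    Parameters
    ----------
    mode
        "quadrature" (default): self-contained deterministic mapping from
        trait correlations to p-value correlations.  "polynomial": apply
        user-supplied polynomial coefficients (highest degree first, as for
        ``numpy.polyval``) to the trait correlations.
    use_abs
        Use the absolute p-value correlation matrix in the
        eigen-decompositions (default).
    """
    p = np.asarray(_pvalues(p_values), dtype=float)
    k = p.size
    if k == 1:
        return float(p[0])
    corr = np.asarray(trait_corr, dtype=float)
    if corr.shape != (k, k) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("trait_corr must be a symmetric k x k matrix")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("trait_corr must have unit diagonal")
    if np.linalg.eigvalsh(corr)[0] < -1e-8:
        raise ValueError("trait_corr must be positive semidefinite")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    corr = corr[np.ix_(order, order)]
    if mode == "quadrature":
        rho = pvalue_correlation(corr)
    elif mode == "polynomial":
        if poly_coefficients is None:
            raise ValueError("polynomial mode requires coefficients")
        rho = np.polyval(np.asarray(poly_coefficients, dtype=float), corr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    if use_abs:
        rho = np.abs(rho)
    meff_top = [
        li_ji_meff(np.linalg.eigvalsh(rho[:j, :j])) if j > 1 else 1.0
        for j in range(1, k + 1)
    ]
    meff = meff_top[-1]
    t = np.min(meff * ps / np.array(meff_top))
    return float(min(t, 1.0))
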