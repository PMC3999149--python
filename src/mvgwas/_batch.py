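"""Vectorized measure engines for the permutation/power harness.

Every public function here takes a genotype stack ``G`` of shape (R, P, n)
(R datasets, P pairings per dataset — P = 1 for the observed pairing) and a
trait stack ``Y`` of shape (R, n, k), and returns the association measure
with shape (R, P).  The scalar API in :mod:`mvgwas.univariate` /
:mod:`mvgwas.multivariate` is the reference; agreement is asserted in tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .multivariate import LN10, BayesPriors
from .univariate import _pvalue_corr_table

__all__ = [
    "cross_products",
    "uv_p_matrix",
    "minp_measure",
    "cca_measure",
    "bayes_measure",
    "meta_measure",
    "fisher_measure",
    "tates_measure",
    "uvpca_measure",
]


def _center(G, Y):
    gc = G - G.mean(axis=-1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    return gc, yc


def cross_products(G, Y):
    """Centered cross-products shared by all measures.

    Returns ``(gc, yc, sgg, sgy, syy)`` with shapes (R,P,n), (R,n,k), (R,P),
    (R,P,k), (R,k,k).
    """
    gc, yc = _center(G, Y)
    sgg = np.einsum("rpn,rpn->rp", gc, gc)
    sgy = np.einsum("rpn,rnk->rpk", gc, yc)
    syy = np.einsum("rnk,rnl->rkl", yc, yc)
    return gc, yc, sgg, sgy, syy


def uv_p_matrix(G, Y, cp=None):
    """Per-trait two-sided OLS p-values and slope signs, shapes (R, P, k)."""
    if cp is None:
        cp = cross_products(G, Y)
    gc, yc, sgg, sgy, syy = cp
    n = Y.shape[1]
    syy_diag = np.einsum("rkk->rk", syy)
    r2 = sgy**2 / (sgg[..., None] * syy_diag[:, None, :])
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    t = np.sqrt(r2 * (n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(t, n - 2)
    return np.minimum(p, 1.0), np.sign(sgy)


def minp_measure(G, Y, cp=None):
    p, _ = uv_p_matrix(G, Y, cp)
    return p.min(axis=-1)


def cca_measure(G, Y, cp=None):
    """CCA / MANOVA F-test p-value per (dataset, pairing)."""
    if cp is None:
        cp = cross_products(G, Y)
    gc, yc, sgg, sgy, syy = cp
    n, k = Y.shape[1], Y.shape[2]
    w = np.linalg.solve(syy[:, None, :, :], sgy[..., None])[..., 0]
    r2 = np.einsum("rpk,rpk->rp", sgy, w) / sgg
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    df2 = n - 1 - k
    f = (df2 / k) * r2 / (1.0 - r2)
    return stats.f.sf(f, k, df2)


def bayes_measure(G, Y, priors: BayesPriors | None = None, cp=None):
    """Conjugate multivariate-regression log10 Bayes factor, shape (R, P)."""
    if priors is None:
        priors = BayesPriors()
    if cp is None:
        cp = cross_products(G, Y)
    gc, yc, sgg, sgy, syy = cp
    n, k = Y.shape[1], Y.shape[2]
    vb = priors.b_prior_scale
    if vb == 0:
        return np.zeros(sgg.shape)
    shrink = 1.0 / vb + sgg  # (R,P)
    s_mat = priors.iw_scale * np.eye(k)
    r0 = s_mat + syy  # (R,k,k)
    r1 = r0[:, None, :, :] - np.einsum("rpk,rpl->rpkl", sgy, sgy) / shrink[..., None, None]
    _, ld0 = np.linalg.slogdet(r0)
    _, ld1 = np.linalg.slogdet(r1)
    m = n - 1
    return (-0.5 * k) * np.log1p(vb * sgg) / LN10 + (
        0.5 * (priors.iw_df + m)
    ) * (ld0[:, None] - ld1) / LN10


def meta_measure(G, Y, cp=None):
    """Equal-n sample-size-weighted Z meta-analysis p-value, shape (R, P)."""
    p, sign = uv_p_matrix(G, Y, cp)
    k = p.shape[-1]
    z = sign * stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16) / 2.0)
    zc = z.sum(axis=-1) / math.sqrt(k)
    return 2.0 * stats.norm.sf(np.abs(zc))


def fisher_measure(G, Y, cp=None):
    p, _ = uv_p_matrix(G, Y, cp)
    x = -2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum(axis=-1)
    return stats.chi2.sf(x, 2 * p.shape[-1])


def _li_ji_batch(lam):
    """Li-Ji effective number of tests along the last axis (tolerant floor)."""
    lam = np.abs(lam)
    return (
        (lam >= 1 - 1e-9).astype(float) + lam - np.floor(lam + 1e-9)
    ).sum(axis=-1)


def tates_measure(G, Y, cp=None):
    """Extended-Simes trait-based p-value using per-dataset trait correlations."""
    if cp is None:
        cp = cross_products(G, Y)
    gc, yc, sgg, sgy, syy = cp
    p, _ = uv_p_matrix(G, Y, cp)
    R, P, k = p.shape
    if k == 1:
        return p[..., 0]
    d = np.sqrt(np.einsum("rkk->rk", syy))
    corr = syy / (d[:, :, None] * d[:, None, :])
    grid, rho_tab = _pvalue_corr_table()
    rho = np.interp(np.abs(corr), grid, rho_tab)
    ii = np.arange(k)
    rho[:, ii, ii] = 1.0
    order = np.argsort(p, axis=-1, kind="stable")  # (R,P,k)
    ps = np.take_along_axis(p, order, axis=-1)
    ridx = np.arange(R)[:, None, None, None]
    rows = order[..., :, None]
    cols = order[..., None, :]
    rho_ord = rho[ridx, rows, cols]  # (R,P,k,k)
    meff = np.empty((R, P, k))
    meff[..., 0] = 1.0
    for j in range(2, k + 1):
        lam = np.linalg.eigvalsh(rho_ord[..., :j, :j])
        meff[..., j - 1] = _li_ji_batch(lam)
    t = (meff[..., -1:] * ps / meff).min(axis=-1)
    return np.minimum(t, 1.0)


def uvpca_measure(G, Y, cp=None):
    """Univariate p-value of the first principal component of the traits."""
    if cp is None:
        cp = cross_products(G, Y)
    gc, yc, sgg, sgy, syy = cp
    n = Y.shape[1]
    _, vecs = np.linalg.eigh(syy)
    v1 = vecs[..., -1]  # (R,k)
    scores = np.einsum("rnk,rk->rn", yc, v1)  # centered since yc is
    sgs = np.einsum("rpn,rn->rp", gc, scores)
    sss = np.einsum("rn,rn->r", scores, scores)
    r2 = sgs**2 / (sgg * sss[:, None])
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    t = np.sqrt(r2 * (n - 2) / (1.0 - r2))
    return np.minimum(2.0 * stats.t.sf(t, n - 2), 1.0)
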