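"""Direct and indirect multivariate association tests for a single variant.

Five procedures, each consuming a genotype dosage vector and an n x k trait
matrix and returning an :class:`MVResult`:

* :func:`cca_test` — canonical correlation / MANOVA F-test (the MV-PLINK
  MQFAM statistic).
* :func:`bayes_mv_bf` — conjugate Bayesian multivariate regression Bayes
  factor with a matrix-normal effect prior and inverse-Wishart error prior
  (the MV-SNPTEST multiple-phenotype score).
* :func:`ordinal_reverse_lrt` — proportional-odds "reverse" regression of
  genotype on all traits with a joint likelihood-ratio test (MultiPhen).
* :func:`bimbam_partition_bf` — Bayes factor averaged over all partitions of
  the traits into unaffected / directly / indirectly affected (MV-BIMBAM
  ``-mph2``).
* :func:`pch_test` — principal component of heritability with training/test
  splits, bagging, and a permutation null (PCHAT).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from scipy import stats
from scipy.special import expit, logsumexp

from .errors import ConvergenceError, MonomorphicInputError, RankDeficientError

__all__ = [
    "MVResult",
    "BayesPriors",
    "PCHSettings",
    "cca_test",
    "bayes_mv_bf",
    "ordinal_reverse_lrt",
    "bimbam_partition_bf",
    "pch_test",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class MVResult:
    """One method's output on one dataset."""

    method: str
    measure: float
    measure_kind: str  # "p_value" | "log10_bf"
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.measure_kind not in ("p_value", "log10_bf"):
            raise ValueError(f"unknown measure_kind {self.measure_kind!r}")
        if self.measure_kind == "p_value" and not 0 <= self.measure <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def smaller_is_significant(self) -> bool:
        return self.measure_kind == "p_value"


@dataclass(frozen=True)
class BayesPriors:
    """Priors for the Bayesian multivariate tests.

    ``b_prior_scale`` is the scalar v_b of the matrix-normal effect prior
    beta | Sigma ~ N(b_prior_mean, v_b * Sigma); ``iw_scale`` and ``iw_df``
    parameterize the inverse-Wishart prior on the error covariance with
    density |Sigma|^{-(nu+k+1)/2} exp(-tr(S Sigma^{-1})/2), S = iw_scale * I,
    nu = iw_df.  ``bimbam_sigma_a`` is the grid of prior effect standard
    deviations (on the standardized-trait scale) averaged over by the
    partition Bayes factor.
    """

    b_prior_mean: float = 0.0
    b_prior_scale: float = 0.02
    iw_df: float = 4.0
    iw_scale: float = 6.0
    bimbam_sigma_a: tuple[float, ...] = (0.1, 0.2)

    def __post_init__(self):
        if self.b_prior_scale < 0:
            raise ValueError("b_prior_scale must be >= 0")
        if self.iw_scale <= 0 or self.iw_df <= 0:
            raise ValueError("inverse-Wishart parameters must be positive")
        if any(s <= 0 for s in self.bimbam_sigma_a):
            raise ValueError("sigma_a grid values must be positive")


def _as_gy(genotype, traits):
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(traits, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if g.shape[0] != y.shape[0]:
        raise ValueError("genotype and trait dimensions disagree")
    if np.ptp(g) == 0:
        raise MonomorphicInputError("genotype vector is constant")
    return g, y


# ---------------------------------------------------------------------------
# Canonical correlation (MV-PLINK)
# ---------------------------------------------------------------------------


def cca_test(genotype, traits) -> MVResult:
    """Canonical-correlation F-test of one variant against k traits.

    With a single genotype variable the first (only) canonical correlation r
    satisfies r^2 = R^2 of the OLS regression of G on the traits, and Rao's F
    for Wilks' lambda is exact:

        F = ((n - 1 - k) / k) * r^2 / (1 - r^2)   on (k, n - 1 - k) df.

    Equivalent to a MANOVA of the traits on the genotype.  The detail field
    carries the canonical trait loadings.
    """
    g, y = _as_gy(genotype, traits)
    n, k = y.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    gc = g - g.mean()
    yc = y - y.mean(axis=0)
    syy = yc.T @ yc
    ev = np.linalg.eigvalsh(syy)
    if ev[0] <= 1e-10 * max(ev[-1], 1.0):
        raise RankDeficientError("trait matrix is rank deficient")
    syg = yc.T @ gc
    sgg = gc @ gc
    w = np.linalg.solve(syy, syg)
    r2 = float(syg @ w / sgg)
    r2 = min(max(r2, 0.0), 1.0 - 1e-15)
    df2 = n - 1 - k
    f = (df2 / k) * r2 / (1.0 - r2)
    p = float(stats.f.sf(f, k, df2))
    nrm = np.linalg.norm(w)
    loadings = w / nrm if nrm > 0 else w
    return MVResult(
        "cca",
        p,
        "p_value",
        {"canonical_r": math.sqrt(r2), "F": f, "loadings": loadings},
    )


# ---------------------------------------------------------------------------
# Conjugate multivariate-regression Bayes factor (MV-SNPTEST)
# ---------------------------------------------------------------------------


def bayes_mv_bf(genotype, traits, priors: BayesPriors | None = None) -> MVResult:
    """Closed-form log10 Bayes factor for Y = mu + G beta + E vs beta = 0.

    Rows of E are iid N(0, Sigma); beta | Sigma ~ N(m0, v_b Sigma); Sigma is
    inverse-Wishart(S = iw_scale * I, nu = iw_df), shared by both models; the
    intercept carries a flat prior (handled by centering, effective sample
    size m = n - 1).  Integrating beta and Sigma gives matrix-variate-t
    marginals whose ratio reduces to determinants:

        BF = (1 + v_b s_g)^{-k/2} * ( |S + R0| / |S + R1| )^{(nu + m)/2}

    with s_g = sum(gc^2), R0 = Yc'Yc and R1 the residual cross-product after
    shrinkage regression of Yc on gc.  Dosage (non-integer) genotypes are
    accepted as-is.
    """
    if priors is None:
        priors = BayesPriors()
    g, y = _as_gy(genotype, traits)
    n, k = y.shape
    vb = priors.b_prior_scale
    if vb == 0:
        return MVResult("bayes", 0.0, "log10_bf", {"beta_post": np.zeros(k)})
    gc = g - g.mean()
    yc = y - y.mean(axis=0)
    if priors.b_prior_mean != 0.0:
        yc = yc - priors.b_prior_mean * gc[:, None]
    sg = gc @ gc
    syg = yc.T @ gc
    r0 = yc.T @ yc
    shrink = 1.0 / vb + sg
    r1 = r0 - np.outer(syg, syg) / shrink
    s_mat = priors.iw_scale * np.eye(k)
    _, ld0 = np.linalg.slogdet(s_mat + r0)
    _, ld1 = np.linalg.slogdet(s_mat + r1)
    m = n - 1
    log10bf = (-0.5 * k) * math.log1p(vb * sg) / LN10 + (
        0.5 * (priors.iw_df + m)
    ) * (ld0 - ld1) / LN10
    return MVResult(
        "bayes",
        float(log10bf),
        "log10_bf",
        {"beta_post": syg / shrink},
    )


# ---------------------------------------------------------------------------
# Reverse ordinal regression (MultiPhen)
# ---------------------------------------------------------------------------


def _prop_odds_loglik_parts(theta, beta, x, codes, n_cat):
    eta = x @ beta
    upper = np.where(codes < n_cat - 1, theta[np.minimum(codes, n_cat - 2)] - eta, np.inf)
    lower = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    a_cdf = expit(upper)
    b_cdf = expit(lower)
    prob = a_cdf - b_cdf
    return a_cdf, b_cdf, prob


def _po_grad_hess(theta, beta, x, codes, n_cat):
    """Log-likelihood, gradient, and Hessian of the cumulative-logit model."""
    n, k = x.shape
    a_cdf, b_cdf, prob = _prop_odds_loglik_parts(theta, beta, x, codes, n_cat)
    ll = float(np.sum(np.log(prob)))
    a = a_cdf * (1 - a_cdf)
    a[codes == n_cat - 1] = 0.0
    b = b_cdf * (1 - b_cdf)
    b[codes == 0] = 0.0
    inv_p = 1.0 / prob
    iu = np.minimum(codes, n_cat - 2)
    il = np.maximum(codes - 1, 0)
    has_u = codes < n_cat - 1
    has_l = codes > 0
    both = has_u & has_l
    du = np.where(has_u, a * inv_p, 0.0)  # dl/d t_upper
    dl = np.where(has_l, -b * inv_p, 0.0)  # dl/d t_lower
    g_theta = np.zeros(n_cat - 1)
    np.add.at(g_theta, iu, du)
    np.add.at(g_theta, il, dl)
    g_beta = x.T @ (-(du + dl))
    grad = np.concatenate([g_theta, g_beta])
    # per-observation second derivatives w.r.t. (t_upper, t_lower)
    huu = np.where(has_u, a * (1 - 2 * a_cdf) * inv_p - (a * inv_p) ** 2, 0.0)
    hll = np.where(has_l, -b * (1 - 2 * b_cdf) * inv_p - (b * inv_p) ** 2, 0.0)
    hul = np.where(both, a * b * inv_p**2, 0.0)
    npar = (n_cat - 1) + k
    hess = np.zeros((npar, npar))
    np.add.at(hess, (iu, iu), huu)
    np.add.at(hess, (il, il), hll)
    np.add.at(hess, (iu, il), hul)
    np.add.at(hess, (il, iu), hul)
    # chain rule: d t/d beta = -x for both cutpoints
    w_u = huu + hul
    w_l = hll + hul
    for c in range(n_cat - 1):
        row = -(x.T @ (w_u * (iu == c))) - (x.T @ (w_l * (il == c)))
        hess[c, n_cat - 1 :] = row
        hess[n_cat - 1 :, c] = row
    w_b = huu + hll + 2 * hul
    hess[n_cat - 1 :, n_cat - 1 :] = (x * w_b[:, None]).T @ x
    return ll, grad, hess


def _fit_proportional_odds(x, codes, n_cat, max_iter=60, tol=1e-8):
    """Newton maximization of the proportional-odds (cumulative logit) model.

    ``codes`` are ordinal category codes 0..n_cat-1; ``x`` is the predictor
    matrix.  Starts at beta = 0 with empirical cumulative-logit cutpoints (so
    the starting log-likelihood is the intercepts-only maximum).  Steps are
    halved when the likelihood does not improve or cutpoint ordering breaks.
    Returns (theta, beta, loglik, hessian, n_iter, grad_norm, converged).
    """
    n, k = x.shape
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / n
    theta = np.log(cum / (1 - cum))
    beta = np.zeros(k)
    ll, grad, hess = _po_grad_hess(theta, beta, x, codes, n_cat)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            return theta, beta, ll, hess, it, grad_norm, True
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            th_new = theta + step * delta[: n_cat - 1]
            be_new = beta + step * delta[n_cat - 1 :]
            if np.all(np.diff(th_new) > 0) or n_cat == 2:
                _, _, prob_new = _prop_odds_loglik_parts(th_new, be_new, x, codes, n_cat)
                if np.all(prob_new > 0):
                    ll_new = float(np.sum(np.log(prob_new)))
                    if ll_new >= ll - 1e-12:
                        break
            step *= 0.5
        else:
            return theta, beta, ll, hess, it, grad_norm, False
        improved = ll_new - ll
        theta, beta = th_new, be_new
        ll, grad, hess = _po_grad_hess(theta, beta, x, codes, n_cat)
        if improved < 1e-12 and grad_norm < 1e-4:
            return theta, beta, ll, hess, it, grad_norm, True
    return theta, beta, ll, hess, max_iter, grad_norm, False


def ordinal_reverse_lrt(
    genotype, traits, collapse_min_count: int = 5, max_iter: int = 60
) -> MVResult:
    """Joint LRT from a proportional-odds regression of genotype on traits.

    Genotype categories (0 < 1 < 2) are the ordinal response; the test
    statistic is 2(l_full - l_null) against the intercepts-only model, with
    chi^2 reference on one degree of freedom per (non-constant) trait.  When
    the rarest genotype category holds fewer than ``collapse_min_count``
    observations it is merged into its neighbor (with two categories the
    model is a binary logistic regression) — the regime where the original
    implementation showed convergence failures at low MAF.
    """
    g, y = _as_gy(genotype, traits)
    n, k = y.shape
    if n <= k:
        raise ValueError("need n > k")
    keep = np.ptp(y, axis=0) > 0
    if not keep.all():
        warnings.warn("constant trait column(s) dropped from the ordinal model")
        y = y[:, keep]
    k_eff = y.shape[1]
    if k_eff == 0:
        raise ValueError("no non-constant traits")
    values, codes = np.unique(g, return_inverse=True)
    n_cat = values.size
    counts = np.bincount(codes)
    while n_cat > 2 and counts.min() < collapse_min_count:
        i = int(np.argmin(counts))
        j = i - 1 if i > 0 else i + 1
        codes[codes == i] = j
        _, codes = np.unique(codes, return_inverse=True)
        counts = np.bincount(codes)
        n_cat -= 1
    counts = counts.astype(float)
    ll_null = float(np.sum(counts * np.log(counts / n)))
    theta, beta, ll_full, hess, n_iter, grad_norm, ok = _fit_proportional_odds(
        y, codes, n_cat, max_iter=max_iter
    )
    if not ok:
        raise ConvergenceError(
            f"proportional-odds fit did not converge in {n_iter} iterations",
            n_iter=n_iter,
            grad_norm=grad_norm,
        )
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, k_eff))
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov)[n_cat - 1 :], 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p_marg = 2.0 * stats.norm.sf(np.abs(z))
    except np.linalg.LinAlgError:
        p_marg = np.full(k_eff, np.nan)
    return MVResult(
        "ordinal",
        p,
        "p_value",
        {
            "lrt": lrt,
            "df": k_eff,
            "betas": beta,
            "marginal_p": p_marg,
            "n_categories": n_cat,
            "n_iter": n_iter,
        },
    )


# ---------------------------------------------------------------------------
# Partition-averaged Bayes factor (MV-BIMBAM)
# ---------------------------------------------------------------------------


def _nig_log_bf(y, g, covariates, sigma_a):
    """Conjugate univariate regression log-BF for adding g to y ~ covariates.

    Prior: effect ~ N(0, sigma_a^2 sigma^2); flat prior on the covariate
    coefficients; Jeffreys prior on sigma^2.  ``covariates`` must include the
    intercept column.
    """
    q_mat, _ = np.linalg.qr(covariates)
    yt = y - q_mat @ (q_mat.T @ y)
    gt = g - q_mat @ (q_mat.T @ g)
    s = gt @ gt
    if s <= 0:
        raise MonomorphicInputError("genotype constant after covariate projection")
    m = y.shape[0] - covariates.shape[1]
    rss0 = yt @ yt
    rss1 = rss0 - (yt @ gt) ** 2 / (s + sigma_a**-2)
    return -0.5 * math.log1p(sigma_a**2 * s) - 0.5 * m * (
        math.log(rss1) - math.log(rss0)
    )


def bimbam_partition_bf(genotype, traits, priors: BayesPriors | None = None) -> MVResult:
    """Bayes factor averaged over all U/D/I partitions of the traits.

    Every assignment of the k traits to {unaffected, directly affected,
    indirectly affected} with at least one directly affected trait is an
    alternative model.  Its Bayes factor against the global null factorizes
    into per-trait terms: each D trait is regressed on genotype with the U
    traits as covariates (normal effect prior, averaged over the sigma_a
    grid); the I- and U-trait factors are identical under null and
    alternative and cancel.  The overall BF is the uniform-weight average
    over partitions; the detail carries each trait's marginal posterior
    probability of being U/D/I given association.
    """
    if priors is None:
        priors = BayesPriors()
    g, y = _as_gy(genotype, traits)
    n, k = y.shape
    if k > 10:
        raise ValueError("partition enumeration guarded at k <= 10")
    ones = np.ones((n, 1))
    grid = priors.bimbam_sigma_a
    cache: dict = {}

    def d_term(j, u_set):
        key = (j, u_set)
        if key not in cache:
            cov = np.hstack([ones, y[:, sorted(u_set)]]) if u_set else ones
            logs = [_nig_log_bf(y[:, j], g, cov, s_a) for s_a in grid]
            cache[key] = logsumexp(logs) - math.log(len(grid))
        return cache[key]

    partitions = [
        p for p in itertools.product("UDI", repeat=k) if "D" in p
    ]
    log_bfs = np.empty(len(partitions))
    for i, part in enumerate(partitions):
        u_set = frozenset(j for j, c in enumerate(part) if c == "U")
        log_bfs[i] = sum(d_term(j, u_set) for j, c in enumerate(part) if c == "D")
    log_overall = logsumexp(log_bfs) - math.log(len(partitions))
    post = np.exp(log_bfs - logsumexp(log_bfs))
    classes = ("U", "D", "I")
    marginal = np.zeros((k, 3))
    for w, part in zip(post, partitions):
        for j, c in enumerate(part):
            marginal[j, classes.index(c)] += w
    return MVResult(
        "bimbam",
        float(log_overall / LN10),
        "log10_bf",
        {"partition_posteriors": dict(zip(partitions, post)), "marginal_udi": marginal},
    )


# ---------------------------------------------------------------------------
# Principal component of heritability (PCHAT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCHSettings:
    """Tunable settings of the PCH test (defaults follow the study protocol).

    ``n_train`` individuals per training subset; ``n_splits`` subset splits
    for the observed statistic and ``n_splits_null`` per permutation;
    ``n_bags`` bootstrap bags per training subset; ``n_null`` genotype
    permutations for the null distribution.
    """

    n_train: int = 150
    n_splits: int = 200
    n_bags: int = 50
    n_null: int = 1000
    n_splits_null: int = 50
    aggregate: str = "mean"


def _slope_t(g, y):
    gc = g - g.mean()
    yc = y - y.mean()
    sgg = gc @ gc
    slope = (gc @ yc) / sgg
    rss = max(yc @ yc - slope**2 * sgg, 1e-300)
    se = math.sqrt(rss / (len(g) - 2) / sgg)
    return slope / se if se > 0 else 0.0


def _pch_statistic(g, y, n_train, n_splits, n_bags, rng):
    """Mean over splits of the held-out t statistic for the bagged PCH score."""
    n, k = y.shape
    tstats = []
    skipped = 0
    weight_acc = np.zeros(k)
    for _ in range(n_splits):
        idx = rng.permutation(n)
        train, test = idx[:n_train], idx[n_train:]
        gtr, ytr = g[train], y[train]
        if np.ptp(gtr) == 0 or np.ptp(g[test]) == 0:
            skipped += 1
            continue
        ws = []
        for _ in range(n_bags):
            bag = rng.integers(0, n_train, n_train)
            gb, yb = gtr[bag], ytr[bag]
            if np.ptp(gb) == 0:
                continue
            gbc = gb - gb.mean()
            ybc = yb - yb.mean(axis=0)
            sgg = gbc @ gbc
            ahat = ybc.T @ gbc / sgg
            resid = ybc - np.outer(gbc, ahat)
            sig_e = resid.T @ resid / max(len(gb) - 2, 1)
            try:
                w = np.linalg.solve(sig_e, ahat)
            except np.linalg.LinAlgError:
                continue
            nrm = np.linalg.norm(w)
            if nrm == 0:
                continue
            w = w / nrm
            if w @ ahat < 0:  # sign-align bags before averaging
                w = -w
            ws.append(w)
        if not ws:
            skipped += 1
            continue
        wbar = np.mean(ws, axis=0)
        nrm = np.linalg.norm(wbar)
        if nrm == 0:
            skipped += 1
            continue
        wbar = wbar / nrm
        weight_acc += wbar
        score = y[test] @ wbar
        tstats.append(_slope_t(g[test], score))
    if not tstats:
        raise MonomorphicInputError("all PCH training splits were degenerate")
    wmean = weight_acc / max(len(tstats), 1)
    return float(np.mean(tstats)), skipped, wmean


def pch_test(
    genotype,
    traits,
    settings: PCHSettings | None = None,
    rng: Generator | None = None,
) -> MVResult:
    """Principal-component-of-heritability association test.

    Within each training subset, bagged estimates of the trait combination
    maximizing the heritable variance fraction (weights proportional to
    Sigma_e^{-1} a_hat) are averaged; the held-out individuals are scored
    with the averaged weights and the score regressed on genotype.  The
    observed statistic (mean held-out t over splits) is referred to a
    permutation null summarized by its mean, standard deviation, and a
    moment-matched t degree of freedom.
    """
    if settings is None:
        settings = PCHSettings()
    if rng is None:
        rng = default_rng()
    g, y = _as_gy(genotype, traits)
    if y.shape[0] <= settings.n_train + 2:
        raise ValueError("sample too small for the configured training-subset size")
    obs, skipped, weights = _pch_statistic(
        g, y, settings.n_train, settings.n_splits, settings.n_bags, rng
    )
    null = np.empty(settings.n_null)
    for i in range(settings.n_null):
        gp = rng.permutation(g)
        null[i], _, _ = _pch_statistic(
            gp, y, settings.n_train, settings.n_splits_null, settings.n_bags, rng
        )
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate permutation null")
    excess = float(stats.kurtosis(null, fisher=True, bias=False))
    df = 4.0 + 6.0 / excess if excess > 0.05 else 1e6
    df = min(max(df, 5.0), 1e6)
    scale = sd * math.sqrt((df - 2.0) / df)  # sd of t_df times this scale = sd
    t_std = (obs - mu) / scale
    p = float(2.0 * stats.t.sf(abs(t_std), df))
    return MVResult(
        "pch",
        p,
        "p_value",
        {
            "statistic": obs,
            "null_mean": mu,
            "null_sd": sd,
            "null_df": df,
            "weights": weights,
            "skipped_splits": skipped,
        },
    )
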