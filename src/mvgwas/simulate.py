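"""Simulation of single-QTL, multi-trait quantitative phenotype data.

The generative model: one bi-allelic quantitative trait locus (QTL) in
Hardy-Weinberg equilibrium with minor allele frequency ``q`` (the minor allele
is the effect allele), and ``k`` quantitative traits

    Y_j = a_j * G + e_j,        j = 1..k,

where ``G`` in {0, 1, 2} counts minor alleles, the additive per-allele effect
``a_j = sqrt(h2_j / (2 p q))`` is chosen so the QTL explains exactly the
fraction ``h2_j`` of the variance of a unit-variance trait, and the residual
vector ``e`` is multivariate normal with mean zero, per-trait variance
``1 - h2_j`` and pairwise residual correlation ``rE``.  Traits are finally
centered and scaled to zero sample mean and unit sample variance.

The cross-trait covariance induced by the QTL before scaling is
``a_j * a_l * 2 p q``; its sign (the sign of the genetic correlation rG) is
the product of the per-trait effect signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "ScenarioSpec",
    "SimDataset",
    "simulate_genotypes",
    "qtl_effect_size",
    "effect_sizes",
    "residual_covariance",
    "simulate_residuals",
    "assemble_traits",
    "simulate_dataset",
    "simulate_replicates",
    "scenario_grid",
    "unequal_h2_grid",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulation scenario.

    Parameters
    ----------
    maf_q
        Minor allele frequency of the QTL, in (0, 0.5].
    h2
        Per-trait QTL heritabilities h2_j in [0, 1).
    effect_sign
        Per-trait effect sign in {-1, 0, +1}; zero iff h2_j is zero.  The
        sign pattern encodes the sign of the QTL-induced genetic correlation.
    residual_corr
        Pairwise residual correlation rE between traits (equicorrelated).
    """

    maf_q: float
    h2: tuple[float, ...] = (0.001, 0.0, 0.0)
    effect_sign: tuple[int, ...] = (1, 0, 0)
    residual_corr: float = 0.0
    n_individuals: int = 1000
    n_replicates: int = 1000
    n_permutations_per_replicate: int = 10
    seed: int | None = None
    name: str = ""

    def __post_init__(self):
        h2 = tuple(float(v) for v in self.h2)
        sign = tuple(int(v) for v in self.effect_sign)
        object.__setattr__(self, "h2", h2)
        object.__setattr__(self, "effect_sign", sign)
        if len(h2) != len(sign):
            raise ValueError("h2 and effect_sign must have equal length")
        if self.n_individuals < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.maf_q <= 0.5:
            raise ValueError(f"maf_q must be in (0, 0.5], got {self.maf_q}")
        for v, s in zip(h2, sign):
            if not 0 <= v < 1:
                raise ValueError(f"h2 values must be in [0, 1), got {v}")
            if (v == 0) != (s == 0):
                raise ValueError("h2_j == 0 must coincide with effect_sign_j == 0")
            if s not in (-1, 0, 1):
                raise ValueError("effect signs must be -1, 0 or +1")
        # positive-definiteness of the implied residual covariance
        sigma = residual_covariance(h2, self.residual_corr)
        if np.linalg.eigvalsh(sigma)[0] <= 1e-12:
            raise ValueError(
                f"residual covariance not positive definite (rE={self.residual_corr})"
            )
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        n_assoc = sum(1 for s in self.effect_sign if s != 0)
        if n_assoc >= 2:
            rg = "+" if all(s >= 0 for s in self.effect_sign) else "-"
        else:
            rg = "0"
        return f"assoc{n_assoc}_rG{rg}_rE{self.residual_corr:g}_q{self.maf_q:g}"

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def effects(self) -> np.ndarray:
        """Signed per-allele effect sizes a_j."""
        return effect_sizes(self.h2, self.effect_sign, self.maf_q)


@dataclass(frozen=True)
class SimDataset:
    """One simulated replicate: genotypes plus standardized trait matrix."""

    genotype: np.ndarray  # (n,) ints in {0, 1, 2}
    traits: np.ndarray  # (n, k) standardized
    truth: ScenarioSpec | None = None
    effects: np.ndarray | None = None  # realized a_j

    @property
    def n(self) -> int:
        return self.genotype.shape[0]

    @property
    def k(self) -> int:
        return self.traits.shape[1]


def simulate_genotypes(n: int, q: float, rng: Generator) -> np.ndarray:
    """Sample ``n`` genotypes as the sum of two independent Bernoulli(q) alleles.

    Genotype frequencies follow Hardy-Weinberg proportions (p^2, 2pq, q^2).
    """
    if not 0 <= q <= 0.5:
        raise ValueError(f"minor allele frequency must be in [0, 0.5], got {q}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.binomial(2, q, size=n).astype(np.int64)


def qtl_effect_size(h2_j: float, q: float) -> float:
    """Per-allele additive effect a_j giving explained variance exactly h2_j.

    With residual variance 1 - h2_j the additive term a_j*G contributes
    variance a_j^2 * 2pq = h2_j, so the trait has unit variance and the QTL
    explains exactly fraction h2_j.  Effects are larger for rarer alleles.
    """
    if not 0 <= h2_j < 1:
        raise ValueError(f"h2 must be in [0, 1), got {h2_j}")
    if h2_j == 0:
        return 0.0
    if not 0 < q <= 0.5:
        raise ValueError("effect size undefined for a monomorphic locus (q = 0)")
    p = 1.0 - q
    return math.sqrt(h2_j / (2.0 * p * q))


def effect_sizes(
    h2: Sequence[float], effect_sign: Sequence[int], q: float
) -> np.ndarray:
    return np.array(
        [s * qtl_effect_size(v, q) for v, s in zip(h2, effect_sign)], dtype=float
    )


def residual_covariance(h2: Sequence[float], rE: float) -> np.ndarray:
    """Residual covariance: var_j = 1 - h2_j, corr(e_j, e_l) = rE for j != l."""
    sd = np.sqrt(1.0 - np.asarray(h2, dtype=float))
    k = sd.shape[0]
    corr = np.full((k, k), rE, dtype=float)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def simulate_residuals(
    n: int, h2: Sequence[float], rE: float, rng: Generator
) -> np.ndarray:
    """Draw n residual vectors from MVN(0, Sigma_e)."""
    sigma = residual_covariance(h2, rE)
    w = np.linalg.eigvalsh(sigma)
    if w[0] <= 1e-12:
        raise ValueError("residual covariance not positive definite")
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, len(h2)))
    return z @ chol.T


def assemble_traits(
    genotype: np.ndarray, a: np.ndarray, residuals: np.ndarray
) -> np.ndarray:
    """Y_j = a_j*G + e_j, then center and scale each column (sample sd, ddof=1)."""
    genotype = np.asarray(genotype, dtype=float)
    if residuals.shape[0] != genotype.shape[0]:
        raise ValueError("genotype and residual dimensions disagree")
    if residuals.shape[1] != np.shape(a)[0]:
        raise ValueError("effect vector and residual dimensions disagree")
    y = genotype[:, None] * np.asarray(a, dtype=float)[None, :] + residuals
    y = y - y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant trait column; cannot standardize")
    return y / sd


def simulate_dataset(spec: ScenarioSpec, rng: Generator | None = None) -> SimDataset:
    """Simulate a single replicate under ``spec``.

    If no generator is passed, one is created deterministically from the
    spec's seed (replicate 0 of the spec's replicate stream).
    """
    if rng is None:
        rng = default_rng(SeedSequence(spec.seed).spawn(1)[0])
    g = simulate_genotypes(spec.n_individuals, spec.maf_q, rng)
    a = spec.effects()
    e = simulate_residuals(spec.n_individuals, spec.h2, spec.residual_corr, rng)
    y = assemble_traits(g, a, e)
    return SimDataset(genotype=g, traits=y, truth=spec, effects=a)


def simulate_replicates(
    spec: ScenarioSpec, n_replicates: int | None = None
) -> Iterator[SimDataset]:
    """Yield independent replicates with per-replicate child seeds.

    A single master seed (spec.seed) spawns one child seed per replicate, so
    any replicate is reproducible in isolation and the stream is safe to
    parallelize.
    """
    r = spec.n_replicates if n_replicates is None else n_replicates
    for child in SeedSequence(spec.seed).spawn(r):
        yield simulate_dataset(spec, default_rng(child))


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------

#: Effect-sign patterns: (# associated traits, rG sign label, signs)
_SIGN_PATTERNS = [
    (1, "0", (1, 0, 0)),
    (2, "+", (1, 1, 0)),
    (2, "-", (-1, 1, 0)),
    (3, "+", (1, 1, 1)),
    (3, "-", (-1, 1, 1)),
]


def scenario_grid(
    mafs: Sequence[float] = (0.01, 0.4),
    residual_corrs: Sequence[float] = (0.0, 0.3, 0.7),
    h2_assoc: float = 0.001,
    **overrides,
) -> list[ScenarioSpec]:
    """The default 30-scenario study grid.

    {1, 2, 3} associated traits (with both rG signs for 2 and 3) crossed with
    rE in {0, 0.3, 0.7} and MAF in {0.01, 0.4}; every associated trait has
    QTL heritability 0.1%.  Supplementary grids are obtained by passing other
    MAFs (0.05, 0.10, 0.25) or via :func:`unequal_h2_grid`.
    """
    grid = []
    for n_assoc, rg, signs in _SIGN_PATTERNS:
        for re_ in residual_corrs:
            for q in mafs:
                h2 = tuple(h2_assoc if s != 0 else 0.0 for s in signs)
                grid.append(
                    ScenarioSpec(
                        maf_q=q,
                        h2=h2,
                        effect_sign=signs,
                        residual_corr=re_,
                        **overrides,
                    )
                )
    return grid


def unequal_h2_grid(
    mafs: Sequence[float] = (0.01, 0.4),
    residual_corrs: Sequence[float] = (0.0, 0.3, 0.7),
    h2: Sequence[float] = (0.001, 0.002, 0.0005),
    **overrides,
) -> list[ScenarioSpec]:
    """Supplementary grid: all three traits associated with unequal h2.

    Default heritabilities 0.1% / 0.2% / 0.05%, both rG signs.
    """
    h2 = tuple(h2)
    grid = []
    for signs in [(1, 1, 1), (-1, 1, 1)]:
        for re_ in residual_corrs:
            for q in mafs:
                grid.append(
                    ScenarioSpec(
                        maf_q=q,
                        h2=h2,
                        effect_sign=signs,
                        residual_corr=re_,
                        name=f"assoc3uneq_rG{'+' if signs[0] > 0 else '-'}"
                        f"_rE{re_:g}_q{q:g}",
                        **overrides,
                    )
                )
    return grid
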