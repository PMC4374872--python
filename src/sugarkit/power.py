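"""Power calculations for quantitative-trait genetic association tests.

A single additive variant tested by linear regression is a 1-degree-of-
freedom test whose large-sample statistic is noncentral chi-square with
noncentrality lambda = n * r2 / (1 - r2), where r2 is the fraction of
phenotypic variance the variant explains.  Power is the probability that
the statistic exceeds the central chi-square(1) critical value.  The
variant's population frequency is absorbed by the variance-explained
parametrization and does not enter mode-1 power.

For the cross-challenge question — does a variant shift one normalized
endpoint differently from another — the tested trait is the difference D
of two standardized endpoints with correlation rho, so var(D) =
2(1 - rho).  A per-allele effect difference b on D with genotype variance
2*maf*(1 - maf) under Hardy-Weinberg equilibrium is equivalent to
r2 = b^2 * 2*maf*(1-maf) / (var(D) + b^2 * 2*maf*(1-maf)), and power
follows from the mode-1 formula.  A Monte-Carlo oracle verifies both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PowerSpec:
    """Parametrization of one genetic power question."""

    n: int
    alpha: float = 0.05
    mode: str = "variance_explained"
    r2: Optional[float] = None
    maf: Optional[float] = None
    beta_diff: Optional[float] = None
    endpoint_corr: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("variance_explained", "effect_difference"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "variance_explained":
            if self.r2 is None or not 0 <= self.r2 < 1:
                raise ValueError("variance_explained mode needs 0 <= r2 < 1")
        else:
            if self.maf is None or not 0 < self.maf <= 0.5:
                raise ValueError("effect_difference mode needs 0 < maf <= 0.5")
            if self.beta_diff is None:
                raise ValueError("effect_difference mode needs beta_diff")
            if not -1 < self.endpoint_corr < 1:
                raise ValueError("endpoint_corr must be in (-1, 1)")

    def power(self) -> float:
        if self.mode == "variance_explained":
            return power_variance_explained(self.n, self.r2, self.alpha,
                                            maf=self.maf)
        return power_effect_difference(
            self.n, self.maf, self.beta_diff, self.endpoint_corr, self.alpha
        )


def power_variance_explained(
    n: int, r2: float, alpha: float = 0.05, maf: Optional[float] = None
) -> float:
    """Power of the 1-df test of a variant explaining ``r2`` of phenotypic
    variance at sample size ``n``.  ``r2 = 0`` returns alpha exactly.  A
    supplied allele frequency is accepted and ignored: the variance-
    explained parametrization absorbs it."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if maf is not None:
        logger.info("allele frequency %.3g ignored in variance-explained mode", maf)
    if r2 == 0.0:
        return alpha
    lam = n * r2 / (1.0 - r2)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def power_variance_explained_finite(
    n: int, r2: float, alpha: float = 0.05
) -> float:
    """Exact finite-sample power of the regression slope t-test: noncentral
    F with (1, n-2) degrees of freedom.  Converges to the noncentral
    chi-square value as n grows; preferred as the reference when checking
    simulated rejection rates at moderate n."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if r2 == 0.0:
        return alpha
    lam = n * r2 / (1.0 - r2)
    fcrit = stats.f.ppf(1.0 - alpha, 1, n - 2)
    return float(stats.ncf.sf(fcrit, 1, n - 2, lam))


def power_effect_difference(
    n: int,
    maf: float,
    beta_diff: float,
    endpoint_corr: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Power to detect a per-allele effect ``beta_diff`` on the difference
    of two standardized endpoints with correlation ``endpoint_corr``."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if beta_diff == 0.0:
        return alpha
    var_d = 2.0 * (1.0 - endpoint_corr)
    var_g = 2.0 * maf * (1.0 - maf)
    signal = beta_diff**2 * var_g
    r2 = signal / (var_d + signal)
    return power_variance_explained(n, r2, alpha)


def power_by_simulation(
    spec: PowerSpec, n_reps: int = 2000, seed: int = 0
) -> Tuple[float, float]:
    """Monte-Carlo power: simulate Hardy-Weinberg genotypes, add the
    specified effect to a unit-variance phenotype, fit the unadjusted
    linear model per replicate, and count two-sided rejections at alpha.

    Returns (rejection fraction, binomial standard error).  The per-
    replicate slope test is the closed-form OLS t-test, vectorized over
    replicates.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    maf = spec.maf if spec.maf is not None else 0.3
    var_g = 2.0 * maf * (1.0 - maf)
    if spec.mode == "variance_explained":
        # per-allele beta on a phenotype with unit residual variance such
        # that the variant explains r2 of the total variance
        r2 = spec.r2
        beta = math.sqrt(r2 / (1.0 - r2) / var_g) if r2 > 0 else 0.0
        resid_sd = 1.0
    else:
        beta = spec.beta_diff
        resid_sd = math.sqrt(2.0 * (1.0 - spec.endpoint_corr))
    n = spec.n
    g = rng.binomial(2, maf, size=(n_reps, n)).astype(float)
    y = beta * g + rng.normal(0.0, resid_sd, size=(n_reps, n))
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.sum(gc * gc, axis=1)
    sxx = np.where(sxx == 0, np.nan, sxx)  # monomorphic draws cannot reject
    bhat = np.sum(gc * yc, axis=1) / sxx
    rss = np.sum(yc * yc, axis=1) - bhat**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    t = bhat / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)
    reject = np.nan_to_num(pvals, nan=1.0) < spec.alpha
    frac = float(np.mean(reject))
    return frac, math.sqrt(frac * (1.0 - frac) / n_reps)
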