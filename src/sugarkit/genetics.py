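"""SNP panels, genetic risk scores, and covariate-adjusted associations.

The risk scores are unweighted sums of trait-raising allele counts: 34
fasting-glucose SNPs give a glucose score in [0, 68], 14 fasting-insulin
SNPs an insulin score in [0, 28].  Associations are ordinary least squares
with the genotype coded additively (0/1/2 effect alleles), with or without
age, sex, and ethnicity as covariates; ethnicity enters as indicator
variables against a non-Hispanic-White reference, and can instead define
strata fitted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TRAITS = ("fasting_glucose", "fasting_insulin")
ALLELES = ("A", "C", "G", "T")
ETHNICITY_REFERENCE = "non_hispanic_white"

MISSING_POLICIES = ("absent", "scale", "mean_impute")


@dataclass
class SnpPanel:
    """Effect-allele definitions: one row per SNP with its trait."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, trait

    def __post_init__(self) -> None:
        t = self.table
        for col in ("snp_id", "effect_allele", "trait"):
            if col not in t.columns:
                raise ValueError(f"panel missing column {col!r}")
        if t["snp_id"].duplicated().any():
            raise ValueError("panel snp_ids must be unique")
        bad = set(t["effect_allele"]) - set(ALLELES)
        if bad:
            raise ValueError(f"invalid effect allele(s) {sorted(bad)}")
        bad = set(t["trait"]) - set(TRAITS)
        if bad:
            raise ValueError(f"invalid trait(s) {sorted(bad)}")

    def snps_for(self, trait: str) -> list:
        if trait not in TRAITS:
            raise ValueError(f"unknown trait {trait!r}")
        return self.table.loc[self.table["trait"] == trait, "snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def synthetic_panel(n_glucose: int = 34, n_insulin: int = 14) -> SnpPanel:
    """A synthetic stand-in SNP panel with the study's panel sizes.

    The real panel (34 fasting-glucose and 14 fasting-insulin loci with
    their published effect alleles) is supplementary user data; this
    placeholder carries generated rs-style identifiers and alternating
    effect alleles so every panel-shaped code path can run without it.
    """
    rows = []
    for i in range(n_glucose):
        rows.append((f"rsFG{i + 1:03d}", ALLELES[i % 4], "fasting_glucose"))
    for i in range(n_insulin):
        rows.append((f"rsFI{i + 1:03d}", ALLELES[(i + 1) % 4], "fasting_insulin"))
    return SnpPanel(
        pd.DataFrame(rows, columns=["snp_id", "effect_allele", "trait"])
    )


def grs(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    trait: str,
    missing_policy: str = "absent",
) -> pd.Series:
    """Unweighted genetic risk score: sum of effect-allele counts over the
    trait's panel SNPs, in [0, 2K] for K SNPs.

    Missing calls follow ``missing_policy``: ``absent`` (default) drops the
    participant's score entirely — missing data are not imputed; ``scale``
    rescales the sum of observed calls to the full panel size; and
    ``mean_impute`` fills each missing call with that SNP's cohort mean.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    snps = panel.snps_for(trait)
    absent = [s for s in snps if s not in genotypes.columns]
    if absent:
        raise ValueError(f"panel SNP(s) absent from genotype matrix: {absent}")
    calls = genotypes[snps].astype(float)
    if missing_policy == "absent":
        score = calls.sum(axis=1, min_count=len(snps))
    elif missing_policy == "scale":
        observed = calls.notna().sum(axis=1)
        score = calls.sum(axis=1, min_count=1) * len(snps) / observed
    else:  # mean_impute
        score = calls.fillna(calls.mean()).sum(axis=1)
    score.name = f"grs_{trait}"
    return score


@dataclass
class AssocResult:
    """Per-allele slope from an additive linear model."""

    beta: float
    se: float
    p: float
    n: int
    model: str = "unadjusted"
    stratum: str = "all"


def _design(
    predictor: pd.Series,
    covariates: Optional[pd.DataFrame],
    adjust: bool,
    include_ethnicity: bool = True,
) -> pd.DataFrame:
    X = pd.DataFrame({"predictor": predictor.astype(float)})
    if adjust:
        if covariates is None:
            raise ValueError("adjust=True requires covariates")
        if "age" in covariates:
            X["age"] = covariates["age"].astype(float)
        if "sex" in covariates:
            X["sex_male"] = (covariates["sex"] == "male").astype(float)
        if "bmi" in covariates:
            X["bmi"] = covariates["bmi"].astype(float)
        if include_ethnicity and "ethnicity" in covariates:
            dummies = pd.get_dummies(covariates["ethnicity"], prefix="eth")
            ref = f"eth_{ETHNICITY_REFERENCE}"
            if ref in dummies:
                dummies = dummies.drop(columns=ref)
            # drop any all-zero indicator (level not present)
            dummies = dummies.loc[:, dummies.sum() > 0]
            X = pd.concat([X, dummies.astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def _fit_predictor(
    phenotype: pd.Series,
    predictor: pd.Series,
    covariates: Optional[pd.DataFrame],
    adjust: bool,
    include_ethnicity: bool = True,
    min_n: int = 10,
) -> AssocResult:
    y = pd.Series(phenotype).astype(float)
    x = pd.Series(predictor).astype(float).reindex(y.index)
    X = _design(x, covariates, adjust, include_ethnicity)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if len(y) < min_n:
        raise ValueError(f"need >= {min_n} complete cases, have {len(y)}")
    if X["predictor"].nunique() < 2:
        raise ValueError("predictor is monomorphic in the analysis set")
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params["predictor"]),
        se=float(fit.bse["predictor"]),
        p=float(fit.pvalues["predictor"]),
        n=int(len(y)),
        model="adjusted" if adjust else "unadjusted",
    )


def single_variant_assoc(
    phenotype: pd.Series,
    genotype_column: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    adjust: bool = False,
) -> AssocResult:
    """Per-allele OLS association of a phenotype with one SNP coded 0/1/2,
    optionally adjusted for age, sex, and ethnicity."""
    geno = pd.Series(genotype_column).astype(float)
    vals = geno.dropna()
    if not np.isin(vals.to_numpy(), (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype column must be coded 0/1/2")
    return _fit_predictor(phenotype, geno, covariates, adjust)


def grs_assoc(
    phenotype: pd.Series,
    grs_scores: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    adjust: bool = False,
    stratify_by_ethnicity: bool = False,
) -> pd.DataFrame:
    """Association of a phenotype with a genetic risk score.

    Returns a tidy report with an overall row and, when stratified, one
    unadjusted-for-ethnicity row per ethnic group (strata with fewer than
    10 complete cases are skipped with a warning).
    """
    rows = []
    overall = _fit_predictor(phenotype, grs_scores, covariates, adjust)
    rows.append(overall)
    if stratify_by_ethnicity:
        if covariates is None or "ethnicity" not in covariates:
            raise ValueError("stratification requires an ethnicity covariate")
        for group, idx in covariates.groupby("ethnicity").groups.items():
            try:
                res = _fit_predictor(
                    phenotype.loc[idx],
                    grs_scores.loc[idx],
                    covariates.loc[idx],
                    adjust,
                    include_ethnicity=False,
                )
            except ValueError as exc:
                logger.warning("stratum %s skipped: %s", group, exc)
                continue
            res.stratum = str(group)
            rows.append(res)
    return pd.DataFrame(
        [
            {"model": r.model, "stratum": r.stratum, "term": "grs",
             "beta": r.beta, "se": r.se, "p": r.p, "n": r.n}
            for r in rows
        ]
    )


@dataclass
class EthnicityEffect:
    f_stat: float
    p: float
    df_num: int
    df_den: int
    n: int


def ethnicity_effect_on_endpoint(
    endpoint: pd.Series,
    ethnicity: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> EthnicityEffect:
    """Joint F-test of ethnicity indicators on an endpoint, adjusted for
    age, sex, and BMI when provided."""
    y = pd.Series(endpoint).astype(float)
    eth = pd.Series(ethnicity).reindex(y.index)
    if eth.nunique() < 2:
        raise ValueError("need at least 2 ethnic groups")
    X = pd.DataFrame(index=y.index)
    if covariates is not None:
        if "age" in covariates:
            X["age"] = covariates["age"].astype(float)
        if "sex" in covariates:
            X["sex_male"] = (covariates["sex"] == "male").astype(float)
        if "bmi" in covariates:
            X["bmi"] = covariates["bmi"].astype(float)
    dummies = pd.get_dummies(eth, prefix="eth")
    ref = f"eth_{ETHNICITY_REFERENCE}"
    if ref in dummies:
        dummies = dummies.drop(columns=ref)
    dummies = dummies.loc[:, dummies.sum() > 0]
    if dummies.shape[1] < 1:
        raise ValueError("need at least 2 ethnic groups")
    X = pd.concat([X, dummies.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    fit = sm.OLS(y, X).fit()
    terms = [c for c in X.columns if c.startswith("eth_")]
    contrast = np.zeros((len(terms), X.shape[1]))
    for i, t in enumerate(terms):
        contrast[i, list(X.columns).index(t)] = 1.0
    f = fit.f_test(contrast)
    return EthnicityEffect(
        f_stat=float(f.fvalue), p=float(f.pvalue),
        df_num=int(f.df_num), df_den=int(f.df_denom), n=int(len(y)),
    )
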