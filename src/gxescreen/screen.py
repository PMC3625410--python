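"""Marginal, correlation and interaction scans over (SNP, exposure) pairs.

Each scan fits one survey-weighted regression per factor or per pair on
that factor's own complete-case subsample, adjusting for age, sex, race
and BMI by default.  The interaction screen fits the multiplicative
model

    logit P(case) = a + b_g*g + b_e*e + b_gxe*(g*e) + covariates

with g the risk-allele dosage and e the standardized exposure, and
collects the Wald p-value of b_gxe for every pair into the observed set
P_real.  Conditional odds ratios re-express the same fit as per-allele
ORs at exposure levels -1/0/+1 SD and per-SD exposure ORs at dosages
0/1/2, with delta-method confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExposurePanel, transform_exposures
from .survey_glm import (
    DegenerateOutcomeError,
    FitResult,
    SurveyDesign,
    fit_survey_linear,
    fit_survey_logistic,
    wald_contrast,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ADJUSTMENTS",
    "build_design_matrix",
    "marginal_scan",
    "ge_correlation_scan",
    "interaction_screen",
    "conditional_or",
    "stratified_screen",
    "sensitivity_screen",
    "p_real",
]

DEFAULT_ADJUSTMENTS = ("age", "sex", "race", "bmi")


def _covariate_columns(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Adjustment block: numeric columns as-is, categoricals as indicator
    columns dropping the first level."""
    blocks = []
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            # fixed level order so the matrix is independent of row order
            dummies = dummies[sorted(dummies.columns)]
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(cov))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)


def build_design_matrix(
    df: pd.DataFrame,
    snp: str | None = None,
    exposure: str | None = None,
    interaction: bool = False,
    covariates=DEFAULT_ADJUSTMENTS,
) -> pd.DataFrame:
    """Model matrix with intercept, focal terms named 'g', 'e', 'g:e',
    and adjustment covariates.  The product term requires both parents."""
    if interaction and (snp is None or exposure is None):
        raise ValueError("interaction term requires both a SNP and an exposure")
    parts = {"intercept": np.ones(len(df))}
    if snp is not None:
        parts["g"] = df[snp].to_numpy(dtype=float)
    if exposure is not None:
        parts["e"] = df[exposure].to_numpy(dtype=float)
    if interaction:
        parts["g:e"] = parts["g"] * parts["e"]
    X = pd.DataFrame(parts, index=df.index)
    cov = _covariate_columns(df, covariates)
    return pd.concat([X, cov], axis=1)


def _complete_case(df: pd.DataFrame, cols) -> pd.Series:
    return df[list(cols)].notna().all(axis=1)


def _fit_pair(df, design, snp, exposure, covariates, interaction=True):
    """Fit the pair model on its complete-case subsample.

    Returns (fit | None, n, mask).  Degenerate subsamples give None.
    """
    needed = ["outcome", snp, exposure, *covariates]
    mask = _complete_case(df, needed).to_numpy()
    sub = df.loc[mask]
    if len(sub) == 0:
        return None, 0, mask
    X = build_design_matrix(sub, snp, exposure, interaction, covariates)
    try:
        fit = fit_survey_logistic(X, sub["outcome"].to_numpy(), design.subset(mask))
    except (DegenerateOutcomeError, ValueError) as exc:
        logger.warning("pair (%s, %s) not fitted: %s", snp, exposure, exc)
        return None, len(sub), mask
    return fit, len(sub), mask


def marginal_scan(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    factors,
    covariates=DEFAULT_ADJUSTMENTS,
) -> pd.DataFrame:
    """Adjusted marginal association of each factor with the outcome.

    One survey-logistic model per factor on that factor's complete-case
    subsample; the factor enters as a single numeric term (per-allele for
    dosages, per-SD for standardized exposures).  Constant or all-missing
    factors are skipped with a log entry.
    """
    rows = []
    for factor in factors:
        needed = ["outcome", factor, *covariates]
        mask = _complete_case(cohort, needed).to_numpy()
        sub = cohort.loc[mask]
        vals = sub[factor]
        if len(sub) == 0 or vals.nunique() < 2:
            logger.warning("marginal scan: factor %s degenerate, skipped", factor)
            continue
        X = build_design_matrix(sub, snp=factor, covariates=covariates)
        try:
            fit = fit_survey_logistic(X, sub["outcome"].to_numpy(), design.subset(mask))
        except DegenerateOutcomeError:
            logger.warning("marginal scan: outcome degenerate for %s, skipped", factor)
            continue
        term = fit["g"]
        ci = wald_contrast(fit, np.eye(len(fit.params))[fit.names.index("g")])["ci"]
        rows.append(
            {
                "factor": factor,
                "or": np.exp(term["estimate"]),
                "ci_low": np.exp(ci[0]),
                "ci_high": np.exp(ci[1]),
                "p": term["p"],
                "n": fit.n,
                "n_cases": fit.n_cases,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def ge_correlation_scan(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    snps,
    exposures,
    covariates=DEFAULT_ADJUSTMENTS,
) -> pd.DataFrame:
    """Association of each raw exposure with each dosage:
    survey-weighted linear regression of log10(exposure) on the dosage,
    adjusted for the covariates.  The slope is also reported as percent
    change in exposure per risk allele, 100*(10^slope - 1).

    Exposure columns must hold strictly positive raw concentrations.
    """
    rows = []
    for eid in exposures:
        pos = cohort[eid].dropna()
        if (pos <= 0).any():
            raise ValueError(f"{eid}: non-positive values; log10 scan impossible")
        for sid in snps:
            needed = [sid, eid, *covariates]
            mask = _complete_case(cohort, needed).to_numpy()
            sub = cohort.loc[mask]
            if len(sub) == 0 or sub[sid].nunique() < 2:
                logger.warning("correlation scan: (%s, %s) degenerate, skipped", sid, eid)
                continue
            X = build_design_matrix(sub, snp=sid, covariates=covariates)
            y = np.log10(sub[eid].to_numpy(dtype=float))
            fit = fit_survey_linear(X, y, design.subset(mask))
            term = fit["g"]
            rows.append(
                {
                    "snp": sid,
                    "exposure": eid,
                    "slope": term["estimate"],
                    "se": term["se"],
                    "p": term["p"],
                    "pct_change_per_allele": 100.0 * (10.0 ** term["estimate"] - 1.0),
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConditionalOR:
    """Conditional odds ratios from one interaction fit.

    per_allele: exposure level c in {-1, 0, +1} SD -> (OR, lo, hi)
    per_sd:     dosage g in {0, 1, 2} -> (OR, lo, hi)
    """

    per_allele: dict
    per_sd: dict


def conditional_or(fit: FitResult, alpha: float = 0.05) -> ConditionalOR:
    """Per-allele OR at exposure c is exp(b_g + c*b_gxe); per-SD exposure
    OR at dosage g is exp(b_e + g*b_gxe).  Delta-method CIs via the Wald
    contrast on the log-odds scale.  At c = 0 the per-allele OR collapses
    to the fit's own exp(b_g)."""
    for term in ("g", "e", "g:e"):
        if term not in fit.names:
            raise ValueError(f"fit lacks required term {term!r}")
    k = len(fit.params)
    ig, ie, ix = (fit.names.index(t) for t in ("g", "e", "g:e"))

    def _or_at(base_idx, mult_idx, level):
        c = np.zeros(k)
        c[base_idx] = 1.0
        c[mult_idx] += level
        w = wald_contrast(fit, c, alpha=alpha)
        return (np.exp(w["estimate"]), np.exp(w["ci"][0]), np.exp(w["ci"][1]))

    per_allele = {c: _or_at(ig, ix, c) for c in (-1.0, 0.0, 1.0)}
    per_sd = {g: _or_at(ie, ix, g) for g in (0.0, 1.0, 2.0)}
    return ConditionalOR(per_allele=per_allele, per_sd=per_sd)


def interaction_screen(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    snps,
    exposures,
    covariates=DEFAULT_ADJUSTMENTS,
    with_conditional: bool = True,
) -> pd.DataFrame:
    """Fit the multiplicative interaction model for every (SNP, exposure)
    pair on its own complete-case subsample.

    Exposure columns are expected already standardized (SD units).  The
    returned table has one row per attempted pair, sorted by interaction
    p-value; non-converged pairs keep their row, flagged, so exclusions
    are visible.  Results do not depend on input ordering.
    """
    rows = []
    for sid in sorted(snps):
        for eid in sorted(exposures):
            fit, n, _ = _fit_pair(cohort, design, sid, eid, covariates)
            row = {"snp": sid, "exposure": eid, "n": n}
            if fit is None:
                row.update(
                    beta_gxe=np.nan, se_gxe=np.nan, p=np.nan, or_gxe=np.nan,
                    beta_g=np.nan, beta_e=np.nan, n_cases=0, n_controls=0,
                    converged=False,
                )
                rows.append(row)
                continue
            term = fit["g:e"]
            row.update(
                beta_gxe=term["estimate"],
                se_gxe=term["se"],
                p=term["p"],
                or_gxe=np.exp(term["estimate"]),
                beta_g=fit["g"]["estimate"],
                beta_e=fit["e"]["estimate"],
                n_cases=fit.n_cases,
                n_controls=fit.n_controls,
                converged=fit.converged and not fit.separation,
            )
            if with_conditional:
                cor = conditional_or(fit)
                for c, (orv, lo, hi) in cor.per_allele.items():
                    tag = f"allele_or_at_e{int(c):+d}"
                    row[tag] = orv
                    row[f"{tag}_lo"] = lo
                    row[f"{tag}_hi"] = hi
                for g, (orv, lo, hi) in cor.per_sd.items():
                    tag = f"exposure_or_at_g{int(g)}"
                    row[tag] = orv
                    row[f"{tag}_lo"] = lo
                    row[f"{tag}_hi"] = hi
            rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["p", "snp", "exposure"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def p_real(screen_table: pd.DataFrame) -> np.ndarray:
    """Observed interaction p-values from converged pairs (the P_real set)."""
    ok = screen_table["converged"] & screen_table["p"].notna()
    return screen_table.loc[ok, "p"].to_numpy()


def stratified_screen(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    snps,
    exposures,
    stratify_by: str = "race",
    min_cases: int = 20,
    covariates=("age", "sex", "bmi"),
) -> pd.DataFrame:
    """interaction_screen run separately within each level of a
    categorical variable.  Levels with fewer than min_cases complete-case
    cases are reported as underpowered rather than fitted.  The
    stratifying variable is dropped from the adjustment set."""
    frames = []
    for level in sorted(cohort[stratify_by].dropna().unique()):
        mask = (cohort[stratify_by] == level).to_numpy()
        sub = cohort.loc[mask]
        n_cases = int((sub["outcome"] == 1).sum())
        if n_cases < min_cases:
            logger.warning(
                "stratum %s=%s has %d cases (<%d); skipped as underpowered",
                stratify_by, level, n_cases, min_cases,
            )
            frames.append(
                pd.DataFrame(
                    [{"stratum": level, "underpowered": True, "n_cases": n_cases}]
                )
            )
            continue
        tab = interaction_screen(
            sub, design.subset(mask), snps, exposures, covariates=covariates
        )
        tab.insert(0, "stratum", level)
        tab["underpowered"] = False
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def sensitivity_screen(
    raw_cohort: pd.DataFrame,
    design: SurveyDesign,
    snps,
    exposures,
    transform: str = "log10",
    extra_adjust=(),
    covariates=DEFAULT_ADJUSTMENTS,
) -> pd.DataFrame:
    """Re-run the interaction screen under a modified specification:
    raw-scale (untransformed) exposure standardization, extra adjustment
    covariates (e.g. a correlated co-exposure), or an alternative factor
    set.  Takes raw (unstandardized) exposure columns; output is
    row-comparable with the main screen.
    """
    panel = ExposurePanel(columns=list(exposures), transform=transform)
    prepared = transform_exposures(raw_cohort, panel)
    adjust = tuple(covariates) + tuple(extra_adjust)
    return interaction_screen(prepared, design, snps, exposures, covariates=adjust)
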