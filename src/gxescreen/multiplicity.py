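"""Multiplicity control for the interaction screen.

Two devices:

1.  An effective-number-of-tests Bonferroni correction for correlated
    factors.  The eigenvalue (Nyholt) estimator maps a correlation
    matrix of M factors to M_eff = 1 + (M-1) * (1 - Var(lambda)/M),
    where lambda are the eigenvalues and the variance uses denominator
    M-1.  Uncorrelated factors give M_eff = M; perfectly redundant ones
    give M_eff = 1.  Genetic and exposure counts multiply to the total
    effective tests, which divides the nominal significance level.

2.  A parametric-bootstrap false-discovery-rate estimator for the
    interaction terms.  For each pair a no-interaction model (the null,
    retaining both main effects and all covariates) is fitted; replicate
    outcomes are generated from that fitted null, the interaction model
    is refitted on each, and the interaction p-values form the null set
    P_null.  The FDR at threshold t is

        fdr(t) = (#{P_null < t} / B) / #{P_real < t}.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import _complete_case, build_design_matrix
from .survey_glm import DegenerateOutcomeError, SurveyDesign, fit_survey_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "MeffSummary",
    "FdrEstimate",
    "effective_tests",
    "combine_effective_tests",
    "bonferroni_adjust",
    "stratified_correlation",
    "bootstrap_null",
    "estimate_fdr",
]


@dataclass
class MeffSummary:
    """Effective number of independent tests for one factor set."""

    label: str
    corr: np.ndarray
    eigenvalues: np.ndarray
    m: int
    m_eff: float


def effective_tests(
    corr, label: str = "", use_abs: bool = False
) -> MeffSummary:
    """Eigenvalue-based effective number of tests for M correlated factors.

    Parameters
    ----------
    corr : symmetric matrix with unit diagonal.
    use_abs : work on absolute correlations (variant); the default keeps
        signed correlations, matching the original estimator.
    """
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if use_abs:
        C = np.abs(C)
    M = C.shape[0]
    lam = np.linalg.eigvalsh(C)
    if M == 1:
        m_eff = 1.0
    else:
        # Var(lambda) with denominator M-1; since trace(C) = M and
        # sum(lambda^2) = ||C||_F^2, the variance has the closed form
        # (||C||_F^2 - M)/(M-1), exact where eigenvalue round-off is not
        var_lam = (float(np.sum(C * C)) - M) / (M - 1)
        m_eff = 1.0 + (M - 1) * (1.0 - var_lam / M)
    m_eff = float(np.clip(m_eff, 1.0, M))
    return MeffSummary(label=label, corr=C, eigenvalues=lam, m=M, m_eff=m_eff)


def combine_effective_tests(
    meff_g: float, meff_e: float, alpha: float = 0.05
) -> dict:
    """Total effective tests for a two-way factor screen and the adjusted
    significance level: total = Meff_G * Meff_E, adjusted = alpha/total."""
    if meff_g < 1 or meff_e < 1:
        raise ValueError("effective test counts must be >= 1")
    total = meff_g * meff_e
    return {"total": total, "adjusted_alpha": alpha / total}


def bonferroni_adjust(p, total: float) -> np.ndarray:
    """Bonferroni-adjusted p-values at the effective test count."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * total)


def _nearest_psd_corr(C: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalization to unit diagonal."""
    lam, V = np.linalg.eigh(C)
    if lam.min() >= -1e-10:
        return C
    lam = np.clip(lam, 1e-10, None)
    A = (V * lam) @ V.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def stratified_correlation(
    X: pd.DataFrame,
    strata,
    min_rows: int = 3,
) -> pd.DataFrame:
    """Pearson correlation computed within each stratum on
    pairwise-complete rows, pooled as the sample-size-weighted average of
    the per-stratum matrices.  Strata with fewer than min_rows complete
    rows contribute nothing (logged).  If pooling breaks positive
    semi-definiteness, the nearest correlation matrix (eigenvalue
    clipping) is returned."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 factors to correlate")
    strata = pd.Series(np.asarray(strata, dtype=object), index=X.index)
    acc = np.zeros((X.shape[1], X.shape[1]))
    wsum = 0.0
    for level in pd.unique(strata):
        sub = X.loc[strata == level]
        n_complete = int(sub.notna().all(axis=1).sum())
        if n_complete < min_rows:
            logger.warning(
                "stratum %s has %d complete rows (<%d); excluded from pooled correlation",
                level, n_complete, min_rows,
            )
            continue
        C = sub.corr(method="pearson", min_periods=min_rows).to_numpy()
        if np.isnan(C).any():
            logger.warning("stratum %s produced undefined correlations; excluded", level)
            continue
        acc += len(sub) * C
        wsum += len(sub)
    if wsum == 0:
        raise ValueError("no stratum had enough complete rows")
    pooled = acc / wsum
    pooled = 0.5 * (pooled + pooled.T)
    np.fill_diagonal(pooled, 1.0)
    pooled = _nearest_psd_corr(pooled)
    return pd.DataFrame(pooled, index=X.columns, columns=X.columns)


def _pair_rng(master_seed: int, snp: str, exposure: str) -> np.random.Generator:
    """Deterministic per-pair substream, stable across execution order."""
    digest = hashlib.blake2s(
        f"{snp}|{exposure}".encode(), digest_size=4
    ).digest()
    pair_key = int.from_bytes(digest, "big")
    return np.random.default_rng([master_seed % (2**31), pair_key])


def bootstrap_null(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    pairs,
    B: int,
    seed: int,
    mode: str = "parametric",
    covariates=("age", "sex", "race", "bmi"),
) -> pd.DataFrame:
    """Null distribution of interaction p-values by parametric bootstrap.

    For each (snp, exposure) pair: fit the no-interaction model on the
    pair's complete-case subsample, then B times regenerate the outcome
    from the fitted null and refit the interaction model, keeping the
    interaction term's p-value.

    mode "parametric" draws replicate outcomes as Bernoulli at each
    row's fitted probability; mode "literal" resamples the fitted
    probabilities themselves with replacement and uses them as the
    dependent values of a quasi-binomial refit.  Replicates whose refit
    fails are dropped and logged; a pair losing more than 10 % of its
    replicates is flagged.

    Returns a tidy frame (snp, exposure, replicate, p, flagged); the p
    column pooled over pairs is the P_null set of size ~ B * #pairs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in {"parametric", "literal"}:
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    records = []
    for snp, exposure in pairs:
        needed = ["outcome", snp, exposure, *covariates]
        mask = _complete_case(cohort, needed).to_numpy()
        sub = cohort.loc[mask]
        sub_design = design.subset(mask)
        if len(sub) == 0:
            logger.warning("pair (%s, %s): empty subsample, skipped", snp, exposure)
            continue
        X0 = build_design_matrix(sub, snp, exposure, interaction=False,
                                 covariates=covariates)
        X1 = build_design_matrix(sub, snp, exposure, interaction=True,
                                 covariates=covariates)
        y = sub["outcome"].to_numpy(dtype=float)
        try:
            null_fit = fit_survey_logistic(X0, y, sub_design)
        except DegenerateOutcomeError:
            logger.warning("pair (%s, %s): degenerate outcome, skipped", snp, exposure)
            continue
        from scipy.special import expit

        p_hat = expit(np.clip(X0.to_numpy(dtype=float) @ null_fit.params, -30, 30))
        rng = _pair_rng(seed, snp, exposure)
        ix = X1.columns.get_loc("g:e")
        pvals = []
        n_dropped = 0
        for b in range(B):
            if mode == "parametric":
                y_star = (rng.random(len(sub)) < p_hat).astype(float)
            else:  # literal: resample fitted dependent values with replacement
                y_star = rng.choice(p_hat, size=len(sub), replace=True)
            try:
                refit = fit_survey_logistic(X1, y_star, sub_design)
            except (DegenerateOutcomeError, np.linalg.LinAlgError):
                n_dropped += 1
                pvals.append(np.nan)
                continue
            if not refit.converged:
                n_dropped += 1
                pvals.append(np.nan)
                continue
            pvals.append(refit.pvalues[ix])
        flagged = n_dropped > 0.10 * B
        if n_dropped:
            logger.warning(
                "pair (%s, %s): %d/%d bootstrap replicates dropped%s",
                snp, exposure, n_dropped, B, " (pair flagged)" if flagged else "",
            )
        for b, p in enumerate(pvals):
            if np.isfinite(p):
                records.append(
                    {"snp": snp, "exposure": exposure, "replicate": b,
                     "p": p, "flagged": flagged}
                )
    return pd.DataFrame(records)


@dataclass
class FdrEstimate:
    """Bootstrap FDR of the interaction screen at requested thresholds
    and at every observed p-value."""

    p_real: np.ndarray
    p_null: np.ndarray
    B: int
    at_threshold: dict  # t -> fdr(t), NaN when no observed p < t
    at_observed: pd.DataFrame = field(default=None)  # per observed p

    def fdr(self, t: float) -> float:
        n_pos = int(np.sum(self.p_real < t))
        if n_pos == 0:
            return np.nan
        return (np.sum(self.p_null < t) / self.B) / n_pos


def estimate_fdr(
    p_real,
    p_null,
    B: int,
    thresholds=(0.05,),
) -> FdrEstimate:
    """fdr(t) = (#{P_null < t}/B) / #{P_real < t}.

    Values above 1 are reported as-is (interpretable as 'everything at
    this threshold is consistent with the null'); zero observed positives
    give an undefined (NaN) estimate.  Also evaluates the estimator at
    each observed p, i.e. t set to that p-value's own magnitude plus an
    infinitesimal so the point itself counts as a positive.
    """
    p_real = np.asarray(p_real, dtype=float)
    p_null = np.asarray(p_null, dtype=float)
    if p_real.size == 0:
        raise ValueError("P_real is empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    est = FdrEstimate(p_real=p_real, p_null=p_null, B=B, at_threshold={})
    for t in thresholds:
        est.at_threshold[t] = est.fdr(t)

    order = np.argsort(p_real)
    rows = []
    for rank, idx in enumerate(order, start=1):
        p = p_real[idx]
        n_null = int(np.sum(p_null <= p))
        rows.append(
            {"p": p, "rank": rank, "fdr_at_p": (n_null / B) / rank,
             "capped": (n_null / B) / rank > 1.0}
        )
    est.at_observed = pd.DataFrame(rows)
    return est
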