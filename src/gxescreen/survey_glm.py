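"""Design-based generalized linear models for complex survey data.

Implements probability-weighted logistic (and linear) regression with
Taylor-linearized variance estimation: point estimates solve the weighted
score equations, and the covariance is a sandwich estimator built from
between-PSU variation of score totals within strata, under the standard
with-replacement approximation for the first sampling stage.  Inference
uses a t reference distribution with design degrees of freedom
(number of PSUs minus number of strata), matching the behaviour of
mainstream survey software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "SurveyDesign",
    "FitResult",
    "fit_survey_logistic",
    "fit_survey_linear",
    "fit_logistic",
    "wald_contrast",
    "ConvergenceError",
    "DegenerateOutcomeError",
]

MAX_ETA = 30.0  # linear predictor clamp; expit saturates well before this


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class DegenerateOutcomeError(ValueError):
    """Outcome has a single class; a logistic model cannot be fitted."""


@dataclass(frozen=True)
class SurveyDesign:
    """Per-row survey design: stratum, primary sampling unit, weight.

    PSUs are nested in strata; the pair (stratum, psu) identifies a
    first-stage cluster.  Weights must be strictly positive and finite.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        strata = np.asarray(self.strata)
        psu = np.asarray(self.psu)
        w = np.asarray(self.weights, dtype=float)
        if not (len(strata) == len(psu) == len(w)):
            raise ValueError("design columns must have equal length")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            bad = np.flatnonzero(~np.isfinite(w) | (w <= 0))
            raise ValueError(
                f"weights must be positive and finite; offending rows: {bad[:10].tolist()}"
            )
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "psu", psu)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.strata[mask], self.psu[mask], self.weights[mask])

    @property
    def n_strata(self) -> int:
        return len(pd.unique(self.strata))

    @property
    def n_psu(self) -> int:
        # count distinct (stratum, psu) pairs
        key = pd.MultiIndex.from_arrays([self.strata, self.psu])
        return len(key.unique())

    @property
    def df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psu - self.n_strata

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        stratum: str = "stratum",
        psu: str = "psu",
        weight: str = "weight",
    ) -> "SurveyDesign":
        return cls(
            frame[stratum].to_numpy(),
            frame[psu].to_numpy(),
            frame[weight].to_numpy(dtype=float),
        )


@dataclass
class FitResult:
    """One fitted survey GLM: coefficients, design-based covariance, Wald tests."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    df: int
    n: int
    n_cases: int
    n_controls: int
    converged: bool
    n_iter: int
    separation: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([_wald_p(t, self.df) for t in self.tvalues])

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "estimate": self.params[i],
            "se": self.bse[i],
            "t": self.tvalues[i],
            "p": self.pvalues[i],
        }

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = _t_quantile(1 - alpha / 2, self.df)
        se = self.bse
        return np.column_stack([self.params - q * se, self.params + q * se])

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "params": self.params.tolist(),
            "se": self.bse.tolist(),
            "pvalues": self.pvalues.tolist(),
            "df": self.df,
            "n": self.n,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "converged": self.converged,
            "separation": self.separation,
        }


def _t_quantile(q: float, df: int) -> float:
    if df >= 1:
        return float(stats.t.ppf(q, df))
    return float(stats.norm.ppf(q))


def _wald_p(t: float, df: int) -> float:
    if not np.isfinite(t):
        return np.nan
    if df >= 1:
        return float(2.0 * stats.t.sf(abs(t), df))
    return float(2.0 * stats.norm.sf(abs(t)))


def _irls_logistic(X, y, w, tol=1e-8, max_iter=50):
    """Weighted logistic IRLS.  Accepts fractional y in [0, 1].

    Returns (beta, info, mu, converged, n_iter).  Convergence is on the
    score norm relative to the total weight.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
    beta[0] = special.logit(ybar) if np.allclose(X[:, 0], 1.0) else 0.0
    scale = max(1.0, float(np.sqrt(np.sum(w))))
    converged = False
    info = None
    mu = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -MAX_ETA, MAX_ETA)
        mu = special.expit(eta)
        s = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = (X * s[:, None]).T @ X
        if np.linalg.norm(score) <= tol * scale:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving if the penalized update overshoots
        new = beta + step
        ll_old = _wllik(X, y, w, beta)
        for _ in range(8):
            if _wllik(X, y, w, new) >= ll_old - 1e-12:
                break
            step *= 0.5
            new = beta + step
        beta = new
    return beta, info, mu, converged, it


def _wllik(X, y, w, beta):
    eta = np.clip(X @ beta, -MAX_ETA, MAX_ETA)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _taylor_cov(X, resid_scores, design: SurveyDesign, bread_inv: np.ndarray):
    """Sandwich covariance from between-PSU score totals within strata.

    resid_scores: per-row score contributions u_i = w_i * (y_i - mu_i) * x_i.
    Singleton-PSU strata contribute deviations from the grand mean of all
    PSU totals (the 'centered at grand mean' convention).
    """
    p = X.shape[1]
    key = pd.MultiIndex.from_arrays([design.strata, design.psu])
    df_scores = pd.DataFrame(resid_scores, index=key)
    psu_totals = df_scores.groupby(level=[0, 1], sort=False).sum()
    strata_of_psu = psu_totals.index.get_level_values(0)
    totals = psu_totals.to_numpy()
    grand_mean = totals.mean(axis=0)

    G = np.zeros((p, p))
    for h in pd.unique(strata_of_psu):
        Z = totals[strata_of_psu == h]
        n_h = Z.shape[0]
        if n_h >= 2:
            Zc = Z - Z.mean(axis=0)
            G += (n_h / (n_h - 1)) * (Zc.T @ Zc)
        else:
            zc = (Z[0] - grand_mean)[:, None]
            G += zc @ zc.T
    cov = bread_inv @ G @ bread_inv
    return 0.5 * (cov + cov.T)  # enforce symmetry


def _prepare(X, y, design):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != len(yv) or len(yv) != len(design):
        raise ValueError("X, y and design must align row-wise")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("X and y must be complete (drop missing rows first)")
    return Xm, yv, names


def fit_survey_logistic(
    X,
    y,
    design: SurveyDesign,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FitResult:
    """Survey-weighted logistic regression with Taylor-linearized covariance.

    Parameters
    ----------
    X : DataFrame or 2-D array
        Design matrix including the intercept column.
    y : 1-D binary array (fractional values in [0,1] are accepted, which
        supports quasi-likelihood refits on resampled fitted values).
    design : SurveyDesign aligned with the rows of X.
    """
    Xm, yv, names = _prepare(X, y, design)
    if yv.min() < 0 or yv.max() > 1:
        raise ValueError("outcome values must lie in [0, 1]")
    is_binary = np.all((yv == 0) | (yv == 1))
    if is_binary and (yv.min() == yv.max()):
        raise DegenerateOutcomeError(
            "outcome is constant; both classes must be present"
        )

    beta, info, mu, converged, n_iter = _irls_logistic(Xm, yv, design.weights, tol, max_iter)
    try:
        bread_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bread_inv = np.linalg.pinv(info)
    u = Xm * (design.weights * (yv - mu))[:, None]
    cov = _taylor_cov(Xm, u, design, bread_inv)

    eta = Xm @ beta
    separation = bool(np.max(np.abs(eta)) >= MAX_ETA - 1e-6)
    flags = []
    if not converged:
        flags.append("non-converged")
    if separation:
        flags.append("separation")
    n_cases = int(np.sum(yv == 1)) if is_binary else int(round(float(np.sum(yv))))
    return FitResult(
        names=names,
        params=beta,
        cov=cov,
        df=design.df,
        n=len(yv),
        n_cases=n_cases,
        n_controls=len(yv) - n_cases,
        converged=converged,
        n_iter=n_iter,
        separation=separation,
        flags=flags,
    )


def fit_survey_linear(X, y, design: SurveyDesign) -> FitResult:
    """Survey-weighted least squares with Taylor-linearized covariance."""
    Xm, yv, names = _prepare(X, y, design)
    w = design.weights
    info = (Xm * w[:, None]).T @ Xm
    rhs = Xm.T @ (w * yv)
    try:
        beta = np.linalg.solve(info, rhs)
        bread_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(info, rhs, rcond=None)[0]
        bread_inv = np.linalg.pinv(info)
    resid = yv - Xm @ beta
    u = Xm * (w * resid)[:, None]
    cov = _taylor_cov(Xm, u, design, bread_inv)
    return FitResult(
        names=names,
        params=beta,
        cov=cov,
        df=design.df,
        n=len(yv),
        n_cases=0,
        n_controls=0,
        converged=True,
        n_iter=1,
    )


def fit_logistic(X, y, tol: float = 1e-8, max_iter: int = 50):
    """Unweighted logistic MLE with model-based (inverse-information)
    covariance and a normal reference.  Used by the power simulator, where
    simple random sampling is assumed.

    Returns (beta, cov, pvalues, converged).
    """
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if yv.min() == yv.max():
        raise DegenerateOutcomeError("outcome is constant")
    w = np.ones(len(yv))
    beta, info, _, converged, _ = _irls_logistic(Xm, yv, w, tol, max_iter)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, cov, p, converged


def wald_contrast(fit: FitResult, c, alpha: float = 0.05) -> dict:
    """Estimate, SE, CI and p-value for the linear combination c'beta.

    The CI is on the linear-predictor (log-odds) scale; callers exponentiate
    for odds ratios.  A zero contrast returns estimate 0, SE 0 and an
    undefined (NaN) p-value.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (len(fit.params),):
        raise ValueError(
            f"contrast length {c.shape} does not match {len(fit.params)} coefficients"
        )
    est = float(c @ fit.params)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        return {"estimate": est, "se": 0.0, "ci": (est, est), "p": np.nan}
    t = est / se
    q = _t_quantile(1 - alpha / 2, fit.df)
    return {
        "estimate": est,
        "se": se,
        "ci": (est - q * se, est + q * se),
        "p": _wald_p(t, fit.df),
    }
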