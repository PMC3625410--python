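"""Synthetic survey-structured cohorts with known G, E and GxE effects.

The generator emulates the statistical structure of a pooled national
health-examination survey: a stratified, clustered, probability-weighted
sample of participants with self-reported ancestry in five groups, 18
risk-allele-coded SNP dosages drawn under Hardy-Weinberg proportions at
ancestry-specific allele frequencies, five log-normal serum exposure
biomarkers with a specified log-scale correlation matrix (including one
near-duplicate pair at rho = 0.96), demographic covariates, and a binary
disease outcome drawn from a logistic model whose intercept is calibrated
so the case fraction lands on a 9-10 % target.

Every cohort carries its generating specification, so downstream stages
can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .survey_glm import SurveyDesign

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "apply_missingness",
    "study_spec",
    "STUDY_EXPOSURES",
    "STUDY_EXPOSURE_CORR",
]

RACE_LEVELS = ["mexican_american", "other_hispanic", "nh_white", "nh_black", "other"]

# The five serum biomarkers the screen targets, with plausible log10
# concentration scales (means/SDs on the log10 scale).  cis- and
# trans-beta-carotene are near-duplicates (rho = 0.96); the two
# organochlorine pollutants are moderately correlated; the carotenes run
# weakly negative against gamma-tocopherol.
STUDY_EXPOSURES = [
    ("trans_b_carotene", 1.2, 0.35),
    ("cis_b_carotene", 0.4, 0.33),
    ("g_tocopherol", 2.3, 0.25),
    ("heptachlor_epoxide", -0.9, 0.30),
    ("pcb170", -1.1, 0.28),
]

STUDY_EXPOSURE_CORR = np.array(
    [
        [1.00, 0.96, -0.20, 0.05, 0.05],
        [0.96, 1.00, -0.20, 0.05, 0.05],
        [-0.20, -0.20, 1.00, 0.15, 0.20],
        [0.05, 0.05, 0.15, 1.00, 0.34],
        [0.05, 0.05, 0.20, 0.34, 1.00],
    ]
)

# 18 diabetes-associated loci; risk-allele frequencies per ancestry group
# (mexican_american, other_hispanic, nh_white, nh_black, other).  Values
# span the 5-95 % range seen for common GWAS loci, with one locus nearly
# fixed (97 %) in one group to exercise the low-MAF edge of the QC.
STUDY_SNPS = [
    ("snp01", (0.28, 0.30, 0.26, 0.10, 0.25)),
    ("snp02", (0.32, 0.31, 0.30, 0.28, 0.33)),
    ("snp03", (0.25, 0.28, 0.30, 0.35, 0.27)),
    ("snp04", (0.70, 0.68, 0.65, 0.60, 0.66)),
    ("snp05", (0.45, 0.44, 0.40, 0.50, 0.42)),
    ("snp06", (0.85, 0.84, 0.80, 0.97, 0.83)),
    ("snp07", (0.20, 0.22, 0.18, 0.25, 0.21)),
    ("snp08", (0.55, 0.54, 0.52, 0.48, 0.53)),
    ("snp09", (0.38, 0.36, 0.35, 0.30, 0.34)),
    ("snp10", (0.62, 0.60, 0.58, 0.65, 0.61)),
    ("snp11", (0.15, 0.17, 0.12, 0.20, 0.14)),
    ("snp12", (0.48, 0.47, 0.45, 0.40, 0.46)),
    ("snp13", (0.33, 0.35, 0.36, 0.42, 0.34)),
    ("snp14", (0.75, 0.73, 0.72, 0.68, 0.71)),
    ("snp15", (0.27, 0.26, 0.24, 0.30, 0.25)),
    ("snp16", (0.52, 0.50, 0.49, 0.55, 0.51)),
    ("snp17", (0.42, 0.40, 0.38, 0.44, 0.41)),
    ("snp18", (0.08, 0.09, 0.07, 0.12, 0.08)),
]

# Oversampled-minority proportions typical of the survey design emulated.
STUDY_ANCESTRY = [
    ("mexican_american", 0.25),
    ("other_hispanic", 0.05),
    ("nh_white", 0.42),
    ("nh_black", 0.22),
    ("other", 0.06),
]


@dataclass
class CovariateModel:
    """Age / sex / BMI generation parameters and their outcome log-ORs."""

    age_mean: float = 45.0
    age_sd: float = 16.0
    age_range: tuple = (20.0, 85.0)
    prop_female: float = 0.52
    bmi_mean: float = 27.5
    bmi_sd: float = 5.5
    bmi_range: tuple = (15.0, 60.0)
    beta_age: float = 0.06  # per year
    beta_female: float = -0.35
    beta_bmi: float = 0.09  # per kg/m^2


@dataclass
class SyntheticSpec:
    """Full generating specification for one synthetic cohort."""

    n_participants: int = 6000
    n_strata: int = 14
    psus_per_stratum: int = 2
    weight_model: str = "lognormal"  # "uniform" or "lognormal"
    weight_sigma: float = 0.5
    weight_stratum_coupling: float = 0.0  # >0 couples weight scale to stratum
    ancestry_groups: list = field(default_factory=lambda: list(STUDY_ANCESTRY))
    snps: list = field(default_factory=lambda: list(STUDY_SNPS))
    exposures: list = field(default_factory=lambda: list(STUDY_EXPOSURES))
    exposure_corr: np.ndarray = field(
        default_factory=lambda: STUDY_EXPOSURE_CORR.copy()
    )
    intercept: float | None = None  # None -> calibrated to target_case_fraction
    beta_g: dict = field(default_factory=dict)  # snp id -> per-allele log-OR
    beta_e: dict = field(default_factory=dict)  # exposure id -> per-SD log-OR
    beta_gxe: dict = field(default_factory=dict)  # (snp, exposure) -> log-OR
    target_case_fraction: float = 0.095
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    missingness: dict = field(default_factory=dict)  # column -> proportion
    seed: int = 0

    def __post_init__(self):
        self.exposure_corr = np.asarray(self.exposure_corr, dtype=float)
        self.validate()

    def validate(self):
        m = len(self.exposures)
        C = self.exposure_corr
        if C.shape != (m, m):
            raise ValueError(f"exposure_corr must be {m}x{m}, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("exposure_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("exposure_corr must have unit diagonal")
        lo = float(np.linalg.eigvalsh(C)[0])
        if lo < -1e-8:
            raise ValueError(
                f"exposure_corr is not positive semi-definite (min eigenvalue {lo:.3e})"
            )
        for sid, freqs in self.snps:
            for f in freqs:
                if not 0.0 < f < 1.0:
                    raise ValueError(f"allele frequency for {sid} must be in (0,1), got {f}")
        props = [p for _, p in self.ancestry_groups]
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError("ancestry proportions must sum to 1")
        if not 0.0 < self.target_case_fraction < 1.0:
            raise ValueError("target_case_fraction must be in (0,1)")
        for col, p in self.missingness.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"missingness for {col} must be in [0,1), got {p}")

    @property
    def snp_ids(self) -> list[str]:
        return [sid for sid, _ in self.snps]

    @property
    def exposure_ids(self) -> list[str]:
        return [eid for eid, _, _ in self.exposures]

    def to_json(self) -> str:
        d = asdict(self)
        d["exposure_corr"] = self.exposure_corr.tolist()
        d["beta_gxe"] = {f"{g}|{e}": v for (g, e), v in self.beta_gxe.items()}
        return json.dumps(d, indent=2)


@dataclass
class SyntheticCohort:
    """A generated cohort, its survey design, and the truth that made it."""

    cohort: pd.DataFrame
    design: SurveyDesign
    truth: SyntheticSpec

    def write(self, table_path, truth_path=None, sep="\t"):
        """Write the cohort table plus a JSON sidecar of the truth spec."""
        self.cohort.to_csv(table_path, sep=sep, index=False)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                fh.write(self.truth.to_json())


def _calibrate_intercept(eta0: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection for the intercept giving E[expit(a + eta0)] = target.

    The expectation is over the supplied draw of the non-intercept linear
    predictor; the map a -> mean prob is strictly increasing, so bisection
    on [-40, 40] always brackets any target in (0, 1).
    """
    from scipy.special import expit

    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + eta0))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"case fraction {target} unreachable for this specification")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-2:
            break
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw one cohort under the specification.

    Genotypes are Binomial(2, RAF) within ancestry group (Hardy-Weinberg
    proportions); exposures are multivariate normal on the log10 scale,
    then exponentiated to concentrations; the outcome is Bernoulli from
    the logistic model.  A fixed seed makes the output bit-for-bit
    reproducible.
    """
    from scipy.special import expit

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    # --- survey design ------------------------------------------------
    stratum = rng.integers(0, spec.n_strata, size=n)
    psu = rng.integers(0, spec.psus_per_stratum, size=n)
    if spec.weight_model == "uniform":
        weight = np.ones(n)
    elif spec.weight_model == "lognormal":
        weight = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=n)
    else:
        raise ValueError(f"unknown weight model {spec.weight_model!r}")
    if spec.weight_stratum_coupling > 0:
        # informative-design option: weight scale varies by stratum
        factors = np.exp(
            spec.weight_stratum_coupling * rng.standard_normal(spec.n_strata)
        )
        weight = weight * factors[stratum]

    # --- ancestry and genotypes ---------------------------------------
    labels = [g for g, _ in spec.ancestry_groups]
    props = np.array([p for _, p in spec.ancestry_groups])
    race_idx = rng.choice(len(labels), size=n, p=props)
    race = np.array(labels, dtype=object)[race_idx]

    geno = {}
    for sid, freqs in spec.snps:
        raf = np.asarray(freqs, dtype=float)[race_idx]
        geno[sid] = rng.binomial(2, raf).astype(float)

    # --- exposures (log10-scale MVN, then back-transform) -------------
    m = len(spec.exposures)
    L = np.linalg.cholesky(spec.exposure_corr + 1e-12 * np.eye(m))
    z = rng.standard_normal((n, m)) @ L.T  # standardized log10 deviates
    expo = {}
    for j, (eid, mu10, sd10) in enumerate(spec.exposures):
        expo[eid] = 10.0 ** (mu10 + sd10 * z[:, j])

    # --- covariates -----------------------------------------------------
    cm = spec.covariate_model
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, size=n), *cm.age_range)
    female = rng.random(n) < cm.prop_female
    bmi = np.clip(rng.normal(cm.bmi_mean, cm.bmi_sd, size=n), *cm.bmi_range)

    # --- linear predictor (intercept excluded) -------------------------
    eta0 = np.zeros(n)
    eta0 += cm.beta_age * (age - cm.age_mean)
    eta0 += cm.beta_female * female
    eta0 += cm.beta_bmi * (bmi - cm.bmi_mean)
    for sid, b in spec.beta_g.items():
        eta0 += b * geno[sid]
    eidx = {eid: j for j, eid in enumerate(spec.exposure_ids)}
    for eid, b in spec.beta_e.items():
        eta0 += b * z[:, eidx[eid]]
    for (sid, eid), b in spec.beta_gxe.items():
        eta0 += b * geno[sid] * z[:, eidx[eid]]

    if spec.intercept is None:
        alpha = _calibrate_intercept(eta0, spec.target_case_fraction)
    else:
        alpha = spec.intercept
    prob = expit(alpha + eta0)
    outcome = (rng.random(n) < prob).astype(float)

    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "outcome": outcome,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "race": race,
            "bmi": bmi,
            "stratum": stratum,
            "psu": psu,
            "weight": weight,
        }
    )
    for eid in spec.exposure_ids:
        frame[eid] = expo[eid]
    for sid in spec.snp_ids:
        frame[sid] = geno[sid]

    cohort = SyntheticCohort(
        cohort=frame,
        design=SurveyDesign(stratum, psu, weight),
        truth=spec,
    )
    if spec.missingness:
        cohort = apply_missingness(cohort, spec.missingness, seed=spec.seed + 1)
    return cohort


def apply_missingness(
    cohort: SyntheticCohort, pattern: dict, seed: int
) -> SyntheticCohort:
    """Knock out values completely at random, column by column.

    Different per-column proportions give each (SNP, exposure) pair its
    own complete-case subsample size, reproducing the unequal-subsample
    structure of assay panels that cover different survey participants.
    """
    for col, p in pattern.items():
        if not 0.0 <= p < 1.0:
            raise ValueError(f"missing proportion for {col} must be in [0,1), got {p}")
        if col not in cohort.cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    rng = np.random.default_rng(seed)
    frame = cohort.cohort.copy()
    for col, p in pattern.items():
        if p > 0:
            mask = rng.random(len(frame)) < p
            frame.loc[mask, col] = np.nan
    return SyntheticCohort(cohort=frame, design=cohort.design, truth=cohort.truth)


def study_spec(
    n_participants: int = 6000,
    seed: int = 0,
    beta_gxe: dict | None = None,
    with_missingness: bool = True,
    **overrides,
) -> SyntheticSpec:
    """Specification emulating the pooled two-cycle survey analysis:
    18 SNPs, 5 exposure biomarkers (one pair at rho = 0.96), five ancestry
    groups, ~9.5 % cases, and per-assay missingness that makes pair
    subsamples unequal.

    Main effects default to the marginal pattern the screen targets:
    near-null genetics (per-allele OR about 1.0-1.1) and per-SD exposure
    ORs spanning protective (0.6, the carotenes) to adverse (1.5-1.7,
    tocopherol and the pollutants).
    """
    beta_g = {sid: np.log(1.05) for sid, _ in STUDY_SNPS}
    beta_g["snp02"] = np.log(1.15)  # the few nominally associated loci
    beta_g["snp08"] = np.log(1.10)
    beta_e = {
        "trans_b_carotene": np.log(0.6),
        "cis_b_carotene": np.log(0.6),
        "g_tocopherol": np.log(1.5),
        "heptachlor_epoxide": np.log(1.5),
        "pcb170": np.log(1.7),
    }
    missingness = {}
    if with_missingness:
        missingness = {
            "trans_b_carotene": 0.30,
            "cis_b_carotene": 0.30,
            "g_tocopherol": 0.25,
            "heptachlor_epoxide": 0.60,
            "pcb170": 0.60,
        }
        missingness.update({sid: 0.12 for sid, _ in STUDY_SNPS})
    return SyntheticSpec(
        n_participants=n_participants,
        beta_g=beta_g,
        beta_e=beta_e,
        beta_gxe=dict(beta_gxe or {}),
        missingness=missingness,
        seed=seed,
        **overrides,
    )
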