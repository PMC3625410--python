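"""Cohort input, variable coding and genetic QC.

Covers the data-preparation conventions of the screen: cases defined by
fasting blood glucose >= 126 mg/dL, SNPs coded as risk-allele dosage
(0/1/2) with the risk allele taken from the literature map rather than
the VCF REF/ALT orientation, exposures log10-transformed and expressed
in standard-deviation units, and per-ancestry allele frequencies plus a
chi-square Hardy-Weinberg equilibrium check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSchema",
    "RiskAlleleMap",
    "ExposurePanel",
    "read_cohort",
    "read_risk_allele_map",
    "code_genotypes_from_vcf",
    "define_cases",
    "transform_exposures",
    "allele_frequency",
    "hwe_test",
]

FBG_CASE_THRESHOLD = 126.0  # mg/dL, fasting blood glucose case cutoff


@dataclass
class CohortSchema:
    """Column-name mapping from an input table onto the analysis frame."""

    outcome: str | None = "outcome"
    fbg: str | None = None
    participant_id: str = "participant_id"
    age: str = "age"
    sex: str = "sex"
    race: str = "race"
    bmi: str = "bmi"
    stratum: str = "stratum"
    psu: str = "psu"
    weight: str = "weight"
    exposures: list = field(default_factory=list)
    snps: list = field(default_factory=list)

    @property
    def design_columns(self) -> list[str]:
        return [self.stratum, self.psu, self.weight]


@dataclass
class RiskAlleleMap:
    """snp id -> (risk allele base, source citation)."""

    entries: dict

    def __post_init__(self):
        for sid, (allele, _src) in self.entries.items():
            if allele not in {"A", "C", "G", "T"}:
                raise ValueError(f"risk allele for {sid} must be A/C/G/T, got {allele!r}")

    def risk_allele(self, sid: str) -> str:
        return self.entries[sid][0]

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries


@dataclass
class ExposurePanel:
    """Which exposure columns to use, their transform, and the moments
    actually applied (recorded after transform_exposures runs)."""

    columns: list
    transform: str = "log10"  # "log10" or "raw"
    weighted_moments: bool = False
    moments: dict = field(default_factory=dict)  # column -> (mean, sd)


def read_cohort(path, schema: CohortSchema, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited cohort table and validate it against the schema.

    Missing values are empty cells or 'NA'.  Unparseable numeric cells
    become missing with a logged count.  Missing design columns or
    duplicated participant ids are fatal, as is any non-positive weight.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype=str)

    required = [schema.participant_id] + schema.design_columns
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"required columns absent from {path}: {missing_cols}")

    dup = raw[schema.participant_id].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicated participant ids: {raw.loc[dup, schema.participant_id].tolist()[:5]}"
        )

    out = pd.DataFrame({"participant_id": raw[schema.participant_id]})
    numeric_cols = (
        [schema.weight, schema.age, schema.bmi]
        + ([schema.outcome] if schema.outcome and schema.outcome in raw.columns else [])
        + ([schema.fbg] if schema.fbg and schema.fbg in raw.columns else [])
        + list(schema.exposures)
        + list(schema.snps)
    )
    rename = {
        schema.age: "age",
        schema.bmi: "bmi",
        schema.weight: "weight",
        schema.outcome: "outcome",
        schema.fbg: "fbg",
    }
    for col in numeric_cols:
        if col is None or col not in raw.columns:
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        n_bad = int((vals.isna() & raw[col].notna()).sum())
        if n_bad:
            logger.warning("column %s: %d unparseable cells set missing", col, n_bad)
        out[rename.get(col, col)] = vals
    for col, name in [(schema.sex, "sex"), (schema.race, "race"),
                      (schema.stratum, "stratum"), (schema.psu, "psu")]:
        if col in raw.columns:
            out[name] = raw[col]

    w = out["weight"]
    bad_w = w.isna() | (w <= 0)
    if bad_w.any():
        rows = out.loc[bad_w, "participant_id"].tolist()[:5]
        raise ValueError(f"non-positive or missing weights for participants {rows}")

    for sid in schema.snps:
        if sid in out.columns:
            d = out[sid]
            bad = d.notna() & ~d.isin([0, 1, 2])
            if bad.any():
                raise ValueError(f"dosages for {sid} must be 0/1/2 or missing")
    return out


def read_risk_allele_map(path) -> RiskAlleleMap:
    """Two- or three-column TSV: snp id, risk allele[, citation]."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    entries = {}
    for _, row in tab.iterrows():
        sid, allele = row[0], row[1]
        src = row[2] if tab.shape[1] > 2 and pd.notna(row.get(2)) else ""
        entries[sid] = (allele, src)
    return RiskAlleleMap(entries)


def code_genotypes_from_vcf(vcf_path, risk_map: RiskAlleleMap, snp_ids=None) -> pd.DataFrame:
    """Risk-allele dosages (0/1/2) per sample from a biallelic VCF.

    The dosage counts copies of the mapped risk allele, which may be
    either REF or ALT — coding follows the literature designation, not
    the VCF orientation.  Sites are matched by ID first, then by
    chrom:pos (1-based).  A requested site absent from the VCF yields an
    all-missing column with a warning; a mapped allele that is neither
    REF nor ALT at its site is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    wanted = set(snp_ids) if snp_ids is not None else set(risk_map.entries)
    columns: dict[str, np.ndarray] = {}

    for variant in vcf:
        sid = variant.ID
        if sid not in wanted:
            sid = f"{variant.CHROM}:{variant.POS}"
            if sid not in wanted:
                continue
        if len(variant.ALT) != 1:
            raise ValueError(f"site {sid} is not biallelic")
        risk = risk_map.risk_allele(sid)
        ref, alt = variant.REF, variant.ALT[0]
        if risk == alt:
            flip = False
        elif risk == ref:
            flip = True
        else:
            raise ValueError(
                f"risk allele {risk} for {sid} is neither REF ({ref}) nor ALT ({alt})"
            )
        # gt_types: 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=UNKNOWN
        gt = variant.gt_types.astype(float)
        alt_dosage = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        columns[sid] = 2.0 - alt_dosage if flip else alt_dosage
    vcf.close()

    for sid in wanted - set(columns):
        logger.warning("site %s absent from VCF; dosage column all-missing", sid)
        columns[sid] = np.full(len(samples), np.nan)
    return pd.DataFrame(columns, index=pd.Index(samples, name="sample"))


def define_cases(fbg: pd.Series | np.ndarray) -> pd.Series:
    """Binary case status from fasting blood glucose: 1 iff FBG >= 126 mg/dL.

    Missing FBG gives missing outcome (the participant is excluded from
    every model); negative FBG is fatal.
    """
    fbg = pd.Series(fbg, dtype=float)
    if (fbg.dropna() < 0).any():
        raise ValueError("negative fasting blood glucose values present")
    out = (fbg >= FBG_CASE_THRESHOLD).astype(float)
    out[fbg.isna()] = np.nan
    return out


def transform_exposures(
    cohort: pd.DataFrame,
    panel: ExposurePanel,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Transform and standardize exposure columns in place (on a copy).

    Each column becomes (f(x) - mean) / sd with f = log10 or identity per
    the panel's transform flag.  Moments are computed on the non-missing
    entries of the analysis sample (unweighted by default; survey-weighted
    if the panel requests it) and recorded in panel.moments.
    """
    out = cohort.copy()
    for col in panel.columns:
        x = out[col].astype(float)
        obs = x.notna()
        if panel.transform == "log10":
            n_bad = int((x[obs] <= 0).sum())
            if n_bad:
                raise ValueError(
                    f"{col}: {n_bad} non-positive values; log10 transform impossible"
                )
            vals = np.log10(x[obs])
        elif panel.transform == "raw":
            vals = x[obs]
        else:
            raise ValueError(f"unknown transform {panel.transform!r}")
        if panel.weighted_moments:
            if weights is None:
                raise ValueError("weighted moments requested but no weights supplied")
            w = np.asarray(weights, dtype=float)[obs.to_numpy()]
            mean = float(np.average(vals, weights=w))
            sd = float(np.sqrt(np.average((vals - mean) ** 2, weights=w)))
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"{col}: zero or undefined variance; cannot standardize")
        panel.moments[col] = (mean, sd)
        z = pd.Series(np.nan, index=out.index)
        z[obs] = (vals - mean) / sd
        out[col] = z
    return out


def allele_frequency(
    dosages: pd.Series | np.ndarray, groups: pd.Series | np.ndarray | None = None
) -> pd.Series:
    """Risk-allele frequency = sum(dosage) / (2 * non-missing n), per group.

    With no grouping, returns a single-entry Series labelled 'all'.  A
    group with no non-missing dosages gets a missing frequency.
    """
    d = pd.Series(dosages, dtype=float).reset_index(drop=True)
    bad = d.dropna()[~d.dropna().isin([0, 1, 2])]
    if len(bad):
        raise ValueError("dosages must be 0/1/2 or missing")
    if groups is None:
        groups = pd.Series("all", index=d.index)
    else:
        groups = pd.Series(np.asarray(groups, dtype=object), index=d.index)

    def _freq(sub):
        obs = sub.dropna()
        if len(obs) == 0:
            return np.nan
        return obs.sum() / (2.0 * len(obs))

    return d.groupby(groups).apply(_freq)


def hwe_test(n0: int, n1: int, n2: int, method: str = "chisq") -> tuple[float, float]:
    """Hardy-Weinberg equilibrium test from genotype counts.

    Observed counts (n0, n1, n2) for dosages 0/1/2 are compared with
    p^2 / 2pq / q^2 expectations at the estimated allele frequency.  The
    default is the 1-df Pearson chi-square without continuity
    correction; method="exact" gives the conditional exact test (sum of
    heterozygote-count probabilities no larger than the observed one),
    preferable at low minor-allele counts.  A monomorphic sample has no
    HWE departure to measure and returns (0.0, 1.0) by convention.

    Returns (statistic, p); for the exact test the statistic slot holds
    the observed heterozygote count.
    """
    counts = np.array([n0, n1, n2], dtype=float)
    if counts.min() < 0 or counts.sum() < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = counts.sum()
    q = (counts[1] + 2 * counts[2]) / (2 * n)  # dosage-allele frequency
    if q == 0.0 or q == 1.0:
        logger.info("monomorphic sample in HWE test; p = 1 by convention")
        return 0.0, 1.0
    if method == "exact":
        return float(n1), _hwe_exact_p(int(n0), int(n1), int(n2))
    if method != "chisq":
        raise ValueError(f"unknown HWE method {method!r}")
    p = 1.0 - q
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p: P(heterozygote count as or less probable than observed),
    conditional on the allele counts.  Log-space closed form, so it is
    stable for any sample size."""
    from scipy.special import gammaln

    n = n0 + n1 + n2
    rare = min(n1 + 2 * n0, n1 + 2 * n2)

    def logprob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1) - gammaln(h + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
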