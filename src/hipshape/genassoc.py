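"""SNP quality control and additive association testing for mode scores.

QC keeps a SNP iff minor-allele frequency >= 1%, call rate >= 95% and the
Hardy–Weinberg conditional exact test gives p > 5e-7 (all thresholds
configurable).  Association is ordinary least squares of a mode score on
(intercept, effect-allele dosage, covariates), with a two-sided Wald t test
on the dosage coefficient; betas are in reference-SD units per effect allele.

Three covariate-adjustment models are predefined:

* ``model1`` — age, sex
* ``model2`` — age, sex, height
* ``model3`` — age, sex, BMI
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landmark_io import CovariateTable, GenotypeDosageTable
from .ssm import ModeScores

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "AssociationResult",
    "AssociationTable",
    "qc_filter",
    "hwe_exact_test",
    "fit_snp_mode",
    "run_associations",
    "bonferroni_threshold",
    "display_threshold",
    "build_association_table",
    "count_significant",
    "load_reference_associations",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate-adjustment set."""

    label: str
    covariates: tuple[str, ...]


MODEL_SPECS: dict[str, ModelSpec] = {
    "model1": ModelSpec("model1", ("age", "sex")),
    "model2": ModelSpec("model2", ("age", "sex", "height")),
    "model3": ModelSpec("model3", ("age", "sex", "bmi")),
}


@dataclass(frozen=True)
class AssociationResult:
    """One SNP x mode x model fit."""

    snp_id: str
    hsm: int
    model: str
    beta: float
    se: float
    p: float
    n: int
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact test of Hardy–Weinberg proportions.

    Given genotype counts, condition on the observed allele counts and sum
    the null probabilities of all heterozygote counts (same parity as the
    observed minor-allele count) whose probability does not exceed that of
    the observed configuration.  Monomorphic SNPs return 1.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log weight of each heterozygote count h (shared normalisation dropped):
    #   w(h) = 2^h / (h! * ((n_rare - h) / 2)! * (n - h - (n_rare - h) / 2)!)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logw = (
        hets * math.log(2.0)
        - _lgamma1p(hets)
        - _lgamma1p(rare_hom)
        - _lgamma1p(common_hom)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    w_obs = w[hets == n_Aa][0]
    return float(min(1.0, w[w <= w_obs * (1.0 + 1e-12)].sum()))


def _lgamma1p(x: np.ndarray) -> np.ndarray:
    return np.array([math.lgamma(v + 1.0) for v in np.asarray(x, float)])


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    genotypes: GenotypeDosageTable,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 5e-7,
) -> tuple[GenotypeDosageTable, pd.DataFrame]:
    """Apply per-SNP QC; returns the filtered table and a report.

    A SNP is retained iff MAF >= ``maf_min`` AND call rate >= ``call_rate_min``
    AND HWE exact p > ``hwe_p_min``.  SNPs without hard genotype counts skip
    the HWE test with a logged warning.  The report lists every SNP with its
    statistics, kept flag and exclusion reasons.
    """
    eaf = genotypes.observed_eaf()
    maf = np.minimum(eaf, 1.0 - eaf)
    call = genotypes.call_rate()
    rows = []
    keep = []
    for snp in genotypes.snp_ids:
        reasons = []
        if maf[snp] < maf_min:
            reasons.append("MAF")
        if call[snp] < call_rate_min:
            reasons.append("call rate")
        info = genotypes.info.loc[snp]
        hwe_p = np.nan
        if np.isfinite(info[["n_AA", "n_Aa", "n_aa"]].astype(float)).all():
            hwe_p = hwe_exact_test(int(info["n_AA"]), int(info["n_Aa"]),
                                   int(info["n_aa"]))
            if not hwe_p > hwe_p_min:
                reasons.append("HWE")
        else:
            log.warning("SNP %s has no hard genotype counts; HWE test skipped", snp)
        kept = not reasons
        keep.append(kept)
        rows.append({
            "snp_id": snp,
            "maf": float(maf[snp]),
            "call_rate": float(call[snp]),
            "hwe_p": hwe_p,
            "kept": kept,
            "reasons": ";".join(reasons),
        })
    report = pd.DataFrame(rows).set_index("snp_id")
    kept_ids = [s for s, k in zip(genotypes.snp_ids, keep) if k]
    filtered = GenotypeDosageTable(
        genotypes.info.loc[kept_ids].copy(),
        genotypes.dosages.loc[kept_ids].copy(),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Association fitting
# ---------------------------------------------------------------------------


def fit_snp_mode(
    scores: ModeScores,
    hsm: int,
    dosage: pd.Series,
    covariates: CovariateTable,
    spec: ModelSpec,
    snp_id: str = "",
    timepoint: str = "",
) -> AssociationResult:
    """OLS of one mode score on (intercept, dosage, covariates in ``spec``).

    Complete cases only (inner join on subject id, NaNs dropped).  The p-value
    is two-sided from the t distribution with n - (len(covariates) + 2)
    degrees of freedom.
    """
    y = scores.mode(hsm)
    cov = covariates.data[list(spec.covariates)]
    frame = pd.concat(
        [y.rename("y"), dosage.rename("dosage"), cov], axis=1, join="inner"
    ).dropna()
    n = len(frame)
    n_params = len(spec.covariates) + 2
    if n < n_params + 1:
        raise ValueError(
            f"only {n} complete cases; need at least {n_params + 1} "
            f"for {spec.label}"
        )
    X = np.column_stack([
        np.ones(n),
        frame["dosage"].to_numpy(float),
        frame[list(spec.covariates)].to_numpy(float),
    ])
    if frame["dosage"].nunique() < 2:
        raise ValueError(f"degenerate design: constant dosage for {snp_id or 'SNP'}")
    yv = frame["y"].to_numpy(float)
    q, r = np.linalg.qr(X)
    if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
        raise ValueError("degenerate design: collinear columns")
    coef = np.linalg.solve(r, q.T @ yv)
    resid = yv - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    var_beta = sigma2 * float((rinv[1] @ rinv[1]))
    beta = float(coef[1])
    se = math.sqrt(var_beta)
    tval = beta / se
    p = float(2.0 * stats.t.sf(abs(tval), df))
    return AssociationResult(
        snp_id=snp_id or str(dosage.name or "SNP"),
        hsm=hsm,
        model=spec.label,
        beta=beta,
        se=se,
        p=max(p, np.finfo(float).tiny),
        n=n,
        timepoint=timepoint,
    )


def run_associations(
    scores: ModeScores,
    genotypes: GenotypeDosageTable,
    covariates: CovariateTable,
    pairs: list[tuple[str, int]],
    specs: list[ModelSpec] | None = None,
    timepoint: str = "",
) -> list[AssociationResult]:
    """Fit every (snp, mode) pair under each covariate model."""
    specs = specs or [MODEL_SPECS["model1"]]
    results = []
    for snp, hsm in pairs:
        dosage = genotypes.dosages.loc[snp]
        dosage.index = dosage.index.astype(str)
        for spec in specs:
            results.append(
                fit_snp_mode(scores, hsm, dosage, covariates, spec,
                             snp_id=snp, timepoint=timepoint)
            )
    return results


# ---------------------------------------------------------------------------
# Thresholding and table assembly
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise alpha divided by the number of tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def display_threshold(threshold: float) -> str:
    """Reporting convention: thresholds are displayed to three decimals."""
    return f"{threshold:.3f}"


@dataclass
class AssociationTable:
    """Adult discovery rows merged with cohort look-up results and flags."""

    data: pd.DataFrame
    threshold: float
    timepoints: list[str]

    def missing_pairs(self) -> list[tuple[str, int]]:
        miss = self.data[self.data["n_timepoints_tested"] == 0]
        return [(r["snp_id"], int(r["hsm"])) for _, r in miss.iterrows()]


def build_association_table(
    adult_results: pd.DataFrame,
    cohort_results: list[AssociationResult],
    threshold: float,
) -> AssociationTable:
    """Assemble the candidate-SNP look-up table.

    ``adult_results`` must provide columns ``hsm``, ``snp_id``,
    ``effect_allele``, ``eaf``, ``beta_adult``, ``p_adult`` (one row per
    adult-discovered SNP x mode pair).  Cohort results are matched on
    (snp_id, hsm) and spread into per-timepoint beta/p columns.  Flags:

    * ``sig_<tp>`` — p < threshold at that timepoint;
    * ``direction_consistent`` — every tested timepoint beta shares the
      adult beta's sign;
    * ``weak_evidence`` — direction-consistent and min p across timepoints
      < 0.1.

    Pairs absent from the cohort results are kept with
    ``n_timepoints_tested = 0`` rather than dropped silently.
    """
    required = {"hsm", "snp_id", "effect_allele", "eaf", "beta_adult", "p_adult"}
    if not required.issubset(adult_results.columns):
        raise ValueError(f"adult results need columns {sorted(required)}")
    timepoints = sorted({r.timepoint for r in cohort_results})
    lookup: dict[tuple[str, int, str], AssociationResult] = {}
    for r in cohort_results:
        lookup[(r.snp_id, r.hsm, r.timepoint)] = r

    rows = []
    for _, adult in adult_results.iterrows():
        key_base = (str(adult["snp_id"]), int(adult["hsm"]))
        row = {
            "hsm": int(adult["hsm"]),
            "snp_id": str(adult["snp_id"]),
            "effect_allele": adult["effect_allele"],
            "eaf": float(adult["eaf"]),
            "beta_adult": float(adult["beta_adult"]),
            "p_adult": float(adult["p_adult"]),
        }
        tested, consistent, min_p, any_sig = 0, True, np.inf, False
        for tp in timepoints:
            res = lookup.get((*key_base, tp))
            if res is None:
                row[f"beta_{tp}"] = np.nan
                row[f"p_{tp}"] = np.nan
                row[f"sig_{tp}"] = False
                continue
            tested += 1
            row[f"beta_{tp}"] = res.beta
            row[f"p_{tp}"] = res.p
            sig = res.p < threshold
            row[f"sig_{tp}"] = bool(sig)
            any_sig = any_sig or sig
            min_p = min(min_p, res.p)
            if np.sign(res.beta) != np.sign(row["beta_adult"]):
                consistent = False
        row["n_timepoints_tested"] = tested
        row["meets_threshold_any"] = any_sig
        row["direction_consistent_with_adult"] = bool(consistent and tested > 0)
        row["weak_evidence"] = bool(
            consistent and tested > 0 and min_p < 0.1
        )
        if tested == 0:
            log.warning("no cohort result for SNP %s / mode %d",
                        key_base[0], key_base[1])
        rows.append(row)
    return AssociationTable(pd.DataFrame(rows), threshold, timepoints)


def count_significant(table: AssociationTable, rule: str = "either_timepoint"):
    """Count rows meeting the threshold under a rule.

    ``either_timepoint`` and ``both_timepoints`` return an integer;
    ``per_timepoint`` returns a {timepoint: count} dict.
    """
    df = table.data
    sig_cols = [f"sig_{tp}" for tp in table.timepoints]
    if not sig_cols:
        return {} if rule == "per_timepoint" else 0
    if rule == "either_timepoint":
        return int(df[sig_cols].any(axis=1).sum())
    if rule == "both_timepoints":
        tested = df[[f"p_{tp}" for tp in table.timepoints]].notna()
        return int((df[sig_cols].to_numpy() & tested.to_numpy()).all(axis=1).sum())
    if rule == "per_timepoint":
        return {tp: int(df[f"sig_{tp}"].sum()) for tp in table.timepoints}
    raise ValueError(f"unknown rule {rule!r}")


def load_reference_associations() -> pd.DataFrame:
    """Reference table of adult candidate-SNP effect estimates shipped with
    the package, with the published adolescent look-up values alongside."""
    from importlib.resources import files

    path = files("hipshape").joinpath("data/reference_candidate_snps.tsv")
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
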