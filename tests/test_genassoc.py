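import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hipshape as hs
from hipshape.genassoc import MODEL_SPECS, display_threshold
from hipshape.landmark_io import CovariateTable, GenotypeDosageTable


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over every heterozygote configuration."""
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        weights[h] = Fraction(2**h, math.factorial(h)
                              * math.factorial(rare_hom)
                              * math.factorial(common_hom))
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def test_hwe_monomorphic():
    assert hs.hwe_exact_test(0, 0, 25) == 1.0
    assert hs.hwe_exact_test(25, 0, 0) == 1.0


def test_hwe_matches_enumeration_oracle_random(rng):
    for _ in range(300):
        n = int(rng.integers(1, 51))
        n_aa = int(rng.integers(0, n + 1))
        n_ab = int(rng.integers(0, n - n_aa + 1))
        counts = (n - n_aa - n_ab, n_ab, n_aa)
        assert hs.hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-10)


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_hwe_allele_label_symmetry(a, b, c):
    if a + b + c == 0:
        return
    assert hs.hwe_exact_test(a, b, c) == pytest.approx(
        hs.hwe_exact_test(c, b, a), abs=1e-12)


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hs.hwe_exact_test(-1, 0, 3)
    with pytest.raises(ValueError):
        hs.hwe_exact_test(0, 0, 0)


def test_hwe_known_textbook_value():
    # classic worked example: 1469/138/5 yields p ~ 0.32, well above chance
    p = hs.hwe_exact_test(1469, 138, 5)
    assert p == pytest.approx(hwe_enumeration_oracle(1469, 138, 5), rel=1e-9)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _panel(rows):
    """rows: list of (snp_id, dosages list possibly with NaN, counts or None)."""
    ids = [f"s{i}" for i in range(len(rows[0][1]))]
    info_recs, dos_recs, index = [], [], []
    for snp_id, dosages, counts in rows:
        rec = {"effect_allele": "G", "other_allele": "A"}
        if counts is not None:
            rec.update(dict(zip(("n_AA", "n_Aa", "n_aa"), counts)))
        info_recs.append(rec)
        dos_recs.append(dosages)
        index.append(snp_id)
    info = pd.DataFrame(info_recs, index=pd.Index(index, name="snp_id"))
    dos = pd.DataFrame(dos_recs, index=info.index, columns=ids, dtype=float)
    return GenotypeDosageTable(info, dos)


def _dosages_from_counts(n_AA, n_Aa, n_aa, n_missing=0):
    return [0.0] * n_AA + [1.0] * n_Aa + [2.0] * n_aa + [np.nan] * n_missing


def test_qc_low_maf_removed():
    n = 1000
    rows = [("common", _dosages_from_counts(640, 320, 40), (640, 320, 40)),
            ("rare", _dosages_from_counts(990, 10, 0), (990, 10, 0))]
    filtered, report = hs.qc_filter(_panel(rows))
    assert filtered.snp_ids == ["common"]
    assert report.loc["rare", "reasons"] == "MAF"


def test_qc_low_call_rate_removed():
    rows = [("patchy", _dosages_from_counts(50, 30, 14, n_missing=6), (50, 30, 14))]
    filtered, report = hs.qc_filter(_panel(rows))
    assert filtered.snp_ids == []
    assert report.loc["patchy", "call_rate"] == pytest.approx(0.94)
    assert report.loc["patchy", "reasons"] == "call rate"


def test_qc_hwe_failure_removed():
    # all heterozygotes: grossly out of HWE
    n = 200
    rows = [("badhwe", _dosages_from_counts(0, n, 0), (0, n, 0))]
    filtered, report = hs.qc_filter(_panel(rows))
    assert filtered.snp_ids == []
    assert "HWE" in report.loc["badhwe", "reasons"]
    assert report.loc["badhwe", "hwe_p"] < 5e-7


def test_qc_dosage_only_skips_hwe(caplog):
    rows = [("noCounts", _dosages_from_counts(60, 30, 10), None)]
    with caplog.at_level("WARNING"):
        filtered, report = hs.qc_filter(_panel(rows))
    assert filtered.snp_ids == ["noCounts"]
    assert np.isnan(report.loc["noCounts", "hwe_p"])
    assert any("HWE test skipped" in r.message for r in caplog.records)


def test_qc_toy_panel_matches_hand_applied_rules():
    """Six constructed SNPs; survivor set computed by hand."""
    n = 400
    rows = [
        # fine: MAF 0.25, full call rate, HWE-ish counts
        ("ok1", _dosages_from_counts(225, 150, 25), (225, 150, 25)),
        # fine: MAF 0.5 exactly in HWE
        ("ok2", _dosages_from_counts(100, 200, 100), (100, 200, 100)),
        # MAF 0.5% -> out
        ("lowmaf", _dosages_from_counts(396, 4, 0), (396, 4, 0)),
        # call rate 90% -> out
        ("lowcall", _dosages_from_counts(200, 120, 40, n_missing=40),
         (200, 120, 40)),
        # extreme heterozygote excess -> HWE out
        ("hwefail", _dosages_from_counts(0, 400, 0), (0, 400, 0)),
        # two reasons at once: rare AND badly typed
        ("both", _dosages_from_counts(356, 4, 0, n_missing=40), (356, 4, 0)),
    ]
    filtered, report = hs.qc_filter(_panel(rows))
    assert filtered.snp_ids == ["ok1", "ok2"]
    assert report.loc["both", "reasons"] == "MAF;call rate"
    assert report["kept"].sum() == 2


# ---------------------------------------------------------------------------
# fit_snp_mode
# ---------------------------------------------------------------------------


def _assoc_inputs(n=120, seed=0, beta=0.5, noise_sd=0.0, age_coef=0.1):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    dosage = pd.Series(rng.choice([0.0, 1.0, 2.0], size=n, p=[0.4, 0.4, 0.2]),
                       index=ids, name="rsX")
    cov = CovariateTable(pd.DataFrame({
        "age": rng.normal(14.0, 0.5, n),
        "sex": rng.integers(0, 2, n),
        "height": rng.normal(160.0, 8.0, n),
        "weight": rng.normal(55.0, 10.0, n),
    }, index=pd.Index(ids, name="id")))
    y = beta * dosage.to_numpy() + age_coef * cov.data["age"].to_numpy()
    y = y + noise_sd * rng.standard_normal(n)
    scores = hs.ModeScores(ids, y[:, None])
    return scores, dosage, cov


def test_noiseless_exact_recovery():
    scores, dosage, cov = _assoc_inputs(beta=0.5, noise_sd=0.0)
    res = hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"],
                          snp_id="rsX")
    assert res.beta == pytest.approx(0.5, abs=1e-10)


def test_small_fixture_matches_normal_equations_and_statsmodels():
    """8 printed subjects; oracle = explicit normal equations + t CDF,
    cross-checked against statsmodels OLS."""
    import statsmodels.api as sm

    ids = [f"s{i}" for i in range(8)]
    dosage = pd.Series([0, 1, 2, 1, 0, 2, 1, 0], index=ids, dtype=float)
    age = np.array([13.5, 13.9, 14.1, 13.7, 14.0, 13.6, 13.8, 14.2])
    sex = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    y = np.array([0.21, -0.44, 1.02, 0.35, -0.97, 1.40, 0.05, -0.66])
    cov = CovariateTable(pd.DataFrame(
        {"age": age, "sex": sex, "height": 160.0, "weight": 55.0},
        index=pd.Index(ids, name="id")))
    scores = hs.ModeScores(ids, y[:, None])
    res = hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"])

    X = np.column_stack([np.ones(8), dosage, age, sex])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta_hat
    df = 8 - 4
    sigma2 = resid @ resid / df
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov_beta[1, 1])
    p = 2 * stats.t.sf(abs(beta_hat[1] / se), df)
    assert res.beta == pytest.approx(beta_hat[1], abs=1e-10)
    assert res.se == pytest.approx(se, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)
    assert res.n == 8

    fit = sm.OLS(y, X).fit()
    assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
    assert res.se == pytest.approx(fit.bse[1], abs=1e-10)
    assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_constant_dosage_degenerate():
    scores, dosage, cov = _assoc_inputs()
    dosage[:] = 1.0
    with pytest.raises(ValueError, match="degenerate"):
        hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"])


def test_too_few_complete_cases():
    scores, dosage, cov = _assoc_inputs(n=4)
    with pytest.raises(ValueError, match="complete cases"):
        hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"])


def test_missing_covariates_dropped_complete_case():
    scores, dosage, cov = _assoc_inputs(n=60, noise_sd=0.3)
    cov.data.iloc[:10, cov.data.columns.get_loc("age")] = np.nan
    res = hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"])
    assert res.n == 50


def test_planted_beta_recovery_simulation(rng):
    hits = 0
    reps = 60
    for i in range(reps):
        n = 800
        ids = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.35, n).astype(float)
        y = -0.054 * g + rng.standard_normal(n)
        cov = CovariateTable(pd.DataFrame({
            "age": rng.normal(14, 0.3, n), "sex": rng.integers(0, 2, n),
            "height": 160.0, "weight": 55.0,
        }, index=pd.Index(ids, name="id")))
        res = hs.fit_snp_mode(hs.ModeScores(ids, y[:, None]), 1,
                              pd.Series(g, index=ids), cov, MODEL_SPECS["model1"])
        if abs(res.beta - (-0.054)) <= 3 * res.se:
            hits += 1
    assert hits >= reps - 2  # ~99.7% coverage expected


def test_estimator_consistency(rng):
    errors = {}
    for n in (250, 1000, 4000):
        biases = []
        for _ in range(30):
            ids = [f"s{i}" for i in range(n)]
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.2 * g + rng.standard_normal(n)
            cov = CovariateTable(pd.DataFrame({
                "age": rng.normal(14, 0.3, n), "sex": rng.integers(0, 2, n),
                "height": 160.0, "weight": 55.0,
            }, index=pd.Index(ids, name="id")))
            res = hs.fit_snp_mode(hs.ModeScores(ids, y[:, None]), 1,
                                  pd.Series(g, index=ids), cov,
                                  MODEL_SPECS["model1"])
            biases.append(res.beta - 0.2)
        errors[n] = abs(np.mean(biases))
    assert errors[4000] < errors[250] + 0.01


def test_independent_covariate_adjustment_changes_little(rng):
    n = 1500
    ids = [f"s{i}" for i in range(n)]
    g = rng.binomial(2, 0.35, n).astype(float)
    y = 0.1 * g + rng.standard_normal(n)
    cov = CovariateTable(pd.DataFrame({
        "age": rng.normal(14, 0.3, n), "sex": rng.integers(0, 2, n),
        "height": rng.normal(160, 8, n), "weight": rng.normal(55, 10, n),
    }, index=pd.Index(ids, name="id")))
    scores = hs.ModeScores(ids, y[:, None])
    dosage = pd.Series(g, index=ids)
    base = hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS["model1"])
    for label in ("model2", "model3"):
        other = hs.fit_snp_mode(scores, 1, dosage, cov, MODEL_SPECS[label])
        assert abs(other.beta - base.beta) < 2 * base.se


# ---------------------------------------------------------------------------
# Bonferroni threshold
# ---------------------------------------------------------------------------


def test_bonferroni_eight_tests():
    thr = hs.bonferroni_threshold(0.05, 8)
    assert thr == pytest.approx(0.00625)
    assert display_threshold(thr) == "0.006"


def test_bonferroni_trivial_cases():
    assert hs.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    assert hs.bonferroni_threshold(0.05, 10) == pytest.approx(0.005)


def test_bonferroni_invalid():
    with pytest.raises(ValueError):
        hs.bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        hs.bonferroni_threshold(1.5, 4)


# ---------------------------------------------------------------------------
# Association table assembly
# ---------------------------------------------------------------------------


def reference_cohort_results():
    """AssociationResults built from the shipped reference look-up values."""
    ref = hs.load_reference_associations()
    out = []
    for _, row in ref.iterrows():
        for tp in ("age14", "age18"):
            out.append(hs.AssociationResult(
                snp_id=row["snp_id"], hsm=int(row["hsm"]), model="model1",
                beta=float(row[f"beta_{tp}"]), se=0.015,
                p=float(row[f"p_{tp}"]), n=int(row[f"n_{tp}"]), timepoint=tp))
    return ref, out


def test_reference_table_six_significant_rows():
    ref, cohort = reference_cohort_results()
    table = hs.build_association_table(ref, cohort,
                                       hs.bonferroni_threshold(0.05, 8))
    assert len(table.data) == 9
    assert hs.count_significant(table, "either_timepoint") == 6


def test_reference_table_four_significant_at_both():
    ref, cohort = reference_cohort_results()
    table = hs.build_association_table(ref, cohort, 0.006)
    assert hs.count_significant(table, "both_timepoints") == 4
    both = table.data[(table.data["sig_age14"]) & (table.data["sig_age18"])]
    assert set(zip(both["snp_id"], both["hsm"])) == {
        ("rs2158915", 1), ("rs10743612", 1), ("rs6537291", 2), ("rs2158915", 5)}


def test_reference_table_weak_evidence_all_rows():
    ref, cohort = reference_cohort_results()
    table = hs.build_association_table(ref, cohort, 0.006)
    assert table.data["direction_consistent_with_adult"].all()
    assert table.data["weak_evidence"].all()


def test_threshold_monotone_bounds():
    ref, cohort = reference_cohort_results()
    everything = hs.build_association_table(ref, cohort, 1.0)
    nothing = hs.build_association_table(ref, cohort, 0.0)
    assert hs.count_significant(everything, "either_timepoint") == 9
    assert hs.count_significant(nothing, "either_timepoint") == 0
    thresholds = [0.0, 1e-6, 1e-4, 0.006, 0.05, 1.0]
    counts = [hs.count_significant(hs.build_association_table(ref, cohort, t),
                                   "either_timepoint") for t in thresholds]
    assert counts == sorted(counts)


def test_per_timepoint_counts():
    ref, cohort = reference_cohort_results()
    table = hs.build_association_table(ref, cohort, 0.006)
    assert hs.count_significant(table, "per_timepoint") == {
        "age14": 5, "age18": 5}


def test_missing_pair_reported_not_dropped():
    ref, cohort = reference_cohort_results()
    cohort = [r for r in cohort if r.snp_id != "rs1885245"]
    table = hs.build_association_table(ref, cohort, 0.006)
    assert len(table.data) == 9
    assert table.missing_pairs() == [("rs1885245", 2)]


def test_empty_table_counts_zero():
    ref = hs.load_reference_associations().iloc[:0]
    table = hs.build_association_table(ref, [], 0.006)
    assert hs.count_significant(table, "either_timepoint") == 0


def test_type_one_error_calibration_small(rng):
    """Null p-values uniform: small version of the acceptance check."""
    reps, n = 200, 300
    ids = [f"s{i}" for i in range(n)]
    g = rng.binomial(2, 0.3, n).astype(float)
    cov = CovariateTable(pd.DataFrame({
        "age": rng.normal(14, 0.3, n), "sex": rng.integers(0, 2, n),
        "height": 160.0, "weight": 55.0,
    }, index=pd.Index(ids, name="id")))
    dosage = pd.Series(g, index=ids)
    rejections = 0
    for _ in range(reps):
        y = rng.standard_normal(n)
        res = hs.fit_snp_mode(hs.ModeScores(ids, y[:, None]), 1, dosage, cov,
                              MODEL_SPECS["model1"])
        rejections += res.p < 0.05
    lo, hi = stats.binom.interval(0.999, reps, 0.05)
    assert lo <= rejections <= hi
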