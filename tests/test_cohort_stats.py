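"""Statistical layer: hand-worked examples, printed-value recomputation,
independent oracles (closed forms, statsmodels) and schema validation."""

import json

import numpy as np
import pandas as pd
import pytest

from dentofacial.cohort_stats import (
    GroupSummary,
    StatResult,
    analysis_report,
    cohen_d_pooled,
    cohen_dz,
    describe,
    levene,
    load_cohort_csv,
    mann_whitney,
    paired_t_with_ci,
    percent_of_mean_with_ci,
    power_correlation_fisher_z,
    power_paired_t,
    power_two_sample_t,
    shapiro_wilk,
    spearman,
    two_sample_t,
    validate_cohort,
)
from dentofacial.errors import (
    DegenerateVarianceError,
    DomainError,
    EmptyInputError,
    PairingError,
    SampleSizeError,
    SchemaError,
)
from dentofacial.synthetic import CohortSimConfig, gen_cohort_table


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def test_statresult_invariants():
    with pytest.raises(DomainError):
        StatResult(test="x", estimate=5.0, ci_low=1.0, ci_high=4.0)
    with pytest.raises(DomainError):
        StatResult(test="x", estimate=0.0, p=1.5)
    r = StatResult(test="x", estimate=2.0, ci_low=1.0, ci_high=3.0, p=0.5, n=(3, 4))
    assert json.dumps(r.as_dict())  # JSON-serializable


def test_group_summary_validation():
    with pytest.raises(SampleSizeError):
        GroupSummary(0.0, 1.0, 1)
    with pytest.raises(DomainError):
        GroupSummary(0.0, 0.0, 5)


# ---------------------------------------------------------------------------
# Descriptives and elementary tests
# ---------------------------------------------------------------------------


def test_describe_hand_case():
    d = describe([1.0, 2.0, 3.0, 4.0, 10.0])
    assert d["n"] == 5
    assert d["mean"] == pytest.approx(4.0)
    assert d["median"] == 3.0
    assert d["sd"] == pytest.approx(np.std([1, 2, 3, 4, 10], ddof=1))
    assert d["iqr"] == (2.0, 4.0)
    assert (d["min"], d["max"]) == (1.0, 10.0)
    with pytest.raises(EmptyInputError):
        describe([])
    with pytest.raises(DomainError):
        describe([1.0, np.nan])


def test_shapiro_gate_bounds():
    rng = np.random.default_rng(0)
    r = shapiro_wilk(rng.normal(0, 1, 98))
    assert 0.0 <= r.p <= 1.0 and r.estimate <= 1.0
    with pytest.raises(SampleSizeError):
        shapiro_wilk([1.0, 2.0])


def test_spearman_hand_case():
    # ranks differ by d = (1, 1, 1, 1, 0): rho = 1 - 6*4 / (5*24) = 0.8
    r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert r.estimate == pytest.approx(0.8)
    with pytest.raises(PairingError):
        spearman([1, 2, 3], [1, 2])
    with pytest.raises(SampleSizeError):
        spearman([1, 2], [1, 2])


def test_spearman_perfect_monotone():
    r = spearman([1, 2, 3, 4], [10, 100, 1000, 10000])
    assert r.estimate == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Paired t with CI
# ---------------------------------------------------------------------------


def test_paired_t_hand_case():
    # differences (1, 2, 3): mean 2, sd 1, se 1/sqrt(3), df 2
    r = paired_t_with_ci([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert r.estimate == pytest.approx(2.0)
    assert r.aux["t"] == pytest.approx(2.0 * np.sqrt(3.0))
    # t_crit(0.975, 2) = 4.302653 (hand table value)
    hw = 4.302653 * 1.0 / np.sqrt(3.0)
    assert r.ci_low == pytest.approx(2.0 - hw, abs=1e-5)
    assert r.ci_high == pytest.approx(2.0 + hw, abs=1e-5)
    assert r.p == pytest.approx(0.074180, abs=1e-5)


def test_paired_t_summary_mode_matches_samples():
    a = np.array([5.0, 7.0, 9.0, 4.0, 6.0])
    b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    d = a - b
    r1 = paired_t_with_ci(a, b)
    r2 = paired_t_with_ci(mean_diff=d.mean(), sd_diff=d.std(ddof=1), n=5)
    assert r1.ci_low == pytest.approx(r2.ci_low)
    assert r1.p == pytest.approx(r2.p)


def test_paired_t_errors():
    with pytest.raises(PairingError):
        paired_t_with_ci([1, 2], [1, 2, 3])
    with pytest.raises(PairingError):
        paired_t_with_ci([1, 2], [1, 2], mean_diff=1.0, sd_diff=1.0, n=2)
    with pytest.raises(DomainError):
        paired_t_with_ci(mean_diff=1.0, n=5)
    with pytest.raises(DegenerateVarianceError):
        paired_t_with_ci([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    with pytest.raises(SampleSizeError):
        paired_t_with_ci(mean_diff=1.0, sd_diff=1.0, n=1)
    with pytest.raises(DomainError):
        paired_t_with_ci(mean_diff=1.0, sd_diff=1.0, n=5, alpha=1.5)


def test_percent_of_mean_reference_values():
    # printed summary inputs: mean diff 285,052.34, SD 137,012.73, n = 98,
    # reference mean 1,626,120.79
    r = paired_t_with_ci(mean_diff=285_052.34, sd_diff=137_012.73, n=98)
    assert round(r.ci_low) == 257_583
    assert round(r.ci_high) in (312_521, 312_522)
    pct = percent_of_mean_with_ci(r, 1_626_120.79)
    assert pct == (17.53, 15.84, 19.22)
    with pytest.raises(DomainError):
        percent_of_mean_with_ci(r, 0.0)
    with pytest.raises(DomainError):
        percent_of_mean_with_ci(StatResult(test="x", estimate=1.0), 10.0)


# ---------------------------------------------------------------------------
# Two-sample comparisons
# ---------------------------------------------------------------------------


def test_levene_gating_routes():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 60)
    b = rng.normal(0, 1, 60)
    r = two_sample_t(a, b)
    assert r.aux["pooled"] is True
    assert r.aux["levene_p"] == pytest.approx(levene(a, b).p)
    c = rng.normal(0, 6, 60)  # strongly unequal variance
    r2 = two_sample_t(a, c)
    assert r2.aux["pooled"] is False
    assert r2.aux["df"] != int(r2.aux["df"])  # Welch fractional df


def test_two_sample_t_summary_table5():
    # Table-5 style summary inputs: female vs male V_total
    r = two_sample_t(
        GroupSummary(1_583_561.0, 225_978.0, 64),
        GroupSummary(1_706_232.0, 151_086.0, 34),
    )
    assert round(r.p, 3) == 0.005
    assert r.aux["pooled"] is True
    assert r.estimate == pytest.approx(-122_671.0)


def test_two_sample_t_mixed_inputs_rejected():
    with pytest.raises(PairingError):
        two_sample_t(GroupSummary(0.0, 1.0, 5), [1.0, 2.0, 3.0])


def test_two_sample_t_degenerate_cases():
    r = two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])
    assert r.p == 1.0 and r.estimate == 0.0
    with pytest.raises(DegenerateVarianceError):
        two_sample_t([2.0, 2.0, 2.0], [3.0, 3.0])


def test_mann_whitney_exact_hand_case():
    # {1,2} vs {3,4}: most extreme of C(4,2) = 6 orderings -> p = 2/6
    r = mann_whitney([1.0, 2.0], [3.0, 4.0])
    assert r.p == pytest.approx(1.0 / 3.0)
    assert r.aux["method"] == "exact"


def test_mann_whitney_tie_fallback():
    r = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
    assert r.aux["method"] == "asymptotic"


# ---------------------------------------------------------------------------
# Effect sizes and power
# ---------------------------------------------------------------------------


def test_effect_sizes_reference_values():
    assert round(cohen_dz(285_052.34, 137_012.73), 2) == 2.08
    d = cohen_d_pooled(1_583_561.0, 225_978.0, 69, 1_706_232.0, 151_086.0, 29)
    assert round(d, 2) == 0.59
    with pytest.raises(DomainError):
        cohen_dz(1.0, 0.0)
    with pytest.raises(DomainError):
        cohen_d_pooled(0.0, 0.0, 5, 1.0, 1.0, 5)
    with pytest.raises(SampleSizeError):
        cohen_d_pooled(0.0, 1.0, 1, 1.0, 1.0, 5)


def test_power_reference_values():
    assert power_paired_t(2.08, 98) > 0.999
    d = cohen_d_pooled(1_583_561.0, 225_978.0, 69, 1_706_232.0, 151_086.0, 29)
    # the printed 0.76 arises from the unrounded d; the 2-dp d gives 0.75
    assert round(power_two_sample_t(d, 69, 29), 2) == 0.76
    assert round(power_two_sample_t(0.59, 69, 29), 4) == 0.7515
    assert round(power_correlation_fisher_z(0.448, 98), 3) == 0.997
    assert power_correlation_fisher_z(0.3, 50) == pytest.approx(0.564, abs=5e-4)


def test_power_zero_effect_equals_alpha():
    for alpha in (0.05, 0.01):
        assert power_paired_t(0.0, 30, alpha) == pytest.approx(alpha, abs=1e-12)
        assert power_two_sample_t(0.0, 20, 25, alpha) == pytest.approx(alpha, abs=1e-12)
        assert power_correlation_fisher_z(0.0, 40, alpha) == pytest.approx(
            alpha, abs=1e-12
        )


def test_power_monotone_in_n_and_effect():
    assert power_paired_t(0.5, 50) > power_paired_t(0.5, 20) > power_paired_t(0.2, 20)
    assert power_two_sample_t(0.8, 40, 40) > power_two_sample_t(0.4, 40, 40)
    assert power_correlation_fisher_z(0.5, 100) > power_correlation_fisher_z(0.5, 30)


def test_power_against_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.stats.power")
    assert power_paired_t(0.4, 35) == pytest.approx(
        sm.TTestPower().power(0.4, 35, 0.05, alternative="two-sided"), abs=1e-9
    )
    assert power_two_sample_t(0.6, 40, 25) == pytest.approx(
        sm.TTestIndPower().power(0.6, 40, 0.05, ratio=25 / 40.0,
                                 alternative="two-sided"),
        abs=1e-9,
    )


def test_power_domain_errors():
    with pytest.raises(DomainError):
        power_paired_t(0.5, 30, alpha=0.0)
    with pytest.raises(SampleSizeError):
        power_paired_t(0.5, 1)
    with pytest.raises(SampleSizeError):
        power_two_sample_t(0.5, 1, 30)
    with pytest.raises(DomainError):
        power_correlation_fisher_z(1.0, 30)
    with pytest.raises(SampleSizeError):
        power_correlation_fisher_z(0.5, 3)


# ---------------------------------------------------------------------------
# Cohort table validation
# ---------------------------------------------------------------------------


def _table(**overrides):
    base = {
        "subject_id": ["S001", "S002", "S003"],
        "sex": ["female", "male", "female"],
        "age": [20, 22, 19],
        "v_total": [1.5e6, 1.7e6, 1.6e6],
        "v_superimposed": [1.2e6, 1.5e6, 1.3e6],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def test_validate_cohort_derives_columns():
    t = validate_cohort(_table())
    assert t["rtv"].tolist() == pytest.approx([3e5, 2e5, 3e5])
    assert t["pct_si"].iloc[0] == pytest.approx(80.0)


def test_validate_cohort_missing_column():
    with pytest.raises(SchemaError) as exc:
        validate_cohort(_table().drop(columns=["age"]))
    assert "age" in str(exc.value)


def test_validate_cohort_negative_volume_names_row():
    with pytest.raises(SchemaError) as exc:
        validate_cohort(_table(v_total=[1.5e6, -5.0, 1.6e6]))
    assert "row(s) 2" in str(exc.value)


def test_validate_cohort_bad_sex_and_superimposed():
    with pytest.raises(SchemaError):
        validate_cohort(_table(sex=["female", "other", "male"]))
    with pytest.raises(SchemaError):
        validate_cohort(_table(v_superimposed=[1.2e6, 1.8e6, 1.3e6]))


def test_validate_cohort_inconsistent_rtv():
    with pytest.raises(SchemaError) as exc:
        validate_cohort(_table(rtv=[3e5, 2e5, 999.0]))
    assert "row(s) 3" in str(exc.value)


def test_validate_cohort_empty():
    with pytest.raises(EmptyInputError):
        validate_cohort(_table().iloc[:0])


def test_load_cohort_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    _table().to_csv(path, index=False)
    t = load_cohort_csv(path)
    assert len(t) == 3
    with pytest.raises(SchemaError):
        load_cohort_csv(tmp_path / "missing.csv")


# ---------------------------------------------------------------------------
# analysis_report
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def default_cohort():
    table, _ = gen_cohort_table(CohortSimConfig(seed=0))
    return table


def test_report_structure_and_determinism(default_cohort):
    r1 = analysis_report(default_cohort)
    r2 = analysis_report(default_cohort)
    assert r1 == r2
    assert json.dumps(r1)  # fully JSON-serializable
    assert r1["n"] == 98
    gs = r1["group_sizes"]
    assert gs["female"] + gs["male"] == 98
    assert gs["age_lt_21"] + gs["age_ge_21"] == 98
    for key in (
        "descriptives", "normality", "normal_gate",
        "spearman_total_vs_remaining", "paired_total_vs_superimposed",
        "sex_comparison", "age_comparison", "sex_effect_v_total",
        "correlation_achieved_power",
    ):
        assert key in r1


def test_report_paired_block_consistent(default_cohort):
    r = analysis_report(default_cohort)
    block = r["paired_total_vs_superimposed"]["overall"]
    v = default_cohort["v_total"].to_numpy()
    s = default_cohort["v_superimposed"].to_numpy()
    assert block["estimate"] == pytest.approx((v - s).mean())
    pct = block["percent_of_mean"]
    assert pct["estimate"] == pytest.approx(
        100.0 * (v - s).mean() / v.mean(), abs=0.005
    )
    assert block["cohen_dz"] == pytest.approx(
        (v - s).mean() / (v - s).std(ddof=1), abs=1e-4
    )
    assert 0.0 <= block["achieved_power"] <= 1.0


def test_report_comparisons_respect_normal_gate(default_cohort):
    r = analysis_report(default_cohort)
    for var, entry in r["sex_comparison"].items():
        expected = "two_sample_t" if r["normal_gate"][var] else "mann_whitney"
        assert entry["test"] == expected


def test_report_single_row_collects_errors():
    t = _table().iloc[:1]
    r = analysis_report(t)
    assert r["n"] == 1
    assert "error" in r["spearman_total_vs_remaining"]["overall"]
    assert "error" in r["sex_comparison"]["v_total"]
    assert json.dumps(r)


def test_report_alpha_and_age_cut_propagate(default_cohort):
    r = analysis_report(default_cohort, alpha=0.01, age_cut=22)
    assert r["alpha"] == 0.01
    assert "age_lt_22" in r["group_sizes"]
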