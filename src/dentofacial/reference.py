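"""Reference cohort summary statistics (study defaults).

Printed summary statistics of the original 98-subject cohort, bundled so
the recomputation battery (effect sizes, confidence intervals, percent-of-
mean values, achieved power) can be reproduced from summary inputs alone.
All volumes in mm^3 of the scaled (x15.56) configuration.
"""

from __future__ import annotations

from .cohort_stats import (
    GroupSummary,
    StatResult,
    cohen_d_pooled,
    cohen_dz,
    paired_t_with_ci,
    percent_of_mean_with_ci,
    power_correlation_fisher_z,
    power_paired_t,
    power_two_sample_t,
    two_sample_t,
)

N_TOTAL = 98

# overall descriptives
V_TOTAL_MEAN = 1_626_120.79
V_TOTAL_SD = 210_659.56
RTV_MEAN = 285_052.34
RTV_SD = 137_012.73
SI_MEAN = 82.64
SI_SD = 7.36
SI_MIN = 51.69
SI_MAX = 93.70

# paired total-vs-superimposed difference (equals RTV by construction)
PAIRED_DIFF = {"mean_diff": RTV_MEAN, "sd_diff": RTV_SD, "n": N_TOTAL}

# sex groups: the cohort-description split and the comparison-analysis split
SEX_SPLIT_DESCRIPTION = {"female": 64, "male": 34}
SEX_SPLIT_ANALYSIS = {"female": 69, "male": 29}
FEMALE_V_TOTAL = {"mean": 1_583_561.0, "sd": 225_978.0}
MALE_V_TOTAL = {"mean": 1_706_232.0, "sd": 151_086.0}

# per-subgroup paired differences with reported 95% CIs and references
SUBGROUP_PAIRED = {
    "female": {
        "mean_diff": 285_296.23,
        "ci": (248_004.0, 322_587.0),
        "reference_mean": FEMALE_V_TOTAL["mean"],
        "n": SEX_SPLIT_DESCRIPTION["female"],
    },
    "male": {
        "mean_diff": 284_593.25,
        "reference_mean": MALE_V_TOTAL["mean"],
        "n": SEX_SPLIT_DESCRIPTION["male"],
    },
    "age_lt_21": {
        "mean_diff": 294_131.51,
        "reference_mean": 1_652_082.0,
    },
}

# Spearman rho, total vs remaining volume
SPEARMAN = {
    "overall": 0.448,
    "female": 0.515,
    "male": 0.142,
    "age_lt_21": 0.662,
    "age_ge_21": 0.122,
}

AGE_MEAN = 20.56
AGE_SD = 1.29
AGE_RANGE = (18, 27)

ALPHA = 0.05


def recompute_reference_battery() -> dict:
    """Recompute the summary-input battery from the bundled constants.

    Everything is derived by the cohort_stats layer from printed summary
    inputs; nothing is copied from reported downstream results.
    """
    paired = paired_t_with_ci(**PAIRED_DIFF, alpha=ALPHA)
    pct_overall = percent_of_mean_with_ci(paired, V_TOTAL_MEAN)

    def subgroup_pct(key: str) -> tuple:
        sg = SUBGROUP_PAIRED[key]
        if "ci" in sg:
            res = StatResult(
                test="paired_t",
                estimate=sg["mean_diff"],
                ci_low=sg["ci"][0],
                ci_high=sg["ci"][1],
            )
            return percent_of_mean_with_ci(res, sg["reference_mean"])
        return (
            round(100.0 * sg["mean_diff"] / sg["reference_mean"], 2),
            None,
            None,
        )

    dz = cohen_dz(PAIRED_DIFF["mean_diff"], PAIRED_DIFF["sd_diff"])
    d_sex = cohen_d_pooled(
        FEMALE_V_TOTAL["mean"],
        FEMALE_V_TOTAL["sd"],
        SEX_SPLIT_ANALYSIS["female"],
        MALE_V_TOTAL["mean"],
        MALE_V_TOTAL["sd"],
        SEX_SPLIT_ANALYSIS["male"],
    )
    sex_t = two_sample_t(
        GroupSummary(
            FEMALE_V_TOTAL["mean"],
            FEMALE_V_TOTAL["sd"],
            SEX_SPLIT_DESCRIPTION["female"],
        ),
        GroupSummary(
            MALE_V_TOTAL["mean"],
            MALE_V_TOTAL["sd"],
            SEX_SPLIT_DESCRIPTION["male"],
        ),
        alpha=ALPHA,
    )
    return {
        "paired_diff_mean": paired.estimate,
        "paired_diff_ci_lower": paired.ci_low,
        "paired_diff_ci_upper": paired.ci_high,
        "diff_pct_of_total_overall": pct_overall[0],
        "diff_pct_ci_lower": float(pct_overall[1]),
        "diff_pct_ci_upper": float(pct_overall[2]),
        "diff_pct_of_total_women": subgroup_pct("female")[0],
        "diff_pct_women_ci": subgroup_pct("female")[1:],
        "diff_pct_of_total_men": subgroup_pct("male")[0],
        "diff_pct_of_total_under21": subgroup_pct("age_lt_21")[0],
        "cohen_dz_paired": dz,
        "cohen_d_sex": d_sex,
        "sex_t_p_value": sex_t.p,
        "achieved_power_paired": power_paired_t(dz, N_TOTAL, ALPHA),
        "achieved_power_sex": power_two_sample_t(
            d_sex,
            SEX_SPLIT_ANALYSIS["female"],
            SEX_SPLIT_ANALYSIS["male"],
            ALPHA,
        ),
        "achieved_power_correlation": power_correlation_fisher_z(
            SPEARMAN["overall"], N_TOTAL, ALPHA
        ),
    }
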