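"""Cohort statistics: descriptives, gated comparisons, effect sizes, power.

The layer mirrors the study's statistical plan: Shapiro-Wilk normality
gating, Spearman rank correlation, paired-sample t with 95% CI (also from
summary statistics), Levene-gated Student/Welch t or Mann-Whitney U for
group comparisons, Cohen's dz / pooled d effect sizes, and achieved-power
functions (noncentral t for the t-tests, Fisher-z normal approximation for
the correlation). Standard tests delegate to :mod:`scipy.stats`; only the
assembly, gating and power formulas are authored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    DomainError,
    EmptyInputError,
    PairingError,
    SampleSizeError,
    SchemaError,
)

__all__ = [
    "StatResult",
    "GroupSummary",
    "describe",
    "shapiro_wilk",
    "spearman",
    "paired_t_with_ci",
    "percent_of_mean_with_ci",
    "two_sample_t",
    "levene",
    "mann_whitney",
    "cohen_dz",
    "cohen_d_pooled",
    "power_paired_t",
    "power_two_sample_t",
    "power_correlation_fisher_z",
    "load_cohort_csv",
    "validate_cohort",
    "analysis_report",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class StatResult:
    """One test outcome: estimate, 95% CI where defined, p-value, n, extras."""

    test: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    n: int | tuple = 0
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise DomainError(
                    f"{self.test}: CI ({self.ci_low}, {self.ci_high}) does not "
                    f"bracket estimate {self.estimate}"
                )
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise DomainError(f"{self.test}: p-value {self.p} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": list(self.n) if isinstance(self.n, tuple) else self.n,
            "aux": dict(self.aux),
        }


@dataclass(frozen=True)
class GroupSummary:
    """Summary-statistics stand-in for a raw sample: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise SampleSizeError(f"group summary needs n >= 2, got {self.n}")
        if self.sd <= 0:
            raise DomainError(f"group summary needs SD > 0, got {self.sd}")


def _sample(values, op: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(-1)
    if arr.size == 0:
        raise EmptyInputError(f"{op}: empty sample")
    if not np.isfinite(arr).all():
        raise DomainError(f"{op}: sample contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Descriptives and elementary tests
# ---------------------------------------------------------------------------


def describe(values) -> dict:
    """Mean, SD (n-1), median, IQR (25th/75th, linear interp.), min, max."""
    x = _sample(values, "describe")
    q25, q75 = np.percentile(x, [25.0, 75.0])
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "iqr": (float(q25), float(q75)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def shapiro_wilk(values) -> StatResult:
    """Shapiro-Wilk normality test; the parametric/non-parametric gate."""
    x = _sample(values, "shapiro_wilk")
    if not (3 <= x.size <= 5000):
        raise SampleSizeError(
            f"shapiro_wilk requires 3 <= n <= 5000, got n={x.size}"
        )
    res = stats.shapiro(x)
    return StatResult(
        test="shapiro_wilk",
        estimate=float(res.statistic),
        p=float(res.pvalue),
        n=int(x.size),
        aux={"W": float(res.statistic)},
    )


def spearman(x, y) -> StatResult:
    """Spearman's rho (average ranks for ties) with two-sided p."""
    xa = _sample(x, "spearman")
    ya = _sample(y, "spearman")
    if xa.size != ya.size:
        raise PairingError(
            f"spearman requires paired samples, got lengths {xa.size} != {ya.size}"
        )
    if xa.size < 3:
        raise SampleSizeError(f"spearman requires n >= 3, got n={xa.size}")
    res = stats.spearmanr(xa, ya)
    return StatResult(
        test="spearman",
        estimate=float(res.statistic),
        p=float(res.pvalue),
        n=int(xa.size),
        aux={"rho": float(res.statistic)},
    )


def paired_t_with_ci(
    a=None,
    b=None,
    *,
    mean_diff: float | None = None,
    sd_diff: float | None = None,
    n: int | None = None,
    alpha: float = 0.05,
) -> StatResult:
    """Paired-sample t-test with 95% CI of the mean difference (a - b).

    Either two paired samples or the summary triple (``mean_diff``,
    ``sd_diff``, ``n``) of the differences.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if mean_diff is not None or sd_diff is not None or n is not None:
        if a is not None or b is not None:
            raise PairingError(
                "paired_t_with_ci takes samples or summaries, not both"
            )
        if mean_diff is None or sd_diff is None or n is None:
            raise DomainError(
                "summary mode needs all of mean_diff, sd_diff and n"
            )
        md, sdd, nn = float(mean_diff), float(sd_diff), int(n)
    else:
        aa = _sample(a, "paired_t_with_ci")
        bb = _sample(b, "paired_t_with_ci")
        if aa.size != bb.size:
            raise PairingError(
                f"paired samples differ in length: {aa.size} != {bb.size}"
            )
        d = aa - bb
        md = float(np.mean(d))
        sdd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        nn = int(d.size)
    if nn < 2:
        raise SampleSizeError(f"paired_t_with_ci requires n >= 2, got n={nn}")
    if sdd <= 0:
        raise DegenerateVarianceError(
            "paired_t_with_ci: zero variance of differences"
        )
    se = sdd / np.sqrt(nn)
    df = nn - 1
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    tstat = md / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return StatResult(
        test="paired_t",
        estimate=md,
        ci_low=md - tcrit * se,
        ci_high=md + tcrit * se,
        p=p,
        n=nn,
        aux={"t": float(tstat), "df": df, "sd_diff": sdd, "se": float(se)},
    )


def percent_of_mean_with_ci(diff: StatResult, reference_mean: float) -> tuple:
    """(estimate, CI low, CI high) as percent of a reference mean, 2 dp."""
    if reference_mean <= 0:
        raise DomainError(
            f"reference mean must be positive, got {reference_mean}"
        )
    if diff.ci_low is None or diff.ci_high is None:
        raise DomainError("percent_of_mean_with_ci needs a result with a CI")
    return tuple(
        round(100.0 * v / reference_mean, 2)
        for v in (diff.estimate, diff.ci_low, diff.ci_high)
    )


def levene(g1, g2) -> StatResult:
    """Classical Levene test (center = mean) for equality of variances."""
    a = _sample(g1, "levene")
    b = _sample(g2, "levene")
    if a.size < 2 or b.size < 2:
        raise SampleSizeError(
            f"levene requires n >= 2 per group, got {a.size} and {b.size}"
        )
    res = stats.levene(a, b, center="mean")
    return StatResult(
        test="levene",
        estimate=float(res.statistic),
        p=float(res.pvalue),
        n=(int(a.size), int(b.size)),
        aux={"F": float(res.statistic)},
    )


def two_sample_t(g1, g2, alpha: float = 0.05) -> StatResult:
    """Two-sample t-test, Levene-gated between Student and Welch forms.

    Raw samples: pooled (Student) variance when Levene's p > 0.05, else the
    unequal-variance (Welch) form. Summary inputs (:class:`GroupSummary`)
    always use the pooled form, since no per-subject spread is available to
    gate on.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    summary = isinstance(g1, GroupSummary) or isinstance(g2, GroupSummary)
    if summary:
        if not (isinstance(g1, GroupSummary) and isinstance(g2, GroupSummary)):
            raise PairingError(
                "two_sample_t: mix of raw sample and GroupSummary"
            )
        m1, s1, n1 = g1.mean, g1.sd, g1.n
        m2, s2, n2 = g2.mean, g2.sd, g2.n
        pooled = True
        levene_p = None
    else:
        a = _sample(g1, "two_sample_t")
        b = _sample(g2, "two_sample_t")
        if a.size < 2 or b.size < 2:
            raise SampleSizeError(
                f"two_sample_t requires n >= 2 per group, got {a.size} and {b.size}"
            )
        m1, s1, n1 = float(np.mean(a)), float(np.std(a, ddof=1)), int(a.size)
        m2, s2, n2 = float(np.mean(b)), float(np.std(b, ddof=1)), int(b.size)
        if s1 == 0.0 and s2 == 0.0:
            if m1 == m2:
                return StatResult(
                    test="two_sample_t",
                    estimate=0.0,
                    p=1.0,
                    n=(n1, n2),
                    aux={"t": 0.0, "df": n1 + n2 - 2, "pooled": True},
                )
            raise DegenerateVarianceError(
                "two_sample_t: both groups constant with unequal means"
            )
        levene_p = float(levene(a, b).p)
        pooled = levene_p > 0.05
    diff = m1 - m2
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if se == 0.0:
        raise DegenerateVarianceError("two_sample_t: zero standard error")
    tstat = diff / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return StatResult(
        test="two_sample_t",
        estimate=float(diff),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        p=p,
        n=(int(n1), int(n2)),
        aux={
            "t": float(tstat),
            "df": float(df),
            "pooled": bool(pooled),
            "levene_p": levene_p,
        },
    )


def mann_whitney(g1, g2) -> StatResult:
    """Mann-Whitney U; exact when n1*n2 <= 400 with no ties, else normal
    approximation with tie correction. Two-sided."""
    a = _sample(g1, "mann_whitney")
    b = _sample(g2, "mann_whitney")
    if a.size < 1 or b.size < 1:
        raise SampleSizeError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test="mann_whitney",
        estimate=float(res.statistic),
        p=float(res.pvalue),
        n=(int(a.size), int(b.size)),
        aux={"U": float(res.statistic), "method": method},
    )


# ---------------------------------------------------------------------------
# Effect sizes and achieved power
# ---------------------------------------------------------------------------


def cohen_dz(mean_diff: float, sd_diff: float) -> float:
    """Paired effect size dz = mean difference / SD of differences."""
    if sd_diff <= 0:
        raise DomainError(f"sd_diff must be positive, got {sd_diff}")
    return float(mean_diff) / float(sd_diff)


def cohen_d_pooled(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Two-sample effect size |m1 - m2| / pooled SD (n-1 weights)."""
    if s1 <= 0 or s2 <= 0:
        raise DomainError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise SampleSizeError(
            f"cohen_d_pooled requires n >= 2 per group, got {n1} and {n2}"
        )
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float(abs(m1 - m2) / sp)


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")


def _nct_two_tail(tcrit: float, df: float, ncp: float) -> float:
    """P(|T| > tcrit) for noncentral t, robust to scipy deep-tail NaNs.

    scipy's nct evaluation can underflow to NaN in the tail opposite the
    noncentrality when |ncp| is large; that term is negligible there, so a
    non-finite tail is replaced by 0.
    """
    hi = float(stats.nct.sf(tcrit, df, ncp))
    lo = float(stats.nct.cdf(-tcrit, df, ncp))
    if not np.isfinite(hi):
        hi = 0.0
    if not np.isfinite(lo):
        lo = 0.0
    return min(max(hi + lo, 0.0), 1.0)


def power_paired_t(dz: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of the two-sided paired t-test via noncentral t."""
    _check_alpha(alpha)
    if n < 2:
        raise SampleSizeError(f"power_paired_t requires n >= 2, got {n}")
    df = n - 1
    ncp = float(dz) * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return _nct_two_tail(tcrit, df, ncp)


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Achieved power of the two-sided pooled two-sample t-test."""
    _check_alpha(alpha)
    if n1 < 2 or n2 < 2:
        raise SampleSizeError(
            f"power_two_sample_t requires n >= 2 per group, got {n1} and {n2}"
        )
    df = n1 + n2 - 2
    ncp = float(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return _nct_two_tail(tcrit, df, ncp)


def power_correlation_fisher_z(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power to detect a correlation of size rho via the Fisher z approximation."""
    _check_alpha(alpha)
    if not (-1.0 < rho < 1.0):
        raise DomainError(f"|rho| must be < 1, got {rho}")
    if n < 4:
        raise SampleSizeError(
            f"power_correlation_fisher_z requires n >= 4, got {n}"
        )
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zr = abs(np.arctanh(rho)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(zr - za) + stats.norm.cdf(-zr - za))


# ---------------------------------------------------------------------------
# Cohort table I/O and validation
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("subject_id", "sex", "age", "v_total", "v_superimposed")
_SEXES = {"female", "male"}


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort table; derive rtv / pct_si when absent.

    Violations raise :class:`SchemaError` naming the offending rows (1-based
    data row numbers, header excluded).
    """
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {', '.join(missing)}")
    if len(table) == 0:
        raise EmptyInputError("cohort table has no rows")
    t = table.copy()
    problems: list[str] = []

    def check(mask: pd.Series, msg: str) -> None:
        bad = np.flatnonzero(np.asarray(mask))
        if bad.size:
            rows = ", ".join(str(i + 1) for i in bad[:10])
            more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
            problems.append(f"{msg} at row(s) {rows}{more}")

    for col in ("age", "v_total", "v_superimposed"):
        t[col] = pd.to_numeric(t[col], errors="coerce")
        check(t[col].isna(), f"non-numeric {col}")
    t["sex"] = t["sex"].astype(str).str.strip().str.lower()
    check(~t["sex"].isin(_SEXES), "sex must be 'female' or 'male'")
    if not problems:
        check(t["age"] <= 0, "age must be positive")
        check(t["v_total"] <= 0, "v_total must be positive")
        check(t["v_superimposed"] < 0, "v_superimposed must be non-negative")
        check(
            t["v_superimposed"] > t["v_total"] * (1 + 1e-9),
            "v_superimposed exceeds v_total",
        )
    if problems:
        raise SchemaError("; ".join(problems))
    rtv_calc = t["v_total"] - t["v_superimposed"]
    if "rtv" in t.columns:
        t["rtv"] = pd.to_numeric(t["rtv"], errors="coerce")
        check(t["rtv"].isna(), "non-numeric rtv")
        if not problems:
            check(
                (t["rtv"] - rtv_calc).abs() > 1e-6 * t["v_total"],
                "rtv inconsistent with v_total - v_superimposed",
            )
    else:
        t["rtv"] = rtv_calc
    si_calc = 100.0 * t["v_superimposed"] / t["v_total"]
    if "pct_si" in t.columns:
        t["pct_si"] = pd.to_numeric(t["pct_si"], errors="coerce")
        check(t["pct_si"].isna(), "non-numeric pct_si")
        if not problems:
            check(
                (t["pct_si"] - si_calc).abs() > 1e-6 * 100.0,
                "pct_si inconsistent with v_superimposed / v_total",
            )
    else:
        t["pct_si"] = si_calc
    if problems:
        raise SchemaError("; ".join(problems))
    return t


def load_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"cohort file not found: {p}")
    try:
        table = pd.read_csv(p)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse cohort CSV {p}: {exc}") from exc
    return validate_cohort(table)


# ---------------------------------------------------------------------------
# Full analysis report
# ---------------------------------------------------------------------------

_VARIABLES = ("v_total", "v_superimposed", "rtv", "pct_si")


def _try(entry_fn):
    """Run one report entry, collecting sample-size/degeneracy errors."""
    try:
        out = entry_fn()
        return out.as_dict() if isinstance(out, StatResult) else out
    except (SampleSizeError, DegenerateVarianceError, EmptyInputError) as exc:
        return {"error": type(exc).__name__, "message": str(exc)}


def _group_comparison(g1, g2, normal: bool, alpha: float) -> dict:
    """Levene-gated t when the normality gate passes, else Mann-Whitney."""
    if normal:
        return _try(lambda: two_sample_t(g1, g2, alpha=alpha))
    return _try(lambda: mann_whitney(g1, g2))


def _paired_block(df: pd.DataFrame, alpha: float) -> dict:
    block = _try(
        lambda: paired_t_with_ci(
            df["v_total"].to_numpy(), df["v_superimposed"].to_numpy(), alpha=alpha
        )
    )
    if "error" not in block:
        res = StatResult(
            test="paired_t",
            estimate=block["estimate"],
            ci_low=block["ci_low"],
            ci_high=block["ci_high"],
            p=block["p"],
            n=block["n"],
            aux=block["aux"],
        )
        ref = float(df["v_total"].mean())
        pct = percent_of_mean_with_ci(res, ref)
        block["percent_of_mean"] = {
            "reference_mean": ref,
            "estimate": pct[0],
            "ci_low": pct[1],
            "ci_high": pct[2],
        }
        block["cohen_dz"] = round(
            cohen_dz(block["estimate"], block["aux"]["sd_diff"]), 4
        )
        block["achieved_power"] = _try(
            lambda: power_paired_t(
                cohen_dz(block["estimate"], block["aux"]["sd_diff"]),
                int(block["n"]),
                alpha,
            )
        )
    return block


def analysis_report(
    cohort: pd.DataFrame, alpha: float = 0.05, age_cut: int = 21
) -> dict:
    """Full battery on a validated cohort table.

    Descriptives per variable; Shapiro-Wilk gating; total-vs-remaining
    Spearman overall and per subgroup; paired total-vs-superimposed
    comparison with CI, percent-of-mean, dz and achieved power, overall and
    per subgroup; sex and age-group comparisons per variable with the
    Levene-gated t (normal gate passed) or Mann-Whitney; sex effect size and
    its achieved power. Deterministic for a fixed input table.
    """
    df = validate_cohort(cohort)
    groups = {
        "overall": df,
        "female": df[df["sex"] == "female"],
        "male": df[df["sex"] == "male"],
        f"age_lt_{age_cut}": df[df["age"] < age_cut],
        f"age_ge_{age_cut}": df[df["age"] >= age_cut],
    }
    report: dict = {
        "n": int(len(df)),
        "alpha": alpha,
        "age_cut": age_cut,
        "group_sizes": {k: int(len(g)) for k, g in groups.items()},
    }

    report["descriptives"] = {
        name: {var: describe(g[var].to_numpy()) for var in _VARIABLES}
        for name, g in groups.items()
        if len(g) > 0
    }
    report["descriptives"].setdefault("overall", {})["age"] = describe(
        df["age"].to_numpy()
    )

    normality = {}
    gate = {}
    for var in _VARIABLES:
        entry = _try(lambda v=var: shapiro_wilk(df[v].to_numpy()))
        normality[var] = entry
        gate[var] = "error" not in entry and entry["p"] > alpha
    report["normality"] = normality
    report["normal_gate"] = gate

    report["spearman_total_vs_remaining"] = {
        name: _try(
            lambda g=g: spearman(g["v_total"].to_numpy(), g["rtv"].to_numpy())
        )
        for name, g in groups.items()
    }

    report["paired_total_vs_superimposed"] = {
        name: _paired_block(g, alpha) if len(g) > 0 else {"error": "EmptyInputError"}
        for name, g in groups.items()
    }

    female = groups["female"]
    male = groups["male"]
    young = groups[f"age_lt_{age_cut}"]
    old = groups[f"age_ge_{age_cut}"]
    report["sex_comparison"] = {
        var: _group_comparison(
            female[var].to_numpy(), male[var].to_numpy(), gate[var], alpha
        )
        for var in _VARIABLES
    }
    report["age_comparison"] = {
        var: _group_comparison(
            young[var].to_numpy(), old[var].to_numpy(), gate[var], alpha
        )
        for var in _VARIABLES
    }

    def sex_effect():
        d = cohen_d_pooled(
            float(female["v_total"].mean()),
            float(female["v_total"].std(ddof=1)),
            int(len(female)),
            float(male["v_total"].mean()),
            float(male["v_total"].std(ddof=1)),
            int(len(male)),
        )
        return {
            "cohen_d": round(d, 4),
            "achieved_power": power_two_sample_t(
                d, int(len(female)), int(len(male)), alpha
            ),
        }

    report["sex_effect_v_total"] = _try(sex_effect)

    def corr_power():
        rho = report["spearman_total_vs_remaining"]["overall"]
        if "error" in rho:
            raise SampleSizeError(rho["message"])
        return power_correlation_fisher_z(rho["estimate"], int(len(df)), alpha)

    report["correlation_achieved_power"] = _try(corr_power)
    return report
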