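"""Cohort statistics: descriptives, rank tests, regression, and agreement.

Conventions (documented because the comparisons must be reproducible):

* quartiles use linear interpolation between order statistics (the default of
  mainstream statistical environments);
* Spearman p-values use the t approximation for n ≥ 10 and exact permutation
  enumeration below;
* the T0-vs-T1 change test defaults to the two-sample rank-sum form, with the
  conventional paired signed-rank available behind ``mode="signed-rank"``;
* the concordance correlation coefficient uses population (1/n) moments and a
  Fisher-z confidence interval with the asymptotic variance;
* no multiple-testing correction; significance is flagged at p ≤ 0.05.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "DescriptiveSummary",
    "CorrelationResult",
    "WilcoxonResult",
    "JarqueBeraResult",
    "RegressionResult",
    "ConcordanceResult",
    "StatsReport",
    "describe",
    "spearman",
    "wilcoxon_change_test",
    "jarque_bera",
    "univariate_regression",
    "concordance",
    "build_report",
]

SIGNIFICANCE_LEVEL = 0.05


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[~np.isnan(arr)]


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Listwise deletion: drop any pair with a missing member."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.size} vs {y.size}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


@dataclass(frozen=True)
class DescriptiveSummary:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_nonmissing: int


def describe(values) -> DescriptiveSummary:
    """Median / quartile / extrema summary with missing values dropped."""
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError("describe: no non-missing values")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return DescriptiveSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
        n_nonmissing=int(arr.size),
    )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_used: int


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for small n (ties handled via ranks)."""
    n = rx.size
    rx_c = rx - rx.mean()
    denom = math.sqrt(float((rx_c**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    stats = (perms - ry.mean()) @ rx_c / denom
    return float(np.mean(np.abs(stats) >= abs(observed) - 1e-12))


def spearman(x, y, exact_below: int = 10) -> CorrelationResult:
    """Spearman rank correlation with listwise deletion and average ranks.

    Requires at least four complete pairs. The two-sided p-value uses the
    t approximation on the post-deletion sample size (exact permutation below
    ``exact_below`` pairs).
    """
    xc, yc = _complete_pairs(x, y)
    n = xc.size
    if n < 4:
        raise ValueError(f"spearman: need >= 4 complete pairs, got {n}")
    rx = sps.rankdata(xc, method="average")
    ry = sps.rankdata(yc, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("spearman: zero variance in ranks, correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < exact_below:
        p = _spearman_exact_p(rx, ry, rho)
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n_used=n)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    mode: str
    method: str
    n_t0: int
    n_t1: int


def wilcoxon_change_test(t0, t1, mode: str = "rank-sum") -> WilcoxonResult:
    """T0-vs-T1 change test.

    ``mode="rank-sum"`` (default) treats T0 and T1 as two independent groups,
    using the Mann–Whitney form of the rank-sum test: exact p for small
    tie-free samples, normal approximation with continuity correction
    otherwise. ``mode="signed-rank"`` runs the conventional paired test on the
    nonzero differences.
    """
    a = _clean(t0)
    b = _clean(t1)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_change_test: empty input")
    if mode == "rank-sum":
        if a.size < 3 or b.size < 3:
            raise ValueError("rank-sum mode: need >= 3 values per group")
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return WilcoxonResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            mode=mode,
            method=method,
            n_t0=int(a.size),
            n_t1=int(b.size),
        )
    if mode == "signed-rank":
        xp, yp = _complete_pairs(t0, t1)
        diffs = yp - xp
        nonzero = diffs[diffs != 0]
        if nonzero.size < 3:
            raise ValueError(
                "signed-rank mode: need >= 3 nonzero paired differences"
            )
        res = sps.wilcoxon(xp, yp, zero_method="wilcox")
        return WilcoxonResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            mode=mode,
            method="scipy-auto",
            n_t0=int(xp.size),
            n_t1=int(yp.size),
        )
    raise ValueError(f"unknown mode {mode!r}; use 'rank-sum' or 'signed-rank'")


@dataclass(frozen=True)
class JarqueBeraResult:
    statistic: float
    p_value: float
    skewness: float
    kurtosis: float
    n: int


def jarque_bera(values) -> JarqueBeraResult:
    """Jarque–Bera normality test with population moments.

    ``JB = n/6 · (S² + (K − 3)²/4)``; p from χ² with 2 degrees of freedom.
    """
    arr = _clean(values)
    n = arr.size
    if n < 5:
        raise ValueError(f"jarque_bera: need n >= 5, got {n}")
    centered = arr - arr.mean()
    m2 = float((centered**2).mean())
    if m2 == 0:
        raise ValueError("jarque_bera: zero variance")
    s = float((centered**3).mean()) / m2**1.5
    k = float((centered**4).mean()) / m2**2
    jb = n / 6.0 * (s * s + (k - 3.0) ** 2 / 4.0)
    return JarqueBeraResult(
        statistic=float(jb),
        p_value=float(sps.chi2.sf(jb, df=2)),
        skewness=s,
        kurtosis=k,
        n=n,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r2: float
    slope_p_value: float
    n_used: int


def univariate_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with adjusted R².

    ``adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2)``; two-sided slope p-value.
    """
    xc, yc = _complete_pairs(x, y)
    n = xc.size
    if n < 3:
        raise ValueError(f"univariate_regression: need >= 3 complete pairs, got {n}")
    if np.ptp(xc) == 0:
        raise ValueError("univariate_regression: predictor is constant")
    fit = sps.linregress(xc, yc)
    r2 = float(fit.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        adjusted_r2=float(adj),
        slope_p_value=float(fit.pvalue),
        n_used=n,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.ccc <= self.ci_high:
            raise ValueError("confidence interval does not bracket the estimate")


def concordance(x, y, ci_level: float = 0.95) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with a Fisher-z interval.

    ``CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`` with population (1/n)
    moments. The interval transforms the point estimate with atanh and uses
    the asymptotic variance of the transformed statistic.
    """
    xc, yc = _complete_pairs(x, y)
    n = xc.size
    if n < 3:
        raise ValueError(f"concordance: need >= 3 pairs, got {n}")
    mx, my = float(xc.mean()), float(yc.mean())
    sx2 = float(((xc - mx) ** 2).mean())
    sy2 = float(((yc - my) ** 2).mean())
    sxy = float(((xc - mx) * (yc - my)).mean())
    if sx2 == 0 and sy2 == 0:
        raise ValueError("concordance: zero variance in both vectors")
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    if abs(ccc) >= 1.0 - 1e-12 or sx2 == 0 or sy2 == 0:
        return ConcordanceResult(ccc=float(ccc), ci_low=float(ccc), ci_high=float(ccc), n=n)
    r = sxy / math.sqrt(sx2 * sy2)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
    one_m = 1.0 - ccc * ccc
    if r == 0:
        var_z = 1.0 / (n - 2)  # degenerate fallback; CCC ~ 0 here anyway
    else:
        var_z = (
            (1.0 - r * r) * ccc * ccc / (one_m * r * r)
            + 2.0 * ccc**3 * (1.0 - ccc) * u2 / (r * one_m**2)
            - ccc**4 * u2 * u2 / (2.0 * r * r * one_m**2)
        ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    half = sps.norm.ppf(0.5 + ci_level / 2.0) * math.sqrt(var_z)
    return ConcordanceResult(
        ccc=float(ccc),
        ci_low=float(math.tanh(z - half)),
        ci_high=float(math.tanh(z + half)),
        n=n,
    )


# --- report assembly --------------------------------------------------------

DESCRIPTIVE_VARIABLES = [
    "symptom_months",
    "age_years",
    "basal_diameter_um",
    "minimum_diameter_um",
    "la_mm2",
    "norm_la",
    "pra_mm2",
    "norm_pra",
    "piin",
    "ta_mm2",
    "bcva_t0_logmar",
    "delta_bcva_logmar",
    "ez_t0_um",
    "delta_ez_um",
    "elm_t0_um",
    "delta_elm_um",
]

CORRELATION_VARIABLES = [
    "minimum_diameter_um",
    "ta_mm2",
    "bcva_t0_logmar",
    "delta_bcva_logmar",
    "ez_t0_um",
    "delta_ez_um",
    "elm_t0_um",
    "delta_elm_um",
    "symptom_months",
    "age_years",
]

CHANGE_TEST_PAIRS = [
    ("ez_um", "ez_t0_um", "ez_t1_um"),
    ("elm_um", "elm_t0_um", "elm_t1_um"),
    ("bcva_logmar", "bcva_t0_logmar", "bcva_t1_logmar"),
]

GRADER_AREAS = [
    ("la_mm2", "grader2_la_mm2"),
    ("pra_mm2", "grader2_pra_mm2"),
    ("ta_mm2", "grader2_ta_mm2"),
]

_REQUIRED_REPORT_COLUMNS = ["piin", "la_mm2", "pra_mm2", "ta_mm2"]


@dataclass
class StatsReport:
    """Descriptives, index correlations, change tests, regression, agreement."""

    n_eyes: int
    descriptives: dict = field(default_factory=dict)
    normality: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    change_tests: dict = field(default_factory=dict)
    regression: dict | None = None
    concordance: dict | None = None
    categorical: dict = field(default_factory=dict)
    significance_level: float = SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StatsReport":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        lines = [f"Cohort report (n = {self.n_eyes})", ""]
        lines.append("Descriptive statistics (median / q1 / q3 / max / min):")
        for name in DESCRIPTIVE_VARIABLES:
            d = self.descriptives.get(name)
            if d is None:
                continue
            lines.append(
                f"  {name:22s} {d['median']:>10.3f} {d['q1']:>10.3f} "
                f"{d['q3']:>10.3f} {d['max']:>10.3f} {d['min']:>10.3f}"
            )
        if self.categorical:
            for name, counts in self.categorical.items():
                summary = ", ".join(f"{k}: {v}" for k, v in counts.items())
                lines.append(f"  {name:22s} {summary}")
        lines.append("")
        lines.append("Index correlations (Spearman rho, p, n):")
        for name in CORRELATION_VARIABLES:
            c = self.correlations.get(name)
            if c is None:
                continue
            flag = "*" if c["p_value"] <= self.significance_level else " "
            lines.append(
                f"  {name:22s} rho={c['rho']:+.3f}  p={c['p_value']:.3g}{flag}"
                f"  n={c['n_used']}"
            )
        if self.change_tests:
            lines.append("")
            lines.append("T0 vs T1 change tests:")
            for name, t in self.change_tests.items():
                lines.append(
                    f"  {name:22s} stat={t['statistic']:.1f}  p={t['p_value']:.3g}"
                    f"  ({t['mode']})"
                )
        if self.regression is not None:
            r = self.regression
            lines.append("")
            lines.append(
                "Regression |d-BCVA| ~ index: "
                f"slope={r['slope']:.3f} intercept={r['intercept']:.3f} "
                f"adjR2={r['adjusted_r2']:.3f} p={r['slope_p_value']:.3g}"
            )
        if self.concordance is not None:
            lines.append("")
            lines.append("Intergrader agreement (CCC [95% CI]):")
            for name, c in self.concordance.items():
                lines.append(
                    f"  {name:22s} {c['ccc']:.3f} "
                    f"[{c['ci_low']:.3f}, {c['ci_high']:.3f}]  n={c['n']}"
                )
        return "\n".join(lines) + "\n"


def build_report(
    scored: pd.DataFrame,
    change_test_mode: str = "rank-sum",
) -> StatsReport:
    """Assemble the full cohort report from a scored table.

    Emits the descriptive block, the index-vs-variable Spearman block, the
    T0-vs-T1 change tests, the index → |Δ-BCVA| regression, and — when a
    second grader's area columns exist — the agreement block.
    """
    missing = [c for c in _REQUIRED_REPORT_COLUMNS if c not in scored.columns]
    if missing:
        raise KeyError(f"scored cohort missing required columns: {missing}")
    scored = scored.copy()
    if (
        "grader2_ta_mm2" in scored.columns
        and "grader2_la_mm2" in scored.columns
        and "grader2_pra_mm2" not in scored.columns
    ):
        scored["grader2_pra_mm2"] = scored["grader2_ta_mm2"] - scored["grader2_la_mm2"]

    report = StatsReport(n_eyes=int(len(scored)))

    for name in DESCRIPTIVE_VARIABLES:
        if name in scored.columns and scored[name].notna().any():
            report.descriptives[name] = asdict(describe(scored[name]))
            if scored[name].notna().sum() >= 5 and scored[name].nunique() > 1:
                report.normality[name] = asdict(jarque_bera(scored[name]))

    if "sex" in scored.columns:
        counts = scored["sex"].value_counts(dropna=False)
        report.categorical["sex"] = {str(k): int(v) for k, v in counts.items()}

    for name in CORRELATION_VARIABLES:
        if name in scored.columns:
            try:
                report.correlations[name] = asdict(spearman(scored["piin"], scored[name]))
            except ValueError:
                continue

    for label, t0_col, t1_col in CHANGE_TEST_PAIRS:
        if t0_col in scored.columns and t1_col in scored.columns:
            try:
                report.change_tests[label] = asdict(
                    wilcoxon_change_test(
                        scored[t0_col], scored[t1_col], mode=change_test_mode
                    )
                )
            except ValueError:
                continue

    if "delta_bcva_logmar" in scored.columns:
        try:
            report.regression = asdict(
                univariate_regression(scored["piin"], scored["delta_bcva_logmar"])
            )
        except ValueError:
            report.regression = None

    grader_cols = [g2 for _, g2 in GRADER_AREAS if g2 in scored.columns]
    if grader_cols:
        report.concordance = {}
        for g1, g2 in GRADER_AREAS:
            if g2 in scored.columns:
                report.concordance[g1] = asdict(concordance(scored[g1], scored[g2]))
    return report
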