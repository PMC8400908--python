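"""Univariate 2x2 association of binary exposures with bleeding.

Each candidate exposure (grouped genotype, haplotype indicator or clinical
covariate) is cross-tabulated against the outcome on its own complete
cases.  The test is the uncorrected Pearson chi-square when every expected
cell count is at least five, otherwise the two-sided Fisher exact test
(point-probability method).  Odds-ratio confidence intervals use Woolf's
logit method, with a Haldane-Anscombe 0.5 continuity correction (flagged)
when a cell is empty.  No multiplicity correction is applied by default —
mirroring the motivating analysis — but Bonferroni/Benjamini-Hochberg
adjustment is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_io import AnalysisTable

__all__ = [
    "ContingencyTable",
    "ContingencyResult",
    "ScreenResult",
    "crosstab_2x2",
    "association_test",
    "odds_ratio_woolf",
    "univariate_screen",
]

#: Minimum expected cell count for the chi-square test to be used.
EXPECTED_CELL_THRESHOLD = 5.0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows exposed/unexposed, columns outcome/no outcome.

    ``a`` = exposed cases, ``b`` = exposed controls, ``c`` = unexposed
    cases, ``d`` = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    outcome_label: str = "case"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        if t.sum() == 0:
            return t
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass
class TestResult:
    p_value: float
    method: str  # "chi_square" | "fisher_exact" | "degenerate"
    statistic: float


@dataclass
class ContingencyResult:
    """Odds ratio with Woolf CI and the associated test."""

    table: ContingencyTable
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    alpha: float = 0.05
    haldane_corrected: bool = False
    undefined: bool = False
    label: str = ""


@dataclass
class ScreenResult:
    results: dict  # name -> ContingencyResult, ranked by p-value
    selected: list
    alpha: float
    forced: tuple


def crosstab_2x2(exposure: np.ndarray, outcome: np.ndarray,
                 label: str = "exposed") -> ContingencyTable:
    """Cross-tabulate two aligned binary vectors, dropping pairs with a
    missing (NaN) entry in either."""
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if exposure.shape != outcome.shape:
        raise ValueError("exposure and outcome must be aligned")
    ok = ~(np.isnan(exposure) | np.isnan(outcome))
    e, y = exposure[ok], outcome[ok]
    for name, v in (("exposure", e), ("outcome", y)):
        if not set(np.unique(v)) <= {0.0, 1.0}:
            raise ValueError(f"{name} is not binary 0/1")
    return ContingencyTable(
        a=int(((e == 1) & (y == 1)).sum()),
        b=int(((e == 1) & (y == 0)).sum()),
        c=int(((e == 0) & (y == 1)).sum()),
        d=int(((e == 0) & (y == 0)).sum()),
        exposure_label=label,
    )


def association_test(ct: ContingencyTable,
                     expected_threshold: float = EXPECTED_CELL_THRESHOLD) -> TestResult:
    """Uncorrected chi-square if all expected cells >= threshold, else
    two-sided Fisher exact (sum of tables with point probability <= that
    of the observed table)."""
    t = ct.as_array()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin: association test degenerate, p = 1",
                      RuntimeWarning)
        return TestResult(p_value=1.0, method="degenerate", statistic=0.0)
    if ct.expected().min() >= expected_threshold:
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return TestResult(p_value=float(p), method="chi_square",
                          statistic=float(chi2))
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(p_value=float(p), method="fisher_exact",
                      statistic=float(odds))


def odds_ratio_woolf(ct: ContingencyTable, alpha: float = 0.05) -> ContingencyResult:
    """Cross-product odds ratio with Woolf's logit-method CI.

    OR = (a d)/(b c); CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any empty cell triggers a Haldane-Anscombe +0.5 to all cells (flagged);
    a zero cross-product pair (a = d = 0 or b = c = 0) leaves the OR
    undefined (NaN, flagged).
    """
    test = association_test(ct)
    a, b, c, d = float(ct.a), float(ct.b), float(ct.c), float(ct.d)
    undefined = (a == 0 and d == 0) or (b == 0 and c == 0)
    if undefined:
        return ContingencyResult(ct, float("nan"), float("nan"), float("nan"),
                                 test.p_value, test.method, alpha,
                                 haldane_corrected=False, undefined=True)
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_point) - z * se))
    ci_high = float(np.exp(np.log(or_point) + z * se))
    return ContingencyResult(ct, float(or_point), ci_low, ci_high,
                             test.p_value, test.method, alpha,
                             haldane_corrected=haldane)


def univariate_screen(at: AnalysisTable, candidates: Sequence[str] | None = None,
                      alpha: float = 0.05,
                      forced: Sequence[str] = ("age_ge_65", "sex_male"),
                      adjust: str | None = None) -> ScreenResult:
    """Test every candidate exposure against the outcome; select those with
    p < alpha plus the forced clinical confounders (age, sex by default).

    ``adjust`` may be ``"bonferroni"`` or ``"bh"`` to apply a multiplicity
    correction to the p-values before selection (off by default, matching
    the motivating analysis).
    """
    if candidates is None:
        candidates = at.exposure_cols
    y_full = at.frame[at.outcome_col].to_numpy(dtype=float)
    results = {}
    for name in candidates:
        x = at.frame[name].to_numpy(dtype=float)
        ct = crosstab_2x2(x, y_full, label=name)
        res = odds_ratio_woolf(ct, alpha=alpha)
        res.label = name
        results[name] = res
    if adjust:
        names = list(results)
        raw = np.array([results[n].p_value for n in names])
        if adjust == "bonferroni":
            adj = np.minimum(raw * len(raw), 1.0)
        elif adjust == "bh":
            order = np.argsort(raw)
            ranked = raw[order] * len(raw) / (np.arange(len(raw)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(raw)
            adj[order] = np.minimum(ranked, 1.0)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for n, p in zip(names, adj):
            results[n].p_value = float(p)
    ranked = dict(sorted(results.items(), key=lambda kv: kv[1].p_value))
    selected = [n for n, r in ranked.items() if r.p_value < alpha]
    for f in forced:
        if f in results and f not in selected:
            selected.append(f)
    return ScreenResult(results=ranked, selected=selected, alpha=alpha,
                        forced=tuple(forced))
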