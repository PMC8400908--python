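"""Multivariable logistic modelling and clinical risk statistics.

The core fit is a maximum-likelihood logistic regression (Newton-Raphson
via statsmodels) with Wald standard errors from the inverse observed
information.  Backward elimination repeatedly removes the term with the
largest Wald p-value at or above the retention threshold, never removing
forced-in confounders.  Model diagnostics are the Hosmer-Lemeshow
calibration chi-square (df = groups - 2) and the AUROC.

Clinical risk statistics follow the conventions of the motivating
analysis:

- attributable risk (%) = ((AOR - 1)/AOR) x 100, computed on the
  reciprocal for protective terms ("risk attributable to *not* carrying
  the protective diplotype");
- RRR = (AOR - 1)/AOR, ARR = RRR x risk_reference, NNG = ceil(1/ARR),
  where the reference risk convention ("risk without genotyping") is
  configurable and audited side by side because no single convention is
  canonical;
- the weighted risk score (WRS) assigns each retained binary term an
  integer point equal to its rounded beta coefficient (protective terms
  recoded to their absence first, minimum one point), sums points over the
  variables a subject carries, and stratifies subjects at the 25th/75th
  score percentiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .association import crosstab_2x2, odds_ratio_woolf

__all__ = [
    "LogisticFit",
    "EliminationResult",
    "HosmerLemeshowResult",
    "RiskStat",
    "RiskScores",
    "StratifiedRisk",
    "SeparationWarning",
    "fit_logistic_mle",
    "backward_eliminate",
    "hosmer_lemeshow",
    "auroc",
    "attributable_risk",
    "nng",
    "nng_audit",
    "weighted_risk_score",
    "stratify_by_percentile",
]


class SeparationWarning(UserWarning):
    """Quasi-complete separation: coefficients diverging."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    ``terms`` excludes the intercept; ``beta``/``se``/``wald_p`` include it
    under index ``"const"``.  ``aor`` and ``aor_ci`` are exp(beta) with
    Wald 95% limits for the non-intercept terms.
    """

    terms: list
    beta: pd.Series
    se: pd.Series
    wald_p: pd.Series
    aor: pd.Series
    aor_ci: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    gradient_norm: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.beta["const"])
        for t in self.terms:
            eta = eta + self.beta[t] * X[t].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class EliminationResult:
    fit: LogisticFit
    path: list  # (removed term, Wald p at removal), in removal order
    candidates: list
    forced_in: tuple


@dataclass
class HosmerLemeshowResult:
    chi2: float
    df: int
    p_value: float
    g_used: int
    table: pd.DataFrame


@dataclass
class RiskStat:
    """Attributable-risk / NNG record for one model term."""

    term: str
    aor: float
    aor_used: float  # after inversion for protective terms
    inverted: bool
    attributable_risk_pct: float
    rrr: float
    arr: float
    nng: float
    risk_reference: float
    reference_kind: str
    flagged: str = ""


@dataclass
class RiskScores:
    points_map: dict          # reported term (post-recode) -> integer points
    term_recode: dict         # reported term -> (source term, flipped flag)
    wrs: np.ndarray
    rounding: str


@dataclass
class StratifiedRisk:
    cut_low: float
    cut_high: float
    group: np.ndarray         # "low" | "mid" | "high" per subject
    counts: pd.DataFrame      # cases/controls per group
    group_or: dict            # "low"/"high" -> ContingencyResult vs mid


# ---------------------------------------------------------------------------
# model fitting


def _as_design(X: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    return X


def fit_logistic_mle(X: pd.DataFrame, y: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 200,
                     add_intercept: bool = True) -> LogisticFit:
    """Newton-Raphson MLE with Wald SEs from the inverse observed
    information; AOR CIs are exp(beta +/- 1.96 se).

    Rank-deficient designs raise with the aliased columns named; diverging
    coefficients (|beta| > 15) flag non-convergence with a
    :class:`SeparationWarning`.
    """
    Xd = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        aliased = _aliased_columns(Xd)
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    model = sm.Logit(y, Xd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        try:
            res = model.fit(method="newton", tol=tol, maxiter=max_iter, disp=0)
        except np.linalg.LinAlgError:
            # singular Hessian (typically separation): quasi-Newton fallback
            res = model.fit(method="lbfgs", maxiter=10 * max_iter, disp=0)
    beta = res.params
    grad_norm = float(np.linalg.norm(model.score(res.params.to_numpy())))
    converged = bool(res.mle_retvals.get("converged", True))
    # Wald SEs from the pseudo-inverse of the observed information, so a
    # flagged separated fit still returns finite diagnostics where defined
    cov = np.linalg.pinv(-model.hessian(beta.to_numpy()))
    bse = pd.Series(np.sqrt(np.abs(np.diag(cov))), index=Xd.columns)
    wald_p = pd.Series(
        2 * stats.norm.sf(np.abs(beta.to_numpy()) / np.where(bse > 0, bse, np.nan)),
        index=Xd.columns,
    )
    if np.abs(beta.drop("const", errors="ignore")).max() > 15:
        warnings.warn(
            "coefficients diverging (|beta| > 15): quasi-complete separation; "
            "inspect the offending term or collapse sparse categories",
            SeparationWarning,
        )
        converged = False
    terms = [c for c in Xd.columns if c != "const"]
    z = stats.norm.ppf(0.975)
    aor = np.exp(beta[terms])
    ci = pd.DataFrame(
        {
            "low": np.exp(beta[terms] - z * bse[terms]),
            "high": np.exp(beta[terms] + z * bse[terms]),
        },
        index=terms,
    )
    return LogisticFit(
        terms=terms,
        beta=beta,
        se=bse,
        wald_p=wald_p,
        aor=aor,
        aor_ci=ci,
        loglik=float(res.llf),
        n=len(y),
        converged=converged,
        gradient_norm=grad_norm,
    )


def _aliased_columns(Xd: pd.DataFrame) -> list:
    cols = list(Xd.columns)
    kept: list = []
    aliased = []
    M = Xd.to_numpy()
    for j, c in enumerate(cols):
        trial = M[:, [cols.index(k) for k in kept] + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(c)
        else:
            aliased.append(c)
    return aliased


def backward_eliminate(X: pd.DataFrame, y: np.ndarray,
                       candidates: Sequence[str],
                       forced_in: Sequence[str] = (),
                       alpha: float = 0.05) -> EliminationResult:
    """Backward elimination on Wald p-values.

    Starting from ``candidates`` plus ``forced_in``, refit after removing
    the term with the largest Wald p >= alpha until every removable term
    has p < alpha.  Forced-in terms are never removed.  The elimination
    path is deterministic given the design (largest-p ties broken by
    column name).
    """
    candidates = list(dict.fromkeys(candidates))
    forced_in = tuple(forced_in)
    missing = [c for c in list(candidates) + list(forced_in) if c not in X.columns]
    if missing:
        raise KeyError(f"candidate terms not in design: {missing}")
    current = list(dict.fromkeys(list(candidates) + list(forced_in)))
    path = []
    while True:
        fit = fit_logistic_mle(X[current], y)
        removable = [t for t in current if t not in forced_in]
        if not removable:
            break
        pvals = fit.wald_p[removable]
        worst_p = pvals.max()
        if worst_p < alpha:
            break
        worst = sorted(pvals.index[pvals == worst_p])[0]
        path.append((worst, float(worst_p)))
        current.remove(worst)
        if not current:
            fit = fit_logistic_mle(X[[]], y)
            break
    return EliminationResult(fit=fit, path=path, candidates=candidates,
                             forced_in=forced_in)


# ---------------------------------------------------------------------------
# diagnostics


def hosmer_lemeshow(probs: np.ndarray, y: np.ndarray,
                    g: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow calibration test.

    Subjects are ranked by fitted probability and split into ``g``
    quantile groups with tied fitted values kept together;
    chi2 = sum (O - E)^2 / (E (1 - E/n_g)) over groups, df = groups - 2.
    If ties collapse groups, the reduced group count is used (warned) and
    the df follows.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if g < 3:
        raise ValueError("need at least 3 groups")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, g + 1)[1:-1]))
    group = np.searchsorted(edges, probs, side="right")
    labels = np.unique(group)
    if len(labels) < g:
        warnings.warn(
            f"tied fitted probabilities reduced the groups to {len(labels)}",
            RuntimeWarning,
        )
    if len(labels) < 3:
        warnings.warn("fewer than 3 distinct risk groups: test undefined",
                      RuntimeWarning)
        return HosmerLemeshowResult(float("nan"), 0, float("nan"),
                                    len(labels), pd.DataFrame())
    rows = []
    chi2 = 0.0
    for lab in labels:
        sel = group == lab
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(probs[sel].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        rows.append({"n": n_g, "observed": obs, "expected": exp,
                     "mean_prob": float(probs[sel].mean())})
    df = len(labels) - 2
    p = float(stats.chi2.sf(chi2, df))
    return HosmerLemeshowResult(float(chi2), df, p, len(labels),
                                pd.DataFrame(rows))


def auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity;
    ties count one half."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: only one outcome class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# risk statistics


def attributable_risk(aor: float) -> tuple:
    """Attributable risk percent, ((AOR - 1)/AOR) x 100.

    Protective odds ratios (AOR < 1) are inverted first — the statistic
    then reads "risk attributable to not having the protective factor".

    Returns ``(percent, aor_used, inverted)``.
    """
    if aor <= 0:
        raise ValueError("adjusted odds ratio must be positive")
    inverted = aor < 1.0
    aor_used = 1.0 / aor if inverted else aor
    pct = (aor_used - 1.0) / aor_used * 100.0
    return float(pct), float(aor_used), inverted


def nng(aor: float, risk_reference: float,
        reference_kind: str = "overall_incidence",
        term: str = "") -> RiskStat:
    """Number needed to genotype.

    RRR = (AOR - 1)/AOR on the risk-direction odds ratio (protective AORs
    inverted, as in :func:`attributable_risk`); ARR = RRR x
    ``risk_reference``; NNG = ceil(1/ARR).  ``reference_kind`` records the
    provenance of the reference risk (overall cohort incidence,
    reference-group incidence, or a user-supplied value).
    """
    if not 0.0 < risk_reference < 1.0:
        raise ValueError("risk_reference must lie in (0, 1)")
    pct, aor_used, inverted = attributable_risk(aor)
    rrr = (aor_used - 1.0) / aor_used
    flagged = ""
    if rrr <= 0:
        return RiskStat(term, aor, aor_used, inverted, pct, rrr, 0.0,
                        float("inf"), risk_reference, reference_kind,
                        flagged="null effect: NNG infinite")
    arr = rrr * risk_reference
    n = math.ceil(1.0 / arr)
    if n > 10_000:
        flagged = "near-null effect: NNG impractically large"
    return RiskStat(term, aor, aor_used, inverted, pct, rrr, arr, float(n),
                    risk_reference, reference_kind, flagged=flagged)


def nng_audit(aor: float, overall_incidence: float,
              exposed_risk: float | None = None,
              unexposed_risk: float | None = None,
              term: str = "") -> dict:
    """NNG under every available reference-risk convention, side by side.

    The motivating analysis does not state which reference risk its NNG
    used, so downstream reports should show all conventions.
    """
    out = {"overall_incidence": nng(aor, overall_incidence,
                                    "overall_incidence", term)}
    if exposed_risk is not None:
        out["exposed_group_incidence"] = nng(aor, exposed_risk,
                                             "exposed_group_incidence", term)
    if unexposed_risk is not None:
        out["unexposed_group_incidence"] = nng(aor, unexposed_risk,
                                               "unexposed_group_incidence", term)
    return out


# ---------------------------------------------------------------------------
# weighted risk score


def weighted_risk_score(fit: LogisticFit, X: pd.DataFrame,
                        rounding: str = "nearest_int") -> RiskScores:
    """Integer-point weighted risk score from a fitted model.

    Each retained binary term contributes points equal to its beta rounded
    to the nearest integer (minimum one point); protective terms (beta <
    0) are recoded to their absence — the indicator is flipped and the
    beta's sign with it — before rounding.  ``rounding="raw_beta"`` skips
    rounding, making the score the linear predictor minus the intercept
    (on the recoded indicators).
    """
    if rounding not in ("nearest_int", "raw_beta"):
        raise ValueError("rounding must be 'nearest_int' or 'raw_beta'")
    points_map: dict = {}
    recode: dict = {}
    wrs = np.zeros(len(X), dtype=float)
    for term in fit.terms:
        x = X[term].to_numpy(dtype=float)
        if set(np.unique(x[~np.isnan(x)])) - {0.0, 1.0}:
            raise ValueError(f"WRS requires binary terms; {term!r} is not")
        beta = float(fit.beta[term])
        name = term
        if beta < 0:
            x = 1.0 - x
            beta = -beta
            name = f"no_{term}"
        if rounding == "nearest_int":
            pts = max(1.0, float(math.floor(beta + 0.5)))
        else:
            pts = beta
        points_map[name] = pts
        recode[name] = (term, name != term)
        wrs += pts * x
    return RiskScores(points_map=points_map, term_recode=recode, wrs=wrs,
                      rounding=rounding)


def stratify_by_percentile(wrs: np.ndarray, outcome: np.ndarray,
                           q: tuple = (25, 75),
                           cuts: tuple | None = None) -> StratifiedRisk:
    """Stratify subjects at score percentiles and compare the outer groups
    to the middle by odds ratio.

    Cut points default to the empirical ``q`` percentiles of the score
    (``cuts`` overrides, e.g. to apply published cut points).  Tie policy:
    low group takes scores <= the lower cut, high group scores >= the
    upper cut, middle is the strict interior — with integer scores the
    group sizes therefore deviate from the nominal quartile split.
    """
    wrs = np.asarray(wrs, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if cuts is None:
        cut_low, cut_high = (float(np.percentile(wrs, qq)) for qq in q)
    else:
        cut_low, cut_high = map(float, cuts)
    if cut_low >= cut_high or np.unique(wrs).size == 1:
        warnings.warn("degenerate score distribution: single stratum",
                      RuntimeWarning)
        group = np.full(len(wrs), "mid", dtype=object)
        counts = _strata_counts(group, outcome)
        return StratifiedRisk(cut_low, cut_high, group, counts, {})
    group = np.where(wrs <= cut_low, "low",
                     np.where(wrs >= cut_high, "high", "mid")).astype(object)
    counts = _strata_counts(group, outcome)
    group_or = {}
    for g in ("low", "high"):
        if (group == g).sum() == 0:
            continue
        sel = (group == g) | (group == "mid")
        ct = crosstab_2x2((group[sel] == g).astype(float), outcome[sel],
                          label=f"{g} vs mid")
        group_or[g] = odds_ratio_woolf(ct)
    return StratifiedRisk(cut_low, cut_high, group, counts, group_or)


def _strata_counts(group: np.ndarray, outcome: np.ndarray) -> pd.DataFrame:
    rows = []
    for g in ("low", "mid", "high"):
        sel = group == g
        rows.append({"group": g, "n": int(sel.sum()),
                     "cases": int(outcome[sel].sum()),
                     "controls": int(sel.sum() - outcome[sel].sum())})
    return pd.DataFrame(rows).set_index("group")
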