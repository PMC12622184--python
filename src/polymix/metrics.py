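"""Case-control evaluation battery for one standardized score.

Covers the usual PGS reporting set:

* OR per SD with Wald 95% CI and p-value, from logistic regression of case
  status on the score corrected for age and sex (optionally plus PCs);
* AUROC from the score's ranks (a univariate logistic model is monotone in
  the score, so its AUROC equals the rank AUROC), with a Hanley–McNeil CI;
* AUPRC as average precision (step-wise, no interpolation);
* incremental Nagelkerke R-squared over an age+sex base model,
  (R2_full - R2_base) / (1 - R2_base);
* liability-scale R-squared via the Lee et al. (2012) transformation of the
  observed-scale case-control R-squared, with ascertainment correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score

from polymix.combine import _fit_logit  # shared logistic backend


@dataclass
class EstimateCI:
    estimate: float
    ci_low: float
    ci_high: float


@dataclass
class ORResult:
    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float


@dataclass
class MetricReport:
    """Full evaluation of one score in one validation cohort."""

    or_per_sd: ORResult
    auroc: EstimateCI
    auprc: float
    ngk_r2_incremental: float
    liab_r2: float
    prevalence_K: float
    n_cases: int
    n_controls: int

    def to_flat_dict(self) -> dict:
        return {
            "or_per_sd": self.or_per_sd.or_per_sd,
            "or_ci_low": self.or_per_sd.ci_low,
            "or_ci_high": self.or_per_sd.ci_high,
            "p_value": self.or_per_sd.p_value,
            "auroc": self.auroc.estimate,
            "auroc_ci_low": self.auroc.ci_low,
            "auroc_ci_high": self.auroc.ci_high,
            "auprc": self.auprc,
            "ngk_r2_incremental": self.ngk_r2_incremental,
            "liab_r2": self.liab_r2,
            "prevalence_K": self.prevalence_K,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _check_classes(case: np.ndarray) -> tuple[int, int]:
    n_case = int(case.sum())
    n_ctrl = len(case) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError(f"degenerate classes: {n_case} cases / {n_ctrl} controls")
    return n_case, n_ctrl


def or_per_sd(score, case, age, sex, pcs: np.ndarray | None = None) -> ORResult:
    """Odds ratio per SD of the score from multivariate logistic regression.

    The model is case ~ score + age + sex, optionally extended with PC
    columns (used by the stratification analyses). Wald 95% CI.
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=float)
    _check_classes(case)
    if np.std(score) == 0.0:
        raise ValueError("zero variance predictor")
    cols = [np.ones(len(score)), score, np.asarray(age, dtype=float),
            np.asarray(sex, dtype=float)]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        cols.extend(pcs[:, j] for j in range(pcs.shape[1]))
    design = np.column_stack(cols)
    res = _fit_logit(case, design)
    beta = float(res.params[1])
    se = float(res.bse[1])
    return ORResult(
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(res.pvalues[1]),
        beta=beta,
        se=se,
    )


def auroc(score, case) -> EstimateCI:
    """Probability a random case outranks a random control; ties count half.

    Computed from midranks (the Mann–Whitney U statistic); CI by the
    Hanley–McNeil variance approximation, clipped to [0, 1].
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=int)
    n1, n0 = _check_classes(case)
    ranks = rankdata(score)
    u = ranks[case == 1].sum() - n1 * (n1 + 1) / 2.0
    a = u / (n1 * n0)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    return EstimateCI(float(a), float(max(a - 1.96 * se, 0.0)),
                      float(min(a + 1.96 * se, 1.0)))


def auprc(score, case) -> float:
    """Area under the precision-recall curve as average precision.

    Step-wise sum of precision x recall increments over descending score
    thresholds; no linear interpolation (interpolation inflates AUPRC).
    In the null limit this equals the case fraction.
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=int)
    _check_classes(case)
    return float(average_precision_score(case, score))


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo R-squared from model and intercept-only log-likelihoods."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_r2)


def nagelkerke_incremental(score, case, age, sex) -> float:
    """Incremental Nagelkerke R2 of the score over an age+sex base model.

    (R2_full - R2_base) / (1 - R2_base), with full = score + age + sex.
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    _check_classes(case)
    n = len(case)
    ones = np.ones(n)
    full = _fit_logit(case, np.column_stack([ones, score, age, sex]))
    base = _fit_logit(case, np.column_stack([ones, age, sex]))
    ll_null = float(full.llnull)
    r2_full = nagelkerke_r2(float(full.llf), ll_null, n)
    r2_base = nagelkerke_r2(float(base.llf), ll_null, n)
    return (r2_full - r2_base) / (1.0 - r2_base)


def observed_scale_incremental_r2(score, case, age, sex) -> float:
    """Incremental linear-model R2 of case status on the observed 0/1 scale.

    Linear-probability fits of case ~ score + age + sex versus
    case ~ age + sex; returns (R2_full - R2_base) / (1 - R2_base). This is
    the observed-scale quantity the Lee liability transformation expects.
    """
    case = np.asarray(case, dtype=float)
    _check_classes(case)
    n = len(case)
    ones = np.ones(n)

    def r2(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, case, rcond=None)
        resid = case - design @ coef
        tss = np.sum((case - case.mean()) ** 2)
        return 1.0 - float(np.sum(resid**2)) / tss

    base = r2(np.column_stack([ones, np.asarray(age, float), np.asarray(sex, float)]))
    full = r2(np.column_stack([ones, np.asarray(score, float),
                               np.asarray(age, float), np.asarray(sex, float)]))
    return (full - base) / (1.0 - base)


def liability_r2(r2_obs: float, K: float, P: float) -> float:
    """Lee et al. (2012) observed-to-liability-scale R-squared transformation.

    With t = the liability threshold (upper-K quantile of the standard
    normal), z = phi(t) the normal density there, and m = z/K the mean
    liability of cases:

        C     = K^2 (1-K)^2 / (z^2 P (1-P))
        theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t)
        R2_l  = C R2_obs / (1 + C theta R2_obs)

    ``K`` is the population prevalence, ``P`` the case fraction in the
    analysis sample; theta vanishes when P == K (no ascertainment).
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0,1), got {K}")
    if not 0.0 < P < 1.0:
        raise ValueError(f"case fraction P must lie in (0,1), got {P}")
    t = norm.isf(K)
    z = norm.pdf(t)
    m = z / K
    c = K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))
    d = m * (P - K) / (1.0 - K)
    theta = d * (d - t)
    return float(c * r2_obs / (1.0 + c * theta * r2_obs))


def evaluate_score(score, case, age, sex, prevalence_K: float | None = None,
                   pcs: np.ndarray | None = None) -> MetricReport:
    """Run the full battery for one standardized score in one cohort.

    ``prevalence_K`` is the population prevalence used for the liability
    conversion; ``None`` falls back to the sample case fraction (no
    ascertainment correction).
    """
    case_arr = np.asarray(case, dtype=int)
    n_cases, n_controls = _check_classes(case_arr)
    p_frac = n_cases / len(case_arr)
    k = p_frac if prevalence_K is None else float(prevalence_K)
    r2_obs = observed_scale_incremental_r2(score, case_arr, age, sex)
    return MetricReport(
        or_per_sd=or_per_sd(score, case_arr, age, sex, pcs=pcs),
        auroc=auroc(score, case_arr),
        auprc=auprc(score, case_arr),
        ngk_r2_incremental=nagelkerke_incremental(score, case_arr, age, sex),
        liab_r2=liability_r2(r2_obs, k, p_frac),
        prevalence_K=k,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def reports_to_tsv(reports: dict[str, MetricReport], path) -> None:
    """Flat TSV, one row per (score x cohort) label."""
    rows = []
    for label, rep in reports.items():
        row = {"label": label}
        row.update(rep.to_flat_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
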