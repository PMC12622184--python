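"""Percentile-based risk stratification and extreme-tail group search.

Persons are binned into 100 score percentiles (ceil-rank with average
ties); per-bin disease prevalence gets Wilson 95% CIs. The extreme-tail
search scans candidate tail cuts on a fixed grid from the 50% tail inward
and returns the largest contiguous tail whose odds ratio versus the middle
quintile (percentiles 40-60, half-open (40, 60]) meets a fold criterion —
e.g. at least 3-, 4- or 5-fold increased odds for the upper tail, or at
most 1/3-fold for the lower tail. The criterion uses the OR point estimate
by default; a CI-bound variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from polymix.combine import SeparationError, _fit_logit


@dataclass
class PercentileTable:
    """Per-percentile counts and prevalence with Wilson 95% CIs."""

    table: pd.DataFrame  # percentile, n, n_cases, prevalence, ci_low, ci_high

    def __post_init__(self) -> None:
        t = self.table
        required = {"percentile", "n", "n_cases", "prevalence", "ci_low", "ci_high"}
        if not required.issubset(t.columns):
            raise ValueError(f"percentile table lacks columns {required - set(t.columns)}")

    @property
    def total_n(self) -> int:
        return int(self.table["n"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class TailResult:
    """Outcome of the iterative tail search for one fold threshold.

    ``found`` is False when no grid cut met the criterion; then
    ``or_estimate`` carries the best (most extreme) OR achieved and
    ``cut_percentile`` is NaN.
    """

    side: str
    fold_threshold: float
    found: bool
    cut_percentile: float
    proportion_of_population: float
    or_estimate: float
    or_ci_low: float
    or_ci_high: float
    n_tail: int
    n_reference: int

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "fold_threshold": self.fold_threshold,
            "found": self.found,
            "cut_percentile": self.cut_percentile,
            "proportion_of_population": self.proportion_of_population,
            "or_estimate": self.or_estimate,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "n_tail": self.n_tail,
            "n_reference": self.n_reference,
        }


def tails_to_tsv(results: list[TailResult], path) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def assign_percentiles(score) -> np.ndarray:
    """Percentile bin 1..100 per person: ceil(100 * rank / n), average ranks for ties."""
    score = np.asarray(score, dtype=float)
    n = len(score)
    if n < 100:
        raise ValueError(f"need at least 100 persons for percentile bins, got {n}")
    ranks = rankdata(score)  # average ties
    return np.ceil(100.0 * ranks / n).astype(int)


def prevalence_by_percentile(percentiles, case) -> PercentileTable:
    """Per-bin prevalence with Wilson 95% confidence intervals."""
    percentiles = np.asarray(percentiles, dtype=int)
    case = np.asarray(case, dtype=int)
    rows = []
    for p in np.unique(percentiles):
        mask = percentiles == p
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty percentile bin {p}")
        k = int(case[mask].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((int(p), n, k, k / n, float(lo), float(hi)))
    return PercentileTable(pd.DataFrame(
        rows, columns=["percentile", "n", "n_cases", "prevalence", "ci_low", "ci_high"]))


def percentile_distribution_summary(percentiles, case) -> dict[str, dict[str, float]]:
    """Median and IQR of the percentile variable, separately for cases and controls."""
    percentiles = np.asarray(percentiles, dtype=float)
    case = np.asarray(case, dtype=int)
    out = {}
    for label, mask in (("cases", case == 1), ("controls", case == 0)):
        vals = percentiles[mask]
        if len(vals) == 0:
            raise ValueError(f"no {label} in cohort")
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out[label] = {"median": float(med), "q25": float(q25), "q75": float(q75)}
    return out


def middle_quintile_mask(score) -> np.ndarray:
    """Reference group: percentile bins in the half-open quintile (40, 60]."""
    perc = assign_percentiles(score)
    return (perc > 40) & (perc <= 60)


def tail_grid(step: float = 0.1) -> np.ndarray:
    """Candidate tail sizes in percent of the population, 50 down to ``step``."""
    if step <= 0 or step > 50:
        raise ValueError("step must lie in (0, 50]")
    n_steps = int(round(50.0 / step))
    return np.round(50.0 - step * np.arange(n_steps), 10)


def tail_odds_ratio(score, case, cut: float, side: str,
                    covariates: np.ndarray | None = None,
                    middle: np.ndarray | None = None):
    """OR of tail membership versus the middle quintile at one candidate cut.

    The tail is the top (or bottom) ``cut`` percent of the score
    distribution by percentile rank; the logistic model is
    case ~ tail + covariates, restricted to tail-or-middle persons.
    Persons falling in both (cuts above 40%) count as tail.

    Returns (or, ci_low, ci_high, n_tail, n_reference).
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=float)
    n = len(score)
    pr = 100.0 * rankdata(score) / n
    if side == "upper":
        tail = pr > 100.0 - cut
    elif side == "lower":
        tail = pr <= cut
    else:
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    if middle is None:
        middle = middle_quintile_mask(score)
    if not middle.any():
        raise ValueError("middle quintile is empty")
    use = tail | middle
    x = tail[use].astype(float)
    y = case[use]
    if x.sum() == 0:
        raise ValueError(f"empty tail at cut {cut}")
    cols = [np.ones(int(use.sum())), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov[use, j] for j in range(cov.shape[1]))
    res = _fit_logit(y, np.column_stack(cols))
    beta, se = float(res.params[1]), float(res.bse[1])
    return (float(np.exp(beta)), float(np.exp(beta - 1.96 * se)),
            float(np.exp(beta + 1.96 * se)), int(tail.sum()),
            int((middle & ~tail).sum()))


def find_extreme_tail(score, case, fold: float, side: str = "upper",
                      step: float = 0.1,
                      covariates: np.ndarray | None = None,
                      use_ci_bound: bool = False) -> TailResult:
    """Largest contiguous score tail meeting a fold-change odds criterion.

    Scans candidate cuts from the 50% tail inward on a fixed grid
    (:func:`tail_grid`); at each cut a logistic regression of case status on
    tail membership plus ``covariates``, restricted to tail-or-middle-quintile
    persons, yields the OR versus the middle quintile. The first (largest)
    cut whose OR point estimate is >= ``fold`` (upper) or <= ``fold``
    (lower) is returned; if no cut qualifies the result carries the best
    achieved OR with ``found=False``.
    """
    if side == "upper" and fold < 1.0:
        raise ValueError("upper-tail fold threshold must be >= 1")
    if side == "lower" and not 0.0 < fold <= 1.0:
        raise ValueError("lower-tail fold threshold must lie in (0, 1]")
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=float)
    n = len(score)
    middle = middle_quintile_mask(score)
    best_or = None
    best = None
    n_separated = 0
    n_fits = 0
    for cut in tail_grid(step):
        try:
            est = tail_odds_ratio(score, case, cut, side,
                                  covariates=covariates, middle=middle)
        except SeparationError:
            n_separated += 1
            continue
        except ValueError:
            continue  # empty tail at tiny cuts
        n_fits += 1
        orr, lo, hi, n_tail, n_ref = est
        crit = lo if (use_ci_bound and side == "upper") else (
            hi if use_ci_bound else orr)
        meets = crit >= fold if side == "upper" else crit <= fold
        if meets:
            return TailResult(side, fold, True, float(cut),
                              100.0 * n_tail / n, orr, lo, hi, n_tail, n_ref)
        better = (best_or is None or
                  (side == "upper" and orr > best_or) or
                  (side == "lower" and orr < best_or))
        if better:
            best_or = orr
            best = (cut, est)
    if n_fits == 0:
        raise SeparationError("all tail fits separated or empty; no OR estimable")
    cut, (orr, lo, hi, n_tail, n_ref) = best
    return TailResult(side, fold, False, float("nan"),
                      100.0 * n_tail / n, orr, lo, hi, n_tail, n_ref)
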