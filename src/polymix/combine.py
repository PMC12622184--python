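"""Multi-score combination: mixing weights from a tuning set.

Several component polygenic scores (one per trait, already residualized and
standardized) are combined into a single score by one joint logistic
regression of case status on all components, with no covariates
("unadjusted"). The fitted coefficients are the mixing weights; their
positive parts, normalized to sum to 100, are the scaled per-trait
contributions. Plain maximum-likelihood logistic regression is used — no
penalty — and collinearity is surfaced, not silently regularized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)


class SeparationError(ValueError):
    """Perfect separation: the joint logistic fit is degenerate."""


class CollinearityError(ValueError):
    """Component score columns are linearly dependent."""


@dataclass
class MixingModel:
    """Per-trait combination coefficients plus scaled contributions.

    ``coefficients`` are log-odds per SD of each component score (signed;
    negative coefficients are retained in the combination). The scaled
    contributions floor negatives at zero and normalize the rest to 100%.
    """

    trait_names: list[str]
    coefficients: np.ndarray
    intercept: float
    tuning_set_id: str = "tuning"
    ancestry_tuning: str = "ALL"
    scaled_contributions: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.trait_names):
            raise ValueError("coefficient count does not match trait_names")
        if self.scaled_contributions is None:
            self.scaled_contributions = scale_contributions(self.coefficients)
        else:
            self.scaled_contributions = np.asarray(self.scaled_contributions, dtype=float)
        total = np.nansum(self.scaled_contributions)
        if np.isfinite(total) and abs(total - 100.0) > 1e-9 and not np.isnan(
            self.scaled_contributions
        ).all():
            raise ValueError(f"scaled contributions sum to {total}, expected 100")

    def to_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "tuning_set_id": self.tuning_set_id,
            "ancestry_tuning": self.ancestry_tuning,
            "scaled_contributions": [float(c) for c in self.scaled_contributions],
        }

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MixingModel":
        return cls(
            trait_names=list(d["trait_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            tuning_set_id=d.get("tuning_set_id", "tuning"),
            ancestry_tuning=d.get("ancestry_tuning", "ALL"),
            scaled_contributions=np.asarray(d["scaled_contributions"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "MixingModel":
        with open(path, "rt") as fh:
            return cls.from_dict(json.load(fh))


def scale_contributions(coefficients: np.ndarray) -> np.ndarray:
    """Floor negative coefficients at 0 and normalize the rest to 100%.

    Signed shares cannot be meaningfully normalized to 100%, so negative
    mixing weights contribute 0% while remaining active in the linear
    combination itself. All-nonpositive coefficients give NaN contributions
    with a warning.
    """
    pos = np.clip(np.asarray(coefficients, dtype=float), 0.0, None)
    total = pos.sum()
    if total == 0.0:
        warnings.warn("no positive mixing weights: scaled contributions undefined")
        return np.full(len(pos), np.nan)
    return pos / total * 100.0


def _fit_logit(y: np.ndarray, design: np.ndarray, maxiter: int = 100):
    """Unpenalized logistic fit; raises SeparationError on (near-)separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                "perfect separation detected; refusing to report mixing weights"
            ) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            f"logistic fit did not converge within {maxiter} iterations"
        )
    return res


def fit_mixing_weights(scores: pd.DataFrame, case, tuning_set_id: str = "tuning",
                       ancestry_tuning: str = "ALL",
                       min_class_size: int = 20) -> MixingModel:
    """Joint unadjusted logistic regression of case status on all component scores.

    Parameters
    ----------
    scores
        One column per component trait (adjusted, standardized scores),
        column order defining the trait order of the model.
    case
        Binary outcome vector aligned with ``scores`` rows.

    Raises on fewer than two traits, fewer than ``min_class_size`` cases or
    controls, collinear components, or perfect separation.
    """
    case = np.asarray(case, dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 component traits; see two_score_combine")
    n_case = int(case.sum())
    n_ctrl = len(case) - n_case
    if n_case < min_class_size or n_ctrl < min_class_size:
        raise ValueError(
            f"tuning set has {n_case} cases / {n_ctrl} controls; "
            f"need at least {min_class_size} of each"
        )
    X = scores.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(case)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (scores.columns[i], scores.columns[j])
            for i in range(X.shape[1])
            for j in range(i + 1, X.shape[1])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(
            f"component scores are collinear (degenerate pairs: {pairs}); "
            "remove or merge duplicated components"
        )
    res = _fit_logit(case, design)
    # Contributions are scale-free: normalize per-SD coefficients so that
    # rescaling any component leaves the reported percentages unchanged.
    # For standardized inputs (the intended use) SDs are 1 and this is a no-op.
    per_sd = res.params[1:] * X.std(axis=0, ddof=1)
    return MixingModel(
        trait_names=list(scores.columns),
        coefficients=res.params[1:],
        intercept=float(res.params[0]),
        tuning_set_id=tuning_set_id,
        ancestry_tuning=ancestry_tuning,
        scaled_contributions=scale_contributions(per_sd),
    )


def apply_mixing(model: MixingModel, scores: pd.DataFrame) -> np.ndarray:
    """Linear combination sum_t coef_t * score_t (intercept omitted).

    The intercept is irrelevant because the combined score is re-standardized
    before evaluation. Raises on trait-set mismatch or an all-zero model.
    """
    if list(scores.columns) != list(model.trait_names):
        raise ValueError(
            f"trait mismatch: model has {model.trait_names}, "
            f"scores have {list(scores.columns)}"
        )
    if np.all(model.coefficients == 0.0):
        raise ValueError("degenerate mixing model: all coefficients are zero")
    return scores.to_numpy(dtype=float) @ model.coefficients


def two_score_combine(primary, all_ancestry, case,
                      trait_names: tuple[str, str] = ("primary", "all_ancestry"),
                      tuning_set_id: str = "tuning",
                      ancestry_tuning: str = "ALL") -> MixingModel:
    """Two-component special case: one ancestry-specific and one all-ancestry score.

    Weights derive from the joint predictive performance in the tuning set —
    the same unadjusted logistic fit as :func:`fit_mixing_weights`.
    """
    df = pd.DataFrame({
        trait_names[0]: np.asarray(primary, dtype=float),
        trait_names[1]: np.asarray(all_ancestry, dtype=float),
    })
    return fit_mixing_weights(df, case, tuning_set_id=tuning_set_id,
                              ancestry_tuning=ancestry_tuning)
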