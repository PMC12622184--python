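"""Population-structure adjustment of raw polygenic scores.

Raw scores are regressed on the leading principal components (OLS with
intercept) within a reference set, the residuals extracted, then
standardized to mean zero / SD one using the reference set's moments.
Ancestry subsetting happens AFTER standardization, so ancestry-specific
subsets need not be centred — that order is the contract, not an accident.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class AdjustedScore:
    """A residualized (and possibly standardized) score vector.

    ``coefficients`` holds the fitted OLS coefficients (intercept first,
    then one per PC) so the same projection can be applied to held-out
    persons. ``mean``/``sd`` are the standardization moments of the
    reference set (``None`` until :func:`standardize` runs).
    """

    person_ids: list[str]
    values: np.ndarray
    reference_set_id: str
    n_pcs: int
    coefficients: np.ndarray | None = None
    mean: float | None = None
    sd: float | None = None

    @property
    def standardized(self) -> bool:
        return self.sd is not None

    def __len__(self) -> int:
        return len(self.values)


def _find_collinear_columns(design: np.ndarray) -> list[int]:
    """Identify PC columns (0-based, excluding intercept) spanned by earlier ones."""
    bad = []
    for j in range(1, design.shape[1]):
        prior = design[:, :j]
        col = design[:, j]
        resid = col - prior @ np.linalg.lstsq(prior, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(col), 1.0):
            bad.append(j - 1)
    return bad


def residualize_on_pcs(scores: np.ndarray, pcs: np.ndarray, n_pcs: int,
                       person_ids: list[str] | None = None,
                       reference_set_id: str = "reference") -> AdjustedScore:
    """OLS-residualize a score vector on an intercept plus the first n_pcs PCs.

    Returns the residuals together with the fitted coefficients so the same
    projection can be applied to held-out persons via :func:`project`.
    Raises on missing values or a rank-deficient PC design (the offending
    PC columns are named).
    """
    scores = np.asarray(scores, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    if n_pcs > pcs.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} but only {pcs.shape[1]} PCs available")
    if np.isnan(scores).any() or np.isnan(pcs[:, :n_pcs]).any():
        raise ValueError("missing values in scores or PCs")
    n = len(scores)
    used = pcs[:, :n_pcs]
    # All-zero PCs carry no structure: keep a zero coefficient, skip the fit.
    nonzero = np.any(used != 0.0, axis=0)
    design = np.column_stack([np.ones(n), used[:, nonzero]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _find_collinear_columns(design)
        names = [f"PC{np.flatnonzero(nonzero)[j] + 1}" for j in bad]
        raise ValueError(
            f"rank-deficient PC matrix: PC column(s) {names} "
            "are collinear with earlier columns"
        )
    fit_coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    resid = scores - design @ fit_coef
    coef = np.zeros(n_pcs + 1)
    coef[0] = fit_coef[0]
    coef[1:][nonzero] = fit_coef[1:]
    if person_ids is None:
        person_ids = [str(i) for i in range(n)]
    return AdjustedScore(list(person_ids), resid, reference_set_id, n_pcs,
                         coefficients=coef)


def project(fitted: AdjustedScore, scores: np.ndarray, pcs: np.ndarray,
            person_ids: list[str] | None = None) -> AdjustedScore:
    """Apply a previously fitted residualization (and standardization) to new data.

    For leakage-averse workflows: fit in a tuning set, project onto held-out
    persons. The default pipeline instead fits within the evaluation set
    itself, mirroring common practice for PGS evaluation.
    """
    if fitted.coefficients is None:
        raise ValueError("fitted AdjustedScore carries no regression coefficients")
    scores = np.asarray(scores, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    design = np.column_stack([np.ones(len(scores)), pcs[:, :fitted.n_pcs]])
    resid = scores - design @ fitted.coefficients
    if fitted.standardized:
        resid = (resid - fitted.mean) / fitted.sd
    if person_ids is None:
        person_ids = [str(i) for i in range(len(scores))]
    return AdjustedScore(list(person_ids), resid, fitted.reference_set_id,
                         fitted.n_pcs, coefficients=fitted.coefficients,
                         mean=fitted.mean, sd=fitted.sd)


def standardize(adjusted: AdjustedScore) -> AdjustedScore:
    """Scale to mean zero, SD one using the reference set's moments.

    Sample SD (n-1 denominator). Idempotent: standardizing an already
    standardized score re-centres with (0, 1) moments to machine precision.
    Raises on zero variance.
    """
    vals = np.asarray(adjusted.values, dtype=float)
    mu = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot standardize a constant score")
    out = (vals - mu) / sd
    # Moments of the ORIGINAL reference scale are what held-out projection needs.
    if adjusted.standardized:
        mean, scale = adjusted.mean + mu * adjusted.sd, adjusted.sd * sd
    else:
        mean, scale = mu, sd
    return replace(adjusted, values=out, mean=mean, sd=scale)


def adjust_scores(scores: np.ndarray, pcs: np.ndarray, n_pcs: int = 20,
                  person_ids: list[str] | None = None,
                  reference_set_id: str = "reference") -> AdjustedScore:
    """Residualize on PCs then standardize — the full adjustment contract."""
    return standardize(residualize_on_pcs(scores, pcs, n_pcs,
                                          person_ids=person_ids,
                                          reference_set_id=reference_set_id))
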