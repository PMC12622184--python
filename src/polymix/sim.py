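"""Synthetic multi-ancestry cohort generation under a logit-liability model.

The generator emulates the statistical structure a PGS evaluation assumes:
per-person trait-level polygenic scores with a chosen correlation matrix,
ancestry-separating principal components, age and sex covariates, and a
binary disease outcome drawn from a logistic liability whose intercept is
solved per ancestry so that the expected prevalence matches a target K.

Ancestry labels default to the EUR / AFR / AMR / ASN convention (ASN being
a single merged Asian group) but any labels are accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

SCORE_PREFIX = "score_"

#: Ancestry offsets are placed on the unit circle in the (PC1, PC2) plane,
#: scaled by ``pc_separation``; remaining PCs are pure noise.
def _ancestry_offsets(n_groups: int) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n_groups) / max(n_groups, 1)
    return np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Parameters
    ----------
    n_per_ancestry
        Ancestry label -> number of persons.
    prevalence
        Ancestry label -> target disease prevalence K in (0, 1).
    trait_names
        Ordered component-trait names, e.g. ``["AF", "HF", "BMI", ...]``.
    score_corr
        Symmetric positive-definite trait-score correlation matrix with unit
        diagonal; ``None`` means independent scores.
    liability_loadings
        Ancestry label -> per-trait log-odds contribution of one unit of the
        (standard-normal) trait score to the disease liability. Differing
        vectors model cross-ancestry attenuation.
    age_range
        ``(min, max)`` age in years; ages are drawn uniformly and entered
        into the liability standardized by the closed-form uniform moments.
    beta_age, beta_sex
        Log-odds per SD of age and per unit of sex (sex ~ Bernoulli(0.5)).
    n_pcs
        Number of principal components carried on each person (default 20).
    pc_separation
        Scale of the between-ancestry offsets on PC1/PC2.
    n_variants
        If positive, :func:`emit_genotype_layer` can attach a genotype layer
        with this many variants; 0 means trait scores are emitted directly.
    seed
        Master seed; identical configs give byte-identical cohorts.
    """

    n_per_ancestry: Mapping[str, int]
    prevalence: Mapping[str, float]
    trait_names: Sequence[str]
    score_corr: np.ndarray | None = None
    liability_loadings: Mapping[str, Sequence[float]] | None = None
    age_range: tuple[float, float] = (40.0, 75.0)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    n_pcs: int = 20
    pc_separation: float = 3.0
    n_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_names = list(self.trait_names)
        if self.score_corr is not None:
            self.score_corr = np.asarray(self.score_corr, dtype=float)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def ancestries(self) -> list[str]:
        return list(self.n_per_ancestry)

    def resolved_corr(self) -> np.ndarray:
        if self.score_corr is None:
            return np.eye(self.n_traits)
        return self.score_corr

    def loadings_for(self, ancestry: str) -> np.ndarray:
        if self.liability_loadings is None:
            return np.zeros(self.n_traits)
        return np.asarray(self.liability_loadings[ancestry], dtype=float)

    def validate(self) -> None:
        if not self.n_per_ancestry:
            raise ValueError("n_per_ancestry is empty")
        for anc, n in self.n_per_ancestry.items():
            if n <= 0:
                raise ValueError(f"non-positive cohort size for ancestry {anc!r}")
            if anc not in self.prevalence:
                raise ValueError(f"no prevalence given for ancestry {anc!r}")
        for anc, k in self.prevalence.items():
            if not 0.0 < k < 1.0:
                raise ValueError(f"prevalence for {anc!r} must lie in (0,1), got {k}")
        corr = self.resolved_corr()
        if corr.shape != (self.n_traits, self.n_traits):
            raise ValueError("score_corr shape does not match trait_names")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("score_corr must have unit diagonal")
        if not np.allclose(corr, corr.T):
            raise ValueError("score_corr must be symmetric")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("score_corr is not positive definite") from exc
        if self.liability_loadings is not None:
            for anc in self.n_per_ancestry:
                lv = self.loadings_for(anc)
                if lv.shape != (self.n_traits,):
                    raise ValueError(
                        f"liability_loadings[{anc!r}] has length {lv.size}, "
                        f"expected {self.n_traits}"
                    )
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")


@dataclass
class Cohort:
    """A simulated (or loaded) cohort.

    ``df`` carries one row per person with columns ``person_id``,
    ``ancestry``, ``age``, ``sex``, ``case``, ``PC1..PCn`` and one
    ``score_<trait>`` column per trait (raw scale).
    """

    df: pd.DataFrame
    trait_names: list[str] = field(default_factory=list)
    n_pcs: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pc_columns(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_pcs)]

    def pcs(self) -> np.ndarray:
        return self.df[self.pc_columns].to_numpy(dtype=float)

    def trait_scores(self) -> pd.DataFrame:
        """Raw trait scores as a DataFrame indexed like ``df``, one column per trait."""
        cols = {t: self.df[SCORE_PREFIX + t] for t in self.trait_names}
        return pd.DataFrame(cols)

    def subset(self, mask: np.ndarray | pd.Series) -> "Cohort":
        return Cohort(self.df.loc[mask].reset_index(drop=True), list(self.trait_names), self.n_pcs)

    def by_ancestry(self, ancestry: str) -> "Cohort":
        return self.subset((self.df["ancestry"] == ancestry).to_numpy())

    def assert_evaluable(self) -> None:
        """Every ancestry group must contain at least one case and one control."""
        for anc, grp in self.df.groupby("ancestry"):
            n_case = int(grp["case"].sum())
            if n_case == 0 or n_case == len(grp):
                raise ValueError(
                    f"ancestry {anc!r} has {n_case} cases out of {len(grp)}; "
                    "evaluation needs both classes"
                )

    def to_phenotype_tsv(self, path, include_scores: bool = False) -> None:
        cols = ["person_id", "ancestry", "age", "sex", "case"] + self.pc_columns
        if include_scores:
            cols += [SCORE_PREFIX + t for t in self.trait_names]
        self.df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_phenotype_tsv(cls, path) -> "Cohort":
        df = pd.read_csv(path, sep="\t")
        pc_cols = [c for c in df.columns if c.startswith("PC") and c[2:].isdigit()]
        traits = [c[len(SCORE_PREFIX):] for c in df.columns if c.startswith(SCORE_PREFIX)]
        return cls(df, traits, len(pc_cols))


def _solve_intercept(eta: np.ndarray, target_k: float, tol: float = 1e-3,
                     max_iter: int = 100) -> float:
    """Bisect the liability intercept so mean(expit(c + eta)) == target_k.

    Raises if the target prevalence is unreachable within ``max_iter``
    bisection steps given the spread of ``eta``.
    """
    lo, hi = -40.0, 40.0

    def f(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target_k

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"target prevalence {target_k} unreachable given liability spread"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    raise ValueError(
        f"prevalence calibration did not converge to {target_k} "
        f"within {max_iter} bisection iterations"
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a multi-ancestry cohort from the logit-liability model.

    Per person: trait scores ~ MVN(0, score_corr); PCs standard normal with
    ancestry offsets on PC1/PC2; age ~ U(age_range); sex ~ Bernoulli(0.5);
    disease from logit P(case) = intercept_a + loadings_a . scores
    + beta_age * age_std + beta_sex * sex, with intercept_a solved by
    bisection so the expected prevalence equals ``prevalence[a]`` (tol 1e-3).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    corr = config.resolved_corr()
    chol = np.linalg.cholesky(corr)
    offsets = _ancestry_offsets(len(config.ancestries))
    lo_age, hi_age = config.age_range
    age_mu = 0.5 * (lo_age + hi_age)
    age_sd = (hi_age - lo_age) / math.sqrt(12.0)

    frames = []
    counter = 0
    for idx, anc in enumerate(config.ancestries):
        n = int(config.n_per_ancestry[anc])
        k = float(config.prevalence[anc])
        loadings = config.loadings_for(anc)

        age = rng.uniform(lo_age, hi_age, size=n)
        sex = rng.integers(0, 2, size=n)
        scores = rng.standard_normal((n, config.n_traits)) @ chol.T
        pcs = rng.standard_normal((n, config.n_pcs))
        pcs[:, 0] += config.pc_separation * offsets[idx, 0]
        if config.n_pcs > 1:
            pcs[:, 1] += config.pc_separation * offsets[idx, 1]

        age_std = (age - age_mu) / age_sd
        eta = scores @ loadings + config.beta_age * age_std + config.beta_sex * sex
        intercept = _solve_intercept(eta, k)
        case = (rng.random(n) < expit(intercept + eta)).astype(int)

        data = {
            "person_id": [f"P{counter + i:07d}" for i in range(n)],
            "ancestry": anc,
            "age": age,
            "sex": sex,
            "case": case,
        }
        counter += n
        for j in range(config.n_pcs):
            data[f"PC{j + 1}"] = pcs[:, j]
        for j, t in enumerate(config.trait_names):
            data[SCORE_PREFIX + t] = scores[:, j]
        frames.append(pd.DataFrame(data))

    df = pd.concat(frames, ignore_index=True)
    return Cohort(df, list(config.trait_names), config.n_pcs)


def split_tuning_validation(cohort: Cohort, tuning_fraction: float,
                            seed: int) -> tuple[Cohort, Cohort]:
    """Plain random split into a tuning set and a validation (testing) set.

    The split is unstratified random over persons. Partitions are disjoint,
    exhaustive, and reproducible under ``seed``.
    """
    if not 0.0 < tuning_fraction < 1.0:
        raise ValueError("tuning_fraction must lie strictly in (0,1)")
    n = len(cohort)
    n_tune = int(round(tuning_fraction * n))
    if n_tune == 0 or n_tune == n:
        raise ValueError(
            f"tuning_fraction {tuning_fraction} yields an empty partition at n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tune_idx = np.sort(perm[:n_tune])
    valid_idx = np.sort(perm[n_tune:])
    return (
        Cohort(cohort.df.iloc[tune_idx].reset_index(drop=True), list(cohort.trait_names), cohort.n_pcs),
        Cohort(cohort.df.iloc[valid_idx].reset_index(drop=True), list(cohort.trait_names), cohort.n_pcs),
    )


def emit_genotype_layer(cohort: Cohort, config: SimConfig, seed: int,
                        missing_fraction: float = 0.0,
                        regenerate_case: bool = True):
    """Attach a genotype layer consistent with the cohort's trait scores.

    Draws per-variant allele frequencies uniform on [0.05, 0.95], dosages
    binomial(2, f), and per-trait weights iid normal (sd 1/sqrt(n_variants)).
    Each ``score_<trait>`` column of ``cohort`` is REPLACED in place by the
    dot product of the complete dosage matrix with that trait's weights, so
    a scoring engine run on the emitted files can be checked against cohort
    truth. A ``missing_fraction`` of dosage entries is then masked.

    Because the replacement severs the original scores' link to disease,
    ``regenerate_case`` (default) redraws case status from the same
    logit-liability model using the new scores, standardized by their exact
    binomial moments (mean 2 f w, variance 2 f (1-f) w^2 summed over
    variants), with the intercept re-solved per ancestry.

    Returns ``(DosageMatrix, {trait: ScoringModel})``.
    """
    from polymix.scoring import DosageMatrix, ScoringModel

    m = config.n_variants
    if m <= 0:
        raise ValueError("n_variants must be positive to emit a genotype layer")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must lie in [0,1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    freqs = rng.uniform(0.05, 0.95, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)

    bases = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    oth_idx = (eff_idx + shift) % 4
    effect_alleles = bases[eff_idx]
    other_alleles = bases[oth_idx]
    variant_ids = [f"rs{i + 1}" for i in range(m)]
    positions = np.arange(1, m + 1) * 1000

    models: dict[str, ScoringModel] = {}
    score_moments: dict[str, tuple[float, float]] = {}
    for t in cohort.trait_names:
        weights = rng.normal(0.0, 1.0 / math.sqrt(m), size=m)
        cohort.df[SCORE_PREFIX + t] = dosages @ weights
        score_moments[t] = (
            float(np.sum(2.0 * freqs * weights)),
            float(np.sqrt(np.sum(2.0 * freqs * (1.0 - freqs) * weights**2))),
        )
        records = pd.DataFrame(
            {
                "rsID": variant_ids,
                "chr_name": 1,
                "chr_position": positions,
                "effect_allele": effect_alleles,
                "other_allele": other_alleles,
                "effect_weight": weights,
            }
        )
        models[t] = ScoringModel(records, headers=[f"#trait={t}", "#genome_build=GRCh38"])

    if regenerate_case:
        std_scores = np.column_stack([
            (cohort.df[SCORE_PREFIX + t].to_numpy() - score_moments[t][0])
            / score_moments[t][1]
            for t in cohort.trait_names
        ])
        lo_age, hi_age = config.age_range
        age_mu = 0.5 * (lo_age + hi_age)
        age_sd = (hi_age - lo_age) / math.sqrt(12.0)
        age_std = (cohort.df["age"].to_numpy() - age_mu) / age_sd
        sex = cohort.df["sex"].to_numpy()
        anc_labels = cohort.df["ancestry"].to_numpy()
        case = np.empty(n, dtype=int)
        for anc in config.ancestries:
            mask = anc_labels == anc
            if not mask.any():
                continue
            eta = (std_scores[mask] @ config.loadings_for(anc)
                   + config.beta_age * age_std[mask] + config.beta_sex * sex[mask])
            intercept = _solve_intercept(eta, float(config.prevalence[anc]))
            case[mask] = (rng.random(int(mask.sum())) < expit(intercept + eta)).astype(int)
        cohort.df["case"] = case

    if missing_fraction > 0:
        mask = rng.random((n, m)) < missing_fraction
        dosages = dosages.copy()
        dosages[mask] = np.nan

    matrix = DosageMatrix(
        person_ids=list(cohort.df["person_id"]),
        variant_ids=variant_ids,
        counted_alleles=list(effect_alleles),
        dosages=dosages,
    )
    return matrix, models
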