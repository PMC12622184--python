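"""End-to-end study pipeline: simulate -> score -> adjust -> combine -> evaluate.

Replicates the standard evaluation design for combined polygenic scores: a
cohort is split into a tuning set (mixing weights are fitted there) and a
validation set (all reporting happens there); per-ancestry metric reports
are produced for every single-trait score, for the combined score under
ancestry-specific tuning, and for the combined score under pooled tuning.
Percentile stratification and extreme-tail search run on one designated
ancestry. A manifest records seeds, counts and artifact hashes, and a
leakage check asserts that no person sits in both sets.

All randomness flows from a single master seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polymix._version import __version__ as _pkg_version
from polymix.adjust import adjust_scores
from polymix.combine import MixingModel, apply_mixing, fit_mixing_weights
from polymix.metrics import MetricReport, evaluate_score, reports_to_tsv
from polymix.scoring import (
    compute_scores,
    read_raw,
    read_scoring_file,
    write_raw,
    write_scoring_file,
)
from polymix.sim import Cohort, SimConfig, emit_genotype_layer, simulate_cohort, split_tuning_validation
from polymix.strata import (
    PercentileTable,
    TailResult,
    assign_percentiles,
    find_extreme_tail,
    percentile_distribution_summary,
    prevalence_by_percentile,
    tails_to_tsv,
)

log = logging.getLogger("polymix.pipeline")

_STAGES = {"simulate": 0, "genotypes": 1, "split": 2}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    sim: SimConfig
    tuning_fraction: float = 0.3
    n_pcs: int = 20
    seed: int = 0
    out_dir: str = "polymix_out"
    folds: tuple[float, ...] = (3.0, 4.0, 5.0)
    lower_fold: float = 1.0 / 3.0
    stratify_ancestry: str | None = None
    stratify_step: float = 0.5
    stratify_pcs: int | None = None
    missing_fraction: float = 0.0
    #: ancestries tuned on the pooled tuning set MINUS themselves (the
    #: strategy used when an ancestry's own tuning subset is too small).
    tune_on_rest: tuple[str, ...] = ()

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 < self.tuning_fraction < 1.0:
            raise ValueError("tuning_fraction must lie in (0,1)")
        if self.n_pcs > self.sim.n_pcs:
            raise ValueError("n_pcs exceeds the PCs carried by the simulation")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        sim_raw = dict(raw.pop("sim"))
        if "score_corr" in sim_raw and sim_raw["score_corr"] is not None:
            sim_raw["score_corr"] = np.asarray(sim_raw["score_corr"], dtype=float)
        if "age_range" in sim_raw:
            sim_raw["age_range"] = tuple(sim_raw["age_range"])
        sim = SimConfig(**sim_raw)
        for key in ("folds", "tune_on_rest"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


@dataclass
class StudyResult:
    reports: dict[str, MetricReport]
    mixing_models: dict[str, MixingModel]
    percentile_table: PercentileTable | None
    percentile_summary: dict | None
    tails: list[TailResult]
    manifest: dict
    out_dir: Path


def _adjusted_trait_frame(cohort: Cohort, n_pcs: int, set_id: str) -> pd.DataFrame:
    """Residualize + standardize every trait score within this set."""
    pcs = cohort.pcs()
    out = {}
    for t in cohort.trait_names:
        adj = adjust_scores(cohort.df[f"score_{t}"].to_numpy(), pcs, n_pcs,
                            person_ids=list(cohort.df["person_id"]),
                            reference_set_id=set_id)
        out[t] = adj.values
    return pd.DataFrame(out)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full study and write the report bundle to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.seed)

    # --- simulate -----------------------------------------------------------
    sim_cfg = replace(config.sim, seed=stage_seed(master, "simulate"))
    cohort = simulate_cohort(sim_cfg)
    log.info("simulated %d persons (%d cases) across %s",
             len(cohort), int(cohort.df["case"].sum()), sim_cfg.ancestries)

    # --- optional genotype layer + scoring engine round trip ----------------
    genotype_files: list[Path] = []
    if sim_cfg.n_variants > 0:
        matrix, models = emit_genotype_layer(
            cohort, sim_cfg, stage_seed(master, "genotypes"),
            missing_fraction=config.missing_fraction)
        raw_path = out / "genotypes.raw"
        write_raw(matrix, raw_path)
        genotype_files.append(raw_path)
        matrix = read_raw(raw_path)
        for t, model in models.items():
            spath = out / f"weights_{t}.txt"
            write_scoring_file(model, spath)
            genotype_files.append(spath)
            model = read_scoring_file(spath)
            result = compute_scores(model, matrix, mode="sum")
            cohort.df[f"score_{t}"] = result.scores["score"].to_numpy()
        log.info("scored %d variants for %d traits via the scoring engine",
                 sim_cfg.n_variants, len(models))

    cohort.assert_evaluable()

    # --- split --------------------------------------------------------------
    tune, valid = split_tuning_validation(cohort, config.tuning_fraction,
                                          stage_seed(master, "split"))
    tune_ids = set(tune.df["person_id"])
    valid_ids = set(valid.df["person_id"])
    if tune_ids & valid_ids:
        raise RuntimeError("tuning/validation leakage: shared person ids")
    log.info("split: %d tuning / %d validation", len(tune), len(valid))

    # --- adjust within each set ----------------------------------------------
    tune_adj = _adjusted_trait_frame(tune, config.n_pcs, "tuning")
    valid_adj = _adjusted_trait_frame(valid, config.n_pcs, "validation")

    # --- mixing models --------------------------------------------------------
    mixing: dict[str, MixingModel] = {}
    mixing["ALL"] = fit_mixing_weights(tune_adj, tune.df["case"].to_numpy(),
                                       tuning_set_id="tuning", ancestry_tuning="ALL")
    for anc in sim_cfg.ancestries:
        if anc in config.tune_on_rest:
            mask = (tune.df["ancestry"] != anc).to_numpy()
        else:
            mask = (tune.df["ancestry"] == anc).to_numpy()
        case_sub = tune.df.loc[mask, "case"].to_numpy()
        n_case = int(case_sub.sum())
        if n_case < 20 or (mask.sum() - n_case) < 20:
            log.warning("skipping ancestry-tuned model for %s: "
                        "%d cases / %d controls in tuning subset",
                        anc, n_case, int(mask.sum()) - n_case)
            continue
        mixing[anc] = fit_mixing_weights(
            tune_adj.loc[mask], case_sub, tuning_set_id="tuning",
            ancestry_tuning=("ALL_minus_" + anc) if anc in config.tune_on_rest else anc)

    # --- evaluate in validation ----------------------------------------------
    valid_pcs = valid.pcs()[:, : config.n_pcs]
    reports: dict[str, MetricReport] = {}

    def eval_in_ancestry(values: np.ndarray, anc: str, label: str) -> None:
        mask = (valid.df["ancestry"] == anc).to_numpy()
        sub = valid.df.loc[mask]
        k = float(sub["case"].mean())
        reports[label] = evaluate_score(
            values[mask], sub["case"].to_numpy(), sub["age"].to_numpy(),
            sub["sex"].to_numpy(), prevalence_K=k)

    combined_pooled = adjust_scores(apply_mixing(mixing["ALL"], valid_adj),
                                    valid_pcs, config.n_pcs,
                                    reference_set_id="validation").values
    combined_anc: dict[str, np.ndarray] = {}
    for anc in sim_cfg.ancestries:
        for t in cohort.trait_names:
            eval_in_ancestry(valid_adj[t].to_numpy(), anc, f"{t}|{anc}")
        eval_in_ancestry(combined_pooled, anc, f"combined_pooled|{anc}")
        if anc in mixing:
            vals = adjust_scores(apply_mixing(mixing[anc], valid_adj),
                                 valid_pcs, config.n_pcs,
                                 reference_set_id="validation").values
            combined_anc[anc] = vals
            eval_in_ancestry(vals, anc, f"combined_ancestry|{anc}")

    # --- stratification in the designated ancestry ----------------------------
    target = config.stratify_ancestry
    if target is None:
        target = valid.df["ancestry"].value_counts().idxmax()
    strat_score = combined_anc.get(target, combined_pooled)
    mask = (valid.df["ancestry"] == target).to_numpy()
    sub = valid.df.loc[mask]
    perc_table = None
    perc_summary = None
    tails: list[TailResult] = []
    if mask.sum() >= 100 and 0 < sub["case"].sum() < len(sub):
        perc = assign_percentiles(strat_score[mask])
        perc_table = prevalence_by_percentile(perc, sub["case"].to_numpy())
        perc_summary = percentile_distribution_summary(perc, sub["case"].to_numpy())
        n_strat_pcs = config.stratify_pcs if config.stratify_pcs is not None else config.n_pcs
        cov = np.column_stack([sub["age"].to_numpy(), sub["sex"].to_numpy(),
                               sub[[f"PC{i+1}" for i in range(n_strat_pcs)]].to_numpy()])
        for fold in config.folds:
            tails.append(find_extreme_tail(strat_score[mask], sub["case"].to_numpy(),
                                           fold, side="upper",
                                           step=config.stratify_step, covariates=cov))
        tails.append(find_extreme_tail(strat_score[mask], sub["case"].to_numpy(),
                                       config.lower_fold, side="lower",
                                       step=config.stratify_step, covariates=cov))
        log.info("stratified %s: %d upper folds, lower fold %.3g",
                 target, len(config.folds), config.lower_fold)
    else:
        log.warning("stratification skipped for %s: too few persons or one class",
                    target)

    # --- write outputs ---------------------------------------------------------
    reports_to_tsv(reports, out / "metrics.tsv")
    contrib_rows = []
    for anc, model in mixing.items():
        for t, coef, contrib in zip(model.trait_names, model.coefficients,
                                    model.scaled_contributions):
            contrib_rows.append({"tuning": anc, "trait": t,
                                 "coefficient": coef, "contribution_pct": contrib})
    pd.DataFrame(contrib_rows).to_csv(out / "contributions.tsv", sep="\t",
                                      index=False, float_format="%.8g")
    if perc_table is not None:
        perc_table.to_tsv(out / "percentiles.tsv")
    else:
        (out / "percentiles.tsv").write_text("percentile\tn\tn_cases\tprevalence\tci_low\tci_high\n")
    tails_to_tsv(tails, out / "tails.tsv")
    (out / "tuning_ids.txt").write_text("\n".join(sorted(tune_ids)) + "\n")
    (out / "validation_ids.txt").write_text("\n".join(sorted(valid_ids)) + "\n")

    artifacts = ["metrics.tsv", "contributions.tsv", "percentiles.tsv",
                 "tails.tsv", "tuning_ids.txt", "validation_ids.txt"]
    artifacts += [p.name for p in genotype_files]
    manifest = {
        "polymix_version": _pkg_version,
        "master_seed": master,
        "stage_seeds": {s: stage_seed(master, s) for s in _STAGES},
        "counts": {
            "n_total": len(cohort),
            "n_tuning": len(tune),
            "n_validation": len(valid),
            "cases_by_ancestry": {
                anc: int(cohort.df.loc[cohort.df["ancestry"] == anc, "case"].sum())
                for anc in sim_cfg.ancestries
            },
        },
        "leakage_free": True,
        "stratify_ancestry": target,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2)

    return StudyResult(reports, mixing, perc_table, perc_summary, tails,
                       manifest, out)


def check_manifest(out_dir) -> None:
    """Verify artifact hashes and the tuning/validation leakage guard."""
    out = Path(out_dir)
    with open(out / "manifest.json", "rt") as fh:
        manifest = json.load(fh)
    for name, digest in manifest["artifacts"].items():
        actual = _sha256(out / name)
        if actual != digest:
            raise RuntimeError(f"artifact {name} hash mismatch")
    tune_ids = set((out / "tuning_ids.txt").read_text().split())
    valid_ids = set((out / "validation_ids.txt").read_text().split())
    shared = tune_ids & valid_ids
    if shared:
        raise RuntimeError(f"leakage: {len(shared)} person id(s) in both sets")
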