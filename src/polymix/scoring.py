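"""Per-person polygenic scoring from weight files and dosage matrices.

Reproduces PLINK2 ``--score`` semantics: allele matching with strand-flip
resolution, mean-dosage imputation of missing genotypes, and sum or average
scoring modes. Scoring files follow the PGS Catalog dialect (``#`` header
lines, then tab-separated ``rsID  chr_name  chr_position  effect_allele
other_allele  effect_weight``); dosages come from PLINK ``.raw`` text
exports or VCF (DS field preferred, GT hard calls otherwise).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_ID_ALIASES = ("rsID", "variant_id", "ID", "rsid", "id", "SNP")
_COL_RENAME = {
    "chr_name": "chromosome",
    "chr_position": "position",
    "effect_weight": "weight",
}


def _complement(allele: str) -> str | None:
    if len(allele) == 1:
        return _COMPLEMENT.get(allele.upper())
    return None


def _is_ambiguous_pair(effect: str, other: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved."""
    return _complement(effect) == other.upper() if other else False


@dataclass
class ScoringModel:
    """One trait's per-variant effect weights.

    ``records`` has columns ``variant_id``, ``chromosome``, ``position``,
    ``effect_allele``, ``other_allele``, ``weight``. ``headers`` preserves
    the ``#``-prefixed metadata lines of the source file.
    """

    records: pd.DataFrame
    headers: list[str] = field(default_factory=list)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        df = self.records.rename(columns={**_COL_RENAME, **{a: "variant_id" for a in _ID_ALIASES}})
        for col in ("chromosome", "position", "other_allele"):
            if col not in df.columns:
                df[col] = pd.NA
        df = df[["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "weight"]].copy()
        df["variant_id"] = df["variant_id"].astype(str)
        df["weight"] = df["weight"].astype(float)
        dup = df["variant_id"][df["variant_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate variant id(s) in scoring model: {sorted(set(dup))}")
        if not np.isfinite(df["weight"]).all():
            raise ValueError("scoring model contains non-finite weights")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def flagged_alleles(self) -> list[str]:
        """Variant ids whose alleles are not single A/C/G/T bases."""
        ok = self.records["effect_allele"].str.fullmatch("[ACGTacgt]")
        oth = self.records["other_allele"].astype("string")
        ok &= oth.isna() | oth.str.fullmatch("[ACGTacgt]").fillna(False)
        return list(self.records.loc[~ok.fillna(False), "variant_id"])


@dataclass
class DosageMatrix:
    """Persons x variants dosage matrix with counted-allele annotation.

    Entries lie in [0, 2]; missing genotypes are NaN.
    """

    person_ids: list[str]
    variant_ids: list[str]
    counted_alleles: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.person_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix dimensions do not match id lists")
        if len(self.counted_alleles) != m:
            raise ValueError("counted_alleles length does not match variant count")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosage entries must lie within [0, 2]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


def read_scoring_file(path) -> ScoringModel:
    """Parse a PGS-Catalog-style scoring file.

    ``#``-prefixed header lines are preserved as metadata. Rows with
    non-finite weights are rejected and counted. Raises on missing mandatory
    columns (an identifier, ``effect_allele``, ``effect_weight``), duplicate
    variant ids, or a file with no records.
    """
    headers: list[str] = []
    body_lines: list[str] = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                headers.append(line.rstrip("\n"))
            else:
                body_lines.append(line)
    if not body_lines or all(not ln.strip() for ln in body_lines):
        raise ValueError(f"no records in scoring file {path}")
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")
    id_col = next((c for c in _ID_ALIASES if c in df.columns), None)
    missing = [name for name, ok in
               [("identifier", id_col is not None),
                ("effect_allele", "effect_allele" in df.columns),
                ("effect_weight", "effect_weight" in df.columns)] if not ok]
    if missing:
        raise ValueError(f"scoring file {path} lacks mandatory column(s): {missing}")
    if len(df) == 0:
        raise ValueError(f"no records in scoring file {path}")
    weights = pd.to_numeric(df["effect_weight"], errors="coerce")
    bad = ~np.isfinite(weights)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} row(s) with non-finite weights in {path}")
        df = df.loc[~bad].copy()
        if len(df) == 0:
            raise ValueError(f"no records with finite weights in scoring file {path}")
    df["effect_weight"] = pd.to_numeric(df["effect_weight"])
    df = df.rename(columns={id_col: "variant_id"})
    model = ScoringModel(df, headers=headers, n_rejected=n_rejected)
    if model.flagged_alleles:
        warnings.warn(
            f"{len(model.flagged_alleles)} variant(s) with multi-character or "
            f"non-ACGT alleles in {path}"
        )
    return model


def write_scoring_file(model: ScoringModel, path) -> None:
    with open(path, "wt") as fh:
        for line in model.headers:
            fh.write(line.rstrip("\n") + "\n")
        out = model.records.rename(columns={
            "variant_id": "rsID", "chromosome": "chr_name",
            "chr_position": "chr_position", "position": "chr_position",
            "weight": "effect_weight",
        })
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


@dataclass
class Alignment:
    """Result of matching a scoring model against a dosage matrix.

    ``table`` has one row per usable variant with columns ``variant_id``,
    ``matrix_col``, ``weight``, ``orientation`` ("direct" or "flipped") and
    ``strand_complemented``. ``counts`` tallies every disposition.
    """

    table: pd.DataFrame
    counts: dict[str, int]


def match_alleles(model: ScoringModel, matrix: DosageMatrix,
                  drop_ambiguous: bool = False) -> Alignment:
    """Align scoring-model variants to matrix columns by id and allele.

    For each shared variant: counted allele equal to the effect allele means
    the dosage counts effect copies (direct); equal to the other allele means
    flipped (use 2 - dosage). A strand-complement pair is resolved by
    complementing the counted allele, unless the scoring pair itself is
    strand-ambiguous (A/T or C/G), in which case the variant is dropped when
    ``drop_ambiguous`` is set. Anything else is unmatched and excluded.
    """
    col_of = {v: i for i, v in enumerate(matrix.variant_ids)}
    rows = []
    counts = {"direct": 0, "flipped": 0, "strand_complemented": 0,
              "ambiguous_dropped": 0, "unmatched_alleles": 0,
              "absent_from_matrix": 0}
    for rec in model.records.itertuples(index=False):
        vid = rec.variant_id
        if vid not in col_of:
            counts["absent_from_matrix"] += 1
            continue
        j = col_of[vid]
        counted = str(matrix.counted_alleles[j]).upper()
        eff = str(rec.effect_allele).upper()
        oth = str(rec.other_allele).upper() if pd.notna(rec.other_allele) else ""
        if drop_ambiguous and oth and _is_ambiguous_pair(eff, oth):
            counts["ambiguous_dropped"] += 1
            continue
        orientation = None
        complemented = False
        if counted == eff:
            orientation = "direct"
        elif oth and counted == oth:
            orientation = "flipped"
        else:
            comp = _complement(counted)
            if comp is not None and not (oth and _is_ambiguous_pair(eff, oth)):
                if comp == eff:
                    orientation, complemented = "direct", True
                elif oth and comp == oth:
                    orientation, complemented = "flipped", True
        if orientation is None:
            counts["unmatched_alleles"] += 1
            continue
        counts[orientation] += 1
        if complemented:
            counts["strand_complemented"] += 1
        rows.append((vid, j, float(rec.weight), orientation, complemented))
    if not rows and counts["absent_from_matrix"] == len(model):
        raise ValueError("no overlapping variants between scoring model and dosage matrix")
    table = pd.DataFrame(
        rows, columns=["variant_id", "matrix_col", "weight", "orientation",
                       "strand_complemented"],
    )
    return Alignment(table, counts)


@dataclass
class ScoreResult:
    """Raw per-person scores plus coverage bookkeeping."""

    scores: pd.DataFrame  # person_id, score, used_variants
    alignment: Alignment
    mode: str

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_scores(model: ScoringModel, matrix: DosageMatrix,
                   mode: str = "sum", drop_ambiguous: bool = False,
                   alignment: Alignment | None = None) -> ScoreResult:
    """Score every person: sum over variants of weight x effect-allele dosage.

    Missing dosages are imputed with that variant's mean observed dosage
    (PLINK2 default). ``mode="average"`` divides the sum by 2 x (number of
    used variants). A person with no observed dosage at any used variant
    gets a missing (NaN) score with a warning.
    """
    if mode not in ("sum", "average"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if alignment is None:
        alignment = match_alleles(model, matrix, drop_ambiguous=drop_ambiguous)
    tab = alignment.table
    if len(tab) == 0:
        raise ValueError("alignment contains no usable variants")

    cols = tab["matrix_col"].to_numpy()
    weights = tab["weight"].to_numpy(dtype=float)
    sub = matrix.dosages[:, cols].copy()
    flip = (tab["orientation"] == "flipped").to_numpy()
    sub[:, flip] = 2.0 - sub[:, flip]

    observed = ~np.isnan(sub)
    col_has_data = observed.any(axis=0)
    if not col_has_data.all():
        warnings.warn(
            f"{int((~col_has_data).sum())} variant(s) with no observed dosages excluded"
        )
        sub = sub[:, col_has_data]
        weights = weights[col_has_data]
        observed = observed[:, col_has_data]
    m_used = sub.shape[1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(sub, axis=0)
    imputed = np.where(np.isnan(sub), col_means, sub)
    raw = imputed @ weights
    used = observed.sum(axis=1)
    all_missing = used == 0
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} person(s) with all dosages missing; "
                      "score emitted as missing")
        raw = raw.astype(float)
        raw[all_missing] = np.nan
    if mode == "average":
        raw = raw / (2.0 * m_used)
    out = pd.DataFrame({
        "person_id": matrix.person_ids,
        "score": raw,
        "used_variants": used,
    })
    return ScoreResult(out, alignment, mode)


# ---------------------------------------------------------------------------
# Dosage I/O
# ---------------------------------------------------------------------------

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_raw(matrix: DosageMatrix, path) -> None:
    """Write a PLINK `.raw` text export (counted-allele dosage columns, NA missing)."""
    cols = [f"{v}_{a}" for v, a in zip(matrix.variant_ids, matrix.counted_alleles)]
    with open(path, "wt") as fh:
        fh.write("\t".join(_RAW_META + cols) + "\n")
        for i, pid in enumerate(matrix.person_ids):
            vals = []
            for x in matrix.dosages[i]:
                if np.isnan(x):
                    vals.append("NA")
                elif x == int(x):
                    vals.append(str(int(x)))
                else:
                    vals.append(f"{x:.6g}")
            fh.write("\t".join([pid, pid, "0", "0", "0", "-9"] + vals) + "\n")


def read_raw(path) -> DosageMatrix:
    """Read a PLINK `.raw` export; variant columns are `<ID>_<countedallele>`."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing_meta = [c for c in ("FID", "IID") if c not in df.columns]
    if missing_meta:
        raise ValueError(f".raw file {path} lacks column(s) {missing_meta}")
    var_cols = [c for c in df.columns if c not in _RAW_META]
    variant_ids, counted = [], []
    for c in var_cols:
        vid, _, allele = c.rpartition("_")
        if not vid:
            raise ValueError(f"variant column {c!r} lacks a counted-allele suffix")
        variant_ids.append(vid)
        counted.append(allele)
    return DosageMatrix(
        person_ids=[str(x) for x in df["IID"]],
        variant_ids=variant_ids,
        counted_alleles=counted,
        dosages=df[var_cols].to_numpy(dtype=float),
    )


def read_vcf(path, prefer_ds: bool = True) -> DosageMatrix:
    """Read dosages from a VCF: DS FORMAT field preferred, else GT hard calls.

    The ALT allele is the counted allele (so DS counts ALT copies);
    multi-allelic sites keep the first ALT only and are flagged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    persons = list(vcf.samples)
    variant_ids, counted, rows = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) == 0:
            continue
        if len(var.ALT) > 1:
            n_multi += 1
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        variant_ids.append(vid)
        counted.append(var.ALT[0])
        ds = None
        if prefer_ds:
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(len(persons))
            row = np.where(row < 0, np.nan, row)  # cyvcf2 encodes missing as negative
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            row = np.where((gts < 0).any(axis=1), np.nan,
                           (gts == 1).sum(axis=1)).astype(float)
        rows.append(row)
    if not rows:
        raise ValueError(f"no variants read from VCF {path}")
    if n_multi:
        warnings.warn(f"{n_multi} multi-allelic site(s): only the first ALT allele is counted")
    return DosageMatrix(persons, variant_ids, counted, np.column_stack(rows))
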