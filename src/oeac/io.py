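"""Readers, writers and validation for the cohort data model.

Four plain-text tables describe a methylation cohort:

* **beta matrix** — TSV, probes as rows; first column ``probe_id``, one
  column per sample; normalized methylation fractions in [0, 1]; missing
  values written ``NA``.
* **sample sheet** — CSV with columns
  ``sample_id,animal_id,species,tissue,sex,age_years,age_status,origin``.
* **species parameters** — CSV ``species,asm_years,gestation_years``
  (age at sexual maturity and gestation time, years).
* **probe annotation** — TSV
  ``probe_id,chrom,pos,nearest_gene,region_class,dist_to_tss,island_status``
  with 1-based coordinates.

All readers validate on load and raise :class:`FormatError` (malformed
file) or :class:`ValidationError` (well-formed but inconsistent values).
:func:`validate_cohort` joins the tables into a :class:`Cohort` handle
used by the clock, cross-validation, EWAS and classification layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .transform import AgeTransform

__all__ = [
    "FormatError",
    "ValidationError",
    "Cohort",
    "TISSUES",
    "SEXES",
    "ORIGINS",
    "AGE_STATUSES",
    "REGION_CLASSES",
    "ISLAND_STATUSES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_species_params",
    "write_species_params",
    "read_annotation",
    "write_annotation",
    "validate_beta_matrix",
    "validate_sample_sheet",
    "validate_species_params",
    "validate_annotation",
    "validate_cohort",
]

TISSUES = ("blood", "skin")
SEXES = ("F", "M", "unknown")
ORIGINS = ("zoo", "wild")
AGE_STATUSES = ("known", "estimated", "unknown")
REGION_CLASSES = (
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "3'UTR",
    "upstream",
    "downstream",
    "intergenic",
)
ISLAND_STATUSES = ("island", "non-island")

SHEET_COLUMNS = [
    "sample_id",
    "animal_id",
    "species",
    "tissue",
    "sex",
    "age_years",
    "age_status",
    "origin",
]
PARAMS_COLUMNS = ["species", "asm_years", "gestation_years"]
ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "nearest_gene",
    "region_class",
    "dist_to_tss",
    "island_status",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A table is well-formed but violates a data-model invariant."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples beta DataFrame; returns it unchanged."""
    _check_unique(beta.index, "probe ids")
    _check_unique(beta.columns, "sample ids")
    vals = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value out of [0, 1]: probe {beta.index[i]!r}, "
            f"sample {beta.columns[j]!r}, value {vals[i, j]}"
        )
    return beta


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a beta-matrix TSV into a probes x samples DataFrame."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    if df.columns[0] != "probe_id":
        raise FormatError(
            f"{path}: first column must be 'probe_id', got {df.columns[0]!r}"
        )
    df = df.set_index("probe_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from None
    return validate_beta_matrix(df)


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    validate_beta_matrix(beta)
    out = beta.copy()
    out.index.name = "probe_id"
    # 17 significant digits: exact float64 round trip
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def _check_vocab(series: pd.Series, vocab, what: str) -> None:
    bad = sorted(set(series.dropna()) - set(vocab))
    if bad:
        raise ValidationError(f"invalid {what} value(s) {bad}; allowed: {list(vocab)}")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s) {missing}")
    _check_unique(sheet["sample_id"], "sample ids")
    _check_vocab(sheet["tissue"], TISSUES, "tissue")
    _check_vocab(sheet["sex"], SEXES, "sex")
    _check_vocab(sheet["origin"], ORIGINS, "origin")
    _check_vocab(sheet["age_status"], AGE_STATUSES, "age_status")
    age_missing = sheet["age_years"].isna()
    status_unknown = sheet["age_status"] == "unknown"
    if (age_missing != status_unknown).any():
        off = sheet.loc[age_missing != status_unknown, "sample_id"].tolist()
        raise ValidationError(
            f"age_years missing must coincide with age_status='unknown'; "
            f"offending sample(s): {off[:10]}"
        )
    if (sheet["age_years"].dropna() < 0).any():
        off = sheet.loc[sheet["age_years"] < 0, "sample_id"].tolist()
        raise ValidationError(f"negative age_years for sample(s) {off[:10]}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "animal_id": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, index=False, columns=SHEET_COLUMNS)


def validate_species_params(params: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARAMS_COLUMNS if c not in params.columns]
    if missing:
        raise FormatError(f"species params missing column(s) {missing}")
    _check_unique(params["species"], "species")
    for col in ("asm_years", "gestation_years"):
        if (params[col] <= 0).any() or params[col].isna().any():
            off = params.loc[~(params[col] > 0), "species"].tolist()
            raise ValidationError(f"{col} must be > 0; offending species: {off}")
    return params


def read_species_params(path) -> pd.DataFrame:
    return validate_species_params(pd.read_csv(path))


def write_species_params(params: pd.DataFrame, path) -> None:
    validate_species_params(params)
    params.to_csv(path, index=False, columns=PARAMS_COLUMNS)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation missing column(s) {missing}")
    _check_unique(ann["probe_id"], "probe ids")
    _check_vocab(ann["region_class"], REGION_CLASSES, "region_class")
    _check_vocab(ann["island_status"], ISLAND_STATUSES, "island_status")
    if (ann["pos"] < 1).any():
        raise ValidationError("annotation pos must be >= 1 (1-based coordinates)")
    return ann


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


@dataclass
class Cohort:
    """Joined, validated view of a methylation cohort.

    ``beta`` is probes x samples; ``sheet`` is indexed 0..n-1 with one row
    per sample in the same order as ``beta.columns``; ``params`` maps each
    species to its age-transform parameters.
    """

    beta: pd.DataFrame
    sheet: pd.DataFrame
    params: pd.DataFrame
    annotation: pd.DataFrame | None = None

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    def transform_for(self, species: str) -> AgeTransform:
        row = self.params.loc[self.params["species"] == species]
        if row.empty:
            raise ValidationError(f"no age-transform parameters for species {species!r}")
        return AgeTransform(
            float(row["asm_years"].iloc[0]), float(row["gestation_years"].iloc[0])
        )

    def subset(self, sample_ids) -> "Cohort":
        """Restrict to the given samples (order preserved)."""
        sample_ids = list(sample_ids)
        sheet = (
            self.sheet.set_index("sample_id")
            .loc[sample_ids]
            .rename_axis("sample_id")
            .reset_index()
        )
        return Cohort(
            beta=self.beta[sample_ids],
            sheet=sheet,
            params=self.params,
            annotation=self.annotation,
        )

    def stratum(self, stratum: str) -> "Cohort":
        """Restrict to a tissue stratum: 'blood', 'skin' or 'blood+skin'."""
        if stratum == "blood+skin":
            return self
        if stratum not in TISSUES:
            raise ValueError(f"unknown stratum {stratum!r}")
        keep = self.sheet.loc[self.sheet["tissue"] == stratum, "sample_id"]
        return self.subset(keep)


def validate_cohort(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    params: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> Cohort:
    """Join the tables into a :class:`Cohort`, checking cross-references.

    Every sample in ``beta`` must have a sample-sheet row; every species
    contributing aged samples must have transform parameters; annotation,
    if given, must cover every probe.
    """
    validate_beta_matrix(beta)
    validate_sample_sheet(sheet)
    validate_species_params(params)
    sheet_ids = set(sheet["sample_id"])
    orphans = [s for s in beta.columns if s not in sheet_ids]
    if orphans:
        raise ValidationError(f"sample(s) in beta matrix but not sample sheet: {orphans[:10]}")
    in_beta = sheet["sample_id"].isin(beta.columns)
    sheet = (
        sheet.loc[in_beta]
        .set_index("sample_id")
        .loc[beta.columns]
        .rename_axis("sample_id")
        .reset_index()
    )
    aged = sheet.loc[sheet["age_years"].notna(), "species"]
    missing_sp = sorted(set(aged) - set(params["species"]))
    if missing_sp:
        raise ValidationError(
            f"species with aged samples but no transform parameters: {missing_sp}"
        )
    if annotation is not None:
        validate_annotation(annotation)
        unannotated = beta.index.difference(annotation["probe_id"])
        if len(unannotated):
            raise ValidationError(
                f"probe(s) missing from annotation: {list(unannotated[:10])}"
            )
    return Cohort(beta=beta, sheet=sheet, params=params, annotation=annotation)
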