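"""Domain containers and TSV/GMT readers and writers.

Tables travel as tab-separated text (gzip transparently supported through
pandas); gene sets use the GMT dialect (name, description, genes...).
Gene identifiers are opaque, case-sensitive strings — no namespace mapping
is attempted.  Missing values are rejected, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import DataValidationError

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6
TPM_RTOL = 1e-6

#: tissue codes: C = primary colorectal lesion, L = liver metastasis,
#: Ln = tumor-distant normal liver
TISSUES = ("C", "L", "Ln")
HGP_LABELS = ("dHGP", "rHGP", "impure", "unknown")

ANNOTATION_COLUMNS = ("sample_id", "patient_id", "tissue", "hgp")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table (TPM or TPM-like non-negative values).

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    tpm
        If True, every column must sum to 1e6 within relative tolerance 1e-6.
    """

    data: pd.DataFrame
    tpm: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise DataValidationError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise DataValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise DataValidationError(
                f"negative value {values[i, j]} at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.tpm:
            sums = values.sum(axis=0)
            off = ~np.isclose(sums, TPM_TOTAL, rtol=TPM_RTOL, atol=0.0)
            if off.any():
                j = int(np.argwhere(off)[0][0])
                raise DataValidationError(
                    f"sample {cols[j]!r} is not TPM-normalized (column sum {sums[j]:g})"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def renormalize_tpm(self) -> "ExpressionMatrix":
        """Rescale every column to sum to 1e6.  Idempotent."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise DataValidationError(f"cannot TPM-normalize all-zero samples: {bad}")
        return ExpressionMatrix(self.data * (TPM_TOTAL / sums), tpm=True)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], tpm=self.tpm)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise DataValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dups = sorted({g for g in self.genes if g in seen or seen.add(g)})
            raise DataValidationError(
                f"duplicate genes in set {self.name!r}: {dups}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def read_expression(
    path: str | Path,
    tpm_check: bool = False,
    on_invalid_tpm: str = "renormalize",
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    With ``tpm_check``, columns that do not sum to 1e6 are renormalized
    (``on_invalid_tpm="renormalize"``, default) or rejected
    (``on_invalid_tpm="error"``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().to_numpy().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise DataValidationError(
            f"missing value at gene {df.index[loc[0]]!r}, sample {df.columns[loc[1]]!r}"
        )
    mat = ExpressionMatrix(df, tpm=False)
    if tpm_check:
        sums = df.sum(axis=0).to_numpy()
        if np.allclose(sums, TPM_TOTAL, rtol=TPM_RTOL, atol=0.0):
            return ExpressionMatrix(df, tpm=True)
        if on_invalid_tpm == "renormalize":
            logger.warning("columns do not sum to 1e6; renormalizing to TPM")
            return mat.renormalize_tpm()
        raise DataValidationError("expression matrix is not TPM-normalized")
    return mat


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: list[GeneSet] = []
    opener = _opener(path)
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = tuple(g for g in fields[2:] if g != "")
            if not genes:
                raise DataValidationError(
                    f"{path}: line {lineno}: gene set {name!r} has no genes"
                )
            sets.append(GeneSet(name=name, genes=genes, description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    opener = _opener(path)
    with opener(path, "wt") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _opener(path: str | Path):
    import gzip

    return gzip.open if str(path).endswith(".gz") else open


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, patient_id, tissue, hgp)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotations(ann)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise DataValidationError(f"annotation table missing columns: {missing}")
    if ann["sample_id"].duplicated().any():
        dups = sorted(ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist())
        raise DataValidationError(f"duplicate sample ids in annotations: {dups}")
    bad_tissue = sorted(set(ann["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise DataValidationError(f"unknown tissue codes: {bad_tissue}")
    bad_hgp = sorted(set(ann["hgp"]) - set(HGP_LABELS))
    if bad_hgp:
        raise DataValidationError(f"unknown HGP labels: {bad_hgp}")
    # C and Ln are resected once per patient; only L may repeat (multiple lesions)
    for tissue in ("C", "Ln"):
        sub = ann[ann["tissue"] == tissue]
        if sub["patient_id"].duplicated().any():
            dups = sorted(sub.loc[sub["patient_id"].duplicated(), "patient_id"])
            raise DataValidationError(
                f"patients with more than one {tissue} sample: {dups}"
            )
    return ann.reset_index(drop=True)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV (patient_id, covariates..., rfs_time_months, rfs_event)."""
    clin = pd.read_csv(path, sep="\t")
    return validate_clinical(clin)


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient_id", "rfs_time_months", "rfs_event"):
        if col not in clin.columns:
            raise DataValidationError(f"clinical table missing column: {col}")
    if clin["patient_id"].duplicated().any():
        dups = sorted(clin.loc[clin["patient_id"].duplicated(), "patient_id"])
        raise DataValidationError(f"duplicate patients in clinical table: {dups}")
    t = clin["rfs_time_months"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t < 0).any():
        raise DataValidationError("rfs_time_months must be finite and >= 0")
    ev = clin["rfs_event"].astype(bool)
    if ((t <= 0) & ev).any():
        raise DataValidationError("a relapse event requires rfs_time_months > 0")
    clin = clin.copy()
    clin["rfs_event"] = ev
    return clin.reset_index(drop=True)


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False)


def align_cohort(
    expr: ExpressionMatrix, ann: pd.DataFrame, tissue: str
) -> ExpressionMatrix:
    """Restrict a matrix to the annotated samples of one tissue.

    Column order follows annotation order.  Annotated samples of the
    requested tissue that are absent from the matrix are dropped with a
    warning; zero matching samples is an error.
    """
    if tissue not in TISSUES:
        raise DataValidationError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    ann = validate_annotations(ann)
    unannotated = set(expr.sample_ids) - set(ann["sample_id"])
    if unannotated:
        raise DataValidationError(
            f"matrix samples missing from annotations: {sorted(unannotated)}"
        )
    wanted = ann.loc[ann["tissue"] == tissue, "sample_id"].tolist()
    present = [s for s in wanted if s in expr.data.columns]
    dropped = [s for s in wanted if s not in expr.data.columns]
    if dropped:
        logger.warning("dropping %d annotated %s samples absent from matrix: %s",
                       len(dropped), tissue, dropped)
    if not present:
        raise DataValidationError(f"no {tissue} samples found in the matrix")
    return expr.subset_samples(present)
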