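"""Shared data model for the isogenic transcriptome screening pipeline.

Every downstream stage consumes the containers defined here; nothing
re-parses files after :mod:`isoscreen.io` has produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


# Sample roles -----------------------------------------------------------

ROLE_REFERENCE = "reference_es"
ROLE_CLONE = "isogenic_clone"
ROLE_UNRELATED = "unrelated_ipsc"
ROLE_SOMATIC = "somatic"
VALID_ROLES = (ROLE_REFERENCE, ROLE_CLONE, ROLE_UNRELATED, ROLE_SOMATIC)

# Chromosome vocabulary --------------------------------------------------

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y", "unplaced")

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_LOG2_NORMALIZED = "log2_normalized"
VALID_SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_LOG2_NORMALIZED)

IMPRINT_STATUSES = ("none", "known", "predicted")
EXPRESSED_ALLELES = ("maternal", "paternal", "unknown")
XI_CLASSES = ("silenced", "escape", "unknown")

ANNOTATION_COLUMNS = ("chromosome", "position", "imprint_status",
                      "expressed_allele", "xi_class")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag.

    ``values`` is a DataFrame indexed by gene identifier with one column
    per sample.  Gene identifiers may repeat before symbol collapse
    (multiple probes per symbol); sample identifiers are always unique.
    """

    values: pd.DataFrame
    scale_tag: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale_tag not in VALID_SCALES:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, scale_tag or self.scale_tag)


@dataclass
class SampleManifest:
    """Sample -> role mapping with per-sample sex.

    Exactly one ``reference_es`` sample is required; screen operations
    additionally require at least one ``isogenic_clone``.
    """

    roles: pd.Series
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.sex is None:
            self.sex = pd.Series("unknown", index=self.roles.index)
        bad = sorted(set(self.roles) - set(VALID_ROLES))
        if bad:
            raise ValidationError(f"unknown sample roles: {bad}")
        if self.roles.index.duplicated().any():
            raise ValidationError("duplicate sample identifiers in manifest")
        n_ref = int((self.roles == ROLE_REFERENCE).sum())
        if n_ref != 1:
            raise ValidationError(
                f"manifest must name exactly one {ROLE_REFERENCE} sample (found {n_ref})")

    @property
    def samples(self) -> pd.Index:
        return self.roles.index

    @property
    def reference(self) -> str:
        return str(self.roles.index[self.roles == ROLE_REFERENCE][0])

    @property
    def clones(self) -> list[str]:
        return [str(s) for s in self.roles.index[self.roles == ROLE_CLONE]]

    @property
    def unrelated(self) -> list[str]:
        return [str(s) for s in self.roles.index[self.roles == ROLE_UNRELATED]]

    @property
    def somatic(self) -> list[str]:
        return [str(s) for s in self.roles.index[self.roles == ROLE_SOMATIC]]

    def require_clones(self, n: int = 1) -> None:
        if len(self.clones) < n:
            raise ValidationError(f"operation requires >= {n} isogenic clone(s)")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-annotation catalogue and normalise its dtypes.

    The catalogue is a DataFrame indexed by unique gene symbol with
    columns chromosome / position / imprint_status / expressed_allele /
    xi_class.  A missing ``xi_class`` column defaults to ``unknown``.
    """
    ann = annotation.copy()
    if ann.index.duplicated().any():
        dupes = sorted(set(ann.index[ann.index.duplicated()]))
        raise ValidationError(f"duplicate symbols in annotation: {dupes}")
    for col, default in (("imprint_status", "none"),
                         ("expressed_allele", "unknown"),
                         ("xi_class", "unknown")):
        if col not in ann.columns:
            ann[col] = default
    missing = [c for c in ("chromosome", "position") if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation lacks required columns: {missing}")
    ann["chromosome"] = ann["chromosome"].astype(str)
    bad_chrom = sorted(set(ann["chromosome"]) - set(CHROMOSOMES))
    if bad_chrom:
        raise ValidationError(f"unknown chromosomes in annotation: {bad_chrom}")
    ann["position"] = ann["position"].astype(int)
    placed = ann["chromosome"] != "unplaced"
    if (ann.loc[placed, "position"] < 1).any():
        raise ValidationError("positions must be >= 1 for placed genes")
    for col, allowed in (("imprint_status", IMPRINT_STATUSES),
                         ("expressed_allele", EXPRESSED_ALLELES),
                         ("xi_class", XI_CLASSES)):
        bad = sorted(set(ann[col]) - set(allowed))
        if bad:
            raise ValidationError(f"invalid {col} values: {bad}")
    none_imprint = ann["imprint_status"] == "none"
    if (ann.loc[none_imprint, "expressed_allele"] != "unknown").any():
        raise ValidationError(
            "imprint_status='none' requires expressed_allele='unknown'")
    return ann[list(ANNOTATION_COLUMNS)]


def align_annotation(genes: Iterable[str], annotation: pd.DataFrame) -> pd.DataFrame:
    """Return the catalogue aligned to ``genes``.

    Genes absent from the catalogue are assigned chromosome ``unplaced``
    (and thereby excluded later from per-chromosome denominators).
    """
    genes = pd.Index(genes)
    ann = validate_annotation(annotation)
    aligned = ann.reindex(genes)
    missing = aligned["chromosome"].isna()
    aligned.loc[missing, "chromosome"] = "unplaced"
    aligned.loc[missing, "position"] = 0
    aligned.loc[missing, "imprint_status"] = "none"
    aligned.loc[missing, "expressed_allele"] = "unknown"
    aligned.loc[missing, "xi_class"] = "unknown"
    aligned["position"] = aligned["position"].astype(int)
    return aligned


@dataclass
class CtTable:
    """Replicate Ct measurements for expression qPCR.

    ``data`` has columns sample / target / replicate / ct.  The reference
    (normaliser) gene must be measured for every sample carrying any
    target measurement, and the calibrator sample must be present.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "target", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table lacks columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        with_targets = set(self.data.loc[self.data["target"] != self.reference_gene, "sample"])
        with_ref = set(self.data.loc[self.data["target"] == self.reference_gene, "sample"])
        orphans = sorted(with_targets - with_ref)
        if orphans:
            raise ValidationError(
                f"samples lacking reference gene {self.reference_gene!r} "
                f"measurements: {orphans}")

    def targets(self) -> list[str]:
        t = sorted(set(self.data["target"]) - {self.reference_gene})
        return t

    def replicates(self, sample: str, target: str) -> np.ndarray:
        sel = (self.data["sample"] == sample) & (self.data["target"] == target)
        return self.data.loc[sel, "ct"].to_numpy(float)


@dataclass
class MethylationTable:
    """Paired methylated/unmethylated Ct replicates per (sample, locus)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "locus", "replicate", "ct_methylated", "ct_unmethylated"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"methylation table lacks columns: {sorted(missing)}")
        for col in ("ct_methylated", "ct_unmethylated"):
            if self.data[col].isna().any():
                raise ValidationError(f"missing {col} values")
            if (self.data[col] <= 0).any():
                raise ValidationError(f"{col} values must be > 0")


DEFAULT_LADDER = (1.5, 2.0, 5.0, 10.0, 50.0)


@dataclass
class FoldChangeTable:
    """Per-gene signed log2 deviation of every sample from the reference.

    ``delta[g, s] = log2(sample s) - log2(reference)``; the reference
    column is identically zero.  ``ladder`` holds the linear-fold
    thresholds of interest, strictly increasing.
    """

    delta: pd.DataFrame
    reference: str
    ladder: tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        self.ladder = tuple(float(t) for t in self.ladder)
        if any(b <= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValidationError("ladder thresholds must be strictly increasing")
        if self.reference not in self.delta.columns:
            raise ValidationError(f"reference sample {self.reference!r} missing")

    @property
    def genes(self) -> pd.Index:
        return self.delta.index

    @property
    def samples(self) -> pd.Index:
        return self.delta.columns
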