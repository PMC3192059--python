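"""Readers and writers for the pipeline's plain-text exchange formats.

All tables are TSV: tab-separated, UTF-8, ``.`` decimal, no thousands
separators.  The expression table's first column header is literally
``gene``.  Ct and methylation tables carry their metadata (reference
gene, calibrator sample) in leading ``#``-prefixed header lines.
"""

from __future__ import annotations

import hashlib
import json
import datetime
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .types import (CtTable, ExpressionMatrix, MethylationTable,
                    SampleManifest, ValidationError, align_annotation,
                    validate_annotation)


# -- expression / annotation / manifest ---------------------------------

def read_expression_table(path, annotation_path=None, manifest_path=None,
                          scale_tag: str = "raw"):
    """Read an expression TSV, optionally with annotation and manifest.

    Returns ``ExpressionMatrix`` alone, or the triple
    ``(ExpressionMatrix, annotation, SampleManifest)`` when the companion
    paths are given.  Genes absent from the annotation are assigned
    chromosome ``unplaced``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene":
        raise ValidationError(
            f"first column header must be 'gene' (got {header[0] if header else ''!r}) in {path}")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValidationError(f"duplicate sample name {s!r} in {path}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw.columns = ["gene"] + samples
    values = raw.set_index("gene")
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = values.index[bad][0]
            raise ValidationError(
                f"non-numeric value {values.loc[gene, col]!r} at gene "
                f"{gene!r}, sample {col!r} in {path}")
        values[col] = converted
    matrix = ExpressionMatrix(values.astype(float), scale_tag)
    if annotation_path is None and manifest_path is None:
        return matrix
    annotation = read_annotation(annotation_path)
    annotation = align_annotation(matrix.genes.unique(), annotation)
    manifest = read_manifest(manifest_path)
    missing = set(matrix.samples) - set(manifest.samples)
    if missing:
        raise ValidationError(f"samples absent from manifest: {sorted(missing)}")
    return matrix, annotation, manifest


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chromosome": str})
    if "symbol" not in df.columns:
        raise ValidationError(f"annotation {path} lacks a 'symbol' column")
    if df["symbol"].duplicated().any():
        dupes = sorted(set(df.loc[df["symbol"].duplicated(), "symbol"]))
        raise ValidationError(f"duplicate symbols in annotation {path}: {dupes}")
    return validate_annotation(df.set_index("symbol"))


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "symbol"
    out.to_csv(path, sep="\t")


def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "role"}
    if not required <= set(df.columns):
        raise ValidationError(f"manifest {path} needs columns {sorted(required)}")
    sex = df.set_index("sample")["sex"] if "sex" in df.columns else None
    return SampleManifest(df.set_index("sample")["role"], sex)


def write_manifest(manifest: SampleManifest, path) -> None:
    df = pd.DataFrame({"sample": manifest.samples,
                       "role": manifest.roles.values,
                       "sex": manifest.sex.values})
    df.to_csv(path, sep="\t", index=False)


# -- Ct tables -----------------------------------------------------------

def _read_header_meta(path) -> dict[str, str]:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("\t")
            if not value:
                key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_ct_table(path) -> CtTable:
    """Read a Ct TSV whose header declares reference gene and calibrator.

    Expected layout::

        # reference_gene\tGAPDH
        # calibrator_sample\tH9
        sample\ttarget\treplicate\tct
        ...
    """
    meta = _read_header_meta(path)
    for key in ("reference_gene", "calibrator_sample"):
        if key not in meta:
            raise ValidationError(f"Ct table {path} header lacks '# {key}'")
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample": str, "target": str})
    df["ct"] = df["ct"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return CtTable(df, meta["reference_gene"], meta["calibrator_sample"])


def write_ct_table(table: CtTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# reference_gene\t{table.reference_gene}\n")
        fh.write(f"# calibrator_sample\t{table.calibrator_sample}\n")
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_methylation_table(path) -> MethylationTable:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample": str, "locus": str})
    for col in ("ct_methylated", "ct_unmethylated"):
        df[col] = df[col].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return MethylationTable(df)


def write_methylation_table(table: MethylationTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- optional GEO series-matrix adapter ----------------------------------

def read_geo_series_matrix(path, scale_tag: str = "raw") -> ExpressionMatrix:
    """Thin adapter for GEO series-matrix text exports.

    Parses the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` into an :class:`ExpressionMatrix`.  The
    probe-to-symbol annotation is deliberately NOT embedded; supply it
    separately via :func:`read_annotation`.
    """
    lines = []
    inside = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ValidationError(f"no series-matrix table found in {path}")
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines)), sep="\t")
    df = df.rename(columns={df.columns[0]: "gene"}).set_index("gene")
    df.columns = [c.strip('"') for c in df.columns]
    df.index = [str(i).strip('"') for i in df.index]
    return ExpressionMatrix(df.astype(float), scale_tag)


# -- report --------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonify(v) for v in obj)
    if isinstance(obj, pd.DataFrame):
        df = obj.reset_index()
        return {"columns": [str(c) for c in df.columns],
                "rows": _jsonify(df.to_numpy().tolist())}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def write_report(bundle: Mapping[str, Any], path, *, seed=None,
                 checksums: Mapping[str, str] | None = None,
                 timestamp: bool = True) -> dict:
    """Write the per-stage results bundle as a single JSON report.

    The body is a pure function of (bundle, seed, checksums); the
    ``created`` timestamp is the only non-deterministic field.
    """
    doc = {
        "meta": {
            "tool": "isoscreen",
            "version": __version__,
            "seed": seed,
            "input_checksums": dict(checksums or {}),
        },
        "sections": _jsonify({k: v for k, v in bundle.items()
                              if not str(k).startswith("_")}),
    }
    if timestamp:
        doc["meta"]["created"] = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc
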