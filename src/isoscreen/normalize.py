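"""Microarray preprocessing: log2, quantile normalization, baselining.

The pipeline order is log2 -> quantile normalization -> per-gene median
baseline subtraction -> unique-symbol collapse.  Quantile normalization
forces every sample to share one value distribution by replacing each
sample's sorted values with the cross-sample rank means; ties within a
sample receive the average of the rank means they span, which makes the
operation deterministic and exactly idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (SCALE_LOG2, SCALE_LOG2_NORMALIZED, SCALE_RAW,
                    ExpressionMatrix, ValidationError)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationSettings:
    """Preprocessing choices, echoed verbatim into the run report."""

    do_log2: bool = True
    tie_policy: str = "average_rank"
    baseline: str = "per_gene_median_across_samples"
    log2_floor: float = 1.0

    def as_dict(self) -> dict:
        return asdict(self)


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2 of raw intensities.

    Values <= 0 are floored to ``floor`` (default 1.0, i.e. log2 of 0);
    the number of floored cells is logged.
    """
    if floor <= 0:
        raise ValidationError("log2 floor must be positive")
    vals = matrix.values.to_numpy(float)
    n_floored = int((vals <= 0).sum())
    if n_floored:
        log.warning("log2_transform: floored %d non-positive values to %g",
                    n_floored, floor)
        vals = np.where(vals <= 0, floor, vals)
    out = pd.DataFrame(np.log2(vals), index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(out, SCALE_LOG2)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples (columns) to the mean empirical distribution.

    With a single sample this is the identity.  After the operation every
    sample's sorted value multiset is identical.
    """
    X = matrix.values.to_numpy(float)
    n, m = X.shape
    if m < 2:
        return matrix.with_values(matrix.values.copy(), SCALE_LOG2_NORMALIZED)
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie groups: runs of equal values share the mean of the target
        # values spanned by their rank range
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        counts = np.diff(np.r_[starts, n])
        group_sums = np.add.reduceat(target, starts)
        group_means = group_sums / counts
        out[order, j] = np.repeat(group_means, counts)
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.genes, columns=matrix.samples),
        SCALE_LOG2_NORMALIZED)


def baseline_subtract(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (median baselining)."""
    vals = matrix.values
    centered = vals.sub(vals.median(axis=1), axis=0)
    return matrix.with_values(centered)


def collapse_to_unique_symbols(matrix: ExpressionMatrix,
                               symbols: Mapping[str, str] | pd.Series | None = None,
                               ) -> tuple[ExpressionMatrix, pd.Series]:
    """Collapse multi-probe rows to one row per gene symbol.

    ``symbols`` optionally maps row identifiers (probes) to symbols; rows
    without a mapping keep their own identifier as symbol.  For each
    symbol the probe with the highest mean expression across samples is
    kept (ties broken by lexicographically smallest probe identifier), so
    every output row equals some input row.  Returns the collapsed matrix
    (indexed by symbol, ordered by first appearance) and the
    symbol -> kept-probe mapping.
    """
    probes = matrix.genes
    if symbols is None:
        sym = pd.Series(probes, index=probes)
    else:
        symbols = pd.Series(dict(symbols)) if not isinstance(symbols, pd.Series) else symbols
        sym = pd.Series([symbols.get(p, p) for p in probes], index=probes)
    df = matrix.values
    order = pd.DataFrame({
        "symbol": sym.values,
        "probe": probes,
        "mean": df.to_numpy(float).mean(axis=1),
        "pos": np.arange(len(probes)),
    })
    ranked = order.sort_values(["mean", "probe"], ascending=[False, True],
                               kind="mergesort")
    kept = ranked.drop_duplicates("symbol", keep="first")
    first_pos = order.groupby("symbol", sort=False)["pos"].min()
    kept = kept.assign(first=kept["symbol"].map(first_pos)).sort_values("first")
    collapsed = df.iloc[kept["pos"].to_numpy()].copy()
    collapsed.index = pd.Index(kept["symbol"], name="gene")
    mapping = pd.Series(kept["probe"].to_numpy(), index=collapsed.index,
                        name="kept_probe")
    return matrix.with_values(collapsed), mapping


def preprocess(matrix: ExpressionMatrix,
               settings: NormalizationSettings = NormalizationSettings(),
               symbols: Mapping[str, str] | None = None,
               ) -> tuple[ExpressionMatrix, pd.Series]:
    """Full preprocessing chain; returns the collapsed matrix and probe map."""
    m = matrix
    if settings.do_log2 and m.scale_tag == SCALE_RAW:
        m = log2_transform(m, settings.log2_floor)
    if m.scale_tag == SCALE_LOG2:
        m = quantile_normalize(m)
    m = baseline_subtract(m)
    return collapse_to_unique_symbols(m, symbols)
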