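"""Fold-change screens against the reference embryonic stem cell line.

All screens operate on signed log2 deviations from the reference sample
(``delta``).  A gene is flagged at linear threshold ``t`` iff
``|delta| > log2(t)`` (strict by default, matching the ">t fold"
convention); the imprint panel uses the inclusive variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (DEFAULT_LADDER, ExpressionMatrix, FoldChangeTable,
                    SampleManifest, ValidationError)


def compute_fold_changes(matrix: ExpressionMatrix, manifest: SampleManifest,
                         ladder: tuple[float, ...] = DEFAULT_LADDER,
                         ) -> FoldChangeTable:
    """Per-gene subtraction of the reference column (log2 fold changes)."""
    ref = manifest.reference
    if ref not in matrix.samples:
        raise ValidationError(f"reference sample {ref!r} missing from matrix")
    delta = matrix.values.sub(matrix.values[ref], axis=0)
    return FoldChangeTable(delta, ref, tuple(ladder))


def flag_signs(fct: FoldChangeTable, t: float, inclusive: bool = False,
               samples=None) -> pd.DataFrame:
    """Signed flag matrix at linear threshold ``t``.

    Entries are +1 (up), -1 (down) or 0 (not flagged).  ``t = 1`` with
    the strict convention flags every gene with any nonzero deviation;
    callers wanting the degenerate all-genes screen use ``t=1,
    inclusive=True``.
    """
    if t < 1:
        raise ValidationError("fold threshold must be >= 1")
    delta = fct.delta if samples is None else fct.delta[list(samples)]
    cut = np.log2(t)
    mag = delta.abs()
    hit = (mag >= cut) if inclusive else (mag > cut)
    return np.sign(delta).astype(int).where(hit, 0)


@dataclass
class ScreenResult:
    """Per-sample, per-threshold flag counts and signed flag matrices."""

    counts: pd.DataFrame            # samples x thresholds
    signs: dict[float, pd.DataFrame] = field(repr=False, default_factory=dict)
    reference: str = ""

    def flagged(self, sample: str, t: float) -> set[str]:
        s = self.signs[float(t)][sample]
        return set(s.index[s != 0])

    def count_ratio(self, a: str, b: str, t: float) -> float:
        ca, cb = self.counts.loc[a, float(t)], self.counts.loc[b, float(t)]
        return float(ca) / float(cb)

    def to_frame(self) -> pd.DataFrame:
        """Long-format gene/sample/threshold/direction table for export."""
        rows = []
        for t, signs in sorted(self.signs.items()):
            stacked = signs.stack()
            hits = stacked[stacked != 0]
            for (gene, sample), sign in hits.items():
                rows.append((gene, sample, t, "up" if sign > 0 else "down"))
        return pd.DataFrame(rows, columns=["gene", "sample", "threshold", "direction"])


def ladder_counts(fct: FoldChangeTable, manifest: SampleManifest | None = None,
                  inclusive: bool = False) -> ScreenResult:
    """Flag counts per sample across the threshold ladder.

    Counts are monotonically non-increasing in the threshold and the
    flagged sets are nested (larger thresholds select subsets).
    """
    signs = {float(t): flag_signs(fct, t, inclusive) for t in fct.ladder}
    counts = pd.DataFrame(
        {t: (s != 0).sum(axis=0) for t, s in signs.items()})
    counts.index.name = "sample"
    counts.columns.name = "threshold"
    return ScreenResult(counts, signs, fct.reference)


def consensus_screen(fct: FoldChangeTable, manifest: SampleManifest,
                     t: float, require_same_direction: bool = False,
                     inclusive: bool = False) -> pd.DataFrame:
    """Genes flagged at ``t`` in ALL isogenic clones.

    Returns the per-clone direction pattern (+1/-1) for each consensus
    gene.  By default a gene may change direction between clones; pass
    ``require_same_direction=True`` to demand a uniform sign.
    """
    manifest.require_clones(2)
    clones = manifest.clones
    signs = flag_signs(fct, t, inclusive, samples=clones)
    hit_all = (signs != 0).all(axis=1)
    if require_same_direction:
        hit_all &= (signs.abs().sum(axis=1) == signs.sum(axis=1).abs())
    return signs.loc[hit_all]


def similarity_percent(fct: FoldChangeTable, sample: str, t: float = 2.0,
                       denominator: int | None = None,
                       inclusive: bool = False) -> float:
    """Percentage of measured genes NOT deviating beyond ``t``-fold.

    ``denominator`` defaults to the number of measured unique symbols in
    the fold-change table.  The complement (percent dysregulated) plus
    this value is exactly 100 before display rounding.
    """
    denom = denominator if denominator is not None else len(fct.genes)
    if denom <= 0:
        raise ValidationError("similarity denominator must be > 0")
    flagged = int((flag_signs(fct, t, inclusive)[sample] != 0).sum())
    return 100.0 * (1.0 - flagged / denom)
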