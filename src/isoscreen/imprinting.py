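"""Imprinted-gene panels and consensus biomarker candidates.

Genomic imprinting is parent-of-origin-specific monoallelic expression;
reprogramming can erase or disturb it.  The panel restricts the
fold-change screen to a user-supplied imprinted-gene catalogue
(``imprint_status`` of ``known`` or ``predicted``), and the biomarker
screen asks which imprinted genes deviate beyond a high threshold in
every clone simultaneously.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffscreen import consensus_screen, flag_signs
from .types import FoldChangeTable, SampleManifest

log = logging.getLogger(__name__)

_ALLELE_ABBREV = {"maternal": "M", "paternal": "P", "unknown": "unknown"}


def imprint_screen(fct: FoldChangeTable, annotation: pd.DataFrame,
                   manifest: SampleManifest, t: float = 1.5,
                   inclusive: bool = True) -> pd.DataFrame:
    """Panel of imprinted genes deviating at least ``t``-fold in >=1 clone.

    The panel threshold is inclusive (">= t") by convention, unlike the
    strict ladder screens.  Rows carry imprint status, expressed allele,
    per-clone log2 deltas, the maximal absolute linear fold, and a
    consensus flag at each ladder threshold; sorted by max |fold|
    descending.  An empty catalogue yields an empty panel with a warning.
    """
    ann = annotation.reindex(fct.genes)
    catalogue = ann.index[ann["imprint_status"].isin(("known", "predicted"))]
    if len(catalogue) == 0:
        log.warning("imprint_screen: empty imprinted-gene catalogue")
    signs = flag_signs(fct, t, inclusive, samples=manifest.clones)
    hits = [g for g in catalogue if (signs.loc[g] != 0).any()]
    deltas = fct.delta.loc[hits, manifest.clones]
    rows = pd.DataFrame(index=pd.Index(hits, name="symbol"))
    rows["imprint_status"] = ann.loc[hits, "imprint_status"]
    rows["expressed_allele"] = ann.loc[hits, "expressed_allele"].map(_ALLELE_ABBREV)
    for clone in manifest.clones:
        rows[f"delta_{clone}"] = deltas[clone]
    rows["max_abs_fold"] = 2.0 ** deltas.abs().max(axis=1)
    multi_clone = len(manifest.clones) >= 2
    for thr in fct.ladder:
        if multi_clone:
            cons = consensus_screen(fct, manifest, thr)
            rows[f"consensus_{thr:g}x"] = rows.index.isin(cons.index)
        else:
            rows[f"consensus_{thr:g}x"] = False
    return rows.sort_values("max_abs_fold", ascending=False, kind="mergesort")


def biomarker_candidates(fct: FoldChangeTable, annotation: pd.DataFrame,
                         manifest: SampleManifest, t: float = 10.0) -> pd.DataFrame:
    """All-clone consensus genes at ``t``, annotated with imprint status.

    On the isogenic study design this is the detector for the single
    consistently silenced imprinted gene; any non-imprinted consensus
    gene is still listed (with status ``none``) so unexpected candidates
    are never hidden.
    """
    cons = consensus_screen(fct, manifest, t)
    ann = annotation.reindex(cons.index)
    out = pd.DataFrame(index=cons.index.copy())
    out.index.name = "symbol"
    out["imprint_status"] = ann["imprint_status"].fillna("none")
    out["expressed_allele"] = ann["expressed_allele"].fillna("unknown").map(
        _ALLELE_ABBREV)
    out["chromosome"] = ann["chromosome"].fillna("unplaced")
    clone_delta = fct.delta.loc[cons.index, manifest.clones]
    out["mean_log2_delta"] = clone_delta.mean(axis=1)
    out["mean_fold"] = 2.0 ** out["mean_log2_delta"]
    out["direction"] = np.where(out["mean_log2_delta"] > 0, "up", "down")
    return out.sort_values("mean_log2_delta", key=lambda s: s.abs(),
                           ascending=False, kind="mergesort")
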