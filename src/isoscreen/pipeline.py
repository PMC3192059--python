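"""End-to-end orchestration of the screening analysis.

``run_pipeline`` takes the validated inputs and produces the per-stage
results bundle that the CLI serialises into the JSON report.  It exists
so the command line, the test suite and ad-hoc scripts all execute the
identical sequence of operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import chromosome as chrom_mod
from . import clustering, diffscreen, imprinting, msqpcr, normalize, qpcr
from .types import (DEFAULT_LADDER, CtTable, ExpressionMatrix,
                    MethylationTable, SampleManifest)


@dataclass(frozen=True)
class PipelineConfig:
    ladder: tuple[float, ...] = DEFAULT_LADDER
    enrichment_threshold: float = 2.0
    consensus_threshold: float = 10.0
    imprint_threshold: float = 1.5
    hotspot_chromosome: str = "X"
    hotspot_window: int = 10
    hotspot_permutations: int = 10_000
    alpha: float = 0.05
    efficiency: float = 2.0
    seed: int | None = None


def run_pipeline(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                 manifest: SampleManifest, ct: CtTable | None = None,
                 methylation: MethylationTable | None = None,
                 config: PipelineConfig = PipelineConfig(),
                 settings: normalize.NormalizationSettings | None = None,
                 ) -> dict:
    """Run every analysis stage and return the results bundle.

    Sections: normalization settings, threshold-ladder screen with
    similarity percentages, all-clone consensus candidates, sample
    dendrogram, chromosome enrichment with direction split and expected
    counts, X hotspot scan, imprint panel, and (when the tables are
    supplied) qPCR and MS-qPCR summaries.
    """
    settings = settings or normalize.NormalizationSettings()
    collapsed, probe_map = normalize.preprocess(matrix, settings)
    fct = diffscreen.compute_fold_changes(collapsed, manifest, config.ladder)

    screen = diffscreen.ladder_counts(fct)
    similarity = {
        s: {f"{t:g}": round(diffscreen.similarity_percent(fct, s, t), 1)
            for t in config.ladder}
        for s in fct.samples if s != manifest.reference}

    consensus = diffscreen.consensus_screen(fct, manifest,
                                            config.consensus_threshold)
    candidates = imprinting.biomarker_candidates(
        fct, annotation, manifest, config.consensus_threshold)
    panel = imprinting.imprint_screen(fct, annotation, manifest,
                                      config.imprint_threshold)

    dendrogram = clustering.cluster_samples(collapsed)
    enrichment = chrom_mod.chromosome_enrichment(
        fct, annotation, manifest, config.enrichment_threshold)
    split = chrom_mod.direction_split(
        fct, annotation, manifest, config.hotspot_chromosome,
        config.enrichment_threshold)
    expected = chrom_mod.expected_uniform_rate(enrichment)
    hotspots = chrom_mod.hotspot_scan(
        fct, annotation, manifest, config.hotspot_chromosome,
        config.hotspot_window, config.hotspot_permutations,
        seed=config.seed, t=config.enrichment_threshold, alpha=config.alpha)

    bundle: dict = {
        "normalization": settings.as_dict(),
        "screen": {
            "reference": manifest.reference,
            "ladder": list(config.ladder),
            "counts": screen.counts,
            "similarity_percent": similarity,
        },
        "consensus": {
            "threshold": config.consensus_threshold,
            "genes": sorted(consensus.index),
            "candidates": candidates,
        },
        "clustering": {
            "newick": clustering.to_newick(dendrogram),
            "merges": [{"height": h, "a": list(a), "b": list(b)}
                       for h, a, b in dendrogram.merges],
        },
        "enrichment": {
            "threshold": config.enrichment_threshold,
            "table": enrichment.table,
            "autosome_average_percent": enrichment.autosome_average_percent,
            "x_to_autosome_ratio": enrichment.x_to_autosome_ratio,
            "expected_uniform": expected,
            "direction_split": split,
        },
        "hotspots": {
            "chromosome": hotspots.chromosome,
            "window_size": hotspots.window_size,
            "n_perm": hotspots.n_perm,
            "significant": hotspots.significant,
        },
        "imprint_panel": panel,
    }
    if ct is not None:
        bundle["qpcr"] = qpcr.relative_expression_table(
            ct, config.efficiency, manifest, config.alpha)
    if methylation is not None:
        bundle["msqpcr"] = msqpcr.summarize_methylation(
            methylation, config.efficiency, manifest, config.alpha)
    # internal objects some callers want back (not serialised verbatim)
    bundle["_objects"] = {"fct": fct, "collapsed": collapsed,
                          "dendrogram": dendrogram, "enrichment": enrichment,
                          "probe_map": probe_map}
    return bundle
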