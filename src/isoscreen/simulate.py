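"""Synthetic isogenic-reprogramming experiment generator.

Emulates the study design the pipeline analyses: one reference embryonic
stem cell line, several isogenic induced-pluripotent clones carrying
log-normal technical noise, a single maternally-imprinted gene silenced
beyond the consensus-screen threshold in every clone (with a matching
promoter-methylation shift), partial reactivation of silenced
inactive-X genes at ~2x dosage with escape genes exempt, sparse
background dysregulation at a uniform per-gene rate, one genetically
unrelated iPS line with a multiplied background rate, and somatic lines
with a broad differentiated expression shift.  Ct and methylation
tables are synthesised consistently with the expression matrix, and a
ground-truth ledger records every planted effect for recovery testing.

The imprint gene's silencing is planted relative to the reference
sample's realized value with one-sided technical variation, so the
realized fold is at least ``imprint_gene_fold`` in every clone by
construction — the generator's contract is a gene silenced beyond the
screen threshold in all clones, not an effect that merely averages
there.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (ROLE_CLONE, ROLE_REFERENCE, ROLE_SOMATIC, ROLE_UNRELATED,
                    CtTable, ExpressionMatrix, MethylationTable,
                    SampleManifest, ValidationError, validate_annotation)

# Approximate relative gene content per chromosome (protein-coding scale);
# only the proportions matter.
CHROMOSOME_GENE_WEIGHTS: dict[str, int] = {
    "1": 2000, "2": 1230, "3": 1060, "4": 750, "5": 880, "6": 1040,
    "7": 910, "8": 680, "9": 780, "10": 730, "11": 1300, "12": 1030,
    "13": 320, "14": 620, "15": 600, "16": 860, "17": 1180, "18": 270,
    "19": 1470, "20": 540, "21": 230, "22": 440, "X": 840,
}

_SUBSTREAM = {"expression": 0, "ct": 1, "methylation": 2, "layout": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults define the emulated study conditions.

    Rates are probabilities in [0, 1]; fold parameters are linear and
    must exceed 1 (``imprint_gene_fold=None`` disables the planted
    imprint effect, for null calibration).  ``noise_sd`` is the per-value
    log2 technical noise of every sample.  The background rate is per
    clone per gene; aggregated over clones with OR it produces the
    few-percent genome-wide alteration level the screens expect.
    """

    seed: int
    n_genes: int = 2000
    n_clones: int = 6
    n_somatic: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.15
    background_rate: float = 0.004
    background_effect_range: tuple[float, float] = (1.1, 2.5)
    imprint_gene_fold: float | None = 12.0
    xi_silenced_fraction: float = 0.75
    reactivated_fraction: float = 0.2
    shared_core_fraction: float = 0.5
    reactivation_log2: float = 1.0
    unrelated_multiplier: float = 4.0
    somatic_shift_fraction: float = 0.3
    somatic_shift_sd: float = 2.0
    n_imprinted_catalogue: int = 30
    ct_intercept: float = 38.0
    ct_slope: float = 1.0
    ct_noise_sd: float = 0.15
    ct_replicates: int = 3
    meth_imprint_reference: float = 0.1
    meth_imprint_clone: float = 0.5
    meth_xi_reference: float = 0.5
    meth_xi_clone: float = 0.2
    meth_ct_base: float = 24.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("background_rate", "xi_silenced_fraction",
                     "reactivated_fraction", "shared_core_fraction",
                     "somatic_shift_fraction", "meth_imprint_reference",
                     "meth_imprint_clone", "meth_xi_reference",
                     "meth_xi_clone"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1] (got {v})")
        if self.imprint_gene_fold is not None and self.imprint_gene_fold <= 1:
            raise ValidationError("imprint_gene_fold must be > 1 (or None)")
        if self.unrelated_multiplier < 0:
            raise ValidationError("unrelated_multiplier must be >= 0")
        for name in ("n_genes", "n_clones", "ct_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        lo, hi = self.background_effect_range
        if not (0 < lo <= hi):
            raise ValidationError("background_effect_range must be 0 < lo <= hi")

    def rng(self, stream: str) -> np.random.Generator:
        # fixed sub-stream offsets: adding a table never perturbs earlier draws
        return np.random.default_rng([_SUBSTREAM[stream], int(self.seed)])


@dataclass
class SimTruth:
    """Ground-truth ledger of every planted effect."""

    run_id: str
    imprint_gene: str | None
    imprint_effects: dict[str, float]                  # clone -> log2 effect
    core_reactivated: set[str]
    reactivated_by_clone: dict[str, set[str]]          # includes the core
    escape_genes: set[str]
    background: list[tuple[str, str, str, float]]      # gene, sample, dir, log2
    somatic_shifted: dict[str, set[str]]
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "imprint_gene": self.imprint_gene,
            "imprint_effects": dict(self.imprint_effects),
            "core_reactivated": sorted(self.core_reactivated),
            "reactivated_by_clone": {c: sorted(g) for c, g in
                                     self.reactivated_by_clone.items()},
            "escape_genes": sorted(self.escape_genes),
            "background": [list(t) for t in self.background],
            "somatic_shifted": {s: sorted(g) for s, g in
                                self.somatic_shifted.items()},
            "config": dataclasses.asdict(self.config),
        }


@dataclass
class SimulatedExperiment:
    expression: ExpressionMatrix        # raw linear intensities
    annotation: pd.DataFrame
    manifest: SampleManifest
    ct: CtTable
    methylation: MethylationTable
    truth: SimTruth


def _allocate_genes(n_genes: int) -> list[str]:
    """Deterministic largest-remainder allocation of genes to chromosomes."""
    chroms = list(CHROMOSOME_GENE_WEIGHTS)
    weights = np.array([CHROMOSOME_GENE_WEIGHTS[c] for c in chroms], float)
    exact = n_genes * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = n_genes - counts.sum()
    for i in np.argsort(-(exact - counts), kind="stable")[:remainder]:
        counts[i] += 1
    assignment: list[str] = []
    for c, k in zip(chroms, counts):
        assignment.extend([c] * int(k))
    return assignment


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Generate one full synthetic experiment from a seeded config."""
    cfg.validate()
    rng_layout = cfg.rng("layout")
    rng_expr = cfg.rng("expression")

    # -- gene layout ----------------------------------------------------
    chrom_of = _allocate_genes(cfg.n_genes)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    chrom_arr = np.array(chrom_of)
    positions = np.zeros(cfg.n_genes, dtype=int)
    for c in CHROMOSOME_GENE_WEIGHTS:       # fixed order: draws are
        idx = np.flatnonzero(chrom_arr == c)    # reproducible across processes
        if len(idx) == 0:
            continue
        pos = np.sort(rng_layout.choice(150_000_000, size=len(idx), replace=False))
        positions[idx] = pos + 1

    x_idx = np.flatnonzero(chrom_arr == "X")
    autosomal_idx = np.flatnonzero(chrom_arr != "X")

    # housekeeping normaliser: a stable chr12 gene
    chr12 = np.flatnonzero(chrom_arr == "12")
    hk_i = int(chr12[0])
    genes[hk_i] = "GAPDH"

    # planted imprint gene: one autosomal gene (never the housekeeper)
    imprint_i = None
    if cfg.imprint_gene_fold is not None:
        chr20 = [i for i in np.flatnonzero(chrom_arr == "20") if i != hk_i]
        pool = chr20 if chr20 else [i for i in autosomal_idx if i != hk_i]
        imprint_i = int(rng_layout.choice(pool))

    # imprinted-gene catalogue: the planted gene plus decoys without effects
    imprint_status = np.array(["none"] * cfg.n_genes, dtype=object)
    expressed_allele = np.array(["unknown"] * cfg.n_genes, dtype=object)
    decoy_pool = [i for i in autosomal_idx if i not in (hk_i, imprint_i)]
    n_decoys = min(max(cfg.n_imprinted_catalogue - 1, 0), len(decoy_pool))
    decoys = rng_layout.choice(decoy_pool, size=n_decoys, replace=False)
    for j, i in enumerate(decoys):
        imprint_status[i] = "known" if j % 2 == 0 else "predicted"
        expressed_allele[i] = "maternal" if j % 2 == 0 else "paternal"
    if imprint_i is not None:
        imprint_status[imprint_i] = "known"
        expressed_allele[imprint_i] = "paternal"   # maternally silenced

    # inactive-X classes: escape genes are exempt from silencing/reactivation
    xi_class = np.array(["unknown"] * cfg.n_genes, dtype=object)
    n_x = len(x_idx)
    n_silenced = int(round(cfg.xi_silenced_fraction * n_x))
    silenced_x = rng_layout.choice(x_idx, size=n_silenced, replace=False)
    xi_class[x_idx] = "escape"
    xi_class[silenced_x] = "silenced"
    escape_genes = {genes[i] for i in x_idx if xi_class[i] == "escape"}

    annotation = validate_annotation(pd.DataFrame({
        "chromosome": chrom_arr,
        "position": positions,
        "imprint_status": imprint_status,
        "expressed_allele": expressed_allele,
        "xi_class": xi_class,
    }, index=pd.Index(genes, name="symbol")))

    # -- samples ---------------------------------------------------------
    reference = "H9"
    clones = [f"reH9_{i + 1}" for i in range(cfg.n_clones)]
    unrelated = ["iPS_unrelated"]
    somatic = [f"somatic_{i + 1}" for i in range(cfg.n_somatic)]
    samples = [reference] + clones + unrelated + somatic
    roles = ([ROLE_REFERENCE] + [ROLE_CLONE] * cfg.n_clones
             + [ROLE_UNRELATED] + [ROLE_SOMATIC] * cfg.n_somatic)
    manifest = SampleManifest(
        pd.Series(roles, index=pd.Index(samples, name="sample")),
        pd.Series("F", index=pd.Index(samples, name="sample")))

    # -- log2 expression --------------------------------------------------
    baseline = rng_expr.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    baseline[hk_i] = cfg.baseline_mean + 2.0     # well-expressed housekeeper
    log2 = pd.DataFrame(
        baseline[:, None] + rng_expr.normal(0.0, cfg.noise_sd,
                                            (cfg.n_genes, len(samples))),
        index=pd.Index(genes, name="gene"), columns=samples)

    lo, hi = cfg.background_effect_range
    background: list[tuple[str, str, str, float]] = []

    def plant_background(sample: str, rate: float) -> None:
        mask = rng_expr.random(cfg.n_genes) < rate
        mask[hk_i] = False
        if imprint_i is not None:
            mask[imprint_i] = False
        idx = np.flatnonzero(mask)
        signs = rng_expr.choice([-1.0, 1.0], size=len(idx))
        mags = rng_expr.uniform(lo, hi, size=len(idx))
        log2.loc[:, sample] = log2[sample].to_numpy() + np.bincount(
            idx, weights=signs * mags, minlength=cfg.n_genes)
        for i, s, m in zip(idx, signs, mags):
            background.append((genes[i], sample, "up" if s > 0 else "down",
                               float(s * m)))

    # shared reactivation core plus clone-specific remainders
    silenced_list = sorted(genes[i] for i in silenced_x)
    n_core = int(round(cfg.reactivated_fraction * cfg.shared_core_fraction
                       * len(silenced_list)))
    n_extra = int(round(cfg.reactivated_fraction
                        * (1.0 - cfg.shared_core_fraction) * len(silenced_list)))
    core = set(rng_expr.choice(silenced_list, size=n_core, replace=False)) \
        if n_core else set()
    remaining = sorted(set(silenced_list) - core)
    reactivated_by_clone: dict[str, set[str]] = {}
    imprint_effects: dict[str, float] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}

    for clone in clones:
        plant_background(clone, cfg.background_rate)
        extra = set(rng_expr.choice(remaining, size=min(n_extra, len(remaining)),
                                    replace=False)) if n_extra and remaining else set()
        reactivated = core | extra
        reactivated_by_clone[clone] = reactivated
        for g in reactivated:
            log2.loc[g, clone] += cfg.reactivation_log2
        if imprint_i is not None:
            # contract: realized fold >= imprint_gene_fold vs the reference
            eff = -(np.log2(cfg.imprint_gene_fold)
                    + abs(rng_expr.normal(0.0, cfg.noise_sd)))
            log2.iloc[imprint_i, log2.columns.get_loc(clone)] = (
                log2.iloc[imprint_i, log2.columns.get_loc(reference)] + eff)
            imprint_effects[clone] = float(eff)

    for s in unrelated:
        plant_background(s, cfg.background_rate * cfg.unrelated_multiplier)

    somatic_shifted: dict[str, set[str]] = {}
    n_shift = int(round(cfg.somatic_shift_fraction * cfg.n_genes))
    for s in somatic:
        idx = rng_expr.choice(cfg.n_genes, size=n_shift, replace=False)
        idx = idx[idx != hk_i]          # keep the normaliser housekeeping-stable
        shifts = rng_expr.normal(0.0, cfg.somatic_shift_sd, size=len(idx))
        col = log2[s].to_numpy()
        col[idx] += shifts
        log2.loc[:, s] = col
        somatic_shifted[s] = {genes[i] for i in idx}

    expression = ExpressionMatrix(2.0 ** log2, "raw")

    truth = SimTruth(
        run_id=f"sim-seed{cfg.seed}",
        imprint_gene=genes[imprint_i] if imprint_i is not None else None,
        imprint_effects=imprint_effects,
        core_reactivated=core,
        reactivated_by_clone=reactivated_by_clone,
        escape_genes=escape_genes,
        background=background,
        somatic_shifted=somatic_shifted,
        config=cfg,
    )

    ct = _synthesize_ct(cfg, log2, manifest, truth)
    methylation = _synthesize_methylation(cfg, manifest, truth)
    return SimulatedExperiment(expression, annotation, manifest, ct,
                               methylation, truth)


def _qpcr_targets(truth: SimTruth, max_x_targets: int = 3) -> list[str]:
    targets = []
    if truth.imprint_gene:
        targets.append(truth.imprint_gene)
    targets.extend(sorted(truth.core_reactivated)[:max_x_targets])
    return targets


def _synthesize_ct(cfg: SimulationConfig, log2: pd.DataFrame,
                   manifest: SampleManifest, truth: SimTruth) -> CtTable:
    """Ct = intercept - slope * log2(expression) + noise, in triplicate."""
    rng = cfg.rng("ct")
    rows = []
    targets = _qpcr_targets(truth) + ["GAPDH"]
    for target in targets:
        for sample in manifest.samples:
            true_ct = cfg.ct_intercept - cfg.ct_slope * float(log2.loc[target, sample])
            for rep in range(1, cfg.ct_replicates + 1):
                rows.append((sample, target, rep,
                             true_ct + rng.normal(0.0, cfg.ct_noise_sd)))
    df = pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct"])
    return CtTable(df, reference_gene="GAPDH",
                   calibrator_sample=manifest.reference)


def _synthesize_methylation(cfg: SimulationConfig, manifest: SampleManifest,
                            truth: SimTruth) -> MethylationTable:
    """Ct pairs whose mean difference encodes the configured fractions."""
    rng = cfg.rng("methylation")
    loci: list[tuple[str, float, float]] = []   # locus, ref-like frac, clone-like frac
    if truth.imprint_gene:
        loci.append((f"{truth.imprint_gene}_promoter",
                     cfg.meth_imprint_reference, cfg.meth_imprint_clone))
    for g in sorted(truth.core_reactivated)[:2]:
        loci.append((f"{g}_promoter", cfg.meth_xi_reference, cfg.meth_xi_clone))
    reprogrammed = set(manifest.clones) | set(manifest.unrelated)
    rows = []
    for locus, ref_frac, clone_frac in loci:
        for sample in manifest.samples:
            frac = clone_frac if sample in reprogrammed else ref_frac
            diff = np.log2((1.0 - frac) / frac)
            for rep in range(1, cfg.ct_replicates + 1):
                base = cfg.meth_ct_base
                rows.append((sample, locus, rep,
                             base + diff + rng.normal(0.0, cfg.ct_noise_sd),
                             base + rng.normal(0.0, cfg.ct_noise_sd)))
    df = pd.DataFrame(rows, columns=["sample", "locus", "replicate",
                                     "ct_methylated", "ct_unmethylated"])
    return MethylationTable(df)


def truth_recovery_report(fct, annotation: pd.DataFrame,
                          manifest: SampleManifest, truth: SimTruth,
                          consensus_t: float = 10.0, t: float = 2.0) -> dict:
    """Precision/recall of each planted-effect class, plus headline calls.

    Vacuous ratios are reported as null rather than 1.0: precision is
    null with no detections, recall null with empty truth.
    """
    from .chromosome import chromosome_enrichment, direction_split
    from .diffscreen import consensus_screen, flag_signs

    def prf(predicted: set, actual: set) -> dict:
        tp = len(predicted & actual)
        return {
            "n_predicted": len(predicted), "n_true": len(actual),
            "n_recovered": tp,
            "precision": tp / len(predicted) if predicted else None,
            "recall": tp / len(actual) if actual else None,
        }

    cons = set(consensus_screen(fct, manifest, consensus_t).index)
    imprint_truth = {truth.imprint_gene} if truth.imprint_gene else set()

    signs = flag_signs(fct, t, samples=manifest.clones)
    chrom = annotation.reindex(fct.genes)["chromosome"]
    on_x = chrom == "X"
    react_pred = {(g, c) for c in manifest.clones
                  for g in signs.index[on_x & (signs[c] > 0)]}
    react_truth = {(g, c) for c, gs in truth.reactivated_by_clone.items()
                   for g in gs}

    planted = {g for gs in truth.reactivated_by_clone.values() for g in gs}
    planted |= imprint_truth
    bg_pred = {(g, c) for c in manifest.clones
               for g in signs.index[(signs[c] != 0)] if g not in planted}
    bg_truth = {(g, s) for g, s, _, _ in truth.background
                if s in set(manifest.clones)}

    enr = chromosome_enrichment(fct, annotation, manifest, t)
    split = direction_split(fct, annotation, manifest, "X", t)
    frac_up = split["fraction_up"]
    return {
        "run_id": truth.run_id,
        "imprint": prf(cons, imprint_truth),
        "reactivation": prf(react_pred, react_truth),
        "background": prf(bg_pred, bg_truth),
        "headline": {
            "imprint_gene_uniquely_found": cons == imprint_truth and bool(cons),
            "x_enrichment_detected": (enr.x_to_autosome_ratio is not None
                                      and enr.x_to_autosome_ratio > 2.0),
            "x_upregulation_dominant": frac_up is not None and frac_up >= 0.7,
            "x_to_autosome_ratio": enr.x_to_autosome_ratio,
            "x_fraction_up": frac_up,
        },
    }
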