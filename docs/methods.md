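# Methods

## The analysis model

The pipeline targets the isogenic reprogramming design: a reference
embryonic stem cell line, a set of induced pluripotent clones re-derived
from a differentiated descendant of that same line, one genetically
unrelated iPS line and somatic lines as controls. Because genetic
background is shared, the analysis is built entirely on fold changes
against the reference rather than on variance-moderated differential
statistics: the scientific questions — is a gene silenced in *every*
clone, is one chromosome hit more often than the genome-wide rate — are
questions about consistent, large deviations, not about small shifts
against biological replication.

All expression values are treated on the log2 scale. The preprocessing
chain is log2 → quantile normalization → per-gene median baseline
subtraction → unique-symbol collapse. The order is a design choice:
quantile normalization before baselining makes each sample share one
value distribution, and subtracting the per-gene median afterwards
leaves fold changes against the reference untouched (baseline
subtraction cancels in any sample-minus-sample difference). Whether
median baselining should be per-gene across samples or per-sample is
genuinely open for this kind of array processing; per-gene is
implemented, the setting is echoed into the run report so any
discrepancy against other toolchains is attributable.

Quantile normalization resolves ties deterministically: a run of equal
values within a sample receives the mean of the rank-mean targets its
rank range spans. This makes the operation exactly idempotent, which
the suite checks. Symbol collapse keeps the probe with the highest mean
expression across samples (ties: lexicographically smallest probe
identifier); collapse never invents values — every output row is an
input row.

## Screens and their conventions

A gene is flagged at linear threshold *t* when |Δ| > log2 *t*, strictly:
a gene exactly at 2-fold is *not* a ">2-fold" gene. The one deliberate
exception is the imprint panel, whose inclusive "at least 1.5-fold"
convention follows the panel's definition; both conventions are
explicit function arguments. Flagged sets are nested across the
threshold ladder and counts are non-increasing — both properties are
tested against a brute-force elementwise oracle.

The consensus screen intersects per-clone flag sets and is
direction-agnostic by default (the caller may require a uniform sign).
Transcriptome similarity is 100·(1 − flagged/measured) with the
measured unique-symbol count as denominator, rounded to one decimal for
display only.

Chromosome enrichment counts a gene as altered when it is flagged in at
least one clone (an all-clone variant is exposed as a flag). A gene up
in one clone and down in another increments both direction counters, so
direction fractions can sum above 1; the denominator is the altered
gene count. Genes without a chromosome assignment ("unplaced") are
excluded from all per-chromosome denominators; Y genes are tabulated
but excluded from the autosomal average and the X ratio (the design
targets female lines). The hotspot scan slides a 10-gene window along
the position-sorted chromosome and compares each window's altered count
to a seeded shuffle of the altered flags; since every same-size window
has the same exchangeable null, one null sample serves all windows, and
the permutation p-value is checked against the exact hypergeometric
tail in the tests. Window size and permutation count (10⁴) are
defaults of this implementation, not study-derived constants; cytoband
labels require a user-supplied band table, otherwise hotspots are
reported as coordinate ranges.

## qPCR and methylation quantification

Relative expression uses plain comparative ΔΔCt with amplification
efficiency fixed at 2 (no efficiency correction; the base is a config
knob). Replicate scatter propagates to RE by the delta method,
SE = RE·ln 2·√(s²_target/n + s²_ref/n), which the tests hold within 10 %
of a 10⁵-draw parametric bootstrap for Ct SDs up to 0.5 cycles. Whether
error bars belong on the ΔCt or the RE scale is ambiguous in practice;
the RE-scale delta method is used and labelled. The clone-group test is
a two-tailed one-sample t-test of the per-clone RE point estimates
against the reference value — technical replicate error deliberately
does not enter, so significance is a statement about the clone group,
never about an individual line. No multiple-testing correction is
applied, matching the single-gene verification setting.

Methylation-specific qPCR reduces to fraction = 1/(1 + 2^(Ct_M − Ct_U));
the same delta-method propagation and the same group t-test apply.

## Clustering

Samples are clustered by repeatedly merging the pair of clusters with
minimal Euclidean distance between unweighted-mean centroids, the
centroid recomputed from all member points after each merge (for
arithmetic means this equals the weighted child-centroid update; the
explicit recomputation removes any ambiguity). Ties are broken by the
lexicographically smallest pair of cluster representative names, which
makes the topology invariant to input order. Centroid linkage can
invert (a merge below an earlier height); raw heights are kept, and
branch lengths are floored at zero only for Newick export, with a
logged count. The unsquared metric is used. Equivalence with an
independent centroid-linkage implementation is asserted on random
instances in the tests.

## The synthetic experiment generator

The generator emulates the study conditions the analysis assumes, with
one value per biological knob:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | unique symbols, allocated to chr1–22 + X by realistic gene-count weights (~85 X genes) |
| n_clones | 6 | isogenic clones |
| baseline_mean / sd | 8 / 2 | log2 intensity distribution |
| noise_sd | 0.15 | per-value log2 technical noise (log-normal in linear scale) |
| background_rate | 0.004 | per clone per gene dysregulation probability, uniform across chromosomes; OR-aggregated over six clones this yields the ~2 % genome-wide altered level |
| background effect | ±U(1.1, 2.5) log2 | background dysregulation size |
| imprint_gene_fold | 12 | planted silencing of one maternally-imprinted autosomal gene |
| xi_silenced_fraction | 0.75 | X genes subject to inactivation (the rest are escape genes, exempt) |
| reactivated_fraction | 0.2 | silenced X genes reactivated per clone, half as a core shared by all clones, half clone-specific |
| reactivation effect | +1.0 log2 | dosage doubling |
| unrelated_multiplier | 4 | background-rate multiplier for the unrelated iPS line |
| somatic shift | 30 % of genes, N(0, 2) log2 | deliberately crude differentiated-state shift that exists only to exercise the clustering branch separation |

Ct tables are synthesised as Ct = 38 − log2(expression) + N(0, 0.15) in
triplicate with a stable housekeeping normaliser (GAPDH); methylation
Ct pairs encode configured fractions (imprinted promoter 0.1 in the
reference vs 0.5 in clones; inactive-X promoters 0.5 vs 0.2). All
draws come from one seeded generator with fixed per-table sub-streams,
so adding a table never perturbs earlier draws and a seed reproduces
the experiment bitwise across processes.

**Planting of the imprint gene.** The generator's contract is a gene
silenced beyond the consensus threshold in *every* clone. With a purely
additive effect, independent noise on clones and reference would push
the realized fold below 10× in roughly a third of runs (the margin
log2(12/10) ≈ 0.26 is comparable to the √2·0.15 ≈ 0.21 noise on a
delta), which would contradict the contract the recovery analysis
relies on. The planted clone value is therefore defined relative to the
reference sample's realized value, with one-sided (silencing-directed)
half-normal technical variation of the same scale: the realized
silencing fold is ≥ imprint_gene_fold in every clone by construction,
and the per-clone realized effects are recorded in the truth ledger.
The X-reactivation and background effects are ordinary additive
effects with no such guarantee.

**What the generator does not model.** Probe-level bead noise, batch
and scan-date effects, detection-floor censoring, correlated co-regulated
gene modules, copy-number artefacts, and any realistic somatic
transcriptome. Passing recovery tests therefore demonstrates that the
statistics detect the planted structure at realistic effect and noise
scales — not that real microarray data would behave this cleanly.

## Problem sizes and numerical choices

The recovery and calibration analyses run the full pipeline at the
default 2000-gene, 10-sample scale over 100 seeds (end-to-end
recovery) and 200 seeds (null calibration: reactivation and imprint
effects disabled, X percent required to sit within three standard
errors of the autosomal average). Fold-threshold comparisons are exact
floating-point comparisons against log2 *t*; quantile-normalization
equality is asserted to 1e−9; dendrogram tie detection uses a 1e−12
absolute tolerance. Values ≤ 0 entering the log2 transform are floored
to 1.0 with a logged count. Degenerate inputs are defined rather than
accidental: a single-sample quantile normalization is the identity, a
chromosome with no measured genes reports a null percentage, a
zero-variance clone group yields a null p-value with a warning, and a
hotspot scan on a chromosome shorter than the window uses one
whole-chromosome window.

## Known limitations

- The fold screens carry no error model; a gene at 1.99-fold is
  invisible at 2×. This is faithful to the threshold-screen design but
  means counts near a threshold are sensitive to normalization details.
- The consensus screen's all-clone intersection is brittle to a single
  noisy clone by construction; that brittleness is the point of the
  planted-contract generator design above.
- Real probe-to-symbol annotation, imprinted-gene catalogues and
  cytoband tables are user-supplied inputs; none are embedded. The GEO
  series-matrix importer is a thin adapter and performs no probe
  remapping.
- Hotspot p-values are per-window and unadjusted for the number of
  windows scanned; they localize candidate regions rather than provide
  family-wise error control.
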