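# isoscreen

Transcriptome screening for isogenic comparisons of human embryonic stem
cells (hESCs) and induced pluripotent stem cells (hiPSCs).

When iPS clones are re-derived from a differentiated descendant of the
same ES line, every expression difference between a clone and the
reference line reflects reprogramming itself rather than genetic
background. Two epigenetic failure modes dominate that residue:
dysregulation of imprinted genes (parent-of-origin monoallelic
expression being erased or disturbed) and partial reactivation of the
inactive X chromosome in female lines, visible as a chromosome-wide
excess of up-regulated X genes. `isoscreen` implements the complete
analysis for this design, plus a synthetic-experiment generator that
plants each of those effects so the whole pipeline is testable without
any array data.

## What it computes

- **Preprocessing** — log2 transform, quantile normalization (each
  sample's sorted values replaced by cross-sample rank means, ties
  averaged), per-gene median baseline subtraction, and collapse to
  unique gene symbols (highest-mean probe kept).
- **Fold screens** — per-gene signed deviation Δ<sub>gs</sub> =
  log2(x<sub>gs</sub>) − log2(x<sub>g,ref</sub>); a gene is flagged at
  linear fold *t* iff |Δ| > log2 *t* (strict). Threshold-ladder counts
  per sample (1.5/2/5/10/50×), transcriptome similarity
  100·(1 − flagged/measured), and the all-clone consensus screen
  (genes flagged in *every* isogenic clone) that isolates a single
  consistently silenced imprinted gene.
- **Clustering** — agglomerative sample clustering with ordinary
  Euclidean distance between unweighted cluster centroids
  d(A,B) = ‖(1/n)ΣX<sub>a</sub> − (1/m)ΣX<sub>b</sub>‖, Newick export.
- **Chromosome enrichment** — percent of measured genes altered
  (≥1 clone) per chromosome, the autosomal average as the uniform
  null, the X/autosome ratio, the up/down direction split on X, and a
  sliding-window permutation scan for locus-contiguous hotspots
  (null count per window is hypergeometric; p = (1 + #{null ≥ obs})/(1 + N)).
- **Imprint panel** — restriction of the screen to an imprinted-gene
  catalogue at an inclusive 1.5-fold threshold, plus consensus
  biomarker candidates.
- **qPCR / MS-qPCR** — comparative ΔΔCt relative expression
  (RE = 2<sup>−ΔΔCt</sup>, normalized to GAPDH, delta-method standard
  errors from triplicates), methylation fraction
  M/(M+U) = 1/(1 + 2<sup>Ct_M − Ct_U</sup>), and the two-tailed
  one-sample t-test of the clone group against the reference mean
  (α = 0.05).

## Worked example

```bash
isoscreen simulate --seed 7 -o data        # synthetic experiment + truth ledger
isoscreen run-all -d data -o results --seed 7
```

`results/report.json` then contains, for this seed (2000 genes, H9-like
reference, six clones, one unrelated iPS line, two somatic lines):

- `consensus.genes = ["G01805"]` — the single gene deviating >10-fold
  in all six clones; `data/truth.json` confirms `G01805` is the planted
  maternally-imprinted gene, and the qPCR section shows it suppressed in
  every clone (e.g. reH9_1 RE = 0.070 ± 0.010, clone-group
  p ≈ 5·10⁻¹²) while the reference stays at RE = 1.
- `enrichment` — autosome average 2.5 % of genes altered at 2-fold vs
  24.7 % on the X chromosome (ratio 9.9), with 19 of 21 altered X genes
  up-regulated (`fraction_up = 0.90`): the planted partial
  X-reactivation signature.
- `screen.counts` — per-clone 2-fold counts of 11–21 against 32 for the
  unrelated iPS line and ~350–400 for somatic lines;
  `similarity_percent` for clone reH9_1 is 99.5 % at 2-fold.
- `clustering.newick` — the reference merges with the isogenic clones
  first; the unrelated iPS line joins that branch later and the somatic
  lines sit on a distant branch.

`isoscreen recover -d data -o results` scores the run against the truth
ledger (precision/recall per planted effect class).

## Layout

```
src/isoscreen/
  types.py       shared data model (matrix, manifest, annotation, Ct tables)
  io.py          TSV/JSON readers and writers, GEO series-matrix adapter
  normalize.py   log2 / quantile / baseline / symbol collapse
  diffscreen.py  fold-change flags, ladder counts, consensus, similarity
  clustering.py  centroid-linkage dendrogram + Newick
  chromosome.py  enrichment, direction split, hotspot permutation scan
  imprinting.py  imprint panel and biomarker candidates
  qpcr.py        ddCt, replicate SE, group t-test
  msqpcr.py      methylation fraction M/(M+U)
  simulate.py    synthetic experiment generator + truth recovery
  pipeline.py    orchestration used by the CLI and scripts
  cli.py         `isoscreen` command line
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
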