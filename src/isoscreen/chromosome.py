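"""Chromosome-wise dysregulation analysis and X-reactivation detection.

A gene is "altered" when it deviates beyond the fold threshold in at
least one isogenic clone (an all-clone variant is available).  The
autosomal average provides the stochastic null: if incomplete
reprogramming hits genes uniformly, every chromosome should show the
same altered percentage, so an excess on X relative to that baseline is
the signature of partial inactive-X reactivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffscreen import flag_signs
from .types import (AUTOSOMES, FoldChangeTable, SampleManifest,
                    ValidationError)

_CHROM_ORDER = list(AUTOSOMES) + ["X", "Y"]


def _clone_signs(fct: FoldChangeTable, manifest: SampleManifest, t: float,
                 all_clones: bool) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Per-gene altered/up/down indicators aggregated over clones."""
    manifest.require_clones(1)
    signs = flag_signs(fct, t, samples=manifest.clones)
    agg = (lambda df: df.all(axis=1)) if all_clones else (lambda df: df.any(axis=1))
    altered = agg(signs != 0)
    up = (signs > 0).any(axis=1) & altered
    down = (signs < 0).any(axis=1) & altered
    return altered, up, down


@dataclass
class ChromosomeEnrichment:
    """Per-chromosome dysregulation summary.

    ``table`` rows (chromosomes in karyotype order) carry measured and
    altered gene counts, percent altered, and up/down direction counts
    (a gene up in one clone and down in another increments both, so
    up + down >= altered).  Y-chromosome genes are tabulated but excluded
    from the autosomal average and the X ratio; unplaced genes are
    excluded entirely.
    """

    table: pd.DataFrame
    autosome_average_percent: float
    x_to_autosome_ratio: float | None
    threshold: float

    @property
    def x_percent(self) -> float | None:
        if "X" not in self.table.index:
            return None
        v = self.table.loc["X", "percent"]
        return None if pd.isna(v) else float(v)


def chromosome_enrichment(fct: FoldChangeTable, annotation: pd.DataFrame,
                          manifest: SampleManifest, t: float = 2.0,
                          all_clones: bool = False) -> ChromosomeEnrichment:
    """Percent of measured genes altered per chromosome, with X ratio.

    percent = 100 * altered / measured per chromosome; the autosomal
    average is the measured-count-weighted mean over chr1..22, and the
    X ratio divides X's percent by it.  Chromosomes with zero measured
    genes report percent as null (NaN).
    """
    altered, up, down = _clone_signs(fct, manifest, t, all_clones)
    chrom = annotation.reindex(fct.genes)["chromosome"].fillna("unplaced")
    keep = chrom != "unplaced"
    df = pd.DataFrame({"chromosome": chrom[keep],
                       "altered": altered[keep],
                       "up": up[keep],
                       "down": down[keep]})
    grouped = df.groupby("chromosome").agg(
        measured=("altered", "size"), altered=("altered", "sum"),
        up=("up", "sum"), down=("down", "sum"))
    order = [c for c in _CHROM_ORDER if c in grouped.index]
    grouped = grouped.loc[order]
    grouped["percent"] = np.where(grouped["measured"] > 0,
                                  100.0 * grouped["altered"] / grouped["measured"],
                                  np.nan)
    auto = grouped.loc[grouped.index.isin(AUTOSOMES)]
    measured_auto = int(auto["measured"].sum())
    if measured_auto == 0:
        raise ValidationError("no autosomal genes measured")
    avg = 100.0 * float(auto["altered"].sum()) / measured_auto
    x_pct = grouped.loc["X", "percent"] if "X" in grouped.index else np.nan
    ratio = float(x_pct) / avg if (avg > 0 and not pd.isna(x_pct)) else None
    grouped.index.name = "chromosome"
    return ChromosomeEnrichment(grouped, avg, ratio, float(t))


def direction_split(fct: FoldChangeTable, annotation: pd.DataFrame,
                    manifest: SampleManifest, chromosome: str = "X",
                    t: float = 2.0, all_clones: bool = False) -> dict:
    """Up/down split of altered genes on one chromosome.

    A gene counts as "up" if flagged up in >= 1 clone (and likewise
    "down"), so a gene altered in both directions contributes to both
    numerators and fractions can sum above 1.  Returns null fractions
    when nothing is altered.
    """
    altered, up, down = _clone_signs(fct, manifest, t, all_clones)
    chrom = annotation.reindex(fct.genes)["chromosome"].fillna("unplaced")
    on = chrom == chromosome
    n_measured = int(on.sum())
    n_altered = int(altered[on].sum())
    n_up = int(up[on].sum())
    n_down = int(down[on].sum())
    result = {"chromosome": chromosome, "measured": n_measured,
              "altered": n_altered, "up": n_up, "down": n_down,
              "fraction_up": None, "fraction_down": None,
              "percent_of_measured_up": None}
    if n_altered > 0:
        result["fraction_up"] = n_up / n_altered
        result["fraction_down"] = n_down / n_altered
        if n_measured > 0:
            result["percent_of_measured_up"] = 100.0 * n_up / n_measured
    return result


def expected_uniform_rate(enrichment: ChromosomeEnrichment) -> pd.DataFrame:
    """Expected altered counts under a uniform (autosome-average) null.

    expected = measured * autosome_average / 100 per chromosome; the sum
    of autosomal expectations equals the total autosomal altered count
    exactly.  Also reports observed/expected.
    """
    tab = enrichment.table
    expected = tab["measured"] * enrichment.autosome_average_percent / 100.0
    out = pd.DataFrame({"measured": tab["measured"],
                        "observed": tab["altered"],
                        "expected": expected})
    out["obs_over_exp"] = np.where(expected > 0, tab["altered"] / expected, np.nan)
    return out


@dataclass
class HotspotResult:
    """Sliding-window hotspot scan output.

    ``windows`` holds every window in positional order with its altered
    count and permutation p-value; ``significant`` is the subset with
    p < alpha.
    """

    windows: pd.DataFrame
    significant: pd.DataFrame
    chromosome: str
    window_size: int
    n_perm: int
    alpha: float


def hotspot_scan(fct: FoldChangeTable, annotation: pd.DataFrame,
                 manifest: SampleManifest, chromosome: str = "X",
                 window_size: int = 10, n_perm: int = 10_000,
                 seed: int | None = None, t: float = 2.0,
                 alpha: float = 0.05, all_clones: bool = False) -> HotspotResult:
    """Scan for locus-contiguous runs of dysregulated genes.

    Genes on the chromosome are sorted by position; each window of
    ``window_size`` consecutive genes is scored by its altered-gene
    count.  The null shuffles the altered flags across the chromosome's
    genes (seeded), so a window's null count is hypergeometric; the
    permutation p-value is (1 + #{null >= observed}) / (1 + n_perm).
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    altered, _, _ = _clone_signs(fct, manifest, t, all_clones)
    ann = annotation.reindex(fct.genes)
    on = ann["chromosome"] == chromosome
    genes = ann.loc[on].sort_values("position", kind="mergesort")
    flags = altered.reindex(genes.index).to_numpy(bool)
    n = len(flags)
    k = min(window_size, n) if n else 0
    cols = ["chromosome", "start_index", "end_index", "start_pos", "end_pos",
            "altered_in_window", "p_value"]
    if n == 0 or flags.sum() == 0:
        empty = pd.DataFrame(columns=cols)
        return HotspotResult(empty, empty, chromosome, window_size, n_perm, alpha)
    csum = np.r_[0, np.cumsum(flags.astype(int))]
    observed = csum[k:] - csum[:-k]          # count per window
    rng = np.random.default_rng(seed)
    # Exchangeability: under a flag shuffle every same-size window has the
    # same null, so one null sample (count in the first k slots of each
    # shuffled vector) serves all windows.
    null_counts = np.empty(n_perm, dtype=int)
    work = flags.copy()
    for i in range(n_perm):
        rng.shuffle(work)
        null_counts[i] = int(work[:k].sum())
    null_sorted = np.sort(null_counts)
    n_ge = n_perm - np.searchsorted(null_sorted, observed, side="left")
    pvals = (1.0 + n_ge) / (1.0 + n_perm)
    positions = genes["position"].to_numpy()
    windows = pd.DataFrame({
        "chromosome": chromosome,
        "start_index": np.arange(len(observed)),
        "end_index": np.arange(len(observed)) + k - 1,
        "start_pos": positions[:len(observed)],
        "end_pos": positions[k - 1:],
        "altered_in_window": observed,
        "p_value": pvals,
    })[cols]
    significant = windows[windows["p_value"] < alpha].reset_index(drop=True)
    return HotspotResult(windows, significant, chromosome, k, n_perm, alpha)
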