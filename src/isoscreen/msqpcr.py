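"""Methylation fraction from methylation-specific qPCR Ct pairs.

With methylated- and unmethylated-allele amplifications on bisulfite
converted DNA, template amounts scale as efficiency^(-Ct), so the
methylated fraction M/(M+U) reduces to 1 / (1 + eff^(Ct_M - Ct_U)).
Equal Ct values give exactly 0.5 (one methylated and one unmethylated
allele), and fraction(a, b) + fraction(b, a) = 1 identically.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .qpcr import group_t_test
from .types import MethylationTable, ValidationError


def methylation_fraction(ct_methylated, ct_unmethylated,
                         efficiency: float = 2.0):
    """M/(M+U) methylated fraction from a Ct pair (scalar or array)."""
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must be > 1")
    d = np.asarray(ct_methylated, float) - np.asarray(ct_unmethylated, float)
    frac = 1.0 / (1.0 + efficiency ** d)
    if np.ndim(ct_methylated) == 0 and np.ndim(ct_unmethylated) == 0:
        return float(frac)
    return frac


def summarize_methylation(table: MethylationTable, efficiency: float = 2.0,
                          manifest=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per (sample, locus) methylation fraction with delta-method SE.

    The fraction is computed from the replicate-mean Ct difference
    d = mean(Ct_M) - mean(Ct_U); its SE follows from
    |df/dd| = ln(eff) * f * (1 - f) applied to
    SD(d) = sqrt(sd_M^2/n + sd_U^2/n).  With a manifest, the isogenic
    clone group is compared to the reference line's fraction with the
    same one-sample t-test used for expression qPCR.
    """
    rows = []
    for (sample, locus), grp in table.data.groupby(["sample", "locus"]):
        m = grp["ct_methylated"].to_numpy(float)
        u = grp["ct_unmethylated"].to_numpy(float)
        d = float(m.mean() - u.mean())
        frac = 1.0 / (1.0 + efficiency ** d)
        if len(m) > 1:
            sd_d = math.sqrt(np.var(m, ddof=1) / len(m) + np.var(u, ddof=1) / len(u))
            se = math.log(efficiency) * frac * (1.0 - frac) * sd_d
        else:
            se = float("nan")
        rows.append((sample, locus, frac, se, len(m)))
    out = pd.DataFrame(rows, columns=["sample", "locus", "fraction", "se", "n"])
    if manifest is not None:
        out["group_p"] = np.nan
        out["significant"] = False
        for locus, grp in out.groupby("locus"):
            clones = grp[grp["sample"].isin(manifest.clones)]
            ref = grp[grp["sample"] == manifest.reference]
            if len(clones) >= 2 and len(ref) == 1:
                test = group_t_test(clones["fraction"],
                                    float(ref["fraction"].iloc[0]), alpha)
                sel = out["locus"].eq(locus) & out["sample"].isin(manifest.clones)
                out.loc[sel, "group_p"] = test.p
                out.loc[sel, "significant"] = test.significant
    return out
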