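"""Relative expression from qPCR Ct values (comparative ddCt method).

For each sample, dCt = mean Ct(target) - mean Ct(reference gene); the
calibrator sample's dCt is subtracted to give ddCt, and relative
expression RE = efficiency^(-ddCt) with efficiency 2 by default (one
doubling per cycle, no efficiency correction).  Technical-replicate
scatter is propagated to RE with the delta method; the group test
compares the per-clone RE point estimates to the reference line's mean
with a two-tailed one-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CtTable, ValidationError

log = logging.getLogger(__name__)


def replicate_se(re: float, sd_target: float, n_target: int,
                 sd_ref: float, n_ref: int, efficiency: float = 2.0) -> float:
    """Delta-method standard error of RE from replicate Ct scatter.

    SD(dCt) = sqrt(sd_target^2/n_target + sd_ref^2/n_ref), and
    SE(RE) = RE * ln(efficiency) * SD(dCt).
    """
    if n_target < 2 or n_ref < 2:
        log.warning("replicate_se: need >= 2 replicates for an SE")
        return float("nan")
    sd_dct = math.sqrt(sd_target ** 2 / n_target + sd_ref ** 2 / n_ref)
    return re * math.log(efficiency) * sd_dct


def ddct(ct: CtTable, target: str, efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression of ``target`` per sample, calibrator = 1.

    Returns a DataFrame indexed by sample with columns dct, sd_dct,
    ddct, re and se.  The calibrator sample's RE is exactly 1.  RE is
    invariant to adding a constant to every Ct of a sample (the target
    and reference shifts cancel in dCt).
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must be > 1")
    data = ct.data
    tgt = data[data["target"] == target]
    ref = data[data["target"] == ct.reference_gene]
    if tgt.empty:
        raise ValidationError(f"no Ct measurements for target {target!r}")
    samples = sorted(set(tgt["sample"]))
    if ct.calibrator_sample not in samples:
        raise ValidationError(
            f"calibrator sample {ct.calibrator_sample!r} has no "
            f"measurements for target {target!r}")

    def _stats(df: pd.DataFrame, sample: str) -> tuple[float, float, int]:
        vals = df.loc[df["sample"] == sample, "ct"].to_numpy(float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        return float(vals.mean()), sd, len(vals)

    rows = {}
    for s in samples:
        mt, sdt, nt = _stats(tgt, s)
        mr, sdr, nr = _stats(ref, s)
        rows[s] = (mt - mr, sdt, nt, sdr, nr)
    dct_cal = rows[ct.calibrator_sample][0]
    out = pd.DataFrame(index=pd.Index(samples, name="sample"),
                       columns=["dct", "sd_dct", "ddct", "re", "se"],
                       dtype=float)
    for s, (dct_s, sdt, nt, sdr, nr) in rows.items():
        ddct_s = dct_s - dct_cal
        re = efficiency ** (-ddct_s)
        if nt > 1 and nr > 1:
            sd_dct = math.sqrt(sdt ** 2 / nt + sdr ** 2 / nr)
            se = re * math.log(efficiency) * sd_dct
        else:
            sd_dct, se = float("nan"), float("nan")
        out.loc[s] = (dct_s, sd_dct, ddct_s, re, se)
    out.loc[ct.calibrator_sample, "re"] = 1.0   # exact by definition
    return out


@dataclass(frozen=True)
class GroupTestResult:
    t: float
    df: int
    p: float
    significant: bool
    alpha: float = 0.05


def group_t_test(values, reference_mean: float,
                 alpha: float = 0.05) -> GroupTestResult:
    """Two-tailed one-sample t-test of the clone group vs a reference mean.

    ``values`` are per-clone point estimates treated as one group;
    technical-replicate error does not enter.  Requires >= 2 values with
    nonzero variance; a zero-variance group yields a null p with a
    warning rather than a spurious certainty.
    """
    v = np.asarray(list(values), float)
    if v.size < 2:
        raise ValidationError("group t-test requires >= 2 values")
    s = float(np.std(v, ddof=1))
    if s == 0:
        log.warning("group_t_test: zero variance, p undefined")
        return GroupTestResult(float("nan"), v.size - 1, float("nan"), False, alpha)
    t = (float(v.mean()) - reference_mean) / (s / math.sqrt(v.size))
    p = 2.0 * float(stats.t.sf(abs(t), v.size - 1))
    return GroupTestResult(t, v.size - 1, p, p < alpha, alpha)


def relative_expression_table(ct: CtTable, efficiency: float = 2.0,
                              manifest=None, alpha: float = 0.05) -> pd.DataFrame:
    """RE summary for every target, with the clone-group test if possible.

    Long-format export mirroring the bar-plot data: one row per
    (target, sample) with RE, SE and, when a manifest is supplied, the
    group p-value repeated on each clone row of that target.
    """
    frames = []
    for target in ct.targets():
        res = ddct(ct, target, efficiency)
        res = res.reset_index()
        res.insert(0, "target", target)
        if manifest is not None:
            clones = [c for c in manifest.clones if c in set(res["sample"])]
            if len(clones) >= 2:
                ref_mean = float(res.loc[res["sample"] == manifest.reference,
                                         "re"].iloc[0])
                test = group_t_test(res.set_index("sample").loc[clones, "re"],
                                    ref_mean, alpha)
                res["group_p"] = np.where(res["sample"].isin(clones), test.p, np.nan)
                res["significant"] = np.where(res["sample"].isin(clones),
                                              test.significant, False)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
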