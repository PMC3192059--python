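import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from isoscreen.chromosome import (chromosome_enrichment, direction_split,
                                  expected_uniform_rate, hotspot_scan)

from conftest import make_fct, make_manifest


def annotation_for(genes, chromosomes, positions=None):
    positions = positions or list(range(1, len(genes) + 1))
    return pd.DataFrame({"chromosome": chromosomes, "position": positions,
                         "imprint_status": "none",
                         "expressed_allele": "unknown",
                         "xi_class": "unknown"},
                        index=pd.Index(genes, name="symbol"))


def toy_enrichment(n_chr1=100, altered_chr1=2, n_x=150, altered_x=8):
    genes = ([f"a{i}" for i in range(n_chr1)] + [f"x{i}" for i in range(n_x)])
    chroms = ["1"] * n_chr1 + ["X"] * n_x
    deltas = {}
    for i, g in enumerate(genes):
        altered = (g.startswith("a") and i < altered_chr1) or \
                  (g.startswith("x") and int(g[1:]) < altered_x)
        deltas[g] = [2.0 if altered else 0.0, 0.0]
    fct = make_fct(deltas, samples=["c1", "c2"])
    manifest = make_manifest(clones=("c1", "c2"))
    return fct, annotation_for(genes, chroms), manifest


class TestEnrichment:
    def test_toy_percentages_and_ratio(self):
        fct, ann, manifest = toy_enrichment()
        enr = chromosome_enrichment(fct, ann, manifest, t=2.0)
        assert enr.table.loc["1", "percent"] == pytest.approx(2.0)
        assert enr.table.loc["X", "percent"] == pytest.approx(100 * 8 / 150)
        assert enr.autosome_average_percent == pytest.approx(2.0)
        assert enr.x_to_autosome_ratio == pytest.approx((8 / 150) / 0.02)

    def test_autosome_average_is_weighted_mean(self, rng):
        genes = [f"g{i}" for i in range(300)]
        chroms = rng.choice(["1", "2", "3", "X"], size=300).tolist()
        deltas = {g: [float(rng.normal(0, 1.5)), float(rng.normal(0, 1.5))]
                  for g in genes}
        fct = make_fct(deltas, samples=["c1", "c2"])
        manifest = make_manifest(clones=("c1", "c2"))
        enr = chromosome_enrichment(fct, annotation_for(genes, chroms), manifest)
        auto = enr.table.loc[enr.table.index.isin(["1", "2", "3"])]
        weighted = (auto["percent"] * auto["measured"]).sum() / auto["measured"].sum()
        assert enr.autosome_average_percent == pytest.approx(weighted)
        # per-chromosome altered counts partition the genome-wide count
        assert enr.table["altered"].sum() == \
            (pd.concat([auto["altered"]]).sum() + enr.table.loc["X", "altered"])

    def test_altered_counts_each_gene_once(self):
        fct, ann, manifest = toy_enrichment()
        enr = chromosome_enrichment(fct, ann, manifest)
        assert enr.table["altered"].sum() == 10
        assert (enr.table["altered"] <= enr.table["measured"]).all()


class TestDirectionSplit:
    def test_mixed_direction_counting_rule(self):
        # 10 altered: 7 up-only, 2 down-only, 1 both -> fraction_up = 8/10
        deltas = {}
        for i in range(7):
            deltas[f"u{i}"] = [2.0, 0.0]
        for i in range(2):
            deltas[f"d{i}"] = [-2.0, 0.0]
        deltas["m0"] = [2.0, -2.0]
        deltas["quiet"] = [0.0, 0.0]
        genes = list(deltas)
        fct = make_fct(deltas, samples=["c1", "c2"])
        manifest = make_manifest(clones=("c1", "c2"))
        split = direction_split(fct, annotation_for(genes, ["X"] * len(genes)),
                                manifest, "X", t=2.0)
        assert split["altered"] == 10
        assert split["up"] == 8
        assert split["down"] == 3
        assert split["fraction_up"] == pytest.approx(0.8)

    def test_all_up_and_empty_conventions(self):
        fct = make_fct({"a": [3.0], "b": [2.5]})
        manifest = make_manifest(clones=("c1",))
        ann = annotation_for(["a", "b"], ["X", "X"])
        assert direction_split(fct, ann, manifest, "X")["fraction_up"] == 1.0
        quiet = make_fct({"a": [0.0], "b": [0.0]})
        assert direction_split(quiet, ann, manifest, "X")["fraction_up"] is None


class TestExpectedUniformRate:
    def test_expected_counts_and_identity(self):
        fct, ann, manifest = toy_enrichment()
        enr = chromosome_enrichment(fct, ann, manifest)
        exp = expected_uniform_rate(enr)
        assert exp.loc["1", "expected"] == pytest.approx(100 * 2.0 / 100)
        # sum of autosomal expectations equals total autosomal altered
        auto = exp.loc[exp.index != "X"]
        assert auto["expected"].sum() == pytest.approx(auto["observed"].sum())
        assert exp.loc["X", "obs_over_exp"] == pytest.approx(
            enr.x_to_autosome_ratio)


class TestHotspotScan:
    def make_x(self, flags):
        genes = [f"x{i}" for i in range(len(flags))]
        deltas = {g: [2.0 if f else 0.0] for g, f in zip(genes, flags)}
        fct = make_fct(deltas)
        ann = annotation_for(genes, ["X"] * len(genes),
                             positions=[10 * (i + 1) for i in range(len(flags))])
        return fct, ann, make_manifest(clones=("c1",))

    def test_consecutive_run_is_significant(self):
        flags = [False] * 45 + [True] * 10 + [False] * 45
        fct, ann, manifest = self.make_x(flags)
        res = hotspot_scan(fct, ann, manifest, "X", window_size=10,
                           n_perm=5000, seed=11)
        best = res.windows.loc[res.windows["altered_in_window"].idxmax()]
        assert best["altered_in_window"] == 10
        assert best["p_value"] <= 0.001
        assert len(res.significant) >= 1

    def test_zero_altered_reports_nothing(self):
        fct, ann, manifest = self.make_x([False] * 30)
        res = hotspot_scan(fct, ann, manifest, "X", seed=1)
        assert res.windows.empty and res.significant.empty

    def test_fewer_genes_than_window_gives_single_window(self):
        fct, ann, manifest = self.make_x([True, False, True])
        res = hotspot_scan(fct, ann, manifest, "X", window_size=10,
                           n_perm=500, seed=2)
        assert len(res.windows) == 1
        assert res.windows.iloc[0]["altered_in_window"] == 2

    def test_permutation_p_matches_hypergeometric_tail(self):
        """For a window of k genes on a chromosome with K altered of N,
        the shuffle null count is Hypergeom(N, K, k); the permutation
        p-value must agree with the exact tail within Monte-Carlo error."""
        flags = ([True] * 4 + [False] * 6) + [True] * 4 + [False] * 26
        fct, ann, manifest = self.make_x(flags)
        n_perm = 20000
        res = hotspot_scan(fct, ann, manifest, "X", window_size=10,
                           n_perm=n_perm, seed=3)
        N, K, k = len(flags), sum(flags), 10
        for _, w in res.windows.iterrows():
            obs = int(w["altered_in_window"])
            exact = float(hypergeom.sf(obs - 1, N, K, k))
            mc_err = 3 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
            assert abs(w["p_value"] - exact) <= mc_err
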