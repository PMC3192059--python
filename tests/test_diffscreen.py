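import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoscreen import ExpressionMatrix, ValidationError
from isoscreen.diffscreen import (compute_fold_changes, consensus_screen,
                                  flag_signs, ladder_counts,
                                  similarity_percent)

from conftest import make_fct, make_manifest


class TestFoldChanges:
    def test_reference_column_zero_and_never_flagged(self):
        manifest = make_manifest(clones=("c1",))
        values = pd.DataFrame({"H9": [3.0, 5.0], "c1": [4.0, 1.0]},
                              index=pd.Index(["a", "b"], name="gene"))
        fct = compute_fold_changes(
            ExpressionMatrix(values, "log2_normalized"), manifest)
        assert (fct.delta["H9"] == 0).all()
        assert not flag_signs(fct, 1.5)["H9"].any()

    def test_missing_reference_rejected(self):
        manifest = make_manifest(reference="absent", clones=("c1",))
        values = pd.DataFrame({"c1": [1.0]}, index=pd.Index(["a"], name="gene"))
        with pytest.raises(ValidationError):
            compute_fold_changes(ExpressionMatrix(values, "log2_normalized"),
                                 manifest)

    def test_strict_boundary_excluded(self):
        # delta exactly log2(2) = 1.0 is NOT flagged at the 2-fold threshold
        fct = make_fct({"a": [1.0]})
        assert flag_signs(fct, 2.0)["c1"]["a"] == 0
        assert flag_signs(fct, 2.0, inclusive=True)["c1"]["a"] == 1

    def test_direction_sign(self):
        fct = make_fct({"a": [-3.46]})
        assert flag_signs(fct, 10.0)["c1"]["a"] == -1     # log2(10)=3.3219

    def test_baseline_invariance(self):
        # adding a per-gene constant to every sample leaves delta unchanged
        manifest = make_manifest(clones=("c1", "c2"))
        values = pd.DataFrame(np.random.default_rng(5).normal(8, 2, (6, 3)),
                              index=pd.Index(list("abcdef"), name="gene"),
                              columns=["H9", "c1", "c2"])
        fct1 = compute_fold_changes(ExpressionMatrix(values, "log2_normalized"),
                                    manifest)
        shifted = values.add(pd.Series(range(6), index=values.index), axis=0)
        fct2 = compute_fold_changes(ExpressionMatrix(shifted, "log2_normalized"),
                                    manifest)
        pd.testing.assert_frame_equal(fct1.delta, fct2.delta)


class TestLadderCounts:
    def test_toy_counts_by_brute_force(self):
        """Deltas (0, 0.9, 1.2, 2.5, -3.5) against the strict-> rule.

        |d| > 1 (2x): {1.2, 2.5, 3.5} -> 3; |d| > log2(5)=2.322:
        {2.5, 3.5} -> 2; |d| > log2(10)=3.322: {3.5} -> 1.
        """
        fct = make_fct({g: [d] for g, d in
                        zip("abcde", [0.0, 0.9, 1.2, 2.5, -3.5])})
        counts = ladder_counts(fct).counts.loc["c1"]
        assert counts[2.0] == 3
        assert counts[5.0] == 2
        assert counts[10.0] == 1

    def test_nestedness_and_monotone_counts(self, rng):
        genes = [f"g{i}" for i in range(40)]
        fct = make_fct({g: list(rng.normal(0, 2, 3)) for g in genes},
                       samples=["c1", "c2", "c3"])
        res = ladder_counts(fct)
        for s in fct.samples:
            prev = None
            for t in fct.ladder:
                flagged = res.flagged(s, t)
                if prev is not None:
                    assert flagged <= prev
                prev = flagged
            assert (np.diff(res.counts.loc[s].to_numpy()) <= 0).all()

    def test_brute_force_oracle_equivalence(self, rng):
        """Flag sets match an independent elementwise re-evaluation."""
        for trial in range(5):
            arr = rng.normal(0, 2, (50, 10))
            genes = [f"g{i}" for i in range(50)]
            samples = [f"s{j}" for j in range(9)]
            fct = make_fct({g: list(arr[i, 1:]) for i, g in enumerate(genes)},
                           samples=samples)
            res = ladder_counts(fct)
            for t in fct.ladder:
                for j, s in enumerate(samples):
                    expected = {genes[i] for i in range(50)
                                if abs(arr[i, j + 1]) > np.log2(t)}
                    assert res.flagged(s, t) == expected


class TestConsensus:
    def test_gene_missing_in_one_clone_excluded(self):
        fct = make_fct({"a": [4.0, 4.0, 4.0, 4.0, 4.0, 0.5],
                        "b": [4.0] * 6},
                       samples=[f"c{i}" for i in range(1, 7)])
        manifest = make_manifest(clones=[f"c{i}" for i in range(1, 7)])
        cons = consensus_screen(fct, manifest, 10.0)
        assert list(cons.index) == ["b"]

    def test_direction_pattern_and_same_direction_option(self):
        fct = make_fct({"a": [2.0, -2.0], "b": [2.0, 2.0]},
                       samples=["c1", "c2"])
        manifest = make_manifest(clones=("c1", "c2"))
        cons = consensus_screen(fct, manifest, 2.0)
        assert set(cons.index) == {"a", "b"}
        assert list(cons.loc["a"]) == [1, -1]
        same = consensus_screen(fct, manifest, 2.0, require_same_direction=True)
        assert list(same.index) == ["b"]

    def test_degenerate_threshold_returns_all_measured_genes(self):
        fct = make_fct({"a": [0.2, 0.3], "b": [-0.1, 0.4]},
                       samples=["c1", "c2"])
        manifest = make_manifest(clones=("c1", "c2"))
        assert set(consensus_screen(fct, manifest, 1.0, inclusive=True).index) \
            == {"a", "b"}


class TestSimilarity:
    def test_printed_percentage_convention(self):
        # 102 flagged of 25000 measured genes -> 99.592, displayed 99.6
        genes = {f"g{i}": [2.0] for i in range(102)}
        genes.update({f"h{i}": [0.0] for i in range(25000 - 102)})
        fct = make_fct(genes)
        sim = similarity_percent(fct, "c1", 2.0)
        assert sim == pytest.approx(99.592)
        assert round(sim, 1) == 99.6

    def test_no_flags_gives_100(self):
        fct = make_fct({"a": [0.0], "b": [0.5]})
        assert similarity_percent(fct, "c1", 2.0) == pytest.approx(100.0)

    @given(st.integers(0, 40), st.integers(41, 100))
    def test_complement_identity(self, n_flagged, n_total):
        deltas = {f"g{i}": [3.0 if i < n_flagged else 0.0]
                  for i in range(n_total)}
        fct = make_fct(deltas)
        sim = similarity_percent(fct, "c1", 2.0)
        pct_dys = 100.0 * n_flagged / n_total
        assert sim + pct_dys == pytest.approx(100.0, abs=1e-9)
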