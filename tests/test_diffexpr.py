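"""FPKM normalization, contrast scheme, fold change, Welch surrogate and
exclusive-set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import floranet as fn
from floranet.diffexpr import CONTRAST_NAMES, DiffExprError


def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [100, 400, 250], "s2": [10, 40, 25]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    lengths = pd.Series([1000, 2000, 500], index=counts.index, name="length")
    return fn.CountMatrix(counts=counts, lengths=lengths)


class TestFpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s": [100]}, index=pd.Index(["g"], name="gene_id"))
        # pad library to 1e6 with a second gene so N = 1e6 exactly
        counts = pd.DataFrame(
            {"s": [100, 999_900]}, index=pd.Index(["g", "filler"], name="gene_id")
        )
        lengths = pd.Series([1000, 1000], index=counts.index)
        fpkm = fn.compute_fpkm(fn.CountMatrix(counts=counts, lengths=lengths))
        assert fpkm.fpkm.loc["g", "s"] == pytest.approx(100.0)

    def test_cell_by_cell_oracle(self, small_dataset):
        counts, _ = small_dataset
        fpkm = fn.compute_fpkm(counts)
        n = counts.counts.sum(axis=0)
        sub = counts.gene_ids[:5]
        for g in sub:
            for s in counts.sample_ids[:4]:
                expected = counts.counts.loc[g, s] * 1e9 / (n[s] * counts.lengths[g])
                assert fpkm.fpkm.loc[g, s] == pytest.approx(expected, rel=1e-12)

    def test_depth_invariance(self):
        cm = tiny_counts()
        doubled = fn.CountMatrix(counts=cm.counts * 2, lengths=cm.lengths)
        pd.testing.assert_frame_equal(fn.compute_fpkm(cm).fpkm, fn.compute_fpkm(doubled).fpkm)

    def test_column_identity(self, small_fpkm):
        colsum = small_fpkm.fpkm.mul(small_fpkm.lengths, axis=0).sum(axis=0) / 1e9
        assert np.abs(colsum - 1.0).max() < 1e-9

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=pd.Index(["g"], name="gene_id"))
        cm = fn.CountMatrix(counts=counts, lengths=pd.Series([100], index=counts.index))
        with pytest.raises(DiffExprError, match="s2"):
            fn.compute_fpkm(cm)


class TestContrastScheme:
    def test_emits_the_twelve_comparisons(self, design):
        scheme = fn.build_contrast_scheme(design)
        assert [c.name for c in scheme] == list(CONTRAST_NAMES)
        for c in scheme:
            assert len(c.group_a) == 3 and len(c.group_b) == 3

    def test_cross_sex_subset_is_stage_matched(self, design):
        scheme = {c.name: c for c in fn.build_contrast_scheme(design)}
        cross = [n for n in scheme if n[0] == "M" and "F" in n]
        assert sorted(cross) == ["M1vsF1", "M2vsF2", "M3vsF3", "M4vsF4"]
        for name in cross:
            stage_a, stage_b = name.split("vs")
            assert all(s.startswith(stage_a) for s in scheme[name].group_a)
            assert all(s.startswith(stage_b) for s in scheme[name].group_b)

    def test_missing_stage_fails_fast(self):
        ids = [f"{s}_{r}" for s in ("M1", "M2", "M3", "M4", "F1", "F2", "F3")
               for r in (1, 2, 3)]
        design = fn.SampleDesign.from_sample_ids(ids)
        with pytest.raises(DiffExprError, match="F4"):
            fn.build_contrast_scheme(design)


class TestLog2FoldChange:
    def test_direct_evaluation(self):
        fpkm = fn.FpkmMatrix(
            fpkm=pd.DataFrame({"a1": [7.0], "a2": [7.0], "b1": [1.0], "b2": [1.0]},
                              index=["g"]),
            lengths=pd.Series([100], index=["g"]),
        )
        c = fn.Contrast("AvsB", ("a1", "a2"), ("b1", "b2"))
        assert fn.log2_fold_change(fpkm, c, epsilon=1.0)["g"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self, small_fpkm, scheme):
        c = scheme["M1vsF1"]
        same = fn.Contrast("AvsA2", c.group_a, tuple(s + "x" for s in c.group_a))
        frame = small_fpkm.fpkm.copy()
        for s in c.group_a:
            frame[s + "x"] = frame[s]
        doubled = fn.FpkmMatrix(fpkm=frame, lengths=small_fpkm.lengths)
        assert np.allclose(fn.log2_fold_change(doubled, same), 0.0)

    def test_antisymmetry(self, small_fpkm, scheme):
        c = scheme["M3vsF3"]
        fwd = fn.log2_fold_change(small_fpkm, c)
        rev = fn.log2_fold_change(small_fpkm, c.reversed())
        assert np.allclose(fwd, -rev)

    def test_epsilon_must_be_positive(self, small_fpkm, scheme):
        with pytest.raises(DiffExprError):
            fn.log2_fold_change(small_fpkm, scheme["M1vsF1"], epsilon=0.0)


class TestWelch:
    contrast = fn.Contrast("AvsB", ("a1", "a2", "a3"), ("b1", "b2", "b3"))

    @staticmethod
    def frame(a, b):
        return pd.DataFrame([list(a) + list(b)], index=["g"],
                            columns=["a1", "a2", "a3", "b1", "b2", "b3"])

    def test_textbook_fixture(self):
        """Hand-computed Welch t and Satterthwaite df for the fixture."""
        a, b = [1.1, 1.3, 1.2], [3.9, 4.1, 4.0]
        # oracle: explicit formulas, evaluated independently
        va = np.var(a, ddof=1)  # 0.01
        vb = np.var(b, ddof=1)  # 0.01
        t = (np.mean(a) - np.mean(b)) / np.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(-34.29286, abs=1e-4)
        assert df == pytest.approx(4.0)
        expected_p = 2 * stats.t.sf(abs(t), df)
        p = fn.welch_test(self.frame(a, b), self.contrast)["g"]
        assert p == pytest.approx(expected_p, rel=1e-10)

    def test_identical_groups_null(self):
        p = fn.welch_test(self.frame([2, 2, 2], [2, 2, 2]), self.contrast)["g"]
        assert p == 1.0

    def test_group_swap_symmetry(self):
        vals = self.frame([1.0, 2.0, 1.5], [2.5, 3.5, 2.0])
        p_fwd = fn.welch_test(vals, self.contrast)["g"]
        p_rev = fn.welch_test(vals, self.contrast.reversed())["g"]
        assert p_fwd == pytest.approx(p_rev)

    def test_single_replicate_rejected(self):
        c = fn.Contrast("AvsB", ("a1",), ("b1", "b2"))
        vals = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a1", "b1", "b2"])
        with pytest.raises(DiffExprError, match="replicates"):
            fn.welch_test(vals, c)


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (1.0, 0.01, "ns"),   # boundary: strict > 1
            (2.0, 0.04, "up"),
            (-1.5, 0.2, "ns"),   # p gate
            (-1.5, 0.01, "down"),
            (0.5, 0.001, "ns"),
            (3.0, 0.05, "ns"),   # boundary: strict < alpha
        ],
    )
    def test_threshold_rules(self, lfc, p, expected):
        idx = pd.Index(["g"])
        result = fn.call_degs(
            pd.Series([lfc], index=idx), pd.Series([p], index=idx),
            pd.Series([1.0], index=idx), pd.Series([1.0], index=idx), "AvsB",
        )
        assert result.table.loc["g", "call"] == expected


class TestExclusiveSets:
    def test_two_set_example(self):
        family = {"S1": {"a", "b", "c"}, "S2": {"b", "d"}}
        assert fn.exclusive_upregulated(family, "S1") == {"a", "c"}

    def test_single_set_family(self):
        assert fn.exclusive_upregulated({"S": {"x", "y"}}, "S") == {"x", "y"}

    def test_unknown_target(self):
        with pytest.raises(DiffExprError, match="T"):
            fn.exclusive_upregulated({"S": set()}, "T")

    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.sets(st.integers(min_value=0, max_value=12)),
            min_size=1,
            max_size=4,
        )
    )
    def test_exclusive_sets_pairwise_disjoint(self, family):
        exclusives = {t: fn.exclusive_upregulated(family, t) for t in family}
        names = list(exclusives)
        for i, t1 in enumerate(names):
            # brute-force definition: member of t1 and of no other set
            brute = {x for x in family[t1]
                     if not any(x in family[o] for o in family if o != t1)}
            assert exclusives[t1] == brute
            for t2 in names[i + 1:]:
                assert not (exclusives[t1] & exclusives[t2])


def test_null_lfc_centered_at_zero():
    """Across replicate simulated null datasets, the empirical log2FC of
    unperturbed genes averages to ~0."""
    means = []
    for seed in range(200):
        cfg = fn.SimConfig(n_genes=60, de_spec=(), hub_spec=fn.HubSpec(0, 0.9, 0),
                           seed=10_000 + seed)
        counts, _ = fn.simulate_counts(cfg)
        fpkm = fn.compute_fpkm(counts)
        scheme = {c.name: c for c in fn.build_contrast_scheme(cfg.design())}
        means.append(float(fn.log2_fold_change(fpkm, scheme["M3vsM1"]).mean()))
    assert abs(np.mean(means)) < 0.1
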