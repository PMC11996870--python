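"""Consensus merge, RPKM, PCA, rank-sum/BH machinery, differential calls."""

import numpy as np
import pytest

from conftest import brute_force_bh, brute_force_stitch
from se_landscape.differential import (
    DiffParams,
    SignalMatrix,
    bh_fdr,
    call_differential,
    locus_prevalence,
    merge_regions_across_samples,
    pca_scores,
    quantify_rpkm,
    wilcoxon_rank_sum,
)
from se_landscape.intervals import GenomicInterval
from se_landscape.io import CountsMatrix


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


class TestConsensusMerge:
    def test_overlap_merges_with_provenance(self):
        cons = merge_regions_across_samples(
            {"A": [iv(0, 100, name="a1")], "B": [iv(50, 150, name="b1")]}
        )
        assert [(r.start, r.end) for r in cons.regions] == [(0, 150)]
        assert cons.region_ids == ["SE_0001"]
        assert sorted(s for s, _ in cons.provenance["SE_0001"]) == ["A", "B"]

    def test_book_ended_regions_merge(self):
        cons = merge_regions_across_samples({"A": [iv(0, 100)], "B": [iv(100, 200)]})
        assert [(r.start, r.end) for r in cons.regions] == [(0, 200)]

    def test_single_sample_identity_with_ids(self):
        cons = merge_regions_across_samples({"A": [iv(0, 10), iv(500, 600)]})
        assert [(r.start, r.end) for r in cons.regions] == [(0, 10), (500, 600)]
        assert cons.region_ids == ["SE_0001", "SE_0002"]

    def test_matches_brute_force_union_merge(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            per_sample = {}
            for s in range(int(rng.integers(1, 5))):
                n = int(rng.integers(1, 20))
                starts = np.sort(rng.choice(100_000, size=n, replace=False))
                ivs, prev_end = [], -1
                for st in starts:
                    if st <= prev_end:
                        continue
                    end = st + int(rng.integers(1, 3000))
                    ivs.append(iv(int(st), end))
                    prev_end = end
                per_sample[f"s{s}"] = ivs
            cons = merge_regions_across_samples(per_sample)
            all_ivs = [i for v in per_sample.values() for i in v]
            expected = brute_force_stitch(all_ivs, 0)
            assert [(r.chrom, r.start, r.end) for r in cons.regions] == expected


class TestRpkm:
    def test_worked_value(self):
        cm = CountsMatrix(["r"], ["s"], np.array([[200]]), np.array([10_000_000]))
        sm = quantify_rpkm(cm, {"r": 2000})
        assert sm.values[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        cm = CountsMatrix(["r"], ["s"], np.array([[0]]), np.array([10_000_000]))
        assert quantify_rpkm(cm, {"r": 2000}).values[0, 0] == 0.0

    def test_random_triples_match_direct_formula(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 10_000, size=(30, 4))
        lengths = {f"r{i}": int(rng.integers(100, 50_000)) for i in range(30)}
        libs = rng.integers(1_000_000, 90_000_000, size=4)
        cm = CountsMatrix([f"r{i}" for i in range(30)], list("abcd"), c, libs)
        sm = quantify_rpkm(cm, lengths)
        for i in range(30):
            for j in range(4):
                expected = c[i, j] * 1e9 / (lengths[f"r{i}"] * libs[j])
                assert sm.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_linearity_properties(self):
        rng = np.random.default_rng(2)
        c = rng.integers(1, 1000, size=(10, 3))
        lengths = {f"r{i}": 1000 for i in range(10)}
        libs = np.full(3, 10_000_000)
        base = quantify_rpkm(CountsMatrix([f"r{i}" for i in range(10)], list("abc"), c, libs), lengths)
        doubled = quantify_rpkm(CountsMatrix([f"r{i}" for i in range(10)], list("abc"), 2 * c, libs), lengths)
        assert np.allclose(doubled.values, 2 * base.values)
        halved_lib = quantify_rpkm(
            CountsMatrix([f"r{i}" for i in range(10)], list("abc"), c, libs // 2), lengths
        )
        assert np.allclose(halved_lib.values, 2 * base.values)

    def test_missing_length_raises(self):
        cm = CountsMatrix(["r"], ["s"], np.array([[1]]), np.array([100]))
        with pytest.raises(KeyError):
            quantify_rpkm(cm, {})


class TestPca:
    def test_two_antipodal_samples_rank_one(self):
        sm = SignalMatrix(["r1", "r2"], ["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        scores, varexp = pca_scores(sm)
        assert len(varexp) == 1
        assert varexp[0] == pytest.approx(1.0)

    def test_constant_region_leaves_scores_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.random((5, 4))
        sm = SignalMatrix([f"r{i}" for i in range(5)], list("abcd"), vals)
        scores, _ = pca_scores(sm)
        with_const = np.vstack([vals, np.full(4, 3.3)])
        sm2 = SignalMatrix([f"r{i}" for i in range(6)], list("abcd"), with_const)
        scores2, _ = pca_scores(sm2)
        # scores are defined up to sign per component
        for c in scores.columns:
            assert np.allclose(scores[c].abs(), scores2[c].abs(), atol=1e-9)

    def test_component_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        sm = SignalMatrix([f"r{i}" for i in range(20)], [f"s{j}" for j in range(6)],
                          rng.random((20, 6)))
        scores, varexp = pca_scores(sm)
        G = scores.to_numpy().T @ scores.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.allclose(off, 0, atol=1e-8)
        assert varexp.sum() == pytest.approx(1.0)
        assert np.all(np.diff(varexp) <= 1e-12)  # decreasing

    def test_zero_variance_with_scale_errors(self):
        sm = SignalMatrix(["r1"], ["a", "b"], np.array([[2.0, 2.0]]))
        with pytest.raises(ValueError):
            pca_scores(sm, scale=True)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p == 1.0

    def test_tied_large_groups_match_permutation(self):
        rng = np.random.default_rng(6)
        x = np.round(rng.normal(0, 1, 15), 1)
        y = np.round(rng.normal(0.5, 1, 15), 1)
        _, p = wilcoxon_rank_sum(x, y)
        # Monte-Carlo permutation of the rank-sum statistic
        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        obs = ranks[:15].sum()
        mu = ranks.sum() * 15 / 30
        B = 100_000
        idx = np.argsort(rng.random((B, 30)), axis=1)[:, :15]
        perm = ranks[idx].sum(axis=1)
        p_mc = np.mean(np.abs(perm - mu) >= abs(obs - mu) - 1e-9)
        assert abs(p - p_mc) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhFdr:
    def test_hand_evaluated_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_direct_step_up_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 100)))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_permutation_invariance_and_bonferroni_superset(self):
        rng = np.random.default_rng(10)
        p = rng.random(40)
        perm = rng.permutation(40)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))
        alpha = 0.05
        bonf = p < alpha / len(p)
        assert np.all(bh_fdr(p)[bonf] < alpha)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCallDifferential:
    def planted_matrix(self):
        rng = np.random.default_rng(12)
        tumor = [f"T{i}" for i in range(9)]
        normal = [f"N{i}" for i in range(9)]
        vals = rng.lognormal(1, 0.2, size=(20, 18))
        vals[0, :9] = 20 + rng.random(9)  # planted up region
        vals[0, 9:] = 5 + rng.random(9)
        return SignalMatrix([f"r{i}" for i in range(20)], tumor + normal, vals), tumor, normal

    def test_planted_region_called_up(self):
        sm, tumor, normal = self.planted_matrix()
        res = call_differential(sm, tumor, normal)
        assert res[0].call == "up"
        assert res[0].fold_change == pytest.approx(4.0, rel=0.1)
        # exact 9v9 enumeration: minimal two-sided p
        assert res[0].p == pytest.approx(2 / 48620, rel=1e-9)

    def test_fc_gate_blocks_significant_but_small_changes(self):
        tumor = [f"T{i}" for i in range(9)]
        normal = [f"N{i}" for i in range(9)]
        vals = np.ones((1, 18))
        vals[0, :9] = 1.4 + np.arange(9) * 1e-4
        vals[0, 9:] = 1.0 + np.arange(9) * 1e-4
        sm = SignalMatrix(["r0"], tumor + normal, vals)
        res = call_differential(sm, tumor, normal)
        assert res[0].q < 0.05 and res[0].call == "ns"

    def test_zero_normal_mean_finite_via_pseudocount(self):
        tumor = [f"T{i}" for i in range(9)]
        normal = [f"N{i}" for i in range(9)]
        vals = np.zeros((1, 18))
        vals[0, :9] = 5 + np.arange(9) * 0.01
        sm = SignalMatrix(["r0"], tumor + normal, vals)
        res = call_differential(sm, tumor, normal)
        assert np.isfinite(res[0].fold_change)
        assert res[0].call == "up"

    def test_label_swap_maps_up_to_down(self):
        sm, tumor, normal = self.planted_matrix()
        fwd = call_differential(sm, tumor, normal)
        rev = call_differential(sm, normal, tumor)
        for f, r in zip(fwd, rev):
            assert f.p == pytest.approx(r.p)
            if f.call == "up":
                assert r.call == "down"
            if f.call == "down":
                assert r.call == "up"

    def test_group_size_validation(self):
        sm, tumor, normal = self.planted_matrix()
        with pytest.raises(ValueError):
            call_differential(sm, tumor[:1], normal)
        with pytest.raises(ValueError):
            call_differential(sm, tumor, tumor)


class TestLocusPrevalence:
    def test_fraction_of_overlapping_samples(self):
        locus = iv(1000, 2000)
        per_sample = {f"s{i}": [iv(1500, 1600)] for i in range(5)}
        per_sample.update({f"t{i}": [iv(9000, 9500)] for i in range(4)})
        assert locus_prevalence(per_sample, locus) == pytest.approx(5 / 9)

    def test_no_overlap_zero(self):
        assert locus_prevalence({"a": [iv(0, 10)]}, iv(100, 200)) == 0.0

    def test_book_ended_does_not_count(self):
        assert locus_prevalence({"a": [iv(0, 100)]}, iv(100, 200)) == 0.0
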