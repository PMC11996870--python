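"""Target-gene assignment, DEG intersection, TF funnel, PWM scanning."""

import numpy as np
import pandas as pd
import pytest

from se_landscape.intervals import GenomicInterval, TssRecord, point_interval_distance
from se_landscape.motifs import (
    MotifHit,
    pfm_from_consensus,
    pwm_from_counts,
    reverse_complement,
    scan_motif,
)
from se_landscape.targets import (
    intersect_se_targets_with_degs,
    nearest_gene,
    pearson_correlation,
    rank_tf_candidates,
    tf_occupancy_funnel,
)


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


def tss(gene, pos, chrom="chr1"):
    return TssRecord(gene, chrom, pos, "+")


class TestNearestGene:
    def test_contained_tss_wins_with_zero_distance(self):
        a = nearest_gene(iv(100, 200, name="r"), [tss("A", 150), tss("B", 500)])
        assert (a.gene_id, a.distance) == ("A", 0)

    def test_asymmetric_distances(self):
        # A at 90 -> distance 10; B at 210 -> distance 210-199 = 11
        a = nearest_gene(iv(100, 200), [tss("A", 90), tss("B", 210)])
        assert (a.gene_id, a.distance) == ("A", 10)

    def test_exact_tie_breaks_lexicographically(self):
        a = nearest_gene(iv(100, 200), [tss("B", 90), tss("A", 209)])
        assert a.gene_id == "A" and a.distance == 10

    def test_no_tss_on_chromosome_is_explicitly_unassigned(self):
        a = nearest_gene(iv(100, 200, name="r1"), [tss("A", 150, chrom="chr9")])
        assert a.region_id == "r1" and a.gene_id is None and a.distance is None

    def test_matches_brute_force_minimum_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            region = iv(int(rng.integers(0, 90_000)), int(rng.integers(90_001, 100_000)))
            records = [tss(f"g{i}", int(rng.integers(0, 120_000))) for i in range(20)]
            a = nearest_gene(region, records)
            expected = min(
                (point_interval_distance(t.pos, region), t.gene_id) for t in records
            )
            assert (a.distance, a.gene_id) == expected


class TestDegIntersection:
    def deg(self, up, down):
        rows = [(g, 1.0, 0.01, "up") for g in up] + [(g, -1.0, 0.01, "down") for g in down]
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "q", "direction"])

    def test_direction_matched_intersection(self):
        up, down = intersect_se_targets_with_degs(
            {"a", "b", "c"}, {"x"}, self.deg(["b", "c", "d"], ["x", "y"])
        )
        assert up == ["b", "c"] and down == ["x"]

    def test_disjoint_sets_empty(self):
        up, down = intersect_se_targets_with_degs({"a"}, {"b"}, self.deg(["z"], ["w"]))
        assert up == [] and down == []

    def test_direction_mismatch_excluded(self):
        up, down = intersect_se_targets_with_degs({"g"}, set(), self.deg([], ["g"]))
        assert up == [] and down == []


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            r, _ = pearson_correlation(x, y)
            expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert r == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, p = pearson_correlation(x, y)
        r2, p2 = pearson_correlation(3 * x + 7, 0.5 * y - 2)
        assert r == pytest.approx(r2) and p == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestTfFunnel:
    def queries(self):
        return {
            "E1": iv(1000, 2000),
            "E2": iv(5000, 6000),
            "promoter": iv(9000, 10000),
        }

    def test_partial_and_full_occupancy(self):
        sites = {
            "tfA": [iv(1500, 1600)],                       # E1 only
            "tfB": [iv(1500, 1600), iv(5500, 5600), iv(9500, 9600)],
            "tfC": [iv(20000, 20100)],                     # none
        }
        f = tf_occupancy_funnel(sites, self.queries())
        assert bool(f.loc["tfA", "hits_any"]) and not bool(f.loc["tfA", "hits_all"])
        assert bool(f.loc["tfB", "hits_all"])
        assert not bool(f.loc["tfC", "hits_any"])

    def test_counts_match_hand_enumeration(self):
        sites = {
            "t1": [iv(1000, 6000), iv(9100, 9200)],        # all three
            "t2": [iv(1999, 5001)],                        # E1+E2 only
            "t3": [iv(1500, 1501), iv(5999, 6000), iv(9999, 10000)],  # all three
            "t4": [iv(2000, 5000)],                        # book-ended: none
            "t5": [iv(8000, 9001)],                        # promoter only
        }
        f = tf_occupancy_funnel(sites, self.queries())
        assert int(f["hits_any"].sum()) == 4
        assert int(f["hits_all"].sum()) == 2
        assert set(f.index[f["hits_all"]]) == {"t1", "t3"}

    def test_hits_all_implies_hits_any(self):
        rng = np.random.default_rng(8)
        sites = {
            f"tf{i}": [iv(int(s), int(s) + 300) for s in rng.integers(0, 12000, 5)]
            for i in range(20)
        }
        f = tf_occupancy_funnel(sites, self.queries())
        assert bool((f["hits_all"] <= f["hits_any"]).all())
        assert int(f["hits_any"].sum()) >= int(f["hits_all"].sum())


class TestRankTf:
    def test_planted_tf_ranks_first(self):
        rng = np.random.default_rng(30)
        samples = [f"s{i}" for i in range(50)]
        target = rng.normal(size=50)
        rows = {"target": target, "planted": target + rng.normal(0, 0.1, 50)}
        for i in range(10):
            rows[f"tf{i}"] = rng.normal(size=50)
        expr = pd.DataFrame(rows, index=samples).T
        ranking = rank_tf_candidates(
            {"planted", *[f"tf{i}" for i in range(10)]}, expr, "target"
        )
        assert ranking[0][0] == "planted"
        assert ranking[0][1] > max(r for _, r, _ in ranking[1:])

    def test_single_tf_trivial(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [2.0, 1.0], "s3": [3.0, 4.0]},
            index=["target", "tfX"],
        )
        ranking = rank_tf_candidates({"tfX"}, expr, "target")
        assert len(ranking) == 1 and ranking[0][0] == "tfX"

    def test_missing_gene_raises(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [0.5]}, index=["target"])
        with pytest.raises(KeyError):
            rank_tf_candidates({"absent"}, expr, "target")


class TestPwm:
    def test_pseudocount_probabilities(self):
        pfm = np.array([[100, 0, 0, 0]], dtype=float)
        pwm = pwm_from_counts(pfm, pseudocount=0.8)
        # prob_A = (100 + 0.8*0.25) / (100 + 0.8) = 100.2/100.8
        assert 2 ** pwm.matrix[0, 0] * 0.25 == pytest.approx(100.2 / 100.8)

    def test_uniform_column_scores_zero(self):
        pwm = pwm_from_counts(np.array([[25, 25, 25, 25]], dtype=float))
        assert np.allclose(pwm.matrix, 0.0)

    def test_max_score_equals_consensus_scan(self):
        consensus = "ACGTTGAC"
        pwm = pwm_from_counts(pfm_from_consensus(consensus))
        (hit,) = [h for h in scan_motif(pwm, consensus, min_fraction=0.999) if h.strand == "+"]
        assert hit.score == pytest.approx(pwm.max_score)
        assert hit.score_fraction == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.array([[1, -1, 0, 0]], dtype=float))


class TestScanMotif:
    CONS = "ACGTTGAC"

    def pwm(self):
        return pwm_from_counts(pfm_from_consensus(self.CONS))

    def background(self, rng, n):
        while True:
            seq = "".join(rng.choice(list("ACGT"), n))
            if self.CONS not in seq and self.CONS not in reverse_complement(seq):
                return seq

    def test_forward_plant_recovered_at_exact_offset(self):
        rng = np.random.default_rng(40)
        seq = self.background(rng, 100)
        planted = seq[:37] + self.CONS + seq[37 + len(self.CONS):]
        hits = scan_motif(self.pwm(), planted, min_fraction=0.99)
        assert [(h.position, h.strand) for h in hits] == [(37, "+")]

    def test_reverse_plant_reported_at_forward_coordinates(self):
        rng = np.random.default_rng(41)
        seq = self.background(rng, 100)
        rc = reverse_complement(self.CONS)
        planted = seq[:20] + rc + seq[20 + len(rc):]
        hits = scan_motif(self.pwm(), planted, min_fraction=0.99)
        assert [(h.position, h.strand) for h in hits] == [(20, "-")]

    def test_single_mismatch_fails_strict_threshold(self):
        mutated = "ACGTTGAT"  # last base C->T
        seq = "GGGG" + mutated + "GGGG"
        assert scan_motif(self.pwm(), seq, min_fraction=1.0) == []

    def test_n_windows_never_match(self):
        seq = "ACGTNGAC" + "ACGTTGAC"
        hits = scan_motif(self.pwm(), seq, min_fraction=0.99)
        assert [(h.position, h.strand) for h in hits] == [(8, "+")]

    def test_strand_symmetry_property(self):
        rng = np.random.default_rng(42)
        pwm = self.pwm()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 80))
            fwd_hits = scan_motif(pwm, seq, min_fraction=0.5)
            rc_hits = scan_motif(pwm, reverse_complement(seq), min_fraction=0.5)
            L = pwm.length
            reflected = sorted(
                (len(seq) - L - h.position, "+-"[h.strand == "+"], round(h.score, 9))
                for h in rc_hits
            )
            original = sorted(
                (h.position, h.strand, round(h.score, 9)) for h in fwd_hits
            )
            assert original == reflected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_motif(self.pwm(), "")
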