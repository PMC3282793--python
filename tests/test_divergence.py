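import numpy as np
import pytest
from scipy import stats as sps

from barcodegap import (
    distance_matrix,
    divergence_summary,
    gap_histogram,
    paired_inter_distances,
    partition_pairs,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from barcodegap.distances import DistanceMatrix
from barcodegap.errors import DegenerateTestError, InsufficientDataError

from conftest import make_alignment, random_alignment
from oracles import (
    divergence_metrics_oracle,
    rank_sum_exact_oracle,
    signed_rank_exact_oracle,
)


def dm_from_values(labels, species, values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        labels=list(labels), species=list(species), model="k2p",
        values=values, comparable_sites=np.full_like(values, 100, dtype=np.int64),
    )


class TestPartition:
    def test_two_by_two_combinatorics(self):
        labels = ["a1", "a2", "b1", "b2"]
        species = ["A", "A", "B", "B"]
        v = np.array([
            [0, .01, .05, .05],
            [.01, 0, .05, .05],
            [.05, .05, 0, .01],
            [.05, .05, .01, 0],
        ])
        part = partition_pairs(dm_from_values(labels, species, v))
        assert len(part.intra_pairs) == 2
        assert len(part.inter_pairs) == 4

    def test_all_same_species(self):
        v = np.zeros((3, 3))
        part = partition_pairs(dm_from_values(["a", "b", "c"], ["X"] * 3, v))
        assert part.inter_pairs == []
        assert len(part.intra_pairs) == 3

    def test_all_distinct_species(self):
        n = 5
        v = np.full((n, n), 0.1) - 0.1 * np.eye(n)
        part = partition_pairs(
            dm_from_values([f"s{i}" for i in range(n)], [f"sp{i}" for i in range(n)], v)
        )
        assert part.intra_pairs == []
        assert len(part.inter_pairs) == n * (n - 1) // 2

    def test_flagged_missing_excluded_and_counted(self):
        v = np.array([[0, np.nan, .05], [np.nan, 0, .04], [.05, .04, 0]])
        part = partition_pairs(dm_from_values(["a", "b", "c"], ["A", "A", "B"], v))
        assert part.n_excluded == 1
        assert len(part.intra_pairs) == 0
        assert len(part.inter_pairs) == 2

    def test_pair_count_conservation(self, rng):
        aln = random_alignment(rng, n_seq=8, length=60, n_species=3)
        part = partition_pairs(distance_matrix(aln))
        n = 8
        assert len(part.intra_pairs) + len(part.inter_pairs) + part.n_excluded == \
            n * (n - 1) // 2


class TestDivergenceSummary:
    def test_constant_distributions(self):
        labels = ["a1", "a2", "b1", "b2"]
        species = ["A", "A", "B", "B"]
        v = np.array([
            [0, .005, .05, .05],
            [.005, 0, .05, .05],
            [.05, .05, 0, .005],
            [.05, .05, .005, 0],
        ])
        summ = divergence_summary(partition_pairs(dm_from_values(labels, species, v)))
        for metric, mean in [
            ("all_intra", .005), ("mean_theta", .005), ("coalescent_depth", .005),
            ("all_inter", .05), ("theta_prime", .05), ("min_inter", .05),
        ]:
            m = summ[metric]
            assert m.mean == pytest.approx(mean)
            assert m.sd == pytest.approx(0.0)

    def test_single_species_inter_metrics_missing(self):
        v = np.array([[0, .01, .02], [.01, 0, .01], [.02, .01, 0]])
        summ = divergence_summary(partition_pairs(dm_from_values(
            ["a", "b", "c"], ["X"] * 3, v)))
        for metric in ("all_inter", "theta_prime", "min_inter"):
            assert summ[metric] is None
        assert summ["all_intra"] is not None

    def test_species_with_one_sample_skipped_in_theta(self):
        # singleton species contributes to inter metrics but not mean_theta
        labels = ["a1", "a2", "b1"]
        species = ["A", "A", "B"]
        v = np.array([[0, .01, .05], [.01, 0, .06], [.05, .06, 0]])
        summ = divergence_summary(partition_pairs(dm_from_values(labels, species, v)))
        assert summ["mean_theta"].n == 1            # only species A
        assert summ["theta_prime"].n == 2           # both species

    def test_matches_bruteforce_oracle(self, rng):
        aln = random_alignment(rng, n_seq=10, length=200, n_species=5,
                               gap_frac=0, ambig_frac=0)
        dm = distance_matrix(aln)
        part = partition_pairs(dm)
        summ = divergence_summary(part)
        expect = divergence_metrics_oracle(dm.labels, dm.species, dm.values.tolist())
        for metric, vals in expect.items():
            if not vals:
                assert summ[metric] is None
                continue
            m = summ[metric]
            assert m.n == len(vals)
            assert m.mean == pytest.approx(np.mean(vals), abs=1e-12)
            sd = np.std(vals, ddof=1) if len(vals) > 1 else 0.0
            assert m.sd == pytest.approx(sd, abs=1e-12)

    def test_metric_order_invariants(self, rng):
        """min_inter <= all_inter in mean; coalescent depth >= mean theta."""
        for seed in range(5):
            aln = random_alignment(np.random.default_rng(seed), n_seq=12,
                                   length=150, n_species=4, gap_frac=0, ambig_frac=0)
            summ = divergence_summary(partition_pairs(distance_matrix(aln)))
            assert summ["min_inter"].mean <= summ["all_inter"].mean + 1e-15
            assert summ["coalescent_depth"].mean >= summ["mean_theta"].mean - 1e-15


class TestSignedRank:
    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_ranked_positives(self):
        res = wilcoxon_signed_rank([3, 5, 7], [1, 1, 1])
        assert res.w_plus == 6.0
        assert res.w_minus == 0.0
        assert res.n_used == 3
        assert res.direction == "a>b"

    def test_rank_sum_identity(self, rng):
        """W+ + W- == n(n+1)/2 after midranking, including ties."""
        for _ in range(10):
            a = rng.integers(0, 5, 15).astype(float)
            b = rng.integers(0, 5, 15).astype(float)
            try:
                res = wilcoxon_signed_rank(a, b)
            except DegenerateTestError:
                continue
            assert res.w_plus + res.w_minus == pytest.approx(
                res.n_used * (res.n_used + 1) / 2
            )

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            a = np.round(rng.normal(0, 1, n), 1)
            b = np.round(rng.normal(0, 1, n), 1)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(a, b, method="auto")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(signed_rank_exact_oracle(a, b),
                                                abs=1e-9)

    def test_approx_matches_scipy(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.3, 1, 80)
        res = wilcoxon_signed_rank(a, b, method="approx")
        expect = sps.wilcoxon(a, b, correction=True, method="approx").pvalue
        assert res.p_value == pytest.approx(expect, abs=1e-10)


class TestRankSum:
    def test_extreme_separation(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.rank_sum_a == 6.0  # minimum possible
        # one-sided exact p is 1/20, so the two-sided p is 0.1
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.direction == "b>a"

    def test_identical_samples_at_null_mean(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_rank_sum(vals, vals)
        assert res.u_a == pytest.approx(res.n_a * res.n_b / 2)
        assert res.direction == "none"

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(25):
            n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            a = np.round(rng.normal(0, 1, n), 1)
            b = np.round(rng.normal(0.5, 1, m), 1)
            res = wilcoxon_rank_sum(a, b, method="auto")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(rank_sum_exact_oracle(a, b), abs=1e-9)

    def test_approx_matches_scipy(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.4, 1, 50)
        res = wilcoxon_rank_sum(a, b, method="approx")
        expect = sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
        assert res.p_value == pytest.approx(expect, abs=1e-10)

    def test_rejects_on_separated_synthetic_distances(self, rng):
        """inter >> intra should reject at p < 0.01 in essentially every replicate."""
        rejections = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            intra = local.normal(0.005, 0.002, 40).clip(0)
            inter = local.normal(0.05, 0.01, 200).clip(0)
            res = wilcoxon_rank_sum(intra, inter)
            rejections += res.p_value < 0.01
        assert rejections == 20


def test_paired_inter_distances_keys_and_order():
    from barcodegap.divergence import PairPartition

    part_a = PairPartition(
        intra_pairs=[], species_of={}, n_samples=4, n_excluded=0,
        inter_pairs=[("s1", "s2", 0.1), ("s1", "s3", 0.2), ("s2", "s3", 0.3)],
    )
    part_b = PairPartition(
        intra_pairs=[], species_of={}, n_samples=4, n_excluded=0,
        inter_pairs=[("s2", "s1", 0.15), ("s2", "s3", 0.35)],  # s1/s3 missing
    )
    a, b, keys = paired_inter_distances(part_a, part_b)
    assert keys == [("s1", "s2"), ("s2", "s3")]
    assert a == [0.1, 0.3]
    assert b == [0.15, 0.35]


class TestGapHistogram:
    def test_counts_conserved(self, rng):
        aln = random_alignment(rng, n_seq=9, length=120, n_species=3,
                               gap_frac=0, ambig_frac=0)
        part = partition_pairs(distance_matrix(aln))
        h = gap_histogram(part)
        assert h.intra_counts.sum() == len(part.intra_pairs)
        assert h.inter_counts.sum() == len(part.inter_pairs)

    def test_all_below_one_bin(self):
        v = np.array([[0, 0.0004, 0.0007], [0.0004, 0, 0.0002], [0.0007, 0.0002, 0]])
        part = partition_pairs(dm_from_values(["a", "b", "c"], ["A", "A", "A"], v))
        h = gap_histogram(part, bin_width=0.001)
        assert h.n_bins == 1
        assert h.intra_counts[0] == 3

    def test_zero_fraction_inter_pairs(self):
        v = np.array([[0, 0.0, 0.05], [0.0, 0, 0.05], [0.05, 0.05, 0]])
        part = partition_pairs(dm_from_values(["a", "b", "c"], ["A", "B", "C"], v))
        h = gap_histogram(part)
        assert h.zero_fraction_inter_pairs == pytest.approx(1 / 3)

    def test_zero_involved_sample_fraction_constructed(self):
        """3 of 30 samples share a haplotype across species -> fraction 0.1."""
        rng = np.random.default_rng(5)
        chars = np.array(list("ACGT"))
        rows = []
        shared = "".join(chars[rng.integers(0, 4, 60)])
        for sp in range(10):
            base = "".join(chars[rng.integers(0, 4, 60)])
            for k in range(3):
                rows.append((f"sp{sp}_s{k}", f"sp{sp}", base))
        # overwrite one sample in each of three species with the shared haplotype
        rows[0] = (rows[0][0], rows[0][1], shared)
        rows[3] = (rows[3][0], rows[3][1], shared)
        rows[6] = (rows[6][0], rows[6][1], shared)
        aln = make_alignment("x", rows)
        part = partition_pairs(distance_matrix(aln, "p-distance"))
        h = gap_histogram(part)
        assert h.zero_involved_sample_fraction == pytest.approx(3 / 30)

    def test_bins_are_half_open(self):
        v = np.array([[0, 0.001], [0.001, 0]])
        part = partition_pairs(dm_from_values(["a", "b"], ["A", "A"], v))
        h = gap_histogram(part, bin_width=0.001)
        # 0.001 falls in [0.001, 0.002), not [0, 0.001)
        assert h.intra_counts[0] == 0
        assert h.intra_counts[1] == 1

    def test_sections_summary(self):
        v = np.array([[0, 0.005, 0.055], [0.005, 0, 0.052], [0.055, 0.052, 0]])
        part = partition_pairs(dm_from_values(["a", "b", "c"], ["A", "A", "B"], v))
        h = gap_histogram(part)
        assert h.sections[0]["intra_count"] == 1
        assert h.sections[5]["inter_count"] == 2

    def test_invalid_bin_width(self):
        part = partition_pairs(dm_from_values(["a", "b"], ["A", "A"], np.zeros((2, 2))))
        with pytest.raises(ValueError):
            gap_histogram(part, bin_width=0)
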