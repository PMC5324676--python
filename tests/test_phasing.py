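"""Clustering, consensus polishing, haplogroup filtering and coverage ratio."""

import edlib
import numpy as np
import pytest
from scipy import stats

from conftest import noisy_copies
from amplistar.phasing import (
    HaplogroupConsensus,
    PhasingConfig,
    cluster_reads,
    clusters_to_haplogroups,
    coverage_ratio,
    filter_haplogroups,
    polish_consensus,
)
from amplistar.synthetic import LocusSpec, ReadErrorModel, build_reference


def _dist(a, b):
    return edlib.align(a, b, task="distance")["editDistance"]


def _mutate_sites(seq, n_sites, rng):
    """Haplotype differing from seq at n random substitution sites."""
    out = list(seq)
    for pos in sorted(rng.choice(len(seq), size=n_sites, replace=False)):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


SMALL_LOCUS = build_reference(LocusSpec(length=2000, seed=77))


class TestPolishConsensus:
    def test_single_member_is_identity(self):
        assert polish_consensus([SMALL_LOCUS]) == SMALL_LOCUS

    def test_error_free_members_give_source(self):
        assert polish_consensus([SMALL_LOCUS] * 5) == SMALL_LOCUS

    def test_noisy_members_recover_truth(self):
        reads = noisy_copies(SMALL_LOCUS, 30, ReadErrorModel(), seed=21)
        assert polish_consensus(reads) == SMALL_LOCUS

    def test_deterministic_under_member_order(self):
        reads = noisy_copies(SMALL_LOCUS, 12, ReadErrorModel(), seed=4)
        items = [(f"r{i:03d}", s) for i, s in enumerate(reads)]
        shuffled = [items[i] for i in np.random.default_rng(0).permutation(len(items))]
        assert polish_consensus(items) == polish_consensus(shuffled)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            polish_consensus([])


class TestClusterReads:
    def test_homogeneous_reads_give_single_cluster(self):
        reads = noisy_copies(SMALL_LOCUS, 20, ReadErrorModel(), seed=5)
        clusters = cluster_reads(reads, PhasingConfig(seed=1))
        assert len(clusters) == 1
        assert clusters[0].support == 20

    def test_support_conservation(self):
        rng = np.random.default_rng(6)
        other = _mutate_sites(SMALL_LOCUS, 12, rng)
        reads = noisy_copies(SMALL_LOCUS, 14, ReadErrorModel(), seed=6)
        reads += noisy_copies(other, 14, ReadErrorModel(), seed=7)
        clusters = cluster_reads(reads, PhasingConfig(seed=2))
        assert sum(c.support for c in clusters) == 28

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValueError, match="insufficient coverage"):
            cluster_reads([SMALL_LOCUS, SMALL_LOCUS], PhasingConfig())

    def test_two_haplotypes_27_sites_split_pure(self):
        """50/50 mix differing at 27 sites, 5% total error -> 2 clusters,
        each at least 95% pure."""
        rng = np.random.default_rng(9)
        hap2 = _mutate_sites(SMALL_LOCUS, 27, rng)
        model = ReadErrorModel(0.01, 0.02, 0.02)  # 5% total
        a = noisy_copies(SMALL_LOCUS, 20, model, seed=10)
        b = noisy_copies(hap2, 20, model, seed=11)
        reads = [(f"a{i:02d}", s) for i, s in enumerate(a)]
        reads += [(f"b{i:02d}", s) for i, s in enumerate(b)]
        clusters = cluster_reads(reads, PhasingConfig(seed=3))
        assert len(clusters) == 2
        for c in clusters:
            frac_a = sum(1 for rid in c.read_ids if rid.startswith("a")) / c.support
            assert max(frac_a, 1 - frac_a) >= 0.95

    def test_two_to_one_mix_support_ratio_in_binomial_interval(self):
        rng = np.random.default_rng(12)
        hap2 = _mutate_sites(SMALL_LOCUS, 27, rng)
        model = ReadErrorModel(0.01, 0.02, 0.02)
        n = 45
        a = noisy_copies(SMALL_LOCUS, 30, model, seed=13)
        b = noisy_copies(hap2, 15, model, seed=14)
        reads = [(f"a{i:02d}", s) for i, s in enumerate(a)]
        reads += [(f"b{i:02d}", s) for i, s in enumerate(b)]
        clusters = sorted(cluster_reads(reads, PhasingConfig(seed=4)), key=lambda c: -c.support)
        assert len(clusters) == 2
        lo = stats.binom.ppf(0.025, n, 2 / 3)
        hi = stats.binom.ppf(0.975, n, 2 / 3)
        assert lo <= clusters[0].support <= hi

    def test_assignment_matches_exhaustive_bipartition_oracle(self):
        """For 12 reads from 2 known haplotypes, cluster memberships equal the
        best-scoring bipartition over all 2^12 splits (total distance to the
        two true haplotypes)."""
        rng = np.random.default_rng(15)
        hap2 = _mutate_sites(SMALL_LOCUS, 20, rng)
        model = ReadErrorModel(0.01, 0.02, 0.02)
        reads = [(f"r{i:02d}", s) for i, s in enumerate(
            noisy_copies(SMALL_LOCUS, 6, model, seed=16) + noisy_copies(hap2, 6, model, seed=17)
        )]
        clusters = cluster_reads(reads, PhasingConfig(seed=5))
        assert len(clusters) == 2
        d1 = [_dist(s, SMALL_LOCUS) for _, s in reads]
        d2 = [_dist(s, hap2) for _, s in reads]
        best_score, best_mask = None, None
        for mask in range(2 ** len(reads)):
            score = sum(d2[i] if mask >> i & 1 else d1[i] for i in range(len(reads)))
            if best_score is None or score < best_score:
                best_score, best_mask = score, mask
        oracle = {reads[i][0] for i in range(len(reads)) if best_mask >> i & 1}
        got = set(clusters[0].read_ids)
        assert got == oracle or got == {rid for rid, _ in reads} - oracle

    def test_max_subreads_subsampling_is_seeded(self):
        reads = noisy_copies(SMALL_LOCUS, 30, ReadErrorModel(), seed=18)
        cfg = PhasingConfig(max_subreads=20, seed=9)
        c1 = cluster_reads(reads, cfg)
        c2 = cluster_reads(reads, cfg)
        assert [c.read_ids for c in c1] == [c.read_ids for c in c2]
        assert sum(c.support for c in c1) == 20


class TestHaplogroupRecovery:
    @pytest.mark.parametrize("n_haps,ratio", [(1, None), (2, (1, 1)), (2, (2, 1))])
    def test_haplogroup_count_and_classification_recovered(self, n_haps, ratio):
        """Seeded scenarios spanning {1,2} haplotypes x {1:1, 2:1} ratios
        recover the true count and CNV classification."""
        for seed in range(4):
            rng = np.random.default_rng(1000 + seed)
            model = ReadErrorModel(0.015, 0.04, 0.04)
            if n_haps == 1:
                reads = noisy_copies(SMALL_LOCUS, 36, model, seed=2000 + seed)
            else:
                hap2 = _mutate_sites(SMALL_LOCUS, 15, rng)
                n2 = 36 * ratio[1] // (ratio[0] + ratio[1])
                n1 = 36 - n2
                reads = noisy_copies(SMALL_LOCUS, n1, model, seed=3000 + seed)
                reads += noisy_copies(hap2, n2, model, seed=4000 + seed)
            cfg = PhasingConfig(seed=seed)
            clusters = cluster_reads([(f"r{i:02d}", s) for i, s in enumerate(reads)], cfg)
            haps = filter_haplogroups(clusters_to_haplogroups("s", clusters), cfg)
            cr = coverage_ratio(haps, cfg.duplication_threshold)
            assert len(haps) == n_haps, f"seed {seed}"
            if n_haps == 1:
                assert cr.classification == "single"
            elif ratio == (1, 1):
                assert cr.classification == "balanced", f"seed {seed}: {cr.ratio}"
            else:
                assert cr.classification == "duplicated", f"seed {seed}: {cr.ratio}"


def _hap(sample, index, seq, support):
    return HaplogroupConsensus(sample, index, seq, support, [f"r{i}" for i in range(support)])


class TestFilterHaplogroups:
    def test_balanced_pair_retained(self):
        """Supports 226 and 200 both survive and classify balanced."""
        haps = [_hap("s", 1, "ACGT" * 100, 226), _hap("s", 2, "ACGA" * 100, 200)]
        kept = filter_haplogroups(haps, PhasingConfig())
        assert [h.support for h in kept] == [226, 200]
        assert coverage_ratio(kept).classification == "balanced"

    def test_low_support_artifact_removed(self):
        haps = [_hap("s", 1, "ACGT" * 100, 200), _hap("s", 2, "AAAA" * 100, 6)]  # 3%
        kept = filter_haplogroups(haps, PhasingConfig())
        assert len(kept) == 1 and kept[0].support == 200

    def test_off_length_artifact_removed(self):
        haps = [
            _hap("s", 1, "ACGT" * 100, 100),
            _hap("s", 2, "ACGA" * 100, 90),
            _hap("s", 3, "ACGT" * 30, 40),  # 30% of median length
        ]
        kept = filter_haplogroups(haps, PhasingConfig())
        assert len(kept) == 2

    def test_identical_sequences_merged_with_summed_support(self):
        haps = [_hap("s", 1, "ACGT" * 100, 100), _hap("s", 2, "ACGT" * 100, 50)]
        kept = filter_haplogroups(haps, PhasingConfig())
        assert len(kept) == 1
        assert kept[0].support == 150
        assert len(kept[0].member_reads) == 150

    def test_reindexed_by_descending_support(self):
        haps = [_hap("s", 1, "ACGA" * 100, 80), _hap("s", 2, "ACGT" * 100, 120)]
        kept = filter_haplogroups(haps, PhasingConfig())
        assert [(h.index, h.support) for h in kept] == [(1, 120), (2, 80)]

    def test_everything_filtered_is_an_error(self):
        # lengths 400 and 4000: both fall outside (1 +/- 0.2) x median (2200)
        haps = [_hap("s", 1, "ACGT" * 100, 100), _hap("s", 2, "ACGT" * 1000, 100)]
        with pytest.raises(ValueError, match="no haplogroup passes"):
            filter_haplogroups(haps, PhasingConfig())


class TestCoverageRatio:
    def test_balanced_pair(self):
        haps = [_hap("s", 1, "A" * 100, 226), _hap("s", 2, "C" * 100, 200)]
        cr = coverage_ratio(haps)
        assert cr.classification == "balanced"
        assert cr.ratio == pytest.approx(226 / 200)

    def test_duplicated_at_2_3_to_1(self):
        haps = [_hap("s", 1, "A" * 100, 230), _hap("s", 2, "C" * 100, 100)]
        cr = coverage_ratio(haps)
        assert cr.classification == "duplicated"
        assert cr.ratio == pytest.approx(2.3)
        assert cr.numerator_index == 1

    def test_single_haplogroup(self):
        cr = coverage_ratio([_hap("s", 1, "A" * 100, 300)])
        assert cr.classification == "single"
        assert cr.ratio == 1.0

    def test_three_haplogroups_rejected(self):
        haps = [_hap("s", i + 1, b * 100, 50) for i, b in enumerate("ACG")]
        with pytest.raises(ValueError, match="unresolved mixture"):
            coverage_ratio(haps)

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio([_hap("s", 1, "A" * 100, 0)])

    def test_threshold_is_configurable(self):
        haps = [_hap("s", 1, "A" * 100, 150), _hap("s", 2, "C" * 100, 100)]
        assert coverage_ratio(haps, duplication_threshold=1.4).classification == "duplicated"
        assert coverage_ratio(haps, duplication_threshold=1.8).classification == "balanced"
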