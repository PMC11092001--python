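import numpy as np
import pytest

from aohscan import likelihood as lk
from aohscan.panel import collapse_local_patterns

from conftest import make_obs, make_panel, oracle_likelihoods


class TestEmissionProb:
    def test_single_match(self):
        assert lk.emission_prob([1], [1], 0.01) == pytest.approx(0.99)

    def test_match_mismatch_product(self):
        assert lk.emission_prob([1, 0], [1, 1], 0.01) == pytest.approx(0.0099)

    def test_uninformative_epsilon_half(self):
        for k in (1, 2, 3):
            p = lk.emission_prob([1] * k, [0] * k, 0.5)
            assert p == pytest.approx(0.5**k)

    def test_pattern_not_covering_read_errors(self):
        with pytest.raises(ValueError):
            lk.emission_prob([1, 0], [1], 0.01)


class TestPloidyLikelihoods:
    def test_two_pattern_worked_example(self):
        """Patterns {(0,0):1/2,(1,1):1/2}, two reads observing alt at each SNP,
        eps=0: L_hap=0.5, L_dip=0.375, LLR=ln(4/3)."""
        panel = make_panel([(0, 0), (1, 1)])
        ps = collapse_local_patterns(panel, [0, 1])
        reads = [(np.array([0]), np.array([1])), (np.array([1]), np.array([1]))]
        l_hap, l_dip = lk.ploidy_likelihoods(reads, ps, 0.0)
        assert l_hap == pytest.approx(0.5, rel=1e-12)
        assert l_dip == pytest.approx(0.375, rel=1e-12)
        assert np.log(l_hap / l_dip) == pytest.approx(np.log(4 / 3), rel=1e-12)

    def test_single_read_identity(self):
        """One read: L_hap == L_dip exactly (sum over the second haplotype
        marginalizes out), for any panel and epsilon."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            H, S = rng.integers(2, 9), rng.integers(1, 6)
            panel = make_panel(rng.integers(0, 2, (H, S)))
            k = rng.integers(1, S + 1)
            idx = np.sort(rng.choice(S, size=k, replace=False))
            reads = [(idx, rng.integers(0, 2, size=k))]
            ps = collapse_local_patterns(panel, idx)
            l_hap, l_dip = lk.ploidy_likelihoods(reads, ps, float(rng.uniform(0, 0.4)))
            assert l_hap == pytest.approx(l_dip, rel=1e-12)

    def test_repulsion_haplotypes_give_negative_llr(self):
        """Patterns {(0,1):1/2,(1,0):1/2} with both-alt reads: the pair is
        likelier under two haplotypes than one -> LLR < 0."""
        panel = make_panel([(0, 1), (1, 0)])
        ps = collapse_local_patterns(panel, [0, 1])
        reads = [(np.array([0]), np.array([1])), (np.array([1]), np.array([1]))]
        l_hap, l_dip = lk.ploidy_likelihoods(reads, ps, 0.01)
        want = oracle_likelihoods(panel.haplotypes, panel.weights, reads, 0.01)
        np.testing.assert_allclose((l_hap, l_dip), want, rtol=1e-12)
        assert l_hap == pytest.approx(0.5 * 0.99 * 0.01 + 0.5 * 0.01 * 0.99)
        assert np.log(l_hap) - np.log(l_dip) < 0

    def test_empty_read_list_errors(self):
        panel = make_panel([(0,), (1,)])
        ps = collapse_local_patterns(panel, [0])
        with pytest.raises(ValueError):
            lk.ploidy_likelihoods([], ps, 0.01)

    def test_matches_brute_force_oracle(self):
        """200 random instances (H<=6, reads<=4) equal nested-sum oracle to
        1e-12 relative."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            H, S = rng.integers(2, 7), rng.integers(1, 7)
            haps = rng.integers(0, 2, (H, S))
            panel = make_panel(haps)
            reads = []
            for _ in range(rng.integers(1, 5)):
                k = rng.integers(1, min(4, S) + 1)
                idx = np.sort(rng.choice(S, size=k, replace=False))
                reads.append((idx, rng.integers(0, 2, size=k)))
            eps = float(rng.uniform(0.0, 0.45))
            union = np.unique(np.concatenate([i for i, _ in reads]))
            ps = collapse_local_patterns(panel, union)
            got = lk.ploidy_likelihoods(reads, ps, eps)
            want = oracle_likelihoods(haps, panel.weights, reads, eps)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_epsilon_half_means_llr_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            H, S = rng.integers(2, 7), rng.integers(2, 6)
            panel = make_panel(rng.integers(0, 2, (H, S)))
            reads = []
            for _ in range(rng.integers(2, 4)):
                k = rng.integers(1, S + 1)
                idx = np.sort(rng.choice(S, size=k, replace=False))
                reads.append((idx, rng.integers(0, 2, size=k)))
            assert lk.llr_from_reads(reads, panel, 0.5) == pytest.approx(
                0.0, abs=1e-12
            )


class TestAnchorReadSets:
    def test_single_covering_read_gives_llr_zero(self, small_panel):
        obs = make_obs([("r1", 0, 1)])
        bins = {"chr1": np.array([[0, 10_000]])}
        stats = lk.bin_statistics(
            bins, obs, small_panel, lk.EmissionConfig(min_reads_per_bin=1)
        )
        assert stats[0].valid
        assert stats[0].llr_mean == pytest.approx(0.0, abs=1e-12)

    def test_nearest_neighbor_selection_cap(self):
        """m=2: anchor read plus only the nearest SNP-bearing neighbor."""
        positions = [1001, 1101, 1201, 1301]
        panel = make_panel(
            [(0, 0, 0, 0), (1, 1, 1, 1), (0, 1, 0, 1), (1, 0, 1, 0)],
            positions=positions,
        )
        br = lk._BinReads(
            reads=[
                (np.array([0]), np.array([1])),  # anchor read at 1001
                (np.array([1]), np.array([1])),  # 100 bp away
                (np.array([2]), np.array([1])),  # 200 bp away
                (np.array([3]), np.array([1])),  # 300 bp away
            ],
            read_ids=["a", "b", "c", "d"],
            left_pos=np.array([1001, 1101, 1201, 1301]),
            covers=[{0}, {1}, {2}, {3}],
        )
        chosen = lk._anchor_read_set(0, 1001, br, max_reads=2)
        assert chosen == [0, 1]

    def test_anchor_llr_matches_oracle_on_toy_fixture(self):
        """4-haplotype panel, 3 reads: anchored LLR equals direct summation."""
        panel = make_panel([(0, 0, 0), (1, 1, 1), (0, 1, 1), (1, 0, 0)])
        reads = [
            (np.array([0, 1]), np.array([1, 1])),
            (np.array([1]), np.array([0])),
            (np.array([2]), np.array([1])),
        ]
        eps = 0.02
        got = lk.llr_from_reads(reads, panel, eps)
        l_hap, l_dip = oracle_likelihoods(panel.haplotypes, panel.weights, reads, eps)
        assert got == pytest.approx(np.log(l_hap) - np.log(l_dip), rel=1e-12)


class TestBinStatistics:
    def test_mean_and_population_variance(self, small_panel, monkeypatch):
        vals = iter([0.2, 0.4])
        monkeypatch.setattr(
            lk, "snp_anchored_llr", lambda *a, **k: next(vals)
        )
        # two anchors, three reads (> cap 2) to route through per-anchor path
        obs = make_obs([("r1", 0, 1), ("r2", 1, 1), ("r3", 0, 0)])
        bins = {"chr1": np.array([[0, 10_000]])}
        cfg = lk.EmissionConfig(max_reads_per_anchor=2, min_reads_per_bin=2)
        stats = lk.bin_statistics(bins, obs, small_panel, cfg)
        assert stats[0].llr_mean == pytest.approx(0.3)
        assert stats[0].llr_var == pytest.approx(0.01)

    def test_min_reads_rule_invalidates_bin(self, small_panel):
        obs = make_obs([("r1", 0, 1)])
        bins = {"chr1": np.array([[0, 10_000]])}
        stats = lk.bin_statistics(bins, obs, small_panel, lk.EmissionConfig())
        assert not stats[0].valid
        assert stats[0].n_reads == 1

    def test_empty_bin_is_invalid_not_error(self, small_panel):
        bins = {"chr1": np.array([[0, 10_000], [10_000, 20_000]])}
        stats = lk.bin_statistics(bins, make_obs([]), small_panel)
        assert [s.valid for s in stats] == [False, False]

    def test_sparse_bin_shares_one_llr_across_anchors(self, small_panel):
        """With reads <= cap, every anchor sees the same read set, so the
        per-bin variance is exactly zero."""
        obs = make_obs([("r1", 0, 1), ("r2", 1, 1)])
        bins = {"chr1": np.array([[0, 10_000]])}
        stats = lk.bin_statistics(bins, obs, small_panel)
        assert stats[0].valid
        assert stats[0].n_snps_with_llr == 2
        assert stats[0].llr_var == 0.0


class TestDirectionality:
    def test_aoh_bins_score_higher_than_diploid(self):
        """Synthetic AOH vs diploid bins at 0.1x: mean LLR separates with the
        expected sign, and the margin grows with depth."""
        from aohscan.synthetic import (
            SimConfig,
            simulate_individual,
            simulate_panel,
            simulate_reads,
        )
        from aohscan.windowing import GenomeDefinition, make_bins

        margins = {}
        for depth in (0.05, 0.5):
            cfg = SimConfig(chrom_length=10_000_000, depth=depth, seed=11)
            panel = simulate_panel(cfg)
            aoh = [(cfg.chrom, 0, 5_000_000)]
            truth = simulate_individual(panel, aoh, seed=12)
            obs = simulate_reads(truth, cfg, seed=13)
            bins = make_bins(GenomeDefinition({cfg.chrom: cfg.chrom_length}))
            stats = lk.bin_statistics(bins, obs, panel, seed=0)
            inside = [s.llr_mean for s in stats if s.valid and s.end <= 5_000_000]
            outside = [s.llr_mean for s in stats if s.valid and s.start >= 5_000_000]
            assert np.mean(inside) > np.mean(outside)
            margins[depth] = np.mean(inside) - np.mean(outside)
        assert margins[0.5] > margins[0.05]


def test_track_writer_round_trips_fields(tmp_path, small_panel):
    obs = make_obs([("r1", 0, 1), ("r2", 1, 1)])
    bins = {"chr1": np.array([[0, 10_000]])}
    stats = lk.bin_statistics(bins, obs, small_panel)
    lk.write_binstat_track(stats, tmp_path / "track.tsv")
    lines = (tmp_path / "track.tsv").read_text().splitlines()
    assert lines[0].split("\t") == [
        "chrom", "start", "end", "llr_mean", "llr_var", "n_snps", "valid",
    ]
    assert len(lines) == 2
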