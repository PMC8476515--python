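"""Simulator distributions, determinism and planted-truth recovery."""

import numpy as np
import pytest
from scipy import stats

from miser.caller import WT_NO_SCAR, call_read, count_variants
from miser.core import DeletionVariant, MiserError, SizeWindow
from miser.simulate import (
    EmptyLibraryError,
    FitnessLandscape,
    FitnessWindow,
    SimConfig,
    default_simulation,
    emit_reads,
    pool_counts,
    random_orf,
    run_end_to_end,
    sample_library,
    sort_pool,
)


class TestRandomOrf:
    def test_forbidden_motifs_absent(self, orf1368):
        for motif in ("GCTAGC", "ACTAGT", "GCTAGT", "ACTAGC", "GGTCTC", "CGTCTC"):
            assert motif not in orf1368.nt_seq

    def test_reproducible(self):
        a = random_orf(50, np.random.default_rng(3)).nt_seq
        b = random_orf(50, np.random.default_rng(3)).nt_seq
        assert a == b


class TestFitnessLandscape:
    def test_step_rule(self):
        land = FitnessLandscape(
            windows=(FitnessWindow(100, 200, 0.8), FitnessWindow(120, 160, 0.5)),
            baseline=0.01,
        )
        assert land.fitness(99, 200) == 0.8  # span 100-200, only outer window
        assert land.fitness(119, 160) == 0.5  # contained in both; smallest wins
        assert land.fitness(50, 90) == 0.01  # outside all windows
        assert land.fitness(150, 150) == 1.0  # scar-only insertion

    def test_invalid_height(self):
        with pytest.raises(MiserError):
            FitnessWindow(1, 10, 0.0)


class TestSampleLibrary:
    def test_uniform_pairs_give_triangular_length_marginal(self):
        n = 200
        cfg = SimConfig(
            orf=random_orf(n, np.random.default_rng(0)),
            n_library_variants=100_000,
            seed=123,
        )
        library = sample_library(cfg)
        by_k = np.zeros(n, dtype=float)
        for v, c in library.items():
            by_k[v.k] += c
        total_pairs = n * (n + 1) // 2
        expected = np.array([n if k == 0 else n - k for k in range(n)], dtype=float)
        expected = expected / total_pairs * by_k.sum()
        keep = expected >= 5
        chi2 = ((by_k[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01
        # marginal decreases in k over the long run
        assert by_k[:50].sum() > by_k[100:150].sum()

    def test_size_window_respected(self, orf300):
        window = SizeWindow(3 * (300 - 30) + 6, 3 * (300 - 1) + 6)  # k in 1..30
        cfg = SimConfig(orf=orf300, n_library_variants=500, size_window=window, seed=5)
        library = sample_library(cfg)
        assert sum(library.values()) == 500
        assert all(1 <= v.k <= 30 for v in library)

    def test_no_window_no_filtering(self, orf300):
        cfg = SimConfig(orf=orf300, n_library_variants=200, seed=6)
        library = sample_library(cfg)
        assert sum(library.values()) == 200

    def test_infeasible_window_raises(self, orf300):
        # variant ORF lengths are always 3(N - k) + 6, i.e. multiples of 3;
        # a window containing none of them is unreachable
        cfg = SimConfig(
            orf=orf300, n_library_variants=10,
            size_window=SizeWindow(13, 14), seed=0,
        )
        with pytest.raises(EmptyLibraryError):
            sample_library(cfg)

    def test_same_seed_same_multiset(self, orf300):
        cfg = SimConfig(orf=orf300, n_library_variants=300, seed=77)
        assert sample_library(cfg) == sample_library(cfg)


class TestSortPool:
    def test_neutral_selection_preserves_frequencies(self, orf300):
        rng = np.random.default_rng(8)
        cfg = SimConfig(orf=orf300, n_library_variants=40, seed=8)
        library = sample_library(cfg, rng)
        neutral = FitnessLandscape(windows=(), baseline=1.0)
        n = 200_000
        pool = sort_pool(library, neutral, n, rng)
        total_lib = sum(library.values())
        tv = 0.5 * sum(
            abs(pool.get(v, 0) / n - c / total_lib) for v, c in library.items()
        )
        assert tv < 0.02

    def test_hundred_to_one_fitness_ratio(self, orf300):
        # equal abundance, fitness 1.0 vs 0.01 -> expected sorted ratio 100:1
        v_fit = DeletionVariant(40, 80)      # inside the tolerated window
        v_unfit = DeletionVariant(150, 250)  # outside
        library = {v_fit: 1, v_unfit: 1}
        land = FitnessLandscape(windows=(FitnessWindow(30, 100, 1.0),), baseline=0.01)
        n = 50_000
        pool = sort_pool(library, land, n, np.random.default_rng(10))
        p = 0.01 / 1.01
        expect_unfit = n * p
        sd = np.sqrt(n * p * (1 - p))
        assert abs(pool.get(v_unfit, 0) - expect_unfit) < 3 * sd

    def test_zero_reads_empty(self, orf300):
        library = {DeletionVariant(10, 20): 3}
        assert sort_pool(library, FitnessLandscape(), 0, 1) == {}


class TestEmitReads:
    def _cfg(self, orf, **kw):
        defaults = dict(orf=orf, n_library_variants=10, n_reads_naive=0,
                        n_reads_sorted=0, substitution_error_rate=0.0, seed=0)
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_error_free_reads_round_trip_through_caller(self, orf300):
        rng = np.random.default_rng(2)
        pool = {DeletionVariant(60, 120, "AS"): 40, DeletionVariant(200, 200, "TS"): 40}
        cfg = self._cfg(orf300)
        counts = count_variants(
            ((rid, seq) for rid, seq, _ in emit_reads(pool, orf300, cfg, rng)),
            orf300,
        )
        # every callable junction read recovers its exact (a, b); reads with
        # flanks off the read edge are flank_truncated, and reads overlapping
        # the scar by fewer than 6 nt show no motif and read as WT
        assert set(counts.totals()) <= {(60, 120), (200, 200)}
        accounted = counts.n_variant_reads + counts.no_call["flank_truncated"] + counts.wt
        assert accounted == 80
        assert counts.n_variant_reads > 40
        assert counts.no_call["flank_mismatch"] == 0

    def test_wt_fraction_one_reports_all_wt(self, orf300):
        rng = np.random.default_rng(3)
        cfg = self._cfg(orf300)
        reads = list(emit_reads({}, orf300, cfg, rng, n_wt_reads=200))
        assert len(reads) == 200
        for rid, seq, _ in reads:
            assert call_read(seq, orf300).outcome == WT_NO_SCAR

    def test_error_rate_monotonically_increases_flank_mismatch(self, orf300):
        pool = {DeletionVariant(100, 150, "AS"): 3000}
        rates = {}
        for rate in (0.001, 0.05):
            rng = np.random.default_rng(42)
            cfg = self._cfg(orf300, substitution_error_rate=rate)
            counts = count_variants(
                ((rid, seq) for rid, seq, _ in emit_reads(pool, orf300, cfg, rng)),
                orf300,
            )
            rates[rate] = counts.no_call["flank_mismatch"]
        assert rates[0.05] > rates[0.001]

    def test_read_length_exceeding_variant_orf_raises(self, toy_orf):
        cfg = self._cfg(toy_orf, read_len=100)
        with pytest.raises(MiserError):
            list(emit_reads({DeletionVariant(2, 4): 1}, toy_orf, cfg, np.random.default_rng(0)))

    def test_bitwise_reproducible(self, orf300):
        pool = {DeletionVariant(60, 120): 50}
        cfg = self._cfg(orf300, substitution_error_rate=0.01)
        first = list(emit_reads(pool, orf300, cfg, np.random.default_rng(5), n_wt_reads=50))
        second = list(emit_reads(pool, orf300, cfg, np.random.default_rng(5), n_wt_reads=50))
        assert first == second


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def small_scenario(self, orf300):
        cfg = SimConfig(
            orf=orf300,
            n_library_variants=400,
            size_window=SizeWindow(3 * (300 - 30) + 6, 3 * (300 - 1) + 6),
            n_reads_naive=30_000,
            n_reads_sorted=30_000,
            seed=7,
        )
        fitness = FitnessLandscape(
            windows=(FitnessWindow(40, 80), FitnessWindow(150, 210))
        )
        return cfg, fitness

    def test_planted_windows_recovered(self, small_scenario):
        cfg, fitness = small_scenario
        result = run_end_to_end(cfg, fitness)
        assert set(result.jaccard) == {(40, 80), (150, 210)}
        for window, jac in result.jaccard.items():
            assert jac >= 0.8, (window, jac)
        assert result.rank_correlation > 0.7

    def test_neutral_null_calls_no_regions(self, small_scenario):
        cfg, _ = small_scenario
        result = run_end_to_end(cfg, None)
        assert result.regions == []

    def test_more_reads_do_not_hurt_recovery(self, orf300):
        fitness = FitnessLandscape(windows=(FitnessWindow(40, 80),))
        jaccards = []
        for n_reads in (6_000, 24_000):
            cfg = SimConfig(
                orf=orf300, n_library_variants=300,
                size_window=SizeWindow(3 * (300 - 30) + 6, 3 * (300 - 1) + 6),
                n_reads_naive=n_reads, n_reads_sorted=n_reads, seed=19,
            )
            result = run_end_to_end(cfg, fitness)
            jaccards.append(np.mean(list(result.jaccard.values())))
        assert jaccards[1] >= jaccards[0] - 0.05

    def test_default_scenario_construction(self):
        cfg, fitness = default_simulation(seed=1, n_codons=200)
        assert cfg.orf.n_codons == 200
        assert cfg.size_window is not None
        assert len(fitness.windows) == 4
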