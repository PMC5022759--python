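import itertools

import numpy as np
import pytest
import scipy.stats

from gaseg import (CSF, GM, WM, ConfigurationError, GAConfig, GrowConfig,
                   ReferenceSegmentation, SeedSet, candidate_seeds, crossover,
                   fitness, ga_optimize, mutate, naive_seeds, segment,
                   tournament_select, windows_from_means,
                   windows_from_reference)
from gaseg.phantom import DEFAULT_CLASS_MEANS

from conftest import make_blob_fixture

WINDOWS = windows_from_means(DEFAULT_CLASS_MEANS)


class TestCandidateSeeds:
    def test_noise_free_windows_recover_ground_truth_masks(
            self, noise_free_phantom):
        _, image, ref = noise_free_phantom
        masks = candidate_seeds(image, WINDOWS)
        for c, m in ref.masks.items():
            assert np.array_equal(masks[c], m)

    def test_toy_image_matches_exhaustive_pixel_scan(self):
        image = np.array([[10.0, 70.0, 130.0, 210.0],
                          [40.0, 90.0, 160.0, 240.0],
                          [55.0, 120.0, 170.0, 20.0],
                          [60.0, 100.0, 190.0, 0.0]])
        windows = {CSF: (0.0, 50.0), GM: (51.0, 150.0), WM: (151.0, 255.0)}
        masks = candidate_seeds(image, windows)
        for c, (lo, hi) in windows.items():
            expected = np.zeros(image.shape, dtype=bool)
            for r in range(4):
                for s in range(4):
                    expected[r, s] = lo <= image[r, s] <= hi
            assert np.array_equal(masks[c], expected)

    def test_overlapping_windows_rejected(self):
        image = np.zeros((4, 4))
        with pytest.raises(ConfigurationError):
            candidate_seeds(image, {1: (0.0, 100.0), 2: (50.0, 200.0)})

    def test_empty_candidate_mask_rejected(self):
        image = np.zeros((4, 4))
        with pytest.raises(ConfigurationError):
            candidate_seeds(image, {1: (200.0, 210.0)})

    def test_windows_from_reference_recovers_midpoint_windows(
            self, noise_free_phantom):
        _, image, ref = noise_free_phantom
        windows = windows_from_reference(image, ref)
        assert windows[CSF][0] == pytest.approx(30.0, abs=1e-6)
        assert windows[CSF][1] == pytest.approx(90.0)
        assert windows[GM][1] == pytest.approx(160.0)
        assert windows[WM][1] == np.inf


class TestFitness:
    def test_perfect_prediction_costs_zero(self, noise_free_phantom):
        _, _, ref = noise_free_phantom
        res = fitness(ref.label_map(), ref)
        assert res.total_cost == 0.0
        assert all(v == 0.0 for v in res.per_class_cost.values())

    def test_hand_counted_toy_mismatches(self):
        # ref GM: 4 pixels; prediction misses one and adds one elsewhere
        ref_labels = np.zeros((3, 3), dtype=int)
        ref_labels[0:2, 0:2] = GM
        ref_labels[2, 2] = WM
        ref_labels[2, 0] = CSF
        pred = ref_labels.copy()
        pred[1, 1] = 0      # missed GM pixel
        pred[0, 2] = GM     # spurious GM pixel
        ref = ReferenceSegmentation.from_label_map(ref_labels)
        res = fitness(pred, ref)
        assert res.per_class_cost[GM] == 2.0
        assert res.per_class_cost[WM] == 0.0
        assert res.per_class_cost[CSF] == 0.0
        assert res.total_cost == 2.0

    def test_all_background_costs_total_foreground(self, noise_free_phantom):
        _, _, ref = noise_free_phantom
        res = fitness(np.zeros(ref.shape, dtype=int), ref)
        for c, m in ref.masks.items():
            assert res.per_class_cost[c] == float(m.sum())
        assert res.total_cost == float(sum(m.sum() for m in ref.masks.values()))

    def test_symmetric_under_swapping_prediction_and_reference(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 4, size=(12, 12))
        b = rng.integers(0, 4, size=(12, 12))
        classes = (1, 2, 3)
        ra = ReferenceSegmentation(masks={c: a == c for c in classes})
        rb = ReferenceSegmentation(masks={c: b == c for c in classes})
        assert fitness(a, rb).total_cost == fitness(b, ra).total_cost


def _seedset(*coords):
    return SeedSet(class_order=(1, 2, 3), coords=tuple(coords))


class TestOperators:
    def test_single_member_population_always_selected(self):
        s = _seedset((0, 0), (0, 1), (0, 2))
        cfg = GAConfig(population_size=2, tournament_size=2)
        rng = np.random.default_rng(0)
        assert tournament_select([s], [5.0], cfg, rng) is s

    def test_two_member_tournament_picks_best_three_quarters_of_draws(self):
        # entrants drawn with replacement: tournaments {AA, AB, BA, BB}
        # are equiprobable and the better A wins 3 of 4
        a = _seedset((0, 0), (0, 1), (0, 2))
        b = _seedset((1, 0), (1, 1), (1, 2))
        cfg = GAConfig(population_size=2, tournament_size=2)
        rng = np.random.default_rng(42)
        wins = sum(tournament_select([a, b], [1.0, 2.0], cfg, rng) is a
                   for _ in range(10_000))
        assert abs(wins / 10_000 - 0.75) < 0.02

    def test_identical_parents_crossover_to_themselves(self):
        a = _seedset((0, 0), (1, 1), (2, 2))
        c1, c2 = crossover(a, a, np.random.default_rng(0))
        assert c1 == a and c2 == a

    def test_crossover_enumerates_all_swap_patterns(self):
        a = _seedset((0, 0), (0, 1), (0, 2))
        b = _seedset((1, 0), (1, 1), (1, 2))
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(500):
            c1, c2 = crossover(a, b, rng)
            for child in (c1, c2):
                for gene, ga_, gb_ in zip(child.coords, a.coords, b.coords):
                    assert gene in (ga_, gb_)
            # complementary children: together they hold both parents' genes
            for g1, g2, ga_, gb_ in zip(c1.coords, c2.coords, a.coords, b.coords):
                assert {g1, g2} == {ga_, gb_}
            seen.add(c1.coords)
        assert len(seen) == 8  # all 2^3 swap patterns occur

    def test_zero_mutation_rate_is_identity(self):
        s = _seedset((0, 0), (1, 1), (2, 2))
        cand = {c: np.ones((4, 4), dtype=bool) for c in (1, 2, 3)}
        assert mutate(s, cand, 0.0, np.random.default_rng(0)) == s

    def test_full_mutation_with_singleton_candidates_is_deterministic(self):
        s = _seedset((0, 0), (1, 1), (2, 2))
        cand = {}
        for i, c in enumerate((1, 2, 3)):
            m = np.zeros((4, 4), dtype=bool)
            m[3, i] = True
            cand[c] = m
        out = mutate(s, cand, 1.0, np.random.default_rng(0))
        assert out.coords == ((3, 0), (3, 1), (3, 2))

    def test_mutation_resamples_uniformly_over_candidates(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True  # m = 9 candidate pixels
        cand = {1: mask, 2: ~mask, 3: np.zeros((5, 5), dtype=bool)}
        cand[3][0, 0] = True
        s = SeedSet(class_order=(1,), coords=((1, 1),))
        rng = np.random.default_rng(7)
        counts = {}
        n = 10_000
        for _ in range(n):
            out = mutate(s, cand, 1.0, rng)
            counts[out.coords[0]] = counts.get(out.coords[0], 0) + 1
        observed = np.array([counts.get(tuple(c), 0)
                             for c in np.argwhere(mask)])
        chi2 = ((observed - n / 9) ** 2 / (n / 9)).sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=8)


class TestGAOptimize:
    def test_optimum_in_initial_population_is_kept(self, noise_free_phantom,
                                                   grow_cfg, small_ga_cfg):
        _, image, ref = noise_free_phantom
        cand = candidate_seeds(image, WINDOWS)
        best, history = ga_optimize(image, ref, cand, grow_cfg, small_ga_cfg)
        # noise-free classes are separable: every candidate seed set is
        # perfect, so generation 0 already contains the optimum
        assert history[-1] == 0.0
        assert fitness(segment(image, best, grow_cfg), ref).total_cost == 0.0

    def test_matches_exhaustive_search_on_tiny_fixture(self, grow_cfg):
        image, ref = make_blob_fixture()
        windows = windows_from_reference(image, ref)
        cand = candidate_seeds(image, windows)
        coords = {c: np.argwhere(m) for c, m in cand.items()}
        assert all(len(v) <= 20 for v in coords.values())
        brute = min(
            fitness(segment(image, SeedSet(grow_cfg.class_order, combo),
                            grow_cfg), ref).total_cost
            for combo in itertools.product(
                *(map(tuple, coords[c]) for c in grow_cfg.class_order)))
        ga_cfg = GAConfig(population_size=16, generations=30,
                          mutation_rate=0.25, stall_generations=30, rng_seed=5)
        _, history = ga_optimize(image, ref, cand, grow_cfg, ga_cfg)
        assert history[-1] == brute

    def test_single_candidate_per_class_returns_that_seed_set(self, grow_cfg):
        image, ref = make_blob_fixture()
        cand = {}
        for c, m in ref.masks.items():
            only = np.zeros(image.shape, dtype=bool)
            only[tuple(np.argwhere(m)[4])] = True
            cand[c] = only
        ga_cfg = GAConfig(population_size=4, elitism_count=1, generations=3,
                          rng_seed=1)
        best, history = ga_optimize(image, ref, cand, grow_cfg, ga_cfg)
        assert best.coords == tuple(tuple(np.argwhere(cand[c])[0])
                                    for c in grow_cfg.class_order)

    def test_history_is_monotonically_non_increasing(self, grow_cfg):
        image, ref = make_blob_fixture()
        cand = candidate_seeds(image, windows_from_reference(image, ref))
        for seed in range(3):
            _, history = ga_optimize(
                image, ref, cand, grow_cfg,
                GAConfig(population_size=8, generations=12, rng_seed=seed))
            assert all(b <= a for a, b in zip(history, history[1:]))

    def test_bit_reproducible_under_fixed_seed(self, noisy_phantom, grow_cfg,
                                               small_ga_cfg):
        _, image, ref = noisy_phantom
        cand = candidate_seeds(image, windows_from_reference(image, ref))
        out1 = ga_optimize(image, ref, cand, grow_cfg, small_ga_cfg)
        out2 = ga_optimize(image, ref, cand, grow_cfg, small_ga_cfg)
        assert out1[0] == out2[0] and out1[1] == out2[1]


def test_naive_seeds_picks_first_row_major_pixel(noise_free_phantom):
    _, image, ref = noise_free_phantom
    seeds = naive_seeds(image, WINDOWS, class_order=(1, 2, 3))
    for c, coord in seeds.coords_by_class().items():
        expected = tuple(np.argwhere(ref.masks[c])[0])
        assert coord == tuple(int(v) for v in expected)
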