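"""Stochastic generation cycle: step-level laws and whole-cycle invariants."""

import numpy as np
import pytest

from coelosim import (HabitatParams, SimulationConfig, deterministic_recursion,
                      maturation_probability, run_replicates, run_simulation)
from coelosim.params import FEMALE, MALE, DevelopmentParams
from coelosim.simulator import (Cohort, ExtinctionError, census,
                                draw_development_time,
                                draw_habitat_availability,
                                expected_development_time, initialize_cohort,
                                mature, reproduce, survive_viability)


def _cohort(genotype, sex):
    return Cohort(genotype=np.asarray(genotype, dtype=np.int8),
                  sex=np.asarray(sex, dtype=np.int8))


class TestInitialization:
    def test_fixed_allele_gives_monomorphic_cohort(self, rng):
        cfg = SimulationConfig(k=500, p0=1.0)
        eggs = initialize_cohort(cfg, rng)
        assert np.all(eggs.genotype == 0)

    def test_hardy_weinberg_counts(self, rng):
        cfg = SimulationConfig(k=10_000, p0=0.5)
        eggs = initialize_cohort(cfg, rng)
        counts = np.bincount(eggs.genotype, minlength=3)
        # within 4 SD of the multinomial expectation (2500, 5000, 2500)
        assert abs(counts[0] - 2500) < 4 * np.sqrt(10_000 * 0.25 * 0.75)
        assert abs(counts[1] - 5000) < 4 * np.sqrt(10_000 * 0.5 * 0.5)

    def test_allele_frequency_of_founding_props(self, rng):
        cfg = SimulationConfig(k=1000, initial_props=(0.3, 0.5, 0.2))
        eggs = initialize_cohort(cfg, rng)
        counts = np.bincount(eggs.genotype, minlength=3)
        p = (2 * counts[0] + counts[1]) / 2000
        assert p == pytest.approx(0.55, abs=0.05)


class TestViability:
    def test_zero_viability_empties_cohort(self, lab, rng):
        fp, _, _ = lab
        eggs = _cohort([0, 1, 2] * 100, [0, 1] * 150)
        survivors = survive_viability(eggs, fp.replace(V=1e-12), rng)
        assert len(survivors) == 0

    def test_certain_survival_keeps_all(self, rng):
        from coelosim import FitnessParams
        fp = FitnessParams(S=np.ones((2, 3)), T=np.ones((2, 3)), V=1.0)
        eggs = _cohort([1] * 500, [0] * 500)
        assert len(survive_viability(eggs, fp, rng)) == 500

    def test_binomial_moments_for_heterozygote_males(self, lab, rng):
        fp, _, _ = lab
        eggs = _cohort([1] * 10_000, [MALE] * 10_000)
        n = len(survive_viability(eggs, fp, rng))
        # Binomial(10000, 0.3): mean 3000, SD ~45.8; 4 SD band
        assert abs(n - 3000) < 4 * 45.83


class TestDevelopmentTime:
    def test_degenerate_uniform_is_exact(self, rng):
        dp = DevelopmentParams(mu=[[9, 9, 9], [9, 9, 8.8]], c=0.0)
        d = draw_development_time([MALE] * 5, [2] * 5, dp, rng)
        assert np.allclose(d, 8.8)

    def test_support_bounds(self, lab, rng):
        _, dp, _ = lab
        d = draw_development_time([MALE] * 10_000, [0] * 10_000, dp, rng)
        assert np.all(d >= 12.8 * 0.5) and np.all(d <= 12.8 * 1.5)

    def test_closed_form_mean(self, lab, rng):
        # E[D] = mu * (0.75 (1.5^{4/3} - 0.5^{4/3}))^3 ~ 0.9709 mu for c = 0.5
        _, dp, _ = lab
        n = 10 ** 6
        d = draw_development_time([MALE] * n, [0] * n, dp, rng)
        expected = expected_development_time(12.8, 0.5)
        assert expected == pytest.approx(0.9709 * 12.8, abs=0.01)
        se = d.std() / np.sqrt(n)
        assert abs(d.mean() - expected) < 3 * se


class TestHabitatAndMaturation:
    def test_habitat_support(self, rng):
        hp = HabitatParams(a_mean=9, a_var=2)
        a = draw_habitat_availability(hp, rng, size=10_000)
        assert a.min() >= 7 and a.max() <= 11

    def test_unlimited_habitat_never_censors(self, lab, rng):
        # max development time 1.5 * 12.8 = 19.2 < 28 = A_mean - A_var
        fp, dp, hp = lab
        larvae = _cohort([0] * 2000, [MALE] * 2000)
        larvae.dev_time = draw_development_time(larvae.sex, larvae.genotype, dp, rng)
        assert len(mature(larvae, hp, rng)) == 2000

    def test_hard_threshold_without_variability(self, rng):
        hp = HabitatParams(a_mean=9, a_var=0)
        slow = _cohort([0] * 100, [MALE] * 100)
        slow.dev_time = np.full(100, 12.8)
        fast = _cohort([2] * 100, [MALE] * 100)
        fast.dev_time = np.full(100, 8.8)
        assert len(mature(slow, hp, rng)) == 0
        assert len(mature(fast, hp, rng)) == 100

    def test_maturation_probability_against_monte_carlo(self, rng):
        # quadrature oracle for P((u1 u2 u3)^{1/3} < U[7, 11]) with mu = 12.8
        p = maturation_probability(12.8, 0.5, 9.0, 2.0)
        n = 400_000
        dp = DevelopmentParams(mu=np.full((2, 3), 12.8), c=0.5)
        d = draw_development_time([MALE] * n, [0] * n, dp, rng)
        a = rng.uniform(7, 11, size=n)
        mc = np.mean(d < a)
        assert p == pytest.approx(mc, abs=4 * np.sqrt(0.25 / n) + 1e-6)

    @pytest.mark.parametrize("mu,c,a_mean,a_var,expected", [
        (12.8, 0.0, 9.0, 0.0, 0.0),   # slow genotype never matures
        (8.8, 0.0, 9.0, 0.0, 1.0),    # fast genotype always matures
        (10.0, 0.0, 10.0, 2.0, 0.5),  # symmetric window around mu
    ])
    def test_maturation_probability_degenerate_cases(self, mu, c, a_mean,
                                                     a_var, expected):
        assert maturation_probability(mu, c, a_mean, a_var) == pytest.approx(expected)


class TestReproduction:
    @pytest.mark.parametrize("gm,gp,possible", [
        (0, 0, {0}), (0, 1, {0, 1}), (0, 2, {1}),
        (1, 0, {0, 1}), (1, 1, {0, 1, 2}), (1, 2, {1, 2}),
        (2, 0, {1}), (2, 1, {1, 2}), (2, 2, {2}),
    ])
    def test_mendelian_support_exact_on_all_crosses(self, lab, rng, gm, gp, possible):
        fp, _, _ = lab
        adults = _cohort([gm] * 50 + [gp] * 50, [FEMALE] * 50 + [MALE] * 50)
        eggs = reproduce(adults, fp, rng)
        assert set(np.unique(eggs.genotype)) <= possible
        # both parental gametes reach the offspring
        if gm != 1 and gp != 1:
            assert set(np.unique(eggs.genotype)) == possible

    def test_single_cross_clutch_size_and_genotype(self, lab, rng):
        fp, _, _ = lab
        adults = _cohort([0, 2], [FEMALE, MALE])  # AA female x BB male
        eggs = reproduce(adults, fp, rng)
        assert len(eggs) == 70 and np.all(eggs.genotype == 1)

    def test_heterozygote_cross_segregation(self, lab, rng):
        fp, _, _ = lab
        adults = _cohort([1] * 1500 + [1], [FEMALE] * 1500 + [MALE])
        eggs = reproduce(adults, fp, rng)
        props = np.bincount(eggs.genotype, minlength=3) / len(eggs)
        # (1/4, 1/2, 1/4) within 4 SD of the multinomial
        n = len(eggs)
        assert abs(props[0] - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n)
        assert abs(props[1] - 0.50) < 4 * np.sqrt(0.5 * 0.5 / n)

    def test_father_draw_weighted_by_mating_success(self, lab, rng):
        # males: 100 AA + 100 BB with T_m = (1, 0.55, 0.1)
        # P(father AA) = 100 / (100 + 10) = 10/11; AB egg <=> father BB
        fp, _, _ = lab
        n_f = 20_000
        adults = _cohort([0] * n_f + [0] * 100 + [2] * 100,
                         [FEMALE] * n_f + [MALE] * 200)
        eggs = reproduce(adults, fp, rng)
        frac_ab = np.mean(eggs.genotype[:: 70] == 1)  # one egg per female
        assert frac_ab == pytest.approx(1 / 11, abs=4 * np.sqrt((1 / 11) * (10 / 11) / n_f))

    def test_missing_sex_raises_extinction(self, lab, rng):
        fp, _, _ = lab
        with pytest.raises(ExtinctionError):
            reproduce(_cohort([1] * 10, [FEMALE] * 10), fp, rng)


class TestCensus:
    def test_small_cohort_untouched(self, rng):
        eggs = _cohort([0] * 500, [0] * 500)
        assert len(census(eggs, 1000, rng)) == 500

    def test_subsample_unbiased(self, rng):
        n = 70_000
        genotype = np.repeat([0, 1, 2], [35_000, 21_000, 14_000]).astype(np.int8)
        eggs = Cohort(genotype=genotype, sex=np.zeros(n, dtype=np.int8))
        kept = census(eggs, 1000, rng)
        props = np.bincount(kept.genotype, minlength=3) / 1000
        assert props == pytest.approx([0.5, 0.3, 0.2], abs=0.07)

    def test_empty_cohort_is_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            census(_cohort([], []), 1000, rng)


class TestWholeCycle:
    def test_seed_determinism(self, lab, lab_cfg):
        fp, dp, hp = lab
        t1 = run_simulation(lab_cfg.replace(seed=77), fp, dp, hp)
        t2 = run_simulation(lab_cfg.replace(seed=77), fp, dp, hp)
        for a, b in zip(t1.records, t2.records):
            assert np.array_equal(a.egg_counts, b.egg_counts)
            assert np.array_equal(a.adult_counts, b.adult_counts)

    def test_counts_consistent_at_every_stage(self, lab, lab_cfg):
        fp, dp, hp = lab
        traj = run_simulation(lab_cfg.replace(seed=5), fp, dp, hp)
        for rec in traj.records:
            assert np.all(rec.egg_counts >= 0)
            assert np.all(rec.adult_counts >= 0)
            assert rec.adult_counts.sum() <= rec.egg_counts.sum()
            assert rec.egg_props == pytest.approx(
                rec.egg_props / rec.egg_props.sum(), abs=1e-9)

    def test_absorbing_state_without_alpha(self, lab):
        fp, dp, hp = lab
        cfg = SimulationConfig(k=500, n_generations=4, p0=0.0, seed=9)
        traj = run_simulation(cfg, fp, dp, hp)
        assert np.all(traj.p_egg() == 0.0) and np.all(traj.p_adult() == 0.0)

    def test_lab_scenario_alpha_rises(self, lab, lab_cfg):
        # the deterministic recursion predicts a monotone increase from
        # p0 = 0.32; at ~300 adults per replicate, drift noise can break
        # strict per-generation monotonicity occasionally, but the overall
        # G1 -> G5 rise is universal
        fp, dp, hp = lab
        trajs = run_replicates(lab_cfg, fp, dp, hp, n_replicates=30, seed=301)
        rises = [t.p_adult()[5] > t.p_adult()[1] for t in trajs]
        assert all(rises)
        monotone = [bool(np.all(np.diff(t.p_adult()) > 0)) for t in trajs]
        assert np.mean(monotone) >= 0.85


class TestDeterministicRecursion:
    def test_no_selection_keeps_proportions(self):
        from coelosim import FitnessParams
        fp = FitnessParams(S=np.ones((2, 3)), T=np.ones((2, 3)), V=0.5, E=70)
        dp = DevelopmentParams(mu=np.full((2, 3), 9.0), c=0.5)
        hp = HabitatParams(a_mean=30, a_var=2)
        rec = deterministic_recursion(fp, dp, hp, (0.3, 0.5, 0.2), 5)
        # gamete frequencies are preserved; genotypes reach HW after one round
        assert np.allclose(rec.p_egg, 0.55, atol=1e-12)
        assert np.allclose(rec.egg_props[1:], rec.egg_props[1], atol=1e-12)

    def test_paternal_gamete_frequency_hand_value(self, lab):
        # adults at (0.3, 0.5, 0.2) with T_m = (1, 0.55, 0.1):
        # paternal alpha-gamete frequency = 0.4375 / 0.595 ~ 0.73529,
        # so with neutral females (p_f = 0.55) egg AA = 0.55 * 0.73529
        from coelosim import FitnessParams
        fp_lab, _, _ = lab
        T = np.ones((2, 3))
        T[MALE] = fp_lab.T[MALE]
        fp = FitnessParams(S=np.ones((2, 3)), T=T, V=1.0, E=70)
        dp = DevelopmentParams(mu=np.full((2, 3), 9.0), c=0.0)
        hp = HabitatParams(a_mean=30, a_var=0)
        rec = deterministic_recursion(fp, dp, hp, (0.3, 0.5, 0.2), 1)
        assert rec.egg_props[1, 0] == pytest.approx(0.55 * 0.4375 / 0.595, abs=1e-12)

    def test_extinction_signalled_when_one_sex_has_no_weight(self, lab):
        from coelosim import FitnessParams
        fp = FitnessParams(S=np.ones((2, 3)), T=[[1, 1, 1], [0, 0, 0]], V=1.0)
        _, dp, hp = lab
        rec = deterministic_recursion(fp, dp, hp, (0.25, 0.5, 0.25), 3)
        assert rec.extinct
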