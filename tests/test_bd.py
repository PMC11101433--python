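"""Birth-death simulator: parameter draws, event dynamics, binning."""

import numpy as np
import pytest

from fossildiv.bd import (BDConfig, DivDependenceConfig, MassEventConfig,
                          TimeBins, bin_diversity, draw_bd_parameters,
                          simulate_clade, simulate_clade_rare_patterns)


def _free_config(**kw):
    """A config without acceptance constraints (bounds wide open)."""
    base = dict(diversity_bounds=(1, 10**9), p_mass_extinction=0.0,
                n_shift_mean=0.0)
    base.update(kw)
    return BDConfig(**base)


class TestDrawParameters:
    def test_degenerate_rate_interval_pins_all_rates(self, rng):
        cfg = BDConfig(rate_range=(0.3, 0.3))
        p = draw_bd_parameters(cfg, rng)
        assert np.allclose(p.lam_values, 0.3)
        assert np.allclose(p.mu_values, 0.3)

    def test_shift_count_poisson_mean_and_origin_bounds(self):
        rng = np.random.default_rng(0)
        cfg = BDConfig()
        n_lam, n_mu, origins = [], [], []
        for _ in range(10_000):
            p = draw_bd_parameters(cfg, rng)
            n_lam.append(p.lam_values.size - 1)
            n_mu.append(p.mu_values.size - 1)
            origins.append(p.t_origin)
        # mean shift count ~ Poi(4) within 3 standard errors, per process
        se = np.sqrt(4 / 10_000)
        assert abs(np.mean(n_lam) - 4) < 3 * se
        assert abs(np.mean(n_mu) - 4) < 3 * se
        # shifts drawn independently for the two processes
        assert not np.array_equal(n_lam, n_mu)
        assert min(origins) >= 30.0 and max(origins) <= 100.0

    def test_shift_ages_inside_history_and_rates_in_range(self, rng):
        cfg = BDConfig()
        for _ in range(200):
            p = draw_bd_parameters(cfg, rng)
            for ages, vals in ((p.lam_shift_ages, p.lam_values),
                               (p.mu_shift_ages, p.mu_values)):
                assert np.all((ages >= 0) & (ages <= p.t_origin))
                assert np.all((vals >= 0.05) & (vals <= 0.5))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BDConfig(rate_range=(0.5, 0.05))
        with pytest.raises(ValueError):
            BDConfig(p_mass_extinction=1.5)


class TestSimulateClade:
    def test_no_events_single_species_survives(self, rng):
        cfg = _free_config(rate_range=(0.0, 0.0))
        clade = simulate_clade(cfg, rng)
        assert clade.n_species == 1
        assert clade.n_extant == 1
        assert clade.origins[0] == pytest.approx(clade.params.t_origin)

    def test_pure_birth_matches_exponential_expectation(self):
        # E[N(t)] = e^{lambda t}: lambda=0.1, t=30 -> ~20.1
        rng = np.random.default_rng(1)
        cfg = _free_config(rate_range=(0.1, 0.1), t_origin_range=(30.0, 30.0))
        finals = []
        for _ in range(5000):
            p = draw_bd_parameters(cfg, rng)
            p.mu_values = np.zeros_like(p.mu_values)
            clade = simulate_clade(cfg, rng, params=p)
            finals.append(clade.n_extant)
        expected = np.exp(0.1 * 30)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_accepted_simulations_respect_diversity_bounds(self):
        rng = np.random.default_rng(2)
        cfg = BDConfig()
        for _ in range(500):
            clade = simulate_clade(cfg, rng)
            assert 100 <= clade.n_species <= 5000

    def test_mass_extinction_kill_fraction_in_stated_range(self):
        # freeze a 200-species standing clade, force one mass extinction
        rng = np.random.default_rng(3)
        cfg = _free_config(rate_range=(0.0, 0.0), t_origin_range=(2.0, 2.0),
                           n_start_range=(200, 200), p_mass_extinction=1.0)
        fractions = []
        for _ in range(200):
            clade = simulate_clade(cfg, rng)
            fractions.append(1.0 - clade.n_extant / 200)
        assert 0.8 <= np.mean(fractions) <= 0.95

    def test_mass_extinction_gated_on_standing_diversity(self, rng):
        cfg = _free_config(rate_range=(0.0, 0.0), t_origin_range=(5.0, 5.0),
                           n_start_range=(3, 3), p_mass_extinction=1.0,
                           min_lineages_for_me=10)
        for _ in range(20):
            clade = simulate_clade(cfg, rng)
            assert clade.n_extant == 3  # never applied below the gate

    def test_determinism_same_seed_same_history(self):
        cfg = BDConfig()
        a = simulate_clade(cfg, np.random.default_rng(99))
        b = simulate_clade(cfg, np.random.default_rng(99))
        assert np.array_equal(a.origins, b.origins)
        assert np.array_equal(a.extinctions, b.extinctions)

    def test_rejection_budget_exhaustion_names_constraint(self, rng):
        from fossildiv.bd import SimulationRejected

        cfg = _free_config(rate_range=(0.0, 0.0), diversity_bounds=(50, 100),
                           max_attempts=5)
        with pytest.raises(SimulationRejected, match="diversity"):
            simulate_clade(cfg, rng)


class TestRarePatterns:
    def test_requires_exactly_one_regime(self, rng):
        with pytest.raises(ValueError):
            simulate_clade_rare_patterns(BDConfig(), rng)
        with pytest.raises(ValueError):
            BDConfig(mass_speciation=MassEventConfig(),
                     div_dependence=DivDependenceConfig())

    def test_disabled_mass_events_reduce_to_plain_birth_death(self):
        off = MassEventConfig(p_per_bin=0.0, p_me_per_bin=0.0)
        cfg_off = _free_config(rate_range=(0.05, 0.3), mass_speciation=off)
        cfg_plain = _free_config(rate_range=(0.05, 0.3))
        p = draw_bd_parameters(cfg_off, np.random.default_rng(5))
        assert p.ms_ages.size == 0 and p.me_ages.size == 0
        # same realized parameters stepped under either config: identical
        a = simulate_clade(cfg_plain, np.random.default_rng(6), params=p)
        b = simulate_clade(cfg_off, np.random.default_rng(6), params=p)
        assert np.array_equal(a.origins, b.origins)
        assert np.array_equal(a.extinctions, b.extinctions)

    @staticmethod
    def _dd_clade(cfg, seed):
        """Diversity-dependent clade with pinned base rates (growth-capable)."""
        rng = np.random.default_rng(seed)
        p = draw_bd_parameters(cfg, rng)
        p.lam_values = np.array([0.5])
        p.mu_shift_ages = np.empty(0)
        p.mu_values = np.array([0.1])
        return simulate_clade(cfg, rng, params=p)

    def test_carrying_capacity_bounds_standing_diversity(self):
        cfg = BDConfig(
            t_origin_range=(90.0, 90.0),
            diversity_bounds=(1, 10**9),
            div_dependence=DivDependenceConfig(k_range=(50.0, 50.0),
                                               me_ages=()),
        )
        clade = self._dd_clade(cfg, seed=11)
        traj = bin_diversity(clade, TimeBins.regular(100.0, 100)).counts
        # equilibrium K (1 - mu/lambda) = 40: hovers near but never runs away
        assert traj.max() < 75
        assert 15 < np.mean(traj[-30:]) < 60

    def test_fixed_mass_extinctions_cause_diversity_drops(self):
        drops_66, drops_16 = [], []
        for seed in range(8):
            cfg = BDConfig(
                t_origin_range=(90.0, 100.0),
                diversity_bounds=(30, 10**9),
                div_dependence=DivDependenceConfig(k_range=(150.0, 200.0)),
            )
            traj = bin_diversity(self._dd_clade(cfg, seed),
                                 TimeBins.regular(100.0, 100)).counts
            # events kill at 66 and 16 Ma; compare just before vs just after
            if traj[33] >= 20:
                drops_66.append(traj[35] / traj[33])
            if traj[83] >= 20:
                drops_16.append(traj[85] / traj[83])
        assert np.median(drops_66) < 0.6
        assert np.median(drops_16) < 0.6


class TestBinDiversity:
    def test_single_long_lived_species_counted_everywhere(self, rng):
        cfg = _free_config(rate_range=(0.0, 0.0), t_origin_range=(100.0, 100.0))
        clade = simulate_clade(cfg, rng)
        traj = bin_diversity(clade, TimeBins.regular(100.0, 100))
        assert np.array_equal(traj.counts, np.ones(100))

    def test_boundary_crossing_species_counted_in_both_bins(self):
        from fossildiv.bd import BDParams, CladeHistory

        clade = CladeHistory(
            origins=np.array([10.5]), extinctions=np.array([9.5]),
            params=BDParams(10.5, 1, np.empty(0), np.array([0.0]),
                            np.empty(0), np.array([0.0]), np.empty(0),
                            np.empty(0)),
            me_applied=np.empty(0),
        )
        traj = bin_diversity(clade, TimeBins.regular(12.0, 12))
        assert traj.counts[1] == 1  # [11, 10)
        assert traj.counts[2] == 1  # [10, 9)
        assert traj.counts.sum() == 2

    def test_matches_brute_force_interval_overlap(self):
        rng = np.random.default_rng(7)
        cfg = _free_config(rate_range=(0.05, 0.25), t_origin_range=(5.0, 15.0),
                           n_shift_mean=2.0, diversity_bounds=(1, 500))
        bins = TimeBins.regular(15.0, 15)
        for _ in range(100):
            clade = simulate_clade(cfg, rng)
            got = bin_diversity(clade, bins).counts
            brute = np.zeros(bins.n)
            for o, e in zip(clade.origins, clade.extinctions):
                for i in range(bins.n):
                    old, young = bins.edges[i], bins.edges[i + 1]
                    # species interval [e, o] vs bin (young, old], youngest
                    # bin closed at its young edge
                    lo = young if i == bins.n - 1 else np.nextafter(young, old)
                    if o >= lo and e <= old:
                        brute[i] += 1
            assert np.array_equal(got, brute)

    def test_bins_not_covering_history_warn(self, rng):
        cfg = _free_config(rate_range=(0.0, 0.0), t_origin_range=(50.0, 50.0))
        clade = simulate_clade(cfg, rng)
        with pytest.warns(UserWarning, match="cover"):
            bin_diversity(clade, TimeBins.regular(30.0, 30))


class TestTimeBins:
    def test_edges_must_decrease(self):
        with pytest.raises(ValueError):
            TimeBins(np.array([1.0, 2.0, 3.0]))

    def test_regular_bins_contiguous(self):
        b = TimeBins.regular(100.0, 100)
        assert b.n == 100
        assert np.allclose(b.durations, 1.0)
        assert np.allclose(b.starts[1:], b.ends[:-1])
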