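"""Stochastic drift machinery: sampling primitives and full simulations."""

import numpy as np
import pytest

import agedrift as ad
from agedrift.life_tables import LifeTable
from agedrift.fecundity import FecunditySchedule
from agedrift.drift import _apportion


def one_class_population(N=20):
    """Everyone breeds in class 1 and dies: the Wright-Fisher limit."""
    lt = LifeTable(l=np.ones(1))
    fs = ad.normalize(lt, FecunditySchedule(m=np.ones(1)))
    return lt, fs


class TestResampleNewborns:
    def test_fixed_allele_is_degenerate(self, rng):
        np.testing.assert_array_equal(ad.resample_newborns(1.0, 13, rng), [13, 0, 0])
        np.testing.assert_array_equal(ad.resample_newborns(0.0, 13, rng), [0, 0, 13])

    def test_size_thirteen_draw_sums(self, rng):
        for _ in range(100):
            assert ad.resample_newborns(0.5, 13, rng).sum() == 13

    def test_empirical_frequencies_match_hw(self, rng):
        # 1e5 draws of size 13 at p=0.3: genotype fractions converge on
        # (p^2, 2pq, q^2) within 3 Monte-Carlo standard errors
        p, n, size = 0.3, 100_000, 13
        draws = rng.multinomial(size, (p * p, 2 * p * (1 - p), (1 - p) ** 2), size=n)
        totals = sum(ad.resample_newborns(p, size, rng) for _ in range(n))
        freqs = totals / (n * size)
        expect = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        se = np.sqrt(expect * (1 - expect) / (n * size))
        assert (np.abs(freqs - expect) < 3 * se + 1e-9).all()

    def test_invalid_p_rejected(self, rng):
        with pytest.raises(ValueError):
            ad.resample_newborns(1.5, 10, rng)


class TestCull:
    @pytest.mark.parametrize("mode", ["binomial", "faithful"])
    def test_certain_survival_keeps_everyone(self, rng, mode):
        counts = np.array([5, 7, 3])
        np.testing.assert_array_equal(ad.cull_age_class(counts, 1.0, rng, mode), counts)

    @pytest.mark.parametrize("mode", ["binomial", "faithful"])
    def test_certain_death_empties_class(self, rng, mode):
        assert ad.cull_age_class(np.array([5, 7, 3]), 0.0, rng, mode).sum() == 0

    def test_binomial_mean_survivors(self, rng):
        counts = np.array([400, 300, 300])
        P = 0.8
        reps = 3000
        totals = np.zeros(3)
        for _ in range(reps):
            totals += ad.cull_age_class(counts, P, rng, "binomial")
        mean = totals / reps
        se = np.sqrt(counts * P * (1 - P) / reps)
        assert (np.abs(mean - P * counts) < 3 * se).all()

    def test_faithful_mode_pins_class_total(self, rng):
        counts = np.array([40, 30, 30])
        for _ in range(200):
            surv = ad.cull_age_class(counts, 0.85, rng, "faithful")
            assert surv.sum() == round(0.85 * 100)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            ad.cull_age_class(np.array([1, 1, 1]), 1.2, rng)


class TestSelection:
    def test_neutral_leaves_all_genotypes_equal(self):
        P = np.array([0.9, 0.8])
        out = ad.apply_selection(P, 0.0, np.array([True, True]))
        np.testing.assert_allclose(out, np.tile(P, (3, 1)))

    def test_lethal_selection_removes_bb(self):
        out = ad.apply_selection(np.array([0.9]), 1.0, np.array([True]))
        assert out[2, 0] == 0.0 and out[0, 0] == 0.9

    def test_one_percent_arithmetic(self):
        out = ad.apply_selection(np.array([0.99]), 0.01, np.array([True]))
        assert out[2, 0] == pytest.approx(0.9801)

    def test_selection_only_in_reproductive_window(self):
        P = np.array([0.9, 0.9, 0.9])
        out = ad.apply_selection(P, 0.5, np.array([False, True, False]))
        np.testing.assert_allclose(out[2], [0.9, 0.45, 0.9])


class TestHeterozygosity:
    def test_maximal_at_half(self):
        assert ad.heterozygosity(np.array([25, 50, 25])) == pytest.approx(0.5)

    def test_zero_when_fixed(self):
        assert ad.heterozygosity(np.array([100, 0, 0])) == 0.0
        assert ad.heterozygosity(np.array([0, 0, 100])) == 0.0

    def test_observed_is_ab_fraction(self):
        assert ad.heterozygosity(np.array([30, 40, 30]), "observed") == pytest.approx(0.4)

    def test_modes_agree_for_many_newborns(self, rng):
        # law of large numbers: at Nnb = 1e4 a multinomial HW draw has
        # observed AB fraction within MC error of 2p(1-p)
        p = 0.37
        nb = rng.multinomial(10_000, (p * p, 2 * p * (1 - p), (1 - p) ** 2))
        exp_h = ad.heterozygosity(nb, "expected")
        obs_h = ad.heterozygosity(nb, "observed")
        assert obs_h == pytest.approx(exp_h, abs=0.02)


class TestApportion:
    def test_sums_and_rounds(self):
        out = _apportion(np.array([0.25, 0.5, 0.25]), 13)
        assert out.sum() == 13
        np.testing.assert_array_equal(np.sort(out), [3, 3, 7])


class TestRunSimulation:
    def test_seeded_runs_are_bit_reproducible(self, type2):
        fs = ad.gaussian_schedule(type2)
        cfg = ad.SimulationConfig(N_total=200, years=50, replicates=8, seed=99)
        a = ad.run_simulation(type2, fs, cfg)
        b = ad.run_simulation(type2, fs, cfg)
        np.testing.assert_array_equal(a.het, b.het)
        np.testing.assert_array_equal(a.final_p, b.final_p)

    def test_fixation_is_absorbing(self):
        lt, fs = one_class_population()
        cfg = ad.SimulationConfig(N_total=12, years=400, replicates=30, seed=7)
        res = ad.run_simulation(lt, fs, cfg)
        for r in range(30):
            if np.isfinite(res.fixation_times[r]):
                t = int(res.fixation_times[r])
                assert (res.het[r, t - 1 :] == 0).all()
        # a 12-individual WF population is essentially always fixed by t=400
        assert np.isfinite(res.fixation_times).all()
        assert set(np.round(res.final_p, 12)) <= {0.0, 1.0}

    def test_mean_trajectory_declines_under_neutrality(self, type2):
        fs = ad.gaussian_schedule(type2)
        cfg = ad.SimulationConfig(N_total=300, years=150, replicates=60, seed=3)
        res = ad.run_simulation(type2, fs, cfg)
        t = np.arange(res.mean_het.size)
        slope = np.polyfit(t, res.mean_het, 1)[0]
        assert slope < 0

    def test_faithful_mode_keeps_class_totals_stationary(self, type2):
        fs = ad.gaussian_schedule(type2)
        cfg = ad.SimulationConfig(
            N_total=500, years=40, replicates=2, seed=11, cull_mode="faithful"
        )
        res = ad.run_simulation(type2, fs, cfg)
        assert res.het.shape == (2, 40)
        # the faithful cull pins every class total, so the census never moves
        # (checked through the primitive: see TestCull); here the end-to-end
        # run must at least preserve the newborn count contract
        assert res.Nnb == int(round(res.meta["stable_newborn"]))

    def test_selection_accelerates_heterozygosity_loss(self, modern):
        fs = ad.gaussian_schedule(modern)
        base = dict(N_total=400, years=200, replicates=40, shift=-20.0, seed=21)
        neutral = ad.run_simulation(modern, fs, ad.SimulationConfig(**base))
        selected = ad.run_simulation(modern, fs, ad.SimulationConfig(s=0.1, **base))
        assert selected.final.mean() < neutral.final.mean()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ad.SimulationConfig(p0=1.5)
        with pytest.raises(ValueError):
            ad.SimulationConfig(years=0)


class TestSummaries:
    def test_constant_series_has_zero_notch_and_unit_retention(self):
        res = ad.TrajectoryResult(
            het=np.full((10, 30), 0.4),
            final_p=np.full(10, 0.5),
            fixation_times=np.full(10, np.nan),
            config=ad.SimulationConfig(replicates=10, years=30),
            Nnb=10,
            T=5.0,
        )
        table = ad.summarize({"const": res})
        row = table.iloc[0]
        assert row["notch"] == 0.0
        assert row["retention"] == pytest.approx(1.0)

    def test_geometric_decay_recovers_known_ne(self):
        ne_true = 250.0
        t = np.arange(400)
        series = 0.5 * (1 - 1 / (2 * ne_true)) ** t
        rho, ne = ad.fit_retention(series)
        assert ne == pytest.approx(ne_true, rel=0.05)

    def test_retention_requires_positive_points(self):
        with pytest.raises(ValueError):
            ad.fit_retention(np.zeros(10))
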