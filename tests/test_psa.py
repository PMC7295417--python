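import copy

import numpy as np
import pandas as pd
import pytest

from suisim.microsim import simulate_cohort
from suisim.psa import (
    PsaSample,
    ceac,
    compute_voi,
    evpi_per_person,
    evppi,
    population_evpi,
    read_psa_sample,
    run_psa,
    sample_parameter_set,
    write_psa_sample,
)


def make_sample(qalys, params=None, strategies=None):
    """PsaSample with WTP-1 net benefit equal to ``qalys`` (costs all 0)."""
    qalys = np.asarray(qalys, dtype=float)
    n, s = qalys.shape
    strategies = strategies or [f"s{j}" for j in range(s)]
    if params is None:
        params = pd.DataFrame({"u::dummy": np.zeros(n)})
    return PsaSample(
        strategies=strategies,
        costs=np.zeros_like(qalys),
        qalys=qalys,
        params=params,
        seed=0,
        horizon="1y",
    )


def degenerate_psa_params(defaults):
    """All sampling distributions collapsed to point masses."""
    p = copy.deepcopy(defaults)
    for e in p.effects:
        e.crl_low = e.crl_high = e.or_median
    for b in p.baseline_cure:
        b.crl_low = b.crl_high = b.cure_prop
    for c in p.complications:
        c.uncertainty = {}
        c.utility_decrement_se = 0.0
    p.utilities.se = {}
    p.costs.cost_cv = 0.0
    return p


class TestSampling:
    def test_symmetric_beta_mean(self, params, rng):
        """Complication incidences with alpha == beta draw symmetrically
        around 1/2 (sampled through the full parameter-set path)."""
        comp = params.complications[0]
        comp.uncertainty = {"retro-MUS": [5.0, 5.0]}
        draws = np.array(
            [
                sample_parameter_set(params, rng)[1]["comp::infection::retro-MUS"]
                for _ in range(3000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_degenerate_spec_passes_through(self, defaults, rng):
        p = degenerate_psa_params(defaults)
        realized, rec = sample_parameter_set(p, rng)
        assert realized.effect_for("transob-MUS").or_median == 0.738
        assert realized.cure_at(12).cure_prop == p.cure_at(12).cure_prop
        assert realized.costs.procedure_cost == p.costs.procedure_cost
        assert realized.utilities.u_cured == p.utilities.u_cured

    def test_moment_recovery(self, defaults, rng):
        """Sampled-parameter means recover the specification within 3 SE;
        the cure-curve ordering s60 < s12 holds in every draw."""
        recs = [sample_parameter_set(defaults, rng)[1] for _ in range(2000)]
        df = pd.DataFrame.from_records(recs)
        n = len(df)

        def within_3se(col, target):
            se = df[col].std(ddof=1) / np.sqrt(n)
            return abs(df[col].mean() - target) < 3 * se

        mu_sigma_mean = 0.738 * np.exp(0.11506**2 / 2)  # lognormal mean
        assert within_3se("or::transob-MUS", mu_sigma_mean)
        assert within_3se("comp::infection::retro-MUS", 0.03)
        assert within_3se("cost::procedure::retro-MUS", 1800.0)
        assert within_3se("u::cured", 0.85)
        assert (df["cure::60m"] < df["cure::12m"]).all()

    def test_invalid_beta_spec_rejected(self, params, rng):
        params.complications[0].uncertainty = {"retro-MUS": [0.0, 2.0]}
        with pytest.raises(ValueError):
            sample_parameter_set(params, rng)


class TestRunPsa:
    def test_requires_two_draws(self, defaults):
        with pytest.raises(ValueError):
            run_psa(defaults, 1, 5, "1y", seed=1)

    def test_fixed_seed_bit_identical(self, defaults):
        a = run_psa(defaults, 3, 5, "1y", seed=42)
        b = run_psa(defaults, 3, 5, "1y", seed=42)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_degenerate_distributions_reproduce_base_case(self, defaults):
        p = degenerate_psa_params(defaults)
        sample = run_psa(p, 3, 8, "1y", seed=7)
        base = simulate_cohort(p, "retro-MUS", 8, "1y", seed=7)
        j = sample.strategies.index("retro-MUS")
        assert np.allclose(sample.costs[:, j], base.mean_cost)
        assert np.allclose(sample.qalys[:, j], base.mean_qaly)
        assert np.ptp(sample.costs, axis=0).max() == 0.0  # draws identical

    def test_writer_reader_round_trip(self, defaults, tmp_path):
        sample = run_psa(defaults, 3, 4, "1y", seed=9)
        write_psa_sample(sample, tmp_path)
        back = read_psa_sample(tmp_path)
        assert back.strategies == sample.strategies
        assert np.allclose(back.costs, sample.costs)
        assert np.allclose(back.qalys, sample.qalys)
        assert set(back.groups) == set(sample.groups)


class TestCeac:
    def test_single_strategy_probability_one(self):
        sample = make_sample(np.random.default_rng(0).normal(size=(20, 1)))
        curves = ceac(sample, [10_000.0, 20_000.0])
        assert (curves["s0"] == 1.0).all()

    def test_dominant_strategy_everywhere(self):
        qalys = np.column_stack([np.full(15, 2.0), np.full(15, 1.0)])
        curves = ceac(make_sample(qalys), [1.0, 5.0, 10.0])
        assert (curves["s0"] == 1.0).all() and (curves["s1"] == 0.0).all()

    def test_hand_enumerated_fractions(self):
        """3 draws x 2 strategies at WTP 20,000: NMB decided by hand."""
        costs = np.array([[100.0, 200.0], [300.0, 100.0], [50.0, 50.0]])
        qalys = np.array([[0.010, 0.012], [0.020, 0.015], [0.001, 0.001]])
        sample = PsaSample(
            strategies=["A", "B"],
            costs=costs,
            qalys=qalys,
            params=pd.DataFrame({"u::x": np.zeros(3)}),
            seed=0,
            horizon="1y",
        )
        # NMB at 20,000: draw0 A=100, B=40 -> A; draw1 A=100, B=200 -> B;
        # draw2 exact tie -> split equally
        curves = ceac(sample, [20_000.0])
        assert curves.loc[20_000.0, "A"] == pytest.approx(1.5 / 3)
        assert curves.loc[20_000.0, "B"] == pytest.approx(1.5 / 3)

    def test_columns_sum_to_one(self, rng):
        sample = make_sample(rng.normal(size=(50, 4)))
        curves = ceac(sample, [1.0, 2.0, 5.0])
        assert np.allclose(curves.sum(axis=1), 1.0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            ceac(make_sample(rng.normal(size=(5, 2))), [])


class TestEvpi:
    def test_two_by_two_brute_force(self):
        sample = make_sample([[10.0, 5.0], [4.0, 8.0]])
        assert evpi_per_person(sample, wtp=1.0) == pytest.approx(2.0)

    def test_identical_strategies_zero(self, rng):
        col = rng.normal(size=30)
        sample = make_sample(np.column_stack([col, col]))
        assert evpi_per_person(sample, wtp=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_winner_zero(self, rng):
        base = rng.normal(size=30)
        sample = make_sample(np.column_stack([base + 1.0, base]))
        assert evpi_per_person(sample, wtp=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_constant_nmb_shift(self, rng):
        qalys = rng.normal(size=(40, 3))
        a = evpi_per_person(make_sample(qalys), 1.0)
        b = evpi_per_person(make_sample(qalys + 123.4), 1.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestPopulationEvpi:
    @pytest.mark.parametrize(
        "years, expected",
        [(1, 177_855_000.0), (5, 889_275_000.0), (10, 1_778_550_000.0),
         (15, 2_667_825_000.0), (20, 3_557_100_000.0)],
    )
    def test_published_scaling(self, years, expected):
        assert population_evpi(11_857.0, 15_000, years) == pytest.approx(expected)

    def test_zero_years(self):
        assert population_evpi(11_857.0, 15_000, 0, 0.1) == 0.0

    def test_discounted_variant(self):
        got = population_evpi(100.0, 10, 3, discount_rate=0.035)
        expected = 1000.0 * (1 + 1 / 1.035 + 1 / 1.035**2)
        assert got == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            population_evpi(-1.0, 10, 1)


class TestEvppi:
    @staticmethod
    def _linear_toy(n, rng):
        """Two strategies whose WTP-1 NMB is linear in one parameter theta ~
        U(0,1): A(theta) = theta, B = 1/2, crossing at theta = 1/2."""
        theta = rng.uniform(0.0, 1.0, n)
        qalys = np.column_stack([theta, np.full(n, 0.5)])
        params = pd.DataFrame({"u::theta": theta, "cost::noise": rng.normal(size=n)})
        return make_sample(qalys, params, strategies=["A", "B"])

    def test_informative_parameter_matches_closed_form(self, rng):
        """E[max(theta, 1/2)] - 1/2 = 1/8 exactly for theta ~ U(0,1)."""
        sample = self._linear_toy(10_000, rng)
        est = evppi(sample, "utilities", wtp=1.0)
        assert est == pytest.approx(0.125, rel=0.05)

    def test_full_group_approaches_evpi(self, rng):
        sample = self._linear_toy(10_000, rng)
        full = evppi(sample, "all", wtp=1.0)
        total = evpi_per_person(sample, 1.0)
        assert full == pytest.approx(total, rel=0.05)

    def test_pure_noise_parameter_near_zero(self, rng):
        sample = self._linear_toy(10_000, rng)
        assert evppi(sample, "costs", wtp=1.0) < 0.01

    def test_unrecorded_group_rejected(self, rng):
        with pytest.raises(KeyError):
            evppi(self._linear_toy(100, rng), "life_tables", wtp=1.0)

    def test_bounds_on_model_psa(self, defaults):
        sample = run_psa(defaults, 12, 8, "1y", seed=3)
        total = evpi_per_person(sample, 20_000.0)
        nmb = sample.nmb(20_000.0)
        upper = nmb.max(axis=1).mean() - nmb.mean(axis=0).min()
        assert 0.0 <= total <= upper
        for group in sample.groups:
            partial = evppi(sample, group, 20_000.0)
            assert 0.0 <= partial <= total + 1e-9


class TestVoiSummary:
    def test_compute_voi_layout(self, rng):
        sample = self._toy(rng)
        voi = compute_voi(sample, wtp=20_000.0, annual_affected=15_000)
        assert set(voi.population_evpi) == {1, 5, 10, 15, 20}
        assert voi.population_evpi[1] == pytest.approx(
            voi.evpi_per_person * 15_000
        )
        assert voi.evpi_per_person_qaly == pytest.approx(
            voi.evpi_per_person / 20_000.0
        )

    @staticmethod
    def _toy(rng):
        qalys = rng.normal(1.0, 0.1, size=(40, 2))
        params = pd.DataFrame({"u::a": rng.normal(size=40)})
        return make_sample(qalys, params)
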