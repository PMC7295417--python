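import numpy as np
import pytest

from suisim.microsim import (
    CONTAINMENT,
    PatientState,
    SimContext,
    _patient_rng,
    parse_horizon,
    simulate_cohort,
    simulate_patient,
    step_cycle,
)
from suisim.synthetic import SyntheticSpec, random_parameter_set

from conftest import make_degenerate


class TestHorizon:
    def test_labels(self):
        assert parse_horizon("1y", 50) == 12
        assert parse_horizon("10y", 50) == 120
        assert parse_horizon("lifetime", 50) == 600

    def test_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_horizon("forever", 50)


class TestDegenerateClosedForms:
    def test_cured_immortal_one_year_undiscounted(self, params, rng):
        """Certain cure, no complications, no deaths, no discounting: one
        year accrues exactly the cured utility."""
        p = make_degenerate(params, u_cured=0.8)
        cost, qaly = simulate_patient(p, "retro-MUS", "1y", rng)
        assert qaly == pytest.approx(0.8, rel=1e-9)
        assert cost == 0.0

    def test_discounted_geometric_series(self, params, rng):
        """Immortal cured patient at rate r: QALYs equal the half-cycle
        discounted geometric sum u/12 * sum((1+r)^-(t+0.5)/12)."""
        r = 0.035
        u = 0.8
        p = make_degenerate(params, u_cured=u, discount=r)
        cost, qaly = simulate_patient(p, "retro-MUS", "10y", rng)
        expected = sum(
            u / 12.0 * (1 + r) ** (-(t + 0.5) / 12.0) for t in range(120)
        )
        assert qaly == pytest.approx(expected, rel=1e-9)

    def test_certain_death_first_cycle(self, params, rng):
        """Death is absorbing and accrues nothing (death occurs at the start
        of the cycle, before any accrual)."""
        p = make_degenerate(params, annual_q=1.0)
        cost, qaly = simulate_patient(p, "retro-MUS", "10y", rng)
        assert (cost, qaly) == (0.0, 0.0)

    def test_stepping_dead_patient_raises(self, params, rng):
        p = make_degenerate(params)
        ctx = SimContext(p)
        s = PatientState(age=50.0, alive=False)
        with pytest.raises(ValueError):
            step_cycle(s, ctx, rng)


class TestDeterminismAndMonotonicity:
    def test_fixed_seed_bit_identical(self, defaults):
        a = simulate_patient(defaults, "trad-sling", "10y", _patient_rng(7, 3))
        b = simulate_patient(defaults, "trad-sling", "10y", _patient_rng(7, 3))
        assert a == b

    def test_longer_horizon_accrues_at_least_as_much(self, defaults):
        for i in range(20):
            c1, q1 = simulate_patient(defaults, "retro-MUS", "1y", _patient_rng(3, i))
            c10, q10 = simulate_patient(defaults, "retro-MUS", "10y", _patient_rng(3, i))
            assert c1 <= c10 + 1e-12 and q1 <= q10 + 1e-12

    def test_cohort_n1_equals_patient_substream(self, defaults):
        res = simulate_cohort(defaults, "open-colpo", 1, "1y", seed=11)
        cost, qaly = simulate_patient(
            defaults, "open-colpo", "1y", _patient_rng(11, 0)
        )
        assert (res.mean_cost, res.mean_qaly) == (cost, qaly)

    def test_cohort_independent_of_execution_order(self, defaults):
        full = simulate_cohort(defaults, "retro-MUS", 50, "1y", seed=5)
        # patient i's outcome must not depend on how many patients ran before
        cost, qaly = simulate_patient(defaults, "retro-MUS", "1y", _patient_rng(5, 49))
        costs = [
            simulate_patient(defaults, "retro-MUS", "1y", _patient_rng(5, i))[0]
            for i in range(50)
        ]
        assert np.mean(costs) == pytest.approx(full.mean_cost, rel=1e-12)
        assert costs[49] == cost

    def test_standard_error_scales_as_root_n(self, defaults):
        small = simulate_cohort(defaults, "retro-MUS", 400, "1y", seed=2)
        big = simulate_cohort(defaults, "retro-MUS", 1600, "1y", seed=2)
        ratio = small.se_cost / big.se_cost
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestAnalyticCohortOracle:
    def test_two_state_reduction_matches_geometric_series(self, params):
        """Cured/dead model with constant monthly survival s, utility u and
        monthly discount d: mean QALYs -> (u/12) sum s^(t+1) d^(t+0.5).
        Checked within 3 Monte-Carlo standard errors (small-n version of the
        acceptance-scale check)."""
        s_month = 0.99
        u, r = 0.8, 0.035
        q_year = 1.0 - s_month**12
        p = make_degenerate(params, u_cured=u, annual_q=q_year, discount=r)
        res = simulate_cohort(p, "retro-MUS", 4000, "10y", seed=99)
        d = (1 + r) ** (-1.0 / 12.0)
        expected = sum(
            u / 12.0 * s_month ** (t + 1) * d ** (t + 0.5) for t in range(120)
        )
        assert abs(res.mean_qaly - expected) < 3 * res.se_qaly


class TestPathwayRules:
    def test_surgery_cap_and_containment(self, defaults):
        """No trajectory ever has a fourth surgery, and after the third
        failure the patient is in containment for every remaining cycle."""
        ctx = SimContext(defaults)
        violations = self._scan(ctx, n=300, seed=21)
        assert violations == []

    def test_rules_hold_on_randomised_parameters(self):
        p = random_parameter_set(SyntheticSpec(seed=4))
        violations = self._scan(SimContext(p), n=200, seed=8)
        assert violations == []

    @staticmethod
    def _scan(ctx, n, seed, strategy="single-incision"):
        violations = []
        for i in range(n):
            audit = []
            simulate_patient(ctx, strategy, "lifetime", _patient_rng(seed, i), audit)
            third_failure_at = None
            in_containment = False
            for k, row in enumerate(audit):
                if not row["alive"]:
                    # death is absorbing: it ends the trajectory, with no accrual
                    if k != len(audit) - 1 or row["cycle_cost"] or row["cycle_qaly"]:
                        violations.append(f"patient {i}: accrual at/after death")
                    break
                if row["surgeries_done"] > 3:
                    violations.append(f"patient {i}: more than 3 surgeries")
                if in_containment and row["continence"] != CONTAINMENT:
                    violations.append(f"patient {i}: left containment")
                in_containment = in_containment or row["continence"] == CONTAINMENT
                if third_failure_at is None:
                    if row["n_failures"] >= 3:
                        third_failure_at = k
                elif k > third_failure_at and row["continence"] != CONTAINMENT:
                    violations.append(f"patient {i}: no containment after 3rd failure")
        return violations


class TestAccountingIdentity:
    def test_costs_decompose_with_complications_off(self, params):
        """With complication incidences zeroed and no discounting, every
        patient's total cost is exactly (surgeries x tariffs) plus
        containment-months times the containment cost plus UUI line costs
        (here zero, since UUI can only start as a complication)."""
        p = make_degenerate(params, annual_q=0.01, cure12=0.60, cure60=0.20,
                            discount=0.0, zero_costs=False)
        ctx = SimContext(p)
        per_surgery = {
            s: p.costs.procedure_cost[s] + p.costs.perioperative_cost
            for s in p.costs.procedure_cost
        }
        for i in range(40):
            audit = []
            cost, _ = simulate_patient(ctx, "retro-MUS", "lifetime", _patient_rng(13, i), audit)
            expected = 0.0
            for row in audit:
                if row["event"].startswith("surgery:"):
                    expected += per_surgery[row["event"].split(":", 1)[1]]
                if row["continence"] == CONTAINMENT and row["alive"]:
                    expected += p.costs.containment_cost_per_cycle
            assert cost == pytest.approx(expected, rel=1e-9)
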