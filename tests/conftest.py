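import copy

import numpy as np
import pytest

from suisim.synthetic import default_parameter_set


@pytest.fixture(scope="session")
def defaults():
    """Shipped default parameter set (session-wide, treat as read-only)."""
    return default_parameter_set()


@pytest.fixture()
def params(defaults):
    """A mutable copy of the defaults for tests that modify parameters."""
    return copy.deepcopy(defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_degenerate(params, *, u_cured=0.8, annual_q=0.0, discount=0.0,
                    cure12=1.0 - 1e-9, cure60=1.0 - 2e-9, zero_costs=True):
    """Strip the model to an analytically tractable core: everyone is cured
    at surgery, recurrence is negligible, complications and the UUI pathway
    are off, and mortality/discounting are constants chosen by the test."""
    p = params
    for c in p.complications:
        c.incidence_by_strategy = {}
        c.uncertainty = {}
    c12, c60 = p.cure_at(12), p.cure_at(60)
    c12.cure_prop, c12.crl_low, c12.crl_high = cure12, cure12, cure12
    c60.cure_prop, c60.crl_low, c60.crl_high = cure60, cure60, cure60
    p.utilities.u_cured = u_cured
    p.utilities.u_pre_treatment_sui = min(p.utilities.u_pre_treatment_sui, u_cured)
    p.economics.discount_rate_annual = discount
    p.life_table.qx = [annual_q] * len(p.life_table.ages)
    if zero_costs:
        p.costs.procedure_cost = {k: 0.0 for k in p.costs.procedure_cost}
        p.costs.perioperative_cost = 0.0
        p.costs.containment_cost_per_cycle = 0.0
        for line in p.uui_pathway:
            line.cost = 0.0
    return p
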