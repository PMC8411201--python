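"""Sustainability scoring algebra: dot products, weighting, ε-lumping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sustainflux as sf
from sustainflux.core import FluxState
from sustainflux.scoring import PiecewiseRowError, composite_coefficients
from sustainflux.sustainability import ScoringFunction, UnknownCategoryError


def _state(**fluxes):
    return FluxState(status="optimal", objective_value=0.0, fluxes=fluxes)


def test_economic_score_is_hand_dot_product(econ_table, econ_weights):
    state = _state(EX_A=-10.0, EX_P=10.0, EX_W=0.0)
    breakdown = sf.score_flux_state(state, econ_table, econ_weights)
    # E = (-10)(0.2) + (10)(1.0) + 0 = 8.0
    assert breakdown.pillar_totals["econ"] == pytest.approx(8.0, abs=1e-12)
    assert breakdown.total == pytest.approx(8.0, abs=1e-12)


def test_waste_secretion_reduces_score(econ_table, econ_weights):
    state = _state(EX_A=-10.0, EX_P=10.0, EX_W=10.0)
    breakdown = sf.score_flux_state(state, econ_table, econ_weights)
    assert breakdown.total == pytest.approx(7.0, abs=1e-12)


def test_zero_flux_state_scores_zero(econ_table, econ_weights):
    state = _state(EX_A=0.0, EX_P=0.0, EX_W=0.0)
    breakdown = sf.score_flux_state(state, econ_table, econ_weights)
    assert breakdown.total == 0.0
    assert breakdown.contributions == {}


def test_non_optimal_state_rejected(econ_table, econ_weights):
    with pytest.raises(ValueError, match="non-optimal"):
        sf.score_flux_state(FluxState(status="infeasible"), econ_table, econ_weights)


def _three_pillar_table():
    table = sf.SustainabilityTable()
    table.add_row(sf.SustainabilityRow(key="EX_A", econ=0.2,
                                       env={"global_warming": -0.3},
                                       soc={"jobs_created": 0.1}))
    table.add_row(sf.SustainabilityRow(key="EX_P", econ=1.0,
                                       env={"aquatic_eutrophication": -0.05},
                                       soc={"human_toxicity": -0.2}))
    table.add_row(sf.SustainabilityRow(key="EX_W", econ=-0.1,
                                       env={"global_warming": -0.6}))
    return table


def test_total_reconstructs_from_breakdown_exactly():
    table = _three_pillar_table()
    weights = sf.WeightScheme(w_econ=3.0, w_env=2.0, w_soc=1.0,
                              subweights={"global_warming": 2.0},
                              norm_refs={"human_toxicity": 4.0})
    state = _state(EX_A=-10.0, EX_P=9.0, EX_W=1.0)
    breakdown = sf.score_flux_state(state, table, weights)
    pillar_w = weights.pillar_weights()
    rebuilt = {"econ": 0.0, "env": 0.0, "soc": 0.0}
    for (key, cat), value in breakdown.contributions.items():
        rebuilt[table.registry.pillar_of(cat)] += value
    total = sum(pillar_w[p] * rebuilt[p] for p in rebuilt)
    assert abs(total - breakdown.total) <= 1e-12
    for p in rebuilt:
        assert abs(rebuilt[p] - breakdown.pillar_totals[p]) <= 1e-12


def test_linearize_objective_toy_coefficients(toy_a, econ_table, econ_weights):
    coeffs = sf.linearize_objective(econ_table, econ_weights, toy_a)
    assert coeffs == pytest.approx(
        {"EX_A": 0.2, "EX_P": 1.0, "EX_W": -0.1, "R1": 0.0, "R2": 0.0, "R3": 0.0}
    )


def test_linearize_null_table_gives_zero_vector(toy_a, econ_weights):
    table = sf.SustainabilityTable()
    for ex in toy_a.exchange_ids:
        table.add_row(sf.SustainabilityRow(key=ex, econ=0.0))
    coeffs = sf.linearize_objective(table, econ_weights, toy_a)
    assert all(v == 0.0 for v in coeffs.values())


def test_doubling_norm_references_halves_coefficients(toy_a):
    table = _three_pillar_table()
    base = sf.WeightScheme()
    doubled = sf.WeightScheme(norm_refs={cat: 2.0 for cat in table.categories_used()})
    c1 = sf.linearize_objective(table, base, toy_a)
    c2 = sf.linearize_objective(table, doubled, toy_a)
    for rid in c1:
        assert c2[rid] == pytest.approx(c1[rid] / 2.0, abs=1e-15)


def test_score_equals_linearized_dot_product(toy_a2, econ_table, econ_weights):
    weights = sf.WeightScheme(w_econ=1.0, w_env=0.0, w_soc=0.0, epsilon=0.0)
    state = sf.fba(toy_a2, "EX_P")
    coeffs = sf.linearize_objective(econ_table, weights, toy_a2)
    dot = sum(coeffs[rid] * state.fluxes[rid] for rid in coeffs)
    breakdown = sf.score_flux_state(state, econ_table, weights)
    assert breakdown.total == pytest.approx(dot, abs=1e-9)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(alpha=st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
def test_score_is_positively_homogeneous(alpha):
    table = _three_pillar_table()
    weights = sf.WeightScheme(epsilon=0.0)
    base = {"EX_A": -10.0, "EX_P": 9.0, "EX_W": 1.0}
    s1 = sf.score_flux_state(_state(**base), table, weights).total
    scaled = {k: alpha * v for k, v in base.items()}
    s2 = sf.score_flux_state(_state(**scaled), table, weights).total
    assert s2 == pytest.approx(alpha * s1, rel=1e-9, abs=1e-9)


def test_epsilon_lumping_reports_and_bounds_neglected_mass():
    table = _three_pillar_table()
    weights = sf.WeightScheme(epsilon=1e-2)
    state = _state(EX_A=-1e-3, EX_P=5e-3, EX_W=1e-4)
    breakdown = sf.score_flux_state(state, table, weights)
    assert breakdown.contributions == {}
    assert {item.key for item in breakdown.lumped} == {"EX_A", "EX_P", "EX_W"}
    bound = weights.epsilon * sum(
        abs(c) for c in composite_coefficients(table, weights).values()
    )
    assert abs(breakdown.lumped_total) <= bound + 1e-15


def test_lumped_fluxes_do_not_enter_the_total(econ_table):
    weights = sf.WeightScheme(w_econ=1.0, w_env=0.0, w_soc=0.0, epsilon=1e-3)
    state = _state(EX_A=-10.0, EX_P=10.0, EX_W=1e-6)
    breakdown = sf.score_flux_state(state, econ_table, weights)
    assert breakdown.total == pytest.approx(8.0, abs=1e-12)
    assert [item.key for item in breakdown.lumped] == ["EX_W"]


def test_unknown_table_category_rejected_by_name():
    weights = sf.WeightScheme()
    table = sf.SustainabilityTable()
    table.registry.register("novel_metric", "env", harm=False)
    table.add_row(sf.SustainabilityRow(key="EX_A", env={"novel_metric": 1.0}))
    # category registered in the table's registry but not the default one used
    # by a fresh weight scheme lookup
    with pytest.raises(UnknownCategoryError, match="novel_metric"):
        weights.category_scale("novel_metric", sf.DEFAULT_REGISTRY)
    # through the table's own registry it resolves fine
    assert weights.category_scale("novel_metric", table.registry) == 1.0


def test_piecewise_rows_rejected_from_lp_objective(toy_a, econ_weights):
    table = sf.canonical_economic_table()
    fn = ScoringFunction(kind="piecewise", breakpoints=((0.0, 0.0), (10.0, 5.0)))
    table.rows["EX_W"].scoring_fn = fn
    with pytest.raises(PiecewiseRowError, match="EX_W"):
        sf.linearize_objective(table, econ_weights, toy_a)


def test_piecewise_function_interpolates_and_extrapolates():
    fn = ScoringFunction(kind="piecewise",
                         breakpoints=((0.0, 0.0), (5.0, 2.0), (10.0, 2.5)))
    xs = np.linspace(0.0, 10.0, 21)
    expected = np.interp(xs, [0.0, 5.0, 10.0], [0.0, 2.0, 2.5])
    for x, y in zip(xs, expected):
        assert fn(float(x)) == pytest.approx(float(y), abs=1e-12)
    # linear extrapolation beyond the end segments
    assert fn(-5.0) == pytest.approx(-2.0, abs=1e-12)
    assert fn(12.0) == pytest.approx(2.7, abs=1e-12)


def test_piecewise_breakpoints_must_increase():
    with pytest.raises(ValueError, match="strictly increasing"):
        ScoringFunction(kind="piecewise", breakpoints=((0.0, 0.0), (0.0, 1.0)))


def test_piecewise_scoring_enters_evaluation_mode(econ_weights):
    table = sf.canonical_economic_table()
    # diminishing marginal value of the product beyond 5 units
    table.rows["EX_P"].scoring_fn = ScoringFunction(
        kind="piecewise", breakpoints=((0.0, 0.0), (5.0, 5.0), (10.0, 7.5))
    )
    state = _state(EX_A=-10.0, EX_P=10.0, EX_W=0.0)
    breakdown = sf.score_flux_state(state, table, econ_weights)
    # econ contribution of EX_P becomes 1.0 * g(10) = 7.5 instead of 10
    assert breakdown.total == pytest.approx(-2.0 + 7.5, abs=1e-12)


def test_pillar_normalize_divides_by_reference(toy_a):
    table = sf.SustainabilityTable()
    table.add_row(sf.SustainabilityRow(key="EX_A", env={"global_warming": 0.5}),
                  warn_signs=False)
    weights = sf.WeightScheme(norm_refs={"global_warming": 2.0})
    normalized = sf.pillar_normalize(table, weights)
    assert normalized["EX_A"]["global_warming"] == pytest.approx(0.25)
    identity = sf.pillar_normalize(table, sf.WeightScheme())
    assert identity["EX_A"]["global_warming"] == pytest.approx(0.5)


def test_pillar_normalize_empty_table_empty_output():
    assert sf.pillar_normalize(sf.SustainabilityTable(), sf.WeightScheme()) == {}
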