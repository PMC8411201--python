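"""Score optimization, score ranges, trade-off curves, variability reduction."""

import numpy as np
import pytest

import sustainflux as sf
from sustainflux.core import DesignSpec
from sustainflux.lp import InfeasibleModelError


def test_optimizer_avoids_waste_route(toy_a2, econ_table, econ_weights):
    score, state = sf.optimize_sustainability(toy_a2, econ_table, econ_weights,
                                              growth_fraction=0.0)
    assert score == pytest.approx(8.0, abs=1e-7)
    assert state.fluxes["EX_W"] == pytest.approx(0.0, abs=1e-7)


def test_optimum_with_full_growth_constraint(toy_a2, econ_table, econ_weights):
    # biomass proxy is EX_P: at full growth the product flux is pinned at 10
    # and score optimality forces the waste route shut
    score, state = sf.optimize_sustainability(toy_a2, econ_table, econ_weights,
                                              growth_fraction=1.0)
    assert score == pytest.approx(8.0, abs=1e-7)
    assert state.fluxes["EX_W"] == pytest.approx(0.0, abs=1e-7)


def test_all_zero_table_scores_zero(toy_a2, econ_weights):
    table = sf.SustainabilityTable()
    for ex in toy_a2.exchange_ids:
        table.add_row(sf.SustainabilityRow(key=ex, econ=0.0))
    score, _ = sf.optimize_sustainability(toy_a2, table, econ_weights, 0.0)
    assert score == 0.0
    assert sf.sustainability_range(toy_a2, table, econ_weights, 1.0) == (0.0, 0.0)


def test_score_range_brackets_degenerate_optima(toy_a2, econ_table, econ_weights):
    s_min, s_max = sf.sustainability_range(toy_a2, econ_table, econ_weights,
                                           growth_fraction=1.0)
    # product fixed at 10, waste route free in [0, 10] at -0.1 per unit
    assert s_min == pytest.approx(7.0, abs=1e-7)
    assert s_max == pytest.approx(8.0, abs=1e-7)


def test_deleting_the_branch_collapses_the_range(toy_a2, econ_table, econ_weights):
    edited = sf.apply_design(toy_a2, DesignSpec.deletion("R3"))
    s_min, s_max = sf.sustainability_range(edited, econ_table, econ_weights, 1.0)
    assert s_min == pytest.approx(8.0, abs=1e-7)
    assert s_max == pytest.approx(8.0, abs=1e-7)


def _oracle_range(model, table, weights, growth_fraction):
    """Independent bound on the score via the brute-force vertex oracle."""
    coeffs = sf.linearize_objective(table, weights, model)
    constrained = model.copy()
    if growth_fraction > 0 and model.biomass_id is not None:
        mu = sf.brute_force_oracle(model, {model.biomass_id: 1.0})
        bio = constrained.reactions[model.biomass_id]
        bio.lower_bound = max(bio.lower_bound, growth_fraction * mu.objective_value)
    lo = sf.brute_force_oracle(constrained, coeffs, direction="min")
    hi = sf.brute_force_oracle(constrained, coeffs, direction="max")
    return lo.objective_value, hi.objective_value


@pytest.mark.parametrize("fraction", [0.0, 0.5, 1.0])
def test_range_matches_vertex_oracle_on_toys(toys, econ_table, econ_weights, fraction):
    for name in ("TOY-A", "TOY-A2", "TOY-B"):
        model = toys[name]
        got = sf.sustainability_range(model, econ_table, econ_weights, fraction)
        want = _oracle_range(model, econ_table, econ_weights, fraction)
        assert got == pytest.approx(want, abs=1e-6)


def test_tradeoff_flat_when_growth_and_score_agree(toy_a2, econ_table, econ_weights):
    points = sf.score_tradeoff_curve(toy_a2, econ_table, econ_weights, [0.0, 0.5, 1.0])
    assert [p.score for p in points] == pytest.approx([8.0, 8.0, 8.0], abs=1e-7)


def test_tradeoff_strictly_decreasing_under_conflict(toy_b, econ_table, econ_weights):
    points = sf.score_tradeoff_curve(toy_b, econ_table, econ_weights, [0.0, 0.5, 1.0])
    scores = [p.score for p in points]
    # biomass consumes the product precursor B: every unit of growth demanded
    # costs a unit of product, score = 8 - 10 f
    assert scores == pytest.approx([8.0, 3.0, -2.0], abs=1e-7)
    assert all(p.feasible for p in points)
    # cross-check each point against the vertex-enumeration oracle
    for p in points:
        want = _oracle_range(toy_b, econ_table, econ_weights, p.growth_fraction)[1]
        assert p.score == pytest.approx(want, abs=1e-6)


def test_tradeoff_single_point_matches_optimizer(toy_a2, econ_table, econ_weights):
    points = sf.score_tradeoff_curve(toy_a2, econ_table, econ_weights, [0.0])
    direct, _ = sf.optimize_sustainability(toy_a2, econ_table, econ_weights, 0.0)
    assert len(points) == 1 and points[0].score == pytest.approx(direct, abs=1e-9)


def test_tradeoff_requires_sorted_fractions(toy_a2, econ_table, econ_weights):
    with pytest.raises(ValueError, match="ascending"):
        sf.score_tradeoff_curve(toy_a2, econ_table, econ_weights, [1.0, 0.0])


@pytest.mark.parametrize("seed", range(20))
def test_optimize_state_score_equals_range_maximum(seed):
    model = sf.make_random_model(n_metabolites=5, n_reactions=7, seed=seed)
    table = sf.make_random_table(model, seed=seed + 1000)
    weights = sf.WeightScheme(epsilon=0.0)
    score, state = sf.optimize_sustainability(model, table, weights, growth_fraction=0.5)
    s_min, s_max = sf.sustainability_range(model, table, weights, growth_fraction=0.5)
    assert s_min <= score + 1e-7
    assert score == pytest.approx(s_max, abs=1e-6)
    rescored = sf.score_flux_state(state, table, weights,
                                   biomass_id=model.biomass_id).total
    assert rescored == pytest.approx(score, abs=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_score_never_improves_with_growth_demand(seed):
    model = sf.make_random_model(n_metabolites=4, n_reactions=6, seed=seed)
    table = sf.make_random_table(model, seed=seed + 2000)
    weights = sf.WeightScheme()
    points = sf.score_tradeoff_curve(model, table, weights, [0.0, 0.25, 0.5, 0.75, 1.0])
    feasible = [p.score for p in points if p.feasible]
    assert all(a >= b - 1e-7 for a, b in zip(feasible, feasible[1:]))


@pytest.mark.parametrize("seed", range(10))
def test_range_intervals_nest_as_growth_relaxes(seed):
    model = sf.make_random_model(n_metabolites=4, n_reactions=6, seed=seed)
    table = sf.make_random_table(model, seed=seed + 3000)
    weights = sf.WeightScheme()
    tight = sf.sustainability_range(model, table, weights, growth_fraction=1.0)
    loose = sf.sustainability_range(model, table, weights, growth_fraction=0.25)
    assert loose[0] <= tight[0] + 1e-7
    assert loose[1] >= tight[1] - 1e-7


# --- variability reduction ---------------------------------------------------


def test_reduce_variability_single_deletion_closes_range(toy_a2, econ_table, econ_weights):
    result = sf.reduce_variability(toy_a2, econ_table, econ_weights,
                                   [DesignSpec.deletion("R3")], width_tol=0.01,
                                   growth_fraction=1.0)
    assert result.design.deletions == ("R3",)
    assert result.final_width == pytest.approx(0.0, abs=1e-7)
    assert result.initial_width == pytest.approx(1.0, abs=1e-7)
    assert not result.stalled


def test_reduce_variability_accepts_already_narrow_range(toy_a2, econ_table, econ_weights):
    result = sf.reduce_variability(toy_a2, econ_table, econ_weights,
                                   [DesignSpec.deletion("R3")], width_tol=2.0,
                                   growth_fraction=1.0)
    assert result.design == DesignSpec()
    assert not result.stalled


def test_reduce_variability_stalls_without_candidates(toy_a2, econ_table, econ_weights):
    result = sf.reduce_variability(toy_a2, econ_table, econ_weights, [],
                                   width_tol=0.01, growth_fraction=1.0)
    assert result.stalled
    assert result.design == DesignSpec()


def test_reduce_variability_respects_growth_floor(toy_a2, econ_table, econ_weights):
    # deleting R1 (the sole route into the network) would kill growth
    # entirely; the greedy loop must skip it and pick the branch deletion
    result = sf.reduce_variability(
        toy_a2, econ_table, econ_weights,
        [DesignSpec.deletion("R1"), DesignSpec.deletion("R3")],
        width_tol=0.01, growth_fraction=1.0,
    )
    assert result.design.deletions == ("R3",)
    assert result.final_width == pytest.approx(0.0, abs=1e-7)
    edited = sf.apply_design(toy_a2, result.design)
    assert sf.fba(edited, "EX_P").objective_value == pytest.approx(10.0, abs=1e-7)
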