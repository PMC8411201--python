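"""Optimizing and bounding the sustainability indicator score.

The core computation: instead of (or on top of) maximizing growth, the LP
objective becomes the linearized sustainability score — the composite
economic/environmental/societal coefficient vector dotted with the exchange
fluxes.  Growth enters as a constraint, ``v_biomass ≥ f · μ_max`` with
``μ_max`` freshly computed per call, so the same fraction ``f`` works
across chassis of different absolute growth rates.

Because flux optima are typically degenerate, a single optimal score can be
misleading; :func:`sustainability_range` bounds the score over the whole
constrained flux space (an FVA on the score itself), and
:func:`reduce_variability` greedily applies deletions or media edits until
the score range is acceptably narrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import DesignSpec, FluxState, MetabolicModel
from .lp import InfeasibleModelError, apply_design, fba, solve_linear
from .scoring import linearize_objective
from .sustainability import SustainabilityTable, WeightScheme

__all__ = [
    "optimize_sustainability",
    "sustainability_range",
    "score_tradeoff_curve",
    "reduce_variability",
    "TradeoffPoint",
    "VariabilityReduction",
]


def _growth_bound(
    model: MetabolicModel, growth_fraction: float, solver: str
) -> Dict[str, Tuple[float, float]]:
    """Extra bound implementing v_biomass >= fraction * mu_max (fresh mu_max)."""
    if not 0.0 <= growth_fraction <= 1.0:
        raise ValueError("growth_fraction must lie in [0, 1]")
    if growth_fraction == 0.0 or model.biomass_id is None:
        return {}
    mu = fba(model, model.biomass_id, solver=solver)
    if not mu.optimal:
        raise InfeasibleModelError(mu.status, "growth optimum could not be computed")
    return {model.biomass_id: (growth_fraction * mu.objective_value, np.inf)}


def optimize_sustainability(
    model: MetabolicModel,
    table: SustainabilityTable,
    weights: WeightScheme,
    growth_fraction: float = 0.1,
    solver: str = "highs",
) -> Tuple[float, FluxState]:
    """Maximize the linearized sustainability score over the flux space.

    Subject to steady state, bounds, and a growth floor of
    ``growth_fraction`` times the freshly computed maximal growth rate.
    Returns ``(score, flux_state)`` with the attaining state.

    Raises :class:`InfeasibleModelError` when the growth-constrained model
    is infeasible, and :class:`RuntimeError` when the score is unbounded
    (which indicates missing exchange bounds).
    """
    objective = linearize_objective(table, weights, model)
    extra = _growth_bound(model, growth_fraction, solver)
    state = solve_linear(model, objective, "max", extra_bounds=extra, solver=solver)
    if state.status == "unbounded":
        raise RuntimeError(
            "sustainability score is unbounded; review exchange bounds "
            "(an uncapped secretion with positive composite coefficient?)"
        )
    if not state.optimal:
        raise InfeasibleModelError(state.status)
    return state.objective_value, state


def sustainability_range(
    model: MetabolicModel,
    table: SustainabilityTable,
    weights: WeightScheme,
    growth_fraction: float = 1.0,
    solver: str = "highs",
) -> Tuple[float, float]:
    """Bound the score over the growth-constrained flux space: (S_min, S_max).

    This is flux variability analysis applied to the composite score rather
    than to a single reaction; any growth-optimal flux state scores inside
    the returned interval, and the interval only widens as the growth
    fraction decreases.
    """
    objective = linearize_objective(table, weights, model)
    extra = _growth_bound(model, growth_fraction, solver)
    lo = solve_linear(model, objective, "min", extra_bounds=extra, solver=solver)
    hi = solve_linear(model, objective, "max", extra_bounds=extra, solver=solver)
    for state in (lo, hi):
        if state.status == "unbounded":
            raise RuntimeError("sustainability score is unbounded; review exchange bounds")
        if not state.optimal:
            raise InfeasibleModelError(state.status)
    return lo.objective_value, hi.objective_value


@dataclass(frozen=True)
class TradeoffPoint:
    growth_fraction: float
    score: Optional[float]  # None when that growth demand is infeasible
    feasible: bool


def score_tradeoff_curve(
    model: MetabolicModel,
    table: SustainabilityTable,
    weights: WeightScheme,
    fractions: Sequence[float],
    solver: str = "highs",
) -> List[TradeoffPoint]:
    """Optimal score at each growth fraction (ascending); exposes the
    growth-versus-sustainability tension.

    Feasible scores are non-increasing along the curve since raising the
    growth floor only shrinks the feasible region.  Infeasible points are
    recorded as such and the curve continues.
    """
    fractions = list(fractions)
    if sorted(fractions) != fractions:
        raise ValueError("fractions must be sorted ascending")
    points: List[TradeoffPoint] = []
    for f in fractions:
        try:
            score, _ = optimize_sustainability(model, table, weights, growth_fraction=f,
                                               solver=solver)
            points.append(TradeoffPoint(growth_fraction=f, score=score, feasible=True))
        except InfeasibleModelError:
            points.append(TradeoffPoint(growth_fraction=f, score=None, feasible=False))
    return points


@dataclass
class VariabilityReduction:
    """Outcome of the greedy score-range narrowing loop."""

    design: DesignSpec
    initial_width: float
    final_width: float
    stalled: bool
    history: List[Tuple[str, float]] = field(default_factory=list)  # (move, width after)


def _move_sort_key(move: DesignSpec) -> Tuple[int, str]:
    """Deterministic tie-break: deletions before media edits, then lexicographic."""
    is_media = 0 if move.deletions else 1
    return (is_media, move.design_string())


def reduce_variability(
    model: MetabolicModel,
    table: SustainabilityTable,
    weights: WeightScheme,
    candidates: Sequence[DesignSpec],
    width_tol: float,
    growth_fraction: float = 1.0,
    solver: str = "highs",
) -> VariabilityReduction:
    """Greedily shrink the score range below ``width_tol``.

    Each candidate is a single move (one deletion or one exchange-bound
    tightening).  While the score-range width exceeds the tolerance, the
    move that most reduces the width is applied — provided it keeps the
    design feasible and keeps μ_max at or above ``growth_fraction`` of the
    *original* μ_max.  Strict improvement is required each round, so the
    loop terminates; if no move improves the width the result carries a
    ``stalled`` flag.
    """
    if width_tol < 0:
        raise ValueError("width_tol must be non-negative")

    mu_floor = 0.0
    if model.biomass_id is not None and growth_fraction > 0.0:
        mu0 = fba(model, model.biomass_id, solver=solver)
        if not mu0.optimal:
            raise InfeasibleModelError(mu0.status)
        mu_floor = growth_fraction * mu0.objective_value

    def range_width(m: MetabolicModel) -> Optional[float]:
        try:
            s_min, s_max = sustainability_range(m, table, weights, growth_fraction, solver)
        except InfeasibleModelError:
            return None
        return s_max - s_min

    current = model
    width = range_width(model)
    if width is None:
        raise InfeasibleModelError("infeasible", "the starting model has no feasible flux state")
    initial_width = width
    applied = DesignSpec()
    remaining = sorted(candidates, key=_move_sort_key)
    history: List[Tuple[str, float]] = []
    stalled = False
    improvement_tol = 1e-12

    while width > width_tol:
        best: Optional[Tuple[float, DesignSpec, MetabolicModel]] = None
        for move in remaining:
            try:
                trial = apply_design(current, move)
            except Exception:
                continue
            if mu_floor > 0.0:
                mu = fba(trial, trial.biomass_id, solver=solver)
                if not mu.optimal or mu.objective_value < mu_floor - 1e-9:
                    continue
            w = range_width(trial)
            if w is None or w >= width - improvement_tol:
                continue
            if best is None or w < best[0] - improvement_tol:
                best = (w, move, trial)
        if best is None:
            stalled = True
            break
        width, move, current = best
        applied = applied.merge(move)
        remaining = [m for m in remaining if m is not move]
        history.append((move.design_string(), width))

    return VariabilityReduction(
        design=applied,
        initial_width=initial_width,
        final_width=width,
        stalled=stalled,
        history=history,
    )
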