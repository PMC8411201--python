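"""Linear-programming engine: FBA, FVA, model editing, mass-balance checks.

The solver sits behind a small contract — any LP backend able to return
optimal basic solutions at tight primal feasibility tolerance can be
plugged in via the ``solver`` config key.  The default backend is HiGHS
through :func:`scipy.optimize.linprog`, which is deterministic for a fixed
model and configuration.

Returned optima are polished by projecting the solution onto the
steady-state subspace, so ``max |S v|`` of an optimal flux state is at
machine precision rather than at the solver's feasibility tolerance.
Alternative optima are real: :func:`fba` returns *one* optimal vertex, and
any scientific claim about a flux should be made through :func:`fva` (or
the score ranges built on it), never through which vertex happened to be
returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import DesignSpec, FluxState, MetabolicModel, ModelValidationError

__all__ = [
    "fba",
    "fva",
    "apply_design",
    "check_mass_balance",
    "solve_linear",
    "MassBalanceReport",
    "InfeasibleModelError",
    "SOLVERS",
]

#: LP backends honouring the solver contract, keyed by config name.
SOLVERS = {
    "highs": "highs",        # let HiGHS choose simplex/ipm; crossover gives a vertex
    "highs-ds": "highs-ds",  # dual simplex
    "highs-ipm": "highs-ipm",
}

_LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class InfeasibleModelError(RuntimeError):
    """Raised by operations that require a feasible model."""

    def __init__(self, status: str, message: str = ""):
        self.status = status
        super().__init__(message or f"model is {status}")


def _project_steady_state(v: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Project v onto the affine set {S v = 0} (minimum-norm correction)."""
    residual = S @ v
    if residual.size == 0 or np.max(np.abs(residual)) == 0.0:
        return v
    correction, *_ = np.linalg.lstsq(S, residual, rcond=None)
    return v - correction


def solve_linear(
    model: MetabolicModel,
    objective: Mapping[str, float],
    direction: str = "max",
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    solver: str = "highs",
) -> FluxState:
    """Optimize an arbitrary linear functional of the fluxes.

    ``objective`` maps reaction ids to objective coefficients (missing ids
    contribute 0).  ``extra_bounds`` tightens bounds for the duration of the
    solve without touching the model.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    if solver not in SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; known: {sorted(SOLVERS)}")
    for rid in objective:
        if rid not in model.reactions:
            raise KeyError(f"objective reaction {rid!r} not in model")

    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    if n == 0:
        return FluxState(status="infeasible")
    lb, ub = model.bounds_arrays()
    if extra_bounds:
        index = {rid: j for j, rid in enumerate(rxn_ids)}
        for rid, (new_lb, new_ub) in extra_bounds.items():
            j = index[rid]
            lb[j] = max(lb[j], new_lb)
            ub[j] = min(ub[j], new_ub)
    if np.any(lb > ub + 1e-12):
        return FluxState(status="infeasible")

    c = np.zeros(n)
    for j, rid in enumerate(rxn_ids):
        c[j] = objective.get(rid, 0.0)
    sign = -1.0 if direction == "max" else 1.0

    res = linprog(
        sign * c,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=np.column_stack([lb, ub]),
        method=SOLVERS[solver],
        options=dict(_LP_OPTIONS),
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxState(status=status)

    v = _project_steady_state(np.asarray(res.x, dtype=float), S)
    fluxes = {rid: float(v[j]) for j, rid in enumerate(rxn_ids)}
    objective_value = float(c @ v)
    return FluxState(status="optimal", objective_value=objective_value, fluxes=fluxes)


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    direction: str = "max",
    solver: str = "highs",
) -> FluxState:
    """Flux balance analysis: optimize one reaction flux at steady state.

    Parameters
    ----------
    objective
        Reaction id to optimize; defaults to the model's objective reaction.
    direction
        ``"max"`` (default) or ``"min"``.

    Returns a :class:`FluxState`; its ``status`` is ``"infeasible"`` or
    ``"unbounded"`` (with no flux map) when no optimum exists.
    """
    objective = objective if objective is not None else model.objective_id
    if objective is None:
        raise ValueError("no objective reaction: pass one or set model.objective_id")
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    return solve_linear(model, {objective: 1.0}, direction=direction, solver=solver)


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: float = 1.0,
    objective: Optional[str] = None,
    solver: str = "highs",
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis.

    For each listed reaction (default: all), the minimum and maximum flux
    subject to steady state, bounds, and — unless ``fraction_of_optimum`` is
    0 — the objective flux being at least ``fraction_of_optimum`` times its
    freshly computed optimum.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    objective = objective if objective is not None else model.objective_id
    reactions = list(reactions) if reactions is not None else list(model.reactions)
    for rid in reactions:
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model")

    extra: Dict[str, Tuple[float, float]] = {}
    if fraction_of_optimum > 0.0:
        if objective is None:
            raise ValueError("an objective is required unless fraction_of_optimum is 0")
        opt = fba(model, objective, solver=solver)
        if not opt.optimal:
            raise InfeasibleModelError(opt.status)
        extra[objective] = (fraction_of_optimum * opt.objective_value, np.inf)

    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        lo = solve_linear(model, {rid: 1.0}, "min", extra_bounds=extra, solver=solver)
        hi = solve_linear(model, {rid: 1.0}, "max", extra_bounds=extra, solver=solver)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleModelError(lo.status if not lo.optimal else hi.status)
        out[rid] = (lo.objective_value, hi.objective_value)
    return out


def apply_design(model: MetabolicModel, design: DesignSpec) -> MetabolicModel:
    """Return a new model with the design applied; the input is untouched.

    Deletions force bounds to [0, 0] (ids retained), insertions are
    appended, media edits replace exchange bounds.
    """
    new = model.copy()
    for rid in design.deletions:
        if rid not in new.reactions:
            raise ModelValidationError(f"deletion target {rid!r} not in model")
        if rid == new.biomass_id:
            raise ModelValidationError(f"cannot delete the biomass reaction {rid!r}")
        rxn = new.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    for rxn in design.insertions:
        if rxn.id in new.reactions:
            raise ModelValidationError(f"insertion duplicates reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in new.metabolites:
                raise ModelValidationError(
                    f"insertion {rxn.id!r} references unknown metabolite {mid!r}"
                )
        new.add_reaction(rxn.copy())
    for ex_id, (lb, ub) in design.media:
        if ex_id not in new.reactions:
            raise ModelValidationError(f"media edit target {ex_id!r} not in model")
        if lb > ub:
            raise ModelValidationError(f"media edit for {ex_id!r} has lb {lb} > ub {ub}")
        new.reactions[ex_id].lower_bound = lb
        new.reactions[ex_id].upper_bound = ub
    new.validate()
    return new


@dataclass
class MassBalanceReport:
    """Element-balance audit of the non-exchange reactions.

    ``unbalanced`` maps reaction id to its net element imbalance
    (element → produced-minus-consumed count); ``skipped`` lists reactions
    that could not be checked because a participating metabolite has no
    formula.  Exchange reactions are exempt by definition — they exist to
    move mass across the boundary.
    """

    unbalanced: Dict[str, Dict[str, float]]
    skipped: List[str]
    checked: List[str]

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def check_mass_balance(model: MetabolicModel, tol: float = 1e-9) -> MassBalanceReport:
    """List every non-exchange reaction whose elemental totals do not cancel."""
    formulas = {
        mid: met.element_counts()
        for mid, met in model.metabolites.items()
    }
    unbalanced: Dict[str, Dict[str, float]] = {}
    skipped: List[str] = []
    checked: List[str] = []
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange:
            continue
        if any(formulas[mid] is None for mid in rxn.stoichiometry):
            skipped.append(rid)
            continue
        net: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for element, count in formulas[mid].items():
                net[element] = net.get(element, 0.0) + coeff * count
        net = {e: x for e, x in net.items() if abs(x) > tol}
        checked.append(rid)
        if net:
            unbalanced[rid] = net
    return MassBalanceReport(unbalanced=unbalanced, skipped=skipped, checked=checked)
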