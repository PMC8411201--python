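"""Desk-scale fixtures, random model generators and the brute-force oracle.

The toy networks are hand-sized stand-ins for genome-scale models, built to
have fully hand-derivable optima:

* ``TOY-A``: one carbon source A (uptake capped at 10), a linear route
  A → B → P and a lossy branch B → 0.5 P + W.  The branch is strictly
  product-suboptimal, so FVA pins it to zero at the product optimum.
* ``TOY-A2``: as TOY-A but the branch is B → P + W — equal product yield,
  so the product optimum is degenerate and waste secretion ranges over
  [0, 10] while the economics differ between the routes.
* ``TOY-B``: adds a biomass drain competing with the product for B, giving
  a genuine growth-versus-sustainability trade-off.

Random models are built by *planting* a feasible uptake → chain → secretion
path and then decorating it with random side reactions; feasibility (and a
strictly positive secretion optimum) holds by construction, so no rejection
sampling is needed and every seed is usable.

:func:`brute_force_oracle` solves small LPs by exhaustive enumeration of
basic solutions of ``{S v = 0, lb ≤ v ≤ ub}`` — independent of any LP
backend, it is the reference the solver is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction
from .sustainability import (
    SustainabilityRow,
    SustainabilityTable,
    WeightScheme,
)

__all__ = [
    "make_toy_models",
    "canonical_economic_table",
    "canonical_economic_weights",
    "make_random_model",
    "make_random_table",
    "brute_force_oracle",
    "OracleResult",
]

_UB = 1000.0  # practical "unbounded" cap for secretions and internal reactions


def _toy_base(model_id: str, branch_product_yield: float) -> MetabolicModel:
    model = MetabolicModel(id=model_id)
    for mid, formula in (("A", "C6"), ("B", "C6"), ("P", "C6"), ("W", "C1")):
        model.add_metabolite(Metabolite(id=mid, compartment="c", formula=formula))
    model.add_reaction(Reaction("EX_A", {"A": -1.0}, -10.0, 0.0, is_exchange=True))
    model.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, _UB))
    model.add_reaction(Reaction("R2", {"B": -1.0, "P": 1.0}, 0.0, _UB))
    model.add_reaction(
        Reaction("R3", {"B": -1.0, "P": branch_product_yield, "W": 1.0}, 0.0, _UB)
    )
    model.add_reaction(Reaction("EX_P", {"P": -1.0}, 0.0, _UB, is_exchange=True))
    model.add_reaction(Reaction("EX_W", {"W": -1.0}, 0.0, _UB, is_exchange=True))
    model.objective_id = "EX_P"
    # The product drain doubles as the growth proxy in the toys without an
    # explicit biomass pseudo-reaction.
    model.biomass_id = "EX_P"
    model.validate()
    return model


def make_toy_models() -> Dict[str, MetabolicModel]:
    """The canonical named toy models; constructed exactly, no randomness."""
    toy_a = _toy_base("TOY-A", branch_product_yield=0.5)
    toy_a2 = _toy_base("TOY-A2", branch_product_yield=1.0)

    toy_b = _toy_base("TOY-B", branch_product_yield=1.0)
    toy_b.add_reaction(Reaction("BIOMASS", {"B": -1.0}, 0.0, _UB))
    toy_b.biomass_id = "BIOMASS"
    toy_b.objective_id = "BIOMASS"
    toy_b.validate()
    return {"TOY-A": toy_a, "TOY-A2": toy_a2, "TOY-B": toy_b}


def canonical_economic_table() -> SustainabilityTable:
    """Economic coefficients used throughout the toy examples.

    Substrate A costs 0.2 per unit uptaken (the negative uptake flux turns
    it into a cost), product P sells at 1.0, waste W costs 0.1 per unit to
    manage (entered as a negative price).
    """
    table = SustainabilityTable()
    table.add_row(SustainabilityRow(key="EX_A", econ=0.2))
    table.add_row(SustainabilityRow(key="EX_P", econ=1.0))
    table.add_row(SustainabilityRow(key="EX_W", econ=-0.1))
    return table


def canonical_economic_weights() -> WeightScheme:
    """Pure-economic weighting (environmental and societal pillars off)."""
    return WeightScheme(w_econ=1.0, w_env=0.0, w_soc=0.0)


# ---------------------------------------------------------------------------
# Random feasible models (planted-path construction)
# ---------------------------------------------------------------------------

def make_random_model(
    n_metabolites: int, n_reactions: int, seed: int
) -> MetabolicModel:
    """A random feasible network with a planted uptake → chain → secretion path.

    The planted path guarantees a strictly positive optimum on the planted
    secretion ``EX_snk``.  Remaining reaction slots are filled with random
    irreversible (occasionally reversible) side reactions over the
    metabolite pool plus occasional extra secretion exchanges; all
    stoichiometric coefficients are small integers or halves, all bounds
    finite.  Fully reproducible from the seed.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites to host the planted path")
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions (uptake, conversion, secretion)")
    rng = np.random.default_rng(seed)
    model = MetabolicModel(id=f"random-{seed}")

    mids = [f"M{i + 1}" for i in range(n_metabolites)]
    for mid in mids:
        model.add_metabolite(Metabolite(id=mid))

    chain_len = min(n_metabolites, n_reactions - 1)  # metabolites on the path
    model.add_reaction(Reaction("EX_src", {mids[0]: -1.0}, -10.0, 0.0, is_exchange=True))
    for i in range(chain_len - 1):
        model.add_reaction(
            Reaction(f"C{i + 1}", {mids[i]: -1.0, mids[i + 1]: 1.0}, 0.0, _UB)
        )
    model.add_reaction(
        Reaction("EX_snk", {mids[chain_len - 1]: -1.0}, 0.0, _UB, is_exchange=True)
    )

    coeff_choices = (0.5, 1.0, 2.0)
    extra = n_reactions - (chain_len + 1)
    for k in range(extra):
        if rng.random() < 0.3:
            mid = mids[int(rng.integers(n_metabolites))]
            ex_id = f"EX_{mid}"
            if ex_id not in model.reactions:
                model.add_reaction(Reaction(ex_id, {mid: -1.0}, 0.0, _UB, is_exchange=True))
                continue
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(n_metabolites, size=min(n_sub + n_prod, n_metabolites),
                           replace=False)
        subs = picks[:n_sub]
        prods = picks[n_sub:]
        if len(prods) == 0:
            subs, prods = picks[:-1], picks[-1:]
        stoich = {mids[int(i)]: -float(rng.choice(coeff_choices)) for i in subs}
        stoich.update({mids[int(i)]: float(rng.choice(coeff_choices)) for i in prods})
        lb = -_UB if rng.random() < 0.2 else 0.0
        model.add_reaction(Reaction(f"X{k + 1}", stoich, lb, _UB))

    model.objective_id = "EX_snk"
    model.biomass_id = "EX_snk"
    model.validate()
    return model


def make_random_table(
    model: MetabolicModel,
    seed: int,
    econ_range: Tuple[float, float] = (-1.0, 1.0),
    env_magnitude: float = 1.0,
    soc_magnitude: float = 1.0,
) -> SustainabilityTable:
    """Random coefficients per exchange: uniform economics, non-positive harms.

    Environmental categories and societal harms are drawn uniformly from
    ``[-magnitude, 0]`` (harm coefficients are non-positive by convention);
    societal benefits from ``[0, magnitude]``.
    """
    rng = np.random.default_rng(seed)
    table = SustainabilityTable()
    for ex in model.exchange_ids:
        env = {
            "global_warming": -float(rng.uniform(0.0, env_magnitude)),
            "aquatic_eutrophication": -float(rng.uniform(0.0, env_magnitude)),
        }
        soc = {
            "human_toxicity": -float(rng.uniform(0.0, soc_magnitude)),
            "jobs_created": float(rng.uniform(0.0, soc_magnitude)),
        }
        table.add_row(
            SustainabilityRow(
                key=ex,
                econ=float(rng.uniform(*econ_range)),
                env=env,
                soc=soc,
            )
        )
    return table


# ---------------------------------------------------------------------------
# Brute-force LP oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    status: str  # "optimal" | "infeasible"
    objective_value: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None


def brute_force_oracle(
    model: MetabolicModel,
    objective: Mapping[str, float],
    direction: str = "max",
    max_reactions: int = 10,
    feas_tol: float = 1e-7,
) -> OracleResult:
    """Optimize a linear flux functional by enumerating basic solutions.

    Every vertex of the bounded polytope ``{S v = 0, lb ≤ v ≤ ub}`` is a
    basic solution: a choice of rank(S) basic columns with every non-basic
    flux pinned at one of its bounds.  Exhaustively enumerating these and
    keeping the feasible best is exponential but exact, independent of any
    LP backend, and fast for the ≤ ``max_reactions``-reaction fixtures it
    is meant for.  All bounds must be finite (a bounded polytope is empty
    or has a vertex, so enumeration decides feasibility too).
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    if n == 0:
        return OracleResult(status="infeasible")
    if n > max_reactions:
        raise ValueError(
            f"oracle capped at {max_reactions} reactions, model has {n}"
        )
    lb, ub = model.bounds_arrays()
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds on every reaction")
    if np.any(lb > ub):
        return OracleResult(status="infeasible")

    c = np.array([objective.get(rid, 0.0) for rid in rxn_ids])
    sign = 1.0 if direction == "max" else -1.0
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    scale = max(1.0, float(np.max(np.abs(ub))), float(np.max(np.abs(lb))))

    best_value = -np.inf
    best_v: Optional[np.ndarray] = None
    for basic in combinations(range(n), rank):
        S_B = S[:, basic]
        if rank and np.linalg.matrix_rank(S_B) < rank:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, side in zip(nonbasic, choice):
                v[j] = lb[j] if side == 0 else ub[j]
            if rank:
                rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(S.shape[0])
                x_B, *_ = np.linalg.lstsq(S_B, rhs, rcond=None)
                v[list(basic)] = x_B
            if np.max(np.abs(S @ v), initial=0.0) > feas_tol * scale:
                continue
            if np.any(v < lb - feas_tol * scale) or np.any(v > ub + feas_tol * scale):
                continue
            value = sign * float(c @ v)
            if value > best_value:
                best_value = value
                best_v = v

    if best_v is None:
        return OracleResult(status="infeasible")
    return OracleResult(
        status="optimal",
        objective_value=sign * best_value,
        fluxes={rid: float(best_v[j]) for j, rid in enumerate(rxn_ids)},
    )
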