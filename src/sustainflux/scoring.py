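"""Sustainability indicator scoring of flux states.

The sustainability indicator score of a flux state is a weighted sum over
the exchange fluxes (and biomass) of their per-unit economic, environmental
and societal coefficients:

    S = w̄_econ · E + w̄_env · V + w̄_soc · C

where ``w̄`` are the pillar weights renormalized to one and each pillar
subtotal is the sum, over its categories, of

    contribution(exchange j, category c) = s_{j,c} · g_j(v_j) · u_c / r_c

with ``s_{j,c}`` the table coefficient, ``g_j`` the row's flux transfer
function (identity unless a nonlinear response was declared), ``u_c`` the
category sub-weight and ``r_c`` the normalization reference that brings the
category onto the common scale.  With all-linear rows the score is exactly
a dot product of the flux vector with a composite coefficient vector, which
is what :func:`linearize_objective` hands to the LP optimizer.

Exchanges whose |flux| falls below the small-flux threshold ε are neglected
and reported as *lumped*; their total neglected contribution is bounded by
ε · Σ_j |composite coefficient_j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .core import FluxState, MetabolicModel
from .sustainability import (
    BIOMASS_KEY,
    CategoryRegistry,
    SustainabilityTable,
    WeightScheme,
)

__all__ = [
    "ScoreBreakdown",
    "LumpedFlux",
    "score_flux_state",
    "linearize_objective",
    "pillar_normalize",
    "composite_coefficients",
    "PiecewiseRowError",
]


class PiecewiseRowError(ValueError):
    """Raised when piecewise rows reach an operation that needs linearity."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(
            "rows with piecewise scoring functions cannot enter a linear "
            f"objective: {sorted(self.keys)}; use evaluation-mode scoring "
            "(score_flux_state) instead"
        )


@dataclass(frozen=True)
class LumpedFlux:
    key: str
    flux: float
    neglected: float  # pillar-weighted contribution that was dropped


@dataclass
class ScoreBreakdown:
    """The sustainability indicator score, decomposed by exchange and category.

    ``contributions`` holds sub-weighted, normalized (but not pillar-weighted)
    terms; ``pillar_totals`` sums them per pillar (E, V, C); ``total`` applies
    the renormalized pillar weights.  ``lumped`` lists the exchanges whose
    |flux| fell below ε together with the contribution that was neglected.
    """

    contributions: Dict[Tuple[str, str], float]
    pillar_totals: Dict[str, float]
    pillar_weights: Dict[str, float]
    total: float
    lumped: List[LumpedFlux] = field(default_factory=list)
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def lumped_total(self) -> float:
        return sum(item.neglected for item in self.lumped)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (exchange, category) contribution."""
        records = [
            {
                "exchange": key,
                "category": cat,
                "flux": self.fluxes.get(key, 0.0),
                "contribution": value,
            }
            for (key, cat), value in sorted(self.contributions.items())
        ]
        return pd.DataFrame.from_records(
            records, columns=["exchange", "category", "flux", "contribution"]
        )

    def to_dict(self) -> Dict:
        return {
            "total": self.total,
            "pillar_totals": dict(self.pillar_totals),
            "pillar_weights": dict(self.pillar_weights),
            "lumped": [
                {"exchange": it.key, "flux": it.flux, "neglected": it.neglected}
                for it in self.lumped
            ],
            "contributions": {
                f"{key}/{cat}": value for (key, cat), value in sorted(self.contributions.items())
            },
        }


def _row_flux_key(key: str, biomass_id: Optional[str]) -> str:
    """The reaction id whose flux a table row reads."""
    if key == BIOMASS_KEY:
        if biomass_id is None:
            raise ValueError(
                "the table has a biomass row but no biomass reaction id was given"
            )
        return biomass_id
    return key


def score_flux_state(
    state: FluxState,
    table: SustainabilityTable,
    weights: WeightScheme,
    biomass_id: Optional[str] = None,
) -> ScoreBreakdown:
    """Score one flux state against a sustainability table and weight scheme.

    Exchanges with |flux| below ``weights.epsilon`` contribute 0 and are
    reported in the lumped-flux list.  Categories present in the table must
    be resolvable through the weight scheme (or its registry); an unknown
    category is rejected by name.
    """
    if not state.optimal:
        raise ValueError(f"cannot score a non-optimal flux state (status {state.status!r})")
    registry = table.registry
    pillar_w = weights.pillar_weights()

    contributions: Dict[Tuple[str, str], float] = {}
    pillar_totals = {"econ": 0.0, "env": 0.0, "soc": 0.0}
    lumped: List[LumpedFlux] = []
    fluxes_used: Dict[str, float] = {}

    for key, row in table.rows.items():
        v = state.fluxes.get(_row_flux_key(key, biomass_id), 0.0)
        fluxes_used[key] = v
        g_v = row.flux_transfer(v)
        if abs(v) < weights.epsilon:
            neglected = 0.0
            for cat, coeff in row.coefficients().items():
                scale = weights.category_scale(cat, registry)
                neglected += pillar_w[registry.pillar_of(cat)] * coeff * g_v * scale
            if neglected != 0.0 or row.coefficients():
                lumped.append(LumpedFlux(key=key, flux=v, neglected=neglected))
            continue
        for cat, coeff in row.coefficients().items():
            scale = weights.category_scale(cat, registry)
            term = coeff * g_v * scale
            contributions[(key, cat)] = term
            pillar_totals[registry.pillar_of(cat)] += term

    total = sum(pillar_w[p] * pillar_totals[p] for p in ("econ", "env", "soc"))
    return ScoreBreakdown(
        contributions=contributions,
        pillar_totals=pillar_totals,
        pillar_weights=pillar_w,
        total=total,
        lumped=lumped,
        fluxes=fluxes_used,
    )


def composite_coefficients(
    table: SustainabilityTable, weights: WeightScheme
) -> Dict[str, float]:
    """Pillar-weighted, normalized composite coefficient per table key.

    Requires all rows linear; the linear slope folds into the coefficient.
    """
    piecewise = table.has_piecewise_rows()
    if piecewise:
        raise PiecewiseRowError(piecewise)
    registry = table.registry
    pillar_w = weights.pillar_weights()
    out: Dict[str, float] = {}
    for key, row in table.rows.items():
        slope = row.flux_transfer.slope
        comp = 0.0
        for cat, coeff in row.coefficients().items():
            scale = weights.category_scale(cat, registry)
            comp += pillar_w[registry.pillar_of(cat)] * coeff * scale
        out[key] = comp * slope
    return out


def linearize_objective(
    table: SustainabilityTable,
    weights: WeightScheme,
    model: MetabolicModel,
) -> Dict[str, float]:
    """Objective coefficients over all model reactions for the LP optimizer.

    Each exchange with a table row gets its composite coefficient; the
    biomass reaction gets the biomass row's composite; every other reaction
    gets 0.  Rows with piecewise scoring functions are rejected (they are
    evaluation-only).
    """
    table.validate_against(model)
    comp = composite_coefficients(table, weights)
    out = {rid: 0.0 for rid in model.reactions}
    for key, value in comp.items():
        rid = model.biomass_id if key == BIOMASS_KEY else key
        if rid is None:
            raise ValueError(
                "the table has a biomass row but the model declares no biomass reaction"
            )
        out[rid] = out[rid] + value
    return out


def pillar_normalize(
    table: SustainabilityTable, weights: WeightScheme
) -> Dict[str, Dict[str, float]]:
    """Per-key category coefficients divided by their normalization reference.

    Brings all categories onto one common scale prior to weighting.  The
    reference of a registered category defaults to 1.0; an unregistered,
    unconfigured category is rejected by name.
    """
    registry = table.registry
    out: Dict[str, Dict[str, float]] = {}
    for key, row in table.rows.items():
        normalized: Dict[str, float] = {}
        for cat, coeff in row.coefficients().items():
            if (
                cat not in weights.norm_refs
                and cat not in weights.subweights
                and cat not in registry
            ):
                raise KeyError(
                    f"no normalization reference for populated category {cat!r}"
                )
            normalized[cat] = coeff / weights.norm_refs.get(cat, 1.0)
        out[key] = normalized
    return out
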