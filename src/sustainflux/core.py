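"""Core domain types for stoichiometric metabolic models.

A :class:`MetabolicModel` is a bag of metabolites and reactions with flux
bounds, in the usual constraint-based-modelling sense: a steady-state flux
vector ``v`` is feasible when ``S v = 0`` and ``lb <= v <= ub``, where ``S``
is the stoichiometric matrix (metabolites x reactions).

Sign conventions (fixed throughout the package):

* exchange reactions carry exactly one metabolite with coefficient -1, so
  positive flux means secretion and negative flux means uptake;
* flux units are mmol · gDW⁻¹ · h⁻¹.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "DesignSpec",
    "ModelValidationError",
    "parse_formula",
]


class ModelValidationError(ValueError):
    """Raised when a model or design violates a structural invariant."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into element counts.

    Only flat formulas (no parentheses or charges) are supported, which covers
    the formulas stored in FBC ``chemicalFormula`` attributes.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    formula: Optional[str] = None

    def element_counts(self) -> Optional[Dict[str, int]]:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    is_exchange: bool = False

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            is_exchange=self.is_exchange,
        )

    def looks_like_exchange(self) -> bool:
        """True when the stoichiometry matches the exchange convention."""
        return len(self.stoichiometry) == 1 and next(iter(self.stoichiometry.values())) == -1


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, exchange flags and an objective.

    ``metabolites`` and ``reactions`` are insertion-ordered mappings keyed by
    id; order defines the row/column order of :meth:`stoichiometric_matrix`.
    """

    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_id: Optional[str] = None
    objective_id: Optional[str] = None

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={mid: replace(m) for mid, m in self.metabolites.items()},
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_id=self.biomass_id,
            objective_id=self.objective_id,
        )

    # -- queries -----------------------------------------------------------

    @property
    def exchange_ids(self) -> Tuple[str, ...]:
        return tuple(rid for rid, r in self.reactions.items() if r.is_exchange)

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, Tuple[str, ...], Tuple[str, ...]]:
        """Dense S matrix plus the metabolite (row) and reaction (column) ids."""
        met_ids = tuple(self.metabolites)
        rxn_ids = tuple(self.reactions)
        met_index = {mid: i for i, mid in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coeff
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], dtype=float)
        return lb, ub

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError naming the offender."""
        for rid, rxn in self.reactions.items():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rid!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}"
                    )
            if rxn.is_exchange and not rxn.looks_like_exchange():
                raise ModelValidationError(
                    f"reaction {rid!r} is flagged exchange but does not have a "
                    "single metabolite with coefficient -1"
                )
        for attr in ("biomass_id", "objective_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reactions:
                raise ModelValidationError(f"{attr} {rid!r} is not a reaction of the model")

    def structurally_equal(self, other: "MetabolicModel") -> bool:
        """Id-wise equality of metabolites, reactions, stoichiometry and bounds."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for mid, met in self.metabolites.items():
            omet = other.metabolites[mid]
            if (met.compartment, met.formula) != (omet.compartment, omet.formula):
                return False
        for rid, rxn in self.reactions.items():
            orxn = other.reactions[rid]
            if rxn.stoichiometry != orxn.stoichiometry:
                return False
            if (rxn.lower_bound, rxn.upper_bound, rxn.is_exchange) != (
                orxn.lower_bound,
                orxn.upper_bound,
                orxn.is_exchange,
            ):
                return False
        return (self.biomass_id, self.objective_id) == (other.biomass_id, other.objective_id)


@dataclass
class FluxState:
    """One steady-state flux assignment plus the solver verdict.

    ``fluxes`` is None unless ``status == "optimal"``.
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"no flux vector available (status {self.status!r})")
        return self.fluxes[reaction_id]


@dataclass(frozen=True)
class DesignSpec:
    """A candidate strain design: deletions, insertions and media edits.

    Deletions are applied as zero bounds (the reaction id is retained so
    downstream reports can still reference it).  Media edits replace the
    bounds of exchange reactions.
    """

    deletions: Tuple[str, ...] = ()
    insertions: Tuple[Reaction, ...] = ()
    media: Tuple[Tuple[str, Tuple[float, float]], ...] = ()

    @staticmethod
    def deletion(*reaction_ids: str) -> "DesignSpec":
        return DesignSpec(deletions=tuple(reaction_ids))

    @staticmethod
    def media_edit(exchange_id: str, lb: float, ub: float) -> "DesignSpec":
        return DesignSpec(media=((exchange_id, (lb, ub)),))

    def merge(self, other: "DesignSpec") -> "DesignSpec":
        """Combine two designs; later media edits win on the same exchange."""
        media = dict(self.media)
        media.update(dict(other.media))
        return DesignSpec(
            deletions=tuple(dict.fromkeys(self.deletions + other.deletions)),
            insertions=self.insertions + other.insertions,
            media=tuple(sorted(media.items())),
        )

    @property
    def n_interventions(self) -> int:
        return len(self.deletions) + len(self.insertions)

    def design_string(self) -> str:
        """Canonical, deterministic text form used for reporting and tie-breaks."""
        parts = []
        for rid in sorted(self.deletions):
            parts.append(f"del:{rid}")
        for rxn in sorted(self.insertions, key=lambda r: r.id):
            parts.append(f"ins:{rxn.id}")
        for ex, (lb, ub) in sorted(self.media):
            parts.append(f"media:{ex}[{lb:g},{ub:g}]")
        return "+".join(parts) if parts else "wild-type"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.design_string()
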