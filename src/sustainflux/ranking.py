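"""Enumeration and sustainability-ranked comparison of strain designs.

A design is a set of reaction deletions and/or insertions applied to a
chassis model.  Each design is characterized by its chassis, intervention
counts, maximal growth rate, and the interval of sustainability scores it
admits at the required growth fraction.  Designs are ranked by a statistic
of that interval — by default the pessimistic lower bound ``S_min``: under
alternative optima the realized flux distribution is unknown, so the
worst-case score is the defensible ranking criterion.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .core import DesignSpec, MetabolicModel, Reaction
from .lp import InfeasibleModelError, apply_design, fba
from .optimize import sustainability_range
from .sustainability import SustainabilityTable, WeightScheme

__all__ = [
    "DesignResult",
    "enumerate_designs",
    "evaluate_design",
    "rank_designs",
    "DesignSpaceTooLargeError",
    "RANK_STATISTICS",
]

#: Hard default on the number of enumerated designs; above it the
#: enumeration refuses rather than silently sampling.
DEFAULT_DESIGN_CAP = 10_000

#: How a score interval collapses to the rank statistic.
RANK_STATISTICS = {
    "pessimistic": lambda s_min, s_max: s_min,
    "optimistic": lambda s_min, s_max: s_max,
    "midpoint": lambda s_min, s_max: 0.5 * (s_min + s_max),
}

_GROWTH_TOL = 1e-9


class DesignSpaceTooLargeError(RuntimeError):
    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"design space holds {count} designs, above the cap of {cap}; "
            "narrow the candidate lists or raise the cap explicitly"
        )


@dataclass
class DesignResult:
    """One evaluated candidate design."""

    chassis_id: str
    design: DesignSpec
    mu_max: Optional[float]
    score_interval: Optional[Tuple[float, float]]  # None when infeasible
    feasible: bool
    n_deletions: int
    n_insertions: int
    config_hash: str
    note: str = ""

    def statistic(self, name: str = "pessimistic") -> Optional[float]:
        if self.score_interval is None:
            return None
        return RANK_STATISTICS[name](*self.score_interval)

    @property
    def interval_width(self) -> Optional[float]:
        if self.score_interval is None:
            return None
        return self.score_interval[1] - self.score_interval[0]

    def to_dict(self) -> Dict:
        return {
            "chassis": self.chassis_id,
            "design": self.design.design_string(),
            "mu_max": self.mu_max,
            "s_min": None if self.score_interval is None else self.score_interval[0],
            "s_max": None if self.score_interval is None else self.score_interval[1],
            "feasible": self.feasible,
            "deletions": self.n_deletions,
            "insertions": self.n_insertions,
            "note": self.note,
        }


def _subsets(items: Sequence, max_size: int) -> Iterator[Tuple]:
    """All subsets up to max_size, smallest first, lexicographic within a size."""
    for size in range(max_size + 1):
        yield from combinations(items, size)


def count_designs(
    n_deletion_candidates: int, n_insertion_pool: int, max_deletions: int, max_insertions: int
) -> int:
    n_del = sum(comb(n_deletion_candidates, k)
                for k in range(min(max_deletions, n_deletion_candidates) + 1))
    n_ins = sum(comb(n_insertion_pool, k)
                for k in range(min(max_insertions, n_insertion_pool) + 1))
    return n_del * n_ins


def enumerate_designs(
    model: MetabolicModel,
    deletion_candidates: Sequence[str] = (),
    insertion_pool: Sequence[Reaction] = (),
    max_deletions: int = 1,
    max_insertions: int = 0,
    cap: int = DEFAULT_DESIGN_CAP,
) -> Iterator[DesignSpec]:
    """Lazily yield every deletion×insertion combination up to the size caps.

    Deterministic order: the empty (wild-type) design first, then by subset
    size, lexicographic within a size.  Refuses design spaces larger than
    ``cap`` with an error stating the count.
    """
    deletion_candidates = sorted(deletion_candidates)
    insertion_pool = sorted(insertion_pool, key=lambda r: r.id)
    for rid in deletion_candidates:
        if rid not in model.reactions:
            raise KeyError(f"deletion candidate {rid!r} not in model")
    total = count_designs(len(deletion_candidates), len(insertion_pool),
                          max_deletions, max_insertions)
    if total > cap:
        raise DesignSpaceTooLargeError(total, cap)
    for dels in _subsets(deletion_candidates, max_deletions):
        for inss in _subsets(insertion_pool, max_insertions):
            yield DesignSpec(deletions=dels, insertions=inss)


def evaluate_design(
    model: MetabolicModel,
    design: DesignSpec,
    table: SustainabilityTable,
    weights: WeightScheme,
    min_growth_fraction: float = 1.0,
    solver: str = "highs",
) -> DesignResult:
    """Apply a design, compute μ_max and the score interval.

    A design is feasible when the edited model solves and grows (μ_max > 0);
    infeasible designs carry no score interval.  Failures are recorded in
    the result rather than raised, so batch evaluation never aborts.
    """
    config = table.config_hash() + weights.config_hash()
    base = dict(
        chassis_id=model.id,
        design=design,
        n_deletions=len(design.deletions),
        n_insertions=len(design.insertions),
        config_hash=config,
    )
    try:
        edited = apply_design(model, design)
    except Exception as exc:
        return DesignResult(mu_max=None, score_interval=None, feasible=False,
                            note=f"invalid design: {exc}", **base)

    growth_rxn = edited.biomass_id or edited.objective_id
    if growth_rxn is None:
        return DesignResult(mu_max=None, score_interval=None, feasible=False,
                            note="no biomass or objective reaction", **base)
    mu = fba(edited, growth_rxn, solver=solver)
    if not mu.optimal or mu.objective_value <= _GROWTH_TOL:
        return DesignResult(
            mu_max=mu.objective_value if mu.optimal else None,
            score_interval=None, feasible=False,
            note=f"no growth (status {mu.status})", **base,
        )
    try:
        interval = sustainability_range(edited, table, weights,
                                        growth_fraction=min_growth_fraction, solver=solver)
    except (InfeasibleModelError, RuntimeError) as exc:
        return DesignResult(mu_max=mu.objective_value, score_interval=None,
                            feasible=False, note=str(exc), **base)
    return DesignResult(mu_max=mu.objective_value, score_interval=interval,
                        feasible=True, **base)


def rank_designs(
    results: Sequence[DesignResult],
    statistic: str = "pessimistic",
) -> List[DesignResult]:
    """Order designs by the chosen interval statistic, best first.

    Descending by statistic; ties broken by fewer total interventions, then
    narrower score interval, then lexicographic design string.  Infeasible
    designs sort last (by design string).  The output is a stable,
    deterministic permutation of the input.  Mixing results evaluated under
    different tables or weights is rejected via their config hashes.
    """
    if statistic not in RANK_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; known: {sorted(RANK_STATISTICS)}")
    hashes = {r.config_hash for r in results}
    if len(hashes) > 1:
        raise ValueError(
            "results were evaluated under differing sustainability tables or "
            "weight schemes; rank each configuration separately"
        )

    def sort_key(result: DesignResult):
        if not result.feasible:
            return (1, 0.0, 0, 0.0, result.design.design_string(), result.chassis_id)
        return (
            0,
            -result.statistic(statistic),
            result.design.n_interventions,
            result.interval_width,
            result.design.design_string(),
            result.chassis_id,
        )

    return sorted(results, key=sort_key)
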