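"""Sustainability coefficients attached to exchange fluxes.

Every exchange reaction (and, optionally, biomass) carries a row of
per-unit-flux coefficients: one economic value (currency per unit flux) and
one coefficient per environmental or societal impact category.  Categories
live in a registry that assigns each to a pillar (economic, environmental,
societal) and records whether it is a *harm* (impact potentials, toxicity)
or a *benefit* (market value, jobs, social acceptance).

Sign convention: benefit categories carry positive coefficients and harm
categories negative ones, so that a larger composite score is always more
sustainable.  The loader warns when a known harm category is given a
positive coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "BIOMASS_KEY",
    "ECONOMIC_CATEGORY",
    "CategoryRegistry",
    "DEFAULT_REGISTRY",
    "ScoringFunction",
    "SustainabilityRow",
    "SustainabilityTable",
    "WeightScheme",
    "UnknownCategoryError",
]

#: Reserved table key for the coefficients of produced biomass.
BIOMASS_KEY = "BIOMASS"

#: Name of the single economic category.
ECONOMIC_CATEGORY = "econ"

PILLARS = ("econ", "env", "soc")


class UnknownCategoryError(KeyError):
    """A category name that is neither registered nor configured."""


@dataclass(frozen=True)
class CategoryInfo:
    pillar: str  # "econ" | "env" | "soc"
    harm: bool   # harm categories should carry non-positive coefficients


@dataclass
class CategoryRegistry:
    """User-extensible mapping from category name to pillar and harm flag."""

    categories: Dict[str, CategoryInfo] = field(default_factory=dict)

    def register(self, name: str, pillar: str, harm: bool) -> None:
        if pillar not in PILLARS:
            raise ValueError(f"unknown pillar {pillar!r}; expected one of {PILLARS}")
        self.categories[name] = CategoryInfo(pillar=pillar, harm=harm)

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def pillar_of(self, name: str) -> str:
        try:
            return self.categories[name].pillar
        except KeyError:
            raise UnknownCategoryError(name) from None

    def is_harm(self, name: str) -> bool:
        try:
            return self.categories[name].harm
        except KeyError:
            raise UnknownCategoryError(name) from None

    def names(self, pillar: Optional[str] = None) -> Tuple[str, ...]:
        if pillar is None:
            return tuple(self.categories)
        return tuple(n for n, info in self.categories.items() if info.pillar == pillar)

    def copy(self) -> "CategoryRegistry":
        return CategoryRegistry(dict(self.categories))


def _default_registry() -> CategoryRegistry:
    reg = CategoryRegistry()
    reg.register(ECONOMIC_CATEGORY, "econ", harm=False)
    # Environmental impact categories (life-cycle-assessment style, all harms).
    for name in (
        "aquatic_acidification",
        "aquatic_eutrophication",
        "aquatic_ecotoxicity",
        "terrestrial_ecotoxicity",
        "terrestrial_acidification",
        "abiotic_depletion",
        "global_warming",
    ):
        reg.register(name, "env", harm=True)
    # Societal categories: health/land burdens are harms, jobs and acceptance benefits.
    for name in (
        "human_toxicity",
        "ozone_depletion",
        "photochemical_oxidant_creation",
        "land_occupation",
    ):
        reg.register(name, "soc", harm=True)
    for name in ("social_acceptance", "jobs_created"):
        reg.register(name, "soc", harm=False)
    return reg


DEFAULT_REGISTRY = _default_registry()


@dataclass(frozen=True)
class ScoringFunction:
    """Flux → contribution transfer function, linear or piecewise-linear.

    Linear: ``g(v) = slope * v``.  Piecewise: continuous interpolation
    through strictly x-increasing breakpoints, with linear extrapolation
    beyond the end segments.  Piecewise functions are evaluation-only; they
    cannot enter a linear-programming objective.
    """

    kind: str = "linear"  # "linear" | "piecewise"
    slope: float = 1.0
    breakpoints: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.kind not in ("linear", "piecewise"):
            raise ValueError(f"unknown scoring function kind {self.kind!r}")
        if self.kind == "piecewise":
            if len(self.breakpoints) < 2:
                raise ValueError("piecewise scoring function needs at least 2 breakpoints")
            xs = [x for x, _ in self.breakpoints]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError("piecewise breakpoints must be strictly increasing in x")

    @property
    def is_linear(self) -> bool:
        return self.kind == "linear"

    def __call__(self, v: float) -> float:
        if self.kind == "linear":
            return self.slope * v
        pts = self.breakpoints
        # Locate the segment; extrapolate linearly beyond the ends.
        if v <= pts[0][0]:
            (x0, y0), (x1, y1) = pts[0], pts[1]
        elif v >= pts[-1][0]:
            (x0, y0), (x1, y1) = pts[-2], pts[-1]
        else:
            for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
                if x0 <= v <= x1:
                    break
        return y0 + (y1 - y0) * (v - x0) / (x1 - x0)

    # -- text form used by the CSV dialect ("x1:y1|x2:y2|..." or a number) --

    @staticmethod
    def parse(text: str) -> "ScoringFunction":
        text = text.strip()
        if "|" in text or ":" in text:
            pts = []
            for pair in text.split("|"):
                x_str, y_str = pair.split(":")
                pts.append((float(x_str), float(y_str)))
            return ScoringFunction(kind="piecewise", breakpoints=tuple(pts))
        return ScoringFunction(kind="linear", slope=float(text))

    def serialize(self) -> str:
        if self.kind == "linear":
            return repr(self.slope)
        return "|".join(f"{x!r}:{y!r}" for x, y in self.breakpoints)


@dataclass
class SustainabilityRow:
    """Coefficients of one exchange reaction (or biomass) across categories."""

    key: str
    econ: float = 0.0
    env: Dict[str, float] = field(default_factory=dict)
    soc: Dict[str, float] = field(default_factory=dict)
    scoring_fn: Optional[ScoringFunction] = None

    def coefficients(self) -> Dict[str, float]:
        """All category coefficients of the row, economic included."""
        out = {ECONOMIC_CATEGORY: self.econ}
        out.update(self.env)
        out.update(self.soc)
        return out

    @property
    def flux_transfer(self) -> ScoringFunction:
        return self.scoring_fn if self.scoring_fn is not None else ScoringFunction()


@dataclass
class SustainabilityTable:
    """Per-exchange sustainability coefficients keyed by exchange reaction id.

    The reserved key :data:`BIOMASS_KEY` holds the coefficients of produced
    biomass; an absent biomass row means all-zero biomass coefficients.
    """

    rows: Dict[str, SustainabilityRow] = field(default_factory=dict)
    registry: CategoryRegistry = field(default_factory=DEFAULT_REGISTRY.copy)

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    def row(self, key: str) -> SustainabilityRow:
        return self.rows[key]

    def add_row(self, row: SustainabilityRow, warn_signs: bool = True) -> None:
        for cat in row.coefficients():
            if cat not in self.registry:
                raise UnknownCategoryError(cat)
        if warn_signs:
            for cat, value in row.coefficients().items():
                if value > 0 and self.registry.is_harm(cat):
                    warnings.warn(
                        f"row {row.key!r}: harm category {cat!r} has a positive "
                        f"coefficient {value}; harm coefficients are expected to be "
                        "negative (harm reduces the score)",
                        UserWarning,
                        stacklevel=2,
                    )
        self.rows[row.key] = row

    def categories_used(self) -> Tuple[str, ...]:
        """Categories populated (non-zero or explicitly present) in any row."""
        seen: Dict[str, None] = {}
        for row in self.rows.values():
            for cat in row.coefficients():
                seen.setdefault(cat, None)
        return tuple(seen)

    def has_piecewise_rows(self) -> List[str]:
        return [key for key, row in self.rows.items()
                if row.scoring_fn is not None and not row.scoring_fn.is_linear]

    def validate_against(self, model) -> None:
        """Every key must be an exchange of the model or the biomass key."""
        exchange_ids = set(model.exchange_ids)
        for key in self.rows:
            if key == BIOMASS_KEY:
                continue
            if model.biomass_id is not None and key == model.biomass_id:
                continue
            if key not in exchange_ids:
                raise ValueError(
                    f"sustainability table key {key!r} is not an exchange reaction "
                    "of the model (nor the biomass key)"
                )

    def config_hash(self) -> str:
        """Stable digest of the table contents, for mixed-config detection."""
        import hashlib

        payload = {
            key: {
                "econ": row.econ,
                "env": dict(sorted(row.env.items())),
                "soc": dict(sorted(row.soc.items())),
                "fn": row.scoring_fn.serialize() if row.scoring_fn else None,
            }
            for key, row in sorted(self.rows.items())
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class WeightScheme:
    """Pillar weights, per-category sub-weights and normalization references.

    Normalization references (units: category-unit per common-scale unit)
    bring the categories onto one scale before weighting; they default to
    1.0 for registered categories.  ``epsilon`` is the small-flux threshold
    below which exchange contributions are neglected and reported as lumped.
    """

    w_econ: float = 1.0
    w_env: float = 1.0
    w_soc: float = 1.0
    subweights: Dict[str, float] = field(default_factory=dict)
    norm_refs: Dict[str, float] = field(default_factory=dict)
    epsilon: float = 1e-6

    def __post_init__(self):
        if min(self.w_econ, self.w_env, self.w_soc) < 0:
            raise ValueError("pillar weights must be non-negative")
        if self.w_econ + self.w_env + self.w_soc <= 0:
            raise ValueError("pillar weights must sum to a positive value")
        for cat, ref in self.norm_refs.items():
            if ref <= 0:
                raise ValueError(
                    f"normalization reference for {cat!r} must be strictly positive, got {ref}"
                )
        if self.epsilon < 0:
            raise ValueError("small-flux threshold epsilon must be non-negative")

    def pillar_weights(self) -> Dict[str, float]:
        """Pillar weights renormalized to sum to one."""
        total = self.w_econ + self.w_env + self.w_soc
        return {"econ": self.w_econ / total, "env": self.w_env / total, "soc": self.w_soc / total}

    def category_scale(self, category: str, registry: CategoryRegistry) -> float:
        """subweight / normalization-reference for one category.

        A category configured in neither ``subweights`` nor ``norm_refs`` and
        absent from the registry is rejected by name — that is almost always
        a typo in the input table.
        """
        if (
            category not in self.subweights
            and category not in self.norm_refs
            and category not in registry
        ):
            raise UnknownCategoryError(
                f"category {category!r} is absent from the weight scheme and the "
                "category registry"
            )
        return self.subweights.get(category, 1.0) / self.norm_refs.get(category, 1.0)

    def config_hash(self) -> str:
        import hashlib

        payload = {
            "pillars": [self.w_econ, self.w_env, self.w_soc],
            "subweights": dict(sorted(self.subweights.items())),
            "norm_refs": dict(sorted(self.norm_refs.items())),
            "epsilon": self.epsilon,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    # -- config file form --------------------------------------------------

    @staticmethod
    def from_dict(data: Mapping) -> "WeightScheme":
        pillars = data.get("pillars", {})
        return WeightScheme(
            w_econ=float(pillars.get("econ", 1.0)),
            w_env=float(pillars.get("env", 1.0)),
            w_soc=float(pillars.get("soc", 1.0)),
            subweights={k: float(v) for k, v in data.get("subweights", {}).items()},
            norm_refs={k: float(v) for k, v in data.get("norm_refs", {}).items()},
            epsilon=float(data.get("epsilon", 1e-6)),
        )

    def to_dict(self) -> Dict:
        return {
            "pillars": {"econ": self.w_econ, "env": self.w_env, "soc": self.w_soc},
            "subweights": dict(self.subweights),
            "norm_refs": dict(self.norm_refs),
            "epsilon": self.epsilon,
        }
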