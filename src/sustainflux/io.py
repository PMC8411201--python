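"""Reading and writing models, sustainability tables and weight configs.

Two model serializations are supported and round-trip to structurally equal
models:

* SBML Level 3 with the FBC package (flux bounds as parameters, an active
  objective, biomass marked with SBO:0000629).  Species ids carry the usual
  ``M_`` prefix and reactions ``R_``; both are stripped on read.
* A plain tab-separated dialect with columns ``reaction_id``,
  ``stoichiometry`` (semicolon-separated ``met:coeff`` pairs), ``lb``,
  ``ub``, ``is_exchange``, ``is_biomass``.  Header comment lines
  (``# model``, ``# objective``, ``# metabolite <id> <compartment>
  <formula>``) persist the metadata the column set cannot hold.

Exchange reactions are auto-detected in both formats as single-metabolite
reactions with coefficient -1 (secretion-positive convention); a reaction
that is labelled like an exchange but shaped differently triggers a warning
and is not flagged.

Sustainability tables are CSV with columns ``exchange_id``, ``econ``, one
column per impact category, and an optional ``scoring_fn`` column holding
either a slope or piecewise breakpoints ``x1:y1|x2:y2|...``.  Weight
schemes are JSON.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import libsbml
import pandas as pd

from .core import MetabolicModel, Metabolite, ModelValidationError, Reaction
from .sustainability import (
    BIOMASS_KEY,
    CategoryRegistry,
    DEFAULT_REGISTRY,
    ScoringFunction,
    SustainabilityRow,
    SustainabilityTable,
    UnknownCategoryError,
    WeightScheme,
)

__all__ = [
    "read_sbml",
    "write_sbml",
    "read_model_tsv",
    "write_model_tsv",
    "read_sustainability_table",
    "write_sustainability_table",
    "load_weights",
    "save_weights",
    "SBMLParseError",
]

_SBO_EXCHANGE = 627  # SBO:0000627, exchange reaction
_SBO_BIOMASS = 629   # SBO:0000629, biomass production
_SBO_SINK = 632      # SBO:0000632, sink reaction (single-metabolite, non-boundary)
_BIOMASS_OBJECTIVE_ID = "biomass_marker"
_MET_PREFIX = "M_"
_RXN_PREFIX = "R_"


class SBMLParseError(ValueError):
    """Malformed SBML; the message names the offending line."""


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize a model to SBML L3V1 with FBC v2 bounds and objective."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    # SBML SIds forbid '-' and friends; sanitize the model id only
    import re

    sm.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.id) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted({met.compartment for met in model.metabolites.values()} or {"c"}):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for mid, met in model.metabolites.items():
        sp = sm.createSpecies()
        sp.setId(_MET_PREFIX + mid)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula is not None:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, rxn in model.reactions.items():
        r = sm.createReaction()
        r.setId(_RXN_PREFIX + rid)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        # persist the exchange/sink distinction, which is not recoverable from
        # the stoichiometry alone (biomass drains look like exchanges)
        if rxn.is_exchange:
            r.setSBOTerm(_SBO_EXCHANGE)
        elif rid == model.biomass_id:
            r.setSBOTerm(_SBO_BIOMASS)
        elif rxn.looks_like_exchange():
            r.setSBOTerm(_SBO_SINK)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for mid, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_MET_PREFIX + mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    if model.objective_id is not None:
        fo = objective.createFluxObjective()
        fo.setReaction(_RXN_PREFIX + model.objective_id)
        fo.setCoefficient(1.0)
    if model.biomass_id is not None:
        # inactive marker objective recording which reaction is biomass
        marker = mplug.createObjective()
        marker.setId(_BIOMASS_OBJECTIVE_ID)
        marker.setType("maximize")
        fo = marker.createFluxObjective()
        fo.setReaction(_RXN_PREFIX + model.biomass_id)
        fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    """Read an SBML model with FBC bounds and objective.

    Exchange reactions are auto-detected by shape; the biomass reaction is
    recognized by its SBO term; the active objective is taken from the file
    (and can be overridden afterwards on the returned model).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(f"{path}: line {err.getLine()}: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise SBMLParseError(f"{path}: file holds no SBML model")

    model = MetabolicModel(id=sm.getId() or path.stem)

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        fplug = sp.getPlugin("fbc")
        formula = None
        if fplug is not None and fplug.isSetChemicalFormula():
            formula = fplug.getChemicalFormula()
        model.add_metabolite(
            Metabolite(id=_strip(_MET_PREFIX, sp.getId()),
                       compartment=sp.getCompartment() or "c",
                       formula=formula)
        )

    params = {}
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        params[p.getId()] = p.getValue()

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        rid = _strip(_RXN_PREFIX, r.getId())
        rplug = r.getPlugin("fbc")
        if (
            rplug is None
            or not rplug.isSetLowerFluxBound()
            or not rplug.isSetUpperFluxBound()
        ):
            raise ModelValidationError(f"reaction {rid!r} has no flux bounds")
        lb = params[rplug.getLowerFluxBound()]
        ub = params[rplug.getUpperFluxBound()]
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = _strip(_MET_PREFIX, ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = _strip(_MET_PREFIX, ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rxn = Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        sbo = r.getSBOTerm() if r.isSetSBOTerm() else None
        if sbo == _SBO_EXCHANGE:
            rxn.is_exchange = True
        elif sbo in (_SBO_BIOMASS, _SBO_SINK):
            rxn.is_exchange = False
        else:
            rxn.is_exchange = rxn.looks_like_exchange()
            if not rxn.is_exchange and rid.startswith("EX"):
                warnings.warn(
                    f"reaction {rid!r} is named like an exchange but does not have "
                    "a single metabolite with coefficient -1; not flagged as "
                    "exchange",
                    UserWarning,
                    stacklevel=2,
                )
        model.add_reaction(rxn)
        if sbo == _SBO_BIOMASS:
            model.biomass_id = rid

    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getId() == _BIOMASS_OBJECTIVE_ID and obj.getNumFluxObjectives() > 0:
                model.biomass_id = _strip(_RXN_PREFIX, obj.getFluxObjective(0).getReaction())
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if (
            active is not None
            and active.getId() != _BIOMASS_OBJECTIVE_ID
            and active.getNumFluxObjectives() > 0
        ):
            model.objective_id = _strip(_RXN_PREFIX, active.getFluxObjective(0).getReaction())

    model.validate()
    return model


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["reaction_id", "stoichiometry", "lb", "ub", "is_exchange", "is_biomass"]


def _format_number(x: float) -> str:
    return repr(float(x))


def write_model_tsv(model: MetabolicModel, path: Union[str, Path]) -> None:
    lines: List[str] = [f"# model\t{model.id}"]
    if model.objective_id is not None:
        lines.append(f"# objective\t{model.objective_id}")
    for mid, met in model.metabolites.items():
        lines.append(f"# metabolite\t{mid}\t{met.compartment}\t{met.formula or ''}")
    lines.append("\t".join(_TSV_COLUMNS))
    for rid, rxn in model.reactions.items():
        stoich = ";".join(
            f"{mid}:{_format_number(coeff)}" for mid, coeff in rxn.stoichiometry.items()
        )
        lines.append(
            "\t".join(
                [
                    rid,
                    stoich,
                    _format_number(rxn.lower_bound),
                    _format_number(rxn.upper_bound),
                    str(rxn.is_exchange).lower(),
                    str(rid == model.biomass_id).lower(),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_tsv(path: Union[str, Path]) -> MetabolicModel:
    """Read the tab-separated model dialect; semantics match :func:`read_sbml`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    model = MetabolicModel(id=path.stem)
    explicit_metabolites = False
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "model" and len(fields) > 1:
                model.id = fields[1]
            elif fields[0] == "objective" and len(fields) > 1:
                model.objective_id = fields[1]
            elif fields[0] == "metabolite":
                explicit_metabolites = True
                mid = fields[1]
                compartment = fields[2] if len(fields) > 2 and fields[2] else "c"
                formula = fields[3] if len(fields) > 3 and fields[3] else None
                model.add_metabolite(Metabolite(id=mid, compartment=compartment,
                                                formula=formula))
            continue
        if not header_seen:
            if line.split("\t") != _TSV_COLUMNS:
                raise ModelValidationError(
                    f"{path}: line {lineno}: expected header {_TSV_COLUMNS}"
                )
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != len(_TSV_COLUMNS):
            raise ModelValidationError(
                f"{path}: line {lineno}: expected {len(_TSV_COLUMNS)} fields"
            )
        rid, stoich_text, lb_text, ub_text, _flag_text, biomass_text = fields
        stoich: Dict[str, float] = {}
        for pair in stoich_text.split(";"):
            if not pair:
                continue
            mid, _, coeff_text = pair.rpartition(":")
            if not mid:
                raise ModelValidationError(
                    f"{path}: line {lineno}: malformed stoichiometry pair {pair!r}"
                )
            if explicit_metabolites and mid not in model.metabolites:
                raise ModelValidationError(
                    f"{path}: line {lineno}: unknown metabolite {mid!r}"
                )
            if not explicit_metabolites and mid not in model.metabolites:
                model.add_metabolite(Metabolite(id=mid))
            stoich[mid] = stoich.get(mid, 0.0) + float(coeff_text)
        rxn = Reaction(id=rid, stoichiometry=stoich,
                       lower_bound=float(lb_text), upper_bound=float(ub_text))
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"{path}: line {lineno}: reaction {rid!r} has lb > ub"
            )
        is_biomass = biomass_text.strip().lower() in ("true", "1", "yes")
        flagged = _flag_text.strip().lower() in ("true", "1", "yes")
        # exchange by shape; a biomass drain is only an exchange when flagged so
        rxn.is_exchange = rxn.looks_like_exchange() and (flagged or not is_biomass)
        if not rxn.is_exchange and not is_biomass and flagged:
            warnings.warn(
                f"reaction {rid!r} is marked is_exchange but does not match the "
                "exchange convention; not flagged",
                UserWarning,
                stacklevel=2,
            )
        model.add_reaction(rxn)
        if is_biomass:
            model.biomass_id = rid
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Sustainability table CSV
# ---------------------------------------------------------------------------

def write_sustainability_table(table: SustainabilityTable, path: Union[str, Path]) -> None:
    categories = [c for c in table.categories_used() if c != "econ"]
    any_fn = any(row.scoring_fn is not None for row in table.rows.values())
    columns = ["exchange_id", "econ"] + categories + (["scoring_fn"] if any_fn else [])
    records = []
    for key, row in table.rows.items():
        rec = {"exchange_id": key, "econ": row.econ}
        rec.update({c: row.env.get(c, row.soc.get(c, 0.0)) for c in categories})
        if any_fn:
            rec["scoring_fn"] = row.scoring_fn.serialize() if row.scoring_fn else ""
        records.append(rec)
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


def read_sustainability_table(
    path: Union[str, Path],
    model: MetabolicModel,
    policy: Union[str, Iterable[str]] = "zero",
    registry: Optional[CategoryRegistry] = None,
) -> SustainabilityTable:
    """Read a sustainability CSV and validate it against a model.

    ``policy`` controls exchanges of the model that the table does not
    cover: ``"zero"`` adds all-zero rows (one warning per exchange),
    ``"error"`` rejects, and an iterable of ids requires exactly those to
    be present while zero-filling the rest silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    registry = registry if registry is not None else DEFAULT_REGISTRY
    frame = pd.read_csv(path)
    if "exchange_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'exchange_id'")
    category_columns = [
        c for c in frame.columns if c not in ("exchange_id", "econ", "scoring_fn")
    ]
    for cat in category_columns:
        if cat not in registry:
            raise UnknownCategoryError(cat)

    table = SustainabilityTable(registry=registry.copy())
    for _, record in frame.iterrows():
        key = str(record["exchange_id"])
        env: Dict[str, float] = {}
        soc: Dict[str, float] = {}
        for cat in category_columns:
            value = record[cat]
            if pd.isna(value):
                continue
            if registry.pillar_of(cat) == "env":
                env[cat] = float(value)
            else:
                soc[cat] = float(value)
        fn = None
        if "scoring_fn" in frame.columns and not pd.isna(record["scoring_fn"]):
            text = str(record["scoring_fn"]).strip()
            if text:
                fn = ScoringFunction.parse(text)
        econ = 0.0 if "econ" not in frame.columns or pd.isna(record["econ"]) else float(record["econ"])
        table.add_row(SustainabilityRow(key=key, econ=econ, env=env, soc=soc, scoring_fn=fn))

    table.validate_against(model)

    covered = set(table.rows)
    missing = [ex for ex in model.exchange_ids if ex not in covered]
    if isinstance(policy, str):
        if policy == "error":
            if missing:
                raise ValueError(
                    "sustainability table misses model exchanges: " + ", ".join(missing)
                )
        elif policy == "zero":
            for ex in missing:
                warnings.warn(
                    f"exchange {ex!r} has no sustainability row; using zero coefficients",
                    UserWarning,
                    stacklevel=2,
                )
                table.add_row(SustainabilityRow(key=ex))
        else:
            raise ValueError(f"unknown policy {policy!r}; use 'zero', 'error' or an id list")
    else:
        required = set(policy)
        absent = sorted(required - covered)
        if absent:
            raise ValueError(
                "sustainability table misses required exchanges: " + ", ".join(absent)
            )
        for ex in missing:
            table.add_row(SustainabilityRow(key=ex))
    return table


# ---------------------------------------------------------------------------
# Weight scheme config (JSON)
# ---------------------------------------------------------------------------

def load_weights(path: Union[str, Path]) -> WeightScheme:
    path = Path(path)
    data = json.loads(path.read_text())
    if "norm_refs" not in data:
        warnings.warn(
            f"{path}: no normalization references given; all categories default "
            "to a reference of 1.0",
            UserWarning,
            stacklevel=2,
        )
    return WeightScheme.from_dict(data)


def save_weights(weights: WeightScheme, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(weights.to_dict(), indent=2, sort_keys=True) + "\n")
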