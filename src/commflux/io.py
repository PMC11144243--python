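"""Model reading, writing and validation.

Two formats are supported:

* ``json`` — a flat fixture dialect defined by this package: a document with
  ``id``, ``metabolites[]``, ``reactions[]`` and ``biomass_reaction`` keys,
  coefficients as plain decimal numbers, and "unbounded" bounds serialized as
  the numeric ±1000 cap (never infinity literals).
* ``sbml`` — SBML Level 3 with the flux-balance-constraints extension, read
  and written through cobrapy.  Missing charge/formula annotations are
  tolerated on read.

The elemental-balance check parses chemical formulas (``C6H12O6`` style) and
reports the net per-element imbalance of every non-boundary reaction whose
participants all carry formulas.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .model import (
    COMMUNITY_POOL,
    CYTOSOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    Metabolite,
    ModelValidationError,
    Reaction,
    StrainModel,
)


class ModelParseError(ValueError):
    """The file could not be parsed as a model in the declared format."""


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------

def _clamp(value: float) -> float:
    if value == math.inf:
        return DEFAULT_BOUND
    if value == -math.inf:
        return -DEFAULT_BOUND
    return float(value)


def model_to_dict(model: StrainModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": _clamp(r.lower_bound),
                "upper_bound": _clamp(r.upper_bound),
                "is_objective": bool(r.is_objective),
            }
            for r in model.reactions.values()
        ],
        "biomass_reaction": model.biomass_reaction_id,
        "exchange_reactions": list(model.exchange_reaction_ids),
    }


def model_from_dict(doc: dict) -> StrainModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", CYTOSOL),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in doc["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=_clamp(float(r.get("lower_bound", 0.0))),
                upper_bound=_clamp(float(r.get("upper_bound", DEFAULT_BOUND))),
                is_objective=bool(r.get("is_objective", False)),
            )
            for r in doc["reactions"]
        ]
        biomass = doc["biomass_reaction"]
        exchanges = doc.get("exchange_reactions")
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"malformed model document: missing/bad {exc}") from exc
    return StrainModel.from_components(
        doc.get("id", "model"), metabolites, reactions, biomass, exchanges
    )


# --------------------------------------------------------------------------
# SBML via cobrapy
# --------------------------------------------------------------------------

_COMPARTMENT_NAMES = {
    CYTOSOL: "cytosol",
    EXTRACELLULAR: "extracellular space",
    COMMUNITY_POOL: "community pool",
}


def to_cobra(model: StrainModel):
    """Convert to a cobrapy Model (used for SBML serialization and as an
    interoperability bridge)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            m.id,
            name=m.name or m.id,
            compartment=m.compartment,
            formula=m.formula,
            charge=m.charge,
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions.values():
        crxn = cobra.Reaction(r.id)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        crxn.bounds = (r.lower_bound, r.upper_bound)
    cm.objective = model.biomass_reaction_id
    cm.compartments = {k: _COMPARTMENT_NAMES.get(k, k) for k in cm.compartments}
    return cm


def from_cobra(cmodel, biomass_reaction_id: Optional[str] = None) -> StrainModel:
    from cobra.util.solver import linear_reaction_coefficients

    if biomass_reaction_id is None:
        coeffs = linear_reaction_coefficients(cmodel)
        if len(coeffs) != 1:
            raise ModelValidationError(
                f"model {cmodel.id!r}: expected exactly one objective reaction, "
                f"found {sorted(r.id for r in coeffs)}"
            )
        biomass_reaction_id = next(iter(coeffs)).id
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment if m.compartment in _COMPARTMENT_NAMES else CYTOSOL,
            formula=m.formula or None,
            # libsbml reports an unset FBC charge as 0; the two are not
            # distinguishable after a round trip, so 0 normalizes to "absent"
            charge=m.charge if m.charge else None,
        )
        for m in cmodel.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=_clamp(r.lower_bound),
            upper_bound=_clamp(r.upper_bound),
            is_objective=(r.id == biomass_reaction_id),
        )
        for r in cmodel.reactions
    ]
    return StrainModel.from_components(cmodel.id, metabolites, reactions,
                                       biomass_reaction_id)


# --------------------------------------------------------------------------
# read / write front ends
# --------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in {".xml", ".sbml"}:
        return "sbml"
    return "json"


def read_model(path, format: Optional[str] = None) -> StrainModel:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelParseError(f"cannot parse {path} as model JSON: {exc}") from exc
        return model_from_dict(doc)
    if fmt == "sbml":
        import cobra.io

        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of error types
            raise ModelParseError(f"cannot parse {path} as SBML: {exc}") from exc
        return from_cobra(cmodel)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: StrainModel, path, format: Optional[str] = None) -> None:
    model.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n")
    elif fmt == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# --------------------------------------------------------------------------
# elemental balance
# --------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> Dict[str, float]:
    counts: Dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(count) if count else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def check_mass_balance(
    model: StrainModel,
    exempt_reaction_ids: Optional[Iterable[str]] = None,
    tolerance: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction element-imbalance report.

    Exchange reactions, the biomass pseudo-reaction and any explicitly
    exempted reactions (e.g. community import/export) are skipped.  Reactions
    with a participant lacking a formula are reported with status
    ``unchecked``; every other reaction contributes one ``imbalanced`` row per
    element with nonzero net production.  A balanced, fully annotated model
    yields an empty report.
    """
    exempt = set(exempt_reaction_ids or [])
    exempt.update(model.exchange_reaction_ids)
    exempt.add(model.biomass_reaction_id)
    exempt.update(r.id for r in model.reactions.values() if r.is_objective)

    rows: List[dict] = []
    for rxn in model.reactions.values():
        if rxn.id in exempt:
            continue
        formulas = {}
        missing = False
        for met_id in rxn.stoichiometry:
            formula = model.metabolites[met_id].formula
            if not formula:
                missing = True
                break
            formulas[met_id] = parse_formula(formula)
        if missing:
            rows.append(
                {"reaction_id": rxn.id, "element": "", "net_imbalance": float("nan"),
                 "status": "unchecked"}
            )
            continue
        net: Dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for element, count in formulas[met_id].items():
                net[element] = net.get(element, 0.0) + coef * count
        for element in sorted(net):
            if abs(net[element]) > tolerance:
                rows.append(
                    {"reaction_id": rxn.id, "element": element,
                     "net_imbalance": net[element], "status": "imbalanced"}
                )
    return pd.DataFrame(rows, columns=["reaction_id", "element", "net_imbalance", "status"])


def write_mass_balance_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
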