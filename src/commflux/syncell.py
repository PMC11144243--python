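"""Key-reaction identification and synthetic-cell construction.

Given a community function — the community growth rate, one member's growth
rate, or a designated reaction flux (e.g. pollutant consumption at the
pool) — a reaction is *essential* (ER) if constraining it alone to zero
drives the function optimum below a relative floor, and *helpful* (HR) if,
transplanted alone into a chassis (with its transport prerequisites), it
improves the chassis's function by more than a relative gain threshold δ.
Transplanting the key reactions into a chassis strain yields a synthetic
cell intended to recover the community's performance single-handedly.

Essentiality is single-knockout (not set-wise minimal-cut), matching the
small essential-reaction counts such analyses report; the FVA pre-filter at
objective fraction γ only skips reactions that some optimum already leaves
idle, so the confirmed result equals exhaustive knockout enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import lp as _lp
from .community import NAMESPACE_SEP, CommunityModel
from .media import Medium
from .model import (
    COMMUNITY_POOL,
    EXTRACELLULAR,
    Metabolite,
    Reaction,
    StrainModel,
    base_id,
)

COMMUNITY_DONOR = "community"


class FunctionError(ValueError):
    """Target function unachievable or unresolvable on the given model."""


class TransplantError(ValueError):
    """A transplant cannot be mapped unambiguously into the chassis."""


@dataclass
class TargetFunction:
    """What to optimize: community biomass, one member's biomass, or a flux."""

    kind: str
    reaction_id: Optional[str] = None
    strain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in {"community_biomass", "member_biomass", "reaction_flux"}:
            raise ValueError(f"unknown target function kind {self.kind!r}")
        if self.kind == "reaction_flux" and not self.reaction_id:
            raise ValueError("reaction_flux function requires reaction_id")
        if self.kind == "member_biomass" and not self.strain:
            raise ValueError("member_biomass function requires strain")

    def label(self) -> str:
        if self.kind == "member_biomass":
            return f"member_biomass:{self.strain}"
        if self.kind == "reaction_flux":
            return f"reaction_flux:{self.reaction_id}"
        return "community_biomass"

    def objective_for(self, model) -> Optional[str]:
        """Resolve to an objective reaction id (None = model default)."""
        if isinstance(model, CommunityModel):
            if self.kind == "community_biomass":
                return None
            if self.kind == "member_biomass":
                if self.strain not in model.member_biomass:
                    raise FunctionError(f"strain {self.strain!r} not in community")
                return model.member_biomass[self.strain]
            if self.reaction_id in model.reactions:
                return self.reaction_id
            raise FunctionError(f"reaction {self.reaction_id!r} not in community")
        # single model: any biomass-flavoured function is its own objective
        if self.kind in {"community_biomass", "member_biomass"}:
            return None
        rid = self.reaction_id
        if rid in model.reactions:
            return rid
        # community import/export functions map to the chassis exchange
        for prefix in ("IP_", "OP_"):
            if rid.startswith(prefix):
                candidate = f"EX_{rid[len(prefix):]}"
                if candidate in model.reactions:
                    return candidate
        raise FunctionError(f"reaction {rid!r} not resolvable on model {model.id!r}")


@dataclass
class KeyReactionSet:
    essential: List[Tuple[str, str]]  # (reaction id, donor strain)
    helpful: List[Tuple[str, str, float]]  # (reaction id, donor, relative gain)
    function: str
    medium: str

    def __post_init__(self) -> None:
        er = {r for r, _ in self.essential}
        if er & {r for r, _, _ in self.helpful}:
            raise ValueError("essential and helpful sets must be disjoint")

    def essential_ids(self) -> List[str]:
        return [r for r, _ in self.essential]

    def to_frames(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        er = pd.DataFrame(
            [{"reaction_id": r, "donor": d, "gain": ""} for r, d in self.essential],
            columns=["reaction_id", "donor", "gain"],
        )
        hr = pd.DataFrame(
            [{"reaction_id": r, "donor": d, "gain": g} for r, d, g in self.helpful],
            columns=["reaction_id", "donor", "gain"],
        )
        return er, hr


@dataclass
class SyntheticCell:
    chassis: str
    transplanted: List[Tuple[str, str]]  # (reaction id in cell, donor)
    skipped: List[Tuple[str, str, str]]  # (reaction id, donor, reason)
    model: StrainModel


def _donor_of(reaction_id: str) -> str:
    if NAMESPACE_SEP in reaction_id:
        return reaction_id.split(NAMESPACE_SEP, 1)[0]
    return COMMUNITY_DONOR


def _abolished_threshold(intact: float) -> float:
    return max(1e-6 * intact, 1e-9)


def find_essential_reactions(
    cm: CommunityModel,
    function: TargetFunction,
    medium: Medium,
    candidates: Optional[Sequence[str]] = None,
    tolerances: _lp.Tolerances = _lp.DEFAULT_TOLERANCES,
) -> List[Tuple[str, str]]:
    """Reactions whose single knockout abolishes the target function.

    The default candidate set is the FVA pre-filter at γ: only reactions whose
    flux cannot be zero in any γ-optimal solution can be essential, and each
    surviving candidate is still confirmed by an explicit knockout, so the
    result is independent of the pre-filter.
    """
    obj_id = function.objective_for(cm)
    base = _lp.fba(cm, medium, obj_id)
    if base.status != _lp.OPTIMAL or base.objective_value <= tolerances.zero_flux:
        raise FunctionError(
            f"target function {function.label()} not achievable on the intact "
            f"community (status {base.status}, optimum {base.objective_value:.3g})"
        )
    threshold = _abolished_threshold(base.objective_value)
    if candidates is None:
        intervals = _lp.fva(cm, medium, gamma=tolerances.gamma, objective_id=obj_id,
                            tolerances=tolerances)
        candidates = [
            iv.reaction_id
            for iv in intervals
            if iv.min_flux > tolerances.zero_flux or iv.max_flux < -tolerances.zero_flux
        ]
    ko = _lp.single_knockouts(cm, medium, list(candidates), obj_id)
    return [(rid, _donor_of(rid)) for rid, val in sorted(ko.items()) if val < threshold]


# --------------------------------------------------------------------------
# transplantation
# --------------------------------------------------------------------------

def _normalized_stoich(rxn: Reaction) -> Tuple[Tuple[str, float], ...]:
    return tuple(sorted((m, float(c)) for m, c in rxn.stoichiometry.items()))


def _is_carrier(rxn: Reaction, donor: StrainModel) -> bool:
    comps = {donor.metabolites[m].compartment for m in rxn.stoichiometry}
    return rxn.id in donor.exchange_reaction_ids or len(comps) > 1


def carrier_closure(donor: StrainModel, reaction_id: str) -> List[str]:
    """Transport/exchange prerequisites of a donor reaction.

    Collects, to a fixpoint, every donor transport or exchange touching a
    metabolite (by base id) reachable from the seed reaction — the minimal
    plumbing a transplanted pathway step needs to reach substrates and
    dispose of products.
    """
    seed = donor.reactions[reaction_id]
    bases = {base_id(m) for m in seed.stoichiometry}
    chosen: List[str] = []
    changed = True
    while changed:
        changed = False
        for rxn in donor.reactions.values():
            if rxn.id == reaction_id or rxn.is_objective or rxn.id in chosen:
                continue
            if not _is_carrier(rxn, donor):
                continue
            rxn_bases = {base_id(m) for m in rxn.stoichiometry}
            if rxn_bases & bases:
                chosen.append(rxn.id)
                if not rxn_bases <= bases:
                    bases |= rxn_bases
                    changed = True
    return sorted(chosen)


def build_synthetic_cell(
    chassis: StrainModel,
    transplants: Sequence[Tuple[StrainModel, str]],
    cell_id: Optional[str] = None,
) -> SyntheticCell:
    """Add donor reactions (with their metabolites) to a chassis model.

    Metabolites are matched by id; missing ones are created in the chassis
    with the donor's compartment, formula and charge.  Reactions already
    present with identical stoichiometry are skipped; an id collision with
    different stoichiometry is resolved by suffixing the donor id, and a
    donor metabolite living in the community-pool compartment is rejected
    (its member-level counterpart must be transplanted instead).
    """
    model = chassis.copy(cell_id or f"{chassis.id}_syn")
    existing = {_normalized_stoich(r): rid for rid, r in model.reactions.items()}
    transplanted: List[Tuple[str, str]] = []
    skipped: List[Tuple[str, str, str]] = []
    for donor, rid in transplants:
        rxn = donor.reactions[rid]
        if rxn.is_objective:
            skipped.append((rid, donor.id, "biomass reaction"))
            continue
        for met_id in rxn.stoichiometry:
            met = donor.metabolites[met_id]
            if met.compartment == COMMUNITY_POOL:
                raise TransplantError(
                    f"reaction {rid!r} references pool metabolite {met_id!r}; "
                    "transplant the member-level reaction instead"
                )
            if met_id in model.metabolites:
                if model.metabolites[met_id].compartment != met.compartment:
                    raise TransplantError(
                        f"metabolite {met_id!r} maps to different compartments "
                        f"in chassis and donor {donor.id!r}"
                    )
            else:
                model.metabolites[met_id] = Metabolite(
                    id=met_id, name=met.name, compartment=met.compartment,
                    formula=met.formula, charge=met.charge,
                )
        key = _normalized_stoich(rxn)
        if key in existing:
            skipped.append((rid, donor.id, f"duplicate of {existing[key]}"))
            continue
        new_id = rid if rid not in model.reactions else f"{rid}{NAMESPACE_SEP}{donor.id}"
        if new_id in model.reactions:
            raise TransplantError(f"reaction id collision on {new_id!r}")
        new_rxn = Reaction(new_id, dict(rxn.stoichiometry), rxn.lower_bound,
                           rxn.upper_bound, is_objective=False)
        model.reactions[new_id] = new_rxn
        existing[key] = new_id
        if rid in donor.exchange_reaction_ids:
            model.exchange_reaction_ids.append(new_id)
        transplanted.append((new_id, donor.id))
    model.validate()
    return SyntheticCell(chassis=chassis.id, transplanted=transplanted,
                         skipped=skipped, model=model)


def transplants_from_community(
    cm: CommunityModel, reaction_ids: Iterable[str], chassis_id: str
) -> Tuple[List[Tuple[StrainModel, str]], List[Tuple[str, str]]]:
    """Map community-namespace key reactions to donor-level transplants.

    Reactions of the chassis itself and community import/export plumbing are
    dropped (the latter corresponds to medium access, not to a member
    enzyme); member↔pool links map back to the donor's plain exchange.
    Returns (transplants, dropped-with-reason).
    """
    transplants: List[Tuple[StrainModel, str]] = []
    dropped: List[Tuple[str, str]] = []
    for rid in reaction_ids:
        if NAMESPACE_SEP not in rid:
            dropped.append((rid, "community import/export"))
            continue
        sid, local = rid.split(NAMESPACE_SEP, 1)
        if sid == chassis_id:
            dropped.append((rid, "already in chassis"))
            continue
        transplants.append((cm.members[sid], local))
    return transplants, dropped


def find_helpful_reactions(
    donors: Sequence[StrainModel],
    chassis: StrainModel,
    function: TargetFunction,
    medium: Medium,
    tolerances: _lp.Tolerances = _lp.DEFAULT_TOLERANCES,
    exclude_ids: Optional[Iterable[str]] = None,
) -> List[Tuple[str, str, float, List[str]]]:
    """Donor reactions whose lone transplant improves the chassis function.

    Each candidate is transplanted together with its transport prerequisites
    (``carrier_closure``); the recorded relative gain is
    (F_new − F_base) / max(F_base, ε).  Entries with gain > δ that are not in
    ``exclude_ids`` (e.g. already essential) are returned sorted by gain,
    as (reaction id, donor, gain, prerequisite bundle).
    """
    exclude = set(exclude_ids or [])
    base_obj = function.objective_for(chassis)
    base_sol = _lp.fba(chassis, medium, base_obj)
    f_base = base_sol.objective_value if base_sol.status == _lp.OPTIMAL else 0.0
    chassis_stoich = {_normalized_stoich(r) for r in chassis.reactions.values()}
    results: List[Tuple[str, str, float, List[str]]] = []
    for donor in donors:
        for rxn in donor.reactions.values():
            if rxn.is_objective or rxn.id in exclude:
                continue
            if _normalized_stoich(rxn) in chassis_stoich:
                continue  # identical reaction already present: gain 0
            bundle = carrier_closure(donor, rxn.id)
            try:
                cell = build_synthetic_cell(
                    chassis, [(donor, rxn.id)] + [(donor, b) for b in bundle]
                )
            except TransplantError:
                continue
            try:
                obj_id = function.objective_for(cell.model)
            except FunctionError:
                continue
            sol = _lp.fba(cell.model, medium, obj_id)
            f_new = sol.objective_value if sol.status == _lp.OPTIMAL else 0.0
            gain = (f_new - f_base) / max(f_base, tolerances.zero_flux)
            if gain > tolerances.helpful_gain:
                results.append((rxn.id, donor.id, gain, bundle))
    results.sort(key=lambda t: (-t[2], t[0], t[1]))
    return results


def compare_performance(
    entities: Mapping[str, object],
    media: Sequence[Medium],
    function: TargetFunction,
) -> pd.DataFrame:
    """Function optimum per (entity, medium); failures recorded as NaN."""
    rows = {}
    for name, entity in entities.items():
        row = {}
        for medium in media:
            try:
                obj_id = function.objective_for(entity)
                sol = _lp.fba(entity, medium, obj_id)
                row[medium.name] = (
                    sol.objective_value if sol.status == _lp.OPTIMAL else float("nan")
                )
            except (FunctionError, _lp.ObjectiveError):
                row[medium.name] = float("nan")
        rows[name] = row
    return pd.DataFrame(
        [rows[name] for name in rows],
        index=list(rows),
        columns=[m.name for m in media],
    )
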