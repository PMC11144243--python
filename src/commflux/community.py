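"""Compartmented community models with a shared extracellular pool.

``build_community`` wires N single-strain models into one flat LP-ready
model: every member keeps its own reactions under a ``<strain>__`` namespace,
each member's former environment-facing exchange becomes a member↔pool link,
and every extracellular metabolite present in at least one member joins the
shared pool (suffix ``_com``) with one community import (IP) and one export
(OP) reaction.  Steady state on a pool metabolite *a* is then exactly the
community balance  Σ_k v[ex]_a^k + IP_a − OP_a = 0.

The community objective is the weighted sum of member biomass fluxes,
Σ_k c^k·v_biomass^k, optionally constrained by one of four abundance
scenarios.  "Abundance" is interpreted on biomass fluxes (h⁻¹) — the only
reading available to a steady-state framework:

* ``equal``  — all member growth rates equal;
* ``free``   — no coupling, any member may sit at zero;
* ``target`` — the objective is the biomass of one designated member;
* ``fixed``  — member growth rates locked to given proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import lp as _lp
from .media import Medium
from .model import (
    COMMUNITY_POOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    Metabolite,
    ModelValidationError,
    Reaction,
    StrainModel,
    base_id,
)

NAMESPACE_SEP = "__"
POOL_SUFFIX = "_com"


def member_prefix(strain_id: str) -> str:
    return f"{strain_id}{NAMESPACE_SEP}"


def pool_metabolite_id(met_base: str) -> str:
    return f"{met_base}{POOL_SUFFIX}"


@dataclass
class AbundanceScenario:
    mode: str
    target_strain: Optional[str] = None
    weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in {"equal", "free", "target", "fixed"}:
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if self.mode == "target":
            if not self.target_strain:
                raise ValueError("target scenario requires target_strain")
        elif self.target_strain is not None:
            raise ValueError("target_strain only valid for mode='target'")
        if self.mode == "fixed":
            if not self.weights:
                raise ValueError("fixed scenario requires weights")
            total = sum(self.weights.values())
            if any(w < 0 for w in self.weights.values()):
                raise ValueError("fixed weights must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fixed weights must sum to 1, got {total}")
        elif self.weights is not None:
            raise ValueError("weights only valid for mode='fixed'")


FREE = AbundanceScenario("free")
EQUAL = AbundanceScenario("equal")


@dataclass
class CommunityModel:
    """Namespaced member models joined through a shared extracellular pool."""

    id: str
    members: Dict[str, StrainModel]
    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    member_biomass: Dict[str, str]
    #: (strain id, shared-metabolite base id) -> link reaction id
    links: Dict[Tuple[str, str], str]
    import_reactions: Dict[str, str]
    export_reactions: Dict[str, str]
    shared_metabolites: List[str]
    scenario: AbundanceScenario
    objective_weights: Dict[str, float]

    # -- LP hooks ---------------------------------------------------------
    def objective_map(self, objective_id: Optional[str] = None) -> Dict[str, float]:
        if objective_id is not None:
            if objective_id not in self.reactions:
                raise KeyError(f"objective reaction {objective_id!r} not in community")
            return {objective_id: 1.0}
        if self.scenario.mode == "target":
            return {self.member_biomass[self.scenario.target_strain]: 1.0}
        if self.scenario.mode == "fixed":
            # growth rates are locked to proportions; maximize the common
            # community growth mu through the first positively weighted member
            for sid, w in self.scenario.weights.items():
                if w > 0:
                    return {self.member_biomass[sid]: 1.0 / w}
            raise ModelValidationError("fixed scenario has no positive weight")
        return {self.member_biomass[k]: self.objective_weights[k] for k in self.members}

    def coupling_rows(self) -> List[Tuple[Dict[str, float], float]]:
        rows: List[Tuple[Dict[str, float], float]] = []
        sids = list(self.members)
        if self.scenario.mode == "equal":
            for a, b in zip(sids, sids[1:]):
                rows.append(
                    ({self.member_biomass[a]: 1.0, self.member_biomass[b]: -1.0}, 0.0)
                )
        elif self.scenario.mode == "fixed":
            w = self.scenario.weights
            positive = [s for s in sids if w.get(s, 0.0) > 0]
            for s in sids:
                if w.get(s, 0.0) == 0.0:
                    rows.append(({self.member_biomass[s]: 1.0}, 0.0))
            for a, b in zip(positive, positive[1:]):
                rows.append(
                    ({self.member_biomass[a]: w[b], self.member_biomass[b]: -w[a]}, 0.0)
                )
        return rows

    def lp_bounds(self, medium: Optional[Medium] = None) -> Dict[str, tuple]:
        bounds = {
            rid: (r.lower_bound, r.upper_bound) for rid, r in self.reactions.items()
        }
        if medium is not None:
            for met_base, rid in self.import_reactions.items():
                bounds[rid] = (0.0, medium.uptake_allowance(met_base))
        return bounds

    def import_reaction_ids(self) -> List[str]:
        return list(self.import_reactions.values())

    def link_reaction_ids(self) -> List[str]:
        return list(self.links.values())

    def boundary_exempt_ids(self) -> List[str]:
        """Reactions exempt from elemental balance: links, IP/OP, biomass."""
        ids = list(self.links.values())
        ids += list(self.import_reactions.values())
        ids += list(self.export_reactions.values())
        ids += list(self.member_biomass.values())
        return ids

    def as_strain_model(self) -> StrainModel:
        """Flat single-objective view (first member's biomass flagged); used
        only for serialization through model_io."""
        rxns = {k: v.copy() for k, v in self.reactions.items()}
        first_bio = next(iter(self.member_biomass.values()))
        for rid, r in rxns.items():
            r.is_objective = rid == first_bio
        return StrainModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=rxns,
            biomass_reaction_id=first_bio,
            exchange_reaction_ids=[],
        )


@dataclass
class CommunitySolution:
    status: str
    community_objective: float
    member_biomass: Dict[str, float]
    fluxes: Dict[str, float]
    member_exchanges: Dict[str, Dict[str, float]]
    pool_import: Dict[str, float]
    pool_export: Dict[str, float]
    max_residual: float = 0.0
    scenario_objective: float = 0.0
    total_import_flux: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == _lp.OPTIMAL


class CommunityBuildError(ValueError):
    pass


def build_community(
    strains: Sequence[StrainModel],
    scenario: AbundanceScenario = FREE,
    weights_c: Optional[Mapping[str, float]] = None,
    community_id: Optional[str] = None,
    cap: float = DEFAULT_BOUND,
) -> CommunityModel:
    """Assemble single-strain models into one compartmented community model.

    Member intracellular reactions are copied verbatim under the
    ``<strain>__`` namespace; each former exchange ``M_e ->`` becomes the
    link ``<strain>__M_e -> M_com`` carrying v[ex] (positive = secretion into
    the pool), and each shared metabolite gets one IP (``-> M_com``, bounded
    by the active medium) and one OP (``M_com ->``, bounded [0, cap]).
    """
    if not strains:
        raise CommunityBuildError("need at least one strain")
    sids = [s.id for s in strains]
    if len(set(sids)) != len(sids):
        raise CommunityBuildError(f"duplicate strain ids in {sids}")
    for s in strains:
        s.validate()
    if scenario.mode == "target" and scenario.target_strain not in sids:
        raise CommunityBuildError(
            f"target strain {scenario.target_strain!r} not among members {sids}"
        )
    if scenario.mode == "fixed" and set(scenario.weights) != set(sids):
        raise CommunityBuildError("fixed weights must cover exactly the member set")

    metabolites: Dict[str, Metabolite] = {}
    reactions: Dict[str, Reaction] = {}
    member_biomass: Dict[str, str] = {}
    links: Dict[Tuple[str, str], str] = {}
    shared: Dict[str, Metabolite] = {}

    for strain in strains:
        pre = member_prefix(strain.id)
        for met in strain.metabolites.values():
            metabolites[pre + met.id] = Metabolite(
                id=pre + met.id,
                name=met.name,
                compartment=met.compartment,
                formula=met.formula,
                charge=met.charge,
            )
        exchange_ids = set(strain.exchange_reaction_ids)
        for rxn in strain.reactions.values():
            nsid = pre + rxn.id
            stoich = {pre + mid: coef for mid, coef in rxn.stoichiometry.items()}
            if rxn.id in exchange_ids:
                met_id = strain.exchange_metabolite(rxn.id)
                met = strain.metabolites[met_id]
                mb = base_id(met_id)
                pool_id = pool_metabolite_id(mb)
                if mb not in shared:
                    shared[mb] = Metabolite(
                        id=pool_id,
                        name=met.name,
                        compartment=COMMUNITY_POOL,
                        formula=met.formula,
                        charge=met.charge,
                    )
                stoich[pool_id] = -stoich[pre + met_id]
                links[(strain.id, mb)] = nsid
            reactions[nsid] = Reaction(
                id=nsid,
                stoichiometry=stoich,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                is_objective=False,
            )
        member_biomass[strain.id] = pre + strain.biomass_reaction_id

    import_reactions: Dict[str, str] = {}
    export_reactions: Dict[str, str] = {}
    for mb, pool_met in sorted(shared.items()):
        metabolites[pool_met.id] = pool_met
        ip_id, op_id = f"IP_{mb}", f"OP_{mb}"
        reactions[ip_id] = Reaction(ip_id, {pool_met.id: 1.0}, 0.0, 0.0)
        reactions[op_id] = Reaction(op_id, {pool_met.id: -1.0}, 0.0, cap)
        import_reactions[mb] = ip_id
        export_reactions[mb] = op_id

    if weights_c is None:
        objective_weights = {sid: 1.0 for sid in sids}
    else:
        if any(w < 0 for w in weights_c.values()):
            raise CommunityBuildError("objective weights must be non-negative")
        objective_weights = {sid: float(weights_c.get(sid, 0.0)) for sid in sids}

    return CommunityModel(
        id=community_id or "+".join(sids),
        members={s.id: s for s in strains},
        metabolites=metabolites,
        reactions=reactions,
        member_biomass=member_biomass,
        links=links,
        import_reactions=import_reactions,
        export_reactions=export_reactions,
        shared_metabolites=sorted(shared),
        scenario=scenario,
        objective_weights=objective_weights,
    )


def _decompose(cm: CommunityModel, solution: _lp.FluxSolution) -> CommunitySolution:
    if solution.status != _lp.OPTIMAL:
        return CommunitySolution(
            status=solution.status,
            community_objective=float("nan"),
            member_biomass={},
            fluxes={},
            member_exchanges={},
            pool_import={},
            pool_export={},
        )
    fluxes = solution.fluxes
    member_biomass = {sid: fluxes[rid] for sid, rid in cm.member_biomass.items()}
    member_exchanges: Dict[str, Dict[str, float]] = {sid: {} for sid in cm.members}
    for (sid, mb), rid in cm.links.items():
        member_exchanges[sid][mb] = fluxes[rid]
    community_objective = sum(
        cm.objective_weights[sid] * member_biomass[sid] for sid in cm.members
    )
    return CommunitySolution(
        status=_lp.OPTIMAL,
        community_objective=community_objective,
        member_biomass=member_biomass,
        fluxes=fluxes,
        member_exchanges=member_exchanges,
        pool_import={mb: fluxes[rid] for mb, rid in cm.import_reactions.items()},
        pool_export={mb: fluxes[rid] for mb, rid in cm.export_reactions.items()},
        max_residual=solution.max_residual,
        scenario_objective=solution.objective_value,
        total_import_flux=solution.total_import_flux,
    )


def community_fba(
    cm: CommunityModel, medium: Medium, objective_id: Optional[str] = None
) -> CommunitySolution:
    """Maximize the scenario objective over the community LP (Eqs. of the
    community balance + member steady states + scenario coupling)."""
    return _decompose(cm, _lp.fba(cm, medium, objective_id))


def community_pfba(
    cm: CommunityModel,
    medium: Medium,
    objective_id: Optional[str] = None,
    tolerances: _lp.Tolerances = _lp.DEFAULT_TOLERANCES,
    minimize: str = "all",
) -> CommunitySolution:
    return _decompose(
        cm, _lp.pfba(cm, medium, objective_id, tolerances=tolerances, minimize=minimize)
    )


def biomass_ratio_scan(
    cm: CommunityModel,
    substrate_id: str,
    levels: Sequence[float],
    medium: Medium,
) -> pd.DataFrame:
    """Community growth across substrate availabilities (free scenario).

    For each level the substrate's import bound is set to the level with all
    other medium entries fixed.  Ratios between member biomasses are reported
    with a 0/0 guard (NaN = undefined).
    """
    mb = base_id(substrate_id)
    if mb not in cm.shared_metabolites:
        raise KeyError(f"substrate {substrate_id!r} not in the community pool")
    if any(l < 0 for l in levels):
        raise ValueError("availability levels must be non-negative")
    scan_cm = cm
    if cm.scenario.mode != "free":
        scan_cm = build_community(
            list(cm.members.values()), FREE,
            weights_c=cm.objective_weights, community_id=cm.id,
        )
    sids = list(scan_cm.members)
    rows = []
    for level in levels:
        sol = community_fba(scan_cm, medium.with_import(mb, level))
        row = {"availability": float(level), "status": sol.status,
               "community_biomass": sol.community_objective if sol.optimal else float("nan")}
        for sid in sids:
            row[f"biomass_{sid}"] = sol.member_biomass.get(sid, float("nan"))
        for i, a in enumerate(sids):
            for b in sids[i + 1:]:
                va, vb = row[f"biomass_{a}"], row[f"biomass_{b}"]
                row[f"ratio_{b}:{a}"] = (
                    vb / va if sol.optimal and not math.isclose(va, 0.0, abs_tol=1e-12)
                    else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)


def solution_to_frame(sol: CommunitySolution) -> pd.DataFrame:
    return pd.DataFrame(
        {"reaction_id": list(sol.fluxes), "flux": list(sol.fluxes.values())}
    )
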