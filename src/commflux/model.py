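"""Core metabolic-model data types.

A :class:`StrainModel` is a deliberately small stoichiometric container: a set
of metabolites, a set of bounded reactions (one flagged as the biomass
objective), and the list of exchange reactions that connect the model to its
environment.  Flux units are mmol·gDW⁻¹·h⁻¹ for ordinary reactions and h⁻¹
for the biomass pseudo-reaction.

Sign conventions
----------------
Exchange reactions are written as ``M_e ->`` (a single extracellular reactant,
no product).  Positive flux is secretion to the environment; negative flux is
uptake.  This is the dominant convention in constraint-based modeling and the
one the community pool balance relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional

#: Default numeric cap standing in for "unbounded" (mmol·gDW⁻¹·h⁻¹).
DEFAULT_BOUND = 1000.0

CYTOSOL = "c"
EXTRACELLULAR = "e"
COMMUNITY_POOL = "com"
COMPARTMENTS = (CYTOSOL, EXTRACELLULAR, COMMUNITY_POOL)

_SUFFIXES = ("_com", "_e", "_c")


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


def base_id(met_id: str) -> str:
    """Strip the compartment suffix from a metabolite id.

    Extracellular metabolites are matched across strains (and against media
    definitions) by this base id, e.g. ``glc_e``, ``glc_com`` and ``glc`` all
    map to ``glc``.
    """
    for suf in _SUFFIXES:
        if met_id.endswith(suf):
            return met_id[: -len(suf)]
    return met_id


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not one of {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    """A bounded reaction; negative stoichiometric coefficients consume."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_objective: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class StrainModel:
    """A single organism's stoichiometric network with bounds and objective."""

    id: str
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str = ""
    exchange_reaction_ids: List[str] = field(default_factory=list)

    @classmethod
    def from_components(
        cls,
        model_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str,
        exchange_reaction_ids: Optional[Iterable[str]] = None,
    ) -> "StrainModel":
        mets = {m.id: m for m in metabolites}
        rxns = {r.id: r for r in reactions}
        if exchange_reaction_ids is None:
            exchange_reaction_ids = [
                r.id for r in rxns.values() if _looks_like_exchange(r, mets)
            ]
        model = cls(
            id=model_id,
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=biomass_reaction_id,
            exchange_reaction_ids=list(exchange_reaction_ids),
        )
        model.validate()
        return model

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(self.metabolites) != len({m for m in self.metabolites}):
            raise ModelValidationError("duplicate metabolite ids")
        objective_rxns = [r.id for r in self.reactions.values() if r.is_objective]
        if self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"model {self.id!r}: biomass reaction "
                f"{self.biomass_reaction_id!r} not found"
            )
        if objective_rxns != [self.biomass_reaction_id]:
            raise ModelValidationError(
                f"model {self.id!r}: expected exactly one objective reaction "
                f"({self.biomass_reaction_id!r}), found {objective_rxns}"
            )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"model {self.id!r}: reaction {rxn.id!r} references "
                        f"unknown metabolite {met_id!r}"
                    )
        for ex_id in self.exchange_reaction_ids:
            rxn = self.reactions.get(ex_id)
            if rxn is None:
                raise ModelValidationError(
                    f"model {self.id!r}: exchange reaction {ex_id!r} not found"
                )
            if len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"model {self.id!r}: exchange {ex_id!r} must involve "
                    "exactly one metabolite"
                )
            (met_id,) = rxn.stoichiometry
            if self.metabolites[met_id].compartment != EXTRACELLULAR:
                raise ModelValidationError(
                    f"model {self.id!r}: exchange {ex_id!r} metabolite "
                    f"{met_id!r} is not extracellular"
                )

    # -- accessors --------------------------------------------------------
    @property
    def biomass_reaction(self) -> Reaction:
        return self.reactions[self.biomass_reaction_id]

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def exchange_metabolite(self, ex_id: str) -> str:
        (met_id,) = self.reactions[ex_id].stoichiometry
        return met_id

    def copy(self, new_id: Optional[str] = None) -> "StrainModel":
        return StrainModel(
            id=new_id or self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            exchange_reaction_ids=list(self.exchange_reaction_ids),
        )

    # -- LP hooks (used by commflux.lp) -----------------------------------
    def objective_map(self, objective_id: Optional[str] = None) -> Dict[str, float]:
        rid = objective_id or self.biomass_reaction_id
        if rid not in self.reactions:
            raise KeyError(f"objective reaction {rid!r} not in model {self.id!r}")
        return {rid: 1.0}

    def coupling_rows(self):
        return []

    def lp_bounds(self, medium=None) -> Dict[str, tuple]:
        """Effective flux bounds with a medium applied to exchange reactions.

        A medium grants uptake (a negative lower bound) per extracellular
        metabolite, matched by base id.  Non-granted metabolites cannot be
        taken up; mineral ids in the medium's unconstrained set are granted
        at the default cap.  A medium can only restrict relative to the
        model's own bounds, never widen them.
        """
        bounds = {
            rid: (r.lower_bound, r.upper_bound) for rid, r in self.reactions.items()
        }
        if medium is None:
            return bounds
        for ex_id in self.exchange_reaction_ids:
            lb, ub = bounds[ex_id]
            met_base = base_id(self.exchange_metabolite(ex_id))
            allowance = medium.uptake_allowance(met_base)
            bounds[ex_id] = (max(lb, -allowance), ub)
        return bounds


def _looks_like_exchange(rxn: Reaction, mets: Dict[str, Metabolite]) -> bool:
    if len(rxn.stoichiometry) != 1 or rxn.is_objective:
        return False
    (met_id,) = rxn.stoichiometry
    met = mets.get(met_id)
    return met is not None and met.compartment == EXTRACELLULAR
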