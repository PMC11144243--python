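"""Deterministic small strain models and communities with known ground truth.

The toy pair emulates the essential structure of an obligate two-member
pollutant-degradation chain: strain ``A`` hydrolyzes a complex substrate S
extracellularly into an aromatic intermediate I, an amino-acid-like byproduct
P (the only nitrogen carrier) and an assimilable carbon fragment X, but lacks
any deaminase, so it cannot liberate nitrogen on its own.  Strain ``B``
consumes I as carbon and deaminates P, releasing ammonia that both members
assimilate.  Each singleton therefore grows at zero on an S-only medium while
the pair grows at a closed-form positive rate — the in-silico analogue of a
synergistic degrader consortium.  Strain ``C`` is a nitrate-assimilating
helper: it grows on a generic sugar and reduces nitrate to ammonia, secreting
the surplus.

The metabolite naming echoes that chemistry for readability (S ≈ a herbicide
ester, I ≈ its nitrile intermediate, P ≈ glycine, nh3 ≈ ammonia); the
stoichiometry is synthetic and makes no claim of biochemical fidelity, but
every non-boundary reaction is elementally balanced over CHON so the balance
checker can be exercised.

All closed-form optima recorded here are re-derived by an independent dense
LP oracle in the test suite; the generator itself verifies the planted
ground truth of random communities by knockout before returning them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .community import FREE, build_community, community_fba
from .lp import fba, single_knockouts
from .media import Medium
from .model import CYTOSOL, DEFAULT_BOUND, EXTRACELLULAR, Metabolite, Reaction, StrainModel

#: single global fixture seed; all randomness flows through one generator
DEFAULT_SEED = 20240601

_CAP = DEFAULT_BOUND

_FORMULAS = {
    "S": "C12H15NO7",   # ester substrate = I + P + X
    "I": "C7H4O2",      # nitrile-like intermediate (carbon for B)
    "M": "C7H4O2",      # hydration isomer of I
    "Y": "C7H4O2",      # assimilable aromatic acid
    "P": "C2H5NO2",     # glycine-like nitrogen carrier
    "R": "C2H5NO2",     # deamination intermediate (isomer of P)
    "Q": "C2H2O2",      # deaminated carbon skeleton, waste
    "X": "C3H6O3",      # short-chain carbon for A (half a hexose)
    "G": "C6H12O6",     # generic sugar
    "nh3": "H3N",
    "no3": "NO3",
    "h": "H",
    "h2o": "H2O",
}


@dataclass
class FixtureGroundTruth:
    """Analytic expectations recorded by a generator.

    ``optima`` maps ``"<entity>:<medium>"`` to the hand-derived FBA optimum;
    ``edges`` lists designed producer→metabolite→consumer transfers;
    ``essential`` maps a target-function label to the designed essential
    reaction ids (community namespace).
    """

    optima: Dict[str, float] = field(default_factory=dict)
    edges: List[Tuple[str, str, str]] = field(default_factory=list)
    optional_edges: List[Tuple[str, str, str]] = field(default_factory=list)
    essential: Dict[str, List[str]] = field(default_factory=dict)
    shared_metabolites: List[str] = field(default_factory=list)
    media: Dict[str, Medium] = field(default_factory=dict)
    seed: Optional[int] = None
    params: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "optima": self.optima,
            "edges": [list(e) for e in self.edges],
            "optional_edges": [list(e) for e in self.optional_edges],
            "essential": self.essential,
            "shared_metabolites": self.shared_metabolites,
            "media": {k: m.to_dict() for k, m in self.media.items()},
            "seed": self.seed,
            "params": self.params,
        }


def _met(met_id: str, compartment: str, name: str = "") -> Metabolite:
    return Metabolite(
        id=met_id,
        name=name or met_id,
        compartment=compartment,
        formula=_FORMULAS.get(met_id.rsplit("_", 1)[0]),
    )


def _strain(sid, mets, reactions, biomass) -> StrainModel:
    return StrainModel.from_components(sid, mets, reactions, biomass)


def _exchange(met_id: str) -> Reaction:
    return Reaction(f"EX_{met_id[:-2]}", {met_id: -1.0}, -_CAP, _CAP)


# --------------------------------------------------------------------------
# media presets
# --------------------------------------------------------------------------

def toy_media() -> Dict[str, Medium]:
    """The media panel used by the toy consortium.

    ``MM_S`` is the pollutant-only minimal medium (S as sole carbon and
    nitrogen source); the other media supplement or replace it with ammonia,
    sugar and nitrate, mirroring the kind of panel a degradation study
    screens.  ``MM_SCAN`` grants strain B a small baseline carbon and
    nitrogen allowance so the member biomass ratio has a floor when S runs
    out.
    """
    return {
        "MM_S": Medium("MM_S", {"S": 10.0}),
        "MM_S_NH3": Medium("MM_S_NH3", {"S": 10.0, "nh3": 10.0}),
        "MM_S_G_NO3": Medium("MM_S_G_NO3", {"S": 10.0, "G": 5.0, "no3": 10.0}),
        "MM_G_NO3": Medium("MM_G_NO3", {"G": 5.0, "no3": 10.0}),
        "MM_SCAN": Medium("MM_SCAN", {"S": 10.0, "Y": 1.0, "nh3": 0.6}),
    }


# --------------------------------------------------------------------------
# toy pair
# --------------------------------------------------------------------------

def make_toy_pair() -> Tuple[StrainModel, StrainModel, FixtureGroundTruth]:
    """Obligate syntrophic pair (deterministic, no randomness).

    Closed forms on ``MM_S`` (substrate bound u = 10), derived by hand from
    the three binding constraints (carbon of A: v_A ≤ u; carbon of B:
    v_B ≤ u; nitrogen: 0.5 v_A + 0.6 v_B ≤ u):

    * free scenario:  v_A = u, v_B = 5u/6, objective 11u/6 = 55/3;
    * equal scenario: v_A = v_B = 10u/11, objective 20u/11 = 200/11;
    * each singleton: 0.
    """
    a_mets = [
        _met("S_e", EXTRACELLULAR, "ester substrate"),
        _met("I_e", EXTRACELLULAR, "nitrile intermediate"),
        _met("P_e", EXTRACELLULAR, "amino byproduct"),
        _met("X_e", EXTRACELLULAR, "carbon fragment"),
        _met("X_c", CYTOSOL),
        _met("G_e", EXTRACELLULAR, "sugar"),
        _met("G_c", CYTOSOL),
        _met("nh3_e", EXTRACELLULAR, "ammonia"),
        _met("nh3_c", CYTOSOL),
    ]
    a_rxns = [
        _exchange("S_e"), _exchange("I_e"), _exchange("P_e"),
        _exchange("X_e"), _exchange("G_e"), _exchange("nh3_e"),
        # extracellular esterase: S -> I + P + X
        Reaction("DEG1", {"S_e": -1.0, "I_e": 1.0, "P_e": 1.0, "X_e": 1.0}, 0.0, _CAP),
        Reaction("T_X", {"X_e": -1.0, "X_c": 1.0}, 0.0, _CAP),
        Reaction("T_G", {"G_e": -1.0, "G_c": 1.0}, 0.0, _CAP),
        Reaction("GLY", {"G_c": -1.0, "X_c": 2.0}, 0.0, _CAP),
        Reaction("T_NH3", {"nh3_e": -1.0, "nh3_c": 1.0}, 0.0, _CAP),
        Reaction("GROW", {"X_c": -1.0, "nh3_c": -0.5}, 0.0, _CAP, is_objective=True),
    ]
    A = _strain("A", a_mets, a_rxns, "GROW")

    b_mets = [
        _met("I_e", EXTRACELLULAR), _met("M_e", EXTRACELLULAR),
        _met("Y_e", EXTRACELLULAR), _met("Y_c", CYTOSOL),
        _met("P_e", EXTRACELLULAR), _met("R_e", EXTRACELLULAR),
        _met("Q_e", EXTRACELLULAR, "deaminated waste"),
        _met("nh3_e", EXTRACELLULAR), _met("nh3_c", CYTOSOL),
    ]
    b_rxns = [
        _exchange("I_e"), _exchange("M_e"), _exchange("Y_e"), _exchange("P_e"),
        _exchange("R_e"), _exchange("Q_e"), _exchange("nh3_e"),
        # two-step extracellular nitrile degradation: I -> M -> Y
        Reaction("DEG2A", {"I_e": -1.0, "M_e": 1.0}, 0.0, _CAP),
        Reaction("DEG2B", {"M_e": -1.0, "Y_e": 1.0}, 0.0, _CAP),
        Reaction("T_Y", {"Y_e": -1.0, "Y_c": 1.0}, 0.0, _CAP),
        # two-step extracellular deamination: P -> R -> Q + NH3
        Reaction("DEAM1", {"P_e": -1.0, "R_e": 1.0}, 0.0, _CAP),
        Reaction("DEAM2", {"R_e": -1.0, "Q_e": 1.0, "nh3_e": 1.0}, 0.0, _CAP),
        Reaction("T_NH3", {"nh3_e": -1.0, "nh3_c": 1.0}, 0.0, _CAP),
        Reaction("GROW", {"Y_c": -1.0, "nh3_c": -0.6}, 0.0, _CAP, is_objective=True),
    ]
    B = _strain("B", b_mets, b_rxns, "GROW")

    media = toy_media()
    u = 10.0
    gt = FixtureGroundTruth(
        optima={
            "A:MM_S": 0.0,
            "B:MM_S": 0.0,
            "pair_free:MM_S": 11.0 * u / 6.0,
            "pair_free:MM_S:A": u,
            "pair_free:MM_S:B": 5.0 * u / 6.0,
            "pair_equal:MM_S": 20.0 * u / 11.0,
            "pair_free:MM_S_NH3": 2.0 * u,
            "pair_free:MM_S_G_NO3": 2.0 * u,
            "pair_free:MM_G_NO3": 0.0,
            "A_target:MM_S": u,  # target-scenario optimum for member A
        },
        edges=[("A", "I", "B"), ("A", "P", "B"), ("B", "nh3", "A")],
        essential={
            # target function: biomass of the degrader A, medium MM_S,
            # candidates = member reactions (community namespace)
            "member_A:MM_S": [
                "A__EX_S", "A__DEG1", "A__EX_I", "A__EX_P", "A__T_X",
                "A__T_NH3", "A__EX_nh3", "A__GROW",
                "B__EX_P", "B__DEAM1", "B__DEAM2", "B__EX_Q", "B__EX_nh3",
            ],
        },
        shared_metabolites=sorted(
            {"S", "I", "P", "X", "G", "nh3", "M", "Y", "R", "Q"}
        ),
        media=media,
        params={"substrate_bound": u},
    )
    return A, B, gt


# --------------------------------------------------------------------------
# nitrate helper
# --------------------------------------------------------------------------

def make_helper_strain() -> Tuple[StrainModel, FixtureGroundTruth]:
    """Nitrate-reducing helper C: grows on sugar, secretes surplus ammonia.

    Ground truth covers the trio's behaviour: on a nitrate-nitrogen medium
    the trio outgrows the pair (C converts nitrate to ammonia for A); on an
    ammonia medium without sugar it does not (C has no carbon source).
    """
    c_mets = [
        _met("G_e", EXTRACELLULAR), _met("G_c", CYTOSOL),
        _met("no3_e", EXTRACELLULAR, "nitrate"), _met("no3_c", CYTOSOL),
        _met("nh3_e", EXTRACELLULAR), _met("nh3_c", CYTOSOL),
        _met("h_e", EXTRACELLULAR), _met("h_c", CYTOSOL),
        _met("h2o_e", EXTRACELLULAR), _met("h2o_c", CYTOSOL),
    ]
    c_rxns = [
        _exchange("G_e"), _exchange("no3_e"), _exchange("nh3_e"),
        _exchange("h_e"), _exchange("h2o_e"),
        Reaction("T_G", {"G_e": -1.0, "G_c": 1.0}, 0.0, _CAP),
        Reaction("T_NO3", {"no3_e": -1.0, "no3_c": 1.0}, 0.0, _CAP),
        Reaction("T_H", {"h_e": -1.0, "h_c": 1.0}, 0.0, _CAP),
        # assimilatory nitrate reduction: NO3- + 9 H -> NH3 + 3 H2O
        Reaction("NR", {"no3_c": -1.0, "h_c": -9.0, "nh3_c": 1.0, "h2o_c": 3.0},
                 0.0, _CAP),
        Reaction("T_H2O", {"h2o_c": -1.0, "h2o_e": 1.0}, 0.0, _CAP),
        Reaction("T_NH3_SEC", {"nh3_c": -1.0, "nh3_e": 1.0}, 0.0, _CAP),
        Reaction("GROW", {"G_c": -1.0, "nh3_c": -0.3}, 0.0, _CAP, is_objective=True),
    ]
    C = _strain("C", c_mets, c_rxns, "GROW")

    media = toy_media()
    gt = FixtureGroundTruth(
        optima={
            "C:MM_G_NO3": 5.0,
            "C:MM_S": 0.0,
            "trio_free:MM_S_G_NO3": 30.0,
            "pair_free:MM_S_G_NO3": 20.0,
            "trio_free:MM_S_NH3": 20.0,
            "pair_free:MM_S_NH3": 20.0,
            "pair_free:MM_G_NO3": 0.0,
            "trio_free:MM_G_NO3": 10.0,
        },
        # B is itself a net ammonia secretor, so the helper's transfer goes
        # to A (the only net consumer)
        edges=[("C", "nh3", "A")],
        essential={
            # nitrate-reduction chain of C is essential for A's growth when
            # nitrate is the only nitrogen source
            "member_A:MM_G_NO3": ["C__NR", "C__T_NO3", "C__T_NH3_SEC"],
        },
        media=media,
        params={"sugar_bound": 5.0, "nitrate_bound": 10.0},
    )
    return C, gt


# --------------------------------------------------------------------------
# redundant-route trio (for robustness tagging)
# --------------------------------------------------------------------------

def make_redundant_trio() -> Tuple[List[StrainModel], Medium, FixtureGroundTruth]:
    """Two interchangeable producers feeding one consumer.

    ``P1`` and ``P2`` both convert a shared sugar into the same metabolite z
    that ``D`` needs as sole carbon; the producers' own direct growth yield
    is lower (0.8 per sugar) than the route through ``D`` (1.0), so at the
    optimum all carbon flows through z — but either producer can carry it,
    so every z edge is replaceable and must be tagged ``variable`` by
    FVA-based robustness classification.
    """
    def producer(sid: str) -> StrainModel:
        mets = [
            _met("G_e", EXTRACELLULAR), _met("G_c", CYTOSOL),
            Metabolite("z_e", "shared product", EXTRACELLULAR, "C6H12O6"),
            Metabolite("z_c", "shared product", CYTOSOL, "C6H12O6"),
        ]
        rxns = [
            _exchange("G_e"), _exchange("z_e"),
            Reaction("T_G", {"G_e": -1.0, "G_c": 1.0}, 0.0, _CAP),
            Reaction("REL", {"G_c": -1.0, "z_c": 1.0}, 0.0, _CAP),
            Reaction("T_Z_SEC", {"z_c": -1.0, "z_e": 1.0}, 0.0, _CAP),
            Reaction("GROW", {"G_c": -1.25}, 0.0, _CAP, is_objective=True),
        ]
        return _strain(sid, mets, rxns, "GROW")

    d_mets = [
        Metabolite("z_e", "shared product", EXTRACELLULAR, "C6H12O6"),
        Metabolite("z_c", "shared product", CYTOSOL, "C6H12O6"),
    ]
    d_rxns = [
        _exchange("z_e"),
        Reaction("T_Z", {"z_e": -1.0, "z_c": 1.0}, 0.0, _CAP),
        Reaction("GROW", {"z_c": -1.0}, 0.0, _CAP, is_objective=True),
    ]
    D = _strain("D", d_mets, d_rxns, "GROW")
    medium = Medium("MM_G", {"G": 10.0})
    gt = FixtureGroundTruth(
        optima={"community_free:MM_G": 10.0},
        optional_edges=[("P1", "z", "D"), ("P2", "z", "D")],
        media={"MM_G": medium},
    )
    return [producer("P1"), producer("P2"), D], medium, gt


# --------------------------------------------------------------------------
# seeded random communities
# --------------------------------------------------------------------------

def make_random_community(
    n: int,
    seed: int = DEFAULT_SEED,
    pathway_len: int = 3,
    n_vitamins: Optional[int] = None,
    cap_range: Tuple[float, float] = (5.0, 15.0),
    max_retries: int = 5,
) -> Tuple[List[StrainModel], Medium, FixtureGroundTruth]:
    """Seeded pseudo-random community with planted obligate cross-feeds.

    Each strain grows on a private carbon source through a linear pathway of
    ``pathway_len`` steps and requires a growth-coupled cofactor produced as
    a biomass byproduct of the previous strain in a ring — every ring edge is
    obligate: knocking its carrier link zeroes community growth (verified by
    knockout before returning).  Optionally, ``n_vitamins`` growth-factor
    metabolites are each producible by two distinct strains through
    growth-independent side reactions, planting redundant (non-obligate)
    edges whose robustness classification must come out ``variable``.
    Identical ``(n, seed, params)`` reproduce byte-identical models.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_vitamins is None:
        n_vitamins = 1 if n >= 3 else 0
    if n_vitamins > 0 and n < 3:
        raise ValueError("vitamins need at least 3 strains")

    last_err = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, n, attempt]))
        models, medium, gt = _build_random(rng, n, pathway_len, n_vitamins,
                                           cap_range, seed)
        try:
            _verify_random(models, medium, gt)
            return models, medium, gt
        except AssertionError as err:  # pragma: no cover - defensive
            last_err = err
    raise RuntimeError(f"random community generation failed: {last_err}")


def _build_random(rng, n, pathway_len, n_vitamins, cap_range, seed):
    caps = np.round(rng.uniform(*cap_range, size=n), 3)
    q, r, vit_coef = 0.1, 1.0, 0.05
    sids = [f"rc{k}" for k in range(n)]

    # vitamin wiring: consumer + two distinct producers per vitamin
    vitamins = []
    for m in range(n_vitamins):
        consumer = int(rng.integers(n))
        producers = rng.choice(
            [j for j in range(n) if j != consumer], size=2, replace=False
        )
        vitamins.append((m, consumer, sorted(int(j) for j in producers)))

    models = []
    for k in range(n):
        prev = (k - 1) % n
        mets = [
            Metabolite(f"src{k}_e", compartment=EXTRACELLULAR, formula="C6H12O6"),
            Metabolite(f"src{k}_c", compartment=CYTOSOL, formula="C6H12O6"),
            Metabolite(f"x{k}_e", compartment=EXTRACELLULAR, formula="H3N"),
            Metabolite(f"x{k}_c", compartment=CYTOSOL, formula="H3N"),
        ]
        rxns = [
            _exchange(f"src{k}_e"), _exchange(f"x{k}_e"),
            Reaction(f"T_src{k}", {f"src{k}_e": -1.0, f"src{k}_c": 1.0}, 0.0, _CAP),
            Reaction(f"T_x{k}_sec", {f"x{k}_c": -1.0, f"x{k}_e": 1.0}, 0.0, _CAP),
        ]
        chain_in = f"src{k}_c"
        for j in range(pathway_len):
            out = f"pre{k}_c" if j == pathway_len - 1 else f"i{k}_{j}_c"
            mets.append(Metabolite(out, compartment=CYTOSOL, formula="C6H12O6"))
            rxns.append(Reaction(f"CH{k}_{j}", {chain_in: -1.0, out: 1.0}, 0.0, _CAP))
            chain_in = out
        grow_stoich = {f"pre{k}_c": -1.0}
        if n == 1:
            grow_stoich[f"x{k}_c"] = r - q
        else:
            grow_stoich[f"x{k}_c"] = r
            grow_stoich[f"x{prev}_c"] = -q
            mets += [
                Metabolite(f"x{prev}_e", compartment=EXTRACELLULAR, formula="H3N"),
                Metabolite(f"x{prev}_c", compartment=CYTOSOL, formula="H3N"),
            ]
            rxns += [
                _exchange(f"x{prev}_e"),
                Reaction(f"T_x{prev}_upt", {f"x{prev}_e": -1.0, f"x{prev}_c": 1.0},
                         0.0, _CAP),
            ]
        for m, consumer, producers in vitamins:
            if k == consumer:
                mets += [
                    Metabolite(f"vit{m}_e", compartment=EXTRACELLULAR, formula="C6H12O6"),
                    Metabolite(f"vit{m}_c", compartment=CYTOSOL, formula="C6H12O6"),
                ]
                rxns += [
                    _exchange(f"vit{m}_e"),
                    Reaction(f"T_vit{m}_upt", {f"vit{m}_e": -1.0, f"vit{m}_c": 1.0},
                             0.0, _CAP),
                ]
                grow_stoich[f"vit{m}_c"] = -vit_coef
            elif k in producers:
                mets += [
                    Metabolite(f"vit{m}_e", compartment=EXTRACELLULAR, formula="C6H12O6"),
                    Metabolite(f"vit{m}_c", compartment=CYTOSOL, formula="C6H12O6"),
                ]
                rxns += [
                    _exchange(f"vit{m}_e"),
                    Reaction(f"REL{m}", {f"src{k}_c": -1.0, f"vit{m}_c": 1.0}, 0.0, _CAP),
                    Reaction(f"T_vit{m}_sec", {f"vit{m}_c": -1.0, f"vit{m}_e": 1.0},
                             0.0, _CAP),
                ]
        rxns.append(Reaction("GROW", grow_stoich, 0.0, _CAP, is_objective=True))
        models.append(_strain(sids[k], mets, rxns, "GROW"))

    medium = Medium(
        f"RC{n}_{seed}", {f"src{k}": float(caps[k]) for k in range(n)}
    )
    obligate = (
        [(sids[(k - 1) % n], f"x{(k - 1) % n}", sids[k]) for k in range(n)]
        if n > 1 else []
    )
    optional = [
        (sids[j], f"vit{m}", sids[consumer])
        for m, consumer, producers in vitamins
        for j in producers
    ]
    gt = FixtureGroundTruth(
        optima={},
        edges=sorted(set(obligate)),
        optional_edges=sorted(optional),
        media={medium.name: medium},
        seed=seed,
        params={"n": n, "pathway_len": pathway_len, "n_vitamins": n_vitamins,
                "q": q, "r": r, "vit_coef": vit_coef},
    )
    return models, medium, gt


def _verify_random(models, medium, gt) -> None:
    cm = build_community(models, FREE)
    sol = community_fba(cm, medium)
    assert sol.optimal and sol.community_objective > 1e-3, "community not viable"
    gt.optima[f"community_free:{medium.name}"] = sol.community_objective
    ko_targets = {
        (producer, met): cm.links[(producer, met)]
        for producer, met, _consumer in gt.edges
    }
    if ko_targets:
        ko = single_knockouts(cm, medium, list(ko_targets.values()))
        for (producer, met), rid in ko_targets.items():
            assert ko[rid] <= 1e-6 * sol.community_objective, (
                f"planted edge {producer}->{met} is not obligate"
            )
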