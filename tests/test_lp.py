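"""FBA, pFBA, FVA and knockout behaviour on analytically solvable models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commflux import (
    FREE,
    Medium,
    Metabolite,
    Reaction,
    StrainModel,
    Tolerances,
    build_community,
    fba,
    fva,
    pfba,
    single_knockouts,
)
from commflux.lp import OPTIMAL, ObjectiveError

from oracle import dense_objective


def _chain_model(yield_per_substrate=0.5, duplicate_step=False, futile_cycle=False):
    """Linear pathway S_e -> S_c -> P_c -> biomass with tunable extras."""
    mets = [
        Metabolite("s_e", compartment="e", formula="C6H12O6"),
        Metabolite("s_c", formula="C6H12O6"),
        Metabolite("p_c", formula="C6H12O6"),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, -1000, 1000),
        Reaction("T_S", {"s_e": -1.0, "s_c": 1.0}, 0, 1000),
        Reaction("STEP", {"s_c": -1.0, "p_c": 1.0}, 0, 1000),
        Reaction("BIO", {"p_c": -1.0 / yield_per_substrate}, 0, 1000,
                 is_objective=True),
    ]
    if duplicate_step:
        rxns.append(Reaction("STEP_DUP", {"s_c": -1.0, "p_c": 1.0}, 0, 1000))
    if futile_cycle:
        mets += [Metabolite("u_c"), Metabolite("v_c")]
        rxns += [
            Reaction("C1", {"u_c": -1.0, "v_c": 1.0}, -1000, 1000),
            Reaction("C2", {"v_c": -1.0, "u_c": 1.0}, -1000, 1000),
        ]
    return StrainModel.from_components("chain", mets, rxns, "BIO")


S_MEDIUM = Medium("S", {"s": 10.0})


def test_chain_objective_is_import_times_yield():
    for u, y in [(10.0, 0.5), (4.0, 0.25), (7.5, 1.0)]:
        model = _chain_model(y)
        sol = fba(model, Medium("S", {"s": u}))
        assert sol.status == OPTIMAL
        assert sol.objective_value == pytest.approx(u * y, abs=1e-9)


def test_singletons_cannot_grow_on_pollutant_alone(toy_pair, media):
    A, B, _ = toy_pair
    for strain in (A, B):
        sol = fba(strain, media["MM_S"])
        assert sol.status == OPTIMAL
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_empty_medium_yields_no_growth(toy_pair):
    A, _, _ = toy_pair
    barren = Medium("none", {}, unconstrained_minerals=set())
    sol = fba(A, barren)
    assert sol.objective_value <= 1e-9


def test_missing_objective_raises_configuration_error(toy_pair):
    A, _, _ = toy_pair
    with pytest.raises(ObjectiveError):
        fba(A, S_MEDIUM, objective_id="NOT_A_REACTION")


def test_solution_respects_steady_state_and_bounds(toy_pair, media):
    A, B, _ = toy_pair
    cm = build_community([A, B], FREE)
    sol = pfba(cm, media["MM_S"])
    assert sol.max_residual <= 1e-9
    bounds = cm.lp_bounds(media["MM_S"])
    for rid, v in sol.fluxes.items():
        lb, ub = bounds[rid]
        assert lb - 1e-9 <= v <= ub + 1e-9


def test_pfba_objective_matches_gamma_times_fba_optimum(toy_pair, media):
    A, B, _ = toy_pair
    cm = build_community([A, B], FREE)
    ref = fba(cm, media["MM_S"]).objective_value
    for gamma in (1.0, 0.9):
        sol = pfba(cm, media["MM_S"], tolerances=Tolerances(gamma=gamma))
        assert sol.status == OPTIMAL
        assert sol.objective_value == pytest.approx(gamma * ref, abs=1e-6)


def test_pfba_never_exceeds_fba_total_flux(toy_pair, media):
    A, B, _ = toy_pair
    cm = build_community([A, B], FREE)
    dense = fba(cm, media["MM_S"])
    sparse = pfba(cm, media["MM_S"])
    assert sparse.total_absolute_flux <= dense.total_absolute_flux + 1e-6


def test_pfba_silences_futile_cycle():
    model = _chain_model(futile_cycle=True)
    sol = pfba(model, S_MEDIUM)
    assert abs(sol.fluxes["C1"]) <= 1e-9
    assert abs(sol.fluxes["C2"]) <= 1e-9
    assert sol.objective_value == pytest.approx(5.0, abs=1e-6)


def test_pfba_exchange_only_switch_matches_objective():
    model = _chain_model()
    sol = pfba(model, S_MEDIUM, minimize="exchange")
    assert sol.objective_value == pytest.approx(5.0, abs=1e-6)
    with pytest.raises(ValueError):
        pfba(model, S_MEDIUM, minimize="nothing")


def test_fva_biomass_interval_collapses_at_gamma_one():
    model = _chain_model()
    (iv,) = fva(model, S_MEDIUM, gamma=1.0, reaction_ids=["BIO"])
    assert iv.min_flux == pytest.approx(5.0, abs=1e-6)
    assert iv.max_flux == pytest.approx(5.0, abs=1e-6)


def test_fva_blocked_reaction_is_zero_zero():
    # a reaction feeding a dead-end metabolite can carry no steady-state flux
    model = _chain_model()
    model.metabolites["w_c"] = Metabolite("w_c")
    model.reactions["DEAD"] = Reaction("DEAD", {"s_c": -1.0, "w_c": 1.0}, 0, 1000)
    model.validate()
    (iv,) = fva(model, S_MEDIUM, gamma=1.0, reaction_ids=["DEAD"])
    assert iv.min_flux == pytest.approx(0.0, abs=1e-9)
    assert iv.max_flux == pytest.approx(0.0, abs=1e-9)


def test_fva_interval_contains_pfba_flux(toy_pair, media):
    A, B, _ = toy_pair
    cm = build_community([A, B], FREE)
    sol = pfba(cm, media["MM_S"])
    link_ids = cm.link_reaction_ids()
    for iv in fva(cm, media["MM_S"], gamma=1.0, reaction_ids=link_ids):
        v = sol.fluxes[iv.reaction_id]
        assert iv.min_flux - 1e-6 <= v <= iv.max_flux + 1e-6
        assert iv.min_flux <= iv.max_flux + 1e-7


def test_knockout_of_biomass_reaction_zeroes_objective():
    model = _chain_model()
    ko = single_knockouts(model, S_MEDIUM, ["BIO"])
    assert ko["BIO"] == pytest.approx(0.0, abs=1e-9)


def test_knockout_of_duplicated_step_changes_nothing():
    model = _chain_model(duplicate_step=True)
    ko = single_knockouts(model, S_MEDIUM, ["STEP", "STEP_DUP"])
    assert ko["STEP"] == pytest.approx(5.0, abs=1e-6)
    assert ko["STEP_DUP"] == pytest.approx(5.0, abs=1e-6)


def test_knockout_of_unique_degradation_step_is_lethal():
    model = _chain_model()
    ko = single_knockouts(model, S_MEDIUM, ["STEP"])
    assert ko["STEP"] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(KeyError):
        single_knockouts(model, S_MEDIUM, ["NOPE"])


def test_fba_matches_cobrapy_on_growing_medium(toy_pair, media):
    """Independent solver cross-check through the cobrapy/GLPK stack."""
    from commflux.io import to_cobra

    A, _, _ = toy_pair
    medium = media["MM_S_NH3"].with_import("X", 7.0)
    ours = fba(A, medium).objective_value
    cmodel = to_cobra(A)
    bounds = A.lp_bounds(medium)
    for ex_id in A.exchange_reaction_ids:
        cmodel.reactions.get_by_id(ex_id).bounds = bounds[ex_id]
    theirs = cmodel.optimize().objective_value
    assert ours == pytest.approx(theirs, abs=1e-6)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(lam=st.floats(min_value=0.1, max_value=10.0))
def test_scaling_all_imports_scales_the_optimum(lam):
    A, B, _ = __import__("commflux").fixtures.make_toy_pair()
    cm = build_community([A, B], FREE)
    base = fba(cm, Medium("m", {"S": 10.0})).objective_value
    scaled = fba(cm, Medium("m", {"S": 10.0 * lam})).objective_value
    assert scaled == pytest.approx(lam * base, rel=1e-6, abs=1e-6)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(extra=st.floats(min_value=0.0, max_value=50.0),
       which=st.sampled_from(["S", "nh3", "G"]))
def test_relaxing_any_import_bound_never_decreases_objective(extra, which):
    A, B, _ = __import__("commflux").fixtures.make_toy_pair()
    cm = build_community([A, B], FREE)
    base_medium = Medium("m", {"S": 10.0, "nh3": 1.0, "G": 1.0})
    base = fba(cm, base_medium).objective_value
    relaxed = fba(
        cm, base_medium.with_import(which, base_medium.imports[which] + extra)
    ).objective_value
    assert relaxed >= base - 1e-6


def test_objectives_match_dense_oracle_on_small_models(toy_pair, media):
    A, B, _ = toy_pair
    for model, medium in [
        (_chain_model(), S_MEDIUM),
        (A, media["MM_S_NH3"]),
        (B, media["MM_SCAN"]),
    ]:
        assert fba(model, medium).objective_value == pytest.approx(
            dense_objective(model, medium), abs=1e-6
        )
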