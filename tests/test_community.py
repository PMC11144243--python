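"""Community assembly, abundance scenarios and pool conservation."""

import math

import numpy as np
import pytest

from commflux import (
    AbundanceScenario,
    EQUAL,
    FREE,
    Medium,
    Metabolite,
    Reaction,
    StrainModel,
    biomass_ratio_scan,
    build_community,
    community_fba,
    community_pfba,
    fba,
)
from commflux.community import CommunityBuildError

from oracle import dense_objective


def _independent_strain(sid: str, substrate: str, yield_: float) -> StrainModel:
    mets = [
        Metabolite(f"{substrate}_e", compartment="e", formula="C6H12O6"),
        Metabolite(f"{substrate}_c", formula="C6H12O6"),
    ]
    rxns = [
        Reaction(f"EX_{substrate}", {f"{substrate}_e": -1.0}, -1000, 1000),
        Reaction("T", {f"{substrate}_e": -1.0, f"{substrate}_c": 1.0}, 0, 1000),
        Reaction("BIO", {f"{substrate}_c": -1.0 / yield_}, 0, 1000,
                 is_objective=True),
    ]
    return StrainModel.from_components(sid, mets, rxns, "BIO")


def test_single_member_community_equals_strain_fba(toy_pair, helper, media):
    A, B, _ = toy_pair
    C, _ = helper
    for strain in (A, B, C):
        for medium in media.values():
            single = fba(strain, medium).objective_value
            comm = community_fba(build_community([strain], FREE), medium)
            assert comm.community_objective == pytest.approx(single, abs=1e-6)


def test_pool_contains_exactly_the_declared_shared_metabolites(pair_free, toy_pair):
    _, _, gt = toy_pair
    assert pair_free.shared_metabolites == gt.shared_metabolites
    for mb in pair_free.shared_metabolites:
        assert mb in pair_free.import_reactions
        assert mb in pair_free.export_reactions


def test_duplicate_strain_ids_rejected(toy_pair):
    A, _, _ = toy_pair
    with pytest.raises(CommunityBuildError):
        build_community([A, A.copy()])


def test_pair_reaches_recorded_closed_form_and_oracle(pair_free, toy_pair, media):
    _, _, gt = toy_pair
    sol = community_fba(pair_free, media["MM_S"])
    assert sol.optimal
    assert sol.community_objective == pytest.approx(
        gt.optima["pair_free:MM_S"], abs=1e-6
    )
    assert sol.member_biomass["A"] == pytest.approx(
        gt.optima["pair_free:MM_S:A"], abs=1e-6
    )
    assert sol.member_biomass["B"] == pytest.approx(
        gt.optima["pair_free:MM_S:B"], abs=1e-6
    )
    assert sol.community_objective == pytest.approx(
        dense_objective(pair_free, media["MM_S"]), abs=1e-6
    )


def test_equal_scenario_couples_member_growth(pair_equal, toy_pair, media):
    _, _, gt = toy_pair
    sol = community_fba(pair_equal, media["MM_S"])
    assert sol.member_biomass["A"] == pytest.approx(sol.member_biomass["B"], abs=1e-6)
    assert sol.community_objective == pytest.approx(
        gt.optima["pair_equal:MM_S"], abs=1e-6
    )


def test_free_scenario_dominates_equal(pair_free, pair_equal, trio_free,
                                       toy_pair, helper, media):
    A, B, _ = toy_pair
    C, _ = helper
    trio_equal = build_community([A, B, C], EQUAL)
    for free_cm, equal_cm in [(pair_free, pair_equal), (trio_free, trio_equal)]:
        for medium in media.values():
            free = community_fba(free_cm, medium).community_objective
            equal = community_fba(equal_cm, medium).community_objective
            assert free >= equal - 1e-6


def test_target_scenario_maximizes_one_member(toy_pair, media):
    A, B, gt = toy_pair
    cm = build_community([A, B], AbundanceScenario("target", target_strain="A"))
    sol = community_fba(cm, media["MM_S"])
    assert sol.scenario_objective == pytest.approx(gt.optima["A_target:MM_S"], abs=1e-6)
    assert sol.member_biomass["A"] == pytest.approx(gt.optima["A_target:MM_S"], abs=1e-6)


def test_fixed_scenario_locks_biomass_proportions(toy_pair, media):
    A, B, _ = toy_pair
    cm = build_community(
        [A, B], AbundanceScenario("fixed", weights={"A": 0.4, "B": 0.6})
    )
    sol = community_fba(cm, media["MM_S"])
    assert sol.optimal
    mu = sol.scenario_objective
    assert sol.member_biomass["A"] == pytest.approx(0.4 * mu, abs=1e-6)
    assert sol.member_biomass["B"] == pytest.approx(0.6 * mu, abs=1e-6)
    free = community_fba(build_community([A, B], FREE), media["MM_S"])
    assert mu <= free.community_objective + 1e-6
    assert sol.scenario_objective == pytest.approx(
        dense_objective(cm, media["MM_S"]), abs=1e-6
    )


def test_fixed_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        AbundanceScenario("fixed", weights={"A": 0.4, "B": 0.4})
    with pytest.raises(ValueError):
        AbundanceScenario("equal", target_strain="A")
    with pytest.raises(ValueError):
        AbundanceScenario("sorted")


def test_disjoint_strains_add_their_optima():
    s1 = _independent_strain("s1", "glc", 0.5)
    s2 = _independent_strain("s2", "xyl", 0.25)
    medium = Medium("both", {"glc": 10.0, "xyl": 8.0})
    cm = build_community([s1, s2], FREE)
    expected = fba(s1, medium).objective_value + fba(s2, medium).objective_value
    sol = community_fba(cm, medium)
    assert sol.community_objective == pytest.approx(expected, abs=1e-6)
    assert sol.community_objective == pytest.approx(
        dense_objective(cm, medium), abs=1e-6
    )


def test_noninteracting_member_stays_at_zero(toy_pair, trio_free, media):
    """Adding a strain that cannot touch the active substrate changes
    nothing for the pair (it simply idles)."""
    pair = community_fba(build_community(list(toy_pair[:2]), FREE), media["MM_S"])
    trio = community_fba(trio_free, media["MM_S"])
    assert trio.member_biomass["C"] == pytest.approx(0.0, abs=1e-6)
    assert trio.community_objective == pytest.approx(
        pair.community_objective, abs=1e-6
    )


def test_pool_balance_residuals_below_1e9(pair_free, trio_free, media):
    for cm in (pair_free, trio_free):
        for medium in media.values():
            for sol in (community_fba(cm, medium), community_pfba(cm, medium)):
                assert sol.optimal
                for mb in cm.shared_metabolites:
                    total = sum(
                        sol.member_exchanges[sid].get(mb, 0.0) for sid in cm.members
                    )
                    residual = total + sol.pool_import[mb] - sol.pool_export[mb]
                    assert abs(residual) <= 1e-9, (medium.name, mb, residual)


def test_ratio_scan_monotone_and_guarded(pair_free, media):
    scan = biomass_ratio_scan(pair_free, "S", [0.0, 2.0, 5.0, 10.0], media["MM_S"])
    assert scan["biomass_A"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert scan["biomass_B"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert math.isnan(scan["ratio_B:A"].iloc[0])
    assert scan["biomass_A"].is_monotonic_increasing
    assert scan["biomass_B"].is_monotonic_increasing


def test_ratio_scan_with_baseline_floor_matches_closed_form(pair_free, media):
    """With a small fixed carbon/nitrogen allowance for B, the downstream
    member keeps a biomass floor and the B:A ratio rises as substrate
    availability falls (v_A = L, v_B = 5L/6 + 1)."""
    levels = [3.0, 6.0, 10.0]
    scan = biomass_ratio_scan(pair_free, "S", levels, media["MM_SCAN"])
    for _, row in scan.iterrows():
        L = row["availability"]
        assert row["biomass_A"] == pytest.approx(L, abs=1e-6)
        assert row["biomass_B"] == pytest.approx(5 * L / 6 + 1, abs=1e-6)
    ratios = scan["ratio_B:A"]
    assert ratios.is_monotonic_decreasing


def test_ratio_scan_rejects_unknown_substrate(pair_free, media):
    with pytest.raises(KeyError):
        biomass_ratio_scan(pair_free, "caffeine", [1.0], media["MM_S"])
    with pytest.raises(ValueError):
        biomass_ratio_scan(pair_free, "S", [-1.0], media["MM_S"])
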