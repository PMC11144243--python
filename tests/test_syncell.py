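"""Essential/helpful reaction identification and synthetic-cell design."""

import pytest

from commflux import (
    FREE,
    Metabolite,
    Reaction,
    TargetFunction,
    build_community,
    build_synthetic_cell,
    compare_performance,
    fba,
    find_essential_reactions,
    find_helpful_reactions,
    single_knockouts,
    transplants_from_community,
)
from commflux.syncell import (
    FunctionError,
    KeyReactionSet,
    TransplantError,
    carrier_closure,
)

FN_A = TargetFunction("member_biomass", strain="A")


@pytest.fixture(scope="module")
def pair_er(pair_free, media):
    candidates = [r for r in pair_free.reactions if "__" in r]
    return find_essential_reactions(pair_free, FN_A, media["MM_S"],
                                    candidates=candidates)


@pytest.fixture(scope="module")
def syncell(pair_free, pair_er, toy_pair):
    A, _, _ = toy_pair
    transplants, _ = transplants_from_community(
        pair_free, [rid for rid, _ in pair_er], "A")
    return build_synthetic_cell(A, transplants)


def test_target_function_validation():
    with pytest.raises(ValueError):
        TargetFunction("reaction_flux")
    with pytest.raises(ValueError):
        TargetFunction("member_biomass")
    with pytest.raises(ValueError):
        TargetFunction("degradation")
    assert TargetFunction("reaction_flux", reaction_id="IP_S").label() == \
        "reaction_flux:IP_S"


def test_designed_essential_set_is_recovered(pair_er, toy_pair):
    _, _, gt = toy_pair
    assert sorted(r for r, _ in pair_er) == sorted(gt.essential["member_A:MM_S"])
    donors = {r: d for r, d in pair_er}
    assert donors["A__DEG1"] == "A" and donors["B__DEAM1"] == "B"


def test_essentiality_equals_exhaustive_knockout(pair_free, media):
    """The FVA pre-filter must not change the result."""
    er = find_essential_reactions(pair_free, FN_A, media["MM_S"])
    obj = pair_free.member_biomass["A"]
    base = fba(pair_free, media["MM_S"], obj).objective_value
    threshold = max(1e-6 * base, 1e-9)
    ko = single_knockouts(pair_free, media["MM_S"], objective_id=obj)
    exhaustive = sorted(r for r, v in ko.items() if v < threshold)
    assert sorted(r for r, _ in er) == exhaustive


def test_duplicated_reaction_is_never_essential(toy_pair, media):
    A, B, _ = toy_pair
    A2 = A.copy()
    dup = A2.reactions["DEG1"].copy()
    dup.id = "DEG1_DUP"
    A2.reactions["DEG1_DUP"] = dup
    cm = build_community([A2, B], FREE)
    er = {r for r, _ in find_essential_reactions(cm, FN_A, media["MM_S"])}
    assert "A__DEG1" not in er and "A__DEG1_DUP" not in er


def test_unachievable_function_raises_contract_error(pair_free, media):
    with pytest.raises(FunctionError, match="member_biomass:A"):
        find_essential_reactions(pair_free, FN_A, media["MM_G_NO3"])


def test_helper_nitrate_chain_is_essential_in_the_trio(trio_free, helper, media):
    _, gt = helper
    candidates = [r for r in trio_free.reactions if "__" in r]
    er = {r for r, _ in find_essential_reactions(
        trio_free, FN_A, media["MM_G_NO3"], candidates=candidates)}
    assert set(gt.essential["member_A:MM_G_NO3"]) <= er


def test_transplant_of_empty_set_is_identity(toy_pair):
    A, _, _ = toy_pair
    cell = build_synthetic_cell(A, [])
    assert cell.transplanted == []
    assert set(cell.model.reactions) == set(A.reactions)


def test_transplants_skip_duplicates_and_map_links(pair_free, pair_er, toy_pair):
    A, _, _ = toy_pair
    transplants, dropped = transplants_from_community(
        pair_free, [rid for rid, _ in pair_er], "A")
    cell = build_synthetic_cell(A, transplants)
    assert {r for r, _ in cell.transplanted} == {"DEAM1", "DEAM2", "EX_Q"}
    # B's links for P and nh3 collapse onto exchanges A already has
    skipped_ids = {r for r, _, _ in cell.skipped}
    assert {"EX_P", "EX_nh3"} <= skipped_ids
    assert all(d == "B" for _, d in cell.transplanted)
    assert "EX_Q" in cell.model.exchange_reaction_ids


def test_pool_metabolite_transplant_is_rejected(pair_free, toy_pair):
    A, _, _ = toy_pair
    flat = pair_free.as_strain_model()
    with pytest.raises(TransplantError):
        build_synthetic_cell(A, [(flat, "IP_S")])


def test_id_collision_with_different_stoichiometry_is_renamed(toy_pair):
    A, B, _ = toy_pair
    # B's T_NH3 is stoichiometrically identical to A's -> skipped;
    # B's GROW differs but is a biomass reaction -> skipped;
    # B's DEG2A has a fresh id -> added verbatim
    cell = build_synthetic_cell(A, [(B, "T_NH3"), (B, "GROW"), (B, "DEG2A")])
    assert ("T_NH3", "B") not in cell.transplanted
    assert {r for r, _ in cell.transplanted} == {"DEG2A"}
    reasons = {r: why for r, _, why in cell.skipped}
    assert "duplicate" in reasons["T_NH3"] and "biomass" in reasons["GROW"]


def test_dead_transplant_keeps_model_valid_with_zero_gain(toy_pair, helper, media):
    A, _, _ = toy_pair
    C, _ = helper
    # nitrate reduction without any nitrate transport: valid but inert
    cell = build_synthetic_cell(A, [(C, "NR")])
    cell.model.validate()
    assert fba(cell.model, media["MM_S"]).objective_value == pytest.approx(
        fba(A, media["MM_S"]).objective_value, abs=1e-9
    )


def test_syncell_recovers_community_function(syncell, pair_free, media):
    community_opt = fba(
        pair_free, media["MM_S"], pair_free.member_biomass["A"]
    ).objective_value
    alone = fba(syncell.model, media["MM_S"]).objective_value
    assert alone >= (1 - 1e-6) * community_opt


def test_removing_any_transplanted_reaction_abolishes_growth(syncell, media):
    ko = single_knockouts(syncell.model, media["MM_S"],
                          [rid for rid, _ in syncell.transplanted])
    for rid, value in ko.items():
        assert value <= 1e-9, rid


def test_carrier_closure_collects_transport_prerequisites(helper):
    C, _ = helper
    bundle = carrier_closure(C, "NR")
    assert {"T_NO3", "T_H", "T_H2O", "T_NH3_SEC"} <= set(bundle)
    assert {"EX_no3", "EX_h", "EX_h2o"} <= set(bundle)
    assert "T_G" not in bundle


def test_helpful_reactions_flip_nitrate_growth(syncell, helper, media):
    C, _ = helper
    fn = TargetFunction("community_biomass")
    hr = find_helpful_reactions([C], syncell.model, fn, media["MM_G_NO3"])
    assert [r for r, _, _, _ in hr] == ["NR"]
    rid, donor, gain, bundle = hr[0]
    assert donor == "C" and gain > 0.01
    # HR soundness: the recorded transplant reproduces the measured optimum
    without = fba(syncell.model, media["MM_G_NO3"]).objective_value
    augmented = build_synthetic_cell(
        syncell.model, [(C, rid)] + [(C, b) for b in bundle])
    with_hr = fba(augmented.model, media["MM_G_NO3"]).objective_value
    assert without == pytest.approx(0.0, abs=1e-9)
    assert with_hr > 1.0


def test_already_sufficient_chassis_yields_no_helpful_reactions(
        syncell, toy_pair, media):
    _, B, _ = toy_pair
    fn = TargetFunction("community_biomass")
    hr = find_helpful_reactions([B], syncell.model, fn, media["MM_S"])
    assert hr == []


def test_key_reaction_set_disjointness_enforced():
    with pytest.raises(ValueError):
        KeyReactionSet(essential=[("R1", "A")], helpful=[("R1", "B", 0.5)],
                       function="community_biomass", medium="MM_S")


def test_compare_performance_matrix(syncell, pair_free, toy_pair, media):
    A, B, _ = toy_pair
    fn = TargetFunction("member_biomass", strain="A")
    entities = {"A": A, "B": B, "pair": pair_free, "syncell": syncell.model}
    matrix = compare_performance(entities, [media["MM_S"]], fn)
    assert matrix.loc["A", "MM_S"] == pytest.approx(0.0, abs=1e-9)
    assert matrix.loc["B", "MM_S"] == pytest.approx(0.0, abs=1e-9)
    assert matrix.loc["pair", "MM_S"] == pytest.approx(10.0, abs=1e-6)
    assert matrix.loc["syncell", "MM_S"] == pytest.approx(10.0, abs=1e-6)
    empty = compare_performance(entities, [], fn)
    assert empty.shape == (4, 0)
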