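"""Property-class substitution model and binding predictions."""

import pytest
from hypothesis import given, strategies as st

import mbstrip as mb
from mbstrip.binding import DEFAULT_PARAM_GRID, PROPERTY_CLASSES

AA = sorted(PROPERTY_CLASSES)


def test_every_standard_residue_maps_to_exactly_one_class():
    assert set(PROPERTY_CLASSES) == set("ACDEFGHIKLMNPQRSTVWY")


@pytest.mark.parametrize(
    "residue, expected",
    [
        ("K", "polar_basic"),
        ("R", "polar_basic"),  # Lys->Arg stays in the polar basic group
        ("H", "polar_basic"),
        ("A", "nonpolar"),
        ("M", "nonpolar"),
        ("I", "nonpolar"),
        ("S", "polar_uncharged"),
        ("D", "polar_acidic"),
        ("E", "polar_acidic"),
    ],
)
def test_class_assignments(residue, expected):
    assert mb.class_of(residue) == expected


def test_nonstandard_residue_rejected():
    with pytest.raises(ValueError):
        mb.class_of("X")


def test_substitution_penalties(default_params):
    p = default_params
    assert mb.substitution_penalty("A", "A", p) == p.penalty_identity == 0.0
    assert mb.substitution_penalty("K", "R", p) == p.penalty_same_class
    assert mb.substitution_penalty("A", "R", p) == p.penalty_cross_class
    assert mb.substitution_penalty("A", "-", p) == p.penalty_gap


@given(a=st.sampled_from(AA + ["-"]), b=st.sampled_from(AA + ["-"]))
def test_substitution_penalty_is_symmetric(a, b):
    p = mb.BindingModelParams()
    assert mb.substitution_penalty(a, b, p) == mb.substitution_penalty(b, a, p)


def test_parameter_invariants_enforced():
    with pytest.raises(ValueError):
        mb.BindingModelParams(penalty_same_class=5.0, penalty_cross_class=3.0)
    with pytest.raises(ValueError):
        mb.BindingModelParams(penalty_gap=1.0)
    with pytest.raises(ValueError):
        mb.BindingModelParams(core_weight=0.0)


def _window(core, left="", right="", region_index=2, source="test"):
    region = mb.get_region(region_index)
    assert len(core) == region.length
    return mb.EpitopeWindow(
        region=region,
        core_residues=core,
        left_flank=left,
        right_flank=right,
        source_id=source,
    )


def test_identical_windows_bind_with_zero_total(default_params):
    w = _window("KASEDLK", "AEM", "KHG")
    score = mb.binding_score(w, w, default_params)
    assert score.total == 0.0 and score.binds


def test_length_mismatch_rejected(default_params):
    a = _window("KASEDLK", "AEM", "KHG")
    b = _window("KASEDLK", "EM", "KHG")
    with pytest.raises(ValueError, match="equal core/flank"):
        mb.binding_score(a, b, default_params)


def test_seal_fails_epitope_2_but_passes_epitope_4(
    validation_panel, validation_msa, default_params
):
    """Seal's region 2 carries one cross-class (A->R) plus two same-class
    (K->R) core changes and loses binding; its region 4 differs only by a
    same-class R->K and keeps binding."""
    r2 = mb.get_region(2)
    r4 = mb.get_region(4)
    epi2 = mb.consensus_window(validation_msa, validation_panel, r2)
    epi4 = mb.consensus_window(validation_msa, validation_panel, r4)
    seal2 = mb.extract_window(validation_msa, "seal", r2)
    seal4 = mb.extract_window(validation_msa, "seal", r4)

    score2 = mb.binding_score(epi2, seal2, default_params)
    assert score2.core_penalty == 5.0  # 1 + 3 + 1
    assert not score2.binds

    score4 = mb.binding_score(epi4, seal4, default_params)
    assert score4.core_penalty == 1.0  # single same-class K-for-R
    assert score4.binds


def test_chicken_and_dog_share_the_region2_core_but_differ_in_flanks(
    validation_panel, validation_msa, default_params
):
    r2 = mb.get_region(2)
    epi = mb.consensus_window(validation_msa, validation_panel, r2)
    dog = mb.extract_window(validation_msa, "dog", r2)
    chicken = mb.extract_window(validation_msa, "chicken", r2)
    assert dog.core_residues == chicken.core_residues
    assert mb.binding_score(epi, dog, default_params).binds
    assert not mb.binding_score(epi, chicken, default_params).binds


def test_prediction_ignores_flanks_when_flank_weight_is_zero(
    validation_panel, validation_msa
):
    params = mb.BindingModelParams(flank_weight=0.0)
    r2 = mb.get_region(2)
    epi = mb.consensus_window(validation_msa, validation_panel, r2)
    dog = mb.extract_window(validation_msa, "dog", r2)
    chicken = mb.extract_window(validation_msa, "chicken", r2)
    assert (
        mb.binding_score(epi, dog, params).total
        == mb.binding_score(epi, chicken, params).total
    )


@given(
    st.lists(st.sampled_from(["identity", "same", "cross", "gap"]), min_size=7, max_size=7),
    st.integers(min_value=0, max_value=6),
)
def test_total_is_monotone_under_single_column_mismatch_upgrades(kinds, column):
    """Upgrading any one column identity -> same-class -> cross-class -> gap
    never decreases the total score."""
    params = mb.BindingModelParams()
    base = "KASEDLK"  # region 2 core; chosen residues realize each mismatch kind
    by_kind = {"identity": dict(K="K", A="A", S="S", E="E", D="D", L="L"),
               "same": dict(K="R", A="G", S="T", E="D", D="E", L="V"),
               "cross": dict(K="A", A="K", S="K", E="K", D="K", L="K"),
               "gap": dict(K="-", A="-", S="-", E="-", D="-", L="-")}
    order = ["identity", "same", "cross", "gap"]

    def window_for(assignment):
        core = "".join(by_kind[kind][res] for kind, res in zip(assignment, base))
        return _window(core)

    epitope = _window(base)
    current = list(kinds)
    kind_now = current[column]
    idx = order.index(kind_now)
    if idx == 3:
        return  # already a gap; nothing to upgrade
    upgraded = list(current)
    upgraded[column] = order[idx + 1]
    t_before = mb.binding_score(epitope, window_for(current), params).total
    t_after = mb.binding_score(epitope, window_for(upgraded), params).total
    assert t_after >= t_before


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _first_grid_params():
    fields = ("penalty_same_class", "penalty_cross_class", "penalty_gap",
              "core_weight", "flank_weight", "binding_threshold")
    return mb.BindingModelParams(**{f: DEFAULT_PARAM_GRID[f][0] for f in fields})


def test_trivial_constraint_returns_first_grid_point():
    w = _window("KASEDLK", "AEM", "KHG")
    result = mb.calibrate_params([mb.BindingConstraint(w, w, must_bind=True)])
    assert result.feasible
    assert result.params == _first_grid_params()


def test_contradictory_constraints_report_infeasibility():
    w = _window("KASEDLK", "AEM", "KHG")
    result = mb.calibrate_params(
        [
            mb.BindingConstraint(w, w, must_bind=True, label="must"),
            mb.BindingConstraint(w, w, must_bind=False, label="must-not"),
        ]
    )
    assert not result.feasible
    assert result.params is None
    assert result.violated  # names at least one unsatisfiable constraint


def _observed_reactivity_constraints(panel, msa):
    """The observed antibody reactivity profile as binding constraints:
    the broad antibody (epitope 2) reacts with cetaceans, cow, goat, pig,
    dog and rabbit but not seal, chicken or tuna; the narrow antibody
    (epitope 4) reacts only with cetaceans and seal."""
    r2, r4 = mb.get_region(2), mb.get_region(4)
    epi2 = mb.consensus_window(msa, panel, r2)
    epi4 = mb.consensus_window(msa, panel, r4)
    detect_negative = {"seal", "chicken", "tuna"}
    constraints = []
    for record in panel.records:
        w2 = mb.extract_window(msa, record.id, r2)
        w4 = mb.extract_window(msa, record.id, r4)
        constraints.append(
            mb.BindingConstraint(
                epi2, w2, must_bind=record.id not in detect_negative,
                label=f"{record.id}-r2",
            )
        )
        capture_positive = record.group == "target" or record.id == "seal"
        constraints.append(
            mb.BindingConstraint(epi4, w4, must_bind=capture_positive,
                                 label=f"{record.id}-r4")
        )
    return constraints


def test_reactivity_profile_constraints_are_feasible_and_default_params_satisfy_them(
    validation_panel, validation_msa, default_params
):
    constraints = _observed_reactivity_constraints(validation_panel, validation_msa)
    result = mb.calibrate_params(constraints)
    assert result.feasible
    # the shipped defaults satisfy the same constraint set
    for c in constraints:
        score = mb.binding_score(c.epitope, c.species_window, default_params)
        assert score.binds == c.must_bind, c.label
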