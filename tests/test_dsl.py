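"""Grammar, default-expansion, rendering and translation of both DSLs."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrseqopt import examples
from mrseqopt.dsl import (
    DSLError,
    OrdinalDictionary,
    PrescanSpec,
    PulseSpec,
    SequenceSpec,
    SpoilingSpec,
    StrictConstraint,
    VagueConstraint,
    expand_defaults,
    parse_requirement,
    parse_sequence,
    render_requirement,
    render_sequence,
    translate_requirement,
)

# --------------------------------------------------------------------------
# requirements DSL
# --------------------------------------------------------------------------


def test_requirement_gwc_example():
    req = parse_requirement(examples.REQUIREMENT_GWC)
    assert req.goal_direction == "maximize"
    assert req.goal_metric == "GWC"
    assert req.strict_constraints == [
        StrictConstraint("SNR_GM", "gt", 30.0),
        StrictConstraint("SNR_WM", "gt", 30.0),
        StrictConstraint("SNR_GM", "gt", "SNR_WM"),
    ]
    assert req.vague_constraints == [VagueConstraint("avoid", "GHOST")]


def test_requirement_snr_csf_example():
    req = parse_requirement(examples.REQUIREMENT_SNR_CSF)
    assert (req.goal_direction, req.goal_metric) == ("maximize", "SNR_CSF")
    assert req.strict_constraints == [StrictConstraint("SHARPNESS", "gt", 0.85)]
    kinds = [(v.kind, v.metric, v.quantifier) for v in req.vague_constraints]
    assert kinds == [
        ("avoid", "GHOST", None),
        ("avoid", "MOTION_SENS", None),
        ("avoid", "DISTORTION_SENS", None),
        ("aim", "CGC", "high"),
        ("aim", "CWC", "high"),
    ]


def test_goal_only_requirement():
    req = parse_requirement('define optimization requirement : maximize "GWC".')
    assert req.goal_metric == "GWC"
    assert req.strict_constraints == [] and req.vague_constraints == []
    assert req.starting_sequence is None


def test_requirement_with_starting_sequence():
    text = examples.REQUIREMENT_GWC + examples.SEQUENCE_RARE_DEFAULT
    req = parse_requirement(text)
    assert req.starting_sequence is not None
    assert req.starting_sequence.family == "RARE"


@pytest.mark.parametrize(
    "bad",
    [
        "",
        'define optimization requirement : maximize "NOT_A_METRIC".',
        'define optimization requirement : maximize "GWC". obey the following '
        'constraints: "SNR_GM" is weirder than 30.',
        "define optimization requirement maximize",
    ],
)
def test_requirement_errors(bad):
    with pytest.raises(DSLError):
        parse_requirement(bad)


def test_syntax_error_reports_location():
    with pytest.raises(DSLError, match=r"line \d+"):
        parse_sequence('define MRI sequence "x"\n  using a "SpinEcho" banana')


# --------------------------------------------------------------------------
# sequence DSL parsing
# --------------------------------------------------------------------------

EXAMPLE_EXPECTATIONS = {
    "RARE": dict(echo_type="SpinEcho", readout_type="LineReadout", te=44.0, tr=500.0,
                 etl=8, epi_factor=1, n_rows=64, n_columns=64, readout_duration=2.0,
                 measurements=1, refocussing_angle=180.0),
    "SE-EPI": dict(echo_type="SpinEcho", readout_type="EPIReadout", te=50.0, tr=1000.0,
                   etl=1, epi_factor=64, measurements=10, refocussing_angle=180.0),
    "EPI": dict(echo_type="GradientEcho", readout_type="EPIReadout", te=35.0, tr=1000.0,
                epi_factor=64, measurements=10, refocussing_angle=0.0),
    "bSSFP": dict(echo_type="GradientEcho", readout_type="LineReadout", te=4.0, tr=8.0,
                  epi_factor=1, readout_duration=2.0, measurements=1),
    "optimized-1": dict(echo_type="SpinEcho", readout_type="EPIReadout", te=46.0,
                        tr=5014.0, epi_factor=32, n_columns=32, n_rows=32,
                        measurements=10, readout_duration=0.5),
    "optimized-2": dict(echo_type="GradientEcho", readout_type="LineReadout", te=17.0,
                        tr=36.0, epi_factor=1, n_columns=64, measurements=2),
}


@pytest.mark.parametrize("key", sorted(EXAMPLE_EXPECTATIONS))
def test_example_texts_recover_printed_values(key):
    spec = parse_sequence(examples.ALL_SEQUENCE_TEXTS[key])
    for field_name, expected in EXAMPLE_EXPECTATIONS[key].items():
        assert getattr(spec, field_name) == expected, field_name


def test_bssfp_prescans_and_spoiling():
    spec = parse_sequence(examples.SEQUENCE_BSSFP_DEFAULT)
    assert spec.prescans == PrescanSpec(8, "linear")
    assert spec.spoiling == (SpoilingSpec("around_readout", "balanced"),)


def test_optimized_2_prescans_without_type():
    spec = parse_sequence(examples.SEQUENCE_OPTIMIZED_2)
    assert spec.prescans == PrescanSpec(8, None)


def test_upper_level_only_leaves_fields_unset():
    spec = parse_sequence('define MRI sequence "X" using a "GradientEcho" with "EPIReadout".')
    assert (spec.echo_type, spec.readout_type) == ("GradientEcho", "EPIReadout")
    assert spec.te is None and spec.tr is None and spec.n_rows is None
    assert not spec.is_complete()


def test_duplicate_specify_block_rejected():
    text = (
        'define MRI sequence "X" using a "GradientEcho" with "EPIReadout".'
        "Specify measurements with count 1. Specify measurements with count 2."
    )
    with pytest.raises(DSLError, match="duplicate"):
        parse_sequence(text)


def test_unknown_echo_keyword_rejected():
    with pytest.raises(DSLError, match="echo type"):
        parse_sequence('define MRI sequence "X" using a "TurboEcho" with "EPIReadout".')


# --------------------------------------------------------------------------
# default expansion
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "echo,readout,expected",
    [
        ("SpinEcho", "LineReadout", dict(te=44.0, tr=500.0, etl=8, readout_duration=2.0,
                                         measurements=1)),
        ("GradientEcho", "EPIReadout", dict(te=35.0, tr=1000.0, epi_factor=64,
                                            measurements=10)),
        ("SpinEcho", "EPIReadout", dict(te=50.0, tr=1000.0, epi_factor=64)),
        ("GradientEcho", "LineReadout", dict(te=4.0, tr=8.0)),
    ],
)
def test_expand_defaults_families(echo, readout, expected):
    spec = expand_defaults(SequenceSpec("x", echo, readout))
    assert spec.is_complete()
    for field_name, value in expected.items():
        assert getattr(spec, field_name) == value


@pytest.mark.parametrize("family", sorted(examples.DEFAULT_SEQUENCES))
def test_default_texts_are_expansion_fixed_points(family):
    spec = parse_sequence(examples.DEFAULT_SEQUENCES[family])
    assert expand_defaults(spec) == spec


def test_expand_defaults_idempotent_from_upper_level():
    spec = SequenceSpec("x", "SpinEcho", "EPIReadout")
    once = expand_defaults(spec)
    assert expand_defaults(once) == once


# --------------------------------------------------------------------------
# rendering round trips
# --------------------------------------------------------------------------


@pytest.mark.parametrize("key", sorted(examples.ALL_SEQUENCE_TEXTS))
def test_example_text_round_trip(key):
    spec = expand_defaults(parse_sequence(examples.ALL_SEQUENCE_TEXTS[key]))
    assert parse_sequence(render_sequence(spec)) == spec


def test_render_includes_prescan_addition():
    spec = expand_defaults(parse_sequence(examples.SEQUENCE_BSSFP_DEFAULT))
    assert "Add prescans" in render_sequence(spec)
    bare = expand_defaults(parse_sequence(examples.SEQUENCE_EPI_DEFAULT))
    assert "Add prescans" not in render_sequence(bare)


def test_render_incomplete_spec_rejected():
    with pytest.raises(DSLError, match="incomplete"):
        render_sequence(SequenceSpec("x", "SpinEcho", "LineReadout"))


_complete_specs = st.builds(
    SequenceSpec,
    name=st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
                 min_size=1, max_size=8),
    echo_type=st.just("SpinEcho"),
    readout_type=st.sampled_from(["LineReadout", "EPIReadout"]),
    excitation=st.builds(PulseSpec, st.just("sincpulse"),
                         st.integers(1, 359).map(float)),
    refocussing=st.builds(PulseSpec, st.just("sincpulse"),
                          st.integers(1, 359).map(float)),
    readout_duration=st.integers(100, 4000).map(lambda us: us / 1000.0),
    n_columns=st.sampled_from([16, 32, 64]),
    te=st.integers(2, 200).map(float),
    tr=st.integers(4, 6000).map(float),
    epi_factor=st.sampled_from([1, 16, 32]),
    etl=st.sampled_from([1, 8, 16]),
    n_rows=st.sampled_from([16, 32, 64]),
    measurements=st.integers(1, 10),
    prescans=st.one_of(st.none(), st.builds(PrescanSpec, st.integers(1, 10),
                                            st.sampled_from([None, "linear"]))),
    spoiling=st.lists(
        st.builds(SpoilingSpec,
                  st.sampled_from(["around_refocussing", "after_echotrain",
                                   "after_segment", "around_readout"]),
                  st.sampled_from([None, "balanced"])),
        max_size=2).map(tuple),
)


@given(_complete_specs)
def test_round_trip_property(spec):
    """parse(render(s)) == s for every complete sequence specification."""
    assert parse_sequence(render_sequence(spec)) == spec


def test_requirement_render_round_trip():
    req = parse_requirement(examples.REQUIREMENT_SNR_CSF)
    assert parse_requirement(render_requirement(req)) == req


# --------------------------------------------------------------------------
# translation
# --------------------------------------------------------------------------


def test_translate_gwc_requirement():
    problem = translate_requirement(parse_requirement(examples.REQUIREMENT_GWC))
    assert (problem.goal_metric, problem.direction) == ("GWC", "maximize")
    assert [(c.lhs, c.relation, c.rhs) for c in problem.strict] == [
        ("SNR_GM", "gt", 30.0),
        ("SNR_WM", "gt", 30.0),
        ("SNR_GM", "gt", "SNR_WM"),
    ]
    assert [(c.lhs, c.relation, c.rhs) for c in problem.vague] == [("GHOST", "lt", 0.05)]
    assert problem.artifact_flags == {"GHOST"}


def test_translate_snr_csf_requirement():
    problem = translate_requirement(parse_requirement(examples.REQUIREMENT_SNR_CSF))
    assert (problem.goal_metric, problem.direction) == ("SNR_CSF", "maximize")
    assert [(c.lhs, c.relation, c.rhs) for c in problem.strict] == [
        ("SHARPNESS", "gt", 0.85)
    ]
    assert [(c.lhs, c.relation, c.rhs) for c in problem.vague] == [
        ("GHOST", "lt", 0.05),
        ("MOTION_SENS", "lt", 0.05),
        ("DISTORTION_SENS", "lt", 0.05),
        ("CGC", "gt", 10.0),
        ("CWC", "gt", 10.0),
    ]
    assert problem.artifact_flags == {"GHOST", "MOTION_SENS", "DISTORTION_SENS"}


def test_translate_goal_only():
    problem = translate_requirement(
        parse_requirement('define optimization requirement : minimize "ACQ_TIME".')
    )
    assert problem.direction == "minimize"
    assert problem.strict == [] and problem.vague == []


def test_translation_preserves_constraint_order():
    req = parse_requirement(examples.REQUIREMENT_SNR_CSF)
    problem = translate_requirement(req)
    assert [c.lhs for c in problem.vague] == [v.metric for v in req.vague_constraints]


def test_ordinal_dictionary_monotone_in_quantifier():
    dictionary = OrdinalDictionary()
    for metric in ("CGC", "SNR_GM", "SHARPNESS"):
        bounds = [
            dictionary.resolve(VagueConstraint("aim", metric, q)).rhs
            for q in ("very_low", "low", "decent", "high", "very_high")
        ]
        assert bounds == sorted(bounds) and len(set(bounds)) == 5


def test_ordinal_dictionary_requires_quantifier_for_aim():
    with pytest.raises(DSLError, match="quantifier"):
        OrdinalDictionary().resolve(VagueConstraint("aim", "CGC", None))


def test_avoid_applies_to_artifact_metrics_only():
    with pytest.raises(DSLError):
        OrdinalDictionary().resolve(VagueConstraint("avoid", "CGC"))
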