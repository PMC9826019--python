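"""Expression-profile types, the modified H-score, and the two scorers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2refine.profiles import (
    PATTERN_FIELDS,
    ExpressionProfile,
    Her2Score,
    ProfileValidationError,
    RefinedRuleSet,
    guideline_score,
    modified_h_score,
    refined_score,
    validate_profile,
)


def profile(**kwargs) -> ExpressionProfile:
    return ExpressionProfile(case_id="t", **kwargs)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def test_all_zero_profile_is_valid():
    assert validate_profile(profile()) == []


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"weak_complete": 120.0}, "weak_complete"),
        ({"cytoplasmic_pct": -5.0}, "cytoplasmic_pct"),
        ({"faint_complete": float("nan")}, "faint_complete"),
    ],
)
def test_out_of_range_percentage_is_flagged(kwargs, field):
    violations = validate_profile(profile(**kwargs))
    assert len(violations) == 1
    assert violations[0].field == field


def test_membranous_sum_over_100_is_one_violation():
    violations = validate_profile(profile(weak_complete=60.0, moderate_complete=60.0))
    assert [v.field for v in violations] == ["membranous_total"]


def test_scorers_reject_invalid_profiles_naming_the_field():
    bad = profile(weak_complete=120.0)
    for fn in (modified_h_score, refined_score, guideline_score):
        with pytest.raises(ProfileValidationError, match="weak_complete"):
            fn(bad)


def test_cytoplasmic_sum_is_independent_of_membranous_budget():
    # 100% membranous staining plus co-occurring cytoplasmic staining is legal.
    assert validate_profile(profile(strong_complete=100.0, cytoplasmic_pct=80.0)) == []


# ---------------------------------------------------------------------------
# modified H-score
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({"strong_complete": 100.0}, 300.0),  # maximal single term
        ({"faint_incomplete": 100.0}, 25.0),  # 100 x 0.5 x 0.5
        ({"weak_complete": 20.0, "moderate_incomplete": 30.0}, 50.0),
        ({"faint_complete": 10.0, "weak_incomplete": 10.0}, 10.0),
        ({}, 0.0),
    ],
)
def test_modified_h_score_examples(kwargs, expected):
    assert float(modified_h_score(profile(**kwargs))) == pytest.approx(expected)


def test_h_score_excludes_cytoplasmic_staining():
    assert float(modified_h_score(profile(cytoplasmic_pct=90.0))) == 0.0


@st.composite
def valid_pattern_vector(draw, scale=1.0):
    raw = [draw(st.floats(0, 100)) for _ in PATTERN_FIELDS]
    total = sum(raw)
    if total > 100.0 * scale:
        raw = [v * 100.0 * scale / total * 0.999 for v in raw]
    return dict(zip(PATTERN_FIELDS, raw))


@settings(derandomize=True, max_examples=60)
@given(a=valid_pattern_vector(scale=0.5), b=valid_pattern_vector(scale=0.5))
def test_h_score_is_linear_in_the_profile(a, b):
    ab = {k: a[k] + b[k] for k in a}
    total = float(modified_h_score(profile(**ab)))
    parts = float(modified_h_score(profile(**a))) + float(modified_h_score(profile(**b)))
    assert total == pytest.approx(parts, abs=1e-9)


def test_h_score_range_is_0_to_300():
    with pytest.raises(ProfileValidationError):
        modified_h_score(profile(strong_complete=101.0))


# ---------------------------------------------------------------------------
# refined scorer truth table
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        # The four refined 1+ rules
        ({"faint_incomplete": 25.0}, "1+"),  # faint >= 20, any completeness
        ({"faint_complete": 25.0}, "1+"),
        ({"faint_complete": 10.0, "faint_incomplete": 12.0}, "1+"),  # pooled 22
        ({"faint_incomplete": 15.0}, "0"),  # below every 1+ rule
        ({"faint_complete": 19.9}, "0"),
        ({"faint_complete": 20.0}, "1+"),  # boundary inclusive
        ({"weak_complete": 8.0}, "1+"),  # weak complete <= 10 (present)
        ({"weak_complete": 10.0}, "1+"),
        ({"weak_incomplete": 10.0}, "0"),  # weak incomplete needs > 10
        ({"weak_incomplete": 10.1}, "1+"),
        ({"moderate_incomplete": 5.0}, "1+"),  # moderate incomplete <= 10
        ({"moderate_incomplete": 10.0}, "1+"),
        # Upper categories retained / figure-resolved scenarios
        ({"moderate_incomplete": 15.0}, "2+"),
        ({"moderate_complete": 5.0}, "1+"),
        ({"moderate_complete": 40.0}, "2+"),
        ({"weak_complete": 15.0}, "2+"),
        ({"strong_incomplete": 5.0}, "1+"),
        ({"strong_incomplete": 30.0}, "2+"),
        ({"strong_complete": 5.0}, "2+"),
        ({"strong_complete": 50.0}, "3+"),
        # Zero-percentage guards: an unstained case is 0, not 1+
        ({}, "0"),
        ({"cytoplasmic_pct": 60.0}, "0"),
        # Heterogeneous mixtures score the maximum triggered category
        ({"faint_incomplete": 30.0, "moderate_complete": 20.0}, "2+"),
        ({"weak_incomplete": 15.0, "strong_complete": 20.0}, "3+"),
    ],
)
def test_refined_score_truth_table(kwargs, expected):
    assert str(refined_score(profile(**kwargs))) == expected


def test_moderate_incomplete_boundary_is_configurable():
    strict = RefinedRuleSet(moderate_incomplete_inclusive=False)
    p = profile(moderate_incomplete=10.0)
    assert str(refined_score(p)) == "1+"  # default: <= 10 is 1+
    assert str(refined_score(p, strict)) == "2+"  # strict reading: < 10


def test_refined_score_ignores_cytoplasmic_and_total_percentage():
    base = profile(faint_incomplete=25.0)
    with_cyt = profile(faint_incomplete=25.0, cytoplasmic_pct=95.0)
    assert refined_score(base) == refined_score(with_cyt)


def test_custom_thresholds_shift_the_rule_boundaries():
    rules = RefinedRuleSet(faint_total_threshold=30.0)
    assert str(refined_score(profile(faint_incomplete=25.0), rules)) == "0"
    assert str(refined_score(profile(faint_incomplete=35.0), rules)) == "1+"


# ---------------------------------------------------------------------------
# guideline scorer
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({"faint_incomplete": 15.0}, "1+"),
        ({"faint_incomplete": 5.0}, "0"),
        ({"weak_incomplete": 15.0}, "1+"),
        ({"moderate_complete": 40.0}, "2+"),
        ({"weak_complete": 15.0}, "2+"),
        ({"strong_complete": 8.0}, "2+"),
        ({"strong_complete": 60.0}, "3+"),
        ({"faint_complete": 30.0}, "0"),  # undefined under the guideline
    ],
)
def test_guideline_score_truth_table(kwargs, expected):
    assert str(guideline_score(profile(**kwargs))) == expected


def test_refinement_reclassifies_low_faint_incomplete_downward():
    # Faint incomplete in 10-20%: guideline 1+, refined 0.
    p = profile(faint_incomplete=15.0)
    assert str(guideline_score(p)) == "1+"
    assert str(refined_score(p)) == "0"


@settings(derandomize=True, max_examples=100)
@given(pct=st.floats(10.0, 100.0, exclude_min=True))
def test_scorers_agree_on_weak_incomplete_and_strong_complete(pct):
    wi = profile(weak_incomplete=pct)
    assert refined_score(wi) == guideline_score(wi) == Her2Score(1)
    sc = profile(strong_complete=pct)
    assert refined_score(sc) == guideline_score(sc) == Her2Score(3)


# ---------------------------------------------------------------------------
# ordering, monotonicity, totality
# ---------------------------------------------------------------------------


def test_scores_are_totally_ordered_and_parse_round_trip():
    scores = [Her2Score.parse(s) for s in ("0", "1+", "2+", "3+")]
    assert scores == sorted(scores)
    assert [str(s) for s in scores] == ["0", "1+", "2+", "3+"]
    with pytest.raises(ValueError):
        Her2Score(4)


def _random_valid_profile(rng) -> dict:
    raw = rng.uniform(0, 40, size=8) * (rng.random(8) < 0.4)
    total = raw.sum()
    if total > 100:
        raw *= 100.0 / total
    return dict(zip(PATTERN_FIELDS, raw))


def test_refined_score_is_total_over_random_profiles(rng):
    seen = set()
    for _ in range(10_000):
        score = refined_score(profile(**_random_valid_profile(rng)))
        seen.add(str(score))
    assert seen <= {"0", "1+", "2+", "3+"}


def test_refined_score_is_monotone_in_every_pattern(rng):
    """Increasing any single pattern percentage never lowers the score."""
    for _ in range(400):
        kwargs = _random_valid_profile(rng)
        base = refined_score(profile(**kwargs))
        name = rng.choice(PATTERN_FIELDS)
        headroom = 100.0 - sum(kwargs.values())
        if headroom <= 0:
            continue
        bumped = dict(kwargs)
        bumped[name] += rng.uniform(0, headroom)
        assert refined_score(profile(**bumped)) >= base
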