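"""Domain types and scoring engines for detailed HER2 IHC expression profiles.

HER2 immunohistochemistry on invasive breast carcinoma is read per case as
the percentage of invasive tumour cells showing membranous staining at each
of four intensity grades -- faint, weak, moderate, strong -- each further
split by circumferential completeness (complete vs incomplete lateral or
basolateral staining).  Intensity grades follow the magnification rule used
to standardise reads between observers: strong staining is unequivocal at
low power (2-4x), moderate at ~10x, weak at ~20x, and faint staining can
only be appreciated at 40x magnification.  That rule is an annotation
convention for the microscope, not something this module computes.

Three scoring engines operate on a profile:

* :func:`modified_h_score` -- a weighted percentage sum extending the
  classical H-score with a 0.5 weight for faint intensity and a 0.5
  multiplier for incomplete membranous staining.
* :func:`guideline_score` -- the existing ASCO/CAP-style 0/1+/2+/3+ rules,
  kept as the comparator.
* :func:`refined_score` -- the refined rule set that redefines the 1+
  (HER2-low eligible) category, parameterised by :class:`RefinedRuleSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

__all__ = [
    "INTENSITIES",
    "COMPLETENESS",
    "PATTERNS",
    "PATTERN_FIELDS",
    "INTENSITY_WEIGHTS",
    "COMPLETENESS_WEIGHTS",
    "ProfileValidationError",
    "ProfileViolation",
    "Her2Score",
    "HScore",
    "ExpressionProfile",
    "RefinedRuleSet",
    "validate_profile",
    "modified_h_score",
    "refined_score",
    "guideline_score",
]

INTENSITIES = ("faint", "weak", "moderate", "strong")
COMPLETENESS = ("complete", "incomplete")
#: The eight membranous staining patterns, strongest-first is NOT implied;
#: ordering here simply fixes the CSV column order.
PATTERNS = tuple((i, c) for i in INTENSITIES for c in COMPLETENESS)
PATTERN_FIELDS = tuple(f"{i}_{c}" for i, c in PATTERNS)

#: Intensity weights of the modified H-score.
INTENSITY_WEIGHTS = {"faint": 0.5, "weak": 1.0, "moderate": 2.0, "strong": 3.0}
#: Completeness multipliers of the modified H-score.
COMPLETENESS_WEIGHTS = {"complete": 1.0, "incomplete": 0.5}


class ProfileValidationError(ValueError):
    """Raised when a profile violates its invariants.

    Carries the list of :class:`ProfileViolation` that triggered it.
    """

    def __init__(self, violations: list["ProfileViolation"]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


@dataclass(frozen=True)
class ProfileViolation:
    """One invariant violation: which field, what was observed, what holds."""

    field: str
    value: float
    constraint: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.constraint}"


@dataclass(frozen=True, order=True)
class Her2Score:
    """Ordinal IHC score, one of 0, 1+, 2+, 3+ (totally ordered)."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3):
            raise ValueError(f"HER2 score must be 0..3, got {self.value!r}")

    def __str__(self) -> str:
        return "0" if self.value == 0 else f"{self.value}+"

    @classmethod
    def parse(cls, text: str | int | "Her2Score") -> "Her2Score":
        if isinstance(text, Her2Score):
            return text
        if isinstance(text, int):
            return cls(text)
        t = str(text).strip().rstrip("+")
        try:
            return cls(int(t))
        except ValueError as exc:
            raise ValueError(f"cannot parse HER2 score {text!r}") from exc


@dataclass(frozen=True, order=True)
class HScore:
    """Modified H-score value.

    Under the profile invariant (membranous percentages sum to at most 100)
    the attainable range is [0, 300]: the maximum is 100% strong complete
    staining, 100 x 3 x 1.
    """

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 300.0 + 1e-9):
            raise ValueError(f"H-score out of range [0, 300]: {self.value}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-case HER2 staining profile.

    Each of the eight membranous fields is the percentage (0-100) of
    invasive tumour cells whose *strongest* membranous pattern is that
    intensity x completeness combination, so the eight percentages sum to
    at most 100; the remainder is unstained (score-0) cells.  Cytoplasmic
    staining may co-occur with membranous staining and is tracked
    independently.
    """

    case_id: str = ""
    faint_complete: float = 0.0
    faint_incomplete: float = 0.0
    weak_complete: float = 0.0
    weak_incomplete: float = 0.0
    moderate_complete: float = 0.0
    moderate_incomplete: float = 0.0
    strong_complete: float = 0.0
    strong_incomplete: float = 0.0
    cytoplasmic_pct: float = 0.0

    def get(self, intensity: str, completeness: str) -> float:
        return float(getattr(self, f"{intensity}_{completeness}"))

    @property
    def pct(self) -> dict[tuple[str, str], float]:
        """Mapping (intensity, completeness) -> percentage."""
        return {(i, c): self.get(i, c) for i, c in PATTERNS}

    @property
    def membranous_total(self) -> float:
        """Total percentage of cells with any membranous staining."""
        return float(sum(self.pct.values()))

    @property
    def faint_total(self) -> float:
        """Faint staining pooled across completeness."""
        return self.faint_complete + self.faint_incomplete

    def iter_patterns(self) -> Iterator[tuple[str, str, float]]:
        for i, c in PATTERNS:
            yield i, c, self.get(i, c)


def validate_profile(profile: ExpressionProfile) -> list[ProfileViolation]:
    """Return all invariant violations of *profile* (empty list if valid)."""
    violations: list[ProfileViolation] = []
    for name in (*PATTERN_FIELDS, "cytoplasmic_pct"):
        v = getattr(profile, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            violations.append(ProfileViolation(name, v, "must be a finite number"))
        elif not (0.0 <= v <= 100.0):
            violations.append(ProfileViolation(name, v, "percentage must be in [0, 100]"))
    total = profile.membranous_total
    # The sum constraint is only meaningful once every field is in range.
    if not violations and math.isfinite(total) and total > 100.0 + 1e-9:
        violations.append(
            ProfileViolation(
                "membranous_total",
                total,
                "sum of the 8 membranous percentages must be <= 100",
            )
        )
    return violations


def _require_valid(profile: ExpressionProfile) -> None:
    violations = validate_profile(profile)
    if violations:
        raise ProfileValidationError(violations)


def modified_h_score(profile: ExpressionProfile) -> HScore:
    """Modified H-score: sum of percentage x intensity weight x completeness weight.

    Faint, weak, moderate and strong intensities carry weights 0.5, 1, 2
    and 3; incomplete membranous staining is multiplied by 0.5 and complete
    by 1.  Cytoplasmic staining is excluded.  Range [0, 300].
    """
    _require_valid(profile)
    total = 0.0
    for intensity, completeness, pct in profile.iter_patterns():
        total += pct * INTENSITY_WEIGHTS[intensity] * COMPLETENESS_WEIGHTS[completeness]
    return HScore(total)


@dataclass(frozen=True)
class RefinedRuleSet:
    """Thresholds of the refined HER2 scorer.

    The four 1+ thresholds are the refinement proper:

    * faint (complete + incomplete pooled) in >= ``faint_total_threshold`` %
    * weak complete in (0, ``weak_complete_max``] %
    * weak incomplete in > ``weak_incomplete_min`` %
    * moderate incomplete in (0, ``moderate_incomplete_max``] %

    ``upper_threshold`` is the retained 10% boundary of the existing upper
    categories (weak/moderate complete 2+, strong 2+/3+).  Rules of the
    "<= theta" form additionally require a strictly positive percentage,
    otherwise an entirely unstained case would trivially satisfy them.

    ``moderate_incomplete_inclusive`` toggles "<= 10%" (default) versus the
    strict "< 10%" reading of the moderate-incomplete boundary.
    """

    faint_total_threshold: float = 20.0
    weak_complete_max: float = 10.0
    weak_incomplete_min: float = 10.0
    moderate_incomplete_max: float = 10.0
    upper_threshold: float = 10.0
    moderate_incomplete_inclusive: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "moderate_incomplete_inclusive":
                continue
            v = getattr(self, f.name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{f.name} must lie in (0, 100), got {v!r}")

    def with_overrides(self, **kwargs: float) -> "RefinedRuleSet":
        return replace(self, **kwargs)


def refined_score(
    profile: ExpressionProfile, rules: RefinedRuleSet | None = None
) -> Her2Score:
    """Score a profile under the refined rules.

    Categories are evaluated from highest to lowest (3+, 2+, 1+, 0) and the
    first category any pattern triggers is returned, so a heterogeneous case
    scores the maximum category among its patterns.  Cytoplasmic staining
    and the total percentage of positive cells never influence the result.
    """
    rules = rules or RefinedRuleSet()
    _require_valid(profile)

    u = rules.upper_threshold
    mi = profile.moderate_incomplete
    if rules.moderate_incomplete_inclusive:
        mi_is_low = 0.0 < mi <= rules.moderate_incomplete_max
        mi_is_high = mi > rules.moderate_incomplete_max
    else:
        mi_is_low = 0.0 < mi < rules.moderate_incomplete_max
        mi_is_high = mi >= rules.moderate_incomplete_max

    # 3+: retained existing-guideline criterion.
    if profile.strong_complete > u:
        return Her2Score(3)

    # 2+: retained upper categories plus the scenarios the refinement
    # resolves monotonically (strong incomplete > 10, moderate patterns
    # above their boundary, weak complete above the 1+ ceiling, strong
    # complete present but <= 10%).
    if (
        profile.weak_complete > rules.weak_complete_max
        or profile.moderate_complete > u
        or mi_is_high
        or profile.strong_incomplete > u
        or 0.0 < profile.strong_complete <= u
    ):
        return Her2Score(2)

    # 1+: the four refined rules (faint pooled across completeness) plus
    # the low-percentage scenarios resolved to 1+ (moderate complete and
    # strong incomplete present in <= 10%).
    if (
        profile.faint_total >= rules.faint_total_threshold
        or 0.0 < profile.weak_complete <= rules.weak_complete_max
        or profile.weak_incomplete > rules.weak_incomplete_min
        or mi_is_low
        or 0.0 < profile.moderate_complete <= u
        or 0.0 < profile.strong_incomplete <= u
    ):
        return Her2Score(1)

    return Her2Score(0)


def guideline_score(profile: ExpressionProfile) -> Her2Score:
    """Score a profile under the existing ASCO/CAP-style definitions.

    3+ is complete strong staining in > 10% of cells; 2+ is weak-to-moderate
    complete staining in > 10% or strong complete staining in <= 10% (but
    present); 1+ is incomplete staining that is faint or weak in > 10% of
    cells; anything else is 0.  The guideline leaves the remaining pattern
    combinations undefined -- they fall through to 0 here, which is the gap
    the refined scorer closes.
    """
    _require_valid(profile)
    if profile.strong_complete > 10.0:
        return Her2Score(3)
    if (
        profile.weak_complete > 10.0
        or profile.moderate_complete > 10.0
        or 0.0 < profile.strong_complete <= 10.0
    ):
        return Her2Score(2)
    if profile.faint_incomplete > 10.0 or profile.weak_incomplete > 10.0:
        return Her2Score(1)
    return Her2Score(0)
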