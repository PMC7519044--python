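"""WOMAC instrument: scoring, subscales, and severity classification.

The WOMAC (Western Ontario and McMaster Universities Osteoarthritis Index)
is a 24-item patient-reported outcome: 5 pain items, 2 stiffness items and
17 physical-function items, each answered on a 0 (none) .. 4 (extreme)
Likert scale.  The total ranges 0..96.

Severity classes are derived from cut points placed at the midpoints of the
per-item response levels: 1.5 (between "mild" and "moderate" responses) and
2.5 (between "moderate" and "severe"), each multiplied by the number of
items on the scale.  For the 24-item total this gives cut points 36 and 60:
scores below 36 are *mild*, scores from 36 to 60 inclusive are *moderate*,
and scores above 60 are *severe*.  Subscales use the same construction with
their own item counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

from .errors import ValidationError

#: Subscale block sizes, in canonical item order (LK 3.0 ordering: the five
#: pain items first, then the two stiffness items, then the seventeen
#: physical-function items).  Only block membership matters computationally.
SUBSCALE_ITEMS = {"pain": 5, "stiffness": 2, "physical_function": 17}
N_ITEMS = 24
ITEM_MAX = 4

SEVERITY_LABELS = ("mild", "moderate", "severe")

#: Boundary convention: both cut points map to "moderate" ("between 36 and
#: 60" read as inclusive, "below 36"/"above 60" as strict).  Set to False
#: for the half-open variant where the upper cut starts "severe".
BOUNDARIES_INCLUSIVE_TO_MODERATE = True


@dataclass(frozen=True)
class SeverityClass:
    """One of the three ordered severity labels, tagged with the scale
    (``total`` or a subscale name) it classifies."""

    label: str
    scale: str = "total"

    def __post_init__(self):
        if self.label not in SEVERITY_LABELS:
            raise ValidationError(f"unknown severity label {self.label!r}")

    @property
    def rank(self) -> int:
        return SEVERITY_LABELS.index(self.label)

    def __lt__(self, other: "SeverityClass") -> bool:
        return self.rank < other.rank


@dataclass(frozen=True)
class WOMACRecord:
    """One subject's 24 item responses with derived total and subscales."""

    subject_id: str
    items: Tuple[int, ...]
    total: int = field(init=False)

    def __post_init__(self):
        _validate_items(self.items)
        object.__setattr__(self, "total", int(sum(self.items)))

    @property
    def pain(self) -> int:
        return int(sum(self.items[0:5]))

    @property
    def stiffness(self) -> int:
        return int(sum(self.items[5:7]))

    @property
    def physical_function(self) -> int:
        return int(sum(self.items[7:24]))

    def subscale_score(self, subscale: str) -> int:
        if subscale not in SUBSCALE_ITEMS:
            raise ValidationError(
                f"unknown subscale {subscale!r}; expected one of {sorted(SUBSCALE_ITEMS)}"
            )
        return getattr(self, subscale)


def _validate_items(items: Sequence[int]) -> None:
    if len(items) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} item responses, got {len(items)}")
    for i, v in enumerate(items):
        if not float(v).is_integer() or not (0 <= int(v) <= ITEM_MAX):
            raise ValidationError(
                f"item {i + 1} has value {v!r}; responses must be integers in 0..{ITEM_MAX}"
            )


def score_womac(items: Sequence[int], subject_id: str = "anonymous") -> WOMACRecord:
    """Score a complete set of 24 item responses by plain summation.

    Items must be in canonical order (5 pain, 2 stiffness, 17 physical
    function).  Incomplete or out-of-range responses are rejected; there is
    no imputation.
    """
    _validate_items(items)
    return WOMACRecord(subject_id=subject_id, items=tuple(int(v) for v in items))


def severity_cutpoints(n_items: int) -> Tuple[float, float]:
    """Severity cut points for a scale with ``n_items`` 0..4 items.

    The mild/moderate cut is the 1.5 midpoint response level times the item
    count; the moderate/severe cut is the 2.5 midpoint times the item count.
    For the 24-item total this yields (36.0, 60.0).
    """
    if not float(n_items).is_integer() or n_items < 1:
        raise ValidationError(f"n_items must be a positive integer, got {n_items!r}")
    return (1.5 * n_items, 2.5 * n_items)


def classify_severity(
    score: float,
    cutpoints: Tuple[float, float],
    scale: str = "total",
    *,
    inclusive_moderate: bool = BOUNDARIES_INCLUSIVE_TO_MODERATE,
) -> SeverityClass:
    """Assign mild/moderate/severe given a score and (lower, upper) cuts.

    The instrument range implied by the cut points is [0, 4 * n_items]
    (upper cut = 2.5 * n_items, so the maximum is 1.6 * upper); scores
    outside it are rejected.
    """
    lower, upper = cutpoints
    if not lower < upper:
        raise ValidationError(f"cut points must satisfy lower < upper, got {cutpoints}")
    score_max = upper * 1.6  # 4 * n_items
    if not (0 <= score <= score_max):
        raise ValidationError(
            f"score {score} outside the instrument range [0, {score_max}] for scale {scale!r}"
        )
    if inclusive_moderate:
        if score < lower:
            label = "mild"
        elif score <= upper:
            label = "moderate"
        else:
            label = "severe"
    else:
        if score < lower:
            label = "mild"
        elif score < upper:
            label = "moderate"
        else:
            label = "severe"
    return SeverityClass(label=label, scale=scale)


def classify_total(record: WOMACRecord) -> SeverityClass:
    """Severity class of the 24-item total (cuts 36/60)."""
    return classify_severity(record.total, severity_cutpoints(N_ITEMS), scale="total")


def classify_subscale(record: WOMACRecord, subscale: str) -> SeverityClass:
    """Severity class of one subscale, using the same midpoint construction
    with that subscale's item count (pain 7.5/12.5, stiffness 3/5,
    physical function 25.5/42.5)."""
    if subscale not in SUBSCALE_ITEMS:
        raise ValidationError(
            f"unknown subscale {subscale!r}; expected one of {sorted(SUBSCALE_ITEMS)}"
        )
    cuts = severity_cutpoints(SUBSCALE_ITEMS[subscale])
    return classify_severity(record.subscale_score(subscale), cuts, scale=subscale)
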