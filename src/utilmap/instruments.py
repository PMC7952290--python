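"""QoL-AD and EQ-5D instrument types, response encoding and composite scoring.

The QoL-AD is a 13-item Alzheimer's-disease-specific quality-of-life
questionnaire. Each item is answered on a four-point ordinal scale
(poor / fair / good / excellent, scored 1-4) and the composite score is the
item sum, ranging 13-52. Item 7 concerns the respondent's marriage and is
frequently inapplicable, so analyses routinely drop it; the 12-item sum is
then rescaled (standardised) back onto the 13-52 range so composite scores
remain comparable.

The EQ-5D is a generic five-dimension health-status instrument (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression) with
either three (3L) or five (5L) severity levels per dimension; a profile of
levels is a "health state" to which a value set attaches a utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Integral
from typing import Optional, Sequence

from .exceptions import EncodingError, MissingItemsError, StateError

N_ITEMS = 13
ITEM_MARRIAGE = 7  # 1-based index of the item dropped in the 12-item score

#: QoL-AD response labels in ascending order of quality of life.
QOLAD_LABELS = ("poor", "fair", "good", "excellent")
_LABEL_TO_LEVEL = {lab: i + 1 for i, lab in enumerate(QOLAD_LABELS)}

#: EQ-5D dimensions in the instrument's printed order, with short codes.
EQ5D_DIMENSIONS = (
    ("mo", "mobility"),
    ("sc", "self_care"),
    ("ua", "usual_activities"),
    ("pd", "pain_discomfort"),
    ("ad", "anxiety_depression"),
)
EQ5D_CODES = tuple(code for code, _ in EQ5D_DIMENSIONS)

RATERS = ("self", "proxy")
SEXES = ("female", "male")

# The 12-item sum ranges 12-48; the affine map below is the unique one
# sending [12, 48] onto [13, 52], reproducing published worked examples
# (sum 23 -> 24.9, sum 32 -> 34.7, sum 42 -> 45.5 at 1 d.p.).
_STD_SLOPE = 39.0 / 36.0


def encode_response(label) -> int:
    """Encode a QoL-AD response as an ordinal level 1-4.

    Accepts the four labels (case-insensitively, surrounding whitespace
    ignored) or an integer / integer-like string already in 1-4.

    >>> encode_response("Fair")
    2
    """
    if isinstance(label, bool):
        raise EncodingError(f"unrecognised QoL-AD response: {label!r}")
    if isinstance(label, int):
        if 1 <= label <= 4:
            return label
        raise EncodingError(f"QoL-AD response out of range 1-4: {label!r}")
    if isinstance(label, float):
        if label.is_integer():
            return encode_response(int(label))
        raise EncodingError(f"unrecognised QoL-AD response: {label!r}")
    if isinstance(label, str):
        text = label.strip().lower()
        if text in _LABEL_TO_LEVEL:
            return _LABEL_TO_LEVEL[text]
        try:
            value = int(text)
        except ValueError:
            raise EncodingError(f"unrecognised QoL-AD response: {label!r}") from None
        return encode_response(value)
    raise EncodingError(f"unrecognised QoL-AD response: {label!r}")


@dataclass(frozen=True)
class QolAdRecord:
    """One rater's QoL-AD questionnaire for one subject-visit.

    Parameters
    ----------
    items : sequence of length 13
        Ordinal responses in {1, 2, 3, 4}; ``None`` marks a missing item.
        Item 7 (marriage) may legitimately be missing on its own.
    """

    subject_id: str
    visit: int
    rater: str
    items: tuple
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self):
        if self.rater not in RATERS:
            raise ValueError(f"rater must be one of {RATERS}, got {self.rater!r}")
        items = tuple(self.items)
        if len(items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item slots, got {len(items)}")
        for i, v in enumerate(items, start=1):
            if v is not None and (not isinstance(v, Integral) or isinstance(v, bool) or not 1 <= v <= 4):
                raise ValueError(f"item {i} must be in 1-4 or None, got {v!r}")
        object.__setattr__(self, "items", tuple(None if v is None else int(v) for v in items))
        if self.age is not None and not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    def missing_items(self, include_item7: bool = True) -> tuple:
        """1-based indices of missing items among those required."""
        return tuple(
            i
            for i, v in enumerate(self.items, start=1)
            if v is None and (include_item7 or i != ITEM_MARRIAGE)
        )


@dataclass(frozen=True)
class Eq5dState:
    """An EQ-5D health-state profile, at 3 or 5 levels per dimension."""

    version: str
    levels: tuple

    def __post_init__(self):
        if self.version not in ("3L", "5L"):
            raise StateError(f"version must be '3L' or '5L', got {self.version!r}")
        levels = tuple(self.levels)
        top = 3 if self.version == "3L" else 5
        if len(levels) != 5:
            raise StateError(f"expected 5 dimension levels, got {len(levels)}")
        for code, lv in zip(EQ5D_CODES, levels):
            if not isinstance(lv, Integral) or isinstance(lv, bool) or not 1 <= lv <= top:
                raise StateError(
                    f"dimension {code!r} level must be an integer in 1-{top}, got {lv!r}"
                )
        object.__setattr__(self, "levels", tuple(int(v) for v in levels))

    @property
    def is_full_health(self) -> bool:
        return all(lv == 1 for lv in self.levels)

    def __str__(self):
        return "".join(str(lv) for lv in self.levels)


def score_qolad(record, include_item7: bool = False) -> float:
    """Composite QoL-AD score on the 13-52 scale.

    With ``include_item7`` the score is the plain 13-item sum (an integer).
    Without it, the 12-item sum is standardised back onto [13, 52]::

        score = 13 + (sum_of_12 - 12) * 39/36

    so that all-poor still scores 13 and all-excellent still scores 52.

    Parameters
    ----------
    record : QolAdRecord or sequence of 13 responses (ints or ``None``)
    include_item7 : bool
        Whether item 7 (marriage) enters the score.

    Raises
    ------
    MissingItemsError
        If any required item is missing; the exception lists them.
    """
    items = record.items if isinstance(record, QolAdRecord) else tuple(record)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item slots, got {len(items)}")
    required = [
        (i, v)
        for i, v in enumerate(items, start=1)
        if include_item7 or i != ITEM_MARRIAGE
    ]
    missing = [i for i, v in required if v is None]
    if missing:
        raise MissingItemsError(missing)
    total = sum(v for _, v in required)
    if include_item7:
        return float(total)
    return 13.0 + (total - 12) * _STD_SLOPE
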