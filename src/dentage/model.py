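"""Core data model: FDI tooth notation, per-tooth observations, subjects, estimates.

Teeth are identified in FDI (ISO 3950) two-digit notation: the first digit is
the quadrant (1 = maxillary right, 2 = maxillary left, 3 = mandibular left,
4 = mandibular right), the second the position from the midline (1 = central
incisor ... 8 = third molar).  Third molars are far too variable to inform
age estimation and are never consumed by either estimator, although the data
model accepts them so that real exports load without preprocessing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "ToothCode",
    "parse_fdi",
    "ApexStatus",
    "ApexRecord",
    "Stage",
    "StageRecord",
    "Sex",
    "CohortRecord",
    "DAEstimate",
    "FLAG_SUB_NINE",
    "FLAG_INCONSISTENT",
    "FLAG_INCOMPLETE",
    "FLAG_LOW_CONFIDENCE",
]

FLAG_SUB_NINE = "sub_nine"
FLAG_INCONSISTENT = "inconsistent_sequence"
FLAG_INCOMPLETE = "incomplete_data"
FLAG_LOW_CONFIDENCE = "low_confidence"


@dataclass(frozen=True, order=True)
class ToothCode:
    """A permanent tooth in FDI two-digit notation."""

    quadrant: int
    position: int

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError(f"FDI quadrant must be 1-4, got {self.quadrant}")
        if self.position not in range(1, 9):
            raise ValueError(f"FDI position must be 1-8, got {self.position}")

    @property
    def fdi(self) -> str:
        return f"{self.quadrant}{self.position}"

    @property
    def is_third_molar(self) -> bool:
        return self.position == 8

    @property
    def is_maxillary(self) -> bool:
        return self.quadrant in (1, 2)

    @property
    def is_mandibular_left(self) -> bool:
        return self.quadrant == 3

    @property
    def contralateral(self) -> "ToothCode":
        """Mirror tooth across the midline (11 <-> 21, 31 <-> 41, ...)."""
        mirror = {1: 2, 2: 1, 3: 4, 4: 3}
        return ToothCode(mirror[self.quadrant], self.position)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.fdi


def parse_fdi(code_text: str) -> ToothCode:
    """Parse a two-digit FDI code such as ``"31"`` into a :class:`ToothCode`.

    Raises
    ------
    ValueError
        If the token is not two decimal digits or either digit is out of
        range; the message names the offending token.
    """
    text = str(code_text).strip()
    if len(text) != 2 or not text.isdigit():
        raise ValueError(f"invalid FDI tooth code {code_text!r}: expected two digits")
    quadrant, position = int(text[0]), int(text[1])
    try:
        return ToothCode(quadrant, position)
    except ValueError as exc:
        raise ValueError(f"invalid FDI tooth code {code_text!r}: {exc}") from None


class ApexStatus(str, enum.Enum):
    """Radiographic state of the root apex."""

    CLOSED = "closed"
    OPEN = "open"
    UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class ApexRecord:
    """One tooth's apex observation.

    ``root_fraction`` is the proportion of final root length already formed
    and is only meaningful for an open apex; it drives the fallback estimate
    for children in whom no permanent tooth has yet apexified.
    """

    tooth: ToothCode
    apex_status: ApexStatus
    root_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.root_fraction is not None:
            f = float(self.root_fraction)
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"root_fraction for tooth {self.tooth} must lie in [0, 1], got {f}"
                )
            if self.apex_status is ApexStatus.CLOSED and f != 1.0:
                raise ValueError(
                    f"tooth {self.tooth}: a closed apex implies a complete root "
                    f"(root_fraction absent or 1), got {f}"
                )


class Stage(str, enum.Enum):
    """Demirjian formation stage; UNFORMED precedes crypt calcification."""

    UNFORMED = "UNFORMED"
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"

    @property
    def rank(self) -> int:
        return list(Stage).index(self)


#: The seven left-mandibular teeth a complete Demirjian assessment stages.
DEMIRJIAN_TEETH = tuple(ToothCode(3, p) for p in range(1, 8))


@dataclass(frozen=True)
class StageRecord:
    """Demirjian stage for one left-mandibular tooth (31-37)."""

    tooth: ToothCode
    stage: Stage

    def __post_init__(self) -> None:
        if not (self.tooth.quadrant == 3 and 1 <= self.tooth.position <= 7):
            raise ValueError(
                f"Demirjian stages apply to mandibular-left teeth 31-37, got {self.tooth}"
            )


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


@dataclass
class CohortRecord:
    """One (subject, rater, session) assessment of a dentition.

    Teeth absent from ``apex_records`` are treated as unassessable downstream:
    absence of evidence must not be read as an open apex.
    """

    subject_id: str
    sex: Sex
    chronological_age: float
    rater_id: str = "R1"
    session_id: str = "S1"
    apex_records: dict[ToothCode, ApexRecord] = field(default_factory=dict)
    stage_records: dict[ToothCode, StageRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chronological_age > 0:
            raise ValueError(
                f"subject {self.subject_id}: chronological_age must be positive"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.rater_id, self.session_id)

    def apex_status(self, tooth: ToothCode) -> ApexStatus:
        rec = self.apex_records.get(tooth)
        return rec.apex_status if rec is not None else ApexStatus.UNASSESSABLE

    def has_complete_staging(self) -> bool:
        return all(t in self.stage_records for t in DEMIRJIAN_TEETH)


_VALID_FLAGS = frozenset(
    {FLAG_SUB_NINE, FLAG_INCONSISTENT, FLAG_INCOMPLETE, FLAG_LOW_CONFIDENCE}
)


@dataclass(frozen=True)
class DAEstimate:
    """A dental-age estimate: method tag, point value and range, audit flags.

    The ladder method naturally yields ranges (e.g. 12-13 y); the staging
    method yields a point (low == point == high).  ``sub_nine`` marks the
    root-fraction fallback used when no group has yet apexified, and is set
    exactly when the whole range lies below 9 years.
    """

    method: str
    point: float
    low: float
    high: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.method not in ("becker", "demirjian"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if not (self.low <= self.point <= self.high):
            raise ValueError(
                f"estimate point {self.point} outside range [{self.low}, {self.high}]"
            )
        bad = set(self.flags) - _VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags {sorted(bad)}")
        if (FLAG_SUB_NINE in self.flags) != (self.high < 9.0):
            raise ValueError(
                "sub_nine flag must be set exactly when the estimate range "
                f"lies below 9 years (high={self.high}, flags={sorted(self.flags)})"
            )


def apex_map(records: Iterable[ApexRecord] | Mapping[ToothCode, ApexRecord]) -> dict[ToothCode, ApexRecord]:
    """Normalise an apex-record collection to a tooth-keyed mapping."""
    if isinstance(records, Mapping):
        return dict(records)
    out: dict[ToothCode, ApexRecord] = {}
    for rec in records:
        if rec.tooth in out:
            raise ValueError(f"duplicate apex record for tooth {rec.tooth}")
        out[rec.tooth] = rec
    return out
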