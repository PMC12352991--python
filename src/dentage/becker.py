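"""Stepwise dental-age estimation from root apex closure (Becker's ladder).

The method groups the permanent teeth by eruption timing into an ordered
ladder and reads the panoramic radiograph group by group: dental age (DA) is
the DA value attached to the *last* group in which every assessable member
tooth shows a closed apex.  Apexification normally follows functional
eruption by about three years and, unlike eruption itself, is insensitive to
local factors (crowding, early loss of primary teeth), which is what makes
the ladder a reliable chairside instrument.

Two tooth groups — the maxillary lateral incisors and the mandibular second
premolars — develop too variably to be diagnostic and are excluded from the
ladder by default.  The maxillary laterals can be opted back in
(``include_maxillary_laterals``), which adds a 10.5-11 y rung.

Below a DA of roughly 9 years no permanent tooth has an apexified root, so
the ladder is silent; the fallback interpolates each open tooth's observed
root fraction between a per-tooth root-formation onset age and apex-closure
age (see :func:`estimate_subnine`).
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    FLAG_INCOMPLETE,
    FLAG_INCONSISTENT,
    FLAG_LOW_CONFIDENCE,
    FLAG_SUB_NINE,
    ApexRecord,
    ApexStatus,
    DAEstimate,
    ToothCode,
    apex_map,
    parse_fdi,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BeckerGroup",
    "BeckerLadder",
    "DEFAULT_LADDER",
    "GroupState",
    "group_status",
    "estimate_becker",
    "estimate_subnine",
    "SubnineAnchor",
    "default_subnine_anchors",
]


@dataclass(frozen=True)
class BeckerGroup:
    """One rung of the ladder: a set of teeth sharing eruption timing.

    ``index`` is the ordinal among *assessed* groups (1-8); excluded groups
    carry ``index=None`` and, for the mandibular second premolars, no DA
    values at all.
    """

    index: Optional[int]
    label: str
    member_teeth: frozenset[ToothCode]
    da_low: Optional[float]
    da_high: Optional[float]
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.member_teeth:
            raise ValueError(f"group {self.label!r} has no member teeth")
        if (self.da_low is None) != (self.da_high is None):
            raise ValueError(f"group {self.label!r}: da_low/da_high must come together")
        if self.da_low is not None and self.da_low > self.da_high:
            raise ValueError(f"group {self.label!r}: da_low > da_high")
        if not self.excluded and self.index is None:
            raise ValueError(f"assessed group {self.label!r} needs an index")
        if not self.excluded and self.da_low is None:
            raise ValueError(f"assessed group {self.label!r} needs DA values")

    @property
    def midpoint(self) -> Optional[float]:
        if self.da_low is None:
            return None
        return 0.5 * (self.da_low + self.da_high)


def _teeth(*codes: str) -> frozenset[ToothCode]:
    return frozenset(parse_fdi(c) for c in codes)


class BeckerLadder:
    """Ordered eruption-group ladder with per-group DA values.

    Validates on construction: assessed indices must run 1..n in order with
    strictly increasing DA midpoints, and exactly two groups are excluded
    under the default table.
    """

    def __init__(self, groups: Sequence[BeckerGroup], *, require_exclusions: bool = True):
        self.groups = list(groups)
        assessed = self.assessed()
        if [g.index for g in assessed] != list(range(1, len(assessed) + 1)):
            raise ValueError("assessed group indices must run 1..n in ladder order")
        mids = [g.midpoint for g in assessed]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("assessed groups must have strictly increasing DA midpoints")
        lows = [g.da_low for g in assessed]
        highs = [g.da_high for g in assessed]
        if any(b < a for a, b in zip(lows, lows[1:])) or any(
            b < a for a, b in zip(highs, highs[1:])
        ):
            raise ValueError("assessed group DA endpoints must be non-decreasing")
        if require_exclusions and sum(g.excluded for g in self.groups) != 2:
            raise ValueError("the ladder carries exactly two excluded groups")
        seen: set[ToothCode] = set()
        for g in self.groups:
            if seen & g.member_teeth:
                raise ValueError(f"tooth appears in more than one group: {g.label}")
            seen |= g.member_teeth

    def assessed(self) -> list[BeckerGroup]:
        return [g for g in self.groups if not g.excluded]

    def group_of(self, tooth: ToothCode) -> Optional[BeckerGroup]:
        for g in self.groups:
            if tooth in g.member_teeth:
                return g
        return None

    def with_maxillary_laterals(self) -> "BeckerLadder":
        """Return a ladder in which the maxillary lateral incisors are assessed.

        The group slots into DA order (its 10.5-11 y rung sits between the
        maxillary central incisors and the mandibular canine/first-premolar
        group) and assessed indices are renumbered.
        """
        laterals = _teeth("12", "22")
        specs = []  # (label, teeth, low, high, excluded)
        for g in self.groups:
            excluded = g.excluded and g.member_teeth != laterals
            if g.member_teeth == laterals and g.da_low is None:
                raise ValueError("maxillary lateral group carries no DA values")
            specs.append((g.label, g.member_teeth, g.da_low, g.da_high, excluded))
        specs.sort(
            key=lambda s: 0.5 * (s[2] + s[3]) if s[2] is not None else 13.0
        )
        groups, idx = [], 0
        for label, teeth, low, high, excluded in specs:
            idx += 0 if excluded else 1
            groups.append(
                BeckerGroup(None if excluded else idx, label, teeth, low, high, excluded)
            )
        return BeckerLadder(groups, require_exclusions=False)

    @classmethod
    def from_csv(cls, path) -> "BeckerLadder":
        """Load a ladder from CSV (columns: group_index, label, teeth, da_low,
        da_high, excluded; ``teeth`` is a '+'-joined FDI list).  Lets other
        populations' eruption data drop in without code changes."""
        groups = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                idx = row["group_index"].strip()
                low = row["da_low"].strip()
                high = row["da_high"].strip()
                groups.append(
                    BeckerGroup(
                        index=int(idx) if idx else None,
                        label=row["label"],
                        member_teeth=_teeth(*row["teeth"].split("+")),
                        da_low=float(low) if low else None,
                        da_high=float(high) if high else None,
                        excluded=row["excluded"].strip().lower() in ("1", "true", "yes"),
                    )
                )
        return cls(groups, require_exclusions=False)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["group_index", "label", "teeth", "da_low", "da_high", "excluded"])
            for g in self.groups:
                w.writerow(
                    [
                        g.index if g.index is not None else "",
                        g.label,
                        "+".join(sorted(t.fdi for t in g.member_teeth)),
                        g.da_low if g.da_low is not None else "",
                        g.da_high if g.da_high is not None else "",
                        str(g.excluded).lower(),
                    ]
                )


#: Default ladder, in step order.  DA values in years.
DEFAULT_LADDER = BeckerLadder(
    [
        BeckerGroup(1, "mandibular central incisors", _teeth("31", "41"), 9.0, 9.0),
        BeckerGroup(2, "first permanent molars", _teeth("16", "26", "36", "46"), 9.0, 9.5),
        BeckerGroup(3, "mandibular lateral incisors", _teeth("32", "42"), 9.5, 9.5),
        BeckerGroup(4, "maxillary central incisors", _teeth("11", "21"), 10.0, 10.0),
        BeckerGroup(
            None, "maxillary lateral incisors", _teeth("12", "22"), 10.5, 11.0, excluded=True
        ),
        BeckerGroup(
            5, "mandibular canines and first premolars", _teeth("33", "43", "34", "44"), 12.0, 13.0
        ),
        BeckerGroup(6, "maxillary first premolars", _teeth("14", "24"), 13.0, 14.0),
        BeckerGroup(
            None, "mandibular second premolars", _teeth("35", "45"), None, None, excluded=True
        ),
        BeckerGroup(7, "maxillary canines", _teeth("13", "23"), 14.0, 15.0),
        BeckerGroup(8, "second permanent molars", _teeth("17", "27", "37", "47"), 15.0, 15.0),
    ]
)


class GroupState(enum.Enum):
    CLOSED = "closed"
    OPEN = "open"
    UNKNOWN = "unknown"


def group_status(
    group: BeckerGroup,
    records: Iterable[ApexRecord] | Mapping[ToothCode, ApexRecord],
    *,
    bilateral_fallback: bool = True,
) -> GroupState:
    """Classify a tooth group as closed, open or unknown.

    A group is *closed* only when every assessable member tooth shows a
    closed apex — any open member blocks it — and *unknown* when no member
    can be assessed.  With ``bilateral_fallback`` (default) an unassessable
    tooth inherits its contralateral partner's status, exploiting the
    bilateral symmetry of dental development.
    """
    recmap = apex_map(records)

    def effective(tooth: ToothCode) -> ApexStatus:
        rec = recmap.get(tooth)
        if rec is not None and rec.apex_status is not ApexStatus.UNASSESSABLE:
            return rec.apex_status
        if bilateral_fallback:
            mate = recmap.get(tooth.contralateral)
            if mate is not None and mate.apex_status is not ApexStatus.UNASSESSABLE:
                return mate.apex_status
        return ApexStatus.UNASSESSABLE

    statuses = [effective(t) for t in group.member_teeth]
    if ApexStatus.OPEN in statuses:
        return GroupState.OPEN
    if all(s is ApexStatus.UNASSESSABLE for s in statuses):
        return GroupState.UNKNOWN
    return GroupState.CLOSED


def closed_prefix(states: Sequence[GroupState]) -> tuple[int, bool, bool]:
    """Rule engine over an ordered vector of group states.

    Returns ``(k, skipped_unknown, inconsistent)``: ``k`` is the 1-based
    index of the last group in the longest closed prefix (0 if none), where
    unknown groups are skipped without breaking the chain and the first open
    group ends it; ``skipped_unknown`` reports an unknown group inside the
    prefix, ``inconsistent`` a closed group beyond the first open one.
    """
    k = 0
    unknown_pending = False
    skipped = False
    stopped_at = None
    for i, st in enumerate(states, start=1):
        if stopped_at is None:
            if st is GroupState.UNKNOWN:
                unknown_pending = True
            elif st is GroupState.CLOSED:
                k = i
                if unknown_pending:
                    skipped = True
                    unknown_pending = False
            else:
                stopped_at = i
    inconsistent = stopped_at is not None and any(
        st is GroupState.CLOSED for st in states[stopped_at:]
    )
    return k, skipped, inconsistent


_COLLAPSE = {"low": 0.0, "mid": 0.5, "high": 1.0}


def estimate_becker(
    records: Iterable[ApexRecord] | Mapping[ToothCode, ApexRecord],
    ladder: BeckerLadder = DEFAULT_LADDER,
    *,
    include_maxillary_laterals: bool = False,
    collapse: str = "mid",
    bilateral_fallback: bool = True,
    subnine_anchors: Optional[Mapping[ToothCode, "SubnineAnchor"]] = None,
) -> DAEstimate:
    """Estimate dental age from apex-closure observations.

    Walks the assessed groups in ladder order and returns the DA range of
    the last group of the closed prefix; ``collapse`` (low/mid/high) turns
    the range into the point estimate (midpoint by default).  A closed group
    above an open one is reported with an ``inconsistent_sequence`` flag but
    does not override the prefix reading; unknown (unassessable) groups are
    skipped and flagged ``incomplete_data``.  If the first rung — the
    mandibular central incisors — is open, the subject is below the ladder's
    floor and the root-fraction fallback is used.
    """
    if collapse not in _COLLAPSE:
        raise ValueError(f"collapse must be one of {sorted(_COLLAPSE)}, got {collapse!r}")
    recmap = apex_map(records)
    if all(r.apex_status is ApexStatus.UNASSESSABLE for r in recmap.values()) or not recmap:
        raise ValueError("empty assessment: no assessable apex record")

    if include_maxillary_laterals:
        ladder = ladder.with_maxillary_laterals()
    assessed = ladder.assessed()
    states = [
        group_status(g, recmap, bilateral_fallback=bilateral_fallback) for g in assessed
    ]

    if states[0] is GroupState.OPEN:
        return estimate_subnine(recmap.values(), anchors=subnine_anchors, ladder=ladder)

    k, skipped, inconsistent = closed_prefix(states)
    if k == 0:
        # First rung unknown and nothing closed above it: the ladder cannot
        # speak; fall back to root fractions when any are recorded.
        if any(
            r.apex_status is ApexStatus.OPEN and r.root_fraction is not None
            for r in recmap.values()
        ):
            return estimate_subnine(recmap.values(), anchors=subnine_anchors, ladder=ladder)
        raise ValueError(
            "cannot establish dental age: no group closed and no root fractions recorded"
        )

    group = assessed[k - 1]
    flags = set()
    if skipped:
        flags.add(FLAG_INCOMPLETE)
    if inconsistent:
        flags.add(FLAG_INCONSISTENT)
    point = group.da_low + _COLLAPSE[collapse] * (group.da_high - group.da_low)
    return DAEstimate(
        method="becker",
        point=point,
        low=group.da_low,
        high=group.da_high,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class SubnineAnchor:
    """Per-tooth ages bounding linear root growth."""

    root_start_age: float
    apex_age: float

    def __post_init__(self) -> None:
        if not self.root_start_age < self.apex_age:
            raise ValueError("root_start_age must precede apex_age")


#: Years from root-formation onset to apex closure.  Eruption occurs with
#: one-half to two-thirds of the final root formed and the apex closes about
#: three years later, so a ~6 y linear span puts eruption near its middle.
ROOT_SPAN_YEARS = 6.0


def default_subnine_anchors(
    ladder: BeckerLadder = DEFAULT_LADDER,
) -> dict[ToothCode, SubnineAnchor]:
    """Anchor table derived from the ladder: apex age = group DA midpoint,
    root onset ``ROOT_SPAN_YEARS`` earlier.  Editable/replaceable so that
    population-specific eruption data can be dropped in."""
    anchors: dict[ToothCode, SubnineAnchor] = {}
    for g in ladder.assessed():
        for t in g.member_teeth:
            anchors[t] = SubnineAnchor(g.midpoint - ROOT_SPAN_YEARS, g.midpoint)
    return anchors


def estimate_subnine(
    records: Iterable[ApexRecord] | Mapping[ToothCode, ApexRecord],
    anchors: Optional[Mapping[ToothCode, SubnineAnchor]] = None,
    ladder: BeckerLadder = DEFAULT_LADDER,
) -> DAEstimate:
    """Root-fraction fallback for subjects below the ladder floor.

    Each open tooth with a recorded root fraction ``f`` contributes an
    interpolated age ``root_start + f * (apex - root_start)``; the estimate
    is their mean.  This reading is inherently more subjective than apex
    closure, so the result always carries ``low_confidence``.
    """
    recmap = apex_map(records)
    if anchors is None:
        anchors = default_subnine_anchors(ladder)
    contributions: list[float] = []
    for tooth, rec in sorted(recmap.items()):
        if rec.apex_status is not ApexStatus.OPEN or rec.root_fraction is None:
            continue
        anchor = anchors.get(tooth)
        if anchor is None:
            continue
        contributions.append(
            anchor.root_start_age
            + rec.root_fraction * (anchor.apex_age - anchor.root_start_age)
        )
    if not contributions:
        raise ValueError("sub-nine estimate requires root fractions")
    point = sum(contributions) / len(contributions)
    low, high = min(contributions), max(contributions)
    flags = {FLAG_LOW_CONFIDENCE}
    if high < 9.0:
        flags.add(FLAG_SUB_NINE)
    return DAEstimate(
        method="becker", point=point, low=low, high=high, flags=frozenset(flags)
    )
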