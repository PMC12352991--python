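"""Table-driven Demirjian dental-age estimator.

The Demirjian system stages the seven left-mandibular permanent teeth
(31-37, third molar excluded) into formation stages A-H, converts each stage
into a sex-specific biologically weighted score, sums the seven scores into
a dental maturity score (0-100), and maps that score to a dental age through
a sex-specific conversion curve.

This module is deliberately a *table engine*: the numeric standards are
external configuration, because published score/conversion tables are
population-specific and are revised over time.  A packaged table is provided
for testing and demonstration; it is synthetic (see
``data/maturity_table_synthetic.csv``) and is not a published standard.
Conversion between curve knots is piecewise linear.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .model import (
    DEMIRJIAN_TEETH,
    FLAG_LOW_CONFIDENCE,
    FLAG_SUB_NINE,
    DAEstimate,
    Sex,
    Stage,
    StageRecord,
    ToothCode,
    parse_fdi,
)

__all__ = [
    "MaturityTable",
    "load_maturity_table",
    "default_maturity_table",
    "maturity_score",
    "estimate_demirjian",
]

_SCORED_STAGES = [s for s in Stage if s is not Stage.UNFORMED]


@dataclass
class MaturityTable:
    """Sex-specific stage scores and maturity-score -> age conversion curves.

    ``scores[sex][position][stage]`` is the weighted score of that stage for
    the mandibular-left tooth at ``position`` (1-7); ``curves[sex]`` is an
    ordered list of (maturity_score, dental_age) knots.
    """

    scores: dict[Sex, dict[int, dict[Stage, float]]] = field(default_factory=dict)
    curves: dict[Sex, list[tuple[float, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for sex in Sex:
            if sex not in self.scores:
                raise ValueError(f"maturity table missing the {sex.value} score block")
            if sex not in self.curves:
                raise ValueError(f"maturity table missing the {sex.value} conversion curve")
            block = self.scores[sex]
            missing = [p for p in range(1, 8) if p not in block]
            if missing:
                raise ValueError(
                    f"{sex.value} score block missing teeth at positions {missing}"
                )
            total_h = 0.0
            for pos in range(1, 8):
                per_tooth = block[pos]
                absent = [s.value for s in _SCORED_STAGES if s not in per_tooth]
                if absent:
                    raise ValueError(
                        f"{sex.value} tooth 3{pos}: missing scores for stages {absent}"
                    )
                per_tooth.setdefault(Stage.UNFORMED, 0.0)
                seq = [per_tooth[s] for s in Stage]
                for a, b, sa, sb in zip(seq, seq[1:], Stage, list(Stage)[1:]):
                    if b < a:
                        raise ValueError(
                            f"{sex.value} tooth 3{pos}: score decreases from stage "
                            f"{sa.value} to {sb.value}"
                        )
                total_h += per_tooth[Stage.H]
            if total_h > 100.0 + 1e-9:
                raise ValueError(
                    f"{sex.value} all-H maturity score {total_h:.2f} exceeds 100"
                )
            knots = self.curves[sex]
            if len(knots) < 2:
                raise ValueError(f"{sex.value} conversion curve needs >= 2 knots")
            for (s0, a0), (s1, a1) in zip(knots, knots[1:]):
                if not (s1 > s0 and a1 > a0):
                    raise ValueError(
                        f"{sex.value} conversion curve knots must be strictly "
                        f"increasing in both coordinates (at score {s1})"
                    )


def load_maturity_table(path) -> MaturityTable:
    """Load and validate a maturity table from its CSV schema.

    The file mixes two row kinds: score rows fill (sex, tooth_fdi, stage,
    score) and curve rows fill (sex, maturity_score, dental_age); '#' lines
    are comments.
    """
    table = MaturityTable()
    with open(path, newline="") as fh:
        rows = csv.DictReader(row for row in fh if not row.startswith("#"))
        expected = {"sex", "tooth_fdi", "stage", "score", "maturity_score", "dental_age"}
        if rows.fieldnames is None or set(rows.fieldnames) != expected:
            raise ValueError(
                f"maturity table must have columns {sorted(expected)}, "
                f"got {rows.fieldnames}"
            )
        for line, row in enumerate(rows, start=2):
            sex = Sex(row["sex"].strip())
            if row["tooth_fdi"].strip():
                tooth = parse_fdi(row["tooth_fdi"])
                if not (tooth.quadrant == 3 and tooth.position <= 7):
                    raise ValueError(
                        f"line {line}: scores apply to teeth 31-37, got {tooth}"
                    )
                stage = Stage(row["stage"].strip())
                table.scores.setdefault(sex, {}).setdefault(tooth.position, {})[stage] = (
                    float(row["score"])
                )
            elif row["maturity_score"].strip():
                table.curves.setdefault(sex, []).append(
                    (float(row["maturity_score"]), float(row["dental_age"]))
                )
            else:
                raise ValueError(f"line {line}: row is neither a score nor a curve knot")
    for sex in table.curves:
        table.curves[sex].sort()
    table.validate()
    return table


def default_maturity_table() -> MaturityTable:
    """The packaged synthetic table (for tests and demos, not a standard)."""
    ref = resources.files("dentage").joinpath("data/maturity_table_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_maturity_table(path)


def _stage_map(stages: Iterable[StageRecord] | Mapping[ToothCode, StageRecord]) -> dict[ToothCode, StageRecord]:
    if isinstance(stages, Mapping):
        return dict(stages)
    out: dict[ToothCode, StageRecord] = {}
    for rec in stages:
        if rec.tooth in out:
            raise ValueError(f"duplicate stage record for tooth {rec.tooth}")
        out[rec.tooth] = rec
    return out


def maturity_score(
    stages: Iterable[StageRecord] | Mapping[ToothCode, StageRecord],
    sex: Sex,
    table: MaturityTable,
) -> float:
    """Sum of the seven per-tooth stage scores for the given sex.

    All seven teeth 31-37 must be staged; the method defines no substitution
    for missing teeth.
    """
    recmap = _stage_map(stages)
    missing = [t.fdi for t in DEMIRJIAN_TEETH if t not in recmap]
    if missing:
        raise ValueError(
            "Demirjian requires all seven left mandibular teeth staged; "
            f"missing {missing}"
        )
    block = table.scores[Sex(sex)]
    return float(
        sum(block[t.position][recmap[t].stage] for t in DEMIRJIAN_TEETH)
    )


def estimate_demirjian(
    stages: Iterable[StageRecord] | Mapping[ToothCode, StageRecord],
    sex: Sex,
    table: MaturityTable,
) -> DAEstimate:
    """Convert a maturity score to dental age on the sex-specific curve.

    Piecewise-linear interpolation between knots; scores outside the curve's
    support are clamped to the end knots and flagged ``low_confidence``.
    The method yields a point estimate (low == point == high).
    """
    score = maturity_score(stages, sex, table)
    knots = table.curves[Sex(sex)]
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    flags: set[str] = set()
    if score < xs[0] or score > xs[-1]:
        flags.add(FLAG_LOW_CONFIDENCE)
    age = float(np.interp(score, xs, ys))
    if age < 9.0:
        flags.add(FLAG_SUB_NINE)
    return DAEstimate(
        method="demirjian", point=age, low=age, high=age, flags=frozenset(flags)
    )
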