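"""Synthetic dental-maturation cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without radiographs:

* each subject carries a latent maturation tempo ``delta ~ N(0, subject_sd)``
  shared by all of their teeth, plus independent per-tooth noise — the
  minimal decomposition under which both method bias and rater-reliability
  simulations are meaningful;
* tooth ``t`` of subject ``i`` apexifies at
  ``mu_t - female_advance*[F] + delta_i + eps_it - population_shift``,
  where ``population_shift`` > 0 models a systematically advanced
  population (the mechanism behind observed DA overestimation);
* an apex reads *closed* once chronological age reaches the closure age;
  open teeth carry a root fraction growing linearly over ``root_span`` years
  up to closure;
* Demirjian stages are entered at fixed per-tooth offsets before closure
  (stage H at closure), so staging and apexification cohere within subject;
* raters misread teeth near their closure boundary: within
  ``boundary_window`` years of closure the status flips with probability
  ``rater_flip_prob``; each rater may also carry a systematic bias on the
  perceived closure age (``rater_bias_sd``).

Randomness comes from one master seed through per-subject
``SeedSequence`` spawn keys ``(domain, age, sex, index_in_cell, ...)``, so
enlarging one design cell never perturbs subjects in any other cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .becker import DEFAULT_LADDER, BeckerLadder
from .model import (
    ApexRecord,
    ApexStatus,
    CohortRecord,
    Sex,
    Stage,
    StageRecord,
    ToothCode,
)

__all__ = [
    "MaturationParams",
    "AgeSexDesign",
    "SubjectLatent",
    "default_apex_ages",
    "default_params",
    "study_design",
    "simulate_subjects",
    "simulate_cohort",
    "simulate_ratings",
]

#: All teeth the generator emits (third molars never inform estimation).
SIMULATED_TEETH = tuple(
    ToothCode(q, p) for q in (1, 2, 3, 4) for p in range(1, 8)
)

_STAGE_OFFSETS = (-9.0, -7.5, -6.0, -5.0, -4.0, -3.0, -2.0, 0.0)  # A..H entry, years before closure


def default_apex_ages(ladder: BeckerLadder = DEFAULT_LADDER) -> dict[ToothCode, float]:
    """Mean apex-closure ages anchored to the ladder's DA values.

    Teeth the ladder never mentions still need closure ages (they appear on
    the radiograph): maxillary laterals use the midpoint of their quoted
    10.5-11 y closure window; second premolars (upper and lower), for which
    no DA is quoted, sit between the first-premolar and canine rungs at
    13.75 y.
    """
    ages: dict[ToothCode, float] = {}
    for g in ladder.groups:
        for t in g.member_teeth:
            ages[t] = g.midpoint if g.midpoint is not None else 13.75
    for t in SIMULATED_TEETH:
        ages.setdefault(t, 13.75)
    return ages


@dataclass(frozen=True)
class MaturationParams:
    """Generator parameters; ages/SDs in years, probabilities dimensionless."""

    apex_age_mean: dict[ToothCode, float] = field(default_factory=default_apex_ages)
    apex_age_sd: float = 0.35
    subject_sd: float = 0.5
    female_advance: float = 0.25
    population_shift: float = 0.0
    stage_entry_offsets: tuple[float, ...] = _STAGE_OFFSETS
    root_span: float = 6.0
    rater_flip_prob: float = 0.05
    boundary_window: float = 1.0
    rater_bias_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.apex_age_sd < 0 or self.subject_sd < 0 or self.rater_bias_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.rater_flip_prob <= 0.5:
            raise ValueError("rater_flip_prob must lie in [0, 0.5]")
        if self.root_span <= 0 or self.boundary_window < 0:
            raise ValueError("root_span must be positive, boundary_window non-negative")
        offs = self.stage_entry_offsets
        if len(offs) != 8 or any(b <= a for a, b in zip(offs, offs[1:])) or offs[-1] != 0.0:
            raise ValueError(
                "stage_entry_offsets must be 8 strictly increasing values ending at 0"
            )
        missing = [t.fdi for t in SIMULATED_TEETH if t not in self.apex_age_mean]
        if missing:
            raise ValueError(f"apex_age_mean missing teeth {missing}")

    def mean_closure(self, tooth: ToothCode, sex: Sex) -> float:
        adv = self.female_advance if sex is Sex.F else 0.0
        return self.apex_age_mean[tooth] - adv - self.population_shift


def default_params(**overrides) -> MaturationParams:
    return replace(MaturationParams(), **overrides) if overrides else MaturationParams()


@dataclass(frozen=True)
class AgeSexDesign:
    """Subject counts per (integer age, sex) cell."""

    counts: dict[tuple[int, Sex], int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty design")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def total_by_sex(self, sex: Sex) -> int:
        return sum(n for (_, s), n in self.counts.items() if s is sex)

    def cells(self) -> list[tuple[int, Sex, int]]:
        return sorted(
            ((age, sex, n) for (age, sex), n in self.counts.items()),
            key=lambda c: (c[0], c[1].value),
        )


#: Study-style design: 377 subjects aged 8-15, (age: males, females).
_STUDY_CELLS = {
    8: (17, 14),
    9: (22, 15),
    10: (18, 26),
    11: (32, 23),
    12: (29, 33),
    13: (38, 40),
    14: (22, 21),
    15: (15, 12),
}


def study_design() -> AgeSexDesign:
    counts: dict[tuple[int, Sex], int] = {}
    for age, (males, females) in _STUDY_CELLS.items():
        counts[(age, Sex.M)] = males
        counts[(age, Sex.F)] = females
    return AgeSexDesign(counts)


@dataclass(frozen=True)
class SubjectLatent:
    """A simulated subject with its latent maturation state retained.

    ``closure_ages`` is the ground truth a faithful (noise-free) reading
    observes through; rater simulation needs it to decide which teeth sit
    near their closure boundary.
    """

    subject_id: str
    sex: Sex
    chronological_age: float
    tempo: float
    closure_ages: dict[ToothCode, float]


def _subject_rng(seed: int, age: int, sex: Sex, j: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, age, int(sex is Sex.F), j))
    )


def simulate_subjects(
    design: AgeSexDesign, params: MaturationParams, seed: int
) -> list[SubjectLatent]:
    """Draw latent subjects: CA uniform within the age cell, shared tempo,
    per-tooth closure ages."""
    subjects: list[SubjectLatent] = []
    idx = 0
    for age, sex, n in design.cells():
        for j in range(n):
            rng = _subject_rng(seed, age, sex, j)
            ca = float(rng.uniform(age, age + 1))
            tempo = float(rng.normal(0.0, params.subject_sd)) if params.subject_sd else 0.0
            eps = rng.normal(0.0, params.apex_age_sd, size=len(SIMULATED_TEETH))
            closure = {
                t: params.mean_closure(t, sex) + tempo + (float(e) if params.apex_age_sd else 0.0)
                for t, e in zip(SIMULATED_TEETH, eps)
            }
            idx += 1
            subjects.append(
                SubjectLatent(f"S{idx:04d}", sex, ca, tempo, closure)
            )
    return subjects


def _read_apex(
    ca: float, closure: float, params: MaturationParams
) -> tuple[ApexStatus, Optional[float]]:
    if ca >= closure:
        return ApexStatus.CLOSED, None
    frac = (ca - (closure - params.root_span)) / params.root_span
    return ApexStatus.OPEN, float(np.clip(frac, 0.0, 1.0))


def _read_stage(ca: float, closure: float, params: MaturationParams) -> Stage:
    passed = sum(ca >= closure + off for off in params.stage_entry_offsets)
    return Stage.UNFORMED if passed == 0 else list(Stage)[passed]


def _records_for(
    subject: SubjectLatent,
    params: MaturationParams,
    rater_id: str,
    session_id: str,
    *,
    bias: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> CohortRecord:
    apex: dict[ToothCode, ApexRecord] = {}
    stages: dict[ToothCode, StageRecord] = {}
    for tooth in SIMULATED_TEETH:
        true_closure = subject.closure_ages[tooth]
        perceived = true_closure + bias
        status, frac = _read_apex(subject.chronological_age, perceived, params)
        if (
            rng is not None
            and params.rater_flip_prob > 0
            and abs(subject.chronological_age - true_closure) < params.boundary_window
            and rng.random() < params.rater_flip_prob
        ):
            if status is ApexStatus.CLOSED:
                # a just-open apex on a full-length root
                status, frac = ApexStatus.OPEN, 1.0
            else:
                status, frac = ApexStatus.CLOSED, None
        apex[tooth] = ApexRecord(tooth, status, frac)
        if tooth.quadrant == 3:
            stage = _read_stage(subject.chronological_age, perceived, params)
            if rng is not None and params.rater_flip_prob > 0 and rng.random() < params.rater_flip_prob:
                step = 1 if rng.random() < 0.5 else -1
                rank = int(np.clip(stage.rank + step, 0, len(Stage) - 1))
                stage = list(Stage)[rank]
            stages[tooth] = StageRecord(tooth, stage)
    return CohortRecord(
        subject_id=subject.subject_id,
        sex=subject.sex,
        chronological_age=subject.chronological_age,
        rater_id=rater_id,
        session_id=session_id,
        apex_records=apex,
        stage_records=stages,
    )


def simulate_cohort(
    design: AgeSexDesign, params: Optional[MaturationParams] = None, seed: int = 0
) -> list[CohortRecord]:
    """One faithful (noise-free reading) assessment per subject."""
    params = params or MaturationParams()
    return [
        _records_for(s, params, "R1", "S1") for s in simulate_subjects(design, params, seed)
    ]


def simulate_ratings(
    subjects: Sequence[SubjectLatent],
    raters: int,
    sessions: int,
    params: Optional[MaturationParams] = None,
    seed: int = 0,
) -> list[CohortRecord]:
    """Replicate each subject's assessment across raters and sessions with
    independent reading noise (and per-rater bias when ``rater_bias_sd`` > 0).
    """
    if raters < 1 or sessions < 1:
        raise ValueError("need at least one rater and one session")
    params = params or MaturationParams()
    biases = {}
    for r in range(1, raters + 1):
        if params.rater_bias_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(3, r))
            )
            biases[r] = float(rng.normal(0.0, params.rater_bias_sd))
        else:
            biases[r] = 0.0
    out: list[CohortRecord] = []
    for i, subject in enumerate(subjects):
        for r in range(1, raters + 1):
            for s in range(1, sessions + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(2, i, r, s))
                )
                out.append(
                    _records_for(
                        subject,
                        params,
                        rater_id=f"R{r}",
                        session_id=f"S{s}",
                        bias=biases[r],
                        rng=rng,
                    )
                )
    return out
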