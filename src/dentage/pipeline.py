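"""High-level pipeline: run estimators over a cohort into a tidy table."""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import becker as _becker
from . import demirjian as _demirjian
from .demirjian import MaturityTable
from .model import CohortRecord

logger = logging.getLogger(__name__)

__all__ = ["estimate_cohort"]


def estimate_cohort(
    records: Iterable[CohortRecord],
    methods: Sequence[str] = ("becker", "demirjian"),
    *,
    maturity_table: Optional[MaturityTable] = None,
    ladder=_becker.DEFAULT_LADDER,
    include_maxillary_laterals: bool = False,
    collapse: str = "mid",
    strict: bool = False,
) -> pd.DataFrame:
    """Apply the requested estimators to every (subject, rater, session).

    Returns a tidy frame with one row per (record, method): subject_id, sex,
    ca_years, rater_id, session_id, method, da_point, da_low, da_high and a
    '|'-joined flags column.  Records an estimator cannot handle (e.g. no
    staging for the Demirjian method) are skipped with a warning, or raise
    when ``strict``.
    """
    bad = set(methods) - {"becker", "demirjian"}
    if bad:
        raise ValueError(f"unknown method(s) {sorted(bad)}")
    if "demirjian" in methods and maturity_table is None:
        maturity_table = _demirjian.default_maturity_table()

    rows = []
    for rec in records:
        for method in methods:
            try:
                if method == "becker":
                    est = _becker.estimate_becker(
                        rec.apex_records,
                        ladder,
                        include_maxillary_laterals=include_maxillary_laterals,
                        collapse=collapse,
                    )
                else:
                    est = _demirjian.estimate_demirjian(
                        rec.stage_records, rec.sex, maturity_table
                    )
            except ValueError as exc:
                if strict:
                    raise
                logger.warning("subject %s (%s): %s", rec.subject_id, method, exc)
                continue
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "sex": rec.sex.value,
                    "ca_years": rec.chronological_age,
                    "rater_id": rec.rater_id,
                    "session_id": rec.session_id,
                    "method": est.method,
                    "da_point": est.point,
                    "da_low": est.low,
                    "da_high": est.high,
                    "flags": "|".join(sorted(est.flags)),
                }
            )
    if not rows:
        raise ValueError("no estimates could be produced for this cohort")
    return pd.DataFrame(rows)
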