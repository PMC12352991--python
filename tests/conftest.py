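import itertools

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from dentage.becker import DEFAULT_LADDER
from dentage.model import ApexRecord, ApexStatus, ToothCode

#: Teeth of each assessed ladder group, in ladder order (index -> FDI codes).
GROUP_TEETH = {g.index: sorted(t.fdi for t in g.member_teeth) for g in DEFAULT_LADDER.assessed()}
EXCLUDED_TEETH = ["12", "22", "35", "45"]


def apex_records(closed=(), open_=(), fractions=None, unassessable=()):
    """Build an apex-record map over the full ladder dentition.

    Teeth named in ``closed``/``unassessable`` get those statuses; everything
    else is open, with ``fractions`` (fdi -> proportion) attached when given.
    """
    from dentage.model import parse_fdi

    fractions = fractions or {}
    recs = {}
    all_teeth = {t for g in DEFAULT_LADDER.groups for t in g.member_teeth}
    for t in sorted(all_teeth):
        if t.fdi in unassessable:
            recs[t] = ApexRecord(t, ApexStatus.UNASSESSABLE)
        elif t.fdi in closed:
            recs[t] = ApexRecord(t, ApexStatus.CLOSED)
        else:
            recs[t] = ApexRecord(t, ApexStatus.OPEN, fractions.get(t.fdi))
    for fdi in open_:
        t = parse_fdi(fdi)
        recs[t] = ApexRecord(t, ApexStatus.OPEN, fractions.get(fdi))
    return recs


def closed_through(k):
    """FDI codes of all assessed groups with index <= k."""
    return [t for i in range(1, k + 1) for t in GROUP_TEETH[i]]


def vector_records(states):
    """Realize an 8-long group-state vector ('closed'/'open'/'unknown') as
    apex records: open groups get one open member, unknown groups are fully
    unassessable, open teeth carry fraction 0.5 so sub-nine delegation works."""
    closed, unassessable, fractions = [], [], {}
    for idx, state in enumerate(states, start=1):
        teeth = GROUP_TEETH[idx]
        if state == "closed":
            closed += teeth
        elif state == "unknown":
            unassessable += teeth
        else:
            fractions.update({t: 0.5 for t in teeth})
    return apex_records(closed=closed, unassessable=unassessable, fractions=fractions)


def all_state_vectors():
    return itertools.product(["closed", "open", "unknown"], repeat=8)


@pytest.fixture(scope="session")
def maturity_table():
    from dentage.demirjian import default_maturity_table

    return default_maturity_table()


@pytest.fixture
def small_cohort_csv(tmp_path):
    """Two-subject long-format cohort file."""
    path = tmp_path / "cohort.csv"
    rows = ["subject_id,sex,ca_years,rater_id,session_id,tooth_fdi,apex_status,root_fraction,demirjian_stage"]
    for tooth in ["31", "41", "16", "26", "36", "46", "32", "42", "11", "21"]:
        rows.append(f"A,F,10.25,R1,S1,{tooth},closed,,")
    for tooth in ["33", "43", "34", "44", "14", "24", "13", "23", "17", "27", "37", "47"]:
        rows.append(f"A,F,10.25,R1,S1,{tooth},open,0.8,")
    for tooth in ["31", "41"]:
        rows.append(f"B,M,8.1,R1,S1,{tooth},open,0.55,")
    for tooth in ["16", "26", "36", "46"]:
        rows.append(f"B,M,8.1,R1,S1,{tooth},open,0.4,")
    path.write_text("\n".join(rows) + "\n")
    return path
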