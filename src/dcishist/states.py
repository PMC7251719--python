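"""Disease-state labels, the transition graph, and age-group helpers.

States form a directed acyclic graph: a lesion arises in an undetectable
preclinical state, may become screen-detectable, and exits toward invasive
disease, clinical surfacing, or regression.  Screen detection adds two
absorbing states on top of the natural-history graph.
"""

from __future__ import annotations

NO_BC = "no_bc"
DCIS_UNDETECTABLE = "dcis_undetectable"
DCIS_SCREEN_DETECTABLE = "dcis_screen_detectable"
CLINICAL_DCIS = "clinical_dcis"
IBC_PRECLINICAL = "ibc_preclinical"
IBC_CLINICAL = "ibc_clinical"
REGRESSED = "regressed"
SCREEN_DETECTED_DCIS = "screen_detected_dcis"
SCREEN_DETECTED_IBC = "screen_detected_ibc"
DEATH_OTHER = "death_other"

ALL_STATES = frozenset(
    {
        NO_BC,
        DCIS_UNDETECTABLE,
        DCIS_SCREEN_DETECTABLE,
        CLINICAL_DCIS,
        IBC_PRECLINICAL,
        IBC_CLINICAL,
        REGRESSED,
        SCREEN_DETECTED_DCIS,
        SCREEN_DETECTED_IBC,
        DEATH_OTHER,
    }
)

#: Allowed transitions.  The implicit start state of every trajectory is
#: ``NO_BC``; ``DEATH_OTHER`` is reachable from everywhere.
ALLOWED_EDGES = frozenset(
    {
        (NO_BC, DCIS_UNDETECTABLE),
        (NO_BC, DEATH_OTHER),
        (DCIS_UNDETECTABLE, DCIS_SCREEN_DETECTABLE),
        (DCIS_UNDETECTABLE, IBC_PRECLINICAL),
        (DCIS_UNDETECTABLE, REGRESSED),  # optional switch, off by default
        (DCIS_UNDETECTABLE, DEATH_OTHER),
        (DCIS_SCREEN_DETECTABLE, IBC_PRECLINICAL),
        (DCIS_SCREEN_DETECTABLE, CLINICAL_DCIS),
        (DCIS_SCREEN_DETECTABLE, REGRESSED),
        (DCIS_SCREEN_DETECTABLE, SCREEN_DETECTED_DCIS),
        (DCIS_SCREEN_DETECTABLE, DEATH_OTHER),
        (IBC_PRECLINICAL, IBC_CLINICAL),
        (IBC_PRECLINICAL, SCREEN_DETECTED_IBC),
        (IBC_PRECLINICAL, DEATH_OTHER),
        (CLINICAL_DCIS, DEATH_OTHER),
        (IBC_CLINICAL, DEATH_OTHER),
        (REGRESSED, DEATH_OTHER),
        (SCREEN_DETECTED_DCIS, DEATH_OTHER),
        (SCREEN_DETECTED_IBC, DEATH_OTHER),
    }
)

#: Exit paths from the screen-detectable state.
PATH_P1 = "P1"  # -> preclinical invasive disease
PATH_P2 = "P2"  # -> clinical DCIS
PATH_P3 = "P3"  # -> regression
PATHS = (PATH_P1, PATH_P2, PATH_P3)

PATH_EXIT_STATE = {
    PATH_P1: IBC_PRECLINICAL,
    PATH_P2: CLINICAL_DCIS,
    PATH_P3: REGRESSED,
}

#: Diagnosis classes used by schedules and incidence tables.
DIAG_DCIS = "DCIS"
DIAG_IBC = "IBC"

#: Diagnosis events: (diagnosis class, detection mode).
DIAGNOSIS_EVENTS = {
    CLINICAL_DCIS: (DIAG_DCIS, "clinical"),
    SCREEN_DETECTED_DCIS: (DIAG_DCIS, "screen"),
    IBC_CLINICAL: (DIAG_IBC, "clinical"),
    SCREEN_DETECTED_IBC: (DIAG_IBC, "screen"),
}

ADJUSTMENT_AGE_MIN = 30
ADJUSTMENT_AGE_MAX = 80  # exclusive
AGE_GROUP_WIDTH = 5

AGE_GROUPS = tuple(
    f"{lo}-{lo + AGE_GROUP_WIDTH - 1}"
    for lo in range(ADJUSTMENT_AGE_MIN, ADJUSTMENT_AGE_MAX, AGE_GROUP_WIDTH)
)


def age_group_label(age: float) -> str | None:
    """Return the 5-year group label for ``age``, or None outside 30-79."""
    if age < ADJUSTMENT_AGE_MIN or age >= ADJUSTMENT_AGE_MAX:
        return None
    lo = int(age) - int(age) % AGE_GROUP_WIDTH
    return f"{lo}-{lo + AGE_GROUP_WIDTH - 1}"
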