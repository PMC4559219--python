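"""Rule-based identification of prevalent and incident type 2 diabetes.

Case definition on one calendar year of claims, applied to persons fully
enrolled all four quarters:

* a diabetes-related claim (ICD-10 E11, E12 or E14 — E10 and E13 never
  count, E13 being commonly used for pancreoprive diabetes) in at least
  3 of 4 quarters, or
* antidiabetic prescriptions (ATC A10A or A10B) in more than one quarter,
  or
* at least one antidiabetic prescription combined with at least one
  diabetes-related claim.

A case in year Y is *incident* if the person was also fully enrolled in
year Y-1 and had neither a diabetes-related claim nor an antidiabetic
prescription in that washout year.

Comorbidity flags follow fixed ICD-10 lists: adiposity (E66),
hypertension (I10-I13), coronary heart disease (I20-I22, I24-I25),
chronic renal insufficiency (N18, N08.3), stroke/cerebral circulatory
disorders (I63-I64), retinopathy (H35, H36.03). Matching is prefix-based
on the three-character category, except the explicitly subdivided codes
(N08.3, H36.03) which match at their stated precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .agegroups import age_to_group

# diabetes-related claim codes (case definition) vs any diabetes code
# (control exclusion / coding-pattern report)
DIABETES_CLAIM_RE = r"(?:^|;)E1[124]"
ANY_DIABETES_RE = r"(?:^|;)E1[0-4]"
ANTIDIABETIC_RE = r"(?:^|;)A10[AB]"

COMORBIDITY_PATTERNS = {
    "adiposity": r"(?:^|;)E66",
    "hypertension": r"(?:^|;)I1[0-3]",
    "chd": r"(?:^|;)(?:I2[0-2]|I2[45])",
    "stroke": r"(?:^|;)I6[34]",
    "renal": r"(?:^|;)(?:N18|N08\.3)",
    "retinopathy": r"(?:^|;)(?:H35|H36\.03)",
}

QUALIFYING_RULES = ("three_quarters_dx", "repeated_rx", "rx_plus_dx", "none")


@dataclass
class PersonYearProfile:
    """One person's claims activity within one calendar year."""

    person_id: str
    year: int
    enrolled_all_year: bool
    quarters_with_diabetes_claim: frozenset = frozenset()
    quarters_with_antidiabetic_rx: frozenset = frozenset()
    has_any_diabetes_code: bool = False
    age_in_year: int = 0
    sex: str = ""
    district_id: str = ""
    comorbidity_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for qs in (self.quarters_with_diabetes_claim, self.quarters_with_antidiabetic_rx):
            if not set(qs) <= {1, 2, 3, 4}:
                raise ValueError(f"quarter set {set(qs)} not a subset of {{1,2,3,4}}")


@dataclass
class CaseStatus:
    person_id: str
    year: int
    eligible: bool
    prevalent_t2dm: Optional[bool]  # None when not evaluable
    qualifying_rule: str = "none"
    incident_t2dm: Optional[bool] = None  # None when not evaluable


def flag_comorbidities(codes: Iterable[str]) -> dict[str, bool]:
    """Comorbidity flags from a collection of ICD code strings."""
    joined = ";".join(str(c).upper() for c in codes)
    return {
        name: re.search(pat, joined) is not None
        for name, pat in COMORBIDITY_PATTERNS.items()
    }


def classify_prevalent(profile: PersonYearProfile) -> CaseStatus:
    """Apply the three qualification rules to one person-year profile.

    Persons not enrolled all four quarters get a not-evaluable status
    (``eligible=False``, ``prevalent_t2dm=None``) rather than an error.
    The recorded rule is the first satisfied one in the fixed order
    three_quarters_dx > repeated_rx > rx_plus_dx (bookkeeping only —
    case status itself is order-invariant).
    """
    if not profile.enrolled_all_year:
        return CaseStatus(profile.person_id, profile.year, eligible=False, prevalent_t2dm=None)
    n_dx = len(profile.quarters_with_diabetes_claim)
    n_rx = len(profile.quarters_with_antidiabetic_rx)
    if n_dx >= 3:
        rule = "three_quarters_dx"
    elif n_rx >= 2:
        rule = "repeated_rx"
    elif n_rx >= 1 and n_dx >= 1:
        rule = "rx_plus_dx"
    else:
        rule = "none"
    return CaseStatus(
        profile.person_id,
        profile.year,
        eligible=True,
        prevalent_t2dm=rule != "none",
        qualifying_rule=rule,
    )


def classify_incident(
    profile_prev_year: Optional[PersonYearProfile], status_year: CaseStatus
) -> CaseStatus:
    """Set the incident flag on a year-Y case status using the year Y-1 profile.

    Not evaluable (``incident_t2dm=None``) when the prior-year profile is
    missing or not fully enrolled. The washout requires absence of both
    diabetes-related claims and antidiabetic prescriptions in Y-1 (a
    prescription alone qualifies a person as a case, so it counts as a
    diabetes-related claim for washout purposes).
    """
    status = CaseStatus(**vars(status_year))
    if not status.prevalent_t2dm:
        status.incident_t2dm = False
        return status
    if profile_prev_year is None or not profile_prev_year.enrolled_all_year:
        status.incident_t2dm = None
        return status
    clean = (
        len(profile_prev_year.quarters_with_diabetes_claim) == 0
        and len(profile_prev_year.quarters_with_antidiabetic_rx) == 0
    )
    status.incident_t2dm = bool(clean)
    return status


# ---------------------------------------------------------------------------
# vectorized frame API (what the pipeline runs)
# ---------------------------------------------------------------------------

def build_profiles(claims: pd.DataFrame, persons: pd.DataFrame, year: int) -> pd.DataFrame:
    """Aggregate claims of one calendar year into person-year profiles.

    Returns one row per person present in the person table, with columns
    ``enrolled_all_year``, ``n_dx_quarters``, ``n_rx_quarters``,
    ``any_diabetes_code``, ``age``, ``age_group``, ``sex``,
    ``district_id`` and one boolean column per comorbidity. Persons with
    no claims rows in the year count as not enrolled.
    """
    required = {"person_id", "year", "quarter", "enrolled", "icd_codes", "atc_codes"}
    missing = required - set(claims.columns)
    if missing:
        raise ValueError(f"claims table lacks columns: {sorted(missing)}")
    orphans = set(claims["person_id"]) - set(persons["person_id"])
    if orphans:
        shown = sorted(orphans)[:10]
        raise ValueError(
            f"{len(orphans)} claims person_id(s) missing from person table: {shown}"
        )
    cy = claims[(claims["year"] == year) & claims["enrolled"].astype(bool)].copy()
    bad_q = ~cy["quarter"].isin([1, 2, 3, 4])
    if bad_q.any():
        raise ValueError(f"invalid quarter values: {sorted(cy.loc[bad_q, 'quarter'].unique())}")

    icd = cy["icd_codes"].fillna("").astype(str).str.upper()
    atc = cy["atc_codes"].fillna("").astype(str).str.upper()
    cy["_dx"] = icd.str.contains(DIABETES_CLAIM_RE, regex=True)
    cy["_any_dm"] = icd.str.contains(ANY_DIABETES_RE, regex=True)
    cy["_rx"] = atc.str.contains(ANTIDIABETIC_RE, regex=True)
    for name, pat in COMORBIDITY_PATTERNS.items():
        cy[f"_co_{name}"] = icd.str.contains(pat, regex=True)

    grp = cy.groupby("person_id", sort=True)
    agg = grp.agg(
        n_enrolled_quarters=("quarter", "nunique"),
        any_diabetes_code=("_any_dm", "any"),
        **{name: (f"_co_{name}", "any") for name in COMORBIDITY_PATTERNS},
    )
    agg["n_dx_quarters"] = (
        cy[cy["_dx"]].groupby("person_id")["quarter"].nunique().reindex(agg.index, fill_value=0)
    )
    agg["n_rx_quarters"] = cy[cy["_rx"]].groupby("person_id")["quarter"].nunique().reindex(
        agg.index, fill_value=0
    )

    out = persons.set_index("person_id").join(agg, how="left")
    out["n_enrolled_quarters"] = out["n_enrolled_quarters"].fillna(0).astype(int)
    for col in ["any_diabetes_code", *COMORBIDITY_PATTERNS]:
        out[col] = out[col].where(out[col].notna(), False).astype(bool)
    for col in ("n_dx_quarters", "n_rx_quarters"):
        out[col] = out[col].fillna(0).astype(int)
    out["enrolled_all_year"] = out["n_enrolled_quarters"] == 4
    out["year"] = year
    out["age"] = year - out["birth_year"].astype(int)
    out["age_group"] = age_to_group(out["age"].to_numpy())
    return out.reset_index()


def classify_prevalent_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    """Vectorized case classification; adds eligibility, case and rule columns."""
    out = profiles.copy()
    n_dx = out["n_dx_quarters"].to_numpy()
    n_rx = out["n_rx_quarters"].to_numpy()
    eligible = out["enrolled_all_year"].to_numpy(dtype=bool)
    rule = np.where(
        n_dx >= 3,
        "three_quarters_dx",
        np.where(n_rx >= 2, "repeated_rx", np.where((n_rx >= 1) & (n_dx >= 1), "rx_plus_dx", "none")),
    )
    rule = np.where(eligible, rule, "none")
    out["eligible"] = eligible
    out["qualifying_rule"] = rule
    out["prevalent_t2dm"] = eligible & (rule != "none")
    return out


def classify_incident_frame(cases: pd.DataFrame, profiles_prev: pd.DataFrame) -> pd.DataFrame:
    """Vectorized incident flag for a classified year-Y frame.

    Adds ``incident_evaluable`` (fully enrolled and claim-free status
    known for Y-1) and ``incident_t2dm``. The at-risk washout population
    (``at_risk``) — enrolled both years with a claim- and Rx-free year
    Y-1 — is flagged too; it is the incidence denominator.
    """
    prev = profiles_prev.set_index("person_id")
    out = cases.copy().set_index("person_id")
    prev_enrolled = prev["enrolled_all_year"].reindex(out.index, fill_value=False).astype(bool)
    clean = (
        (prev["n_dx_quarters"].reindex(out.index, fill_value=1) == 0)
        & (prev["n_rx_quarters"].reindex(out.index, fill_value=1) == 0)
    )
    out["incident_evaluable"] = out["eligible"] & prev_enrolled
    out["at_risk"] = out["incident_evaluable"] & clean
    out["incident_t2dm"] = out["prevalent_t2dm"] & out["at_risk"]
    out.loc[~out["incident_evaluable"], "incident_t2dm"] = False
    return out.reset_index()


def ascertain_year(claims: pd.DataFrame, persons: pd.DataFrame, year: int) -> pd.DataFrame:
    """Profiles + prevalence classification for one year (convenience)."""
    return classify_prevalent_frame(build_profiles(claims, persons, year))
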