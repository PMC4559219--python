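"""Case-definition rules: quarter-pattern oracle, E-code handling,
incident washout, comorbidity flags, and frame/scalar agreement."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diabsurv import (
    PersonYearProfile,
    build_profiles,
    classify_incident,
    classify_prevalent,
    classify_prevalent_frame,
    flag_comorbidities,
)
from diabsurv.ascertainment import classify_incident_frame


def _profile(dx=(), rx=(), enrolled=True, **kw):
    return PersonYearProfile(
        person_id="p",
        year=2010,
        enrolled_all_year=enrolled,
        quarters_with_diabetes_claim=frozenset(dx),
        quarters_with_antidiabetic_rx=frozenset(rx),
        **kw,
    )


def _powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))


def test_prevalent_matches_brute_force_on_all_256_quarter_patterns():
    """Independent re-statement of the three qualification rules,
    enumerated over every combination of dx-quarters x rx-quarters."""
    for dx in _powerset({1, 2, 3, 4}):
        for rx in _powerset({1, 2, 3, 4}):
            expected = (
                len(dx) >= 3 or len(rx) >= 2 or (len(rx) >= 1 and len(dx) >= 1)
            )
            status = classify_prevalent(_profile(dx=dx, rx=rx))
            assert status.prevalent_t2dm is expected, (dx, rx)
            assert (status.qualifying_rule != "none") is expected


@pytest.mark.parametrize(
    "dx, rx, rule",
    [
        ({1, 2, 4}, (), "three_quarters_dx"),
        ((), {2, 3}, "repeated_rx"),
        ({4}, {2}, "rx_plus_dx"),
        ({1, 2}, (), "none"),
    ],
)
def test_qualifying_rule_bookkeeping(dx, rx, rule):
    assert classify_prevalent(_profile(dx=dx, rx=rx)).qualifying_rule == rule


def test_partial_enrollment_is_not_evaluable():
    status = classify_prevalent(_profile(dx={1, 2, 3, 4}, enrolled=False))
    assert status.eligible is False
    assert status.prevalent_t2dm is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    dx=st.frozensets(st.integers(1, 4)),
    rx=st.frozensets(st.integers(1, 4)),
    add_dx=st.integers(1, 4),
    add_rx=st.integers(1, 4),
)
def test_adding_claims_never_unmakes_a_case(dx, rx, add_dx, add_rx):
    before = classify_prevalent(_profile(dx=dx, rx=rx)).prevalent_t2dm
    after = classify_prevalent(
        _profile(dx=dx | {add_dx}, rx=rx | {add_rx})
    ).prevalent_t2dm
    assert not (before and not after)


def test_incident_requires_clean_fully_enrolled_washout_year():
    case = classify_prevalent(_profile(dx={1, 2, 3}))
    clean_prior = _profile()
    assert classify_incident(clean_prior, case).incident_t2dm is True
    one_claim_prior = _profile(dx={3})
    assert classify_incident(one_claim_prior, case).incident_t2dm is False
    rx_prior = _profile(rx={1})
    assert classify_incident(rx_prior, case).incident_t2dm is False
    partial_prior = _profile(enrolled=False)
    assert classify_incident(partial_prior, case).incident_t2dm is None
    assert classify_incident(None, case).incident_t2dm is None


def test_non_case_is_never_incident():
    non_case = classify_prevalent(_profile(dx={1}))
    assert classify_incident(_profile(), non_case).incident_t2dm is False


# ---------------------------------------------------------------------------
# frame-level profile building
# ---------------------------------------------------------------------------

def _claims_frame(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "year", "quarter", "enrolled", "icd_codes", "atc_codes"]
    )


PERSONS = pd.DataFrame(
    {
        "person_id": ["a", "b", "c"],
        "sex": ["male", "female", "male"],
        "birth_year": [1950, 1960, 1940],
        "district_id": ["D00", "D00", "D01"],
    }
)


def test_partial_enrollment_excluded_from_denominator():
    claims = _claims_frame(
        [("a", 2010, q, True, "E11", "") for q in (1, 2, 3)]
        + [("b", 2010, q, True, "", "") for q in (1, 2, 3, 4)]
        + [("c", 2010, q, True, "", "") for q in (1, 2, 3, 4)]
    )
    prof = build_profiles(claims, PERSONS, 2010)
    a = prof.set_index("person_id").loc["a"]
    assert not a["enrolled_all_year"]
    classified = classify_prevalent_frame(prof)
    assert not classified.set_index("person_id").loc["a", "eligible"]
    assert classified["eligible"].sum() == 2


def test_e13_and_e10_never_count_as_diabetes_claims():
    claims = _claims_frame(
        [("a", 2010, q, True, "E13", "") for q in (1, 2, 3, 4)]
        + [("b", 2010, q, True, "E10", "") for q in (1, 2, 3)]
        + [("b", 2010, 4, True, "", "")]
        + [("c", 2010, q, True, "", "") for q in (1, 2, 3, 4)]
    )
    prof = build_profiles(claims, PERSONS, 2010).set_index("person_id")
    assert prof.loc["a", "n_dx_quarters"] == 0
    assert prof.loc["b", "n_dx_quarters"] == 0
    # but both carry a diabetes code, so neither may serve as control
    assert prof.loc["a", "any_diabetes_code"]
    assert prof.loc["b", "any_diabetes_code"]
    assert not prof.loc["c", "any_diabetes_code"]


def test_age_is_year_minus_birth_year():
    claims = _claims_frame([("a", 2010, 1, True, "", "")])
    prof = build_profiles(claims, PERSONS, 2010).set_index("person_id")
    assert prof.loc["a", "age"] == 60
    assert str(prof.loc["a", "age_group"]) == "60-64"


def test_orphan_claims_rejected_with_ids():
    claims = _claims_frame([("ghost", 2010, 1, True, "", "")])
    with pytest.raises(ValueError, match="ghost"):
        build_profiles(claims, PERSONS, 2010)


@pytest.mark.parametrize(
    "codes, expected_true",
    [
        (["I10"], {"hypertension"}),
        (["I23"], set()),  # I23 deliberately absent from the CHD list
        (["N08.3"], {"renal"}),
        (["N08.2"], set()),
        (["H36.03"], {"retinopathy"}),
        (["H36"], set()),
        (["E66", "I63", "I25"], {"adiposity", "stroke", "chd"}),
        (["I139"], {"hypertension"}),  # prefix match on the 3-char category
    ],
)
def test_comorbidity_flag_code_lists(codes, expected_true):
    flags = flag_comorbidities(codes)
    assert {k for k, v in flags.items() if v} == expected_true


def test_frame_classification_agrees_with_scalar_rules():
    rng = np.random.default_rng(4)
    rows = []
    persons = []
    for i in range(300):
        pid = f"p{i}"
        persons.append((pid, "male", 1950, "D00"))
        n_enrolled = rng.integers(1, 5)
        dxq = set(rng.choice([1, 2, 3, 4], rng.integers(0, 5), replace=False))
        rxq = set(rng.choice([1, 2, 3, 4], rng.integers(0, 3), replace=False))
        for q in range(1, 5):
            rows.append(
                (
                    pid, 2010, q, q <= n_enrolled,
                    "E11" if q in dxq else "",
                    "A10B" if q in rxq else "",
                )
            )
    persons_df = pd.DataFrame(
        persons, columns=["person_id", "sex", "birth_year", "district_id"]
    )
    frame = classify_prevalent_frame(
        build_profiles(_claims_frame(rows), persons_df, 2010)
    )
    for _, row in frame.iterrows():
        scalar = classify_prevalent(
            _profile(
                dx=set(range(1, row["n_dx_quarters"] + 1)),
                rx=set(range(1, row["n_rx_quarters"] + 1)),
                enrolled=row["enrolled_all_year"],
            )
        )
        if scalar.prevalent_t2dm is None:
            assert not row["eligible"]
        else:
            assert row["prevalent_t2dm"] == scalar.prevalent_t2dm


def test_incident_frame_matches_washout_definition():
    claims = _claims_frame(
        # a: case in 2010, clean fully-enrolled 2009 -> incident
        [("a", 2010, q, True, "E11", "") for q in (1, 2, 3)]
        + [("a", 2010, 4, True, "", "")]
        + [("a", 2009, q, True, "", "") for q in (1, 2, 3, 4)]
        # b: case in 2010 but one E14 claim in 2009 -> not incident
        + [("b", 2010, q, True, "E14", "") for q in (1, 2, 3, 4)]
        + [("b", 2009, 1, True, "E14", "")]
        + [("b", 2009, q, True, "", "") for q in (2, 3, 4)]
        # c: case in 2010, enrolled only half of 2009 -> not evaluable
        + [("c", 2010, q, True, "", "A10A") for q in (1, 2, 3, 4)]
        + [("c", 2009, q, True, "", "") for q in (3, 4)]
    )
    prof_2009 = build_profiles(claims, PERSONS, 2009)
    cases_2010 = classify_prevalent_frame(build_profiles(claims, PERSONS, 2010))
    out = classify_incident_frame(cases_2010, prof_2009).set_index("person_id")
    assert bool(out.loc["a", "incident_t2dm"])
    assert not bool(out.loc["b", "incident_t2dm"])
    assert not bool(out.loc["c", "incident_evaluable"])


def test_perfect_coding_recovers_truth_exactly(perfect_coding_config):
    """With complete quarterly E11 coding and full enrollment the
    algorithm has sensitivity 1 and false-positive rate 0 against the
    generator's latent truth."""
    from diabsurv import generate_cohort
    from diabsurv.ascertainment import ascertain_year

    co = generate_cohort(perfect_coding_config)
    frame = ascertain_year(co.claims, co.persons, 2007).merge(co.truth, on="person_id")
    truth = frame["true_t2dm_onset_year"] != ""
    elig = frame["eligible"]
    assert (frame.loc[elig & truth, "prevalent_t2dm"]).all()
    assert (~frame.loc[elig & ~truth, "prevalent_t2dm"]).all()
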