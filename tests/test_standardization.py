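"""Direct standardization arithmetic, its variance, the trend test and
the standardized prevalence ratio."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diabsurv import (
    ReferencePopulation,
    StandardizedEstimate,
    StratifiedRates,
    cochran_armitage_trend,
    compute_spr,
    direct_standardize,
    district_rates,
)


def _rates(rows):
    return StratifiedRates(pd.DataFrame(rows, columns=["age_group", "sex", "cases", "denom"]))


def _ref(rows):
    return ReferencePopulation.from_frame(
        pd.DataFrame(rows, columns=["age_group_label", "sex", "count"])
    )


TWO_STRATA = _rates([("20-24", "male", 20, 100), ("25-29", "male", 40, 100)])


def test_hand_derived_two_stratum_example():
    """p=(0.2,0.4), d=(100,100), reference counts (300,100):
    estimate 0.75*0.2+0.25*0.4=0.25, variance 0.0009+0.00015=0.00105."""
    ref = _ref([("20-24", "male", 300), ("25-29", "male", 100)])
    est = direct_standardize(TWO_STRATA, ref)
    assert est.estimate == pytest.approx(0.25, abs=1e-12)
    assert est.variance == pytest.approx(0.00105, abs=1e-12)
    assert est.ci_low == pytest.approx(0.25 - 1.96 * np.sqrt(0.00105), abs=1e-4)


def test_uniform_rates_give_that_rate_for_any_weights():
    rates = _rates([("20-24", "male", 10, 100), ("25-29", "male", 5, 50)])
    ref = _ref([("20-24", "male", 123), ("25-29", "male", 77)])
    assert direct_standardize(rates, ref).estimate == pytest.approx(0.1)


def test_self_standardization_equals_crude_rate():
    ref = _ref([("20-24", "male", 100), ("25-29", "male", 100)])
    est = direct_standardize(TWO_STRATA, ref)
    assert est.estimate == pytest.approx(60 / 200)


def test_invariant_to_scaling_of_reference_counts():
    r1 = _ref([("20-24", "male", 300), ("25-29", "male", 100)])
    r2 = _ref([("20-24", "male", 3.0), ("25-29", "male", 1.0)])
    a, b = direct_standardize(TWO_STRATA, r1), direct_standardize(TWO_STRATA, r2)
    assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
    assert a.variance == pytest.approx(b.variance, rel=1e-12)


def test_zero_denominator_with_positive_weight_is_an_error():
    rates = _rates([("20-24", "male", 0, 0), ("25-29", "male", 40, 100)])
    ref = _ref([("20-24", "male", 300), ("25-29", "male", 100)])
    with pytest.raises(ValueError, match="20-24"):
        direct_standardize(rates, ref)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 50), st.integers(50, 500), st.integers(1, 1000)),
        min_size=1,
        max_size=8,
    )
)
def test_estimate_bounded_by_stratum_rates(data):
    rows = [(f"g{i}", "male", c, d) for i, (c, d, _) in enumerate(data)]
    refs = [(f"g{i}", "male", w) for i, (_, _, w) in enumerate(data)]
    est = direct_standardize(_rates(rows), _ref(refs))
    p = [c / d for c, d, _ in data]
    assert min(p) - 1e-12 <= est.estimate <= max(p) + 1e-12


def test_variance_agrees_with_binomial_bootstrap(small_cohort):
    """Formula variance vs an empirical bootstrap over stratum-level
    binomial resampling (1000 reps) on a synthetic cohort."""
    from diabsurv.ascertainment import ascertain_year

    frame = ascertain_year(small_cohort.claims, small_cohort.persons, 2010)
    elig = frame[frame["eligible"]]
    rates = StratifiedRates.from_flags(elig, "prevalent_t2dm")
    ref = ReferencePopulation.from_frame(small_cohort.refpop)
    est = direct_standardize(rates, ref)

    f = rates.frame.set_index(["age_group", "sex"]).loc[ref.weights.index]
    d = f["denom"].to_numpy()
    p = (f["cases"] / f["denom"]).to_numpy()
    w = ref.weights.to_numpy()
    rng = np.random.default_rng(123)
    boot = rng.binomial(d, p, size=(1000, len(d))) / d
    emp_var = (boot @ w).var(ddof=1)
    assert emp_var == pytest.approx(est.variance, rel=0.10)


# ---------------------------------------------------------------------------
# Cochran-Armitage
# ---------------------------------------------------------------------------

def _ca_oracle(pairs, scores):
    """Exact-arithmetic evaluation of the defining score statistic."""
    n = [Fraction(c) for c, _ in pairs]
    d = [Fraction(t) for _, t in pairs]
    s = [Fraction(x) for x in scores]
    pbar = sum(n) / sum(d)
    num = sum(si * (ni - di * pbar) for si, ni, di in zip(s, n, d))
    den = pbar * (1 - pbar) * (
        sum(si**2 * di for si, di in zip(s, d))
        - sum(si * di for si, di in zip(s, d)) ** 2 / sum(d)
    )
    return float(num) / float(den) ** 0.5


def test_flat_proportions_give_zero_statistic():
    res = cochran_armitage_trend([(10, 100), (20, 200), (30, 300)])
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_statistic_matches_exact_arithmetic_oracle():
    pairs = [(10, 100), (20, 100), (30, 100)]
    res = cochran_armitage_trend(pairs, scores=(0, 1, 2))
    assert res.z == pytest.approx(_ca_oracle(pairs, (0, 1, 2)), rel=1e-12)
    # and Z^2 equals the chi-squared linear-trend statistic
    assert res.z**2 == pytest.approx(_ca_oracle(pairs, (0, 1, 2)) ** 2, rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    tables=st.lists(
        st.tuples(st.integers(1, 40), st.integers(50, 200)), min_size=2, max_size=6
    )
)
def test_statistic_matches_oracle_on_random_tables(tables):
    scores = tuple(range(len(tables)))
    res = cochran_armitage_trend(tables, scores=scores)
    assert res.z == pytest.approx(_ca_oracle(tables, scores), rel=1e-9)


def test_degenerate_all_zero_groups():
    res = cochran_armitage_trend([(0, 100), (0, 100)])
    assert res.degenerate and res.z == 0.0 and res.pvalue == 1.0


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------

def _se(p, var=1e-8):
    return StandardizedEstimate(p, var, p - 0.01, p + 0.01, "percent")


def test_spr_is_ratio_of_standardized_prevalences():
    res = compute_spr(_se(0.2711), _se(0.0599))
    assert res.spr == pytest.approx(0.2711 / 0.0599)
    assert res.ci_low < res.spr < res.ci_high


def test_identical_inputs_give_unit_spr():
    res = compute_spr(_se(0.1), _se(0.1))
    assert res.spr == pytest.approx(1.0)


def test_zero_unexposed_prevalence_is_an_error():
    with pytest.raises(ValueError):
        compute_spr(_se(0.1), _se(0.0))


# ---------------------------------------------------------------------------
# districts
# ---------------------------------------------------------------------------

def _person_frame(district, stratum_counts):
    """stratum_counts: {(age_group, sex): (cases, denom)} -> per-person rows."""
    rows = []
    for (group, sex), (cases, denom) in stratum_counts.items():
        for i in range(denom):
            rows.append(
                {
                    "district_id": district,
                    "age_group": group,
                    "sex": sex,
                    "prevalent_t2dm": i < cases,
                }
            )
    return pd.DataFrame(rows)


def test_identical_stratum_rates_differ_only_under_district_reference():
    """Two districts with the same age-specific rates but different age
    structures: equal state-referenced estimates, unequal district-
    referenced ones."""
    young_heavy = _person_frame("A", {("20-24", "male"): (10, 100), ("70-74", "male"): (4, 10)})
    old_heavy = _person_frame("B", {("20-24", "male"): (1, 10), ("70-74", "male"): (40, 100)})
    table = pd.concat([young_heavy, old_heavy], ignore_index=True)
    state_ref = _ref([("20-24", "male", 500), ("70-74", "male", 500)])
    out = district_rates(table, state_ref=state_ref).set_index(["district_id", "reference"])
    assert out.loc[("A", "state"), "estimate"] == pytest.approx(
        out.loc[("B", "state"), "estimate"]
    )
    assert out.loc[("A", "district"), "estimate"] != pytest.approx(
        out.loc[("B", "district"), "estimate"]
    )


def test_single_district_self_reference_equals_crude():
    table = _person_frame("A", {("20-24", "male"): (10, 100), ("25-29", "male"): (30, 100)})
    state_ref = _ref([("20-24", "male", 100), ("25-29", "male", 100)])
    out = district_rates(table, state_ref=state_ref).set_index("reference")
    assert out.loc["district", "estimate"] == pytest.approx(20.0)  # percent


def test_configured_district_gradient_is_recovered():
    from diabsurv import CohortConfig, generate_cohort
    from diabsurv.ascertainment import ascertain_year

    mult = [0.5, 0.75, 1.0, 1.25, 1.5]
    cfg = CohortConfig(
        n_persons=30000,
        years=(2010,),
        n_districts=5,
        district_rate_multipliers=mult,
        seed=17,
    )
    co = generate_cohort(cfg)
    frame = ascertain_year(co.claims, co.persons, 2010)
    elig = frame[frame["eligible"]]
    out = district_rates(elig, state_ref=ReferencePopulation.from_frame(co.refpop))
    state = out[out["reference"] == "state"].sort_values("district_id")
    assert list(state["estimate"]) == sorted(state["estimate"])
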