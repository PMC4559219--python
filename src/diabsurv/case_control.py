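"""1:1 age-sex-matched case-control set and comorbidity odds ratios.

Every prevalent T2DM case of a calendar year is matched to one control
drawn uniformly without replacement from the fully enrolled persons of
the same 5-year age band and sex who carry no diabetes code (E10-E14)
that year. Comorbidity burden is then compared as prevalence among cases
vs controls, with the odds ratio computed from the pooled 2x2 table and
a Woolf (log-normal) 95 % confidence interval; matching is accounted for
by design (the control group reproduces the cases' age-sex structure),
not by a conditional pairs analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standardization import Z95


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    year: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each case to one control within (age_group, sex) strata.

    ``cases`` and ``pool`` are per-person frames with ``person_id``,
    ``age_group`` and ``sex`` columns; the pool must already be filtered
    to eligible controls. Sampling is uniform without replacement within
    each stratum and deterministic for a given seed. Returns
    ``(pairs, unmatched)``: cases whose stratum pool is exhausted are
    reported in ``unmatched``, never silently dropped.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    unmatched = []
    strata = sorted(
        set(map(tuple, cases[["age_group", "sex"]].astype(str).drop_duplicates().to_numpy()))
    )
    pool_idx = {
        key: sub["person_id"].sort_values().to_numpy()
        for key, sub in pool.assign(
            age_group=pool["age_group"].astype(str)
        ).groupby(["age_group", "sex"], observed=True)
    }
    for key in strata:
        case_ids = np.sort(
            cases.loc[
                (cases["age_group"].astype(str) == key[0]) & (cases["sex"] == key[1]),
                "person_id",
            ].to_numpy()
        )
        avail = pool_idx.get(key, np.array([], dtype=object))
        m = min(len(case_ids), len(avail))
        chosen = rng.choice(avail, size=m, replace=False) if m > 0 else []
        for cid, ctl in zip(case_ids[:m], chosen):
            pairs.append(
                {
                    "year": year,
                    "case_person_id": cid,
                    "control_person_id": ctl,
                    "age_group": key[0],
                    "sex": key[1],
                }
            )
        for cid in case_ids[m:]:
            unmatched.append(
                {"year": year, "case_person_id": cid, "age_group": key[0], "sex": key[1]}
            )
    return pd.DataFrame(pairs), pd.DataFrame(unmatched)


@dataclass
class ORResult:
    """Comorbidity prevalence among cases/controls (%) and pooled odds ratio."""

    prevalence_cases: float
    prevalence_controls: float
    or_estimate: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


def odds_ratio_from_counts(a: float, b: float, c: float, d: float) -> ORResult:
    """Odds ratio from the 2x2 table (a,b = cases with/without the flag;
    c,d = controls with/without), Woolf CI; 0.5 added to every cell when
    any cell is zero (flagged)."""
    n1 = a + b
    n0 = c + d
    if n1 <= 0 or n0 <= 0:
        raise ValueError("empty case or control group")
    corrected = min(a, b, c, d) <= 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        prevalence_cases=100.0 * (a - 0.5 * corrected) / n1,
        prevalence_controls=100.0 * (c - 0.5 * corrected) / n0,
        or_estimate=float(orr),
        ci_low=float(orr * np.exp(-Z95 * se)),
        ci_high=float(orr * np.exp(Z95 * se)),
        continuity_corrected=corrected,
    )


def odds_ratio_from_prevalences(p_cases: float, p_controls: float) -> float:
    """OR implied by two prevalences (any scale summing odds correctly).

    Accepts proportions or percentages; identical to the 2x2-count OR by
    the algebraic identity OR = [p1/(1-p1)] / [p0/(1-p0)].
    """
    p1, p0 = float(p_cases), float(p_controls)
    if p1 > 1 or p0 > 1:  # percent scale
        p1, p0 = p1 / 100.0, p0 / 100.0
    if not (0 < p1 < 1 and 0 < p0 < 1):
        raise ValueError("prevalences must lie strictly between 0 and 1 (or 0 and 100)")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def prevalence_ci(p_pct: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95 % CI for a prevalence given in percent."""
    p = p_pct / 100.0
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return (100 * max(0.0, p - half), 100 * min(1.0, p + half))


def comorbidity_or(
    pairs: pd.DataFrame,
    flags: pd.DataFrame,
    comorbidities: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-comorbidity prevalences and odds ratios for a matched set.

    ``flags`` is a per-person frame indexed (or indexable) by
    ``person_id`` with one boolean column per comorbidity. Returns one
    row per comorbidity: prev_cases, prev_controls (percent, with CIs),
    or, ci_low, ci_high, continuity_corrected.
    """
    if "person_id" in flags.columns:
        flags = flags.set_index("person_id")
    if comorbidities is None:
        comorbidities = tuple(c for c in flags.columns if flags[c].dtype == bool)
    case_flags = flags.loc[pairs["case_person_id"], list(comorbidities)].to_numpy()
    control_flags = flags.loc[pairs["control_person_id"], list(comorbidities)].to_numpy()
    n = len(pairs)
    rows = []
    for j, name in enumerate(comorbidities):
        a = int(case_flags[:, j].sum())
        c = int(control_flags[:, j].sum())
        res = odds_ratio_from_counts(a, n - a, c, n - c)
        lo1, hi1 = prevalence_ci(res.prevalence_cases, n)
        lo0, hi0 = prevalence_ci(res.prevalence_controls, n)
        rows.append(
            {
                "comorbidity": name,
                "prev_cases": res.prevalence_cases,
                "prev_cases_ci_low": lo1,
                "prev_cases_ci_high": hi1,
                "prev_controls": res.prevalence_controls,
                "prev_controls_ci_low": lo0,
                "prev_controls_ci_high": hi0,
                "or": res.or_estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "continuity_corrected": res.continuity_corrected,
            }
        )
    return pd.DataFrame(rows)
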