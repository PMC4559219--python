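"""Descriptive summaries: the diabetes ICD coding-pattern report.

Physicians frequently attach several different diabetes codes (E10-E14)
to the same person over a year. This report quantifies that multiple
coding: among persons carrying any diabetes code in a year, the share
carrying each code at all (non-exclusive — the shares may sum above
100 %) and the share carrying each code *alone*; plus the share of all
insured persons with antidiabetic prescriptions but no diabetes ICD code
over the whole year.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ascertainment import ANTIDIABETIC_RE, ANY_DIABETES_RE

DIABETES_CODES = ("E10", "E11", "E12", "E13", "E14")


@dataclass
class CodingPatternReport:
    year: int
    n_with_any_code: int
    n_insured: int
    codes: pd.DataFrame  # code, pct_any, pct_alone
    rx_only_pct: float  # % of all insured: antidiabetic Rx but no diabetes ICD all year
    degenerate: bool = False  # no diabetes codes at all in the year

    def to_frame(self) -> pd.DataFrame:
        out = self.codes.copy()
        out.insert(0, "year", self.year)
        return out


def coding_pattern_report(
    claims: pd.DataFrame, persons: pd.DataFrame, year: int
) -> CodingPatternReport:
    """Code-usage proportions among persons with any diabetes code."""
    cy = claims[(claims["year"] == year) & claims["enrolled"].astype(bool)]
    icd = cy["icd_codes"].fillna("").astype(str).str.upper()
    atc = cy["atc_codes"].fillna("").astype(str).str.upper()

    per_code = {}
    for code in DIABETES_CODES:
        has = cy.loc[icd.str.contains(rf"(?:^|;){code}", regex=True), "person_id"]
        per_code[code] = set(has)
    any_dm_persons = set().union(*per_code.values())
    n_any = len(any_dm_persons)

    rx_persons = set(cy.loc[atc.str.contains(ANTIDIABETIC_RE, regex=True), "person_id"])
    dm_code_persons = set(cy.loc[icd.str.contains(ANY_DIABETES_RE, regex=True), "person_id"])
    insured = set(cy["person_id"])
    n_insured = len(insured)
    rx_only = rx_persons - dm_code_persons

    rows = []
    for code in DIABETES_CODES:
        carriers = per_code[code]
        alone = {
            p
            for p in carriers
            if not any(p in per_code[o] for o in DIABETES_CODES if o != code)
        }
        rows.append(
            {
                "code": code,
                "pct_any": 100.0 * len(carriers) / n_any if n_any else 0.0,
                "pct_alone": 100.0 * len(alone) / n_any if n_any else 0.0,
            }
        )
    return CodingPatternReport(
        year=year,
        n_with_any_code=n_any,
        n_insured=n_insured,
        codes=pd.DataFrame(rows),
        rx_only_pct=100.0 * len(rx_only) / n_insured if n_insured else 0.0,
        degenerate=n_any == 0,
    )
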