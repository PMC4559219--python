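"""Seeded synthetic claims-data generator.

Emulates the statistical structure of statutory-health-insurance claims as
consumed by the surveillance pipeline: multi-year enrollment spells on a
quarterly grid, age-graded type 2 diabetes (T2DM) with several overlapping
ICD-10 diabetes codes per person, antidiabetic prescriptions with and
without accompanying diagnoses, and age-graded comorbidities whose
prevalence follows configurable logistic curves separately for persons
with and without T2DM.

A latent truth table (true T2DM onset year per person) is produced as a
separate output so tests can measure the ascertainment algorithm's
sensitivity and false-positive rate; the analysis pipeline never reads it.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, so the same seed and config give
byte-identical output files, and the truth table can be regenerated on its
own (`inject_incident_cases`) without building the claims rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agegroups import AGE_GROUP_LABELS, age_to_group

# Upper bound (exclusive) for single ages drawn inside the open 75+ band.
_OPEN_BAND_MAX_AGE = 91

_CODE_MIX_KEYS = ("e11", "e14", "both", "e10", "e13")


@dataclass(frozen=True)
class LogisticCurve:
    """Logistic prevalence-vs-age curve: asymptote / (1 + exp(-slope*(age-midpoint)))."""

    midpoint: float
    slope: float
    asymptote: float

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        return self.asymptote / (1.0 + np.exp(-self.slope * (age - self.midpoint)))


#: Comorbidities modelled by the generator and flagged by the pipeline.
COMORBIDITIES = ("adiposity", "hypertension", "chd", "stroke", "renal", "retinopathy")

#: One representative ICD-10 code emitted per comorbidity.
_COMORBIDITY_CODE = {
    "adiposity": "E66",
    "hypertension": "I10",
    "chd": "I25",
    "stroke": "I63",
    "renal": "N18",
    "retinopathy": "H35",
}


def _default_age_distribution() -> dict[str, float]:
    # Broadly the age profile of a large German statutory insurer.
    return {
        "0-19": 0.18, "20-24": 0.055, "25-29": 0.06, "30-34": 0.06,
        "35-39": 0.06, "40-44": 0.07, "45-49": 0.08, "50-54": 0.08,
        "55-59": 0.07, "60-64": 0.06, "65-69": 0.06, "70-74": 0.065,
        "75+": 0.10,
    }


def _default_t2dm_prevalence() -> dict[str, float]:
    # Diagnosis-based T2DM prevalence by age: exceeds 5 % in the early 50s,
    # ~15 % at 60-64 and >25 % from 75 on.
    return {
        "0-19": 0.002, "20-24": 0.005, "25-29": 0.007, "30-34": 0.010,
        "35-39": 0.015, "40-44": 0.025, "45-49": 0.040, "50-54": 0.055,
        "55-59": 0.090, "60-64": 0.150, "65-69": 0.200, "70-74": 0.240,
        "75+": 0.280,
    }


def _default_comorbidity_params() -> dict[str, dict[str, LogisticCurve]]:
    # Midpoints and asymptotes chosen so the half-maximum ages and
    # semi-maximum prevalences of the curves resemble claims-based
    # surveillance estimates for a diabetic vs non-diabetic population.
    return {
        "adiposity": {
            "without": LogisticCurve(34.3, 0.12, 0.135),
            "with": LogisticCurve(21.9, 0.12, 0.41),
        },
        "hypertension": {
            "without": LogisticCurve(60.5, 0.10, 0.74),
            "with": LogisticCurve(40.3, 0.10, 0.87),
        },
        "chd": {
            "without": LogisticCurve(70.5, 0.12, 0.27),
            "with": LogisticCurve(62.5, 0.12, 0.35),
        },
        "stroke": {
            "without": LogisticCurve(72.2, 0.12, 0.052),
            "with": LogisticCurve(67.8, 0.12, 0.073),
        },
        "renal": {
            "without": LogisticCurve(72.7, 0.12, 0.102),
            "with": LogisticCurve(64.0, 0.12, 0.124),
        },
        "retinopathy": {
            "without": LogisticCurve(69.1, 0.10, 0.196),
            "with": LogisticCurve(47.9, 0.10, 0.32),
        },
    }


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    Defaults emulate the claims structure the pipeline assumes: a ~47 %
    male insurer population observed 2007-2010, ~88 % of person-years
    fully enrolled, diabetics coded in any given quarter with probability
    ``coding_completeness`` using a persistent per-person mix of E11 /
    E14 / both / E10 / E13, and about half of diabetics on antidiabetic
    drugs (ATC A10A/A10B).
    """

    n_persons: int = 20000
    years: Sequence[int] = (2007, 2008, 2009, 2010)
    age_distribution: Mapping[str, float] = field(default_factory=_default_age_distribution)
    sex_ratio: float = 0.47  # fraction male
    n_districts: int = 4
    t2dm_prevalence_by_age: Mapping[str, float] = field(default_factory=_default_t2dm_prevalence)
    comorbidity_params: Mapping[str, Mapping[str, LogisticCurve]] = field(
        default_factory=_default_comorbidity_params
    )
    coding_completeness: float = 0.85
    drug_treatment_fraction: float = 0.55
    rx_quarter_prob: float = 0.75  # per-quarter Rx probability for drug-treated diabetics
    dropout_rate: float = 0.12  # per person-year probability of losing full-year enrollment
    code_mix: Mapping[str, float] = field(
        default_factory=lambda: {"e11": 0.42, "e14": 0.14, "both": 0.38, "e10": 0.04, "e13": 0.02}
    )
    # optional regional gradient: per-district multiplier on the T2DM
    # prevalence curve (None = no regional variation)
    district_rate_multipliers: Sequence[float] | None = None
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not (isinstance(self.n_persons, (int, np.integer)) and self.n_persons > 0):
            raise ValueError("n_persons must be a positive integer")
        if len(self.years) < 1 or list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be a non-empty strictly increasing list")
        if self.n_districts < 1:
            raise ValueError("n_districts must be a positive integer")
        for name in ("sex_ratio", "coding_completeness", "drug_treatment_fraction",
                     "rx_quarter_prob", "dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.age_distribution) != set(AGE_GROUP_LABELS):
            raise ValueError("age_distribution must give a weight for every age group")
        w = np.array([self.age_distribution[g] for g in AGE_GROUP_LABELS], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("age_distribution weights must be >= 0 and sum to 1")
        for g, p in self.t2dm_prevalence_by_age.items():
            if g not in AGE_GROUP_LABELS:
                raise ValueError(f"t2dm_prevalence_by_age has unknown age group {g!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"t2dm_prevalence_by_age[{g!r}] must be in [0, 1]")
        if set(self.code_mix) != set(_CODE_MIX_KEYS):
            raise ValueError(f"code_mix must have exactly the keys {_CODE_MIX_KEYS}")
        cm = np.array([self.code_mix[k] for k in _CODE_MIX_KEYS], dtype=float)
        if (cm < 0).any() or abs(cm.sum() - 1.0) > 1e-9:
            raise ValueError("code_mix probabilities must be >= 0 and sum to 1")
        if self.district_rate_multipliers is not None:
            m = np.asarray(self.district_rate_multipliers, dtype=float)
            if len(m) != self.n_districts or (m < 0).any():
                raise ValueError(
                    "district_rate_multipliers must give a non-negative factor per district"
                )
        for name, strata in self.comorbidity_params.items():
            for stratum in ("with", "without"):
                if stratum not in strata:
                    raise ValueError(
                        f"comorbidity_params[{name!r}] needs 'with' and 'without' curves"
                    )
                c = strata[stratum]
                if not (0.0 <= c.asymptote <= 1.0):
                    raise ValueError(
                        f"comorbidity_params[{name!r}][{stratum!r}].asymptote must be in [0, 1]"
                    )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "comorbidity_params" in raw:
            raw["comorbidity_params"] = {
                name: {k: LogisticCurve(**v) for k, v in strata.items()}
                for name, strata in raw["comorbidity_params"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class SyntheticCohort:
    """Output bundle of :func:`generate_cohort`."""

    claims: pd.DataFrame
    persons: pd.DataFrame
    truth: pd.DataFrame
    refpop: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("claims", "persons", "truth", "refpop"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# internal seeded stages
# ---------------------------------------------------------------------------

def _streams(seed: int):
    """Named child RNGs so the truth table is reproducible independently."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    return {
        "persons": np.random.default_rng(kids[0]),
        "onset": np.random.default_rng(kids[1]),
        "claims": np.random.default_rng(kids[2]),
        "comorbid": np.random.default_rng(kids[3]),
    }


def _draw_persons(rng, config: CohortConfig) -> pd.DataFrame:
    n = config.n_persons
    first_year = min(config.years)
    weights = np.array([config.age_distribution[g] for g in AGE_GROUP_LABELS])
    gidx = rng.choice(len(AGE_GROUP_LABELS), size=n, p=weights / weights.sum())
    # single age uniform within the band
    lows = np.array([0, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75])
    highs = np.array([20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, _OPEN_BAND_MAX_AGE])
    age = lows[gidx] + np.floor(
        rng.random(n) * (highs[gidx] - lows[gidx])
    ).astype(int)
    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    district = rng.integers(0, config.n_districts, size=n)
    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "birth_year": first_year - age,
            "district_id": [f"D{d:02d}" for d in district],
        }
    )
    return persons


def _assign_onset(
    rng,
    persons: pd.DataFrame,
    config: CohortConfig,
    onset_year_distribution: Mapping[int, float] | None,
) -> pd.DataFrame:
    """Draw latent T2DM status and onset year per person.

    Onset equal to the first study year means prevalent from the start
    (disease acquired then or earlier); later onset years create incident
    cases with no diabetes claims before onset.
    """
    first_year = min(config.years)
    age0 = first_year - persons["birth_year"].to_numpy()
    groups = age_to_group(age0)
    prev = np.array(
        [config.t2dm_prevalence_by_age.get(g, 0.0) for g in np.asarray(groups)]
    )
    if config.district_rate_multipliers is not None:
        mult = np.asarray(config.district_rate_multipliers, dtype=float)
        didx = persons["district_id"].str.slice(1).astype(int).to_numpy()
        prev = np.clip(prev * mult[didx], 0.0, 1.0)
    is_diab = rng.random(len(persons)) < prev
    onset = np.where(is_diab, first_year, -1)
    if onset_year_distribution:
        if len(config.years) < 2:
            raise ValueError("onset_year_distribution requires a config spanning >= 2 years")
        bad = [y for y in onset_year_distribution if y not in list(config.years)[1:]]
        if bad:
            raise ValueError(f"onset years must lie in the second or later study years: {bad}")
        fracs = np.array(list(onset_year_distribution.values()), dtype=float)
        if (fracs < 0).any() or fracs.sum() > 1.0 + 1e-9:
            raise ValueError("onset fractions must be >= 0 and sum to <= 1")
        u = rng.random(len(persons))
        cum = 0.0
        for year, frac in onset_year_distribution.items():
            sel = is_diab & (u >= cum) & (u < cum + frac)
            onset[sel] = year
            cum += frac
    truth = pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "true_t2dm_onset_year": [o if o > 0 else "" for o in onset],
        }
    )
    return truth


def inject_incident_cases(
    config: CohortConfig, onset_year_distribution: Mapping[int, float]
) -> pd.DataFrame:
    """Truth table with a configurable share of diabetics having late onset.

    ``onset_year_distribution`` maps a study year (second or later) to the
    fraction of diabetics whose disease starts that year; the remainder are
    prevalent from the first year. Uses the same seeded streams as
    :func:`generate_cohort`, so the returned table matches the one a full
    generation with the same config would write.
    """
    config.validate()
    if len(config.years) < 2:
        raise ValueError("onset injection requires a config spanning >= 2 years")
    streams = _streams(config.seed)
    persons = _draw_persons(streams["persons"], config)
    return _assign_onset(streams["onset"], persons, config, onset_year_distribution)


def generate_cohort(
    config: CohortConfig,
    onset_year_distribution: Mapping[int, float] | None = None,
    refpop: pd.DataFrame | None = None,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    Returns claims (one row per person-quarter, enrolled or not), the
    person table, the latent truth table, and a reference population
    table. The reference population defaults to the generated cohort's
    own age-sex counts in the first study year (self-standardization), so
    standardized and crude rates coincide on the default path; pass
    ``refpop`` to exercise true external standardization.
    """
    config.validate()
    streams = _streams(config.seed)
    persons = _draw_persons(streams["persons"], config)
    truth = _assign_onset(streams["onset"], persons, config, onset_year_distribution)

    years = np.asarray(list(config.years))
    n = len(persons)
    rng = streams["claims"]

    onset = np.where(
        truth["true_t2dm_onset_year"].to_numpy() == "",
        np.iinfo(np.int32).max,
        pd.to_numeric(truth["true_t2dm_onset_year"], errors="coerce").fillna(np.iinfo(np.int32).max),
    ).astype(np.int64)

    # persistent per-person coding style and treatment status
    mix = np.array([config.code_mix[k] for k in _CODE_MIX_KEYS], dtype=float)
    style = rng.choice(len(_CODE_MIX_KEYS), size=n, p=mix / mix.sum())
    treated = rng.random(n) < config.drug_treatment_fraction

    style_codes = np.array(["E11", "E14", "E11;E14", "E10", "E13"])[style]

    frames = []
    rng_c = streams["comorbid"]
    for year in years:
        age = year - persons["birth_year"].to_numpy()
        # enrollment: with prob dropout_rate the person-year is only
        # partially enrolled (0-3 leading quarters), else all 4 quarters
        partial = rng.random(n) < config.dropout_rate
        n_quarters = np.where(partial, rng.integers(0, 4, size=n), 4)

        diab_active = onset <= year

        # diabetes ICD emission per quarter; Rx per quarter for treated
        code_mask = (
            rng.random((n, 4)) < config.coding_completeness
        ) & diab_active[:, None]
        rx_mask = (
            rng.random((n, 4)) < config.rx_quarter_prob
        ) & (diab_active & treated)[:, None]

        # comorbidities: one draw per person-year from the stratum curve,
        # code placed in one uniformly chosen enrolled quarter
        comorbid_quarter = {}
        for name in COMORBIDITIES:
            curves = config.comorbidity_params.get(name)
            if curves is None:
                continue
            p = np.where(
                diab_active, curves["with"](age), curves["without"](age)
            )
            has = (rng_c.random(n) < p) & (n_quarters > 0)
            q = rng_c.integers(0, np.maximum(n_quarters, 1))
            comorbid_quarter[name] = np.where(has, q, -1)

        for q in range(4):
            enrolled = n_quarters > q
            icd_parts = []
            diab_codes = np.where(enrolled & code_mask[:, q], style_codes, "")
            icd_parts.append(diab_codes)
            for name, cq in comorbid_quarter.items():
                icd_parts.append(
                    np.where(enrolled & (cq == q), _COMORBIDITY_CODE[name], "")
                )
            icd = icd_parts[0]
            for part in icd_parts[1:]:
                sep = np.where((icd != "") & (part != ""), ";", "")
                icd = np.char.add(np.char.add(icd.astype("U40"), sep), part)
            atc = np.where(enrolled & rx_mask[:, q], "A10B", "")
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": persons["person_id"],
                        "year": year,
                        "quarter": q + 1,
                        "enrolled": enrolled,
                        "icd_codes": icd,
                        "atc_codes": atc,
                    }
                )
            )

    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(["person_id", "year", "quarter"], kind="stable").reset_index(
        drop=True
    )

    if refpop is None:
        first_year = int(years.min())
        age0 = first_year - persons["birth_year"].to_numpy()
        tab = (
            pd.DataFrame(
                {"age_group": np.asarray(age_to_group(age0)), "sex": persons["sex"]}
            )
            .value_counts()
            .reset_index(name="count")
        )
        tab = tab.rename(columns={"age_group": "age_group_label"})
        order = {g: i for i, g in enumerate(AGE_GROUP_LABELS)}
        tab = tab.sort_values(
            ["age_group_label", "sex"],
            key=lambda s: s.map(order) if s.name == "age_group_label" else s,
            kind="stable",
        ).reset_index(drop=True)
        refpop = tab

    return SyntheticCohort(claims=claims, persons=persons, truth=truth, refpop=refpop)
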