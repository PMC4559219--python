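"""End-to-end orchestration of the surveillance analysis.

Stages run in a fixed order on the claims/person/reference-population
CSV contracts: ascertainment -> standardized rates & trends ->
case-control odds ratios -> comorbidity curves & age shifts -> district
rates -> coding-pattern report. Every output CSV carries a provenance
header (seed, config hash, timestamp) as ``#`` comment lines, and a
structured count log records the cohort at each eligibility filter step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ascertainment as asc
from . import case_control as cc
from .agegroups import ADULT_AGE_GROUP_LABELS, class_means
from .curves import FPResults, FractionalPolynomial, SemiMaxResult, age_shift, semimax_age
from .report import coding_pattern_report
from .standardization import (
    ReferencePopulation,
    StandardizedEstimate,
    StratifiedRates,
    cochran_armitage_trend,
    compute_spr,
    direct_standardize,
    district_rates,
)

log = logging.getLogger("diabsurv")

SEXES = ("male", "female")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """File-level configuration of one pipeline run."""

    claims_path: str
    persons_path: str
    refpop_path: str | None = None
    years: Sequence[int] | None = None  # default: all years present in the claims
    reference_mode: str = "per_year"  # or "fixed:<year>"
    seed: int = 0
    outdir: str = "results"
    curve_year: int | None = None  # default: last analysis year
    district_bins: Sequence[float] | None = None
    open_end_mean: float = 80.0
    jsonl_log: bool = False

    def validate(self) -> None:
        for name in ("claims_path", "persons_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValueError(f"{name}: file not found: {p}")
        if self.refpop_path is not None and not Path(self.refpop_path).exists():
            raise ValueError(f"refpop_path: file not found: {self.refpop_path}")
        if not (
            self.reference_mode == "per_year"
            or (self.reference_mode.startswith("fixed:") and self.reference_mode[6:].isdigit())
        ):
            raise ValueError("reference_mode must be 'per_year' or 'fixed:<year>'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go
        does not change what they contain)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload.pop("jsonl_log", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every analysis output."""

    cases: pd.DataFrame
    prevalence: pd.DataFrame
    incidence: pd.DataFrame
    trend: pd.DataFrame
    spr: pd.DataFrame
    pairs: pd.DataFrame
    unmatched: pd.DataFrame
    or_results: pd.DataFrame
    curves: pd.DataFrame
    shifts: pd.DataFrame
    districts: pd.DataFrame
    coding: pd.DataFrame
    counts: pd.DataFrame
    curve_fits: dict = field(default_factory=dict, repr=False)

    _TABLES = (
        "cases", "prevalence", "incidence", "trend", "spr", "pairs", "unmatched",
        "or_results", "curves", "shifts", "districts", "coding", "counts",
    )

    def write(self, outdir, seed: int = 0, config_hash: str = "", timestamp: bool = True):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = [f"# seed: {seed}", f"# config_hash: {config_hash}"]
        if timestamp:
            meta.append(f"# generated: {datetime.now(timezone.utc).isoformat()}")
        paths = {}
        for name in self._TABLES:
            p = outdir / f"{name}.csv"
            with open(p, "w") as fh:
                fh.write("\n".join(meta) + "\n")
                getattr(self, name).to_csv(fh, index=False)
            paths[name] = p
        return paths


def read_output_csv(path) -> pd.DataFrame:
    """Read a pipeline output CSV, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# analysis stages on in-memory frames
# ---------------------------------------------------------------------------

def _self_reference(frame: pd.DataFrame) -> ReferencePopulation:
    rates = StratifiedRates.from_flags(frame.assign(_one=True), "_one")
    return ReferencePopulation(rates.frame.set_index(["age_group", "sex"])["denom"].astype(float))


def _sex_restricted(ref: ReferencePopulation, sex: str) -> ReferencePopulation:
    if sex == "all":
        return ref
    sel = ref.counts[ref.counts.index.get_level_values("sex") == sex]
    return ReferencePopulation(sel)


def _standardize_rows(
    frame: pd.DataFrame,
    flag_col: str,
    ref: ReferencePopulation,
    year: int,
    scale: str,
) -> list[dict]:
    """Standardized total/men/women rows plus crude age-group rows."""
    rows = []
    for sex in ("all", *SEXES):
        sub = frame if sex == "all" else frame[frame["sex"] == sex]
        rates = StratifiedRates.from_flags(sub, flag_col)
        sref = _sex_restricted(ref, sex)
        # drop reference strata entirely absent from this (sub)cohort — they
        # carry no information here (e.g. no at-risk children in a small run)
        present = rates.frame.set_index(["age_group", "sex"]).index
        covered = sref.counts.index.intersection(present)
        if len(covered) < len(sref.counts):
            sref = ReferencePopulation(sref.counts.loc[covered])
        est = direct_standardize(rates, sref, scale=scale)
        rows.append(
            {
                "year": year,
                "sex": sex,
                "age_group": "standardized",
                "estimate": est.value,
                "ci_low": est.ci[0],
                "ci_high": est.ci[1],
            }
        )
        for _, r in rates.frame.iterrows():
            p = r["cases"] / r["denom"] if r["denom"] else np.nan
            factor = {"percent": 100.0, "per_1000": 1000.0, "proportion": 1.0}[scale]
            half = (
                1.959963984540054 * np.sqrt(p * (1 - p) / r["denom"]) if r["denom"] else np.nan
            )
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "age_group": r["age_group"],
                    "estimate": p * factor,
                    "ci_low": max(0.0, p - half) * factor,
                    "ci_high": min(1.0, p + half) * factor,
                }
            )
    return rows


def _fit_stratum_curve(
    frame: pd.DataFrame, flag_col: str, open_end_mean: float
) -> tuple[FPResults, SemiMaxResult] | None:
    """FP fit + semi-maximum for one comorbidity stratum (adults only)."""
    tab = (
        frame[frame["age_group"].astype(str).isin(ADULT_AGE_GROUP_LABELS)]
        .groupby("age_group", observed=True)[flag_col]
        .agg(cases="sum", denom="size")
        .reindex(ADULT_AGE_GROUP_LABELS)
        .dropna()
    )
    tab = tab[tab["denom"] > 0]
    if len(tab) < 4:
        return None
    x = class_means(tab.index, open_end_mean)
    y = 100.0 * tab["cases"].to_numpy() / tab["denom"].to_numpy()  # percent scale
    fit = FractionalPolynomial(y, x).fit()
    sm = semimax_age(fit, domain=(20.0, float(x.max())))
    return fit, sm


def run_analysis(
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    refpop: pd.DataFrame | Mapping[int, pd.DataFrame] | None = None,
    years: Sequence[int] | None = None,
    seed: int = 0,
    reference_mode: str = "per_year",
    curve_year: int | None = None,
    district_bins: Sequence[float] | None = None,
    open_end_mean: float = 80.0,
) -> PipelineResult:
    """Run the full analysis on in-memory claims/person tables.

    ``refpop`` may be a single reference table (used for every year), a
    mapping year -> table, or None (each year standardized on its own
    eligible cohort). ``reference_mode='fixed:<year>'`` pins a mapping
    to one year's table, reproducing a fixed-reference sensitivity
    analysis.
    """
    if years is None:
        years = sorted(claims["year"].unique())
    years = [int(y) for y in years]
    curve_year = int(curve_year) if curve_year is not None else years[-1]

    def ref_for(year: int, cohort_frame: pd.DataFrame) -> ReferencePopulation:
        if refpop is None:
            return _self_reference(cohort_frame)
        if isinstance(refpop, Mapping):
            key = year
            if reference_mode.startswith("fixed:"):
                key = int(reference_mode[6:])
            if key not in refpop:
                raise ValueError(f"no reference population table for year {key}")
            return ReferencePopulation.from_frame(refpop[key])
        return ReferencePopulation.from_frame(refpop)

    # --- stage: ascertainment -------------------------------------------
    try:
        yearly: dict[int, pd.DataFrame] = {}
        counts_rows = []
        for year in years:
            profiles = asc.build_profiles(claims, persons, year)
            classified = asc.classify_prevalent_frame(profiles)
            if year - 1 in yearly:
                classified = asc.classify_incident_frame(classified, yearly[year - 1])
            yearly[year] = classified
            n_total = len(classified)
            n_elig = int(classified["eligible"].sum())
            counts_rows.append(
                {
                    "year": year,
                    "n_persons": n_total,
                    "n_fully_enrolled": n_elig,
                    "pct_fully_enrolled": 100.0 * n_elig / n_total if n_total else np.nan,
                    "n_prevalent_t2dm": int(classified["prevalent_t2dm"].sum()),
                    "n_incident_t2dm": int(classified["incident_t2dm"].sum())
                    if "incident_t2dm" in classified
                    else np.nan,
                }
            )
            log.info("ascertainment %s: %s", year, counts_rows[-1])
        counts = pd.DataFrame(counts_rows)
        cases_cols = [
            "person_id", "year", "sex", "district_id", "age", "age_group", "eligible",
            "prevalent_t2dm", "qualifying_rule", "any_diabetes_code",
            "incident_evaluable", "at_risk", "incident_t2dm", *asc.COMORBIDITY_PATTERNS,
        ]
        cases = pd.concat(
            [
                f.reindex(columns=cases_cols)
                for f in yearly.values()
            ],
            ignore_index=True,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("ascertainment", e) from e

    # --- stage: rates & trend -------------------------------------------
    try:
        prev_rows, inc_rows, trend_rows = [], [], []
        trend_counts = []
        for year in years:
            f = yearly[year]
            elig = f[f["eligible"]]
            ref = ref_for(year, elig)
            prev_rows += _standardize_rows(elig, "prevalent_t2dm", ref, year, "percent")
            trend_counts.append(
                (float(elig["prevalent_t2dm"].sum()), float(len(elig)))
            )
            if "at_risk" in f.columns and f["at_risk"].any():
                risk = f[f["at_risk"]]
                inc_rows += _standardize_rows(risk, "incident_t2dm", ref, year, "per_1000")
        if len(years) >= 2:
            tr = cochran_armitage_trend(trend_counts)
            trend_rows.append(
                {
                    "outcome": "prevalence",
                    "years": "-".join(map(str, years)),
                    "z": tr.z,
                    "pvalue": tr.pvalue,
                    "degenerate": tr.degenerate,
                }
            )
        prevalence = pd.DataFrame(prev_rows)
        incidence = pd.DataFrame(inc_rows)
        trend = pd.DataFrame(trend_rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("rates", e) from e

    # --- stage: SPR (standardized comorbidity burden, curve year) --------
    try:
        f = yearly[curve_year]
        elig = f[f["eligible"]]
        ref = ref_for(curve_year, elig)
        spr_rows = []
        for sex in ("all", *SEXES):
            sub = elig if sex == "all" else elig[elig["sex"] == sex]
            with_t2dm = sub[sub["prevalent_t2dm"]]
            without = sub[~sub["prevalent_t2dm"]]
            sref = _sex_restricted(ref, sex)
            # both strata must be standardized on the same weights; restrict
            # the reference to age-sex cells populated in both
            idx1 = _self_reference(with_t2dm).counts.index
            idx0 = _self_reference(without).counts.index
            covered = sref.counts.index.intersection(idx1).intersection(idx0)
            if len(covered) == 0:
                continue
            sref = ReferencePopulation(sref.counts.loc[covered])
            for name in asc.COMORBIDITY_PATTERNS:
                try:
                    e1 = direct_standardize(
                        StratifiedRates.from_flags(with_t2dm, name), sref, scale="percent"
                    )
                    e0 = direct_standardize(
                        StratifiedRates.from_flags(without, name), sref, scale="percent"
                    )
                    spr = compute_spr(e1, e0)
                except ValueError:
                    continue
                spr_rows.append(
                    {
                        "year": curve_year,
                        "sex": sex,
                        "comorbidity": name,
                        "prev_with_t2dm": e1.value,
                        "prev_without_t2dm": e0.value,
                        "spr": spr.spr,
                        "ci_low": spr.ci_low,
                        "ci_high": spr.ci_high,
                    }
                )
        spr_table = pd.DataFrame(spr_rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("spr", e) from e

    # --- stage: case-control --------------------------------------------
    try:
        pairs_frames, unmatched_frames, or_frames = [], [], []
        for year in years:
            f = yearly[year]
            elig = f[f["eligible"]]
            case_f = elig[elig["prevalent_t2dm"]]
            pool = elig[~elig["any_diabetes_code"]]
            pairs, unmatched = cc.match_controls(case_f, pool, year, seed=seed + year)
            if len(pairs) == 0:
                continue
            flags = elig[["person_id", *asc.COMORBIDITY_PATTERNS]]
            ors = cc.comorbidity_or(pairs, flags, tuple(asc.COMORBIDITY_PATTERNS))
            ors.insert(0, "year", year)
            pairs_frames.append(pairs)
            if len(unmatched):
                unmatched_frames.append(unmatched)
            or_frames.append(ors)
        pairs_table = (
            pd.concat(pairs_frames, ignore_index=True) if pairs_frames else pd.DataFrame()
        )
        unmatched_table = (
            pd.concat(unmatched_frames, ignore_index=True) if unmatched_frames else pd.DataFrame()
        )
        or_table = pd.concat(or_frames, ignore_index=True) if or_frames else pd.DataFrame()
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("case_control", e) from e

    # --- stage: comorbidity curves & age shifts --------------------------
    try:
        f = yearly[curve_year]
        elig = f[f["eligible"]]
        curve_rows, shift_rows = [], []
        curve_fits: dict = {}
        for sex in ("all", *SEXES):
            sub = elig if sex == "all" else elig[elig["sex"] == sex]
            for name in asc.COMORBIDITY_PATTERNS:
                fits = {}
                for stratum, mask in (
                    ("with_t2dm", sub["prevalent_t2dm"]),
                    ("without_t2dm", ~sub["prevalent_t2dm"]),
                ):
                    out = _fit_stratum_curve(sub[mask], name, open_end_mean)
                    if out is None:
                        continue
                    fit, sm = out
                    fits[stratum] = (fit, sm)
                    p = list(fit.powers) + [np.nan] * (2 - len(fit.powers))
                    b = list(fit.params) + [np.nan] * (3 - len(fit.params))
                    curve_rows.append(
                        {
                            "comorbidity": name,
                            "sex": sex,
                            "stratum": stratum,
                            "p1": p[0],
                            "p2": p[1],
                            "b0": b[0],
                            "b1": b[1],
                            "b2": b[2],
                            "r_squared": fit.rsquared,
                        }
                    )
                if len(fits) == 2:
                    (fit_w, sm_w), (fit_wo, sm_wo) = fits["with_t2dm"], fits["without_t2dm"]
                    shift = age_shift(sm_w, sm_wo)
                    curve_fits[(name, sex)] = fits
                    shift_rows.append(
                        {
                            "comorbidity": name,
                            "sex": sex,
                            "age_with": sm_w.age_at_semimax if not sm_w.is_nc else "NC",
                            "age_without": sm_wo.age_at_semimax if not sm_wo.is_nc else "NC",
                            "prev_semimax_with": sm_w.prevalence_at_semimax,
                            "prev_semimax_without": sm_wo.prevalence_at_semimax,
                            "shift_years": shift if shift is not None else "NC",
                        }
                    )
        curves_table = pd.DataFrame(curve_rows)
        shifts_table = pd.DataFrame(shift_rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("curves", e) from e

    # --- stage: district rates -------------------------------------------
    try:
        f = yearly[curve_year]
        elig = f[f["eligible"]]
        districts = district_rates(
            elig,
            state_ref=ref_for(curve_year, elig),
            district_refs=None,
            bins=district_bins,
        )
        districts.insert(0, "year", curve_year)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("districts", e) from e

    # --- stage: coding-pattern report ------------------------------------
    try:
        rep = coding_pattern_report(claims, persons, curve_year)
        coding = rep.to_frame()
        coding["rx_only_pct_of_insured"] = rep.rx_only_pct
        coding["n_with_any_code"] = rep.n_with_any_code
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("coding_report", e) from e

    return PipelineResult(
        cases=cases,
        prevalence=prevalence,
        incidence=incidence,
        trend=trend,
        spr=spr_table,
        pairs=pairs_table,
        unmatched=unmatched_table,
        or_results=or_table,
        curves=curves_table,
        shifts=shifts_table,
        districts=districts,
        coding=coding,
        counts=counts,
        curve_fits=curve_fits,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run, write the output bundle."""
    config.validate()
    if config.jsonl_log:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter('{"ts": "%(asctime)s", "stage": "%(name)s", "msg": %(message)r}')
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    claims = pd.read_csv(config.claims_path)
    persons = pd.read_csv(config.persons_path)
    refpop = pd.read_csv(config.refpop_path) if config.refpop_path else None
    result = run_analysis(
        claims,
        persons,
        refpop,
        years=config.years,
        seed=config.seed,
        reference_mode=config.reference_mode,
        curve_year=config.curve_year,
        district_bins=config.district_bins,
        open_end_mean=config.open_end_mean,
    )
    outdir = Path(config.outdir)
    result.write(outdir, seed=config.seed, config_hash=config.hash())
    # echo the configuration for provenance
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return result
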