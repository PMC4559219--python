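"""Direct age-sex standardization, trend testing and prevalence ratios.

Rates are stratified on 5-year age group x sex. Direct standardization
weights each stratum rate p_as by the reference population's stratum
share w_as = N_as / sum(N); the variance treats stratum case counts as
independent binomials:

    p_std  = sum w_as * p_as
    var    = sum w_as^2 * p_as (1 - p_as) / d_as

with a symmetric normal 95 % CI truncated to the admissible range.
Trends over calendar years use the Cochran-Armitage score test; ratios
of two standardized prevalences (with vs without diabetes) get a
log-normal CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95 % normal quantile

_SCALE_FACTOR = {"proportion": 1.0, "percent": 100.0, "per_1000": 1000.0}


@dataclass
class StratifiedRates:
    """Case counts and denominators per (age_group, sex) stratum."""

    frame: pd.DataFrame  # columns: age_group, sex, cases, denom

    def __post_init__(self):
        f = self.frame
        required = {"age_group", "sex", "cases", "denom"}
        if not required <= set(f.columns):
            raise ValueError(f"StratifiedRates frame needs columns {sorted(required)}")
        if (f["cases"] < 0).any() or (f["cases"] > f["denom"]).any():
            raise ValueError("need 0 <= cases <= denom in every stratum")
        dup = f.duplicated(["age_group", "sex"])
        if dup.any():
            raise ValueError("duplicate (age_group, sex) strata")

    @classmethod
    def from_flags(cls, frame: pd.DataFrame, flag_col: str) -> "StratifiedRates":
        """Tabulate a boolean column of a per-person frame by age_group x sex."""
        g = (
            frame.groupby(["age_group", "sex"], observed=True)[flag_col]
            .agg(cases="sum", denom="size")
            .reset_index()
        )
        g["age_group"] = g["age_group"].astype(str)
        return cls(g)

    @property
    def rates(self) -> pd.Series:
        return self.frame["cases"] / self.frame["denom"]


@dataclass
class ReferencePopulation:
    """Reference counts per (age_group, sex); weights are normalized shares."""

    counts: pd.Series  # MultiIndex (age_group, sex) -> count

    def __post_init__(self):
        if (self.counts < 0).any():
            raise ValueError("reference counts must be >= 0")
        if self.counts.sum() <= 0:
            raise ValueError("reference population is empty")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferencePopulation":
        cols = {"age_group_label", "sex", "count"}
        if not cols <= set(frame.columns):
            raise ValueError(f"reference population table needs columns {sorted(cols)}")
        s = frame.set_index(["age_group_label", "sex"])["count"].astype(float)
        s.index = s.index.set_names(["age_group", "sex"])
        return cls(s)

    @classmethod
    def from_csv(cls, path) -> "ReferencePopulation":
        return cls.from_frame(pd.read_csv(path))

    @property
    def weights(self) -> pd.Series:
        return self.counts / self.counts.sum()

    def restrict(self, age_groups: Sequence[str]) -> "ReferencePopulation":
        """Reference restricted to a subset of age groups (e.g. adults only)."""
        sel = self.counts[self.counts.index.get_level_values("age_group").isin(age_groups)]
        return ReferencePopulation(sel)

    def collapse_sex(self) -> "ReferencePopulation":
        s = self.counts.groupby(level="age_group").sum()
        s.index = pd.MultiIndex.from_product([s.index, ["all"]], names=["age_group", "sex"])
        return ReferencePopulation(s)


@dataclass
class StandardizedEstimate:
    """A directly standardized rate with variance and symmetric 95 % CI."""

    estimate: float  # proportion scale
    variance: float  # on the proportion scale
    ci_low: float
    ci_high: float
    scale: str = "proportion"

    @property
    def factor(self) -> float:
        return _SCALE_FACTOR[self.scale]

    @property
    def value(self) -> float:
        """Estimate on the display scale (percent / per 1000 / proportion)."""
        return self.estimate * self.factor

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low * self.factor, self.ci_high * self.factor)


def direct_standardize(
    rates: StratifiedRates,
    ref: ReferencePopulation,
    scale: str = "proportion",
) -> StandardizedEstimate:
    """Directly standardize stratified rates onto a reference population.

    Strata of the reference with zero weight are ignored; a stratum with
    positive reference weight but empty cohort denominator is an error
    (the standardized rate would be undefined there).
    """
    if scale not in _SCALE_FACTOR:
        raise ValueError(f"scale must be one of {sorted(_SCALE_FACTOR)}")
    f = rates.frame.set_index(["age_group", "sex"])
    w = ref.weights
    w = w[w > 0]
    missing = w.index.difference(f.index)
    if len(missing) > 0:
        raise ValueError(f"cohort has no stratum for reference strata {list(missing)}")
    sub = f.loc[w.index]
    if (sub["denom"] <= 0).any():
        bad = sub.index[sub["denom"] <= 0].tolist()
        raise ValueError(f"zero denominator in positively weighted strata {bad}")
    p = (sub["cases"] / sub["denom"]).to_numpy(dtype=float)
    wv = w.to_numpy(dtype=float)
    d = sub["denom"].to_numpy(dtype=float)
    est = float(np.sum(wv * p))
    var = float(np.sum(wv**2 * p * (1.0 - p) / d))
    half = Z95 * np.sqrt(var)
    return StandardizedEstimate(
        estimate=est,
        variance=var,
        ci_low=max(0.0, est - half),
        ci_high=min(1.0, est + half),
        scale=scale,
    )


def crude_rate(rates: StratifiedRates, scale: str = "proportion") -> StandardizedEstimate:
    """Unstandardized (pooled) rate with binomial variance, same container."""
    n = float(rates.frame["cases"].sum())
    d = float(rates.frame["denom"].sum())
    if d <= 0:
        raise ValueError("empty denominator")
    p = n / d
    var = p * (1 - p) / d
    half = Z95 * np.sqrt(var)
    return StandardizedEstimate(p, var, max(0.0, p - half), min(1.0, p + half), scale)


@dataclass
class TrendTestResult:
    z: float
    pvalue: float
    degenerate: bool = False


def cochran_armitage_trend(
    yearly: Sequence[tuple[float, float]], scores: Sequence[float] | None = None
) -> TrendTestResult:
    """Cochran-Armitage test for a linear trend in proportions.

    ``yearly`` is an ordered sequence of (cases, denominator) per group
    (e.g. calendar year); ``scores`` default to 0, 1, 2, ... The
    statistic is

        Z = sum s_i (n_i - d_i pbar) /
            sqrt( pbar (1-pbar) [ sum s_i^2 d_i - (sum s_i d_i)^2 / sum d_i ] )

    with pbar the pooled proportion, referred to the standard normal
    (two-sided p). All-zero or all-full tables are degenerate: Z = 0,
    p = 1, ``degenerate=True``.
    """
    arr = np.asarray(yearly, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need >= 2 (cases, denominator) pairs")
    n, d = arr[:, 0], arr[:, 1]
    if (d <= 0).any() or (n < 0).any() or (n > d).any():
        raise ValueError("need 0 <= cases <= denominator > 0 in every group")
    if scores is None:
        s = np.arange(len(n), dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if len(s) != len(n) or (np.diff(s) <= 0).any():
            raise ValueError("scores must match group count and be strictly increasing")
    pbar = n.sum() / d.sum()
    if pbar in (0.0, 1.0):
        return TrendTestResult(z=0.0, pvalue=1.0, degenerate=True)
    num = float(np.sum(s * (n - d * pbar)))
    den = pbar * (1 - pbar) * (np.sum(s**2 * d) - np.sum(s * d) ** 2 / d.sum())
    if den <= 0:
        return TrendTestResult(z=0.0, pvalue=1.0, degenerate=True)
    z = num / np.sqrt(den)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendTestResult(z=float(z), pvalue=float(p), degenerate=False)


@dataclass
class SPRResult:
    """Standardized prevalence ratio (exposed vs unexposed) with 95 % CI."""

    spr: float
    ci_low: float
    ci_high: float


def compute_spr(
    exposed: StandardizedEstimate, unexposed: StandardizedEstimate
) -> SPRResult:
    """Ratio of two standardized prevalences with a log-normal CI."""
    if unexposed.estimate <= 0:
        raise ValueError("unexposed standardized prevalence must be > 0")
    if exposed.estimate <= 0:
        raise ValueError("exposed standardized prevalence must be > 0")
    spr = exposed.estimate / unexposed.estimate
    se_log = np.sqrt(
        exposed.variance / exposed.estimate**2 + unexposed.variance / unexposed.estimate**2
    )
    return SPRResult(
        spr=float(spr),
        ci_low=float(spr * np.exp(-Z95 * se_log)),
        ci_high=float(spr * np.exp(Z95 * se_log)),
    )


def district_rates(
    case_table: pd.DataFrame,
    state_ref: ReferencePopulation,
    district_refs: dict[str, ReferencePopulation] | None = None,
    flag_col: str = "prevalent_t2dm",
    bins: Sequence[float] | None = None,
    scale: str = "percent",
) -> pd.DataFrame:
    """Per-district standardized rates under two references.

    For each district the flagged rate is standardized (a) on that
    district's own reference population — its burden of disease — and
    (b) on the state-wide reference, which makes districts directly
    comparable irrespective of their age-sex structure. When
    ``district_refs`` is None each district's own age-sex counts serve
    as its reference (self-standardization). ``bins`` (display-scale
    edges) add a prevalence class per estimate for choropleth-style
    grouping.
    """
    rows = []
    for district, sub in case_table.groupby("district_id", sort=True):
        rates = StratifiedRates.from_flags(sub, flag_col)
        if district_refs is None:
            dref = ReferencePopulation(
                rates.frame.set_index(["age_group", "sex"])["denom"].astype(float)
            )
        else:
            if district not in district_refs:
                raise ValueError(f"district {district!r} missing from district reference tables")
            dref = district_refs[district]
        for ref_name, ref in (("district", dref), ("state", state_ref)):
            est = direct_standardize(rates, ref, scale=scale)
            rows.append(
                {
                    "district_id": district,
                    "reference": ref_name,
                    "estimate": est.value,
                    "ci_low": est.ci[0],
                    "ci_high": est.ci[1],
                }
            )
    out = pd.DataFrame(rows)
    if bins is not None:
        out["bin"] = pd.cut(out["estimate"], bins=list(bins)).astype(str)
    return out
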