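"""Fractional-polynomial prevalence curves and the semi-maximum age shift.

The comorbidity-vs-age analysis transforms 5-year age groups to their
class-mean ages, fits prevalence as a fractional polynomial (FP) of age
separately for persons with and without T2DM, and summarises each curve
by the age at which it first reaches half of its maximum over the adult
age domain (the "semi-maximum age", located with Ridders' root finder).
The age shift is the difference of this age between the non-diabetic and
the diabetic stratum, rounded to whole years: how many years earlier the
diabetic population reaches the same relative comorbidity level.

FP conventions (degree <= 2, power set S = {-2, -1, -0.5, 0, 0.5, 1, 2,
3}): the power 0 denotes ln(x); a repeated power p contributes the terms
x^p and x^p * ln(x). Model selection is an exhaustive least-squares
search over all 8 degree-1 and 36 degree-2 power choices, keeping the
minimum-RSS candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Callable, Sequence

import numpy as np

from .agegroups import class_means  # noqa: F401  (re-exported: part of this surface)

#: The fractional-polynomial power set.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp_design(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Design matrix (incl. intercept) for an FP with the given powers."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("fractional polynomials require x > 0")
    lx = np.log(x)
    cols = [np.ones_like(x)]
    prev_p, prev_col = None, None
    for p in powers:
        base = lx if p == 0 else x**p
        col = prev_col * lx if prev_p is not None and p == prev_p else base
        cols.append(col)
        prev_p, prev_col = p, col
    return np.column_stack(cols)


class FractionalPolynomial:
    """Fractional-polynomial regression model of y on x (degree <= 2).

    statsmodels-style: construct from data, call :meth:`fit` to obtain an
    :class:`FPResults`. ``weights`` (e.g. stratum denominators) switch
    the criterion to weighted least squares; the default is unweighted,
    matching a fit to aggregated rates.
    """

    def __init__(
        self,
        y,
        x,
        weights=None,
        max_degree: int = 2,
    ):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.y.shape != self.x.shape or self.y.ndim != 1:
            raise ValueError("y and x must be 1-D arrays of equal length")
        if (self.x <= 0).any():
            raise ValueError("all x must be > 0")
        if (np.diff(self.x) <= 0).any():
            raise ValueError("x must be strictly increasing")
        if max_degree not in (1, 2):
            raise ValueError("max_degree must be 1 or 2")
        self.max_degree = max_degree
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None and (self.weights <= 0).any():
            raise ValueError("weights must be > 0")

    @property
    def candidates(self) -> list[tuple[float, ...]]:
        cands: list[tuple[float, ...]] = [(p,) for p in FP_POWERS]
        if self.max_degree >= 2:
            cands += list(combinations_with_replacement(FP_POWERS, 2))
        return cands

    def _fit_one(self, powers: tuple[float, ...]):
        X = fp_design(self.x, powers)
        if self.weights is not None:
            sw = np.sqrt(self.weights)
            Xw, yw = X * sw[:, None], self.y * sw
        else:
            Xw, yw = X, self.y
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < X.shape[1]:
            return None
        resid = yw - Xw @ beta
        return beta, float(resid @ resid)

    def fit(self) -> "FPResults":
        """Exhaustive search over the FP candidate set; minimum-RSS wins."""
        n_params_max = self.max_degree + 1
        if len(np.unique(self.x)) < n_params_max + 1:
            raise ValueError(
                f"need at least {n_params_max + 1} distinct x values to fit degree "
                f"{self.max_degree} with model selection"
            )
        best = None
        for powers in self.candidates:
            res = self._fit_one(powers)
            if res is None:
                continue
            beta, rss = res
            # strict '<' keeps the earlier (simpler) candidate on exact ties;
            # degree-1 models are enumerated first
            if best is None or rss < best[2]:
                best = (powers, beta, rss)
        if best is None:
            raise ValueError("singular design for every candidate power set")
        powers, beta, rss = best
        if self.weights is not None:
            sw = self.weights
            ybar = np.average(self.y, weights=sw)
            tss = float(np.sum(sw * (self.y - ybar) ** 2))
        else:
            tss = float(np.sum((self.y - np.mean(self.y)) ** 2))
        degenerate = tss <= np.finfo(float).eps * max(1.0, float(np.sum(self.y**2)))
        rsq = 1.0 if degenerate else 1.0 - rss / tss
        return FPResults(
            model=self,
            powers=tuple(powers),
            params=np.asarray(beta),
            rss=rss,
            rsquared=float(min(max(rsq, 0.0), 1.0)) if not degenerate else 1.0,
            degenerate=degenerate,
            domain=(float(self.x.min()), float(self.x.max())),
        )


@dataclass
class FPResults:
    """A fitted fractional-polynomial curve."""

    model: FractionalPolynomial
    powers: tuple[float, ...]
    params: np.ndarray  # (intercept, beta1[, beta2])
    rss: float
    rsquared: float
    degenerate: bool
    domain: tuple[float, float]

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return fp_design(x, self.powers) @ self.params

    def __call__(self, x):
        out = self.predict(x)
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.x)

    def summary(self) -> str:
        lines = [
            "Fractional polynomial fit",
            "=" * 40,
            f"degree:     {len(self.powers)}",
            f"powers:     {self.powers}",
            f"n points:   {len(self.model.x)}",
            f"domain:     [{self.domain[0]:g}, {self.domain[1]:g}] years",
            f"R-squared:  {self.rsquared:.4f}" + ("  (degenerate: flat response)" if self.degenerate else ""),
            "coefficients:",
            f"  intercept  {self.params[0]: .6g}",
        ]
        for i, p in enumerate(self.powers, start=1):
            label = "ln(x)" if p == 0 else f"x^{p:g}"
            if i >= 2 and p == self.powers[i - 2]:
                label += "*ln(x)"
            lines.append(f"  {label:<10} {self.params[i]: .6g}")
        return "\n".join(lines)

    def plot(self, ax=None, n: int = 200, **scatter_kw):
        """Fitted curve over its domain with the fitting points overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(self.domain[0], self.domain[1], n)
        ax.plot(xs, self.predict(xs), label=f"FP{self.powers}")
        ax.scatter(self.model.x, self.model.y, zorder=3, **scatter_kw)
        ax.set_xlabel("age [years]")
        ax.set_ylabel("prevalence")
        return ax


def fit_fp(y, x, weights=None, max_degree: int = 2) -> FPResults:
    """Convenience wrapper: ``FractionalPolynomial(y, x, ...).fit()``."""
    return FractionalPolynomial(y, x, weights=weights, max_degree=max_degree).fit()


# ---------------------------------------------------------------------------
# Ridders' root finder
# ---------------------------------------------------------------------------

def ridders_root(
    f: Callable[[float], float],
    a: float,
    b: float,
    xtol: float = 1e-12,
    ftol: float = 0.0,
    maxiter: int = 100,
) -> float:
    """Root of f on the sign-changing bracket [a, b] by Ridders' method.

    Each iteration evaluates the midpoint m and applies the exponential
    correction to false position,

        x = m + (m - a) * sign(f(a) - f(b)) * f(m) / sqrt(f(m)^2 - f(a) f(b)),

    then re-brackets. Converges when the bracket shrinks below ``xtol``
    or |f| falls to ``ftol``.
    """
    fa, fb = f(a), f(b)
    for v, name in ((fa, "f(a)"), (fb, "f(b)")):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        raise ValueError("f(a) and f(b) must have opposite signs")
    for _ in range(maxiter):
        m = 0.5 * (a + b)
        fm = f(m)
        if not math.isfinite(fm):
            raise ValueError("f evaluated to a non-finite value inside the bracket")
        s = math.sqrt(fm * fm - fa * fb)
        if s == 0.0:
            return m
        x = m + (m - a) * math.copysign(1.0, fa - fb) * fm / s
        fx = f(x)
        if not math.isfinite(fx):
            raise ValueError("f evaluated to a non-finite value inside the bracket")
        if fx == 0.0 or abs(fx) <= ftol:
            return x
        # keep the sign change in the tightest bracket containing x
        if fm * fx < 0:
            a, fa, b, fb = (m, fm, x, fx) if m < x else (x, fx, m, fm)
        elif fa * fx < 0:
            b, fb = x, fx
        else:
            a, fa = x, fx
        if abs(b - a) <= xtol:
            return 0.5 * (a + b)
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# semi-maximum statistic
# ---------------------------------------------------------------------------

@dataclass
class SemiMaxResult:
    """Age at which a fitted prevalence curve first reaches half its maximum.

    ``age_at_semimax`` is None when not calculable (NC) — typically the
    curve already exceeds its semi-maximum at the lower domain edge, so
    the rising-limb crossing lies below the analysis age range.
    """

    age_at_semimax: float | None
    prevalence_at_semimax: float
    curve_max: float
    nc_reason: str | None = None

    @property
    def is_nc(self) -> bool:
        return self.age_at_semimax is None


def semimax_age(
    curve: FPResults,
    domain: tuple[float, float] | None = None,
    grid: int = 2001,
) -> SemiMaxResult:
    """Locate the rising-limb semi-maximum crossing of a fitted curve.

    The curve maximum is taken over the fitted curve on ``domain``
    (default: the fitting domain) via a dense grid scan with local
    ternary refinement; the semi-maximum level is half of it. The
    reported age is the leftmost intersection of curve and level to the
    left of the argmax, solved with :func:`ridders_root`. If the curve
    value at the lower domain edge already exceeds the level, the
    crossing lies below the analysis range: NC.
    """
    lo, hi = domain if domain is not None else curve.domain
    xs = np.linspace(lo, hi, grid)
    ys = curve.predict(xs)
    imax = int(np.argmax(ys))
    # local refinement of the maximum by golden-section on the bracketing cell
    from scipy.optimize import minimize_scalar

    a = xs[max(imax - 1, 0)]
    b = xs[min(imax + 1, grid - 1)]
    if b > a:
        res = minimize_scalar(lambda t: -curve(t), bounds=(a, b), method="bounded")
        x_max, curve_max = float(res.x), float(-res.fun)
        if curve_max < ys[imax]:
            x_max, curve_max = float(xs[imax]), float(ys[imax])
    else:
        x_max, curve_max = float(xs[imax]), float(ys[imax])
    semi = curve_max / 2.0

    if curve(lo) >= semi:
        return SemiMaxResult(
            None,
            semi,
            curve_max,
            nc_reason=f"curve already exceeds its semi-maximum at age {lo:g}",
        )
    rising = xs[: imax + 1]
    vals = ys[: imax + 1] - semi
    crossing = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(crossing) == 0:
        if imax == 0:
            reason = "curve is maximal at the lower domain edge"
        else:
            reason = "no rising-limb crossing of the semi-maximum on the domain"
        return SemiMaxResult(None, semi, curve_max, nc_reason=reason)
    i = int(crossing[0])
    root = ridders_root(lambda t: curve(t) - semi, float(rising[i]), float(rising[i + 1]))
    return SemiMaxResult(float(root), semi, curve_max)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def age_shift(
    with_t2dm: SemiMaxResult, without_t2dm: SemiMaxResult
) -> int | None:
    """Integer age shift: how many years earlier the diabetic stratum
    reaches its semi-maximum. None (NC) when either side is NC."""
    if with_t2dm.is_nc or without_t2dm.is_nc:
        return None
    return _round_half_up(without_t2dm.age_at_semimax - with_t2dm.age_at_semimax)
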