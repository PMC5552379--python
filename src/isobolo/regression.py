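"""Log-dose linear regression, slope test and effective-dose estimation.

The dose-response model is ordinary least squares of %MPE on log10(dose):

    y_i = a + b * x_i + e_i,      x_i = log10(dose_i)

with Q the sum of squared residuals, s^2 = Q/(N-2), and V(b) = s^2/Sxx.
The dose producing a target effect gamma (%MPE) is obtained by inverting
the fitted line, log10(ED_gamma) = (gamma - a)/b, and its log-scale
variance by the delta method:

    V(log ED) = s^2/b^2 * (1/N + (log ED - x_mean)^2 / Sxx)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    UndefinedDoseError,
)
from .io import DoseEffectTable

PAPER_COMPAT = "paper-compat"
STRICT = "strict"

#: Large-sample two-sided 5% critical value used throughout the source tables.
PAPER_T_TABLE = 1.96


def critical_t(alpha: float, df: int, mode: str = STRICT) -> float:
    """Two-sided Student critical value; fixed at 1.96 in paper-compat mode."""
    if mode == PAPER_COMPAT:
        return PAPER_T_TABLE
    if df < 1:
        raise InsufficientDataError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of response (%MPE) on log10(dose in nmol/site)."""

    slope: float            # b, %MPE per log10(nmol)
    intercept: float        # a, %MPE
    s2: float               # residual variance Q/(N-2), %MPE^2
    slope_variance: float   # V(b) = s2/Sxx
    sxx: float              # sum of (x_i - x_mean)^2
    n: int
    x_mean: float
    y_mean: float
    residual_ss: float      # Q
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        assert self.sxx > 0 and self.s2 >= 0 and self.n >= 4

    @property
    def df(self) -> int:
        return self.n - 2

    # sums of the raw summary block, derived from the sufficient statistics
    @property
    def sum_x(self) -> float:
        return self.n * self.x_mean

    @property
    def sum_y(self) -> float:
        return self.n * self.y_mean

    @property
    def sum_x2(self) -> float:
        return self.sxx + self.n * self.x_mean**2

    @property
    def sum_xy(self) -> float:
        return self.slope * self.sxx + self.n * self.x_mean * self.y_mean

    def predict(self, log_dose: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(log_dose, dtype=float)


@dataclass(frozen=True)
class SlopeTest:
    """t-test of the null hypothesis slope == 0."""

    t_slope: float
    t_table: float
    df: int
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class EffectiveDose:
    """An ED_gamma with its log10-scale value and delta-method variance."""

    gamma: float        # target effect, %MPE
    log_ed: float       # log10(nmol/site)
    ed: float           # nmol/site
    variance: float     # log10-scale variance
    df: int             # N - 2 of the underlying fit

    def __post_init__(self) -> None:
        assert self.variance >= 0
        assert math.isclose(self.ed, 10.0**self.log_ed, rel_tol=1e-12)


def fit_log_dose(table: DoseEffectTable) -> RegressionFit:
    """Unweighted least squares of %MPE on log10(dose).

    Raises :class:`DegenerateDesignError` when there is a single dose level
    and :class:`InsufficientDataError` when N < 4.  (Table construction
    already enforces both; this guards tables built by other means.)
    """
    x = table.log_doses
    y = table.responses
    n = table.n
    if n < 4:
        raise InsufficientDataError(f"need N >= 4 records, got {n}")
    x_mean = float(x.mean())
    y_mean = float(y.mean())
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx <= 0.0:
        raise DegenerateDesignError("single dose level: Sxx = 0")
    slope = float(((x - x_mean) * (y - y_mean)).sum() / sxx)
    intercept = y_mean - slope * x_mean
    resid = y - intercept - slope * x
    q = float((resid**2).sum())
    s2 = q / (n - 2)
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        s2=s2,
        slope_variance=s2 / sxx,
        sxx=sxx,
        n=n,
        x_mean=x_mean,
        y_mean=y_mean,
        residual_ss=q,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def slope_test(fit: RegressionFit, alpha: float = 0.05, mode: str = PAPER_COMPAT) -> SlopeTest:
    """Test whether the fitted slope differs from zero.

    ``t_slope = b / sqrt(V(b))`` compared against the two-sided critical
    value at N-2 degrees of freedom (fixed 1.96 in paper-compat mode).
    A perfect fit (V(b) = 0) reports an infinite statistic with a warning.
    """
    if fit.slope_variance == 0.0:
        warnings.warn(
            "V(b) = 0 (perfect fit): slope test degenerate, reporting t = inf",
            stacklevel=2,
        )
        t = math.inf if fit.slope != 0 else 0.0
    else:
        t = fit.slope / math.sqrt(fit.slope_variance)
    t_table = critical_t(alpha, fit.df, mode)
    return SlopeTest(
        t_slope=t,
        t_table=t_table,
        df=fit.df,
        significant=bool(abs(t) > t_table),
        alpha=alpha,
    )


def effective_dose(fit: RegressionFit, gamma: float = 20.0) -> EffectiveDose:
    """Dose producing effect ``gamma`` (%MPE), with log-scale variance.

    Warns when the estimate extrapolates beyond the fitted dose range.
    """
    if fit.slope == 0.0:
        raise UndefinedDoseError("slope is zero: effective dose undefined")
    log_ed = (gamma - fit.intercept) / fit.slope
    if not (fit.x_min <= log_ed <= fit.x_max):
        warnings.warn(
            f"ED_{gamma:g} at log10(dose) = {log_ed:.3f} lies outside the fitted "
            f"range [{fit.x_min:.3f}, {fit.x_max:.3f}] (extrapolation)",
            stacklevel=2,
        )
    variance = (fit.s2 / fit.slope**2) * (1.0 / fit.n + (log_ed - fit.x_mean) ** 2 / fit.sxx)
    return EffectiveDose(
        gamma=gamma,
        log_ed=log_ed,
        ed=10.0**log_ed,
        variance=variance,
        df=fit.df,
    )


def summary_block(
    fit: RegressionFit,
    test: SlopeTest | None = None,
    ed: EffectiveDose | None = None,
    label: str = "",
    dose_unit: str = "nmol/site",
) -> str:
    """Human-readable regression summary mirroring the source table layout."""
    lines = []
    if label:
        lines.append(f"Linear regression summary: {label}")
    else:
        lines.append("Linear regression summary")
    lines += [
        f"  sum_x  = {fit.sum_x:.4f}    sum_y = {fit.sum_y:.4f}    N = {fit.n}",
        f"  x_mean = {fit.x_mean:.4f}    y_mean = {fit.y_mean:.4f}",
        f"  sum_x2 = {fit.sum_x2:.4f}    sum_xy = {fit.sum_xy:.4f}    Sxx = {fit.sxx:.4f}",
        f"  b (slope)     = {fit.slope:.4f} %MPE per log10({dose_unit})",
        f"  a (intercept) = {fit.intercept:.4f} %MPE",
        f"  Q = {fit.residual_ss:.4f}    s2 = {fit.s2:.4f}    V(b) = {fit.slope_variance:.4f}",
    ]
    if test is not None:
        verdict = "differs from zero" if test.significant else "does NOT differ from zero"
        lines.append(
            f"  t_slope = {test.t_slope:.4f} vs t_table({test.df} df, P={test.alpha:g}) "
            f"= {test.t_table:.4f} -> slope {verdict}"
        )
    if ed is not None:
        lines.append(
            f"  DE{ed.gamma:g} = {ed.log_ed:.4f} (log scale) = {ed.ed:.6g} {dose_unit}; "
            f"V_DE{ed.gamma:g} = {ed.variance:.6g} (log scale)"
        )
    return "\n".join(lines)
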