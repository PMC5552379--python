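"""Additivity comparison: theoretical additive ED vs experimental mixture ED.

The theoretical additive mixture ED (Loewe additivity at the fixed ratio) is

    Z_add = f * ED_A + (1 - f) * ED_B          (natural dose scale)
    V(Z_add) = f^2 * V(A) + (1 - f)^2 * V(B)   (log scale, source convention)

and is compared against the experimentally fitted mixture ED Z_mix with a
composite t procedure: the statistic is computed on log10 doses,

    t_critical = (log Z_add - log Z_mix) / sqrt(V(Z_add) + V(Z_mix))

and the critical value is the variance-weighted mean of the two tabular
Student values,

    T_tabulated = (t_add * V(Z_add) + t_mix * V(Z_mix)) / (V(Z_add) + V(Z_mix)).

Note the mixed-scale convention carried over from the design stage: doses are
combined on the natural scale but logged for the statistic, while variances
stay on the log scale throughout.  This reproduces the source arithmetic;
``variance_scale="strict"`` recombines Z_add on the log-consistent scale for
new analyses (see :func:`theoretical_additive`).

The interaction index alpha = Z_mix / Z_add quantifies the departure:
alpha < 1 synergy, alpha = 1 additivity, alpha > 1 sub-additivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError
from .regression import PAPER_COMPAT, EffectiveDose, critical_t

VERDICT_SYNERGY = "synergistic"
VERDICT_ADDITIVE = "additive"
VERDICT_SUBADDITIVE = "sub-additive"


@dataclass(frozen=True)
class AdditivityResult:
    """Outcome of the Z_add vs Z_mix composite t comparison."""

    z_add: float            # nmol/site
    var_z_add: float        # log-scale variance
    z_mix: float            # nmol/site
    var_z_mix: float        # log-scale variance
    t_critical: float       # signed: positive when Z_mix < Z_add
    t_tabulated: float
    df_add: int
    df_mix: int
    significant: bool
    verdict: str
    alpha: float = 0.05

    @property
    def alpha_index(self) -> float:
        """Interaction index Z_mix / Z_add."""
        return self.z_mix / self.z_add


@dataclass(frozen=True)
class IsobologramGeometry:
    """Coordinates for an isobologram in component-dose space (A on x, B on y)."""

    axis_a_intercept: float
    axis_b_intercept: float
    additive_point: tuple[float, float]
    observed_point: tuple[float, float]

    def to_csv(self) -> str:
        rows = [
            ("axis_A", self.axis_a_intercept, 0.0),
            ("axis_B", 0.0, self.axis_b_intercept),
            ("additive", *self.additive_point),
            ("observed", *self.observed_point),
        ]
        return "point,dose_a,dose_b\n" + "\n".join(
            f"{name},{a!r},{b!r}" for name, a, b in rows
        ) + "\n"


def theoretical_additive(
    ed_a: EffectiveDose, ed_b: EffectiveDose, f: float
) -> tuple[float, float]:
    """Theoretical additive mixture ED and its variance.

    Returns ``(z_add, var_z_add)`` with z_add = f*ED_A + (1-f)*ED_B on the
    natural dose scale and var_z_add = f^2*V(A) + (1-f)^2*V(B) on the log
    scale (source convention).
    """
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"proportion factor must lie in [0, 1], got {f!r}")
    if not (ed_a.ed > 0 and ed_b.ed > 0):
        raise ValidationError("EDs must be positive")
    z_add = f * ed_a.ed + (1.0 - f) * ed_b.ed
    var_z_add = f**2 * ed_a.variance + (1.0 - f) ** 2 * ed_b.variance
    return z_add, var_z_add


def composite_t_test(
    z_add: float,
    var_z_add: float,
    df_add: int,
    z_mix: float,
    var_z_mix: float,
    df_mix: int,
    alpha: float = 0.05,
    mode: str = PAPER_COMPAT,
) -> AdditivityResult:
    """Composite t comparison of log Z_add against log Z_mix.

    ``t_critical`` is signed — positive when the mixture is more potent than
    additivity predicts — and significance compares its magnitude against
    the variance-weighted tabular value ``T_tabulated``.  A significant
    result is labelled synergistic when Z_mix < Z_add and sub-additive when
    Z_mix > Z_add.
    """
    if not (z_add > 0 and z_mix > 0):
        raise ValidationError(f"doses must be positive, got {z_add!r}, {z_mix!r}")
    if not (var_z_add > 0 and var_z_mix > 0):
        raise ValidationError(
            f"variances must be strictly positive, got {var_z_add!r}, {var_z_mix!r}"
        )
    x = math.log10(z_add)
    y = math.log10(z_mix)
    pooled = var_z_add + var_z_mix
    t_critical = (x - y) / math.sqrt(pooled)
    t_add = critical_t(alpha, df_add, mode)
    t_mix = critical_t(alpha, df_mix, mode)
    if t_add == t_mix:  # weighted mean of equal values, exactly
        t_tabulated = t_add
    else:
        t_tabulated = (t_add * var_z_add + t_mix * var_z_mix) / pooled
    significant = bool(abs(t_critical) > t_tabulated)
    if not significant:
        verdict = VERDICT_ADDITIVE
    elif z_mix < z_add:
        verdict = VERDICT_SYNERGY
    else:
        verdict = VERDICT_SUBADDITIVE
    return AdditivityResult(
        z_add=z_add,
        var_z_add=var_z_add,
        z_mix=z_mix,
        var_z_mix=var_z_mix,
        t_critical=t_critical,
        t_tabulated=t_tabulated,
        df_add=df_add,
        df_mix=df_mix,
        significant=significant,
        verdict=verdict,
        alpha=alpha,
    )


def interaction_index(z_mix: float, z_add: float) -> float:
    """Interaction index alpha = Z_mix / Z_add (< 1 indicates synergy)."""
    if not (z_mix > 0 and z_add > 0):
        raise ValidationError(f"doses must be positive, got {z_mix!r}, {z_add!r}")
    return z_mix / z_add


def isobologram_coordinates(
    ed_a: float, ed_b: float, f: float, z_add: float, z_mix: float
) -> IsobologramGeometry:
    """Points for the fixed-effect isobologram.

    The additive point splits Z_add into its design components
    (f*ED_A, (1-f)*ED_B); the observed point splits Z_mix in the same fixed
    component ratio, so its coordinates sum to Z_mix.
    """
    for name, v in (("ed_a", ed_a), ("ed_b", ed_b), ("z_add", z_add), ("z_mix", z_mix)):
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v!r}")
    add_a = f * ed_a
    add_b = (1.0 - f) * ed_b
    total = add_a + add_b
    obs_a = z_mix * add_a / total
    obs_b = z_mix * add_b / total
    return IsobologramGeometry(
        axis_a_intercept=ed_a,
        axis_b_intercept=ed_b,
        additive_point=(add_a, add_b),
        observed_point=(obs_a, obs_b),
    )
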