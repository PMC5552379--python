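"""Synthetic dose-effect tables and combination experiments with known truth.

Single-drug responses follow the same model the analysis fits: %MPE linear
in log10(dose) with additive homoscedastic Gaussian noise (no clipping —
real tables contain values below 0 and above 100).  A combination
experiment is generated by running the actual design pipeline on simulated
single-drug data and then placing the mixture ED at ``alpha_true`` times
the true additive ED, so the full analysis chain can be checked for
parameter recovery, type-I error and power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import MixtureDesign, component_doses, dose_ladder, proportion_factor
from .exceptions import ValidationError
from .io import DoseEffectTable
from .regression import effective_dose, fit_log_dose, slope_test

logger = logging.getLogger(__name__)

_MAX_REGEN_ATTEMPTS = 10


@dataclass(frozen=True)
class SimSpec:
    """Generative truth for one single-drug dose-effect table."""

    intercept: float                 # a_true, %MPE
    slope: float                     # b_true, %MPE per log10(nmol)
    sigma: float                     # residual s.d., %MPE
    dose_levels: tuple[float, ...]   # nmol/site
    n_per_dose: tuple[int, ...]      # group sizes, one per dose level
    seed: int = 0
    regimen: str = "simulated"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_levels", tuple(float(d) for d in self.dose_levels))
        n = self.n_per_dose
        if isinstance(n, int):
            n = (n,) * len(self.dose_levels)
        object.__setattr__(self, "n_per_dose", tuple(int(k) for k in n))
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma!r}")
        if any(d <= 0 for d in self.dose_levels):
            raise ValidationError("all dose levels must be positive")
        if len(self.n_per_dose) != len(self.dose_levels):
            raise ValidationError("n_per_dose must match dose_levels in length")
        if any(k < 1 for k in self.n_per_dose):
            raise ValidationError("all group sizes must be >= 1")


@dataclass(frozen=True)
class ComboSimSpec:
    """Generative truth for a full fixed-ratio combination experiment.

    ``alpha_true`` is the generative interaction index: the mixture's true
    ED at effect ``gamma`` equals ``alpha_true * Z_add(truth)`` where
    Z_add(truth) combines the single drugs' TRUE effective doses with the
    proportion factor obtained from the simulated experiment's fits.
    """

    spec_a: SimSpec
    spec_b: SimSpec
    alpha_true: float = 1.0
    slope_mix: float = 20.0
    sigma_mix: float = 20.0
    n_per_dose_mix: int = 12
    n_pairs: int = 6
    step: float = 3.0
    gamma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_true > 0:
            raise ValidationError(f"alpha_true must be > 0, got {self.alpha_true!r}")
        if self.slope_mix == 0:
            raise ValidationError("slope_mix must be nonzero")


@dataclass(frozen=True)
class CombinationSim:
    """A simulated combination experiment plus its generative truth."""

    table_a: DoseEffectTable
    table_b: DoseEffectTable
    table_mix: DoseEffectTable
    design: MixtureDesign
    z_add_true: float      # additive ED built from the TRUE single-drug EDs
    ed_mix_true: float     # alpha_true * z_add_true
    attempts: int          # single-drug regenerations consumed


def simulate_single(spec: SimSpec, rng: np.random.Generator | None = None) -> DoseEffectTable:
    """Draw one dose-effect table from the linear log-dose model.

    All randomness flows from ``spec.seed`` unless an explicit generator is
    supplied (used by :func:`simulate_combination` to keep a single stream).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    doses = np.repeat(spec.dose_levels, spec.n_per_dose)
    mean = spec.intercept + spec.slope * np.log10(doses)
    y = mean + rng.normal(0.0, spec.sigma, size=doses.size)
    return DoseEffectTable.from_arrays(spec.regimen, doses, y)


def _true_ed(spec: SimSpec, gamma: float) -> float:
    return 10.0 ** ((gamma - spec.intercept) / spec.slope)


def simulate_combination(spec: ComboSimSpec) -> CombinationSim:
    """Simulate single-drug tables, derive the fixed-ratio design from their
    fits, and generate the mixture table with interaction index
    ``spec.alpha_true``.

    Single-drug draws whose fitted slope is not significant are regenerated
    (logged, capped at 10 attempts) — a flat fitted curve makes the design
    stage meaningless, mirroring how a real experiment would be redesigned.
    """
    rng = np.random.default_rng(spec.seed)
    gamma = spec.gamma

    for attempt in range(1, _MAX_REGEN_ATTEMPTS + 1):
        table_a = simulate_single(spec.spec_a, rng=rng)
        table_b = simulate_single(spec.spec_b, rng=rng)
        fit_a, fit_b = fit_log_dose(table_a), fit_log_dose(table_b)
        if slope_test(fit_a).significant and slope_test(fit_b).significant:
            break
        logger.info("attempt %d: non-significant single-drug slope, regenerating", attempt)
    else:
        raise ValidationError(
            f"no significant single-drug slopes after {_MAX_REGEN_ATTEMPTS} attempts; "
            "the spec's slope/noise combination is too weak"
        )

    ed_a = effective_dose(fit_a, gamma)
    ed_b = effective_dose(fit_b, gamma)
    if ed_a.variance > 0 and ed_b.variance > 0:
        f = proportion_factor(ed_a.variance, ed_b.variance)
    else:
        f = 0.5  # noiseless draws: both variances vanish, split evenly
    design = component_doses(ed_a.ed, ed_b.ed, f, var_a=ed_a.variance, var_b=ed_b.variance)

    z_add_true = f * _true_ed(spec.spec_a, gamma) + (1.0 - f) * _true_ed(spec.spec_b, gamma)
    ed_mix_true = spec.alpha_true * z_add_true

    ladder = dose_ladder(design, n_pairs=spec.n_pairs, step=spec.step)
    totals = np.repeat(ladder.totals, spec.n_per_dose_mix)
    mean = gamma + spec.slope_mix * (np.log10(totals) - np.log10(ed_mix_true))
    y = mean + rng.normal(0.0, spec.sigma_mix, size=totals.size)
    table_mix = DoseEffectTable.from_arrays("simulated mixture", totals, y)

    return CombinationSim(
        table_a=table_a,
        table_b=table_b,
        table_mix=table_mix,
        design=design,
        z_add_true=z_add_true,
        ed_mix_true=ed_mix_true,
        attempts=attempt,
    )


def table1_like_spec(seed: int = 0) -> SimSpec:
    """A SimSpec matching the scale of the bundled SB366791 table
    (a=20.9, b=16.3, residual s.d. ~25.6 %MPE, unequal group sizes)."""
    return SimSpec(
        intercept=20.9,
        slope=16.3,
        sigma=25.6,
        dose_levels=(0.1, 0.4, 1.0, 2.0, 6.0),
        n_per_dose=(14, 11, 16, 10, 9),
        seed=seed,
        regimen="simulated drug A",
    )
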