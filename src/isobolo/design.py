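"""Fixed-ratio mixture design: proportion factor and geometric dose ladder.

The share of each drug in the mixture is fixed by a variance-weighted
proportion factor computed from the two single-drug ED estimates:

    f = V(B) / (V(A) + V(B))

so the less precisely estimated drug contributes the smaller share.  The
design point puts ``a = f * ED_A`` of drug A and ``b = (1 - f) * ED_B`` of
drug B in the mixture (total ``c = a + b``), and the experiment doses a
geometric ladder of pairs around that point at the constant ratio a : b.

Note the deliberate mixed-scale convention: f is computed from LOG-scale ED
variances (the only variances the upstream regression produces) but applied
to NATURAL-scale EDs.  That is the convention of the source analysis and the
default here; ``scale="strict"`` instead converts the variances to the
natural dose scale (delta method) before weighting, for use beyond
reproduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError
from .regression import EffectiveDose

PAPER_SCALE = "paper"
STRICT_SCALE = "strict"


@dataclass(frozen=True)
class MixtureDesign:
    """Proportion factor and component doses of a fixed-ratio drug pair."""

    f: float                     # proportion factor in (0, 1)
    ed_a: float                  # ED of drug A alone, nmol/site
    ed_b: float                  # ED of drug B alone, nmol/site
    component_a: float           # a = f * ED_A, nmol/site
    component_b: float           # b = (1 - f) * ED_B, nmol/site
    var_a: float | None = None   # log-scale ED variances, when known
    var_b: float | None = None

    @property
    def total(self) -> float:
        """Composed pair dose c = a + b."""
        return self.component_a + self.component_b

    @property
    def ratio(self) -> float:
        """Constant component ratio a : b held along the ladder."""
        return self.component_a / self.component_b


@dataclass(frozen=True)
class DoseLadder:
    """Geometric series of (dose_A, dose_B, total) triples at a fixed ratio."""

    pairs: tuple[tuple[float, float, float], ...]
    step: float

    @property
    def totals(self) -> tuple[float, ...]:
        return tuple(p[2] for p in self.pairs)

    def to_csv(self) -> str:
        lines = ["pair,dose_a,dose_b,total"]
        for i, (da, db, tot) in enumerate(self.pairs, start=1):
            lines.append(f"{i},{da!r},{db!r},{tot!r}")
        return "\n".join(lines) + "\n"


def proportion_factor(var_a: float, var_b: float) -> float:
    """Variance-weighted proportion factor f = V(B) / (V(A) + V(B))."""
    if not (var_a > 0 and var_b > 0):
        raise ValidationError(
            f"variances must be strictly positive, got V(A)={var_a!r}, V(B)={var_b!r}"
        )
    return var_b / (var_a + var_b)


def component_doses(
    ed_a: float,
    ed_b: float,
    f: float,
    var_a: float | None = None,
    var_b: float | None = None,
) -> MixtureDesign:
    """Component doses a = f*ED_A, b = (1-f)*ED_B of the fixed-ratio design.

    ``f`` may sit at the boundaries {0, 1} for degenerate single-drug
    'mixtures'; strictly interior values are required for a usable ladder.
    """
    if not (ed_a > 0 and ed_b > 0):
        raise ValidationError(f"EDs must be positive, got {ed_a!r}, {ed_b!r}")
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"proportion factor must lie in [0, 1], got {f!r}")
    return MixtureDesign(
        f=f,
        ed_a=ed_a,
        ed_b=ed_b,
        component_a=f * ed_a,
        component_b=(1.0 - f) * ed_b,
        var_a=var_a,
        var_b=var_b,
    )


def design_mixture(
    ed_a: EffectiveDose, ed_b: EffectiveDose, scale: str = PAPER_SCALE
) -> MixtureDesign:
    """Build the fixed-ratio design from two single-drug ED estimates.

    ``scale="paper"`` weights by the log-scale ED variances directly;
    ``scale="strict"`` first maps them to the natural dose scale via the
    delta method, V_nat = (ln10 * ED)^2 * V_log.
    """
    if scale == PAPER_SCALE:
        va, vb = ed_a.variance, ed_b.variance
    elif scale == STRICT_SCALE:
        va = (math.log(10.0) * ed_a.ed) ** 2 * ed_a.variance
        vb = (math.log(10.0) * ed_b.ed) ** 2 * ed_b.variance
    else:
        raise ValidationError(f"unknown scale mode {scale!r}")
    f = proportion_factor(va, vb)
    return component_doses(ed_a.ed, ed_b.ed, f, var_a=ed_a.variance, var_b=ed_b.variance)


def dose_ladder(
    design: MixtureDesign,
    n_pairs: int = 6,
    step: float = 3.0,
    anchor: int | None = None,
) -> DoseLadder:
    """Geometric dose ladder around the design point.

    Pair ``anchor`` (1-based; default the 4th of 6, i.e. two steps up and
    three down) is exactly the design point; pair i scales both components
    by ``step ** (i - anchor)``, so the component ratio is constant and the
    totals form an exact geometric series.
    """
    if n_pairs < 2:
        raise ValidationError(f"need at least 2 pairs, got {n_pairs}")
    if not step > 1.0:
        raise ValidationError(f"step must exceed 1, got {step!r}")
    if not (design.component_a > 0 and design.component_b > 0):
        raise ValidationError("design point must have strictly positive components")
    if anchor is None:
        anchor = min(4, n_pairs)
    if not (1 <= anchor <= n_pairs):
        raise ValidationError(f"anchor must lie in [1, {n_pairs}], got {anchor}")
    pairs = []
    for i in range(1, n_pairs + 1):
        scale = step ** (i - anchor)
        da = design.component_a * scale
        db = design.component_b * scale
        pairs.append((da, db, da + db))
    return DoseLadder(pairs=tuple(pairs), step=step)
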