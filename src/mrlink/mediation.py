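"""Two-step MR mediation: product of coefficients, delta method, Sobel.

With ``beta_c`` the total exposure→outcome effect, ``beta_a`` the
exposure→mediator effect and ``beta_b`` the mediator→outcome effect —
each estimated by IVW on its own non-overlapping two-sample dataset —
the indirect (mediated) effect is ``beta_a * beta_b`` with first-order
delta-method SE ``sqrt(beta_a² se_b² + beta_b² se_a²)``, which is also
the Sobel test denominator.  The proportion mediated is
``beta_a * beta_b / beta_c`` (reported in percent); when the total
effect is itself not significant the proportion is suppressed (NA) while
the indirect effect is still reported, since a mediated path can exist
without a detectable total effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from mrlink.estimators import MREstimate, Z95

__all__ = [
    "MediationResult",
    "indirect_effect",
    "sobel_test",
    "proportion_mediated",
    "two_step_pipeline",
]


def indirect_effect(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    second_order: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Product-of-coefficients indirect effect with delta-method CI.

    Returns ``(indirect, se, (ci_low, ci_high))``.  The default SE is
    the first-order delta method, matching the Sobel denominator;
    ``second_order=True`` adds the ``se_a² se_b²`` term.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be > 0")
    ind = beta_a * beta_b
    var = beta_a**2 * se_b**2 + beta_b**2 * se_a**2
    if second_order:
        var += se_a**2 * se_b**2
    se = sqrt(var)
    return ind, se, (ind - Z95 * se, ind + Z95 * se)


def sobel_test(beta_a: float, se_a: float, beta_b: float, se_b: float) -> tuple[float, float]:
    """Sobel z-test of the indirect effect; returns ``(z, two-sided p)``."""
    ind, se, _ = indirect_effect(beta_a, se_a, beta_b, se_b)
    if se == 0.0:
        return 0.0, 1.0
    z = ind / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def proportion_mediated(
    indirect: float,
    indirect_se: float,
    beta_c: float,
    se_c: float,
) -> tuple[float, tuple[float, float]]:
    """Proportion of the total effect carried by the mediator, in percent.

    ``proportion = indirect / beta_c``; its delta-method SE for a ratio
    of independent estimates is
    ``|proportion| sqrt(indirect_se²/indirect² + se_c²/beta_c²)``.
    Returns ``(percent, (ci_low_pct, ci_high_pct))``.
    """
    if beta_c == 0.0:
        raise ZeroDivisionError("proportion undefined for a zero total effect")
    prop = indirect / beta_c
    # |prop| * sqrt(se_ind²/ind² + se_c²/c²), written to stay defined at ind = 0
    se_prop = sqrt(indirect_se**2 / beta_c**2 + indirect**2 * se_c**2 / beta_c**4)
    lo, hi = prop - Z95 * se_prop, prop + Z95 * se_prop
    return 100.0 * prop, (100.0 * lo, 100.0 * hi)


@dataclass
class MediationResult:
    """One exposure–mediator–outcome mediation analysis (a table row)."""

    exposure: str
    mediator: str
    outcome: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    beta_c: float
    se_c: float
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    sobel_z: float
    sobel_pval: float
    proportion_pct: float | None
    proportion_ci: tuple[float, float] | None
    total_significant: bool

    def as_row(self) -> dict:
        na = float("nan")
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "total_beta": self.beta_c,
            "total_ci_low": self.beta_c - Z95 * self.se_c,
            "total_ci_high": self.beta_c + Z95 * self.se_c,
            "beta_a": self.beta_a,
            "a_ci_low": self.beta_a - Z95 * self.se_a,
            "a_ci_high": self.beta_a + Z95 * self.se_a,
            "beta_b": self.beta_b,
            "b_ci_low": self.beta_b - Z95 * self.se_b,
            "b_ci_high": self.beta_b + Z95 * self.se_b,
            "indirect": self.indirect,
            "indirect_ci_low": self.indirect_ci[0],
            "indirect_ci_high": self.indirect_ci[1],
            "sobel_p": self.sobel_pval,
            "proportion_pct": na if self.proportion_pct is None else self.proportion_pct,
            "proportion_ci_low": na if self.proportion_ci is None else self.proportion_ci[0],
            "proportion_ci_high": na if self.proportion_ci is None else self.proportion_ci[1],
        }


def two_step_pipeline(
    total: MREstimate,
    exposure_on_mediator: MREstimate,
    mediator_on_outcome: MREstimate,
    mediator: str | None = None,
    total_alpha: float = 0.05,
) -> MediationResult:
    """Assemble a mediation result from the three IVW estimates.

    ``total`` is the exposure→outcome estimate (beta_c),
    ``exposure_on_mediator`` beta_a, ``mediator_on_outcome`` beta_b.
    The proportion mediated is reported only when the total effect is
    significant at ``total_alpha``; otherwise it is NA and the indirect
    effect stands alone.
    """
    for name, est in (
        ("total", total),
        ("exposure_on_mediator", exposure_on_mediator),
        ("mediator_on_outcome", mediator_on_outcome),
    ):
        if est is None:
            raise ValueError(f"missing step estimate: {name}")
    a, b, c = exposure_on_mediator, mediator_on_outcome, total
    ind, ind_se, ind_ci = indirect_effect(a.beta, a.se, b.beta, b.se)
    z, sobel_p = sobel_test(a.beta, a.se, b.beta, b.se)
    significant = c.pval < total_alpha
    if significant and c.beta != 0.0:
        prop, prop_ci = proportion_mediated(ind, ind_se, c.beta, c.se)
    else:
        prop, prop_ci = None, None
    return MediationResult(
        exposure=total.exposure,
        mediator=mediator or exposure_on_mediator.outcome,
        outcome=total.outcome,
        beta_a=a.beta,
        se_a=a.se,
        beta_b=b.beta,
        se_b=b.se,
        beta_c=c.beta,
        se_c=c.se,
        indirect=ind,
        indirect_se=ind_se,
        indirect_ci=ind_ci,
        sobel_z=z,
        sobel_pval=sobel_p,
        proportion_pct=prop,
        proportion_ci=prop_ci,
        total_significant=significant,
    )
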