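"""Causal-effect estimators for summary-level MR.

All estimators operate on a :class:`~mrlink.harmonize.HarmonizedDataset`
with exposure effects ``gamma_j`` (SE ``se_gamma_j``) and outcome effects
``Gamma_j`` (SE ``se_Gamma_j``):

* **Wald ratio** — per-SNP estimate ``Gamma_j / gamma_j``.
* **IVW** — inverse-variance-weighted mean of the Wald ratios,
  equivalently weighted regression of ``Gamma`` on ``gamma`` through the
  origin with weights ``1/se_Gamma²``.  The fixed-effect SE assumes all
  instruments are valid; the multiplicative-random-effects (MRE) variant
  inflates the SE by ``sqrt(max(1, Q/(k-1)))``; ``mode="auto"`` switches
  to MRE when the Cochran-Q heterogeneity p-value falls below 0.05.
* **MR-Egger** — weighted regression with an intercept; the slope is the
  causal estimate under the InSIDE assumption and the intercept measures
  directional pleiotropy.
* **Weighted median** — the 50% weighted quantile of the Wald ratios,
  consistent when valid instruments carry a majority of the weight; its
  SE comes from a seeded parametric bootstrap.

95% confidence intervals use the 1.96 normal quantile and p-values the
two-sided normal tail throughout (a t reference for Egger is available
via ``pval_reference="t"`` for cross-checking against other tools).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from mrlink.harmonize import HarmonizedDataset

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_ratio",
    "Z95",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with its uncertainty."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    exposure: str = "exposure"
    outcome: str = "outcome"
    qval: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    def as_row(self) -> dict:
        or_, lo, hi = to_odds_ratio(self)
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "OR": or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "p": self.pval,
            "q": self.qval if self.qval is not None else np.nan,
        }


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    # floor against underflow at extreme z so p stays in (0, 1]
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), 1e-300))


def _labels(data: HarmonizedDataset) -> dict:
    return {"exposure": data.exposure_name, "outcome": data.outcome_name}


def wald_ratio(
    gamma: float,
    se_gamma: float,
    Gamma: float,
    se_Gamma: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate ``Gamma/gamma``.

    The default SE is first order, ``|se_Gamma / gamma|``; with
    ``second_order=True`` the exposure uncertainty is propagated too:
    ``sqrt(se_Gamma²/gamma² + Gamma² se_gamma²/gamma⁴)``.
    """
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = abs(se_Gamma / gamma)
    if second_order:
        se = float(np.sqrt(se_Gamma**2 / gamma**2 + Gamma**2 * se_gamma**2 / gamma**4))
    return MREstimate("Wald", float(beta), float(se), _normal_p(beta, se), 1)


def _ivw_core(gamma: np.ndarray, Gamma: np.ndarray, se_Gamma: np.ndarray):
    w = 1.0 / se_Gamma**2
    denom = np.sum(w * gamma**2)
    beta = np.sum(w * gamma * Gamma) / denom
    se_fixed = np.sqrt(1.0 / denom)
    q = float(np.sum(w * (Gamma - beta * gamma) ** 2))
    return float(beta), float(se_fixed), q


def ivw(data: HarmonizedDataset, mode: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate over all instruments.

    ``mode``: ``"fixed"``, ``"mre"`` (multiplicative random effects), or
    ``"auto"`` — MRE when the Cochran-Q p-value is below 0.05, fixed
    otherwise.  Fixed and MRE share the same point estimate; MRE only
    inflates the SE (never below the fixed SE).  A single SNP degenerates
    to the Wald ratio.
    """
    if data.n_snp == 0:
        raise ValueError("IVW needs at least one SNP")
    if mode not in ("fixed", "mre", "auto"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    beta, se_fixed, q = _ivw_core(data.gamma, data.Gamma, data.se_Gamma)
    k = data.n_snp
    if k == 1:
        est = wald_ratio(data.gamma[0], data.se_gamma[0], data.Gamma[0], data.se_Gamma[0])
        return replace(est, method="IVW-fixed", **_labels(data))
    q_pval = float(stats.chi2.sf(q, k - 1))
    inflation = float(np.sqrt(max(1.0, q / (k - 1))))
    if mode == "fixed":
        use_mre = False
    elif mode == "mre":
        use_mre = True
    else:
        use_mre = q_pval < 0.05
    se = se_fixed * inflation if use_mre else se_fixed
    method = "IVW-MRE" if use_mre else "IVW-fixed"
    return MREstimate(method, beta, se, _normal_p(beta, se), k, **_labels(data))


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """WLS via normal equations; returns (coef, unscaled covariance, rss)."""
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ y)
    rss = float(np.sum(w * (y - X @ coef) ** 2))
    return coef, cov, rss


def egger(
    data: HarmonizedDataset, pval_reference: str = "normal"
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope, intercept) estimates.

    Each SNP is oriented so its exposure effect is non-negative (both
    ``gamma`` and ``Gamma`` negated where ``gamma < 0``), then ``Gamma``
    is regressed on ``gamma`` with an intercept, weights ``1/se_Gamma²``.
    SEs are inflated by ``max(1, sqrt(RSS/(k-2)))`` (multiplicative
    random effects, clamped against underdispersion).
    """
    k = data.n_snp
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    if pval_reference not in ("normal", "t"):
        raise ValueError(f"unknown pval_reference {pval_reference!r}")
    sign = np.where(data.gamma < 0, -1.0, 1.0)
    g = data.gamma * sign
    G = data.Gamma * sign
    X = np.column_stack([np.ones(k), g])
    coef, cov, rss = _weighted_lstsq(X, G, 1.0 / data.se_Gamma**2)
    scale = max(1.0, np.sqrt(rss / (k - 2)))
    se0, se1 = np.sqrt(np.diag(cov)) * scale

    def _p(b, s):
        if pval_reference == "t":
            return float(2.0 * stats.t.sf(abs(b) / s, k - 2))
        return _normal_p(b, s)

    slope = MREstimate(
        "Egger-slope", float(coef[1]), float(se1), _p(coef[1], se1), k, **_labels(data)
    )
    intercept = MREstimate(
        "Egger-intercept", float(coef[0]), float(se0), _p(coef[0], se0), k, **_labels(data)
    )
    return slope, intercept


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = 0
) -> MREstimate:
    """Weighted-median causal estimate with bootstrap SE.

    Wald ratios are sorted ascending with normalized IVW weights
    ``w_j = gamma_j²/se_Gamma_j²``; the estimate interpolates the ratio
    whose centred cumulative weight ``s_j = sum_{i<=j} w_i - w_j/2``
    crosses 0.5.  The SE is the SD of the estimate over ``n_boot``
    parametric-bootstrap resamples (Gaussian perturbation of both
    ``gamma`` and ``Gamma``), generated from ``seed``.
    """
    if data.n_snp < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    beta = _weighted_median_point(
        data.gamma, data.Gamma, data.gamma**2 / data.se_Gamma**2
    )
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        g = rng.normal(data.gamma, data.se_gamma)
        G = rng.normal(data.Gamma, data.se_Gamma)
        boots[b] = _weighted_median_point(g, G, g**2 / data.se_Gamma**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        "WeightedMedian", float(beta), se, _normal_p(beta, se), data.n_snp, **_labels(data)
    )


def _weighted_median_point(gamma, Gamma, weights) -> float:
    ratios = Gamma / gamma
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, CI low, CI high)."""
    return (
        float(np.exp(est.beta)),
        float(np.exp(est.ci_low)),
        float(np.exp(est.ci_high)),
    )
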