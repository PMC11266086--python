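"""Heterogeneity, pleiotropy and outlier diagnostics for one MR analysis.

* **Cochran's Q** — weighted dispersion of the per-SNP Wald ratios
  around the IVW estimate; large Q signals heterogeneity, in which case
  the multiplicative-random-effects IVW is the appropriate headline
  model.
* **Egger intercept test** — a nonzero intercept indicates directional
  horizontal pleiotropy.
* **MR-PRESSO** — a parametric-resampling residual-sum-of-squares test:
  a global heterogeneity p-value, per-SNP outlier p-values
  (Bonferroni-adjusted within the dataset), and a distortion test
  comparing the IVW estimate before and after outlier removal against
  random outlier sets of the same size.
* **Outlier-removal loop** — while the Egger intercept is significant
  (p < 0.05), run MR-PRESSO, drop flagged outliers, and repeat, so the
  retained instruments show no detectable directional pleiotropy.
* **Leave-one-out** — the IVW estimate recomputed omitting each SNP in
  turn, to expose single-variant leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrlink.estimators import MREstimate, egger, ivw, _ivw_core
from mrlink.harmonize import HarmonizedDataset

__all__ = [
    "PressoResult",
    "RemovalLog",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "remove_outliers_until_clean",
    "leave_one_out",
    "sensitivity_report",
]


def cochran_q(
    data: HarmonizedDataset, beta_ivw: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test; returns ``(Q, df, p)``.

    ``Q = sum w_j (ratio_j - beta_ivw)²`` with IVW weights
    ``w_j = gamma_j²/se_Gamma_j²``; p from chi-square with k-1 df.
    Identically ``sum (Gamma_j - beta gamma_j)²/se_Gamma_j²``.
    """
    if data.n_snp < 2:
        raise ValueError("Cochran Q needs at least 2 SNPs")
    if beta_ivw is None:
        beta_ivw, _, _ = _ivw_core(data.gamma, data.Gamma, data.se_Gamma)
    w = data.gamma**2 / data.se_Gamma**2
    ratios = data.Gamma / data.gamma
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = data.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(data: HarmonizedDataset) -> tuple[float, float, float]:
    """Directional-pleiotropy test: ``(intercept, se, two-sided p)``."""
    _, intercept = egger(data)
    return intercept.beta, intercept.se, intercept.pval


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_observed: float
    global_pval: float
    outlier_pvals: np.ndarray = field(repr=False)  # Bonferroni-adjusted
    outlier_indices: np.ndarray
    distortion_pval: float
    n_simulations: int
    seed: int | None


def _loo_residual_terms(
    gamma: np.ndarray, Gamma: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Per-SNP terms ``w_j (Gamma_j - beta(-j) gamma_j)²``.

    ``beta(-j)`` is the IVW estimate with SNP j left out.  ``Gamma`` may
    be a matrix (n_sim, k); terms are returned with the same shape.
    """
    gw = gamma * w
    s1 = Gamma @ gw if Gamma.ndim == 2 else np.sum(Gamma * gw)
    s2 = np.sum(gamma**2 * w)
    num = (s1[..., None] if Gamma.ndim == 2 else s1) - Gamma * gw
    beta_loo = num / (s2 - gamma**2 * w)
    return w * (Gamma - beta_loo * gamma) ** 2


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = 0,
) -> PressoResult:
    """MR-PRESSO residual-sum-of-squares outlier detection.

    The observed global statistic is the leave-one-out weighted RSS
    ``sum_j (Gamma_j - beta(-j) gamma_j)² / se_Gamma_j²``; its null
    distribution is built by redrawing ``Gamma_j* ~ N(beta(-j) gamma_j,
    se_Gamma_j²)`` ``n_sim`` times and recomputing the statistic.
    Empirical p-values use the (r+1)/(n+1) estimator so they are never
    zero.  Per-SNP outlier p-values compare each SNP's observed residual
    term with its simulated terms and are Bonferroni-adjusted within the
    dataset; SNPs below ``outlier_alpha`` are flagged.  The distortion
    p-value compares the outlier-removal shift of the IVW estimate with
    shifts from random pseudo-outlier sets of the same size.
    """
    k = data.n_snp
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    w = 1.0 / data.se_Gamma**2
    gamma, Gamma = data.gamma, data.Gamma

    obs_terms = _loo_residual_terms(gamma, Gamma, w)
    rss_obs = float(np.sum(obs_terms))

    # expected outcome effects under each SNP's leave-one-out fit
    gw = gamma * w
    s1 = np.sum(Gamma * gw)
    s2 = np.sum(gamma**2 * w)
    beta_loo = (s1 - Gamma * gw) / (s2 - gamma**2 * w)
    mu = beta_loo * gamma

    Gamma_sim = rng.normal(mu, data.se_Gamma, size=(n_sim, k))
    sim_terms = _loo_residual_terms(gamma, Gamma_sim, w)
    rss_sim = np.sum(sim_terms, axis=1)

    global_pval = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    raw = (np.sum(sim_terms >= obs_terms[None, :], axis=0) + 1.0) / (n_sim + 1.0)
    adj = np.minimum(1.0, raw * k)
    outliers = np.flatnonzero(adj < outlier_alpha)

    distortion_pval = float("nan")
    if 0 < len(outliers) < k - 1:
        beta_all, _, _ = _ivw_core(gamma, Gamma, data.se_Gamma)
        keep = np.setdiff1d(np.arange(k), outliers)
        beta_clean, _, _ = _ivw_core(gamma[keep], Gamma[keep], data.se_Gamma[keep])
        d_obs = abs(beta_clean - beta_all)
        n_out = len(outliers)
        d_null = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            keep_b = np.setdiff1d(np.arange(k), drop)
            beta_b, _, _ = _ivw_core(gamma[keep_b], Gamma[keep_b], data.se_Gamma[keep_b])
            d_null[b] = abs(beta_b - beta_all)
        distortion_pval = float((np.sum(d_null >= d_obs) + 1.0) / (n_sim + 1.0))

    return PressoResult(
        global_rss_observed=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=adj,
        outlier_indices=outliers,
        distortion_pval=distortion_pval,
        n_simulations=n_sim,
        seed=seed,
    )


@dataclass
class RemovalLog:
    """Round-by-round record of the intercept-triggered PRESSO loop."""

    rounds: list[dict] = field(default_factory=list)
    status: str = "clean"  # clean | max-rounds | too-few-snps | no-outliers-flagged
    removed_ids: list[str] = field(default_factory=list)


def remove_outliers_until_clean(
    data: HarmonizedDataset,
    max_rounds: int = 5,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    intercept_alpha: float = 0.05,
    seed: int | None = 0,
) -> tuple[HarmonizedDataset, RemovalLog]:
    """Iterate MR-PRESSO outlier removal until no directional pleiotropy.

    While the Egger intercept p-value is below ``intercept_alpha``, run
    MR-PRESSO, drop flagged outliers, and repeat; stop when the
    intercept is non-significant, nothing is flagged, the dataset would
    shrink below the 4-SNP minimum, or ``max_rounds`` is reached.
    """
    log = RemovalLog()
    current = data
    for round_no in range(1, max_rounds + 1):
        if current.n_snp < 4:
            log.status = "too-few-snps"
            return current, log
        _, _, p_int = egger_intercept_test(current)
        if p_int >= intercept_alpha:
            log.status = "clean"
            return current, log
        presso = mr_presso(current, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
        flagged = presso.outlier_indices
        log.rounds.append(
            {
                "round": round_no,
                "intercept_pval": p_int,
                "presso_global_pval": presso.global_pval,
                "n_flagged": len(flagged),
                "removed": list(current.variant_ids[flagged]),
                "n_before": current.n_snp,
                "n_after": current.n_snp - len(flagged),
            }
        )
        if len(flagged) == 0:
            log.status = "no-outliers-flagged"
            return current, log
        log.removed_ids.extend(current.variant_ids[flagged])
        current = current.drop(flagged)
    log.status = "max-rounds"
    return current, log


def leave_one_out(data: HarmonizedDataset, mode: str = "auto") -> pd.DataFrame:
    """IVW estimates omitting one SNP at a time.

    Returns one row per omitted variant (columns: SNP, beta, se, ci_low,
    ci_high, p) — the text twin of a leave-one-out forest plot.
    """
    if data.n_snp < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    rows = []
    for j in range(data.n_snp):
        est = ivw(data.drop([j]), mode=mode)
        rows.append(
            {
                "SNP": data.variant_ids[j],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.pval,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """All diagnostics for one harmonized analysis."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    intercept_se: float
    intercept_pval: float
    presso: PressoResult | None
    loo: pd.DataFrame = field(repr=False)
    mre_recommended: bool = False


def sensitivity_report(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = 0,
    run_presso: bool = True,
) -> SensitivityReport:
    """Assemble Q, Egger-intercept, MR-PRESSO and leave-one-out results."""
    q, df, q_p = cochran_q(data)
    intercept, int_se, int_p = egger_intercept_test(data)
    presso = (
        mr_presso(data, n_sim=n_sim, seed=seed) if run_presso and data.n_snp >= 4 else None
    )
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept=intercept,
        intercept_se=int_se,
        intercept_pval=int_p,
        presso=presso,
        loo=leave_one_out(data),
        mre_recommended=q_p < 0.05,
    )
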