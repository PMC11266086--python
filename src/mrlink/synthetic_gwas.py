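"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the post-clumping world of a summary-level MR
study: mutually independent biallelic instruments, standardized traits
(so a per-SNP standard error is ``1/sqrt(2 p (1-p) n)``), additive
per-allele effects, and two non-overlapping samples per exposure–outcome
pair.  The causal structure is a mediation triangle

    X --theta--> Y,   X --beta_a--> M --beta_b--> Y,

so the total X->Y effect is ``theta + beta_a * beta_b``.  Directional
pleiotropy (a mean shift in direct SNP->Y effects) and large-effect
outlier SNPs can be injected to exercise the Egger intercept and
MR-PRESSO diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from mrlink.gwas_io import SummaryStatsTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MediationTriplet",
    "simulate_two_sample",
    "simulate_mediation_triplet",
    "block_ld_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic GWAS study.

    Defaults mirror a large European biobank-scale design: ~300
    independent instruments explaining ~10% of the variance of a
    continuous exposure measured in ~435k samples, a binary outcome GWAS
    of ~396k samples, and a mediator GWAS of ~681k samples.  The default
    effect sizes (``theta`` = 0.042, ``beta_a`` = 0.04, ``beta_b`` =
    0.663) give a total effect of 0.0685 on the log-odds scale, the
    magnitude typical of circulating-biomarker -> complex-disease
    analyses.

    Attributes
    ----------
    n_snps:
        Number of independent instruments for the exposure.
    n_exposure, n_outcome, n_mediator:
        GWAS sample sizes for the exposure, outcome and mediator studies.
    theta:
        True direct causal effect of exposure on outcome.
    beta_a, beta_b:
        True exposure->mediator and mediator->outcome effects.
    pleiotropy_mean, pleiotropy_sd:
        Mean and SD of direct SNP->outcome (pleiotropic) effects; both 0
        disables pleiotropy.
    n_outliers, outlier_effect:
        Number of SNPs whose pleiotropic effect is replaced by the fixed
        value ``outlier_effect``.
    maf_range:
        Uniform sampling interval for minor-allele frequencies.
    exposure_h2:
        Total exposure variance explained by the instruments.
    mediator_h2:
        Variance of the mediator explained by its own instrument set
        (used by :func:`simulate_mediation_triplet`).
    seed:
        Single global seed; every draw flows from one generator stream.
    """

    n_snps: int = 300
    n_exposure: int = 435_516
    n_outcome: int = 396_054
    n_mediator: int = 681_275
    theta: float = 0.042
    beta_a: float = 0.04
    beta_b: float = 0.663
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_effect: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.10
    mediator_h2: float = 0.048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("n_exposure", "n_outcome", "n_mediator"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if not 0.0 < self.exposure_h2 < 1.0:
            raise ValueError("exposure_h2 must lie in (0, 1)")
        if not 0.0 < self.mediator_h2 < 1.0:
            raise ValueError("mediator_h2 must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if self.n_outliers > self.n_snps:
            raise ValueError("n_outliers cannot exceed n_snps")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")

    @property
    def total_effect(self) -> float:
        """Direct plus mediated effect: ``theta + beta_a * beta_b``."""
        return self.theta + self.beta_a * self.beta_b


@dataclass
class SimulationTruth:
    """Ground truth underlying one simulated analysis."""

    theta: float
    beta_a: float
    beta_b: float
    total_effect: float
    maf: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)  # true SNP->exposure effects
    alpha: np.ndarray = field(repr=False)  # true direct SNP->outcome effects
    outlier_indices: np.ndarray = field(repr=False)


class MediationTriplet(NamedTuple):
    """Three pairwise two-sample datasets sharing one causal triangle."""

    xy: tuple[SummaryStatsTable, SummaryStatsTable]
    xm: tuple[SummaryStatsTable, SummaryStatsTable]
    my: tuple[SummaryStatsTable, SummaryStatsTable]
    truth: SimulationTruth


def _scaled_effects(rng: np.random.Generator, maf: np.ndarray, h2: float) -> np.ndarray:
    """True per-allele effects on a standardized trait explaining ``h2``.

    Raw effects are standard normal, then rescaled so the exact explained
    variance ``sum(2 p (1-p) beta^2)`` equals ``h2``.
    """
    raw = rng.standard_normal(maf.size)
    var = np.sum(2.0 * maf * (1.0 - maf) * raw**2)
    if var <= 0.0:
        raise ValueError("cannot allocate heritability over zero-variance effects")
    return raw * np.sqrt(h2 / var)


def _observe(
    rng: np.random.Generator, true_beta: np.ndarray, maf: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampling-noise draw of observed (beta, se, p) for one GWAS sample."""
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = rng.normal(true_beta, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return beta, se, pval


def _table(
    trait: str,
    ids: list[str],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pval: np.ndarray,
    n: int,
) -> SummaryStatsTable:
    # non-palindromic A/G pairs: harmonization is exercised separately
    df = pd.DataFrame(
        {
            "SNP": ids,
            "EA": "A",
            "OA": "G",
            "EAF": maf,
            "BETA": beta,
            "SE": se,
            "P": pval,
            "N": n,
        }
    )
    return SummaryStatsTable(trait, df)


def _draw_truth(rng: np.random.Generator, config: SimulationConfig) -> SimulationTruth:
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, config.n_snps)
    gamma = _scaled_effects(rng, maf, config.exposure_h2)
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, config.n_snps)
    if config.pleiotropy_sd == 0.0:
        alpha = np.full(config.n_snps, config.pleiotropy_mean)
    if config.n_outliers:
        outliers = rng.choice(config.n_snps, size=config.n_outliers, replace=False)
        alpha[outliers] = config.outlier_effect
    else:
        outliers = np.empty(0, dtype=int)
    return SimulationTruth(
        theta=config.theta,
        beta_a=config.beta_a,
        beta_b=config.beta_b,
        total_effect=config.total_effect,
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        outlier_indices=np.sort(outliers),
    )


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SimulationTruth]:
    """One exposure GWAS and one outcome GWAS over the same instruments.

    The true outcome association of SNP *j* is
    ``total_effect * gamma_j + alpha_j`` where ``alpha_j`` is its
    pleiotropic effect.  Observed effects add Gaussian sampling noise
    with ``se = 1/sqrt(2 p (1-p) n)`` for the respective sample size.
    Identical configs (including seed) give bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(rng, config)
    ids = [f"rs{j + 1}" for j in range(config.n_snps)]
    Gamma_true = config.total_effect * truth.gamma + truth.alpha
    bx, sx, px = _observe(rng, truth.gamma, truth.maf, config.n_exposure)
    by, sy, py = _observe(rng, Gamma_true, truth.maf, config.n_outcome)
    exposure = _table("exposure", ids, truth.maf, bx, sx, px, config.n_exposure)
    outcome = _table("outcome", ids, truth.maf, by, sy, py, config.n_outcome)
    return exposure, outcome, truth


def simulate_mediation_triplet(config: SimulationConfig) -> MediationTriplet:
    """Three two-sample datasets for two-step MR: X→Y, X→M and M→Y.

    The X→Y and X→M pairs share the same true SNP→X effects but carry
    independent sampling noise (non-overlapping samples).  The M→Y pair
    uses a separate instrument set for the mediator (variance explained
    ``mediator_h2``) whose true outcome effects are ``beta_b`` times the
    SNP→M effects.  Pleiotropy and outliers, if configured, act on the
    X→Y pair only.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(rng, config)
    x_ids = [f"rs{j + 1}" for j in range(config.n_snps)]

    Gamma_true = config.total_effect * truth.gamma + truth.alpha
    # X -> Y pair
    bx, sx, px = _observe(rng, truth.gamma, truth.maf, config.n_exposure)
    by, sy, py = _observe(rng, Gamma_true, truth.maf, config.n_outcome)
    xy = (
        _table("exposure", x_ids, truth.maf, bx, sx, px, config.n_exposure),
        _table("outcome", x_ids, truth.maf, by, sy, py, config.n_outcome),
    )
    # X -> M pair: fresh exposure sample, mediator effects beta_a * gamma
    bx2, sx2, px2 = _observe(rng, truth.gamma, truth.maf, config.n_exposure)
    bm, sm, pm = _observe(rng, config.beta_a * truth.gamma, truth.maf, config.n_mediator)
    xm = (
        _table("exposure", x_ids, truth.maf, bx2, sx2, px2, config.n_exposure),
        _table("mediator", x_ids, truth.maf, bm, sm, pm, config.n_mediator),
    )
    # M -> Y pair: the mediator's own instruments
    m_maf = rng.uniform(*config.maf_range, config.n_snps)
    delta = _scaled_effects(rng, m_maf, config.mediator_h2)
    m_ids = [f"rs9{j + 1:06d}" for j in range(config.n_snps)]
    bm2, sm2, pm2 = _observe(rng, delta, m_maf, config.n_mediator)
    by2, sy2, py2 = _observe(rng, config.beta_b * delta, m_maf, config.n_outcome)
    my = (
        _table("mediator", m_ids, m_maf, bm2, sm2, pm2, config.n_mediator),
        _table("outcome", m_ids, m_maf, by2, sy2, py2, config.n_outcome),
    )
    return MediationTriplet(xy=xy, xm=xm, my=my, truth=truth)


def block_ld_matrix(
    variant_ids: list[str], block_size: int, r2_within: float
) -> pd.DataFrame:
    """Block-diagonal pairwise r² matrix for exercising LD clumping.

    Variants are grouped into consecutive blocks of ``block_size``; every
    pair within a block has r² ``r2_within``, pairs across blocks 0, the
    diagonal 1.
    """
    k = len(variant_ids)
    blocks = np.arange(k) // block_size
    mat = np.where(blocks[:, None] == blocks[None, :], r2_within, 0.0)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=variant_ids, columns=variant_ids)
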