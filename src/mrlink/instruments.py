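"""Instrument selection: p-value thresholding, LD clumping, strength.

Selection follows the conventional genome-wide pipeline: keep variants
associated with the exposure at P <= 5e-8; if fewer than ``min_ivs``
survive, relax once to P <= 5e-6; if still short, the instrument set is
flagged unusable (a state, not an exception).  Retained variants are
greedily clumped to pairwise r² < 0.001 within a 10,000 kb window so
instruments are approximately independent.  Instrument strength is the
F-statistic ``F = r² (N - k - 1) / ((1 - r²) k)`` with r² the fraction of
exposure variance explained; sets with F >= 10 are considered strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrlink.gwas_io import SummaryStatsTable

__all__ = [
    "InstrumentSet",
    "select_by_pvalue",
    "clump",
    "f_statistic",
    "per_snp_strength",
    "explained_variance",
]

P_PRIMARY = 5e-8
P_FALLBACK = 5e-6
MIN_IVS = 3
R2_MAX = 0.001
WINDOW_KB = 10_000
F_STRONG = 10.0


class LDError(KeyError):
    """A required pairwise LD entry is missing."""


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with strength diagnostics."""

    table: SummaryStatsTable
    p_threshold_used: float
    usable: bool

    @property
    def records(self) -> pd.DataFrame:
        return self.table.records

    @property
    def n_snps(self) -> int:
        return len(self.table.records)

    @property
    def r2_explained(self) -> float:
        """Total exposure variance explained, ``sum 2 p (1-p) beta²``."""
        return explained_variance(self.records)

    @property
    def f_per_snp(self) -> np.ndarray:
        return per_snp_strength(self.records)

    @property
    def f_aggregate(self) -> float:
        """Aggregate F over the set, using the set's median sample size."""
        if self.n_snps == 0:
            return float("nan")
        n = float(self.records["N"].median())
        return f_statistic(self.r2_explained, n, self.n_snps)

    @property
    def strong(self) -> bool:
        """Whether the set passes the conventional F >= 10 bar."""
        return self.n_snps > 0 and self.f_aggregate >= F_STRONG


def explained_variance(records: pd.DataFrame) -> float:
    """Variance of a standardized exposure explained by the records."""
    p = records["EAF"].to_numpy(float)
    beta = records["BETA"].to_numpy(float)
    return float(np.sum(2.0 * p * (1.0 - p) * beta**2))


def select_by_pvalue(
    table: SummaryStatsTable,
    primary: float = P_PRIMARY,
    fallback: float = P_FALLBACK,
    min_ivs: int = MIN_IVS,
) -> InstrumentSet:
    """Threshold on association p-values with a one-step relaxation.

    Variants with ``p <= primary`` are selected; if fewer than
    ``min_ivs`` survive, selection is redone at ``fallback`` and the
    threshold actually used is recorded.  A set still smaller than
    ``min_ivs`` is returned flagged ``usable=False``.
    """
    if table.n_snps == 0:
        raise ValueError("cannot select instruments from an empty table")
    pvals = table.records["P"]
    keep = table.records.loc[pvals <= primary]
    threshold = primary
    if len(keep) < min_ivs:
        keep = table.records.loc[pvals <= fallback]
        threshold = fallback
    sub = SummaryStatsTable(table.trait_name, keep.reset_index(drop=True))
    return InstrumentSet(sub, p_threshold_used=threshold, usable=len(keep) >= min_ivs)


def _pair_r2(ld: pd.DataFrame, a: str, b: str) -> float:
    try:
        return float(ld.at[a, b])
    except KeyError as exc:
        raise LDError(f"LD r² missing for pair ({a}, {b})") from exc


def clump(
    instruments: InstrumentSet,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    r2_max: float = R2_MAX,
    window_kb: float = WINDOW_KB,
) -> InstrumentSet:
    """Greedy LD clumping of an instrument set.

    Candidates are visited by ascending p-value (ties broken by variant
    ID, so the result does not depend on input row order); a variant is
    accepted iff its r² with every already-accepted variant lying within
    ``window_kb`` on the same chromosome is below ``r2_max``.

    Parameters
    ----------
    ld
        Square r² DataFrame indexed by variant ID.  ``None`` means the
        instruments are already independent (identity LD).
    positions
        DataFrame with columns ``SNP``/``chrom``/``pos`` (bp).  Without
        positions every pair is treated as within the window; variants on
        different chromosomes are always outside it.
    """
    records = instruments.records
    if ld is None or records.empty:
        return InstrumentSet(instruments.table, instruments.p_threshold_used, instruments.usable)
    missing = [v for v in records["SNP"] if v not in ld.index or v not in ld.columns]
    if missing:
        raise LDError(f"LD matrix does not cover variant(s): {', '.join(missing)}")
    pos: dict[str, tuple[object, float]] = {}
    if positions is not None:
        pos = {
            str(r.SNP): (r.chrom, float(r.pos)) for r in positions.itertuples(index=False)
        }

    order = records.sort_values(["P", "SNP"], kind="mergesort")
    accepted: list[str] = []
    window_bp = window_kb * 1_000.0
    for row in order.itertuples(index=False):
        vid = str(row.SNP)
        ok = True
        for kept in accepted:
            if pos:
                ca, pa = pos[vid]
                cb, pb = pos[kept]
                if ca != cb or abs(pa - pb) > window_bp:
                    continue  # outside the clumping window
            if _pair_r2(ld, vid, kept) >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(vid)
    kept_df = (
        records.set_index("SNP").loc[accepted].reset_index()[records.columns]
    )
    sub = SummaryStatsTable(instruments.table.trait_name, kept_df)
    return InstrumentSet(
        sub,
        p_threshold_used=instruments.p_threshold_used,
        usable=len(kept_df) >= MIN_IVS,
    )


def f_statistic(r2: float, n: float, k: int) -> float:
    """Aggregate instrument-strength F: ``r² (n - k - 1) / ((1 - r²) k)``.

    ``r2`` is the fraction of exposure variance explained by the ``k``
    instruments in a sample of size ``n``.
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return r2 * (n - k - 1) / ((1.0 - r2) * k)


def per_snp_strength(records: pd.DataFrame) -> np.ndarray:
    """Per-SNP instrument strength ``(beta/se)²`` (single-SNP chi-square).

    For one SNP this approximates ``f_statistic(r2_j, n, 1)`` with
    ``r2_j = t²/(t² + n - 2)`` at large n.
    """
    beta = records["BETA"].to_numpy(float)
    se = records["SE"].to_numpy(float)
    return (beta / se) ** 2
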