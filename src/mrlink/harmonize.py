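"""Allele harmonization of exposure and outcome summary records.

Two GWAS may report the same variant on different effect alleles or on
opposite strands.  Harmonization aligns every shared variant to the
exposure's effect allele:

* alleles identical → keep as is;
* alleles swapped → negate the outcome beta and reflect its EAF;
* alleles match after strand complement (with or without a swap) →
  complement, then apply the swap rule;
* palindromic variants (A/T or C/G) are strand-ambiguous: orientation is
  inferred by comparing which side of 0.5 the effect-allele frequency
  falls on in the two studies, and the variant is dropped whenever either
  frequency is too close to 0.5 to call (the "action = 2" convention);
* any other allele combination is dropped as incompatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrlink.gwas_io import SummaryStatsTable
from mrlink.instruments import InstrumentSet

__all__ = ["HarmonizedDataset", "harmonize", "AMBIGUITY_WINDOW"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: EAF interval within which a palindromic SNP's strand cannot be called
AMBIGUITY_WINDOW = (0.42, 0.58)

KEPT = "kept"
FLIPPED = "flipped"
STRAND_FLIPPED = "strand-flipped"
STRAND_AND_FLIPPED = "strand-flipped+flipped"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_INCOMPATIBLE = "dropped-incompatible"

_KEEP_FLAGS = (KEPT, FLIPPED, STRAND_FLIPPED, STRAND_AND_FLIPPED)


@dataclass
class HarmonizedDataset:
    """Aligned per-SNP effect pairs ready for MR estimation.

    Arrays are parallel over kept SNPs: ``gamma``/``se_gamma`` are the
    exposure effects, ``Gamma``/``se_Gamma`` the outcome effects on the
    exposure's effect allele.  ``log`` records one row per shared variant
    with its provenance flag.
    """

    variant_ids: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    log: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.variant_ids.shape:
                raise ValueError("harmonized arrays must be parallel")
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValueError("standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def drop(self, indices) -> "HarmonizedDataset":
        """A copy with the given SNP indices removed."""
        mask = np.ones(self.n_snp, dtype=bool)
        mask[np.asarray(indices, dtype=int)] = False
        return HarmonizedDataset(
            self.variant_ids[mask],
            self.gamma[mask],
            self.se_gamma[mask],
            self.Gamma[mask],
            self.se_Gamma[mask],
            self.exposure_name,
            self.outcome_name,
            self.log,
        )

    def subset(self, mask: np.ndarray) -> "HarmonizedDataset":
        return HarmonizedDataset(
            self.variant_ids[mask],
            self.gamma[mask],
            self.se_gamma[mask],
            self.Gamma[mask],
            self.se_Gamma[mask],
            self.exposure_name,
            self.outcome_name,
            self.log,
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def _classify(
    ea_x: str,
    oa_x: str,
    ea_y: str,
    oa_y: str,
    eaf_x: float | None,
    eaf_y: float | None,
    window: tuple[float, float],
) -> tuple[str, bool]:
    """Return (flag, flip_outcome_sign) for one shared variant."""
    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return DROPPED_INCOMPATIBLE, False
        if eaf_x is None or eaf_y is None:
            return DROPPED_PALINDROMIC, False
        lo, hi = window
        if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
            return DROPPED_PALINDROMIC, False
        # same minor-allele sidedness => same strand orientation
        same_side = (eaf_x < 0.5) == ((eaf_y if ea_y == ea_x else 1.0 - eaf_y) < 0.5)
        if ea_y == ea_x:
            return (KEPT, False) if same_side else (FLIPPED, True)
        # reported on the swapped allele: reflect, then the same logic
        return (FLIPPED, True) if same_side else (KEPT, False)
    if (ea_y, oa_y) == (ea_x, oa_x):
        return KEPT, False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return FLIPPED, True
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return STRAND_FLIPPED, False
    if (cea, coa) == (oa_x, ea_x):
        return STRAND_AND_FLIPPED, True
    return DROPPED_INCOMPATIBLE, False


def harmonize(
    exposure: InstrumentSet | SummaryStatsTable,
    outcome: SummaryStatsTable,
    ambiguity_window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> HarmonizedDataset:
    """Align exposure and outcome records on the exposure effect allele.

    Returns a :class:`HarmonizedDataset` over the kept SNPs; every shared
    variant appears in the ``log`` with its flag (kept / flipped /
    strand-flipped / dropped-palindromic / dropped-incompatible), so
    kept + dropped always equals the shared-variant count.
    """
    exp_table = exposure.table if isinstance(exposure, InstrumentSet) else exposure
    exp = exp_table.records.set_index("SNP")
    out = outcome.records.set_index("SNP")
    shared = [v for v in exp.index if v in out.index]

    rows = []
    for vid in shared:
        ex, oy = exp.loc[vid], out.loc[vid]
        eaf_x = float(ex["EAF"]) if np.isfinite(ex["EAF"]) else None
        eaf_y = float(oy["EAF"]) if np.isfinite(oy["EAF"]) else None
        flag, flip = _classify(
            ex["EA"], ex["OA"], oy["EA"], oy["OA"], eaf_x, eaf_y, ambiguity_window
        )
        Gamma = -float(oy["BETA"]) if flip else float(oy["BETA"])
        rows.append(
            {
                "SNP": vid,
                "flag": flag,
                "gamma": float(ex["BETA"]),
                "se_gamma": float(ex["SE"]),
                "Gamma": Gamma,
                "se_Gamma": float(oy["SE"]),
                "eaf_exposure": eaf_x,
                "eaf_outcome": (1.0 - eaf_y) if (flip and eaf_y is not None) else eaf_y,
            }
        )
    log = pd.DataFrame(
        rows,
        columns=[
            "SNP", "flag", "gamma", "se_gamma", "Gamma", "se_Gamma",
            "eaf_exposure", "eaf_outcome",
        ],
    )
    kept = log[log["flag"].isin(_KEEP_FLAGS)] if len(log) else log
    return HarmonizedDataset(
        variant_ids=kept["SNP"].to_numpy(object) if len(log) else np.empty(0, object),
        gamma=kept["gamma"].to_numpy(float) if len(log) else np.empty(0),
        se_gamma=kept["se_gamma"].to_numpy(float) if len(log) else np.empty(0),
        Gamma=kept["Gamma"].to_numpy(float) if len(log) else np.empty(0),
        se_Gamma=kept["se_Gamma"].to_numpy(float) if len(log) else np.empty(0),
        exposure_name=exp_table.trait_name,
        outcome_name=outcome.trait_name,
        log=log,
    )
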