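"""Reading, validating and writing GWAS summary statistics.

The canonical on-disk dialect is a tab-separated table with a header row
and the columns ``SNP EA OA EAF BETA SE P N``: variant identifier, effect
allele, other allele, effect-allele frequency, per-allele effect (log-odds
for binary traits, SD units for continuous traits), its standard error,
two-sided p-value, and sample size.  Other exports (IEU OpenGWAS,
musculoskeletal-portal dumps, ...) are adapted at the edge through a
column-name mapping, so the rest of the package only ever sees one schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
_NUMERIC = ["EAF", "BETA", "SE", "P", "N"]
_VALID_ALLELES = frozenset("ACGT")

#: relative tolerance for the p-value vs |beta/se| consistency warning;
#: generous because published p-values are rounded to few digits
_PVAL_RTOL = 0.5


class FormatError(ValueError):
    """A summary-statistics file does not conform to the dialect."""


class ValidationError(ValueError):
    """A summary-statistics table violates a record invariant."""


@dataclass
class SummaryStatsTable:
    """Per-SNP association records for one trait in one GWAS sample.

    ``records`` is a DataFrame with the canonical columns; row order is
    preserved from the source.  Variant IDs are unique within a table.
    """

    trait_name: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.records = validate_records(self.records)

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatsTable":
        """Rows for the given variants, keeping this table's row order."""
        keep = self.records["SNP"].isin(set(variant_ids))
        return SummaryStatsTable(self.trait_name, self.records.loc[keep].reset_index(drop=True))


def validate_records(df: pd.DataFrame, *, check_pvals: bool = True) -> pd.DataFrame:
    """Validate and normalise a canonical-column DataFrame.

    Enforces: unique variant IDs, A/C/G/T alleles (uppercased, indels
    rejected), effect allele != other allele, se > 0, 0 < eaf < 1,
    0 < p <= 1, n > 0.  A p-value inconsistent with ``2*Phi(-|beta/se|)``
    raises only a warning (published tables are rounded).
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    df = df[CANONICAL_COLUMNS].copy()
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = int(np.flatnonzero(bad)[0]) + 1 if bad.any() else "?"
            raise FormatError(f"non-numeric value in column {col}, row {row}") from exc
    df["SNP"] = df["SNP"].astype(str)
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()

    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValidationError(f"duplicate variant ID: {df['SNP'][dup].iloc[0]}")
    for col in ("EA", "OA"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(
                f"invalid {col} allele {df[col].iloc[row - 1]!r} in row {row} "
                "(only biallelic SNPs with A/C/G/T alleles are supported)"
            )
    same = df["EA"] == df["OA"]
    if same.any():
        row = int(np.flatnonzero(same)[0]) + 1
        raise ValidationError(f"effect and other allele identical in row {row}")

    checks = [
        ("SE", df["SE"] <= 0, "se must be > 0"),
        ("EAF", (df["EAF"] <= 0) | (df["EAF"] >= 1), "eaf must lie in (0, 1)"),
        ("P", (df["P"] <= 0) | (df["P"] > 1), "p-value must lie in (0, 1]"),
        ("N", df["N"] <= 0, "sample size must be > 0"),
    ]
    for _, bad, msg in checks:
        bad = bad | df[_NUMERIC].isna().any(axis=1)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(f"{msg} (row {row})")

    if check_pvals:
        z = np.abs(df["BETA"].to_numpy() / df["SE"].to_numpy())
        expected = 2.0 * stats.norm.sf(z)
        p = df["P"].to_numpy()
        # only meaningful where the normal p is not astronomically small
        mask = expected > 1e-300
        off = mask & ~np.isclose(p, expected, rtol=_PVAL_RTOL, atol=1e-4)
        if off.any():
            row = int(np.flatnonzero(off)[0]) + 1
            warnings.warn(
                f"p-value in row {row} ({p[row - 1]:.3g}) disagrees with the normal "
                f"two-sided tail of beta/se ({expected[row - 1]:.3g})",
                stacklevel=2,
            )
    return df.reset_index(drop=True)


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        File to read (header row required).
    dialect
        Mapping from canonical column names to the file's column names,
        e.g. ``{"SNP": "rsid", "BETA": "b"}``.  Canonical names missing
        from the mapping are looked up verbatim; extra file columns are
        ignored.
    trait_name
        Label for the trait; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    mapping = {canon: (dialect or {}).get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {', '.join(missing)} "
            f"(present: {', '.join(raw.columns)})"
        )
    df = raw[[mapping[c] for c in CANONICAL_COLUMNS]]
    df.columns = CANONICAL_COLUMNS
    return SummaryStatsTable(trait_name or path.stem, df)


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table in the canonical TSV dialect."""
    table.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


RESULT_COLUMNS = [
    "exposure", "outcome", "method", "nsnp",
    "beta", "se", "OR", "ci_low", "ci_high", "or_ci_low", "or_ci_high", "p", "q",
]

MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome",
    "total_beta", "total_ci_low", "total_ci_high",
    "beta_a", "a_ci_low", "a_ci_high",
    "beta_b", "b_ci_low", "b_ci_high",
    "indirect", "indirect_ci_low", "indirect_ci_high", "sobel_p",
    "proportion_pct", "proportion_ci_low", "proportion_ci_high",
]


def write_results_table(results: Sequence, path: str | Path, *, mixed: str = "error") -> None:
    """Write MR estimates and/or mediation results as TSV.

    All results must be of one kind (``MREstimate`` rows or
    ``MediationResult`` rows).  With ``mixed="sections"`` a heterogeneous
    collection is written as two blank-line-separated sections, estimates
    first; with the default ``mixed="error"`` it raises.

    Round-trip fidelity is 6 significant digits (the write format).
    """
    from mrlink.estimators import MREstimate
    from mrlink.mediation import MediationResult

    results = list(results)
    if not results:
        raise ValueError("cannot write an empty results collection")
    ests = [r for r in results if isinstance(r, MREstimate)]
    meds = [r for r in results if isinstance(r, MediationResult)]
    if len(ests) + len(meds) != len(results):
        raise TypeError("results must be MREstimate or MediationResult instances")
    if ests and meds and mixed != "sections":
        raise ValueError(
            "mixed MREstimate/MediationResult collections need mixed='sections'"
        )
    frames = []
    if ests:
        frames.append(pd.DataFrame([e.as_row() for e in ests], columns=RESULT_COLUMNS))
    if meds:
        frames.append(pd.DataFrame([m.as_row() for m in meds], columns=MEDIATION_COLUMNS))
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            if i:
                fh.write("\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a single-section results TSV as a DataFrame."""
    return pd.read_csv(path, sep="\t")
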