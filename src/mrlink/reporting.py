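"""Pipeline orchestration, FDR correction and result-table emission.

The full design is a four-step bidirectional + two-step analysis over an
exposure X, outcome Y and mediator M:

    step1  X -> Y   (total effect, beta_c)
    step2  Y -> X   (reverse direction)
    step3  X -> M   (beta_a)
    step4  M -> Y   (beta_b)

Steps 1+2 form the bidirectional analysis; steps 1, 3 and 4 feed the
two-step mediation.  Every step runs the same per-analysis procedure:
instrument selection (with the 5e-8 → 5e-6 relaxation), LD clumping,
harmonization, the intercept-triggered MR-PRESSO outlier loop, the three
estimators (IVW with the heterogeneity-driven fixed/MRE switch, MR-Egger,
weighted median) and the sensitivity report.  Benjamini–Hochberg q-values
are computed within explicit families: all p-values of one method across
the outcomes of one direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from mrlink.estimators import MREstimate, egger, ivw, weighted_median
from mrlink.gwas_io import SummaryStatsTable, read_summary_stats, write_results_table
from mrlink.harmonize import AMBIGUITY_WINDOW, harmonize
from mrlink.instruments import (
    MIN_IVS,
    P_FALLBACK,
    P_PRIMARY,
    R2_MAX,
    WINDOW_KB,
    clump,
    select_by_pvalue,
)
from mrlink.mediation import two_step_pipeline
from mrlink.sensitivity import remove_outliers_until_clean, sensitivity_report
from mrlink.synthetic_gwas import SimulationConfig, simulate_mediation_triplet, simulate_two_sample

__all__ = ["bh_adjust", "AnalysisPlan", "run_pipeline", "analyze_pair"]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values for one family of p-values.

    Step-up rule: on the ascending scale, ``q_(i) = min_{j>=i} m p_(j)/j``,
    mapped back to input order.  Each q is at least its own p.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class AnalysisPlan:
    """Ordered (exposure, outcome) analyses with direction labels."""

    steps: list[tuple[str, str, str]]  # (step label, exposure trait, outcome trait)
    #: direction label per step; BH families are (direction, method)
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.directions:
            self.directions = {label: label for label, _, _ in self.steps}

    @property
    def bidirectional_pairs(self) -> list[tuple[str, str]]:
        pairs = {(e, o) for _, e, o in self.steps}
        return [(e, o) for e, o in pairs if (o, e) in pairs]


@dataclass
class AnalysisOutcome:
    """Everything computed for one exposure→outcome analysis."""

    step: str
    exposure: str
    outcome: str
    skipped: bool = False
    reason: str = ""
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: object = None
    removal_log: object = None
    harmonization_log: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)
    instruments: object = None


def analyze_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    step: str = "step1",
    settings: Mapping | None = None,
    seed: int | None = 0,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
) -> AnalysisOutcome:
    """Run the full per-analysis procedure for one exposure→outcome pair."""
    s = dict(settings or {})
    out = AnalysisOutcome(step=step, exposure=exposure.trait_name, outcome=outcome.trait_name)

    selected = select_by_pvalue(
        exposure,
        primary=s.get("p_primary", P_PRIMARY),
        fallback=s.get("p_fallback", P_FALLBACK),
        min_ivs=s.get("min_ivs", MIN_IVS),
    )
    out.counts["selected"] = selected.n_snps
    out.counts["p_threshold_used"] = selected.p_threshold_used
    if not selected.usable:
        out.skipped = True
        out.reason = (
            f"unusable instrument set: {selected.n_snps} variants even at "
            f"p <= {selected.p_threshold_used:g}"
        )
        return out
    clumped = clump(
        selected,
        ld=ld,
        positions=positions,
        r2_max=s.get("r2_max", R2_MAX),
        window_kb=s.get("window_kb", WINDOW_KB),
    )
    out.counts["clumped"] = clumped.n_snps
    out.counts["clump_removed"] = selected.n_snps - clumped.n_snps
    out.instruments = clumped
    out.counts["r2_explained"] = clumped.r2_explained
    out.counts["f_aggregate"] = clumped.f_aggregate
    if not clumped.usable:
        out.skipped = True
        out.reason = f"fewer than {s.get('min_ivs', MIN_IVS)} instruments after clumping"
        return out

    window = tuple(s.get("ambiguity_window", AMBIGUITY_WINDOW))
    data = harmonize(clumped, outcome, ambiguity_window=window)
    out.harmonization_log = data.log
    out.counts["shared"] = len(data.log)
    out.counts["harmonized_kept"] = data.n_snp
    out.counts["harmonized_dropped"] = len(data.log) - data.n_snp
    if data.n_snp < 2:
        out.skipped = True
        out.reason = "fewer than 2 SNPs after harmonization"
        return out

    n_sim = s.get("n_sim", 1000)
    clean, removal = remove_outliers_until_clean(
        data,
        max_rounds=s.get("max_rounds", 5),
        n_sim=n_sim,
        seed=seed,
    )
    out.removal_log = removal
    out.counts["outliers_removed"] = len(removal.removed_ids)
    out.counts["final_snps"] = clean.n_snp

    mode = s.get("ivw_mode", "auto")
    ests = [ivw(clean, mode=mode)]
    if clean.n_snp >= 3:
        slope, intercept = egger(clean)
        ests += [
            slope,
            intercept,
            weighted_median(clean, n_boot=s.get("n_boot", 1000), seed=seed),
        ]
        out.sensitivity = sensitivity_report(clean, n_sim=n_sim, seed=seed)
        out.counts["ivw_model"] = ests[0].method
    out.estimates = ests
    return out


_DEFAULT_PLAN = AnalysisPlan(
    steps=[
        ("step1", "exposure", "outcome"),
        ("step2", "outcome", "exposure"),
        ("step3", "exposure", "mediator"),
        ("step4", "mediator", "outcome"),
    ],
    directions={"step1": "forward", "step2": "reverse", "step3": "forward", "step4": "forward"},
)


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def _simulated_tables(cfg: dict, seed: int) -> dict[str, tuple[SummaryStatsTable, SummaryStatsTable]]:
    """Build per-step table pairs from the simulation config block."""
    block = dict(cfg)
    reverse_block = block.pop("reverse", None)
    sim = SimulationConfig(**{**block, "seed": seed})
    triplet = simulate_mediation_triplet(sim)
    pairs = {"step1": triplet.xy, "step3": triplet.xm, "step4": triplet.my}
    # reverse direction: the outcome trait's own (null-effect) instruments
    rev_defaults = {
        "n_snps": 20,
        "exposure_h2": 0.003,
        "theta": 0.0,
        "beta_a": 0.0,
        "beta_b": 0.0,
        "n_exposure": sim.n_outcome,
        "n_outcome": sim.n_exposure,
    }
    rev = SimulationConfig(**{**rev_defaults, **(reverse_block or {}), "seed": seed + 1})
    rx, ry, _ = simulate_two_sample(rev)
    rx = SummaryStatsTable("outcome", rx.records)
    ry = SummaryStatsTable("exposure", ry.records)
    pairs["step2"] = (rx, ry)
    return pairs


def _file_tables(cfg: dict) -> dict[str, SummaryStatsTable]:
    tables = {}
    for role, spec_ in cfg.items():
        if isinstance(spec_, str):
            spec_ = {"path": spec_}
        tables[role] = read_summary_stats(
            spec_["path"], dialect=spec_.get("dialect"), trait_name=spec_.get("name", role)
        )
    return tables


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> dict:
    """Execute the four-step plan from a YAML config (or mapping).

    The config names either a ``simulation`` block (synthetic mode) or a
    ``datasets`` block with ``exposure``/``outcome``/``mediator`` file
    paths and optional column dialects.  Writes ``results.tsv``,
    ``mediation.tsv``, ``sensitivity.tsv``, per-step harmonization drop
    logs, leave-one-out tables and a run log under ``out_dir``; the run
    is bit-reproducible under a fixed seed.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    settings = dict(cfg.get("thresholds", {}))
    settings.update(cfg.get("estimators", {}))
    settings.update(cfg.get("sensitivity", {}))
    out_dir = Path(out_dir or cfg.get("out_dir", "mrlink_results"))

    plan = _DEFAULT_PLAN
    if "simulation" in cfg:
        pairs = _simulated_tables(cfg["simulation"], seed)
    elif "datasets" in cfg:
        tables = _file_tables(cfg["datasets"])
        pairs = {}
        for label, exp_role, out_role in plan.steps:
            if exp_role in tables and out_role in tables:
                pairs[label] = (tables[exp_role], tables[out_role])
    else:
        raise ValueError("config needs a 'simulation' or 'datasets' block")

    outcomes: list[AnalysisOutcome] = []
    for i, (label, _, _) in enumerate(plan.steps):
        if label not in pairs:
            outcomes.append(
                AnalysisOutcome(step=label, exposure="-", outcome="-", skipped=True,
                                reason="no dataset for this step")
            )
            continue
        exp_t, out_t = pairs[label]
        outcomes.append(
            analyze_pair(exp_t, out_t, step=label, settings=settings, seed=seed + 10 + i)
        )

    # BH within (direction, method) families
    flat: list[tuple[int, int]] = []  # (outcome index, estimate index)
    for i, oc in enumerate(outcomes):
        for j, _ in enumerate(oc.estimates):
            flat.append((i, j))
    families: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, j in flat:
        key = (plan.directions[outcomes[i].step], outcomes[i].estimates[j].method)
        families.setdefault(key, []).append((i, j))
    for members in families.values():
        qs = bh_adjust([outcomes[i].estimates[j].pval for i, j in members])
        for (i, j), q in zip(members, qs):
            outcomes[i].estimates[j] = replace(outcomes[i].estimates[j], qval=float(q))

    by_step = {oc.step: oc for oc in outcomes}
    mediation = None
    med_reason = ""
    needed = ("step1", "step3", "step4")
    if all(lbl in by_step and not by_step[lbl].skipped for lbl in needed):
        est = {lbl: by_step[lbl].estimates[0] for lbl in needed}
        mediation = two_step_pipeline(est["step1"], est["step3"], est["step4"])
    else:
        missing = [lbl for lbl in needed if lbl not in by_step or by_step[lbl].skipped]
        med_reason = f"mediation skipped: step(s) {', '.join(missing)} unavailable"

    bundle = {
        "plan": plan,
        "outcomes": outcomes,
        "mediation": mediation,
        "seed": seed,
        "log": _run_log(outcomes, mediation, med_reason, seed, settings),
    }
    _write_bundle(bundle, out_dir)
    bundle["out_dir"] = out_dir
    return bundle


def _run_log(outcomes, mediation, med_reason, seed, settings) -> dict:
    log = {
        "seed": seed,
        "settings": {k: (list(v) if isinstance(v, tuple) else v) for k, v in settings.items()},
        "steps": {},
    }
    for oc in outcomes:
        entry = {
            "exposure": oc.exposure,
            "outcome": oc.outcome,
            "skipped": oc.skipped,
            "counts": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                       for k, v in oc.counts.items()},
        }
        if oc.skipped:
            entry["reason"] = oc.reason
        if oc.removal_log is not None:
            entry["outlier_loop"] = {
                "status": oc.removal_log.status,
                "removed": list(map(str, oc.removal_log.removed_ids)),
                "rounds": len(oc.removal_log.rounds),
            }
        log["steps"][oc.step] = entry
    if med_reason:
        log["mediation"] = med_reason
    elif mediation is not None:
        log["mediation"] = "computed from steps 1, 3, 4 (IVW)"
    return log


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    estimates = [e for oc in bundle["outcomes"] for e in oc.estimates]
    if estimates:
        write_results_table(estimates, out_dir / "results.tsv")
    if bundle["mediation"] is not None:
        write_results_table([bundle["mediation"]], out_dir / "mediation.tsv")
    sens_rows = []
    for oc in bundle["outcomes"]:
        if oc.harmonization_log is not None:
            oc.harmonization_log.to_csv(
                out_dir / f"harmonization_{oc.step}.tsv", sep="\t", index=False
            )
        if oc.sensitivity is None:
            continue
        rep = oc.sensitivity
        sens_rows.append(
            {
                "step": oc.step,
                "exposure": oc.exposure,
                "outcome": oc.outcome,
                "q_stat": rep.q_stat,
                "q_df": rep.q_df,
                "q_pval": rep.q_pval,
                "egger_intercept": rep.egger_intercept,
                "intercept_se": rep.intercept_se,
                "intercept_pval": rep.intercept_pval,
                "presso_global_pval": rep.presso.global_pval if rep.presso else np.nan,
                "n_outliers_flagged": len(rep.presso.outlier_indices) if rep.presso else 0,
                "outliers_removed": len(oc.removal_log.removed_ids) if oc.removal_log else 0,
                "mre_recommended": rep.mre_recommended,
            }
        )
        rep.loo.to_csv(out_dir / f"leave_one_out_{oc.step}.tsv", sep="\t", index=False)
    if sens_rows:
        pd.DataFrame(sens_rows).to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False)
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(bundle["log"], default=str)), fh, sort_keys=False)
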