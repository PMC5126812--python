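"""End-to-end run orchestration and report generation.

``run_pipeline`` ties the stages together — cohort (generated or read
from CSV), demographics, response-level tables with exact Fisher tests,
utility/VAS summaries with ANOVA, the tertile-based cost-utility
simulation, the attainment sensitivity sweep and the willingness-to-pay
grid — and writes CSV reports, a machine-readable JSON results bundle
and a run log recording the master seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as dstats
from .cohort import DISEASES, Cohort, CohortSpec, default_spec, gen_cohort
from .eq5d import DIMENSIONS, DIMENSION_LABELS, ValueSet
from .io import load_england_value_set, read_cohort, write_cohort
from .simulation import (
    DEFAULT_THRESHOLDS,
    SimConfig,
    build_wtp_table,
    sensitivity,
    simulate,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("boneqol")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    output_dir: Path
    cohort_csv: Path | None = None      # read this cohort instead of generating
    value_set_csv: Path | None = None   # defaults to the packaged England set
    cohort_spec: CohortSpec = field(default_factory=default_spec)
    sim_config: SimConfig = field(default_factory=SimConfig)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    simulate_disease: str = "OI"
    seed: int | None = None             # overrides cohort_spec.seed when set


def _config_digest(cfg: RunConfig) -> str:
    payload = {
        "cohort_csv": str(cfg.cohort_csv) if cfg.cohort_csv else None,
        "value_set_csv": str(cfg.value_set_csv) if cfg.value_set_csv else None,
        "seed": cfg.seed if cfg.seed is not None else cfg.cohort_spec.seed,
        "n_by_disease": cfg.cohort_spec.n_by_disease,
        "utility_mode": cfg.cohort_spec.utility_mode,
        "mixture": {
            "weights": cfg.cohort_spec.utility_mixture.weights,
            "means": cfg.cohort_spec.utility_mixture.means,
            "sds": cfg.cohort_spec.utility_mixture.sds,
            "bounds": cfg.cohort_spec.utility_mixture.bounds,
        },
        "sim": {
            "horizon_years": cfg.sim_config.horizon_years,
            "discount_rate": cfg.sim_config.discount_rate,
            "attainment": cfg.sim_config.attainment,
            "target_utility": cfg.sim_config.target_utility,
            "aging_decrement": cfg.sim_config.aging_decrement,
            "sensitivity_grid": cfg.sim_config.sensitivity_grid,
        },
        "thresholds": list(cfg.thresholds),
        "simulate_disease": cfg.simulate_disease,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _demographics(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for disease in DISEASES:
        sub = cohort.df[cohort.df.disease == disease]
        if sub.empty:
            continue
        rows.append({
            "disease": disease,
            "n": len(sub),
            "age_mean": round(float(sub.age.mean()), 1),
            "age_sd": round(float(sub.age.std(ddof=1)), 1) if len(sub) > 1 else 0.0,
            "age_min": round(float(sub.age.min()), 1),
            "age_max": round(float(sub.age.max()), 1),
            "pct_female": round(100.0 * float((sub.sex == "F").mean())),
        })
    return pd.DataFrame(rows)


def _response_tables(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-dimension level counts/percentages and exact Fisher p-values."""
    recs = []
    pvals: dict[str, float] = {}
    for dim in DIMENSIONS:
        col = dim.lower()
        for disease in DISEASES:
            sub = cohort.df[cohort.df.disease == disease]
            if sub.empty:
                continue
            for lvl in range(1, 6):
                k = int((sub[col] == lvl).sum())
                recs.append({
                    "dimension": dim,
                    "dimension_label": DIMENSION_LABELS[dim],
                    "disease": disease,
                    "level": lvl,
                    "count": k,
                    "percent": round(100.0 * k / len(sub)),
                })
        table = dstats.build_contingency(cohort, dim)
        pvals[dim] = dstats.fisher_exact(table)
    return pd.DataFrame(recs), pvals


def _summaries(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, float]]:
    rows = []
    anova: dict[str, float] = {}
    for variable in ("utility", "vas"):
        for s in dstats.summarize(cohort, variable):
            rows.append({
                "variable": variable, "disease": s.group, "n": s.n,
                "mean": s.mean, "sd": s.sd, "min": s.min, "max": s.max,
            })
        groups = [
            cohort.df.loc[cohort.df.disease == d, variable].dropna().to_numpy()
            for d in DISEASES if (cohort.df.disease == d).any()
        ]
        if len(groups) >= 2:
            _, p = dstats.anova_oneway(*groups)
            anova[variable] = p
    return pd.DataFrame(rows), anova


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    Returns the results dictionary that is also written to
    ``results.json``.  Identical configs (including seed) produce
    byte-identical JSON.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(cfg)
    seed = cfg.seed if cfg.seed is not None else cfg.cohort_spec.seed

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run start: seed=%s config=%s", seed, digest)

        stage = "value set"
        try:
            vs = ValueSet.from_csv(cfg.value_set_csv) if cfg.value_set_csv \
                else load_england_value_set()

            stage = "cohort"
            if cfg.cohort_csv:
                cohort = read_cohort(cfg.cohort_csv, value_set=vs)
            else:
                spec = cfg.cohort_spec
                if cfg.seed is not None:
                    from dataclasses import replace
                    spec = replace(spec, seed=cfg.seed)
                cohort = gen_cohort(spec, value_set=vs)
                write_cohort(cohort, out / "cohort.csv")
            log.info("cohort: n=%d", len(cohort))

            stage = "demographics"
            demo = _demographics(cohort)
            demo.to_csv(out / "demographics.csv", index=False)

            stage = "response tables"
            responses, fisher_p = _response_tables(cohort)
            responses.to_csv(out / "responses.csv", index=False)

            stage = "summaries"
            summaries, anova_p = _summaries(cohort)
            summaries.to_csv(out / "summaries.csv", index=False)

            stage = "simulation"
            target = cohort.subset(cfg.simulate_disease)
            split = dstats.split_tertiles(target)
            result = simulate(split.lower, cfg.sim_config)
            result.per_person.to_csv(out / "simulation.csv", index=False)

            stage = "sensitivity"
            gains = sensitivity(split.lower, cfg.sim_config)
            pd.Series(gains, name="mean_gain").rename_axis("attainment") \
                .to_csv(out / "sensitivity.csv")

            stage = "willingness-to-pay"
            wtp = build_wtp_table(gains, cfg.thresholds, cfg.sim_config)
            wtp.to_csv(out / "wtp.csv")
        except Exception as exc:
            log.error("stage %r failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        results = {
            "seed": seed,
            "config_digest": digest,
            "value_set": {"name": vs.name, "floor": vs.floor},
            "cohort": {
                "n": len(cohort),
                "n_by_disease": {
                    d: int((cohort.df.disease == d).sum())
                    for d in DISEASES if (cohort.df.disease == d).any()
                },
            },
            "demographics": demo.to_dict(orient="records"),
            "fisher_p": fisher_p,
            "summaries": summaries.to_dict(orient="records"),
            "anova_p": anova_p,
            "simulation": {
                "disease": cfg.simulate_disease,
                "n_treated": len(result.per_person),
                "attainment": result.attainment,
                "target_utility": cfg.sim_config.target_utility,
                "middle_tertile_mean": split.middle_mean,
                "total_treated": result.total_treated,
                "total_untreated": result.total_untreated,
                "mean_gain": result.mean_gain,
                "gain_sd": result.gain_sd,
                "gain_interval": list(result.gain_interval),
                "gain_mean_ci": list(result.gain_mean_ci),
            },
            "sensitivity": {str(a): g for a, g in gains.items()},
            "wtp": {
                str(th): {str(a): wtp.table.loc[th, a] for a in wtp.table.columns}
                for th in wtp.table.index
            },
        }
        blob = json.dumps(results, sort_keys=True, indent=2)
        (out / "results.json").write_text(blob)
        log.info("run complete")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
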