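"""End-to-end pipeline: simulate/read -> validate -> summarize -> score
-> age model -> distance sampling, with CSV artifacts and a manifest.

Every run writes its artifacts into one output directory together with
a ``manifest.json`` recording the seed, a hash of the configuration and
library versions, so a rerun with the same config and seed reproduces
the same files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_model import AgeDataset, SamplerConfig, fit_age_model, fit_null_model, \
    loo_compare, prob_overlap_zero
from .aggregation import summarize_replicates
from .distance import candidate_fits, effective_radius, select_model, \
    truncate_distances
from .equivalence import build_equivalence_table
from .errors import ConfigurationError, ValidationError
from .metrics import METRICS_BY_ID
from .synthetic import EffectSpec, StudyDesign, TerrapinSimSpec, \
    simulate_study, simulate_terrapin_distances

log = logging.getLogger("marshequiv")

REPLICATE_COLUMNS = ("pair", "site_type", "metric", "replicate", "value")


def validate_input(table: pd.DataFrame) -> list[str]:
    """Check a replicate table against the documented schema.

    Returns the list of violations (empty when the table is clean);
    nothing is coerced silently.
    """
    errors: list[str] = []
    missing = [c for c in REPLICATE_COLUMNS if c not in table.columns]
    if missing:
        errors.append(f"missing column(s): {missing}")
        return errors
    bad_site = ~table["site_type"].isin(["LS", "NM"])
    for idx in table.index[bad_site][:5]:
        errors.append(f"row {idx}: site_type {table.loc[idx, 'site_type']!r} "
                      "not in {'LS', 'NM'}")
    unknown = ~table["metric"].isin(METRICS_BY_ID)
    for idx in table.index[unknown][:5]:
        errors.append(f"row {idx}: unknown metric {table.loc[idx, 'metric']!r}")
    if "zone" in table.columns:
        nm_sill = (table["site_type"] == "NM") & (table["zone"] == "sill")
        for idx in table.index[nm_sill][:5]:
            errors.append(f"row {idx}: natural marsh sites have no sill zone")
    vals = pd.to_numeric(table["value"], errors="coerce")
    for idx in table.index[vals.isna()][:5]:
        errors.append(f"row {idx}: non-numeric value {table.loc[idx, 'value']!r}")
    ok = ~vals.isna()
    neg = ok & (vals < 0)
    for idx in table.index[neg][:5]:
        errors.append(f"row {idx}: negative value {vals[idx]} for metric "
                      f"{table.loc[idx, 'metric']!r}")
    pct = ok & table["metric"].map(
        lambda m: METRICS_BY_ID[m].units == "%" if m in METRICS_BY_ID else False)
    over = pct & (vals > 100)
    for idx in table.index[over][:5]:
        errors.append(f"row {idx}: percentage above 100 ({vals[idx]})")
    return errors


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    outdir: str = "marshequiv_out"
    seed: int = 0
    input_csv: str | None = None  # replicate CSV; None -> simulate
    design: StudyDesign | None = None
    effects: EffectSpec | None = None
    age_sampler: SamplerConfig | None = None
    terrapin: TerrapinSimSpec | None = None
    n_terrapin_surveys: int = 40
    run_distance: bool = True
    bootstrap: int = 199

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "design" in kwargs and kwargs["design"] is not None:
            d = dict(kwargs["design"])
            if "ages" in d:
                d["ages"] = tuple(d["ages"])
            if "replicate_plan" in d:
                d["replicate_plan"] = {k: tuple(v)
                                       for k, v in d["replicate_plan"].items()}
            kwargs["design"] = StudyDesign(**d)
        if kwargs.get("effects") is not None:
            kwargs["effects"] = EffectSpec(**kwargs["effects"])
        if kwargs.get("age_sampler") is not None:
            kwargs["age_sampler"] = SamplerConfig(**kwargs["age_sampler"])
        if kwargs.get("terrapin") is not None:
            kwargs["terrapin"] = TerrapinSimSpec(**kwargs["terrapin"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        blob = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle.

    Returns a dict of the in-memory results (replicates, summaries,
    equivalence table, age-model report, distance report, manifest).
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    # --- observations -----------------------------------------------------
    t = time.time()
    if config.input_csv is not None:
        table = pd.read_csv(config.input_csv)
    else:
        design = config.design or StudyDesign(seed=config.seed)
        if design.seed != config.seed:
            design = StudyDesign(n_pairs=design.n_pairs, ages=design.ages,
                                 seed=config.seed,
                                 replicate_plan=design.replicate_plan)
        table = simulate_study(design, config.effects or EffectSpec())
    problems = validate_input(table)
    if problems:
        raise ValidationError(problems)
    table.to_csv(outdir / "replicates.csv", index=False)
    stage_times["observations"] = time.time() - t

    # --- summaries and Z-scores -------------------------------------------
    t = time.time()
    summaries = summarize_replicates(table)
    summaries.to_csv(outdir / "site_summaries.csv", index=False)
    eq = build_equivalence_table(summaries)
    eq.z.rename_axis("pair").assign(net_score=eq.net_scores) \
        .to_csv(outdir / "z_table.csv")
    metric_report = pd.DataFrame({
        "mean_z": eq.metric_means,
        "equivalent": eq.equivalent,
        "sd_mode": pd.Series(eq.sd_mode),
    }).rename_axis("metric")
    metric_report.to_csv(outdir / "metric_scores.csv")
    stage_times["equivalence"] = time.time() - t
    log.info("grand mean Z = %.3f +/- %.3f", eq.grand_mean, eq.grand_sd)

    # --- age model ---------------------------------------------------------
    t = time.time()
    design = config.design or StudyDesign(seed=config.seed)
    ages = np.asarray(design.ages, dtype=float)[:len(eq.net_scores)]
    data = AgeDataset(y=eq.net_scores.to_numpy(), age=ages)
    sampler = config.age_sampler or SamplerConfig(seed=config.seed)
    growth = fit_age_model(data, sampler)
    null = fit_null_model(data, sampler)
    comparison = loo_compare(growth, null)
    age_report = growth.summary()
    age_report.to_csv(outdir / "age_model_summary.csv")
    age_json = {
        "beta_age_mean": float(growth.draws["beta1"].mean()),
        "beta_age_ci": [float(np.quantile(growth.draws["beta1"], q))
                        for q in (0.025, 0.975)],
        "p_beta_age_leq_0": prob_overlap_zero(growth),
        "looic_growth": comparison.looic_a,
        "looic_null": comparison.looic_b,
        "delta_looic": comparison.delta,
    }
    (outdir / "age_model.json").write_text(json.dumps(age_json, indent=2))
    stage_times["age_model"] = time.time() - t

    # --- distance sampling -------------------------------------------------
    distance_report = None
    if config.run_distance:
        t = time.time()
        spec = config.terrapin or TerrapinSimSpec()
        sightings = simulate_terrapin_distances(
            spec, config.n_terrapin_surveys, seed=config.seed + 1)
        kept = truncate_distances(sightings["distance_m"].to_numpy())
        fits = candidate_fits(kept)
        best = select_model(fits)
        er = effective_radius(best, n_boot=config.bootstrap,
                              seed=config.seed + 2)
        distance_report = {
            "n_sightings": int(len(sightings)),
            "n_retained": int(kept.size),
            "selected_key": best.key,
            "selected_adjustment": best.adjustment,
            "aic": best.aic,
            "gof_p": best.gof_p,
            "effective_radius_m": er.rho,
            "ci_m": [er.ci_low, er.ci_high],
        }
        pd.DataFrame([{
            "key": f.key, "adjustment": f.adjustment, "n_adj": f.n_adj,
            "aic": f.aic, "gof_p": f.gof_p} for f in fits]) \
            .to_csv(outdir / "distance_fits.csv", index=False)
        (outdir / "distance_report.json").write_text(
            json.dumps(distance_report, indent=2))
        stage_times["distance"] = time.time() - t

    manifest = {
        "package": "marshequiv",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "replicates": table,
        "summaries": summaries,
        "equivalence": eq,
        "age": age_json,
        "distance": distance_report,
        "manifest": manifest,
    }
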