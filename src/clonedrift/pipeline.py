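"""Stage orchestration: YAML-configured end-to-end analyses.

Two canonical workflows are expressible: the survival workflow
(synthetic KM cohort -> attrition fit -> simulated cohort -> cumulative
VAF curves) and the clonality workflow (synthetic VAF dataset -> ABC fits
-> neutral-vs-clonal verdict).  Each stage reads the previous stages'
declared outputs from a shared context, writes files under the output
directory, and the run ends with a manifest (inputs, outputs, seeds,
versions, sha256 checksums).  One master seed is expanded into named
per-stage substreams, so identical config + seed gives identical
manifest checksums (ABC/MCMC stages are deterministic given their
substream seed).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from clonedrift import attrition, clonesim, io, scifer, synth

__all__ = ["StageConfig", "PipelineConfig", "run_pipeline", "load_config"]


class StageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    params: dict[str, Any] = {}


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stages: list[StageConfig] = []
    seed: int = 0
    unit: str = "week"
    out_dir: str = "clonedrift_out"
    log_level: str = "INFO"

    @field_validator("unit")
    @classmethod
    def _unit_ok(cls, v):
        if v not in ("week", "year"):
            raise ValueError("unit must be 'week' or 'year'")
        return v

    @field_validator("stages")
    @classmethod
    def _stages_known(cls, v):
        for s in v:
            if s.name not in _STAGES:
                raise ValueError(
                    f"unknown stage {s.name!r}; known: {sorted(_STAGES)}"
                )
        return v


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.default_rng([master, index]).integers(2**31))


def _st_gen_km_cohort(ctx, out: Path, seed: int, params: dict):
    ap = attrition.AttritionParams(
        n0=params.get("n0", 100),
        delta=params.get("delta", 1 / 3),
        xi=params.get("xi", 0.538),
    )
    df = synth.gen_km_cohort(
        ap,
        n_mice=params.get("n_mice", 36),
        censor_fraction=params.get("censor_fraction", 0.0),
        seed=seed,
    )
    path = out / "km_cohort.csv"
    io.write_survival_csv(df, path)
    ctx["survival"] = df
    return [path]


def _st_fit_attrition(ctx, out: Path, seed: int, params: dict):
    df = ctx.get("survival")
    if df is None:
        df = io.read_survival_csv(params["km"])
    fitter = attrition.AttritionFitter(
        n_samples=params.get("n_samples", 1000), random_state=seed
    )
    fitter.fit(df["time_weeks"], df["event"].astype(bool))
    path = out / "attrition_fit.json"
    io.write_json(fitter.to_json_dict(), path)
    ctx["attrition_fit"] = fitter
    return [path]


def _st_simulate_cohort(ctx, out: Path, seed: int, params: dict):
    cfg = clonesim.SimConfig(
        n_target=params.get("n0", 100),
        regime=params.get("regime", "attrition"),
        lam=params.get("lam", 0.538 / 3),
        delta=params.get("delta", 1 / 3),
        checkpoints=tuple(params.get("checkpoints", (5.0, 25.0, 30.0, 35.0))),
        seed=seed,
    )
    results = clonesim.simulate_cohort(cfg, n_mice=params.get("n_mice", 100))
    paths = []
    rows = []
    for r in results:
        t = r.extinction_time if r.extinction_time is not None else r.censored_at
        rows.append((f"M{r.mouse:03d}", t, int(r.extinction_time is not None)))
    import pandas as pd

    surv = pd.DataFrame(rows, columns=["animal_id", "time_weeks", "event"])
    p = out / "simulated_survival.csv"
    io.write_survival_csv(surv, p)
    paths.append(p)
    ctx["cohort"] = results
    return paths


def _st_cumulative_curves(ctx, out: Path, seed: int, params: dict):
    results = ctx["cohort"]
    checkpoint = params.get("checkpoint", 35.0)
    import pandas as pd

    rows = []
    for r in results:
        spec = r.spectra.get(checkpoint)
        if spec is None or spec.extinct:
            continue
        vafs = clonesim.to_vafs(spec)
        inv, cum = clonesim.cumulative_vaf_curve(vafs)
        rows.append(
            pd.DataFrame({"mouse": r.mouse, "inv_vaf": inv, "cumulative": cum})
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["mouse", "inv_vaf", "cumulative"])
    )
    path = out / f"cumulative_curves_wk{checkpoint:g}.tsv"
    df.to_csv(path, sep="\t", index=False)
    ctx["curves"] = df
    return [path]


def _st_gen_vaf_dataset(ctx, out: Path, seed: int, params: dict):
    scen = synth.SynthScenario(
        tag=params.get("scenario", "neutral_drift"),
        params=params.get("params", {}),
        depth=params.get("depth", 90),
        seed=seed,
    )
    table, truth = synth.gen_vaf_dataset(scen)
    vaf_path = out / "vaf_dataset.tsv"
    io.write_vaf_tsv(table, vaf_path)
    truth_path = out / "vaf_truth.json"
    io.write_json(truth, truth_path)
    ctx["vaf"] = table
    ctx["vaf_truth"] = truth
    return [vaf_path, truth_path]


def _st_abc_fit(ctx, out: Path, seed: int, params: dict):
    table = ctx.get("vaf")
    if table is None:
        table = io.read_vaf_tsv(params["vaf"])
    models = params.get("model", "both")
    models = ("neutral", "selected") if models == "both" else (models,)
    results = {}
    paths = []
    for i, model in enumerate(models):
        est = scifer.SciferABC(
            t=params.get("age", 35.0),
            unit=params.get("unit", "week"),
            model=model,
            n_particles=params.get("n_particles", 20000),
            accept_fraction=params.get("accept_fraction", 0.01),
            depth=params.get("depth", 90),
            random_state=_stage_seed(seed, i),
        )
        est.fit(table["observed_vaf"].to_numpy())
        results[model] = est.result_
        p = out / f"abc_{model}.json"
        io.write_json(est.result_.to_json_dict(), p)
        paths.append(p)
    ctx["abc"] = results
    return paths


def _st_classify_clonality(ctx, out: Path, seed: int, params: dict):
    results = ctx["abc"]
    verdict = scifer.classify_clonality(
        results["neutral"], results["selected"], threshold=params.get("threshold", 0.2)
    )
    path = out / "clonality.json"
    io.write_json(verdict, path)
    ctx["clonality"] = verdict
    return [path]


_STAGES: dict[str, Callable] = {
    "gen_km_cohort": _st_gen_km_cohort,
    "fit_attrition": _st_fit_attrition,
    "simulate_cohort": _st_simulate_cohort,
    "cumulative_curves": _st_cumulative_curves,
    "gen_vaf_dataset": _st_gen_vaf_dataset,
    "abc_fit": _st_abc_fit,
    "classify_clonality": _st_classify_clonality,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Validation happens before any stage runs (pydantic, unknown stages and
    keys rejected); a stage failure halts the run with the stage named.
    """
    import clonedrift

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict[str, Any] = {"unit": config.unit}
    manifest: dict[str, Any] = {
        "version": clonedrift.__version__,
        "seed": config.seed,
        "unit": config.unit,
        "stages": [],
    }
    for i, stage in enumerate(config.stages):
        seed = _stage_seed(config.seed, i)
        try:
            outputs = _STAGES[stage.name](ctx, out, seed, stage.params)
        except Exception as exc:
            raise RuntimeError(f"stage {i} ({stage.name}) failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": stage.name,
                "seed": seed,
                "params": stage.params,
                "outputs": [
                    {"path": str(p), "sha256": _sha256(Path(p))} for p in outputs
                ],
            }
        )
    io.write_json(manifest, out / "manifest.json")
    return manifest
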