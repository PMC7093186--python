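"""End-to-end pipeline: simulate -> extract -> select -> fit -> predict -> rate.

A run is described by a plain-text (YAML) configuration with explicit seeds;
unknown keys are rejected so typos cannot silently change a run.  Stages write
into a scratch subdirectory that is promoted into the output directory only
when every enabled stage succeeds; on failure the scratch directory is renamed
``quarantine-<stage>`` so partial outputs are never mistaken for results.  A
``manifest.json`` records the configuration hash, derived per-stage seeds and
a checksum for every emitted file, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admp import screen_sites, select_admps
from .clock import MethylationClock
from .extract import MethMatrix, build_matrix, extract_sample, write_coverage_file
from .metrics import estimate_tissue_rate, evaluate
from .panel import make_panel, write_panel_bed, write_panel_fasta
from .simulate import (
    DriftModel,
    SampleMeta,
    draw_cohort,
    read_sample_sheet,
    simulate_reads,
    true_methylation,
    write_sample_sheet,
    write_truth_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_study_tables", "DEFAULT_CONFIG"]

log = logging.getLogger("nmrclock")

STAGES = ("simulate", "extract", "select", "fit", "loocv", "predict", "evaluate", "rate")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_regions": 12,
        "total_cpgs": 51,
        "region_length": 300,
        "n_admp": 23,
        "slope_min": 3.0e-4,
        "slope_max": 6.0e-4,
        "sigma_b": 0.03,
        "conversion_efficiency": 0.99,
        "sequencing_error_rate": 0.001,
        "target_coverage": 200,
        "tissue_rates": {"liver": 1.0, "skin": 0.6},
        "cohorts": [
            {"n": 24, "age_min": 39, "age_max": 1144, "tissue": "liver", "batch": "set1"},
            {"n": 19, "age_min": 43, "age_max": 1196, "tissue": "liver", "batch": "set2"},
            {"n": 20, "age_min": 43, "age_max": 1196, "tissue": "skin", "batch": "set2"},
        ],
    },
    "extract": {"min_coverage": 50, "max_mismatch_frac": 0.1},
    "select": {"alpha": 0.05},
    "clock": {"alpha_mix": 0.5, "n_lambda": 100, "train_all": False},
    "inputs": {"matrix": None, "samples": None},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _check_keys(given: dict, template: dict, path: str = "") -> None:
    for key, value in given.items():
        if key not in template:
            raise ValueError(f"unknown config key: {path}{key}")
        tval = template[key]
        if isinstance(tval, dict) and isinstance(value, dict) and key != "tissue_rates":
            _check_keys(value, tval, path=f"{path}{key}.")
        if key == "cohorts" and isinstance(value, list):
            for entry in value:
                _check_keys(entry, tval[0], path=f"{path}cohorts[].")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict) and key != "tissue_rates":
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged, unknown keys rejected)."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, overrides: dict[str, Any] | None = None) -> "RunConfig":
        overrides = overrides or {}
        _check_keys(overrides, DEFAULT_CONFIG)
        data = _merge(DEFAULT_CONFIG, overrides)
        bad = set(data["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(overrides)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def sha256(self) -> str:
        canon = json.dumps(self.data, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the master seed."""
        state = np.random.SeedSequence(int(self.data["seed"])).generate_state(len(STAGES))
        return {s: int(v % (2**31)) for s, v in zip(STAGES, state)}


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_study_tables(
    matrix_path: str | Path, samples_path: str | Path
) -> tuple[MethMatrix, list[SampleMeta], dict[str, list[str]]]:
    """Load a fraction matrix TSV and sample sheet for real-data mode.

    Returns the matrix restricted to the shared samples (in sheet order), the
    matching metadata, and a reconciliation report listing samples present in
    only one of the two files.
    """
    matrix = MethMatrix.from_tsv(matrix_path)
    cohort = read_sample_sheet(samples_path)
    sheet_ids = [s.sample_id for s in cohort]
    mat_ids = set(matrix.sample_ids)
    reconciliation = {
        "only_in_matrix": sorted(mat_ids - set(sheet_ids)),
        "only_in_samples": sorted(set(sheet_ids) - mat_ids),
    }
    shared = [s for s in cohort if s.sample_id in mat_ids]
    if not shared:
        raise ValueError("matrix and sample sheet share no samples")
    frac = matrix.fraction.loc[[s.sample_id for s in shared]]
    cov = (
        matrix.coverage.loc[[s.sample_id for s in shared]]
        if matrix.coverage is not None
        else None
    )
    return MethMatrix(frac, cov), shared, reconciliation


def _write_predictions(path: Path, sample_ids, predicted, actual=None) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "predicted_age_weeks": predicted})
    if actual is not None:
        df["actual_age_weeks"] = actual
        df["residual_weeks"] = df["predicted_age_weeks"] - df["actual_age_weeks"]
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the enabled stages in order and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    work = outdir / ".partial"
    if work.exists():
        shutil.rmtree(work)
    work.mkdir()
    seeds = config.stage_seeds()
    stages = list(config["stages"])
    manifest: dict[str, Any] = {
        "config": config.data,
        "config_sha256": config.sha256,
        "package_version": __version__,
        "stage_seeds": {s: seeds[s] for s in stages},
        "stages_run": [],
        "files": {},
    }

    ctx: dict[str, Any] = {}
    stage = "init"
    try:
        if "simulate" in stages:
            stage = "simulate"
            _stage_simulate(config, seeds["simulate"], work, ctx)
            manifest["stages_run"].append(stage)
        if "extract" in stages:
            stage = "extract"
            _stage_extract(config, work, ctx)
            manifest["stages_run"].append(stage)
        elif config["inputs"]["matrix"] is not None:
            stage = "load"
            matrix, cohort, recon = load_study_tables(
                config["inputs"]["matrix"], config["inputs"]["samples"]
            )
            if recon["only_in_matrix"] or recon["only_in_samples"]:
                log.warning("sample reconciliation: %s", recon)
            ctx["matrix"] = {"train": matrix}
            ctx["cohorts"] = {"train": cohort}
            ctx["train_key"] = "train"
        if "select" in stages:
            stage = "select"
            _stage_select(config, work, ctx)
            manifest["stages_run"].append(stage)
        if "fit" in stages:
            stage = "fit"
            _stage_fit(config, work, ctx)
            manifest["stages_run"].append(stage)
        if "loocv" in stages:
            stage = "loocv"
            _stage_loocv(config, work, ctx)
            manifest["stages_run"].append(stage)
        if "predict" in stages:
            stage = "predict"
            _stage_predict(work, ctx)
            manifest["stages_run"].append(stage)
        if "evaluate" in stages:
            stage = "evaluate"
            _stage_evaluate(work, ctx)
            manifest["stages_run"].append(stage)
        if "rate" in stages:
            stage = "rate"
            _stage_rate(work, ctx)
            manifest["stages_run"].append(stage)
    except Exception as exc:
        quarantine = outdir / f"quarantine-{stage}"
        if quarantine.exists():
            shutil.rmtree(quarantine)
        work.rename(quarantine)
        raise PipelineError(stage, exc) from exc

    # promote scratch outputs, then checksum
    for item in sorted(work.rglob("*")):
        rel = item.relative_to(work)
        dest = outdir / rel
        if item.is_dir():
            dest.mkdir(parents=True, exist_ok=True)
        else:
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(item), str(dest))
            manifest["files"][str(rel)] = _sha256_file(dest)
    shutil.rmtree(work)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# -- stage implementations -------------------------------------------------

def _stage_simulate(config: RunConfig, seed: int, work: Path, ctx: dict) -> None:
    sim = config["simulate"]
    rng_seeds = np.random.SeedSequence(seed).generate_state(4 + len(sim["cohorts"]))
    rng_seeds = [int(v % (2**31)) for v in rng_seeds]
    panel = make_panel(
        sim["n_regions"], sim["total_cpgs"], sim["region_length"], seed=rng_seeds[0]
    )
    model = DriftModel.plant(
        panel,
        n_admp=sim["n_admp"],
        slope_range=(sim["slope_min"], sim["slope_max"]),
        seed=rng_seeds[1],
        tissue_rates=dict(sim["tissue_rates"]),
        sigma_b=sim["sigma_b"],
        conversion_efficiency=sim["conversion_efficiency"],
        sequencing_error_rate=sim["sequencing_error_rate"],
        target_coverage=sim["target_coverage"],
    )
    write_panel_fasta(panel, work / "panel.fasta")
    write_panel_bed(panel, work / "panel.bed")
    write_truth_table(model, work / "truth_sites.tsv")
    cohorts: dict[str, list[SampleMeta]] = {}
    reads: dict[str, dict] = {}
    all_meta: list[SampleMeta] = []
    (work / "reads").mkdir()
    for k, c in enumerate(sim["cohorts"]):
        key = f"{c['tissue']}_{c['batch']}"
        cohort = draw_cohort(
            c["n"], c["age_min"], c["age_max"], c["tissue"], c["batch"],
            seed=rng_seeds[2 + k],
        )
        probs = true_methylation(panel, cohort, model, seed=rng_seeds[2 + k] + 1)
        sample_reads, truth = simulate_reads(
            panel, cohort, probs, model,
            seed=rng_seeds[2 + k] + 2, outdir=work / "reads",
        )
        cohorts[key] = cohort
        reads[key] = sample_reads
        all_meta.extend(cohort)
        truth.to_csv(work / f"truth_counts_{key}.tsv", sep="\t", index=False)
    write_sample_sheet(all_meta, work / "samples.tsv")
    ctx.update(panel=panel, drift=model, cohorts=cohorts, reads=reads)
    ctx["train_key"] = "liver_set1" if "liver_set1" in cohorts else next(iter(cohorts))


def _stage_extract(config: RunConfig, work: Path, ctx: dict) -> None:
    panel = ctx["panel"]
    ext = config["extract"]
    (work / "coverage").mkdir(exist_ok=True)
    matrices: dict[str, MethMatrix] = {}
    for key, cohort in ctx["cohorts"].items():
        records = []
        for sample in cohort:
            recs, assignment = extract_sample(
                ctx["reads"][key][sample.sample_id],
                panel,
                sample.sample_id,
                max_mismatch_frac=ext["max_mismatch_frac"],
            )
            if assignment.n_discarded:
                log.info("%s: discarded %d reads", sample.sample_id, assignment.n_discarded)
            write_coverage_file(recs, work / "coverage" / f"{sample.sample_id}.cov")
            records.append(recs)
        matrix = build_matrix(
            pd.concat(records, ignore_index=True),
            cohort,
            panel.site_ids,
            min_coverage=ext["min_coverage"],
        )
        matrix.to_tsv(work / f"matrix_{key}.tsv")
        matrices[key] = matrix
    ctx["matrix"] = matrices


def _stage_select(config: RunConfig, work: Path, ctx: dict) -> None:
    key = ctx["train_key"]
    matrix = ctx["matrix"][key]
    ages = np.array([s.age_weeks for s in ctx["cohorts"][key]])
    stats = screen_sites(matrix, ages)
    stats.to_csv(work / "admp.tsv", sep="\t", index=False, float_format="%.6g")
    selected = select_admps(stats, alpha=config["select"]["alpha"])
    (work / "selected_sites.txt").write_text("\n".join(selected) + "\n")
    ctx["selected"] = selected
    ctx["admp_stats"] = stats


def _clock_for(config: RunConfig, ctx: dict, key: str) -> MethylationClock:
    matrix = ctx["matrix"][key].restrict(ctx["selected"])
    ages = [s.age_weeks for s in ctx["cohorts"][key]]
    return MethylationClock(
        matrix.fraction, ages,
        alpha_mix=config["clock"]["alpha_mix"],
        n_lambda=config["clock"]["n_lambda"],
    )


def _stage_fit(config: RunConfig, work: Path, ctx: dict) -> None:
    results = _clock_for(config, ctx, ctx["train_key"]).fit()
    results.to_json(work / "model.json")
    ctx["model"] = results


def _stage_loocv(config: RunConfig, work: Path, ctx: dict) -> None:
    loocv = _clock_for(config, ctx, ctx["train_key"]).loocv()
    loocv.frame().to_csv(work / "loocv_predictions.tsv", sep="\t", index=False,
                         float_format="%.4f")
    ctx["loocv"] = loocv


def _stage_predict(work: Path, ctx: dict) -> None:
    model = ctx["model"]
    preds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key, matrix in ctx["matrix"].items():
        if key == ctx["train_key"]:
            continue
        cohort = ctx["cohorts"][key]
        yhat = model.predict(matrix.fraction).to_numpy()
        ages = np.array([s.age_weeks for s in cohort])
        _write_predictions(work / f"predictions_{key}.tsv",
                           [s.sample_id for s in cohort], yhat, ages)
        preds[key] = (yhat, ages)
    ctx["predictions"] = preds


def _stage_evaluate(work: Path, ctx: dict) -> None:
    out: dict[str, dict] = {}
    if "loocv" in ctx:
        out[ctx["train_key"] + "_loocv"] = ctx["loocv"].metrics.to_dict()
    for key, (yhat, ages) in ctx.get("predictions", {}).items():
        out[key] = evaluate(yhat, ages).to_dict()
    with open(work / "metrics.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ctx["metrics"] = out


def _stage_rate(work: Path, ctx: dict) -> None:
    out: dict[str, dict] = {}
    for key, (yhat, ages) in ctx.get("predictions", {}).items():
        out[key] = estimate_tissue_rate(yhat, ages).to_dict()
    if "loocv" in ctx:
        lo = ctx["loocv"]
        out[ctx["train_key"] + "_loocv"] = estimate_tissue_rate(lo.predicted, lo.actual).to_dict()
    with open(work / "rate.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ctx["rates"] = out
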