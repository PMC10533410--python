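"""End-to-end orchestration: simulate/load → preprocess → features →
associations → dynamics → multivariate, with a reproducibility manifest.

A single root seed in the run configuration feeds every stage through
deterministic derived seeds; re-running an unchanged configuration
reproduces all CSV outputs byte-for-byte. Each stage writes its outputs
before the next starts; a stage failure aborts the run with the stage
name and persists a partial manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .associations import associate_features
from .dynamics import compartment_proportions, phenotype_proportions, phenotype_trends
from .features import build_feature_table
from .multivariate import prepare_feature_matrix, repeated_split_auc, shadow_feature_importance
from .preprocess import MIN_CELL_AREA_UM2, preprocess_cells
from .registry import PhenotypeRegistry
from .simulate import Cohort, SyntheticConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "associate", "dynamics", "predict", "importance")


@dataclass
class RunConfig:
    """Run configuration; thresholds default to the analysis' standards."""

    outdir: str = "run"
    seed: int = 0
    # synthetic-cohort settings (used when no input paths are given)
    synthetic: SyntheticConfig | None = None
    cells_path: str | None = None
    contacts_path: str | None = None
    samples_path: str | None = None
    images_path: str | None = None
    min_area_um2: float = MIN_CELL_AREA_UM2
    ki67_quantile: float | None = None
    per_protocol_only: bool = True
    exclude_responder_post_epithelial: bool = False
    correlation_threshold: float = 0.95
    min_unique_values: int = 6
    n_repeats: int = 100
    train_frac: float = 0.75
    importance_runs: int = 100
    importance_trees: int = 100
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, PhenotypeRegistry):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, state, outdir, manifest)
            _write_manifest(manifest, outdir)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _stage_simulate(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    if config.cells_path is not None:
        state["cells"] = io.read_cell_tables(config.cells_path)
        state["contacts"] = io.read_contacts(config.contacts_path)
        state["samples"] = pd.read_csv(config.samples_path)
        state["images"] = pd.read_csv(config.images_path)
        state["registry"] = PhenotypeRegistry()
        manifest["stages"]["simulate"] = {"source": "files", "n_images": len(state["cells"])}
        return
    syn = config.synthetic or SyntheticConfig(seed=config.seed)
    if config.synthetic is None:
        syn = dataclasses.replace(syn, seed=config.seed)
    cohort = simulate_cohort(syn)
    io.write_cohort(cohort, outdir / "inputs")
    state.update(
        cells=cohort.cells,
        contacts=cohort.contacts,
        samples=cohort.samples,
        images=cohort.images,
        registry=syn.registry,
        cohort=cohort,
    )
    manifest["stages"]["simulate"] = {
        "source": "synthetic",
        "n_tumours": len(cohort.samples),
        "n_images": len(cohort.images),
        "n_cells": int(sum(len(t) for t in cohort.cells.values())),
    }


def _require(state: dict, keys: tuple[str, ...], stage: str) -> None:
    missing = [k for k in keys if k not in state]
    if missing:
        raise RuntimeError(
            f"stage {stage!r} needs outputs {missing} from an earlier stage; "
            "enable the producing stage or provide input paths"
        )


def _stage_preprocess(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("cells",), "preprocess")
    n_before = sum(len(t) for t in state["cells"].values())
    processed = {}
    if config.ki67_quantile is not None:
        pooled = pd.concat(state["cells"].values())
        from .preprocess import threshold_positivity

        thr_source = pooled["Ki67"].to_numpy(dtype=float)
        thr = np.quantile(thr_source, config.ki67_quantile)
    for img, t in state["cells"].items():
        t2 = preprocess_cells(t, min_area=config.min_area_um2)
        if config.ki67_quantile is not None:
            t2 = t2.copy()
            t2["ki67_positive"] = t2["Ki67"].to_numpy(dtype=float) > thr
        processed[img] = t2
    state["cells"] = processed
    n_after = sum(len(t) for t in processed.values())
    io.write_cell_tables(processed, outdir / "cells_processed.csv")
    manifest["stages"]["preprocess"] = {
        "cells_in": int(n_before),
        "cells_out": int(n_after),
        "min_area_um2": config.min_area_um2,
    }


def _stage_features(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("cells", "contacts", "images", "registry"), "features")
    timepoints = tuple(dict.fromkeys(state["images"]["timepoint"]))
    table, meta = build_feature_table(
        state["cells"], state["contacts"], state["images"], state["registry"], timepoints
    )
    state["feature_table"], state["feature_meta"] = table, meta
    table.to_csv(outdir / "features.csv")
    meta.to_json(outdir / "feature_metadata.json", orient="records", indent=1)
    per_tp = len(meta) // len(timepoints)
    manifest["stages"]["features"] = {
        "n_tumours": len(table),
        "n_feature_columns": table.shape[1],
        "columns_per_timepoint": per_tp,
        "timepoints": list(timepoints),
    }


def _analysis_samples(config: RunConfig, state: dict) -> pd.DataFrame:
    samples = state["samples"]
    if config.per_protocol_only and "per_protocol" in samples.columns:
        samples = samples[samples["per_protocol"].astype(bool)]
    return samples


def _stage_associate(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("feature_table", "feature_meta", "samples"), "associate")
    res = associate_features(
        state["feature_table"], state["feature_meta"], _analysis_samples(config, state)
    )
    state["associations"] = res
    out = res.copy()
    out["or_c_ci"] = out["or_c_ci"].astype(str)
    out["or_ci_arm_ci"] = out["or_ci_arm_ci"].astype(str)
    out.to_csv(outdir / "associations.csv", index=False)
    manifest["stages"]["associate"] = {
        "n_features": len(res),
        "n_fdr_lt_0.1": int((res["fdr"] < 0.1).sum()),
    }


def _stage_dynamics(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("cells", "images", "samples", "registry"), "dynamics")
    registry = state["registry"]
    images = state["images"].set_index("image_id")
    samples = _analysis_samples(config, state).set_index("tumour_id")
    frames = []
    for img, t in state["cells"].items():
        t = t.copy()
        t["tumour_id"] = images.loc[img, "tumour_id"]
        t["timepoint"] = images.loc[img, "timepoint"]
        frames.append(t)
    cells = pd.concat(frames, ignore_index=True)
    cells["unit"] = cells["tumour_id"] + "|" + cells["timepoint"]
    comp = compartment_proportions(cells, registry.category_map(), tumour_col="unit")
    comp.to_csv(outdir / "compartment_proportions.csv")
    trend_frames = []
    for compartment in ("epithelial", "TME"):
        props = phenotype_proportions(cells, registry, compartment, tumour_col="unit")
        units = props.index.to_series().str.split("|", expand=True)
        groups = pd.DataFrame(
            {
                "timepoint": units[1],
                "arm": samples["arm"].reindex(units[0]).to_numpy(),
                "response": samples["response"].reindex(units[0]).to_numpy(),
            },
            index=props.index,
        )
        keep = groups.dropna().index
        trends = phenotype_trends(props.loc[keep], groups.loc[keep])
        trends["compartment"] = compartment
        trend_frames.append(trends)
    trends = pd.concat(trend_frames, ignore_index=True)
    trends.to_csv(outdir / "phenotype_trends.csv", index=False)
    state["trends"] = trends
    manifest["stages"]["dynamics"] = {"n_trend_rows": len(trends)}


def _predict_inputs(config: RunConfig, state: dict) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    samples = _analysis_samples(config, state).set_index("tumour_id")
    table = state["feature_table"].reindex(samples.index)
    y = (samples["response"] == "pCR").astype(int)
    return table, y, samples["arm"]


def _stage_predict(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("feature_table", "samples"), "predict")
    table, y, arm = _predict_inputs(config, state)
    results = {}
    for arm_name in arm.unique():
        mask = (arm == arm_name).to_numpy()
        sub = table[mask]
        reduced, cmap = prepare_feature_matrix(
            sub.dropna(axis=1, how="all"),
            min_unique=config.min_unique_values,
            threshold=config.correlation_threshold,
            seed=config.seed,
        )
        run = repeated_split_auc(
            reduced,
            y[mask],
            n_repeats=config.n_repeats,
            train_frac=config.train_frac,
            seed=config.seed,
            arm=arm_name,
        )
        run.cluster_map = cmap
        results[arm_name] = run
        pd.DataFrame({"auc": run.aucs}).to_csv(
            outdir / f"aucs_{arm_name.replace('&', 'I')}.csv", index=False
        )
    state["prediction_runs"] = results
    summary = {
        a: {"mean_auc": r.mean_auc, "ci95": r.ci95, "n_features": len(r.retained_features)}
        for a, r in results.items()
    }
    (outdir / "prediction_summary.json").write_text(json.dumps(summary, indent=1))
    manifest["stages"]["predict"] = summary


def _stage_importance(config: RunConfig, state: dict, outdir: Path, manifest: dict) -> None:
    _require(state, ("feature_table", "samples"), "importance")
    table, y, arm = _predict_inputs(config, state)
    mask = (arm == "C&I").to_numpy()
    sub = table[mask].dropna(axis=1, how="all").dropna(axis=0)
    reduced, _ = prepare_feature_matrix(
        sub, min_unique=config.min_unique_values,
        threshold=config.correlation_threshold, seed=config.seed,
    )
    imp = shadow_feature_importance(
        reduced,
        y[mask].loc[reduced.index],
        n_runs=config.importance_runs,
        n_trees=config.importance_trees,
        seed=config.seed,
    )
    imp.to_csv(outdir / "importance.csv", index=False)
    state["importance"] = imp
    manifest["stages"]["importance"] = {
        "n_features": len(imp),
        "n_selected": int(imp["selected"].sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "features": _stage_features,
    "associate": _stage_associate,
    "dynamics": _stage_dynamics,
    "predict": _stage_predict,
    "importance": _stage_importance,
}
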