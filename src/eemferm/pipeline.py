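"""End-to-end analysis orchestration behind a single configuration.

``run_pipeline`` executes simulate/load -> preprocess -> assemble -> LV scan
-> fit -> predict -> report, writing numeric CSV artifacts plus a manifest
(config hash, seed, package versions) from which a run is reproducible.
``compare_runs`` collates the relative prediction errors of several runs into
one tidy table (per experiment / parameter / spectral-input variant).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .alignment import PARAMETERS, split_calibration_prediction
from .chemometrics import (
    lv_scan,
    pca_fit,
    pls_apply,
    predict_trajectories,
    relative_rmse,
    rmse,
    simpls_fit,
)
from .data_model import (
    CultureCondition,
    OfflineTable,
    PlateExperiment,
    SpectrumSeries,
    read_eem_series,
    read_offline_table,
)
from .preprocess import (
    PreprocessConfig,
    downsample_emission,
    mask_scatter,
    reference_to_initial,
    restrict_emission_window,
    smooth_emission,
    unfold_to_features,
)
from .synthetic_data import PRESETS, SimConfig, generate_experiment

__all__ = [
    "AnalysisConfig",
    "PipelineStageError",
    "run_pipeline",
    "compare_runs",
    "load_layout",
    "write_layout",
]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SparseScheduleConfig(BaseModel):
    min_gap_h: float = 5.0
    n_min: int = 6
    n_max: int = 8


class PreprocessSettings(BaseModel):
    em_window_rel: tuple[float, float] | None = (-10.0, 270.0)
    smooth_window_px: int = 25
    target_em_step: float | None = 2.0
    scatter_band_rel: tuple[float, float] = (-10.0, 13.0)
    include_scatter: bool = True
    reference_to_t0: bool = True

    def to_config(self, include_scatter: bool | None = None) -> PreprocessConfig:
        return PreprocessConfig(
            em_window_rel=self.em_window_rel,
            smooth_window_px=self.smooth_window_px,
            target_em_step=self.target_em_step,
            scatter_band_rel=self.scatter_band_rel,
            include_scatter=self.include_scatter if include_scatter is None else include_scatter,
            reference_to_t0=self.reference_to_t0,
        )


class AnalysisConfig(BaseModel):
    """Schema-validated configuration of one full analysis run."""

    mode: str = "preset"  # preset | external
    preset: str = "Mg"
    seed: int | None = None
    spectra_csv: str | None = None
    offline_csv: str | None = None
    layout_yaml: str | None = None
    parameters: list[str] = Field(default_factory=lambda: list(PARAMETERS))
    calibration_conditions: list[str] | None = None  # preset default if None
    t_max_model: float | None = None
    l_max: int = 8
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    sparse: SparseScheduleConfig = Field(default_factory=SparseScheduleConfig)
    sim: dict = Field(default_factory=dict)  # extra SimConfig fields in preset mode
    out_dir: str = "eemferm_run"

    @field_validator("mode")
    @classmethod
    def _mode_known(cls, v: str) -> str:
        if v not in ("preset", "external"):
            raise ValueError("mode must be 'preset' or 'external'")
        return v

    @field_validator("parameters")
    @classmethod
    def _params_known(cls, v: list[str]) -> list[str]:
        bad = [p for p in v if p not in PARAMETERS]
        if bad:
            raise ValueError(f"unknown parameters {bad}; choose from {PARAMETERS}")
        return v

    def model_post_init(self, __context) -> None:
        if self.mode == "preset" and self.seed is None:
            raise ValueError("preset mode requires a seed")
        if self.mode == "external":
            missing = [
                n
                for n in ("spectra_csv", "offline_csv", "layout_yaml")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"external mode requires {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# layout IO
# ---------------------------------------------------------------------------


def write_layout(experiment: PlateExperiment, path: str | Path) -> None:
    doc = {
        "experiment_id": experiment.experiment_id,
        "limited_substrate": experiment.limited_substrate,
        "t_max_model": experiment.t_max_model,
        "conditions": [
            {
                "condition_id": c.condition_id,
                "substrate_fraction": c.substrate_fraction,
                "substrate_conc": c.substrate_conc,
                "cdw_t0": c.cdw_t0,
                "replicate_wells": list(c.replicate_wells),
                "role": c.role,
            }
            for c in experiment.conditions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_layout(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("experiment_id", "limited_substrate", "conditions"):
        if key not in doc:
            raise ValueError(f"layout {path}: missing key {key!r}")
    doc["conditions"] = [CultureCondition(**c) for c in doc["conditions"]]
    return doc


def _load_external(cfg: AnalysisConfig) -> PlateExperiment:
    layout = load_layout(cfg.layout_yaml)
    series = read_eem_series(cfg.spectra_csv)
    well_map = {}
    for c in layout["conditions"]:
        for w in c.replicate_wells:
            well_map[w] = c.condition_id
    for s in series:
        s.condition_id = well_map.get(s.well_id)
    offline = read_offline_table(cfg.offline_csv)
    offline.schedule_label = "full"
    return PlateExperiment(
        experiment_id=layout["experiment_id"],
        limited_substrate=layout["limited_substrate"],
        conditions=layout["conditions"],
        spectra=series,
        offline=offline,
        t_max_model=cfg.t_max_model
        if cfg.t_max_model is not None
        else layout.get("t_max_model"),
    )


# ---------------------------------------------------------------------------
# preprocessing with shared work between scatter variants
# ---------------------------------------------------------------------------


def preprocess_experiment_variants(
    experiment: PlateExperiment, settings: PreprocessSettings
) -> dict[str, PlateExperiment]:
    """Preprocess all series once per scatter variant, sharing the early steps.

    Windowing, smoothing and downsampling are identical whether or not the
    scatter band is later excluded, so they run once; the scatter mask and
    the referencing differ per variant.  Returns {"scatter": ..., "fluorescence": ...}.
    """
    variants: dict[str, list[SpectrumSeries]] = {"scatter": [], "fluorescence": []}
    for s in experiment.spectra:
        shared = []
        for m in s.measurements:
            if settings.em_window_rel is not None:
                m = restrict_emission_window(m, settings.em_window_rel)
            if settings.smooth_window_px > 1:
                m = smooth_emission(m, settings.smooth_window_px)
            if settings.target_em_step is not None:
                m = downsample_emission(m, settings.target_em_step)
            shared.append(m)
        base = SpectrumSeries(
            well_id=s.well_id, measurements=shared, condition_id=s.condition_id, cadence=s.cadence
        )
        fl = SpectrumSeries(
            well_id=s.well_id,
            measurements=[mask_scatter(m, settings.scatter_band_rel) for m in shared],
            condition_id=s.condition_id,
            cadence=s.cadence,
        )
        if settings.reference_to_t0:
            base = reference_to_initial(base)
            fl = reference_to_initial(fl)
        variants["scatter"].append(base)
        variants["fluorescence"].append(fl)
    out = {}
    for name, series in variants.items():
        out[name] = PlateExperiment(
            experiment_id=experiment.experiment_id,
            limited_substrate=experiment.limited_substrate,
            conditions=experiment.conditions,
            spectra=series,
            offline=experiment.offline,
            po2_traces=experiment.po2_traces,
            t_max_model=experiment.t_max_model,
        )
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _reference_ranges(
    offline: OfflineTable, conditions: list[CultureCondition], t_max: float | None
) -> dict[str, np.ndarray]:
    """Measured offline values (non-blank, within the modeling window) per parameter."""
    blank = {c.condition_id for c in conditions if c.role == "blank"}
    vals: dict[str, list[float]] = {p: [] for p in PARAMETERS}
    for s in offline.samples:
        if s.condition_id in blank:
            continue
        if t_max is not None and s.time > t_max + 1e-9:
            continue
        for p in PARAMETERS:
            vals[p].append(getattr(s, p))
    return {p: np.array(v) for p, v in vals.items()}


def _pca_scores_frame(experiment: PlateExperiment, n_pc: int = 3) -> pd.DataFrame:
    blank = {c.condition_id for c in experiment.conditions if c.role == "blank"}
    rows, meta = [], []
    for s in sorted(experiment.spectra, key=lambda s: (s.condition_id or "", s.well_id)):
        if s.condition_id in blank:
            continue
        for m in s.measurements:
            vec, _ = unfold_to_features(m)
            rows.append(vec)
            meta.append((s.well_id, s.condition_id, m.time))
    X = np.vstack(rows)
    model = pca_fit(X, n_pc)
    df = pd.DataFrame(meta, columns=["well", "condition", "time"])
    for k in range(n_pc):
        df[f"pc{k + 1}"] = model.scores[:, k]
    for k in range(n_pc):
        df[f"pc{k + 1}_explained_var_pct"] = 100.0 * model.explained_variance_ratio[k]
    return df


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the full analysis and write the report bundle to cfg.out_dir.

    Returns a dict with the out_dir path, per-parameter scan results, the
    RMSE summary frame, and the manifest.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s complete", name)
        return result

    if cfg.mode == "preset":
        sim_cfg = SimConfig(preset=cfg.preset, seed=cfg.seed, **cfg.sim)
        experiment = stage("simulate", generate_experiment, sim_cfg)
    else:
        experiment = stage("load", _load_external, cfg)
    if cfg.t_max_model is not None:
        experiment.t_max_model = cfg.t_max_model
    logger.info(
        "experiment %s: %d conditions, %d wells, %d offline samples",
        experiment.experiment_id,
        len(experiment.conditions),
        len(experiment.spectra),
        len(experiment.offline.samples),
    )

    variants = stage("preprocess", preprocess_experiment_variants, experiment, cfg.preprocess)
    main_variant = "scatter" if cfg.preprocess.include_scatter else "fluorescence"
    prep = variants[main_variant]

    cal_ids = cfg.calibration_conditions
    if cal_ids is None:
        if cfg.mode != "preset":
            raise PipelineStageError(
                "assemble", ValueError("external mode requires calibration_conditions")
            )
        cal_ids = PRESETS[cfg.preset].calibration_ids
    full_supp_ids = [
        c.condition_id
        for c in experiment.conditions
        if c.substrate_fraction == 1.0 and c.condition_id not in cal_ids and c.role != "blank"
    ]

    ranges = _reference_ranges(
        experiment.offline, experiment.conditions, experiment.t_max_model
    )
    summary_rows = []
    scans = {}
    for parameter in cfg.parameters:
        cal_sparse, cal_full, pred_full = stage(
            f"assemble[{parameter}]",
            split_calibration_prediction,
            prep,
            cal_ids,
            parameter,
            cfg.sparse.min_gap_h,
            cfg.sparse.n_min,
            cfg.sparse.n_max,
        )
        scan = stage(
            f"lv_scan[{parameter}]",
            lv_scan,
            cal_sparse,
            cal_full,
            pred_full,
            full_supp_ids,
            cfg.l_max,
        )
        scans[parameter] = scan
        scan.to_frame().to_csv(out_dir / f"lv_scan_{parameter}.csv", index=False)

        n_lv = scan.selected_n_lv
        model = simpls_fit(cal_sparse.X, cal_sparse.y, n_lv, parameter)
        yhat_cal = pls_apply(model, cal_sparse.X)
        yhat_pred = pls_apply(model, pred_full.X)
        keep = ~pred_full.meta["condition"].isin(full_supp_ids).to_numpy()
        r_cal_full = rmse(cal_full.y, yhat_cal)
        r_pred_full = rmse(pred_full.y, yhat_pred)
        r_pred_m100 = (
            rmse(pred_full.y[keep], yhat_pred[keep]) if keep.any() else float("nan")
        )
        ref = ranges[parameter]
        summary_rows.append(
            {
                "experiment": experiment.experiment_id,
                "parameter": parameter,
                "spectral_input": main_variant,
                "n_lv": n_lv,
                "selection_rule": scan.selection_rule_used,
                "n_cal_spectra": cal_sparse.n_rows,
                "n_pred_spectra": pred_full.n_rows,
                "rmse_cal_sparse": rmse(cal_sparse.y, yhat_cal),
                "rmse_cal_full": r_cal_full,
                "rmse_pred_full": r_pred_full,
                "rmse_pred_full_m100": r_pred_m100,
                "rel_rmse_cal_full_pct": relative_rmse(r_cal_full, ref),
                "rel_rmse_pred_full_pct": relative_rmse(r_pred_full, ref),
                "rel_rmse_pred_full_m100_pct": (
                    relative_rmse(r_pred_m100, ref) if np.isfinite(r_pred_m100) else float("nan")
                ),
            }
        )
        traj = predict_trajectories(
            model, prep.spectra, experiment.conditions, parameter, experiment.t_max_model
        )
        traj.to_csv(out_dir / f"trajectories_{parameter}.csv", index=False)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "rmse_summary.csv", index=False)

    for name, exp_v in variants.items():
        stage(f"pca[{name}]", lambda e=exp_v, n=name: _pca_scores_frame(e).to_csv(
            out_dir / f"pca_scores_{n}.csv", index=False
        ))

    cfg_dict = cfg.model_dump()
    manifest = {
        "eemferm_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "experiment_id": experiment.experiment_id,
        "calibration_conditions": cal_ids,
        "full_supplementation_conditions": full_supp_ids,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "out_dir": out_dir,
        "experiment": experiment,
        "preprocessed": variants,
        "scans": scans,
        "summary": summary,
        "manifest": manifest,
    }


def compare_runs(bundles: list) -> pd.DataFrame:
    """Collate relative prediction RMSEs of several report bundles.

    Accepts run output directories (containing rmse_summary.csv) or the
    dicts returned by :func:`run_pipeline`.  Emits one tidy row per
    (experiment, parameter, spectral input, RMSE variant).
    """
    if len(bundles) < 1:
        raise ValueError("need at least one bundle")
    frames = []
    for b in bundles:
        if isinstance(b, dict):
            frames.append(b["summary"])
        else:
            path = Path(b) / "rmse_summary.csv"
            if not path.exists():
                raise FileNotFoundError(f"{path} not found; is {b} a run directory?")
            frames.append(pd.read_csv(path))
    combined = pd.concat(frames, ignore_index=True)
    param_sets = {tuple(sorted(f["parameter"].unique())) for f in frames}
    if len(param_sets) > 1:
        raise ValueError(f"bundles model different parameters: {param_sets}")
    rows = []
    for _, r in combined.iterrows():
        for variant, col in (
            ("full", "rel_rmse_pred_full_pct"),
            ("full_m100", "rel_rmse_pred_full_m100_pct"),
        ):
            rows.append(
                {
                    "experiment": r["experiment"],
                    "parameter": r["parameter"],
                    "spectral_input": r["spectral_input"],
                    "variant": variant,
                    "rel_rmse_pct": r[col],
                }
            )
    return pd.DataFrame(rows)
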