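"""Temporal alignment of offline references to spectral timestamps and
assembly of calibration / prediction regression datasets.

Offline parameters (glycerol, CDW, pH) are sampled per *condition*, not per
well, and far less often than spectra are recorded.  For every spectral
timestamp the offline value is taken from a piecewise-linear interpolation of
that condition's samples.  Two interpolations exist side by side: the "full"
schedule (all samples, interval down to ~1-1.5 h) and the "sparse" schedule
(6-8 samples at least 5 h apart) that mimics a realistic manual sampling
effort.  Calibration uses the sparse interpolation; the full interpolation of
the same spectra serves as an internal validation reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    CultureCondition,
    OfflineSample,
    OfflineTable,
    PlateExperiment,
    SpectrumSeries,
)
from .preprocess import FeatureIndex, unfold_to_features

__all__ = [
    "RegressionDataset",
    "interpolate_offline",
    "select_sparse_schedule",
    "assemble_dataset",
    "split_calibration_prediction",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("glycerol", "cdw", "ph")


@dataclass
class RegressionDataset:
    """Unfolded spectral matrix X with aligned offline responses y."""

    X: np.ndarray  # (n_rows, n_features)
    y: np.ndarray  # (n_rows,)
    meta: pd.DataFrame  # columns: well, condition, time
    parameter: str  # glycerol | cdw | ph
    schedule: str  # sparse | full
    feature_index: FeatureIndex

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == self.y.shape[0] == len(self.meta)):
            raise ValueError("X, y and meta must agree in row count")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def interpolate_offline(
    samples: list[OfflineSample], query_times: np.ndarray, parameter: str
) -> np.ndarray:
    """Piecewise-linear interpolation of one condition's offline trace.

    Exact at sample times; no extrapolation — queries outside the sampled
    range raise.
    """
    if len(samples) < 2:
        raise ValueError("need at least two offline samples to interpolate")
    t = np.array([s.time for s in samples])
    y = np.array([getattr(s, parameter) for s in samples])
    q = np.asarray(query_times, dtype=float)
    if np.any(q < t[0] - 1e-9) or np.any(q > t[-1] + 1e-9):
        bad = q[(q < t[0] - 1e-9) | (q > t[-1] + 1e-9)]
        raise ValueError(
            f"query times {bad} outside sampled range [{t[0]}, {t[-1]}]; "
            "extrapolation is not supported"
        )
    return np.interp(q, t, y)


def _greedy_sparse_times(
    times: np.ndarray, min_gap_h: float, n_min: int, n_max: int
) -> np.ndarray:
    """Deterministic earliest-first subset: first and last always kept."""
    chosen = [0]
    for i in range(1, times.size - 1):
        if times[i] - times[chosen[-1]] >= min_gap_h - 1e-9:
            chosen.append(i)
    last = times.size - 1
    if chosen[-1] != last:
        # force-include the last sample; drop trailing interior picks that
        # would violate the gap to it
        while len(chosen) > 1 and times[last] - times[chosen[-1]] < min_gap_h - 1e-9:
            chosen.pop()
        chosen.append(last)
    # truncate to n_max, dropping interior picks from the end (keep first/last)
    while len(chosen) > n_max:
        chosen.pop(-2)
    if len(chosen) < n_min:
        raise ValueError(
            f"cannot select {n_min}-{n_max} samples with gaps >= {min_gap_h} h: "
            f"only {len(chosen)} achievable over [{times[0]}, {times[-1]}] h"
        )
    return np.array(chosen)


def select_sparse_schedule(
    full_table: OfflineTable,
    min_gap_h: float = 5.0,
    n_min: int = 6,
    n_max: int = 8,
) -> OfflineTable:
    """Select a sparse sampling schedule from a full table, per condition.

    Greedy earliest-first: keep the first sample, then repeatedly the earliest
    sample at least ``min_gap_h`` after the previously chosen one; the last
    sample is always kept; the subset is truncated to ``n_max`` keeping
    first/last.  Deterministic by construction.
    """
    sparse_samples: list[OfflineSample] = []
    for cid, sub in full_table.by_condition().items():
        times = np.array([s.time for s in sub])
        if times[-1] - times[0] < (n_min - 1) * min_gap_h - 1e-9:
            raise ValueError(
                f"condition {cid}: span {times[-1] - times[0]} h too short for "
                f"{n_min} samples at >= {min_gap_h} h gaps"
            )
        idx = _greedy_sparse_times(times, min_gap_h, n_min, n_max)
        sparse_samples.extend(sub[i] for i in idx)
    return OfflineTable(samples=sparse_samples, schedule_label="sparse")


def _shared_feature_index(series_list: list[SpectrumSeries]) -> FeatureIndex:
    index = None
    for s in series_list:
        for m in s.measurements:
            _, fi = unfold_to_features(m)
            if index is None:
                index = fi
            elif fi != index:
                raise ValueError(
                    f"well {s.well_id} t={m.time}: feature index differs; "
                    "all spectra must share one preprocessing config"
                )
    if index is None:
        raise ValueError("no spectra supplied")
    return index


def assemble_dataset(
    spectra: list[SpectrumSeries],
    offline_table: OfflineTable,
    conditions: list[CultureCondition],
    parameter: str,
    t_max_model: float | None = None,
) -> RegressionDataset:
    """Build a regression dataset from preprocessed spectra and offline data.

    Rows are all spectra of all replicate wells of the listed conditions with
    time <= ``t_max_model`` (and within the offline-sampled range; rows outside
    it are dropped with a warning).  Replicate wells of a condition share the
    same interpolated offline trace, because offline sampling happens once per
    condition per time, not per well.  Rows are sorted canonically by
    (condition, well, time), making assembly permutation-invariant.
    """
    wanted = {c.condition_id: c for c in conditions}
    for c in conditions:
        if c.role == "blank":
            raise ValueError(f"blank condition {c.condition_id} cannot enter a dataset")
    by_cond = offline_table.by_condition()
    missing = [cid for cid in wanted if cid not in by_cond]
    if missing:
        raise ValueError(f"conditions without offline data: {missing}")

    index = None
    rows_X: list[np.ndarray] = []
    rows_meta: list[tuple[str, str, float]] = []
    series_sorted = sorted(
        (s for s in spectra if s.condition_id in wanted),
        key=lambda s: (s.condition_id, s.well_id),
    )
    if not series_sorted:
        raise ValueError("no spectra match the requested conditions")
    n_dropped = 0
    for s in series_sorted:
        samples = by_cond[s.condition_id]
        t_lo, t_hi = samples[0].time, samples[-1].time
        for m in s.measurements:
            if t_max_model is not None and m.time > t_max_model + 1e-9:
                continue
            if m.time < t_lo - 1e-9 or m.time > t_hi + 1e-9:
                n_dropped += 1
                continue
            vec, fi = unfold_to_features(m)
            if index is None:
                index = fi
            elif fi != index:
                raise ValueError(
                    f"well {s.well_id} t={m.time}: inconsistent feature index"
                )
            rows_X.append(vec)
            rows_meta.append((s.well_id, s.condition_id, m.time))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} spectra outside the offline-sampled time range",
            stacklevel=2,
        )
    if not rows_X:
        raise ValueError("no spectra left after time filtering")
    meta = pd.DataFrame(rows_meta, columns=["well", "condition", "time"])
    X = np.vstack(rows_X)
    y = np.empty(len(meta))
    for cid, sub in meta.groupby("condition").groups.items():
        y[sub] = interpolate_offline(
            by_cond[cid], meta.loc[sub, "time"].to_numpy(), parameter
        )
    schedule = offline_table.schedule_label or "full"
    return RegressionDataset(
        X=X, y=y, meta=meta, parameter=parameter, schedule=schedule, feature_index=index
    )


def split_calibration_prediction(
    experiment: PlateExperiment,
    cal_condition_ids: list[str],
    parameter: str,
    sparse_min_gap_h: float = 5.0,
    sparse_n_min: int = 6,
    sparse_n_max: int = 8,
) -> tuple[RegressionDataset, RegressionDataset, RegressionDataset]:
    """Split an experiment into (calibration-sparse, calibration-full, prediction-full).

    Calibration uses exactly two conditions (one high, one low supplementation);
    the prediction dataset holds every other inoculated condition.  The two
    calibration datasets share the identical spectral matrix X and differ only
    in the offline schedule behind y.
    """
    if len(cal_condition_ids) != 2:
        raise ValueError("calibration requires exactly two condition ids")
    cond_map = experiment.condition_map()
    unknown = [c for c in cal_condition_ids if c not in cond_map]
    if unknown:
        raise ValueError(f"unknown calibration conditions: {unknown}")
    cal_conditions = [cond_map[c] for c in cal_condition_ids]
    pred_conditions = [
        c
        for c in experiment.conditions
        if c.condition_id not in cal_condition_ids and c.role != "blank"
    ]
    if not pred_conditions:
        raise ValueError("prediction dataset would be empty: degenerate split")
    overlap = {c.condition_id for c in cal_conditions} & {
        c.condition_id for c in pred_conditions
    }
    if overlap:
        raise ValueError(f"calibration and prediction overlap: {overlap}")

    full_table = experiment.offline
    sparse_table = select_sparse_schedule(
        full_table, min_gap_h=sparse_min_gap_h, n_min=sparse_n_min, n_max=sparse_n_max
    )
    t_max = experiment.t_max_model
    cal_sparse = assemble_dataset(
        experiment.spectra, sparse_table, cal_conditions, parameter, t_max
    )
    cal_full = assemble_dataset(
        experiment.spectra, full_table, cal_conditions, parameter, t_max
    )
    # the two calibration views must be the same spectra; guard against a
    # sparse schedule that truncates the covered time range differently
    if cal_sparse.X.shape != cal_full.X.shape or not np.array_equal(
        cal_sparse.meta[["well", "condition", "time"]].to_numpy(),
        cal_full.meta[["well", "condition", "time"]].to_numpy(),
    ):
        raise ValueError(
            "sparse and full calibration datasets cover different spectra; "
            "check the sparse schedule spans the modeling window"
        )
    pred_full = assemble_dataset(
        experiment.spectra, full_table, pred_conditions, parameter, t_max
    )
    for cid in pred_full.meta["condition"].unique():
        assert cid not in cal_condition_ids, "data leakage: prediction row in calibration"
    return cal_sparse, cal_full, pred_full
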