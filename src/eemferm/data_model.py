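"""Domain types and file IO for 2D fluorescence (excitation-emission matrix) data.

A plate experiment consists of per-well time series of EEM spectra, offline
reference samples (glycerol, cell dry weight, pH) taken per condition, and a
plate layout mapping wells to cultivation conditions.  Spectra are stored on a
shared wavelength grid: excitation scanned coarsely (10 nm steps), emission
recorded at sub-nanometre resolution by a CCD line detector.

The canonical on-disk spectra format is long-form CSV, one row per pixel
(columns: well, time_h, ex_nm, em_nm, intensity).  It is deliberately
language-neutral and diff-able; at the data volumes involved here
(~43 x ~1000 pixels x <=130 time points x <=48 wells) it streams fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEMGrid",
    "EEMeasurement",
    "SpectrumSeries",
    "OfflineSample",
    "OfflineTable",
    "CultureCondition",
    "PlateExperiment",
    "default_grid",
    "read_eem_series",
    "write_eem_series",
    "read_offline_table",
    "write_offline_table",
    "classify_schedule",
    "extract_channel",
]

#: Emission-axis presets.  The instrument's CCD emission axis is reported in
#: two slightly different forms in the literature describing this class of
#: plate reader; both are offered, "caption" (278-720 nm, 0.45 nm steps) being
#: the default.
EMISSION_PRESETS = {
    "caption": (278.0, 720.0, 0.45),
    "methods": (275.0, 725.0, 0.44),
    # 10x coarser axis for quick exploratory runs; not an instrument grid
    "coarse": (278.0, 720.0, 4.5),
}

_UNIFORMITY_TOL = 1e-6  # nm; allowed wobble of emission spacing


def _check_uniform(values: np.ndarray, name: str, tol: float) -> None:
    if values.size < 2:
        return
    d = np.diff(values)
    if np.any(d <= 0):
        raise ValueError(f"{name} wavelengths must be strictly increasing")
    if np.max(d) - np.min(d) > tol:
        raise ValueError(
            f"{name} spacing not uniform within {tol} nm "
            f"(min {np.min(d):.6g}, max {np.max(d):.6g})"
        )


@dataclass(frozen=True)
class EEMGrid:
    """Shared excitation x emission wavelength grid (nm)."""

    excitation: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "excitation", np.asarray(self.excitation, dtype=float))
        object.__setattr__(self, "emission", np.asarray(self.emission, dtype=float))
        _check_uniform(self.excitation, "excitation", _UNIFORMITY_TOL)
        _check_uniform(self.emission, "emission", _UNIFORMITY_TOL)

    @property
    def shape(self) -> tuple[int, int]:
        return self.excitation.size, self.emission.size

    @property
    def emission_step(self) -> float:
        return float(self.emission[1] - self.emission[0]) if self.emission.size > 1 else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEMGrid):
            return NotImplemented
        return (
            self.excitation.shape == other.excitation.shape
            and self.emission.shape == other.emission.shape
            and np.array_equal(self.excitation, other.excitation)
            and np.array_equal(self.emission, other.emission)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: hash on bytes
        return hash((self.excitation.tobytes(), self.emission.tobytes()))


def default_grid(emission_preset: str = "caption") -> EEMGrid:
    """The instrument grid: excitation 280-700 nm in 10 nm steps; emission per preset."""
    lo, hi, step = EMISSION_PRESETS[emission_preset]
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    emission = lo + step * np.arange(n)
    excitation = np.arange(280.0, 700.0 + 1e-9, 10.0)
    return EEMGrid(excitation=excitation, emission=emission)


@dataclass
class EEMeasurement:
    """One 2D fluorescence spectrum of one well at one time point.

    ``valid`` marks pixels still carrying data; preprocessing steps (emission
    windowing, scatter exclusion) turn pixels off and never back on.  Raw
    (pre-referencing) intensities are non-negative; referenced intensities
    (I - I0) may be negative.
    """

    well_id: str
    time: float  # h
    intensities: np.ndarray  # (n_ex, n_em)
    grid: EEMGrid
    valid: np.ndarray = field(default=None)  # bool, same shape; True = usable

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("validity mask shape does not match grid shape")

    def copy(self) -> "EEMeasurement":
        return EEMeasurement(
            well_id=self.well_id,
            time=self.time,
            intensities=self.intensities.copy(),
            grid=self.grid,
            valid=self.valid.copy(),
        )


@dataclass
class SpectrumSeries:
    """Ordered EEM measurements of one well (nominal cadence 0.5 h)."""

    well_id: str
    measurements: list[EEMeasurement]
    condition_id: str | None = None
    cadence: float = 0.5  # h

    def __post_init__(self) -> None:
        times = [m.time for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"well {self.well_id}: measurement times not strictly increasing")
        grids = {id(m.grid) for m in self.measurements}
        if len(grids) > 1:
            g0 = self.measurements[0].grid
            for m in self.measurements[1:]:
                if m.grid != g0:
                    raise ValueError(f"well {self.well_id}: measurements disagree on grid")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements])

    @property
    def grid(self) -> EEMGrid:
        return self.measurements[0].grid

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)


@dataclass
class OfflineSample:
    """One offline reference sample of one condition."""

    condition_id: str
    time: float  # h
    glycerol: float  # g/L
    cdw: float  # g/L
    ph: float
    od600: float | None = None

    def __post_init__(self) -> None:
        if self.glycerol < 0:
            raise ValueError(f"negative glycerol {self.glycerol} at t={self.time}")
        if self.cdw < 0:
            raise ValueError(f"negative CDW {self.cdw} at t={self.time}")
        if not (0.0 < self.ph < 14.0):
            raise ValueError(f"pH {self.ph} out of (0, 14)")


@dataclass
class OfflineTable:
    """Offline samples over time; one trace per condition.

    ``schedule_label`` distinguishes the dense reference schedule ("full",
    sampling as often as every 1-1.5 h) from the realistic sparse schedule
    ("sparse", 6-8 samples at least 5 h apart).  ``None`` means ambiguous.
    """

    samples: list[OfflineSample]
    schedule_label: str | None = None

    def __post_init__(self) -> None:
        for cid, sub in self.by_condition().items():
            times = [s.time for s in sub]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"condition {cid}: offline times not strictly increasing")
        if self.schedule_label not in (None, "full", "sparse"):
            raise ValueError(f"unknown schedule label {self.schedule_label!r}")

    def by_condition(self) -> dict[str, list[OfflineSample]]:
        out: dict[str, list[OfflineSample]] = {}
        for s in self.samples:
            out.setdefault(s.condition_id, []).append(s)
        return out

    def condition(self, condition_id: str) -> list[OfflineSample]:
        sub = [s for s in self.samples if s.condition_id == condition_id]
        if not sub:
            raise KeyError(f"no offline samples for condition {condition_id!r}")
        return sub

    def values(self, condition_id: str, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.condition(condition_id)
        t = np.array([s.time for s in sub])
        y = np.array([getattr(s, parameter) for s in sub])
        return t, y


@dataclass
class CultureCondition:
    """One cultivation condition: a supplementation level replicated in wells."""

    condition_id: str
    substrate_fraction: float  # fraction of full supplementation, 0..1
    substrate_conc: float  # mg/L
    cdw_t0: float  # g/L
    replicate_wells: list[str]
    role: str = "prediction"  # calibration | prediction | blank

    def __post_init__(self) -> None:
        if not (0.0 <= self.substrate_fraction <= 1.0):
            raise ValueError("substrate_fraction must be in [0, 1]")
        if self.role not in ("calibration", "prediction", "blank"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "blank" and self.cdw_t0 != 0.0:
            raise ValueError("blank conditions must have cdw_t0 = 0")


@dataclass
class PlateExperiment:
    """A complete plate run: layout, spectra, offline table, optional pO2 traces."""

    experiment_id: str
    limited_substrate: str  # Mg | K | PO4 | none
    conditions: list[CultureCondition]
    spectra: list[SpectrumSeries]
    offline: OfflineTable
    po2_traces: list | None = None  # list[PO2Trace]; kept loose to avoid a cycle
    t_max_model: float | None = None  # h; analysis cutoff

    def __post_init__(self) -> None:
        known = {c.condition_id for c in self.conditions}
        for s in self.spectra:
            if s.condition_id is not None and s.condition_id not in known:
                raise ValueError(
                    f"series for well {s.well_id} references unknown condition "
                    f"{s.condition_id!r}"
                )
        if self.t_max_model is not None and self.spectra:
            last = max(s.times[-1] for s in self.spectra)
            if self.t_max_model > last + 1e-9:
                raise ValueError(
                    f"t_max_model {self.t_max_model} exceeds last spectral time {last}"
                )

    def condition_map(self) -> dict[str, CultureCondition]:
        return {c.condition_id: c for c in self.conditions}

    def well_condition(self) -> dict[str, str]:
        out = {}
        for c in self.conditions:
            for w in c.replicate_wells:
                out[w] = c.condition_id
        return out


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

SPECTRA_COLUMNS = ["well", "time_h", "ex_nm", "em_nm", "intensity"]
OFFLINE_COLUMNS = ["condition", "time_h", "glycerol_gL", "cdw_gL", "pH"]


def read_eem_series(path: str | Path, format: str = "long_csv") -> list[SpectrumSeries]:
    """Read per-well spectrum series from long-form CSV.

    The wavelength grid is inferred from the file and validated: every
    (well, time) block must cover the identical full grid; a ragged block is a
    hard error naming the first offending (well, time).
    """
    if format != "long_csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        return []

    ex = np.sort(df["ex_nm"].unique())
    em = np.sort(df["em_nm"].unique())
    grid = EEMGrid(excitation=ex, emission=em)
    n_px = ex.size * em.size

    ex_idx = pd.Series(np.arange(ex.size), index=ex)
    em_idx = pd.Series(np.arange(em.size), index=em)

    series_out: list[SpectrumSeries] = []
    for well, wdf in df.groupby("well", sort=True):
        measurements = []
        times = np.sort(wdf["time_h"].unique())
        for t, block in wdf.groupby("time_h", sort=True):
            if len(block) != n_px:
                raise ValueError(
                    f"{path}: ragged grid at well {well!r}, time {t} "
                    f"({len(block)} pixels, expected {n_px})"
                )
            mat = np.full(grid.shape, np.nan)
            mat[ex_idx[block["ex_nm"]].to_numpy(), em_idx[block["em_nm"]].to_numpy()] = (
                block["intensity"].to_numpy()
            )
            if np.isnan(mat).any():
                raise ValueError(
                    f"{path}: duplicate/missing pixels at well {well!r}, time {t}"
                )
            measurements.append(
                EEMeasurement(well_id=str(well), time=float(t), intensities=mat, grid=grid)
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: non-monotonic times for well {well!r}")
        series_out.append(SpectrumSeries(well_id=str(well), measurements=measurements))
    return series_out


def write_eem_series(
    series: Sequence[SpectrumSeries], path: str | Path, format: str = "long_csv"
) -> Path:
    """Write series as canonical long-form CSV.

    Rows are sorted by (well, time, ex, em); floats are written at full
    (round-trip) precision, so write(read(f)) is byte-identical to f for files
    already in canonical order.
    """
    if format != "long_csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    frames = []
    for s in sorted(series, key=lambda s: s.well_id):
        g = s.grid
        n_ex, n_em = g.shape
        for m in s.measurements:
            frames.append(
                pd.DataFrame(
                    {
                        "well": np.repeat(s.well_id, n_ex * n_em),
                        "time_h": m.time,
                        "ex_nm": np.repeat(g.excitation, n_em),
                        "em_nm": np.tile(g.emission, n_ex),
                        "intensity": m.intensities.ravel(),
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=SPECTRA_COLUMNS)
    out.to_csv(path, index=False)
    return path


def classify_schedule(
    times: Sequence[float], min_gap_h: float = 5.0, n_min: int = 6, n_max: int = 8
) -> str | None:
    """Classify a per-condition sampling schedule as sparse/full, None if ambiguous."""
    t = np.asarray(sorted(times), dtype=float)
    if t.size < 2:
        return None
    gaps = np.diff(t)
    if n_min <= t.size <= n_max and np.all(gaps >= min_gap_h - 1e-9):
        return "sparse"
    return "full"


def read_offline_table(path: str | Path) -> OfflineTable:
    """Read an offline sample table (CSV) and classify its schedule."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OFFLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    has_od = "od600" in df.columns
    samples = []
    for row in df.sort_values(["condition", "time_h"]).itertuples(index=False):
        samples.append(
            OfflineSample(
                condition_id=str(row.condition),
                time=float(row.time_h),
                glycerol=float(row.glycerol_gL),
                cdw=float(row.cdw_gL),
                ph=float(row.pH),
                od600=float(row.od600) if has_od and not pd.isna(row.od600) else None,
            )
        )
    table = OfflineTable(samples=samples)
    labels = {
        classify_schedule([s.time for s in sub])
        for sub in table.by_condition().values()
    }
    labels.discard(None)
    table.schedule_label = labels.pop() if len(labels) == 1 else None
    return table


def write_offline_table(table: OfflineTable, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(table.samples, key=lambda s: (s.condition_id, s.time))
    df = pd.DataFrame(
        {
            "condition": [s.condition_id for s in rows],
            "time_h": [s.time for s in rows],
            "glycerol_gL": [s.glycerol for s in rows],
            "cdw_gL": [s.cdw for s in rows],
            "pH": [s.ph for s in rows],
        }
    )
    if any(s.od600 is not None for s in rows):
        df["od600"] = [s.od600 for s in rows]
    df.to_csv(path, index=False)
    return path


def extract_channel(
    series: SpectrumSeries, ex_nm: float, em_nm: float
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Read one detector pixel over time (nearest grid pixel; no interpolation).

    Returns (times, intensities, (ex_used, em_used)).  Typical channels:
    scattered light at ex = em = 600 nm (biomass proxy), GFP at ex 420 nm /
    em 530 nm.
    """
    g = series.grid
    for want, axis, name in ((ex_nm, g.excitation, "excitation"), (em_nm, g.emission, "emission")):
        if want < axis[0] - 1e-9 or want > axis[-1] + 1e-9:
            raise ValueError(
                f"requested {name} {want} nm outside grid range "
                f"[{axis[0]}, {axis[-1]}]"
            )
    i_ex = int(np.argmin(np.abs(g.excitation - ex_nm)))
    i_em = int(np.argmin(np.abs(g.emission - em_nm)))
    times = series.times
    vals = np.array([m.intensities[i_ex, i_em] for m in series.measurements])
    return times, vals, (float(g.excitation[i_ex]), float(g.emission[i_em]))
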