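"""Oxygen transfer rate (OTR) from optode fluorescence / headspace pO2 traces.

A micro-scale respiration monitor measures the oxygen partial pressure in the
sealed headspace of each well through fluorescence quenching of an oxygen
sensor spot (Stern-Volmer relation, I0/I = 1 + Ksv * pO2).  The device cycles
between flushing phases (headspace refreshed with air) and stop-flow measuring
phases; during a measuring phase the cells deplete headspace oxygen and the
pO2 decline rate gives the OTR through an ideal-gas balance:

    OTR = -(dpO2/dt) * Vg / (Vl * R * T)        [mol O2 / L liquid / h]

with the slope from an ordinary-least-squares fit over a point window centred
on the phase.  This is a standard stop-flow headspace balance, a
faithful-in-spirit simplification of device-specific calculation schemes.

Internally pO2 is handled in bar; traces in % air saturation are converted
assuming 0.2095 bar O2 at 1 atm (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PO2Trace",
    "OTRTrace",
    "stern_volmer_po2",
    "otr_from_po2",
    "R_BAR_L",
    "O2_PARTIAL_PRESSURE_AIR_BAR",
]

R_BAR_L = 0.0831446  # universal gas constant, L bar / (mol K)
O2_PARTIAL_PRESSURE_AIR_BAR = 0.2095  # O2 partial pressure of air at 1 atm


@dataclass
class PO2Trace:
    """Headspace oxygen partial pressure of one well over time.

    ``phase`` marks each point as belonging to a stop-flow ``measure`` phase
    or an air ``flush`` phase; only measuring phases carry OTR information.
    """

    well_id: str
    times: np.ndarray  # h
    po2: np.ndarray  # % air saturation or bar, per `unit`
    phase: np.ndarray | None = None  # "measure" | "flush" per point
    unit: str = "percent_air"  # percent_air | bar

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        if self.times.shape != self.po2.shape:
            raise ValueError("times and po2 must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.po2 < 0):
            raise ValueError("pO2 must be non-negative")
        if self.unit not in ("percent_air", "bar"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.shape != self.times.shape:
                raise ValueError("phase markers must match times in length")

    def po2_bar(self, percent_to_bar: float = O2_PARTIAL_PRESSURE_AIR_BAR) -> np.ndarray:
        if self.unit == "bar":
            return self.po2
        return self.po2 / 100.0 * percent_to_bar


@dataclass
class OTRTrace:
    """Oxygen transfer rate of one well, one value per measuring phase."""

    well_id: str
    times: np.ndarray  # h, phase midpoints
    otr: np.ndarray  # mmol O2 / L / h

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.otr = np.asarray(self.otr, dtype=float)
        if not np.all(np.isfinite(self.otr)):
            raise ValueError("OTR values must be finite")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def stern_volmer_po2(i0: float, i: float, ksv: float) -> float:
    """Invert Stern-Volmer quenching: pO2 = (I0/I - 1) / Ksv.

    ``i0`` is the unquenched (zero-oxygen) intensity.  A measured intensity
    slightly above i0 (noise) clamps to pO2 = 0 with a warning.
    """
    i0 = float(i0)
    i = float(i)
    if i <= 0 or i0 <= 0:
        raise ValueError("intensities must be positive")
    if ksv <= 0:
        raise ValueError("Stern-Volmer constant must be positive")
    po2 = (i0 / i - 1.0) / ksv
    if po2 < 0:
        warnings.warn(
            f"intensity {i} above unquenched reference {i0}; clamping pO2 to 0",
            stacklevel=2,
        )
        return 0.0
    return po2


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t0 = t - t.mean()
    return float((t0 @ (y - y.mean())) / (t0 @ t0))


def _phase_runs(phase: np.ndarray) -> list[np.ndarray]:
    """Contiguous index runs where phase == 'measure'."""
    is_meas = phase == "measure"
    runs = []
    start = None
    for i, flag in enumerate(is_meas):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(np.arange(start, i))
            start = None
    if start is not None:
        runs.append(np.arange(start, len(is_meas)))
    return runs


def otr_from_po2(
    trace: PO2Trace,
    vg: float,
    vl: float,
    temperature: float,
    window: int = 5,
    percent_to_bar: float = O2_PARTIAL_PRESSURE_AIR_BAR,
) -> OTRTrace:
    """Oxygen transfer rate from a headspace pO2 trace, one value per measuring phase.

    Parameters
    ----------
    trace : PO2Trace
        Headspace pO2; points must carry phase markers (a trace without
        markers is treated as one single measuring phase).
    vg, vl : float
        Headspace gas volume and liquid filling volume, L.
    temperature : float
        Cultivation temperature, K.
    window : int
        Number of consecutive points, centred on the phase midpoint, used for
        the least-squares slope.  Phases with fewer points are skipped with a
        warning.
    """
    if vg <= 0 or vl <= 0:
        raise ValueError("vg and vl must be positive")
    if window < 2:
        raise ValueError("window must be >= 2 points")
    po2_bar = trace.po2_bar(percent_to_bar)
    if trace.phase is None:
        runs = [np.arange(trace.times.size)]
    else:
        runs = _phase_runs(trace.phase)
    times_out = []
    otr_out = []
    for run in runs:
        if run.size < window:
            warnings.warn(
                f"well {trace.well_id}: measuring phase with {run.size} points "
                f"shorter than window {window}; skipped",
                stacklevel=2,
            )
            continue
        mid = run.size // 2
        lo = max(0, mid - window // 2)
        hi = min(run.size, lo + window)
        lo = max(0, hi - window)
        sel = run[lo:hi]
        slope = _ols_slope(trace.times[sel], po2_bar[sel])  # bar / h
        otr_mol = -slope * vg / (vl * R_BAR_L * temperature)  # mol / L / h
        times_out.append(float(np.mean(trace.times[run])))
        otr_out.append(otr_mol * 1000.0)  # mmol / L / h
    return OTRTrace(well_id=trace.well_id, times=np.array(times_out), otr=np.array(otr_out))


def read_po2_csv(path) -> list[PO2Trace]:
    """Read pO2 traces (columns: well, time_h, po2[, phase]) from CSV."""
    df = pd.read_csv(path)
    for col in ("well", "time_h", "po2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    traces = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time_h")
        traces.append(
            PO2Trace(
                well_id=str(well),
                times=sub["time_h"].to_numpy(),
                po2=sub["po2"].to_numpy(),
                phase=sub["phase"].to_numpy() if "phase" in sub.columns else None,
            )
        )
    return traces


def write_otr_csv(traces: list[OTRTrace], path) -> None:
    frames = [
        pd.DataFrame({"well": t.well_id, "time_h": t.times, "otr_mmol_L_h": t.otr})
        for t in sorted(traces, key=lambda t: t.well_id)
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["well", "time_h", "otr_mmol_L_h"])
    )
    out.to_csv(path, index=False)
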