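"""Spectral preprocessing chain for EEM time series.

Fixed step order (each step optional and pure):

1. ``restrict_emission_window`` -- keep only emission pixels between -10 and
   +270 nm relative to the excitation wavelength of each row,
2. ``smooth_emission`` -- unweighted moving average along the emission axis
   (default 25 pixels) with truncated (shrinking) edge windows,
3. ``downsample_emission`` -- bin-average the emission axis to a coarser
   uniform step (default 2 nm),
4. ``mask_scatter`` (optional, "fluorescence-only" mode) -- discard pixels in
   the elastic scatter band, -10 to +13 nm relative to excitation,
5. ``reference_to_initial`` -- subtract each well's first spectrum
   pixel-by-pixel (I - I0), so later spectra are changes from inoculation.

All steps are mask-aware: masked pixels never contribute to means and the
masked set only ever grows along the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import EEMGrid, EEMeasurement, SpectrumSeries

__all__ = [
    "PreprocessConfig",
    "restrict_emission_window",
    "smooth_emission",
    "downsample_emission",
    "mask_scatter",
    "reference_to_initial",
    "unfold_to_features",
    "refold_from_features",
    "FeatureIndex",
    "run_chain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the preprocessing chain.

    ``None`` for a band/step disables that step; ``smooth_window_px=1`` is an
    identity smooth.  ``include_scatter=False`` switches to fluorescence-only
    modeling by masking the scatter band before referencing.
    """

    em_window_rel: tuple[float, float] | None = (-10.0, 270.0)  # nm rel. to excitation
    smooth_window_px: int = 25
    target_em_step: float | None = 2.0  # nm
    scatter_band_rel: tuple[float, float] = (-10.0, 13.0)  # nm rel. to excitation
    include_scatter: bool = True
    reference_to_t0: bool = True

    def __post_init__(self) -> None:
        if self.smooth_window_px < 1 or self.smooth_window_px % 2 == 0:
            raise ValueError("smooth_window_px must be odd and >= 1")
        for band in (self.em_window_rel, self.scatter_band_rel):
            if band is not None and not band[0] < band[1]:
                raise ValueError(f"band {band}: low must be < high")


def _relative_offset(grid: EEMGrid) -> np.ndarray:
    """(n_ex, n_em) matrix of emission wavelength minus excitation wavelength."""
    return grid.emission[None, :] - grid.excitation[:, None]


def restrict_emission_window(
    m: EEMeasurement, window_rel: tuple[float, float]
) -> EEMeasurement:
    """Mask pixels whose emission offset (lam_em - lam_ex) falls outside [low, high].

    Band endpoints are inclusive.  The grid is unchanged; only the validity
    mask shrinks.  Fully masked rows are allowed (logged).
    """
    low, high = window_rel
    out = m.copy()
    rel = _relative_offset(m.grid)
    out.valid &= (rel >= low) & (rel <= high)
    dead = np.flatnonzero(~out.valid.any(axis=1))
    if dead.size:
        logger.info(
            "emission window (%g, %g) masked entire rows at excitation %s nm",
            low, high, m.grid.excitation[dead],
        )
    return out


def smooth_emission(m: EEMeasurement, window_px: int) -> EEMeasurement:
    """Moving average along emission over unmasked pixels; edges truncate.

    Each output pixel is the mean of the unmasked pixels inside a window of
    ``window_px`` pixels centred on it; at the grid edges the window shrinks
    to the available pixels.  Masked pixels remain masked and untouched.
    """
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 1")
    out = m.copy()
    if window_px == 1:
        return out
    n = m.grid.emission.size
    if window_px > n:
        logger.info("smoothing window %d exceeds row length %d; rows collapse to their own mean", window_px, n)
    half = window_px // 2
    v = out.valid
    data = np.where(v, out.intensities, 0.0)
    csum = np.concatenate([np.zeros((data.shape[0], 1)), np.cumsum(data, axis=1)], axis=1)
    ccnt = np.concatenate([np.zeros((v.shape[0], 1)), np.cumsum(v, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    wsum = csum[:, hi] - csum[:, lo]
    wcnt = ccnt[:, hi] - ccnt[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = wsum / wcnt
    out.intensities = np.where(v & (wcnt > 0), smoothed, out.intensities)
    return out


def downsample_emission(m: EEMeasurement, target_step_nm: float) -> EEMeasurement:
    """Rebuild the emission axis at a coarser uniform step by bin-averaging.

    The output axis starts at the native first emission wavelength; output
    pixel k covers native wavelengths in [center - step/2, center + step/2).
    An output pixel is valid iff at least one contributing native pixel is
    valid; its value is the mean over the valid contributors.
    """
    g = m.grid
    native_step = g.emission_step
    if target_step_nm < native_step - 1e-12:
        raise ValueError(
            f"target step {target_step_nm} nm below native step {native_step} nm"
        )
    em = g.emission
    n_out = int(np.floor((em[-1] - em[0]) / target_step_nm + 1e-9)) + 1
    centers = em[0] + target_step_nm * np.arange(n_out)
    bins = np.floor((em - em[0] + target_step_nm / 2) / target_step_nm + 1e-12).astype(int)
    keep = bins < n_out  # native pixels beyond the last half-bin are dropped
    bins = bins[keep]

    v = m.valid[:, keep]
    data = np.where(v, m.intensities[:, keep], 0.0)
    n_ex = g.excitation.size
    sums = np.zeros((n_ex, n_out))
    cnts = np.zeros((n_ex, n_out))
    for i in range(n_ex):
        sums[i] = np.bincount(bins, weights=data[i], minlength=n_out)
        cnts[i] = np.bincount(bins, weights=v[i].astype(float), minlength=n_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = sums / cnts
    new_valid = cnts > 0
    vals[~new_valid] = 0.0
    new_grid = EEMGrid(excitation=g.excitation, emission=centers)
    return EEMeasurement(
        well_id=m.well_id, time=m.time, intensities=vals, grid=new_grid, valid=new_valid
    )


def mask_scatter(m: EEMeasurement, band_rel: tuple[float, float]) -> EEMeasurement:
    """Discard the elastic scatter band: pixels with lam_em - lam_ex in [low, high]."""
    low, high = band_rel
    out = m.copy()
    rel = _relative_offset(m.grid)
    out.valid &= ~((rel >= low) & (rel <= high))
    return out


def reference_to_initial(series: SpectrumSeries) -> SpectrumSeries:
    """Subtract the well's first spectrum from every spectrum (I - I0).

    The first output spectrum is identically zero on valid pixels; later
    spectra may go negative.  Masks must agree across time.  Deliberately not
    idempotent: re-referencing an already referenced series subtracts the
    (zero) first spectrum again, leaving it unchanged in value but the
    operation is defined relative to whatever the series' first measurement is.
    """
    if not series.measurements:
        raise ValueError("cannot reference an empty series")
    first = series.measurements[0]
    for m in series.measurements[1:]:
        if not np.array_equal(m.valid, first.valid):
            raise ValueError(
                f"well {series.well_id}: inconsistent masks across time; "
                "reference after masking steps"
            )
    i0 = first.intensities
    out = []
    for m in series.measurements:
        mm = m.copy()
        mm.intensities = m.intensities - i0
        out.append(mm)
    return SpectrumSeries(
        well_id=series.well_id,
        measurements=out,
        condition_id=series.condition_id,
        cadence=series.cadence,
    )


@dataclass(frozen=True)
class FeatureIndex:
    """Maps flattened feature positions to (lam_ex, lam_em) pixels.

    Order is excitation-major, emission-minor over the valid pixels, so two
    measurements with the same grid and mask unfold into comparable vectors.
    """

    ex_nm: np.ndarray
    em_nm: np.ndarray
    grid_shape: tuple[int, int]
    flat_positions: np.ndarray  # indices into the flattened (C-order) grid

    def __len__(self) -> int:
        return self.ex_nm.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureIndex):
            return NotImplemented
        return (
            self.grid_shape == other.grid_shape
            and np.array_equal(self.flat_positions, other.flat_positions)
            and np.array_equal(self.ex_nm, other.ex_nm)
            and np.array_equal(self.em_nm, other.em_nm)
        )


def unfold_to_features(m: EEMeasurement) -> tuple[np.ndarray, FeatureIndex]:
    """Flatten the valid pixels of a measurement into a feature vector."""
    flat_valid = m.valid.ravel()
    pos = np.flatnonzero(flat_valid)
    if pos.size == 0:
        raise ValueError(f"well {m.well_id} t={m.time}: no unmasked pixels to unfold")
    n_em = m.grid.emission.size
    index = FeatureIndex(
        ex_nm=m.grid.excitation[pos // n_em],
        em_nm=m.grid.emission[pos % n_em],
        grid_shape=m.grid.shape,
        flat_positions=pos,
    )
    return m.intensities.ravel()[pos], index


def refold_from_features(
    vector: np.ndarray, index: FeatureIndex, grid: EEMGrid
) -> EEMeasurement:
    """Inverse of :func:`unfold_to_features` (masked pixels are zero/invalid)."""
    if grid.shape != index.grid_shape:
        raise ValueError("grid shape does not match feature index")
    mat = np.zeros(grid.shape)
    mat.ravel()[index.flat_positions] = vector
    valid = np.zeros(grid.shape, dtype=bool)
    valid.ravel()[index.flat_positions] = True
    return EEMeasurement(well_id="", time=0.0, intensities=mat, grid=grid, valid=valid)


def run_chain(series: SpectrumSeries, cfg: PreprocessConfig) -> SpectrumSeries:
    """Apply the full preprocessing chain to one well's series.

    Order: window -> smooth -> downsample -> [scatter exclusion] -> reference.
    """
    out = []
    for m in series.measurements:
        if cfg.em_window_rel is not None:
            m = restrict_emission_window(m, cfg.em_window_rel)
        if cfg.smooth_window_px > 1:
            m = smooth_emission(m, cfg.smooth_window_px)
        if cfg.target_em_step is not None:
            m = downsample_emission(m, cfg.target_em_step)
        if not cfg.include_scatter:
            m = mask_scatter(m, cfg.scatter_band_rel)
        out.append(m)
    result = SpectrumSeries(
        well_id=series.well_id,
        measurements=out,
        condition_id=series.condition_id,
        cadence=series.cadence,
    )
    if cfg.reference_to_t0:
        result = reference_to_initial(result)
    return result
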