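"""Tissue mean-diffusivity (MDT) and conventional ADC estimation.

The tissue diffusivity map is the log-slope of the signal between two high
b-values,

    MDT = [ln S(b1) - ln S(b2)] / (b2 - b1),        b1 < b2,

computed voxelwise and converted to um^2/ms. With b1 = 1500 and
b2 = 2500 s/mm^2 and spherical encoding, free water (3.0 um^2/ms) has
attenuated to ~5.5e-4 at b2 — below 0.1% — so CSF contributes essentially
nothing to either shell and the slope reflects tissue alone. The
conventional ADC, computed against the b = 0 signal, includes the full CSF
contribution and is therefore biased high wherever CSF shares the voxel.

Voxels whose signal falls below a configurable floor (default 1e-6) are
flagged invalid rather than clamped: a rectified noise floor must not
masquerade as low diffusivity. Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import Grid
from .phantom import PhantomVolume

__all__ = [
    "SIGNAL_FLOOR",
    "DISPLAY_WINDOW",
    "MDTMap",
    "CorticalMask",
    "compute_mdt",
    "compute_adc",
    "mdt_map",
    "adc_map",
    "apply_cortical_mask",
    "render_window",
    "pv_bias_report",
]

#: Signals at or below this are treated as unmeasurable (voxel invalid).
SIGNAL_FLOOR = 1e-6

#: Default display window, um^2/ms — tight enough that cortex/WM contrast
#: fills the range while suppressed CSF stays dark.
DISPLAY_WINDOW = (0.5, 0.9)

#: um^2/ms per (1/(s/mm^2)) — converts a log-slope over b to display units.
_SLOPE_TO_UM2_MS = 1e3


@dataclass
class MDTMap:
    """Scalar diffusivity volume (um^2/ms) with validity mask and affine."""

    values: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(repr=False)
    b_pair: tuple[float, float] = (1500.0, 2500.0)
    window: tuple[float, float] = DISPLAY_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")
        if not (self.window[0] < self.window[1]):
            raise ValueError("window lo must be < hi")
        if not np.isfinite(self.values[self.valid]).all():
            raise ValueError("values must be finite on valid voxels")

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.affine)


@dataclass
class CorticalMask:
    """Binary mask restricting display to the cortical ribbon."""

    mask: np.ndarray
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")


def _log_slope(s_low, s_high, b_low: float, b_high: float, floor: float):
    s1 = np.asarray(s_low, dtype=float)
    s2 = np.asarray(s_high, dtype=float)
    valid = (s1 > floor) & (s2 > floor) & np.isfinite(s1) & np.isfinite(s2)
    values = np.full(s1.shape, np.nan)
    values[valid] = (
        (np.log(s1[valid]) - np.log(s2[valid])) / (b_high - b_low) * _SLOPE_TO_UM2_MS
    )
    return values, valid


def compute_mdt(
    s1: float, s2: float, b1: float = 1500.0, b2: float = 2500.0,
    floor: float = SIGNAL_FLOOR,
) -> float:
    """Scalar two-shell tissue diffusivity: ``[ln s1 - ln s2]/(b2 - b1)``.

    ``s1``/``s2`` are the signals at the lower/higher b-value; the result is
    in um^2/ms. Raises if either signal is at or below the floor.
    """
    if not (b2 > b1 >= 0):
        raise ValueError(f"need b2 > b1 >= 0, got b1={b1}, b2={b2}")
    if not (s1 > floor and s2 > floor):
        raise ValueError(f"signals must exceed the floor {floor}")
    return float((np.log(s1) - np.log(s2)) / (b2 - b1) * _SLOPE_TO_UM2_MS)


def compute_adc(
    s0: float, sb: float, b: float = 1000.0, floor: float = SIGNAL_FLOOR
) -> float:
    """Scalar conventional ADC from the b = 0 signal: ``ln(s0/sb)/b``, um^2/ms."""
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    if not (s0 > floor and sb > floor):
        raise ValueError(f"signals must exceed the floor {floor}")
    return float((np.log(s0) - np.log(sb)) / b * _SLOPE_TO_UM2_MS)


def mdt_map(
    s1: np.ndarray,
    s2: np.ndarray,
    affine: np.ndarray,
    b1: float = 1500.0,
    b2: float = 2500.0,
    floor: float = SIGNAL_FLOOR,
    window: tuple[float, float] = DISPLAY_WINDOW,
) -> MDTMap:
    """Voxelwise two-shell diffusivity map with floor-based validity."""
    if not (b2 > b1 >= 0):
        raise ValueError(f"need b2 > b1 >= 0, got b1={b1}, b2={b2}")
    values, valid = _log_slope(s1, s2, b1, b2, floor)
    return MDTMap(values=values, valid=valid, affine=affine, b_pair=(b1, b2),
                  window=window)


def adc_map(
    s0: np.ndarray,
    sb: np.ndarray,
    affine: np.ndarray,
    b: float = 1000.0,
    floor: float = SIGNAL_FLOOR,
) -> MDTMap:
    """Voxelwise conventional ADC map (same container as the MDT map)."""
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    values, valid = _log_slope(s0, sb, 0.0, b, floor)
    return MDTMap(values=values, valid=valid, affine=affine, b_pair=(0.0, b))


def apply_cortical_mask(m: MDTMap, mask: CorticalMask, tol: float = 1e-3) -> MDTMap:
    """Restrict a diffusivity map to a cortical mask.

    The mask is resampled onto the map grid with nearest-neighbor
    interpolation (binary semantics) before intersection with the map's
    validity. An empty mask is legal (fully invalid result) but warned about.
    """
    map_grid = m.grid
    if mask.mask.shape == map_grid.shape and np.allclose(
        mask.affine, m.affine, atol=tol
    ):
        resampled = mask.mask
    else:
        mask_grid = Grid(mask.mask.shape, mask.affine)
        centers = map_grid.voxel_centers()
        coords = mask_grid.world_to_voxel(centers)  # (N, 3) fractional voxels
        # nearest voxel, with each mask voxel covering +-0.5 around its center
        nearest = np.round(coords).astype(np.int64)
        inside = np.all(
            (coords >= -0.5) & (coords <= np.asarray(mask.mask.shape) - 0.5), axis=1
        )
        nearest = np.clip(nearest, 0, np.asarray(mask.mask.shape) - 1)
        resampled = np.zeros(len(coords), dtype=bool)
        resampled[inside] = mask.mask[tuple(nearest[inside].T)]
        resampled = resampled.reshape(map_grid.shape)
    if not resampled.any():
        import warnings

        warnings.warn("cortical mask is empty after resampling", stacklevel=2)
    values = np.where(resampled, m.values, np.nan)
    return MDTMap(
        values=values,
        valid=m.valid & resampled,
        affine=m.affine,
        b_pair=m.b_pair,
        window=m.window,
    )


def render_window(
    m: MDTMap, lo: Optional[float] = None, hi: Optional[float] = None
) -> np.ndarray:
    """Window a diffusivity map into [0, 1] for display.

    ``(clamp(v, lo, hi) - lo) / (hi - lo)``; invalid voxels render as 0
    (dark), which is what makes suppressed CSF appear black next to tissue
    within the default 0.5-0.9 um^2/ms window.
    """
    lo = m.window[0] if lo is None else lo
    hi = m.window[1] if hi is None else hi
    if lo >= hi:
        raise ValueError(f"window lo must be < hi, got ({lo}, {hi})")
    out = np.zeros(m.values.shape)
    v = np.clip(m.values[m.valid], lo, hi)
    out[m.valid] = (v - lo) / (hi - lo)
    return out


def pv_bias_report(
    phantom_or_csf,
    mdt: MDTMap,
    adc: MDTMap,
    truth: Optional[np.ndarray] = None,
    truth_valid: Optional[np.ndarray] = None,
    bins: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """CSF-fraction-stratified bias/RMSE of MDT and ADC vs tissue truth.

    The first argument is either a :class:`PhantomVolume` (CSF fractions and
    ground truth are taken from it) or a CSF-fraction array, in which case
    ``truth``/``truth_valid`` must be given. All inputs must share one grid.
    For each CSF-fraction bin the mean signed bias and RMSE of both
    estimators against the CSF-excluded ground-truth tissue diffusivity are
    tabulated; empty bins are reported with a zero count and NaN statistics.
    """
    if isinstance(phantom_or_csf, PhantomVolume):
        from .phantom import ground_truth_tissue_md

        csf_fraction = phantom_or_csf.csf_fraction()
        if truth is None:
            truth, truth_valid = ground_truth_tissue_md(phantom_or_csf)
    else:
        csf_fraction = np.asarray(phantom_or_csf, dtype=float)
        if truth is None or truth_valid is None:
            raise ValueError("truth and truth_valid required with array input")
    shapes = {csf_fraction.shape, mdt.values.shape, adc.values.shape, truth.shape}
    if len(shapes) != 1:
        raise ValueError("all volumes must be grid-matched")
    rows = []
    base_valid = mdt.valid & adc.valid & np.asarray(truth_valid, dtype=bool)
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = base_valid & (csf_fraction > lo if lo > 0 else csf_fraction >= lo)
        sel &= csf_fraction <= hi
        n = int(sel.sum())
        if n:
            mdt_err = mdt.values[sel] - truth[sel]
            adc_err = adc.values[sel] - truth[sel]
            row = {
                "mdt_bias": float(mdt_err.mean()),
                "mdt_rmse": float(np.sqrt((mdt_err**2).mean())),
                "adc_bias": float(adc_err.mean()),
                "adc_rmse": float(np.sqrt((adc_err**2).mean())),
            }
        else:
            row = {k: np.nan for k in ("mdt_bias", "mdt_rmse", "adc_bias", "adc_rmse")}
        rows.append({"csf_lo": lo, "csf_hi": hi, "n_voxels": n, **row})
    return pd.DataFrame(rows)
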