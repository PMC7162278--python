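"""Two-compartment decomposition of CT volumes.

A voxel of lung (or lung-equivalent phantom) is modelled as a mixture of
two submaterials with known CT numbers — air and a representative dense
material (muscle, blood, or polyurethane).  Because the CT number of a
mixture is, to first order, the volume-weighted mean of its components,
the air volume fraction of a voxel with CT number ``HU`` is

    f_air = (HU - HU_high) / (HU_low - HU_high)

where ``HU_high`` is the CT number of the dense material and ``HU_low``
that of air.  The decomposition is affine in HU, so any normalised linear
blurring of the image (the partial volume effect) leaves the *sum* of the
fractions over a region unchanged: total air volume estimated this way is
insensitive to spatial resolution, unlike threshold segmentation.

This module holds the grid containers (:class:`HUVolume`,
:class:`FractionMap`), the calibration (:class:`Calibration`), ROI
statistics, and the fraction/volume/mass arithmetic.  All grids are
indexed ``(z, y, x)`` with per-axis spacing in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HUVolume",
    "Calibration",
    "RoiSpec",
    "FractionMap",
    "measure_roi_hu",
    "hu_to_fraction",
    "raw_fraction",
    "fraction_to_hu",
    "fraction_volume",
    "fraction_mass",
]


def _check_grid(values: np.ndarray, spacing) -> tuple[np.ndarray, tuple[float, float, float]]:
    values = np.asarray(values)
    if values.ndim != 3 or values.size == 0:
        raise ValueError("grid must be a non-empty 3-D array")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths (mm), got {spacing}")
    return values, spacing


@dataclass
class HUVolume:
    """A 3-D grid of CT numbers (Hounsfield units).

    Parameters
    ----------
    values
        CT numbers, shape ``(nz, ny, nx)``. Must be finite.
    spacing
        Voxel size in mm, order ``(z, y, x)``.
    provenance
        Free-text origin tag (scanner model, or "simulated").
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values, self.spacing = _check_grid(self.values, self.spacing)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class FractionMap:
    """Per-voxel volume fraction of one submaterial, in ``[0, 1]``.

    ``fraction_of`` names the stored submaterial: "air" gives the AV/TV
    map, "PU" the polyurethane fraction of a foam phantom.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    fraction_of: str = "air"

    def __post_init__(self) -> None:
        self.values, self.spacing = _check_grid(self.values, self.spacing)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("fractions must lie in [0, 1]; clip upstream")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class Calibration:
    """CT numbers of the two submaterials of the decomposition.

    ``hu_high`` is the dense material (representative tissue or PU),
    ``hu_low`` is air.  ``labels`` names them, high material first.
    """

    hu_high: float
    hu_low: float
    labels: tuple[str, str] = ("tissue", "air")

    def __post_init__(self) -> None:
        if self.hu_high == self.hu_low:
            raise ValueError("degenerate calibration: hu_high == hu_low")
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be below hu_high")



@dataclass(frozen=True)
class RoiSpec:
    """A geometric region of interest for calibration measurements.

    ``center`` is a 0-based voxel-index coordinate ``(z, y, x)``
    (fractional values place the centre between voxels); ``extent`` is
    the radius (sphere/cylinder) or half-widths (box) in mm.  A cylinder
    has its axis along z with ``extent = (radius_mm, half_height_mm)``.
    Membership is by voxel-centre inclusion; the ROI must lie entirely
    inside the grid.
    """

    shape: str
    center: tuple[float, float, float]
    extent: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "box"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if any(e <= 0 for e in self.extent):
            raise ValueError("ROI extent must be positive")

    def mask(self, volume: HUVolume) -> np.ndarray:
        """Boolean membership mask on the volume's grid."""
        nz, ny, nx = volume.shape
        sz, sy, sx = volume.spacing
        cz, cy, cx = self.center
        if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"ROI center {self.center} outside grid {volume.shape}")
        z = (np.arange(nz) - cz)[:, None, None] * sz
        y = (np.arange(ny) - cy)[None, :, None] * sy
        x = (np.arange(nx) - cx)[None, None, :] * sx
        if self.shape == "sphere":
            (r,) = self.extent
            self._check_inside(volume, (r, r, r))
            return z * z + y * y + x * x <= r * r
        if self.shape == "cylinder":
            r, hh = self.extent
            self._check_inside(volume, (hh, r, r))
            return (y * y + x * x <= r * r) & (np.abs(z) <= hh)
        hz, hy, hx = self.extent
        self._check_inside(volume, (hz, hy, hx))
        return (np.abs(z) <= hz) & (np.abs(y) <= hy) & (np.abs(x) <= hx)

    def _check_inside(self, volume: HUVolume, half_mm: tuple[float, float, float]) -> None:
        # ROI must lie entirely inside the grid (in physical coordinates)
        for c, n, s, h in zip(self.center, volume.shape, volume.spacing, half_mm):
            lo = c * s - h
            hi = c * s + h
            if lo < -s / 2 or hi > (n - 0.5) * s:
                raise ValueError(
                    f"ROI {self.label or self.shape} extends outside the grid "
                    f"(center {self.center}, extent {self.extent} mm)"
                )


def measure_roi_hu(volume: HUVolume, roi: RoiSpec) -> tuple[float, float, int]:
    """Mean and sample SD of the CT numbers inside an ROI.

    Returns ``(mean_hu, sd_hu, n_voxels)``.  SD uses the n-1 convention;
    it is 0.0 for a single-voxel ROI.
    """
    sel = volume.values[roi.mask(volume)]
    if sel.size == 0:
        raise ValueError("ROI contains no voxel centers")
    mean = float(sel.mean())
    sd = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    return mean, sd, int(sel.size)


def hu_to_fraction(volume: HUVolume, cal: Calibration, material: str = "low") -> FractionMap:
    """Convert CT numbers to the volume fraction of one submaterial.

    With ``material="low"`` (the default) and an air/tissue calibration
    this is the AV/TV map: ``f = (HU - hu_high) / (hu_low - hu_high)``,
    clipped to [0, 1].  ``material="high"`` swaps the roles and yields
    ``1 - f`` (the PU fraction of a foam scan, say).  The number of
    clipped voxels and the raw range are logged at INFO.
    :func:`raw_fraction` gives the unclipped array for conservation
    analyses.
    """
    raw = raw_fraction(volume.values, cal, material)
    n_low = int(np.count_nonzero(raw < 0.0))
    n_high = int(np.count_nonzero(raw > 1.0))
    if n_low or n_high:
        logger.info(
            "hu_to_fraction: clipped %d voxels below 0 and %d above 1 "
            "(raw range %.4f..%.4f)",
            n_low, n_high, float(raw.min()), float(raw.max()),
        )
    label = cal.labels[1] if material == "low" else cal.labels[0]
    return FractionMap(np.clip(raw, 0.0, 1.0), volume.spacing, fraction_of=label)


def raw_fraction(hu: np.ndarray, cal: Calibration, material: str = "low") -> np.ndarray:
    """Unclipped two-compartment fraction of one submaterial (default: the
    low/air material)."""
    f_low = (np.asarray(hu, dtype=np.float64) - cal.hu_high) / (cal.hu_low - cal.hu_high)
    if material == "low":
        return f_low
    if material == "high":
        return 1.0 - f_low
    raise ValueError("material must be 'low' or 'high'")


def fraction_to_hu(fractions: np.ndarray, cal: Calibration) -> np.ndarray:
    """Inverse map: HU = f * hu_low + (1 - f) * hu_high."""
    f = np.asarray(fractions, dtype=np.float64)
    return f * cal.hu_low + (1.0 - f) * cal.hu_high


def fraction_volume(fmap: FractionMap, mask: np.ndarray | None = None) -> float:
    """Total submaterial volume in cm^3: sum of fractions x voxel volume."""
    values = fmap.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(f"mask shape {mask.shape} != map shape {values.shape}")
        values = values[mask]
    return float(values.sum(dtype=np.float64)) * fmap.voxel_volume_mm3 / 1000.0


def fraction_mass(fmap: FractionMap, density_g_cm3: float, mask: np.ndarray | None = None) -> float:
    """Submaterial mass in grams: fraction volume (cm^3) x density (g/cm^3)."""
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    return fraction_volume(fmap, mask) * density_g_cm3
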