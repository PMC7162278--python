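"""Relative air volume histogram (RAVH) and COPD image biomarkers.

The RAVH summarises the per-voxel air volume fraction (AV/TV) of the
lung as a 40-bin histogram with bin centroids 1.25%..98.75% in steps of
2.5%, each bin expressed as a percent of total lung volume.  Healthy
parenchyma concentrates around the 88.75% bin; emphysematous air spaces
and trapped air pile up in the top (98.75%) bin.  The derived
biomarkers:

- ``mean_avtv`` — mean AV/TV over the lung, percent;
- ``rv_nl``     — relative volume of "normal lung": sum of the bins
  centred 81.25..91.25%;
- ``rv_dl``     — relative volume of "damaged lung": the 98.75% bin;
- ``r_dl_nl``   — the damaged-to-normal ratio;
- ``pe_910``, ``pe_950`` — comparator percent-emphysema values from
  fixed CT-number thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import FractionMap, HUVolume
from .segment import BinaryMask, percent_emphysema

logger = logging.getLogger(__name__)

__all__ = ["RAVH", "BiomarkerSet", "compute_ravh", "compute_biomarkers", "group_mean_ravh",
           "BIN_CENTERS", "NORMAL_LUNG_BINS", "DAMAGED_LUNG_BIN"]

N_BINS = 40
BIN_WIDTH = 2.5  # percent AV/TV
#: Bin centroids in percent AV/TV: 1.25, 3.75, ..., 98.75.
BIN_CENTERS = np.arange(N_BINS) * BIN_WIDTH + BIN_WIDTH / 2.0
#: Indices of the bins centred 81.25..91.25% (normal lung).
NORMAL_LUNG_BINS = tuple(range(32, 37))
#: Index of the 98.75% bin (damaged lung / trapped air).
DAMAGED_LUNG_BIN = 39


@dataclass
class RAVH:
    """40-bin relative air volume histogram (percent of lung volume)."""

    relative_volumes: np.ndarray
    n_voxels: int
    bin_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())

    def __post_init__(self) -> None:
        self.relative_volumes = np.asarray(self.relative_volumes, dtype=np.float64)
        if self.relative_volumes.shape != (N_BINS,):
            raise ValueError(f"RAVH needs exactly {N_BINS} bins")
        if np.any(self.relative_volumes < 0):
            raise ValueError("relative volumes must be non-negative")
        total = self.relative_volumes.sum()
        if not math.isclose(total, 100.0, rel_tol=1e-9):
            raise ValueError(f"relative volumes must sum to 100%, got {total!r}")

    def rv(self, bin_index: int) -> float:
        return float(self.relative_volumes[bin_index])


@dataclass
class BiomarkerSet:
    """The six image biomarkers for one subject or phantom (percent units,
    except the dimensionless ``r_dl_nl``)."""

    mean_avtv: float
    pe_910: float
    pe_950: float
    rv_nl: float
    rv_dl: float
    r_dl_nl: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_avtv": self.mean_avtv,
            "pe_910": self.pe_910,
            "pe_950": self.pe_950,
            "rv_nl": self.rv_nl,
            "rv_dl": self.rv_dl,
            "r_dl_nl": self.r_dl_nl,
        }


def compute_ravh(fmap: FractionMap, mask: BinaryMask | np.ndarray) -> RAVH:
    """Histogram the masked AV/TV values into the 40 standard bins.

    Bin k covers [2.5k, 2.5(k+1)) percent, half-open, with the last bin
    closed at 100% (a voxel of exactly 100% AV/TV lands in the 98.75%
    bin).  Relative volume is the voxel-count fraction, valid for the
    uniform grid of a single scan.
    """
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != fmap.shape:
        raise ValueError("mask and fraction map shapes differ")
    f = fmap.values[m]
    if f.size == 0:
        raise ValueError("empty mask")
    idx = np.minimum((f * 100.0 / BIN_WIDTH).astype(np.int64), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(np.float64)
    return RAVH(100.0 * counts / f.size, n_voxels=int(f.size))


def compute_biomarkers(
    fmap: FractionMap,
    hu: HUVolume,
    mask: BinaryMask | np.ndarray,
) -> BiomarkerSet:
    """All six biomarkers from aligned AV/TV map, HU volume and lung mask.

    ``r_dl_nl`` is reported as ``inf`` (with a warning) when the
    normal-lung relative volume is zero, preserving the ordering of
    extreme disease-like cases.
    """
    if isinstance(mask, np.ndarray):
        mask = BinaryMask(mask, fmap.spacing, semantics="lung minus airways")
    if fmap.shape != hu.shape or fmap.shape != mask.shape:
        raise ValueError("fraction map, HU volume and mask must be aligned")
    ravh = compute_ravh(fmap, mask)
    rv_nl = float(ravh.relative_volumes[list(NORMAL_LUNG_BINS)].sum())
    rv_dl = ravh.rv(DAMAGED_LUNG_BIN)
    if rv_nl > 0:
        r_dl_nl = rv_dl / rv_nl
    else:
        logger.warning("rv_nl is zero; reporting r_dl_nl as +inf")
        r_dl_nl = math.inf
    return BiomarkerSet(
        mean_avtv=float(fmap.values[mask.values].mean() * 100.0),
        pe_910=percent_emphysema(hu, mask, -910.0),
        pe_950=percent_emphysema(hu, mask, -950.0),
        rv_nl=rv_nl,
        rv_dl=rv_dl,
        r_dl_nl=r_dl_nl,
    )


def group_mean_ravh(ravhs: list[RAVH]) -> RAVH:
    """Per-bin arithmetic mean of a group of RAVHs (still sums to 100%)."""
    if not ravhs:
        raise ValueError("need at least one RAVH")
    mean_rv = np.mean([r.relative_volumes for r in ravhs], axis=0)
    return RAVH(mean_rv, n_voxels=int(sum(r.n_voxels for r in ravhs)))
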