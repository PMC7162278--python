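"""Threshold segmentation, lung masking and airway removal.

The comparator methods for emphysema quantification segment air-like
voxels by a fixed CT-number threshold (classically -850 to -950 HU) or by
Otsu's histogram criterion.  The lung mask itself is built from the
air-volume-fraction (AV/TV) map: everything with more than ~1% air that
is not exterior air, keeping the largest connected components.  The
trachea and proximal bronchi — pure air, AV/TV ~= 1 — are removed by
region growing from a seed in the trachea with a 95% AV/TV stopping
criterion, so that percent-emphysema and histogram biomarkers are
computed on parenchyma only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FractionMap, HUVolume

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "AirwaySeed",
    "threshold_segment",
    "otsu_threshold",
    "lung_mask",
    "remove_airways",
    "find_trachea_seed",
    "percent_emphysema",
]

#: 6-connected (face-neighbour) structuring element; conservative against
#: diagonal leakage through partial-volume-blurred interfaces.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class BinaryMask:
    """A boolean grid plus what "true" means (lung, airway, air cavity...)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    semantics: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def volume_cm3(self) -> float:
        return float(np.count_nonzero(self.values)) * float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class AirwaySeed:
    """Seed voxel in the trachea and the minimum AV/TV for region growth."""

    position: tuple[int, int, int]
    criterion: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.criterion <= 1.0):
            raise ValueError("criterion must be in (0, 1]")


def threshold_segment(volume: HUVolume, threshold: float, polarity: str = "below") -> BinaryMask:
    """Binary segmentation at a fixed CT-number threshold.

    ``polarity="below"`` marks voxels with HU strictly below the
    threshold (air-like); ``"above"`` marks HU strictly above (solid).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if polarity == "below":
        values = volume.values < threshold
    elif polarity == "above":
        values = volume.values > threshold
    else:
        raise ValueError(f"polarity must be 'below' or 'above', got {polarity!r}")
    return BinaryMask(values, volume.spacing, semantics=f"HU {polarity} {threshold:g}")


def otsu_threshold(volume: HUVolume, mask: np.ndarray | None = None) -> float:
    """Otsu's threshold on the integer-HU histogram of a (masked) volume.

    The histogram uses bins of width 1 HU centred on integers.  Candidate
    cuts lie between consecutive *occupied* bins; the cut maximising the
    between-class variance is returned as the midpoint of the two bin
    centres it separates (hence half-integral values on real CT data);
    ties break toward the lowest threshold.  Raises on a constant region,
    where no threshold separates anything.
    """
    hu = volume.values if mask is None else volume.values[np.asarray(mask, dtype=bool)]
    hu = np.round(hu.ravel()).astype(np.int64)
    centers, counts = np.unique(hu, return_counts=True)
    if centers.size < 2:
        raise ValueError("constant region: Otsu threshold undefined")
    centers = centers.astype(np.float64)
    counts = counts.astype(np.float64)

    # between-class variance for every cut between occupied bins i and i+1
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    sigma_b = w0 * w1 * (m0 / w0 - m1 / w1) ** 2
    i = int(np.argmax(sigma_b))  # argmax returns the first (lowest) tie
    return float((centers[i] + centers[i + 1]) / 2.0)


def _largest_components(mask: np.ndarray, keep: int, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1][:keep] + 1
    logger.info("component sizes (voxels): %s; keeping %d", np.sort(sizes)[::-1][:5], len(order))
    return np.isin(labels, order)


def lung_mask(
    fmap: FractionMap,
    body_threshold: float = 0.01,
    *,
    keep_components: int = 2,
    exterior_threshold: float = 0.95,
    connectivity: int = 6,
) -> BinaryMask:
    """Segment the lungs from an AV/TV map.

    Exterior air — connected components of fraction > ``exterior_threshold``
    touching the grid boundary — is removed first; within the remaining
    body, voxels with AV/TV > ``body_threshold`` (default 1%) are lung
    candidates, of which the ``keep_components`` largest connected
    components (default two, the anatomical lungs) are retained.
    """
    structure = STRUCT_6 if connectivity == 6 else STRUCT_26
    f = fmap.values

    exterior = np.zeros(f.shape, dtype=bool)
    high = f > exterior_threshold
    labels, n = ndimage.label(high, structure=structure)
    if n:
        border = np.unique(np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ]))
        border = border[border > 0]
        if border.size:
            exterior = np.isin(labels, border)

    candidates = (f > body_threshold) & ~exterior
    lungs = _largest_components(candidates, keep_components, structure)
    if not lungs.any():
        raise ValueError("no lung candidate component found")
    return BinaryMask(lungs, fmap.spacing, semantics="lung")


def remove_airways(
    fmap: FractionMap,
    lungs: BinaryMask,
    seed: AirwaySeed,
    *,
    connectivity: int = 6,
) -> BinaryMask:
    """Subtract the trachea and connected bronchi from a lung mask.

    Region-grows (default 6-connectivity) from the seed over voxels with
    AV/TV >= the seed's criterion (default 0.95) — anywhere on the grid,
    since the trachea lies outside the lung components — and removes the
    grown region from the lung mask.  Note any near-pure-air region
    connected to the airway tree above the criterion (e.g. a large bulla
    opening into a bronchus) is removed with it.
    """
    if fmap.shape != lungs.shape:
        raise ValueError("fraction map and lung mask shapes differ")
    z, y, x = seed.position
    if fmap.values[z, y, x] < seed.criterion:
        raise ValueError(
            f"seed AV/TV {fmap.values[z, y, x]:.3f} below criterion {seed.criterion}"
        )
    structure = STRUCT_6 if connectivity == 6 else STRUCT_26
    growable = fmap.values >= seed.criterion
    labels, _ = ndimage.label(growable, structure=structure)
    airway = labels == labels[z, y, x]
    removed_cm3 = float(np.count_nonzero(airway & lungs.values)) * float(np.prod(fmap.spacing)) / 1000.0
    logger.info("remove_airways: removed %.2f cm^3 from the lung mask", removed_cm3)
    return BinaryMask(lungs.values & ~airway, lungs.spacing, semantics="lung minus airways")


def find_trachea_seed(
    fmap: FractionMap,
    *,
    n_slices: int = 10,
    min_fraction: float = 0.99,
    criterion: float = 0.95,
) -> AirwaySeed:
    """Locate a trachea seed automatically.

    Scans the ``n_slices`` most superior axial slices (lowest z indices)
    for in-plane connected components of AV/TV >= ``min_fraction`` that
    do not touch the slice border (the trachea is the only round,
    near-pure-air structure inside the body there), picks the roundest
    one — smallest normalised second moment of its pixel scatter — and
    seeds at the voxel nearest its centroid.  A manually supplied seed
    always takes precedence over this heuristic.
    """
    best = None  # (roundness, z, y, x)
    for z in range(min(n_slices, fmap.shape[0])):
        plane = fmap.values[z] >= min_fraction
        labels, n = ndimage.label(plane)
        for lab in range(1, n + 1):
            ys, xs = np.nonzero(labels == lab)
            if (ys.min() == 0 or xs.min() == 0
                    or ys.max() == plane.shape[0] - 1 or xs.max() == plane.shape[1] - 1):
                continue  # touches the border: exterior air, not trachea
            # normalised second moment: pi/2 * E[r^2] / area is 1 for a disk
            r2 = (ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2
            roundness = 2.0 * np.pi * r2.mean() / ys.size
            i = int(np.argmin(r2))
            cand = (roundness, z, int(ys[i]), int(xs[i]))
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        raise ValueError("no candidate trachea component in the superior slices")
    _, z, y, x = best
    return AirwaySeed((z, y, x), criterion)


def percent_emphysema(volume: HUVolume, lungs_no_airways: BinaryMask, threshold: float) -> float:
    """Percent of lung voxels with HU strictly below the threshold.

    The classical low-attenuation-area metric (PE_-910, PE_-950),
    computed after airway removal.
    """
    mask = lungs_no_airways.values
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty lung mask")
    n_low = int(np.count_nonzero(volume.values[mask] < threshold))
    return 100.0 * n_low / n
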