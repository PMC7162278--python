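"""Digital lung-equivalent phantoms and a desk-scale CT simulator.

Two phantom families mirror the physical validation objects used for
two-compartment lung densitometry:

* **Cavity phantoms** — polyurethane (PU) boxes whose interior is divided
  by thin septa into air cavities of width comparable to the CT voxel,
  emulating emphysematous air spaces.  Five printed geometries (septa
  3/2/0.7/0.7/1 mm, cavity widths 1.9/2/2.8/3/4 mm, 4/4/8/6/4 cavities)
  probe the partial volume effect at the cavity/septum scale.

* **Foam phantoms** — PU foams of 10/20/60 pores per inch (pore spacing
  25.4/PPI mm), emulating alveoli and sub-voxel air spaces.  The digital
  stand-in is an orthogonal strut lattice whose strut radius is solved on
  the generated grid so the realized solid fraction equals
  ``mass / (density x cube volume)``.  The lattice is tilted relative to
  the reconstruction axes so that strut planes sweep several lattice
  periods across the block, giving the z-homogeneous per-slice mass that
  a real (random) foam has; an axis-aligned lattice would concentrate
  two thirds of its mass in discrete planes.

Ground truth is always the voxel count of the generated high-resolution
occupancy grid — exact by construction — never the printed volumes of
the physical phantoms.

The CT simulator maps occupancy to CT numbers (volume-weighted mix of
the air and solid HU), applies an in-plane Gaussian point-spread
function, box-averages to the reconstruction grid and slice thickness,
and optionally adds Gaussian HU noise; it is deterministic given the
scene, the configuration and the seed.

:func:`generate_cohort` draws synthetic parenchymal AV/TV samples for
control-like (unimodal around the 88.75% histogram bin) and COPD-like
(added near-100% trapped-air component) subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import FractionMap, HUVolume
from .segment import BinaryMask

__all__ = [
    "CavityPhantomSpec",
    "FoamSpec",
    "PhantomScene",
    "CTSimConfig",
    "CAVITY_SPECS",
    "FOAM_SPECS",
    "SLICE_THICKNESSES_MM",
    "build_cavity_phantom",
    "build_foam_phantom",
    "simulate_ct",
    "simulate_ct_multi",
    "recon_axis_centers",
    "fractional_mass",
    "generate_cohort",
]

#: Slice thicknesses of the multiplanar foam reconstructions (mm).
SLICE_THICKNESSES_MM = (0.47, 0.94, 1.88, 2.82, 4.7)


@dataclass(frozen=True)
class CavityPhantomSpec:
    """Geometry of one cavity phantom.

    ``n_cavities`` cavities of width ``cavity_width`` (mm) separated by
    septa of width ``septum_width`` (mm) partition the interior along x;
    each cavity spans ``interior_height`` (y) by ``interior_depth`` (z).
    Walls and caps of ``wall_thickness`` enclose the interior.
    ``outer_dims`` (x, y, z, mm) is derived from the layout when None;
    an explicit value that cannot hold the layout raises.
    """

    septum_width: float
    cavity_width: float
    n_cavities: int
    wall_thickness: float = 5.0
    interior_height: float = 20.0
    interior_depth: float = 20.0
    outer_dims: tuple[float, float, float] | None = None
    labels: tuple[str, str] = ("PU", "air")

    def __post_init__(self) -> None:
        for name in ("septum_width", "cavity_width", "wall_thickness",
                     "interior_height", "interior_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cavities < 1:
            raise ValueError("need at least one cavity")
        if self.outer_dims is not None:
            ox, oy, oz = self.outer_dims
            if ox < self.layout_width + 2 * self.wall_thickness - 1e-9:
                raise ValueError(
                    f"cavities + septa ({self.layout_width:.2f} mm) exceed the inner "
                    f"width of outer_dims {self.outer_dims} with "
                    f"{self.wall_thickness} mm walls"
                )
            if (oy < self.interior_height + 2 * self.wall_thickness - 1e-9
                    or oz < self.interior_depth + 2 * self.wall_thickness - 1e-9):
                raise ValueError("outer_dims cannot hold the interior plus walls")

    @property
    def layout_width(self) -> float:
        """Extent of the cavity/septum partition along x (mm)."""
        return self.n_cavities * self.cavity_width + (self.n_cavities - 1) * self.septum_width

    @property
    def derived_outer_dims(self) -> tuple[float, float, float]:
        if self.outer_dims is not None:
            return self.outer_dims
        w = 2 * self.wall_thickness
        return (self.layout_width + w, self.interior_height + w, self.interior_depth + w)

    @property
    def analytic_air_volume_cm3(self) -> float:
        """Continuum air volume of the layout (cross-check only; grid
        ground truth is authoritative)."""
        return (self.n_cavities * self.cavity_width
                * self.interior_height * self.interior_depth) / 1000.0


#: The five printed cavity geometries (septum width, cavity width, count).
CAVITY_SPECS = (
    CavityPhantomSpec(septum_width=3.0, cavity_width=1.9, n_cavities=4),
    CavityPhantomSpec(septum_width=2.0, cavity_width=2.0, n_cavities=4),
    CavityPhantomSpec(septum_width=0.7, cavity_width=2.8, n_cavities=8),
    CavityPhantomSpec(septum_width=0.7, cavity_width=3.0, n_cavities=6),
    CavityPhantomSpec(septum_width=1.0, cavity_width=4.0, n_cavities=4),
)


@dataclass(frozen=True)
class FoamSpec:
    """A cubic PU foam phantom modelled as a tilted orthogonal strut lattice.

    The lattice spacing is ``25.4 / ppi`` mm (the pore size); the strut
    radius is solved on the generated grid so the realized solid volume
    fraction equals ``total_mass_g / (pu_density x side^3)``.  ``tilt_deg``
    rotates the lattice about the two in-plane axes; ``jitter`` (fraction
    of the spacing, with ``jitter_seed``) randomises per-cell strut
    positions.
    """

    ppi: int
    total_mass_g: float
    side_mm: float = 50.0
    pu_density_g_cm3: float = 1.12
    tilt_deg: tuple[float, float] = (11.0, 6.0)
    jitter: float = 0.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if self.ppi <= 0 or self.total_mass_g <= 0 or self.side_mm <= 0 or self.pu_density_g_cm3 <= 0:
            raise ValueError("ppi, mass, side and density must be positive")
        if not (0.0 < self.target_fraction < 0.1):
            raise ValueError(
                f"implied PU volume fraction {self.target_fraction:.4f} outside (0, 0.1)"
            )
        if self.lattice_spacing_mm >= self.side_mm:
            raise ValueError("lattice spacing must be below the cube side")
        if not (0.0 <= self.jitter <= 0.4):
            raise ValueError("jitter must be in [0, 0.4] lattice spacings")

    @property
    def lattice_spacing_mm(self) -> float:
        return 25.4 / self.ppi

    @property
    def target_fraction(self) -> float:
        """PU volume fraction implied by mass, density and cube volume."""
        volume_cm3 = (self.side_mm / 10.0) ** 3
        return self.total_mass_g / (self.pu_density_g_cm3 * volume_cm3)

    @property
    def analytic_strut_radius_mm(self) -> float:
        """Thin-strut estimate r = a sqrt(f / 3 pi); the grid solve refines it."""
        return self.lattice_spacing_mm * math.sqrt(self.target_fraction / (3.0 * math.pi))


#: The three printed foams: 10/20/60 PPI with masses 2.82/3.02/2.67 g.
FOAM_SPECS = (
    FoamSpec(ppi=10, total_mass_g=2.82),
    FoamSpec(ppi=20, total_mass_g=3.02),
    FoamSpec(ppi=60, total_mass_g=2.67),
)


@dataclass
class PhantomScene:
    """High-resolution binary material map with exact ground truth.

    ``material_map`` is True where solid (PU); ``resolution_mm`` is the
    isotropic grid step.  ``ground_truth`` holds the exact solid/air
    volumes (cm^3) counted on this grid, plus the solid mass when a
    density is known.
    """

    material_map: np.ndarray
    resolution_mm: float
    ground_truth: dict[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        self.material_map = np.asarray(self.material_map, dtype=bool)
        if self.material_map.ndim != 3:
            raise ValueError("material map must be 3-D")
        if self.resolution_mm <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_map.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        r = self.resolution_mm
        return (r, r, r)


@dataclass(frozen=True)
class CTSimConfig:
    """Acquisition/reconstruction parameters of the simulated scan.

    ``psf_fwhm_mm`` is the in-plane Gaussian point spread; ``recon_spacing_mm``
    the output voxel pitch (z, y, x); ``slice_thickness_mm`` the z
    box-averaging width (defaults to the z pitch); ``noise_sd_hu`` additive
    Gaussian HU noise seeded by ``seed``; ``pad_mm`` surrounds the scene
    with air before blurring (exterior air of a real scan).
    """

    hu_solid: float = 113.4
    hu_air: float = -999.5
    psf_fwhm_mm: float = 0.6
    recon_spacing_mm: tuple[float, float, float] = (0.47, 0.47, 0.47)
    slice_thickness_mm: float | None = None
    noise_sd_hu: float = 0.0
    seed: int = 0
    pad_mm: float = 0.0
    boundary: str = "nearest"

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0 or self.noise_sd_hu < 0 or self.pad_mm < 0:
            raise ValueError("psf_fwhm, noise_sd and pad must be non-negative")
        if self.boundary not in ("nearest", "wrap"):
            raise ValueError("boundary must be 'nearest' or 'wrap'")
        if any(s <= 0 for s in self.recon_spacing_mm):
            raise ValueError("recon spacing must be positive")
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def effective_slice_thickness_mm(self) -> float:
        return self.slice_thickness_mm if self.slice_thickness_mm is not None else self.recon_spacing_mm[0]


# ---------------------------------------------------------------------------
# cavity phantoms

def build_cavity_phantom(spec: CavityPhantomSpec, resolution_mm: float) -> PhantomScene:
    """Rasterise a cavity phantom onto an isotropic grid.

    The grid covers exactly the phantom's outer box; voxels are solid PU
    except where their centre falls inside a cavity.  Requires at least
    4 grid samples across the thinnest septum.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    if spec.septum_width / resolution_mm < 4 or spec.cavity_width / resolution_mm < 4:
        raise ValueError(
            f"resolution {resolution_mm} mm does not resolve the septa/cavities "
            f"({spec.septum_width}/{spec.cavity_width} mm; need >= 4 samples)"
        )
    ox, oy, oz = spec.derived_outer_dims
    h = resolution_mm
    nx, ny, nz = (int(round(d / h)) for d in (ox, oy, oz))
    solid = np.ones((nz, ny, nx), dtype=bool)

    # voxel-centre coordinates along each axis
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h
    w = spec.wall_thickness
    in_y = (yc >= w) & (yc <= w + spec.interior_height)
    in_z = (zc >= w) & (zc <= w + spec.interior_depth)
    x0 = (ox - spec.layout_width) / 2.0  # layout centred in x
    in_cavity_x = np.zeros(nx, dtype=bool)
    for i in range(spec.n_cavities):
        lo = x0 + i * (spec.cavity_width + spec.septum_width)
        in_cavity_x |= (xc >= lo) & (xc <= lo + spec.cavity_width)
    solid[np.ix_(in_z, in_y, in_cavity_x)] = False

    return PhantomScene(
        solid, h, _ground_truth(solid, h, density=1.169),
        description=(f"cavity phantom: {spec.n_cavities} x {spec.cavity_width} mm cavities, "
                     f"{spec.septum_width} mm septa"),
    )


def _ground_truth(solid: np.ndarray, resolution_mm: float, density: float | None = None) -> dict[str, float]:
    vox_cm3 = resolution_mm ** 3 / 1000.0
    n_solid = int(np.count_nonzero(solid))
    gt = {
        "solid_volume_cm3": n_solid * vox_cm3,
        "air_volume_cm3": (solid.size - n_solid) * vox_cm3,
    }
    if density is not None:
        gt["solid_mass_g"] = gt["solid_volume_cm3"] * density
    return gt


# ---------------------------------------------------------------------------
# foam phantoms

def _rotation_matrix(tilt_deg: tuple[float, float]) -> np.ndarray:
    ax, ay = (math.radians(t) for t in tilt_deg)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    return ry @ rx


def _lattice_distance(points_xyz: np.ndarray, a: float, jitter: float, rng_tables) -> np.ndarray:
    """Distance from lab-frame points (n, 3) to the nearest lattice line.

    Lines run along each lattice axis at transverse positions that are
    integer multiples of ``a`` (plus optional per-cell jitter).  With
    jitter only the nearest cell's line is examined — valid for the thin
    struts (r << a) used here.
    """
    d2_min = None
    for axis in range(3):
        t = [0, 1, 2]
        t.remove(axis)
        u, v = points_xyz[:, t[0]], points_xyz[:, t[1]]
        ju = np.round(u / a)
        jv = np.round(v / a)
        du = u - ju * a
        dv = v - jv * a
        if jitter > 0.0:
            tab_u, tab_v = rng_tables[axis]
            m = tab_u.shape[0]
            iu = (ju.astype(np.int64) % m)
            iv = (jv.astype(np.int64) % m)
            du = du - tab_u[iu, iv]
            dv = dv - tab_v[iu, iv]
        d2 = du * du + dv * dv
        d2_min = d2 if d2_min is None else np.minimum(d2_min, d2)
    return np.sqrt(d2_min, dtype=np.float32)


def build_foam_phantom(
    spec: FoamSpec,
    resolution_mm: float,
    region_mm: tuple[float, float, float] | None = None,
) -> PhantomScene:
    """Rasterise a foam block onto an isotropic grid.

    ``region_mm`` (x, y, z) selects a representative sub-block of the
    cube (the pores are uniform by construction, so ground-truth mass
    scales with the block's share of the cube volume); default is the
    full cube.  The strut radius is the quantile of the
    distance-to-lattice field at the target solid fraction, so the
    realized fraction matches the target essentially exactly.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    r0 = spec.analytic_strut_radius_mm
    if resolution_mm > r0 * 1.25:
        raise ValueError(
            f"resolution {resolution_mm} mm does not resolve the ~{r0:.4f} mm strut radius"
        )
    dims = region_mm if region_mm is not None else (spec.side_mm,) * 3
    if any(d <= 0 or d > spec.side_mm + 1e-9 for d in dims):
        raise ValueError("region must be positive and fit inside the cube")
    a = spec.lattice_spacing_mm
    h = resolution_mm
    nx, ny, nz = (int(round(d / h)) for d in dims)
    rot = _rotation_matrix(spec.tilt_deg)

    rng_tables = None
    if spec.jitter > 0.0:
        rng = np.random.default_rng(spec.jitter_seed)
        m = 257  # prime table size; lattice indices wrap pseudo-randomly
        amp = spec.jitter * a
        rng_tables = [
            (rng.uniform(-amp, amp, (m, m)), rng.uniform(-amp, amp, (m, m)))
            for _ in range(3)
        ]

    # distance field, computed per z-slab to bound peak memory
    dist = np.empty((nz, ny, nx), dtype=np.float32)
    xc = (np.arange(nx, dtype=np.float64) + 0.5) * h
    yc = (np.arange(ny, dtype=np.float64) + 0.5) * h
    for iz in range(nz):
        zc = (iz + 0.5) * h
        lab = np.empty((ny * nx, 3))
        lab[:, 0] = np.tile(xc, ny)       # x
        lab[:, 1] = np.repeat(yc, nx)     # y
        lab[:, 2] = zc                    # z
        lattice_frame = lab @ rot  # rot^T applied to row vectors
        dist[iz] = _lattice_distance(lattice_frame, a, spec.jitter, rng_tables).reshape(ny, nx)

    n_target = int(round(spec.target_fraction * dist.size))
    if n_target < 1:
        raise ValueError("target fraction unachievable on this grid")
    flat = dist.ravel()
    radius = float(np.partition(flat, n_target - 1)[n_target - 1])
    solid = dist <= radius
    realized = np.count_nonzero(solid) / solid.size
    if abs(realized - spec.target_fraction) > 0.05 * spec.target_fraction:
        raise ValueError(
            f"realized solid fraction {realized:.5f} deviates more than 5% from "
            f"target {spec.target_fraction:.5f}; refine the resolution"
        )
    return PhantomScene(
        solid, h, _ground_truth(solid, h, density=spec.pu_density_g_cm3),
        description=f"{spec.ppi} PPI foam block {dims[0]}x{dims[1]}x{dims[2]} mm, strut r={radius:.4f} mm",
    )


# ---------------------------------------------------------------------------
# CT simulation

def recon_axis_centers(n_in: int, in_spacing: float, out_pitch: float,
                       width: float) -> np.ndarray:
    """Physical centres (mm) of the reconstruction samples along one axis.

    The sample train is centred within the grid extent; samples whose
    ``width``-mm window would leave the grid are dropped.  Shared by the
    resampler and by analyses that need recon-voxel coordinates.
    """
    extent = n_in * in_spacing
    n_out = int(math.floor((extent - width) / out_pitch + 1e-9)) + 1
    if n_out < 1:
        raise ValueError("box window wider than the grid extent")
    first_center = (extent - (n_out - 1) * out_pitch) / 2.0
    return first_center + out_pitch * np.arange(n_out)


def _box_resample(arr: np.ndarray, axis: int, in_spacing: float,
                  out_pitch: float, width: float) -> np.ndarray:
    """Box-average ``arr`` along ``axis``: output samples at pitch
    ``out_pitch`` (mm), each the mean over a ``width``-mm window.  Exact
    for the piecewise-constant voxel model (integral-image evaluation).
    Output samples whose window would leave the grid are dropped.
    """
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0]
    centers = recon_axis_centers(n, in_spacing, out_pitch, width)
    lo = (centers - width / 2.0) / in_spacing
    hi = (centers + width / 2.0) / in_spacing
    lo = np.clip(lo, 0.0, n)
    hi = np.clip(hi, 0.0, n)

    cum = np.concatenate([np.zeros((1,) + arr.shape[1:], dtype=np.float64),
                          np.cumsum(arr, axis=0, dtype=np.float64)], axis=0)

    def integral(pos: np.ndarray) -> np.ndarray:
        i0 = np.floor(pos).astype(np.int64)
        i0 = np.minimum(i0, n - 1)
        frac = pos - i0
        return cum[i0] + frac.reshape((-1,) + (1,) * (arr.ndim - 1)) * (cum[i0 + 1] - cum[i0])

    out = (integral(hi) - integral(lo)) / ((hi - lo).reshape((-1,) + (1,) * (arr.ndim - 1)))
    return np.moveaxis(out.astype(np.float32), 0, axis)


def simulate_ct(scene: PhantomScene, cfg: CTSimConfig) -> HUVolume:
    """Simulate a CT acquisition of a phantom scene.

    Pipeline: occupancy -> HU mix -> optional air padding -> in-plane
    Gaussian PSF at scene resolution -> box-average resampling to the
    reconstruction pitch (y, x) and slice thickness (z) -> optional
    Gaussian HU noise.  Deterministic given (scene, cfg).  ``boundary``
    selects the blur edge handling: "nearest" (scene embedded in a wider
    field, e.g. air-padded) or "wrap" (scene is a representative periodic
    block; blurring conserves in-plane sums exactly).
    """
    return simulate_ct_multi(scene, cfg, (cfg.effective_slice_thickness_mm,))[
        cfg.effective_slice_thickness_mm
    ]


def simulate_ct_multi(
    scene: PhantomScene,
    cfg: CTSimConfig,
    slice_thicknesses_mm: tuple[float, ...],
) -> dict[float, HUVolume]:
    """Reconstruct one blurred acquisition at several slice thicknesses.

    The expensive in-plane stages (HU mix, PSF, in-plane resampling) run
    once; only the z box-averaging differs per thickness, with the z
    pitch equal to the thickness (contiguous slices).  Returns a dict
    thickness -> HUVolume.
    """
    h = scene.resolution_mm
    sz, sy, sx = cfg.recon_spacing_mm
    if any(s < h - 1e-12 for s in (sy, sx)) or any(t < h - 1e-12 for t in slice_thicknesses_mm):
        raise ValueError("reconstruction spacing finer than the scene resolution")
    hu = scene.material_map.astype(np.float32)
    hu *= (cfg.hu_solid - cfg.hu_air)
    hu += cfg.hu_air
    if cfg.pad_mm > 0:
        npad = int(round(cfg.pad_mm / h))
        hu = np.pad(hu, npad, mode="constant", constant_values=cfg.hu_air)
    if cfg.psf_fwhm_mm > 0:
        sigma_vox = cfg.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / h
        ndimage.gaussian_filter1d(hu, sigma_vox, axis=1, output=hu, mode=cfg.boundary)
        ndimage.gaussian_filter1d(hu, sigma_vox, axis=2, output=hu, mode=cfg.boundary)
    hu = _box_resample(hu, 2, h, sx, sx)
    hu = _box_resample(hu, 1, h, sy, sy)
    out: dict[float, HUVolume] = {}
    for t in slice_thicknesses_mm:
        vol = _box_resample(hu, 0, h, t, t)
        if cfg.noise_sd_hu > 0:
            rng = np.random.default_rng(cfg.seed)
            vol = vol + rng.normal(0.0, cfg.noise_sd_hu, vol.shape).astype(np.float32)
        out[t] = HUVolume(vol.astype(np.float32), (t, sy, sx), provenance="simulated")
    return out


def fractional_mass(spec: FoamSpec, slice_thickness_mm: float) -> float:
    """Reference PU mass of one coronal slice: total mass weighted by the
    slice's share of the cube side."""
    if not (0.0 < slice_thickness_mm <= spec.side_mm):
        raise ValueError("slice thickness must be in (0, side]")
    return spec.total_mass_g * slice_thickness_mm / spec.side_mm


# ---------------------------------------------------------------------------
# synthetic patient cohort

def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Resampling-based truncated normal draw (vectorised)."""
    out = rng.normal(mu, sd, n)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


def generate_cohort(
    n_control: int,
    n_copd: int,
    seed: int,
    *,
    n_voxels: int = 20000,
    control_mean: float = 0.8875,
    control_sd: float = 0.065,
    copd_mean: float = 0.86,
    copd_sd: float = 0.09,
    between_subject_sd: float = 0.015,
    trapped_air_fraction: float = 0.18,
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7),
) -> list[tuple[FractionMap, BinaryMask, str]]:
    """Draw synthetic parenchymal AV/TV samples for a two-group cohort.

    Controls are unimodal: voxel AV/TV ~ Normal(subject mean, sd),
    truncated to [0, 0.975) so the histogram peaks near the 88.75% bin
    with an empty top bin.  COPD subjects mix the same parenchymal
    component with a ``trapped_air_fraction`` share of near-pure-air
    voxels drawn uniformly in [0.98, 1.0) — the damaged-lung signal that
    fills the 98.75% bin.  The truncation makes the injected fraction
    identifiable as RV_DL.  Subject means vary by ``between_subject_sd``.

    Returns ``(fraction_map, mask, label)`` triples; the mask marks all
    voxels (the maps are parenchyma-only samples, airway-free by
    construction).  Fully deterministic given the seed.
    """
    if n_control < 1 or n_copd < 1:
        raise ValueError("need at least one subject per group")
    if not (0.0 <= trapped_air_fraction < 1.0):
        raise ValueError("trapped_air_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    side = max(2, int(round(n_voxels ** (1.0 / 3.0))))
    shape = (side, side, side)
    nv = int(np.prod(shape))
    top_edge = 0.975  # lower edge of the 98.75% bin

    cohort: list[tuple[FractionMap, BinaryMask, str]] = []
    for label, n_subj, mu, sd in (
        ("control", n_control, control_mean, control_sd),
        ("copd", n_copd, copd_mean, copd_sd),
    ):
        for _ in range(n_subj):
            mu_s = rng.normal(mu, between_subject_sd)
            f = _truncated_normal(rng, mu_s, sd, 0.0, top_edge, nv)
            if label == "copd" and trapped_air_fraction > 0:
                trapped = rng.random(nv) < trapped_air_fraction
                f[trapped] = rng.uniform(0.98, 1.0, int(trapped.sum()))
            fmap = FractionMap(f.reshape(shape), spacing, fraction_of="air")
            mask = BinaryMask(np.ones(shape, dtype=bool), spacing, semantics="lung minus airways")
            cohort.append((fmap, mask, label))
    return cohort
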