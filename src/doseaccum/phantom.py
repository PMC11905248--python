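"""Synthetic pelvis phantom with known ground-truth deformations.

The generator emulates the imaging and planning conditions of a 0.35 T
MR-linac prostate SBRT program: near-isotropic 1.5 mm volumetric scans, a
five-fraction 36.25 Gy prescription normalized so that PTV_eval D95% equals
the prescription, and inter-fractional anatomy changes (bladder filling,
rectal distension, smooth random organ motion) applied as analytically known
displacement fields.  Because the truth field behind every "daily" case is
known, registration, dose warping and accumulation can all be validated
without clinical data.

Intensities are piecewise-constant per organ plus Gaussian noise — enough
structure for intensity-driven registration, with no attempt at MR physics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core import (
    DisplacementField,
    GeometryError,
    GridDescriptor,
    ImageVolume,
    StructureSet,
    sample_volume,
)

DEFAULT_PRESCRIPTION_GY = 36.25
DEFAULT_N_FRACTIONS = 5


class ParameterError(ValueError):
    """A deformation or phantom parameter violates its validity margin."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class OrganParams:
    """Centers (mm, world) and sizes (mm) of the pelvic organ models.

    The prostate/PTV is an ellipsoid; the urethra is a small-radius SI
    cylinder clipped to the prostate, expanded isotropically into its PRV;
    the rectum is an SI cylinder posterior to (and slightly overlapping)
    the prostate; the bladder an ellipsoid antero-superiorly; femoral heads
    are lateral spheres; the penile bulb a small inferior ellipsoid.
    """

    ptv_center: tuple[float, float, float] = (96.0, 96.0, 90.0)
    ptv_semiaxes: tuple[float, float, float] = (28.0, 25.0, 26.0)
    urethra_radius: float = 3.0
    urethra_prv_margin: float = 3.0
    rectum_center_xy: tuple[float, float] = (96.0, 130.0)
    rectum_radius: float = 13.0
    rectum_z_range: tuple[float, float] = (50.0, 130.0)
    bladder_center: tuple[float, float, float] = (96.0, 66.0, 125.0)
    bladder_semiaxes: tuple[float, float, float] = (32.0, 28.0, 25.0)
    femur_radius: float = 20.0
    femur_centers: tuple[tuple[float, float, float], ...] = (
        (30.0, 96.0, 95.0),
        (162.0, 96.0, 95.0),
    )
    bulb_center: tuple[float, float, float] = (96.0, 112.0, 45.0)
    bulb_semiaxes: tuple[float, float, float] = (12.0, 9.0, 9.0)


#: Piecewise-constant organ intensity levels (arbitrary units).
DEFAULT_INTENSITIES = {
    "body": 100.0,
    "prostate": 140.0,
    "urethra": 120.0,
    "rectum": 40.0,
    "bladder": 220.0,
    "femur_left": 170.0,
    "femur_right": 170.0,
    "penile_bulb": 155.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, noise and reproducibility parameters of a planning case."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 1.5
    organ_params: OrganParams = field(default_factory=OrganParams)
    noise_sd: float = 4.0
    penumbra_mm: float = 6.0
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY
    n_fractions: int = DEFAULT_N_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ParameterError("spacing_mm must be positive")
        if self.n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")

    @property
    def grid(self) -> GridDescriptor:
        return GridDescriptor(self.grid_shape, (self.spacing_mm,) * 3)

    def scaled(self, grid_shape: tuple[int, int, int]) -> "PhantomSpec":
        """Same anatomy on a different grid covering the same ~192 mm extent."""
        spacing = 192.0 / grid_shape[0]
        return dataclasses.replace(self, grid_shape=grid_shape, spacing_mm=spacing)


@dataclass(frozen=True)
class DeformationSpec:
    """Parameters of a synthetic inter-fractional deformation.

    Each component must stay inside the diffeomorphism margin: its peak
    displacement may not exceed 0.45x its own correlation length, which
    keeps the numerically checked Jacobian determinant positive.
    """

    bladder_fill_scale: float = 1.05
    rectal_bump_mm: float = 4.0
    rectal_bump_sigma_mm: float = 20.0
    random_field_amp_mm: float = 3.0
    random_field_corr_mm: float = 40.0
    seed: int = 0

    @classmethod
    def identity(cls, seed: int = 0) -> "DeformationSpec":
        """No deformation at all (exact identity field)."""
        return cls(
            bladder_fill_scale=1.0,
            rectal_bump_mm=0.0,
            random_field_amp_mm=0.0,
            seed=seed,
        )

    def validate(self) -> None:
        margin = 0.45
        if abs(self.rectal_bump_mm) > margin * self.rectal_bump_sigma_mm:
            raise ParameterError(
                f"rectal_bump_mm={self.rectal_bump_mm} exceeds invertibility margin "
                f"{margin} x sigma ({margin * self.rectal_bump_sigma_mm:.2f} mm)"
            )
        if abs(self.random_field_amp_mm) > margin * self.random_field_corr_mm:
            raise ParameterError(
                f"random_field_amp_mm={self.random_field_amp_mm} exceeds invertibility "
                f"margin {margin} x corr ({margin * self.random_field_corr_mm:.2f} mm)"
            )


@dataclass
class CaseBundle:
    """A planning case: MR-like image, structures, and the approved plan dose."""

    image: ImageVolume
    structures: StructureSet
    plan_dose: ImageVolume
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY
    n_fractions: int = DEFAULT_N_FRACTIONS

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")
        if np.any(self.plan_dose.data < 0):
            raise ParameterError("plan dose must be non-negative")

    @property
    def grid(self) -> GridDescriptor:
        return self.image.grid


@dataclass
class DailyCase:
    """One day's anatomy: deformed image/structures, the per-fraction re-plan
    dose computed on that anatomy, and the ground-truth pull-back field."""

    fraction_index: int
    image: ImageVolume
    structures: StructureSet
    delivered_fraction_dose: ImageVolume
    truth_field: DisplacementField


# ---------------------------------------------------------------------------
# geometry primitives


def _ellipsoid(grid: GridDescriptor, center, semiaxes) -> np.ndarray:
    xs = grid.world_coords(sparse=True)
    q = sum(((xs[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


def _cylinder_si(grid: GridDescriptor, center_xy, radius, z_range) -> np.ndarray:
    xs = grid.world_coords(sparse=True)
    r2 = (xs[0] - center_xy[0]) ** 2 + (xs[1] - center_xy[1]) ** 2
    return (r2 <= radius**2) & (xs[2] >= z_range[0]) & (xs[2] <= z_range[1])


def _sphere(grid: GridDescriptor, center, radius) -> np.ndarray:
    return _ellipsoid(grid, center, (radius,) * 3)


def _dilate_mm(mask: np.ndarray, margin_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Isotropic dilation by a metric margin via the distance transform."""
    if not mask.any():
        return mask.copy()
    d = distance_transform_edt(~mask, sampling=spacing)
    return d <= margin_mm


def _check_inside(mask: np.ndarray, name: str) -> None:
    """Every organ must be strictly inside the grid (no face contact)."""
    if not mask.any():
        raise GeometryError(f"organ '{name}' is empty on this grid")
    faces = [mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[..., 0], mask[..., -1]]
    if any(f.any() for f in faces):
        raise GeometryError(f"organ '{name}' extends outside the grid")


# ---------------------------------------------------------------------------
# planning case


def make_structures(spec: PhantomSpec) -> StructureSet:
    """Binary organ masks, PTV_eval = PTV minus every OAR (by construction)."""
    grid = spec.grid
    p = spec.organ_params
    spacing = grid.spacing

    ptv = _ellipsoid(grid, p.ptv_center, p.ptv_semiaxes)
    urethra_full = _cylinder_si(
        grid,
        p.ptv_center[:2],
        p.urethra_radius,
        (p.ptv_center[2] - p.ptv_semiaxes[2], p.ptv_center[2] + p.ptv_semiaxes[2]),
    )
    urethra = urethra_full & ptv  # urethra is interior to the prostate
    urethra_prv = _dilate_mm(urethra, p.urethra_prv_margin, spacing)
    rectum = _cylinder_si(grid, p.rectum_center_xy, p.rectum_radius, p.rectum_z_range)
    bladder = _ellipsoid(grid, p.bladder_center, p.bladder_semiaxes)
    femur_l = _sphere(grid, p.femur_centers[0], p.femur_radius)
    femur_r = _sphere(grid, p.femur_centers[1], p.femur_radius)
    bulb = _ellipsoid(grid, p.bulb_center, p.bulb_semiaxes)

    oar_union = urethra_prv | rectum | bladder | femur_l | femur_r | bulb
    ptv_eval = ptv & ~oar_union

    masks = {
        "PTV": ptv,
        "PTV_eval": ptv_eval,
        "urethra": urethra,
        "urethra_PRV": urethra_prv,
        "rectum": rectum,
        "bladder": bladder,
        "femur_left": femur_l,
        "femur_right": femur_r,
        "penile_bulb": bulb,
    }
    for name, m in masks.items():
        _check_inside(m, name)
    return StructureSet(masks, grid)


def make_plan_dose(
    structures: StructureSet,
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
    penumbra_mm: float = 6.0,
) -> ImageVolume:
    """Analytic SBRT-like dose: prescription inside PTV_eval, Gaussian
    penumbra with Euclidean distance outside, renormalized so that
    PTV_eval D95% equals the prescription exactly.
    """
    if "PTV_eval" not in structures or not structures["PTV_eval"].any():
        raise GeometryError("make_plan_dose requires a non-empty PTV_eval mask")
    grid = structures.grid
    target = structures["PTV_eval"]
    dist_out = distance_transform_edt(~target, sampling=grid.spacing)
    dose = prescription_gy * np.exp(-0.5 * (dist_out / penumbra_mm) ** 2)
    # D95% = 5th percentile of in-target voxel doses; renormalize exactly.
    d95 = float(np.quantile(dose[target], 0.05))
    dose *= prescription_gy / d95
    return ImageVolume(dose, grid)


def generate_planning_case(spec: PhantomSpec) -> CaseBundle:
    """Full planning bundle: image + structures + normalized plan dose.

    Deterministic for a fixed spec; the intensity noise stream is the only
    random component and is seeded from ``spec.seed``.
    """
    structures = make_structures(spec)
    grid = spec.grid
    image = np.full(grid.shape, DEFAULT_INTENSITIES["body"], dtype=float)
    # paint organs in a fixed order; later entries overwrite earlier ones
    for name in ("bladder", "rectum", "femur_left", "femur_right", "penile_bulb", "PTV", "urethra"):
        level = DEFAULT_INTENSITIES.get(name, DEFAULT_INTENSITIES.get("prostate"))
        if name == "PTV":
            level = DEFAULT_INTENSITIES["prostate"]
        image[structures[name]] = level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
        image = image + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    dose = make_plan_dose(structures, spec.prescription_gy, spec.penumbra_mm)
    return CaseBundle(
        image=ImageVolume(image, grid),
        structures=structures,
        plan_dose=dose,
        prescription_gy=spec.prescription_gy,
        n_fractions=spec.n_fractions,
    )


# ---------------------------------------------------------------------------
# deformation fields


def synth_displacement_field(
    deform: DeformationSpec,
    grid: GridDescriptor,
    organ_params: OrganParams | None = None,
) -> DisplacementField:
    """Smooth synthetic pull-back field (planning -> daily), in mm.

    Three additive components: a radial bladder filling/emptying term, an
    anterior Gaussian rectal-distension bump, and a band-limited random
    field (white noise smoothed at the requested correlation length and
    rescaled to the requested peak amplitude).  The Jacobian determinant of
    ``id + u`` is verified positive everywhere.
    """
    deform.validate()
    p = organ_params or OrganParams()
    xs = grid.world_coords(sparse=True)
    u = np.zeros((3, *grid.shape))

    # bladder filling: radial expansion about the bladder center, weighted
    # by a Gaussian of the bladder's own ellipsoidal coordinate
    s = deform.bladder_fill_scale
    if s != 1.0:
        q = sum(((xs[a] - p.bladder_center[a]) / p.bladder_semiaxes[a]) ** 2 for a in range(3))
        w = np.exp(-0.5 * q)
        for a in range(3):
            u[a] += (s - 1.0) * (xs[a] - p.bladder_center[a]) * w

    # rectal distension: anterior (-AP) Gaussian bump at the anterior wall
    if deform.rectal_bump_mm != 0.0:
        wall = (
            p.rectum_center_xy[0],
            p.rectum_center_xy[1] - p.rectum_radius,
            0.5 * (p.rectum_z_range[0] + p.rectum_z_range[1]),
        )
        r2 = sum((xs[a] - wall[a]) ** 2 for a in range(3))
        u[1] -= deform.rectal_bump_mm * np.exp(-0.5 * r2 / deform.rectal_bump_sigma_mm**2)

    # smooth random motion
    if deform.random_field_amp_mm > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([int(deform.seed), 2]))
        sigma_vox = deform.random_field_corr_mm / grid.spacing
        noise = np.empty_like(u)
        for a in range(3):
            noise[a] = gaussian_filter(rng.normal(size=grid.shape), sigma=sigma_vox)
        peak = np.sqrt((noise**2).sum(axis=0)).max()
        if peak > 0:
            noise *= deform.random_field_amp_mm / peak
        u += noise

    fld = DisplacementField(u, grid)
    min_jac = float(fld.jacobian_determinant().min())
    if min_jac <= 0.0:
        raise ParameterError(
            f"displacement field is not invertible (min Jacobian determinant {min_jac:.3f})"
        )
    return fld


def invert_displacement_field(
    field_: DisplacementField, n_iter: int = 30, tol_mm: float = 1e-3
) -> DisplacementField:
    """Numerical inverse of ``p -> p + u(p)`` by fixed-point iteration.

    Returns v with ``v(q) = -u(q + v(q))`` so that ``(id+u) o (id+v) = id``
    up to interpolation error; converges for fields inside the
    invertibility margin.
    """
    grid = field_.grid
    v = np.zeros_like(field_.vectors_mm)
    u = field_.vectors_mm
    xs = grid.world_coords(sparse=True)
    for _ in range(n_iter):
        idx = np.empty_like(v)
        for a in range(3):
            idx[a] = (xs[a] + v[a] - grid.origin[a]) / grid.spacing[a]
        v_new = np.empty_like(v)
        for a in range(3):
            v_new[a] = -sample_volume(ImageVolume(u[a], grid), idx, edge="nearest")
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol_mm:
            break
    return DisplacementField(v, grid)


def _resample_through(data: np.ndarray, grid: GridDescriptor, idx: np.ndarray, mode: str) -> np.ndarray:
    return sample_volume(ImageVolume(data, grid), idx, mode=mode, edge="nearest")


def generate_daily_case(
    planning: CaseBundle,
    deform: DeformationSpec,
    fraction_index: int,
    dose_scale: float = 1.0,
) -> DailyCase:
    """Deformed daily anatomy plus its per-fraction re-plan dose.

    The truth field u follows the pull-back convention (planning point p
    maps to daily point p + u(p)); the daily image is the planning image
    pushed forward through u, i.e. sampled through the numerical inverse.
    The delivered dose is re-planned on the daily structures (as in online
    adaptation) and scaled to one fraction; ``dose_scale`` optionally
    emulates a delivery deviation.
    """
    if not (1 <= fraction_index <= planning.n_fractions):
        raise ParameterError(
            f"fraction_index {fraction_index} outside 1..{planning.n_fractions}"
        )
    grid = planning.grid
    u = synth_displacement_field(deform, grid)

    if u.max_magnitude_mm == 0.0:
        daily_image = planning.image.copy()
        daily_structs = planning.structures.copy()
    else:
        inv = invert_displacement_field(u)
        idx = inv.mapped_points_index(grid)
        daily_image = ImageVolume(_resample_through(planning.image.data, grid, idx, "linear"), grid)
        daily_structs = StructureSet(
            {
                name: _resample_through(m.astype(float), grid, idx, "linear") >= 0.5
                for name, m in planning.structures.masks.items()
            },
            grid,
        )

    replan_total = make_plan_dose(daily_structs, planning.prescription_gy)
    delivered = ImageVolume(
        replan_total.data * dose_scale / planning.n_fractions, grid
    )
    return DailyCase(
        fraction_index=fraction_index,
        image=daily_image,
        structures=daily_structs,
        delivered_fraction_dose=delivered,
        truth_field=u,
    )
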