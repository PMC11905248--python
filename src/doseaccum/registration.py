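"""Rigid and hybrid (contour + intensity) deformable registration.

The workflow mirrors automated daily alignment in MR-guided adaptive
radiotherapy: a rigid stage maximizes normalized cross-correlation inside a
PTV-focused box (the PTV_eval bounding box grown by 30 mm right-left and
anterior-posterior and 20 mm superior-inferior), then a multiresolution
cubic B-spline free-form deformation minimizes

    C(u) = w_I * SSD(intensity) + w_C * sum_s SSD(signed distance maps of s)
           + lambda * bending energy,

evaluated only inside the focus box.  The contour term compares truncated
signed Euclidean distance maps of corresponding structures, which makes
surface disagreement differentiable on the grid.  The optimizer is L-BFGS-B
with an analytic gradient; everything is deterministic for fixed inputs.

Fields follow the pull-back convention: a planning-frame point ``p``
corresponds to the daily-frame point ``p + u(p)``, so warping daily data
onto the planning grid samples the daily volume at ``p + u(p)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize
from scipy.ndimage import distance_transform_edt
from scipy.spatial.transform import Rotation

from .core import (
    DisplacementField,
    GeometryError,
    GridDescriptor,
    ImageVolume,
    StructureSet,
    sample_volume,
)

DEFAULT_MARGINS_MM = (30.0, 30.0, 20.0)  # RL, AP, SI


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# focus box


@dataclass(frozen=True)
class FocusBox:
    """World-space axis-aligned box restricting the registration support."""

    lower_mm: tuple[float, float, float]
    upper_mm: tuple[float, float, float]
    margins_mm: tuple[float, float, float] = DEFAULT_MARGINS_MM

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.lower_mm, dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.upper_mm, dtype=float)

    @property
    def center_mm(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def index_slices(self, grid: GridDescriptor) -> tuple[slice, slice, slice]:
        lo = np.maximum(np.ceil(grid.world_to_index(self.lower) - 1e-9), 0).astype(int)
        hi = np.minimum(
            np.floor(grid.world_to_index(self.upper) + 1e-9), np.asarray(grid.shape) - 1
        ).astype(int)
        if np.any(hi < lo):
            raise GeometryError("focus box does not intersect the grid")
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))


def make_focus_box(
    ptv_eval: np.ndarray,
    grid: GridDescriptor,
    margins_mm: tuple[float, float, float] = DEFAULT_MARGINS_MM,
) -> FocusBox:
    """PTV bounding box grown by per-axis margins, clipped to the grid."""
    ptv_eval = np.asarray(ptv_eval, dtype=bool)
    if not ptv_eval.any():
        raise GeometryError("make_focus_box requires a non-empty PTV mask")
    idx = np.argwhere(ptv_eval)
    lo_w = grid.index_to_world(idx.min(axis=0)) - np.asarray(margins_mm, dtype=float)
    hi_w = grid.index_to_world(idx.max(axis=0)) + np.asarray(margins_mm, dtype=float)
    ext = grid.extent_mm
    lo_w = np.maximum(lo_w, ext[0])
    hi_w = np.minimum(hi_w, ext[1])
    return FocusBox(tuple(lo_w), tuple(hi_w), tuple(float(m) for m in margins_mm))


# ---------------------------------------------------------------------------
# rigid stage


@dataclass
class RigidTransform:
    """T(p) = R (p - c) + c + t with R from xyz Euler angles (radians)."""

    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metric_value: float | None = None  # final NCC, set by register_rigid

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_rad).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points, shape (3, ...)."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(3, -1)
        c = np.asarray(self.center_mm, dtype=float)[:, None]
        t = np.asarray(self.translation_mm, dtype=float)[:, None]
        out = self.matrix @ (flat - c) + c + t
        return out.reshape(pts.shape)

    def inverse(self) -> "RigidTransform":
        r_inv = Rotation.from_euler("xyz", self.rotation_rad).inv()
        t = np.asarray(self.translation_mm, dtype=float)
        return RigidTransform(
            rotation_rad=tuple(r_inv.as_euler("xyz")),
            translation_mm=tuple(-(r_inv.as_matrix() @ t)),
            center_mm=self.center_mm,
        )

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center_mm=tuple(center_mm))


@dataclass
class RigidConfig:
    coarse_stride: int = 2
    multi_start_mm: float = 0.0  # extra +/- axis translation starts; 0 = identity only
    max_iterations: int = 200
    xtol: float = 1e-4
    ftol: float = 1e-8
    # results below these magnitudes snap to the exact identity, so that a
    # self-registration leaves downstream warps bit-exact
    snap_tol_mm: float = 0.01
    snap_tol_rad: float = 1e-5


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    box: FocusBox,
    cfg: RigidConfig | None = None,
) -> RigidTransform:
    """Rigid alignment maximizing NCC of ``moving(T(p))`` vs ``fixed(p)``
    over the focus box, via multi-start Powell search (coarse-stride scan,
    full-resolution refinement about the best start)."""
    cfg = cfg or RigidConfig()
    sl = box.index_slices(fixed.grid)
    center = box.center_mm

    def make_metric(stride: int):
        sub = tuple(slice(s.start, s.stop, stride) for s in sl)
        fvals = np.asarray(fixed.data, dtype=float)[sub].ravel()
        axes = [
            fixed.grid.origin[a] + np.arange(s.start, s.stop, stride) * fixed.grid.spacing[a]
            for a, s in enumerate(sl)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])

        def metric(params: np.ndarray) -> float:
            tf = RigidTransform(tuple(params[:3]), tuple(params[3:]), tuple(center))
            q = tf.apply(pts)
            idx = (q - moving.grid.origin[:, None]) / moving.grid.spacing[:, None]
            mvals = sample_volume(moving, idx, mode="linear", edge="constant", cval=0.0)
            val = _ncc(fvals, mvals)
            if not np.isfinite(val):
                raise RegistrationError("non-finite rigid metric (empty box overlap?)")
            return -val

        return metric

    direc = np.diag([0.02, 0.02, 0.02, 2.0, 2.0, 2.0])  # rad / mm initial steps
    starts = [np.zeros(6)]
    if cfg.multi_start_mm > 0:
        for a in range(3):
            for s in (+1, -1):
                x = np.zeros(6)
                x[3 + a] = s * cfg.multi_start_mm
                starts.append(x)

    coarse = make_metric(max(cfg.coarse_stride, 1))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            coarse,
            x0,
            method="Powell",
            options={
                "direc": direc.copy(),
                "maxiter": cfg.max_iterations,
                "xtol": cfg.xtol,
                "ftol": cfg.ftol,
            },
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    fine = make_metric(1)
    res = optimize.minimize(
        fine,
        best_x,
        method="Powell",
        options={
            "direc": (0.25 * direc).copy(),
            "maxiter": cfg.max_iterations,
            "xtol": cfg.xtol * 0.1,
            "ftol": cfg.ftol,
        },
    )
    angles, trans = res.x[:3], res.x[3:]
    if np.abs(trans).max() < cfg.snap_tol_mm and np.abs(angles).max() < cfg.snap_tol_rad:
        angles, trans = np.zeros(3), np.zeros(3)
    tf = RigidTransform(tuple(angles), tuple(trans), tuple(center))
    tf.metric_value = -float(res.fun)
    return tf


# ---------------------------------------------------------------------------
# B-spline machinery


def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2, partition of unity on Z."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    out[m2] = ((2.0 - t[m2]) ** 3) / 6.0
    return out


@dataclass(frozen=True)
class _KnotGrid:
    """Separable cubic B-spline knot lattice covering a world-space box."""

    origin: tuple[float, float, float]  # knot 0 position per axis
    spacing: float
    counts: tuple[int, int, int]

    @classmethod
    def covering(cls, lower: np.ndarray, upper: np.ndarray, spacing: float) -> "_KnotGrid":
        origin = lower - 2.0 * spacing
        counts = tuple(int(np.ceil((u - l) / spacing)) + 5 for l, u in zip(lower, upper))
        return cls(tuple(origin), float(spacing), counts)

    def basis(self, coords: np.ndarray, axis: int) -> np.ndarray:
        """Dense basis matrix A[i, j] = B3((x_i - knot_j) / h)."""
        knots = self.origin[axis] + np.arange(self.counts[axis]) * self.spacing
        return _bspline3((np.asarray(coords)[:, None] - knots[None, :]) / self.spacing)


def _eval_bspline(theta: np.ndarray, ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    return np.einsum("ia,jb,kc,dabc->dijk", ax, ay, az, theta, optimize=True)


def _adjoint_bspline(g: np.ndarray, ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    return np.einsum("ia,jb,kc,dijk->dabc", ax, ay, az, g, optimize=True)


def _bending(theta: np.ndarray) -> tuple[float, np.ndarray]:
    """Axis-wise mean squared second differences of the control lattice
    (a discrete bending-energy surrogate, mesh-size independent)."""
    energy = 0.0
    grad = np.zeros_like(theta)
    for axis in range(1, 4):
        d2 = np.diff(theta, n=2, axis=axis)
        energy += float((d2**2).sum())
        g = np.zeros_like(theta)
        sl = [slice(None)] * 4
        for offset, coef in ((0, 1.0), (1, -2.0), (2, 1.0)):
            sl_a = list(sl)
            n = theta.shape[axis]
            sl_a[axis] = slice(offset, n - 2 + offset)
            g[tuple(sl_a)] += coef * d2
        grad += 2.0 * g
    n = float(theta.size)
    return energy / n, grad / n


# ---------------------------------------------------------------------------
# deformable stage


@dataclass
class RegistrationConfig:
    """Hybrid deformable registration settings.

    ``pyramid_factors`` are fixed-image subsampling strides per level,
    coarse to fine; the control-point spacing at each level is
    ``control_point_spacing_mm`` x factor.  ``ring_only`` restricts the
    cost support to the focus box (the workflow's "ring" region).
    """

    intensity_weight: float = 1.0
    contour_weight: float = 1.0
    regularization_weight: float = 2.0
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    control_point_spacing_mm: float = 20.0
    max_iterations: tuple[int, ...] | int = (60, 40, 30)
    convergence_tol: float = 1e-5
    ring_only: bool = True
    contour_structures: tuple[str, ...] | None = None
    sdm_truncate_mm: float = 20.0
    max_displacement_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.intensity_weight + self.contour_weight <= 0:
            raise ValueError("intensity_weight + contour_weight must be > 0")
        if len(self.pyramid_factors) < 1:
            raise ValueError("at least one pyramid level is required")

    def iterations(self, level: int) -> int:
        if isinstance(self.max_iterations, int):
            return self.max_iterations
        return self.max_iterations[min(level, len(self.max_iterations) - 1)]


@dataclass
class DeformableResult:
    field: DisplacementField
    cost_trace: list[list[float]] = dc_field(default_factory=list)
    diagnostics: dict = dc_field(default_factory=dict)


def _signed_distance(mask: np.ndarray, spacing: np.ndarray, truncate_mm: float) -> np.ndarray:
    """Signed Euclidean distance (positive outside), truncated to +/- limit."""
    if not mask.any():
        return np.full(mask.shape, truncate_mm)
    d_out = distance_transform_edt(~mask, sampling=spacing)
    d_in = distance_transform_edt(mask, sampling=spacing)
    return np.clip(d_out - d_in, -truncate_mm, truncate_mm)


def _crop_pad(vol: ImageVolume, sl: tuple[slice, ...], pad_mm: float) -> ImageVolume:
    """Sub-volume around box slices, padded in mm, with adjusted origin."""
    pad_vox = np.ceil(pad_mm / vol.grid.spacing).astype(int)
    lo = np.maximum([s.start for s in sl] - pad_vox, 0)
    hi = np.minimum([s.stop for s in sl] + pad_vox, vol.grid.shape)
    sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grid = GridDescriptor(
        tuple(int(b - a) for a, b in zip(lo, hi)),
        vol.grid.spacing_mm,
        tuple(vol.grid.index_to_world(lo)),
    )
    return ImageVolume(np.ascontiguousarray(np.asarray(vol.data, dtype=float)[sub]), grid)


class _Term:
    """One SSD data term: fixed volume + moving volume with its gradient."""

    def __init__(self, name: str, fixed: ImageVolume, moving: ImageVolume):
        self.name = name
        self.fixed = fixed
        self.moving = moving
        g = np.gradient(np.asarray(moving.data, dtype=float), *moving.grid.spacing)
        self.moving_grad = [ImageVolume(gi, moving.grid) for gi in g]
        self.weight = 1.0


def register_hybrid_deformable(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_structures: StructureSet,
    moving_structures: StructureSet,
    init: RigidTransform | None = None,
    cfg: RegistrationConfig | None = None,
    box: FocusBox | None = None,
) -> DeformableResult:
    """Hybrid contour+intensity B-spline registration (see module docstring).

    ``fixed`` is the planning image, ``moving`` the daily image; the result
    maps planning points into the daily frame (pull-back).  Structures
    present in only one set are skipped with a warning.  The returned
    ``cost_trace`` holds the accepted cost sequence per pyramid level and
    is monotone non-increasing within each level.
    """
    cfg = cfg or RegistrationConfig()
    if box is None:
        ptv_name = "PTV_eval" if "PTV_eval" in fixed_structures else fixed_structures.names[0]
        box = make_focus_box(fixed_structures[ptv_name], fixed.grid)
    sl = box.index_slices(fixed.grid)
    init = init or RigidTransform.identity(tuple(box.center_mm))

    # contour terms on structures common to both sets
    names = cfg.contour_structures or tuple(fixed_structures.names)
    common: list[str] = []
    for n in names:
        if n in fixed_structures and n in moving_structures:
            common.append(n)
        else:
            warnings.warn(f"structure '{n}' missing from one set; skipped", stacklevel=2)

    pad = min(cfg.max_displacement_mm, 30.0)
    spacing = fixed.grid.spacing
    terms: list[_Term] = []
    if cfg.intensity_weight > 0:
        terms.append(
            _Term("intensity", _crop_pad(fixed, sl, 0.0), _crop_pad(moving, sl, pad))
        )
    sdm_terms: list[_Term] = []
    for n in common:
        f_sdm = _signed_distance(fixed_structures[n], spacing, cfg.sdm_truncate_mm)
        m_sdm = _signed_distance(moving_structures[n], spacing, cfg.sdm_truncate_mm)
        sdm_terms.append(
            _Term(
                f"sdm:{n}",
                _crop_pad(ImageVolume(f_sdm, fixed.grid), sl, 0.0),
                _crop_pad(ImageVolume(m_sdm, moving.grid), sl, pad),
            )
        )
    if cfg.contour_weight <= 0:
        sdm_terms = []
    if not terms and not sdm_terms:
        raise RegistrationError("no active data terms (check weights and structures)")

    levels: list[tuple[_KnotGrid, np.ndarray]] = []  # (knots, theta) per finished level
    u_rigid = lambda pts: init.apply(pts) - pts  # noqa: E731
    cost_trace: list[list[float]] = []

    for level, factor in enumerate(cfg.pyramid_factors):
        stride = int(factor)
        axes = [
            fixed.grid.origin[a] + np.arange(s.start, s.stop, stride) * spacing[a]
            for a, s in enumerate(sl)
        ]
        shape_l = tuple(len(ax) for ax in axes)
        pts = np.stack(np.meshgrid(*axes, indexing="ij"))  # (3, nx, ny, nz)

        # fixed-side values at the level's sample points (strided crop)
        def strided(vol: ImageVolume) -> np.ndarray:
            idx = np.stack(
                np.meshgrid(
                    *[(ax - vol.grid.origin[a]) / vol.grid.spacing[a] for a, ax in enumerate(axes)],
                    indexing="ij",
                )
            )
            return sample_volume(vol, idx, mode="linear", edge="nearest")

        f_vals = {t.name: strided(t.fixed) for t in terms + sdm_terms}

        # displacement carried in from the rigid stage and coarser levels
        u_base = u_rigid(pts)
        for knots_prev, theta_prev in levels:
            axp = [knots_prev.basis(axes[a], a) for a in range(3)]
            u_base = u_base + _eval_bspline(theta_prev, *axp)

        knots = _KnotGrid.covering(box.lower, box.upper, cfg.control_point_spacing_mm * stride)
        basis = [knots.basis(axes[a], a) for a in range(3)]
        theta0 = np.zeros((3, *knots.counts))
        n_pts = float(np.prod(shape_l))

        def data_terms(u: np.ndarray, want_grad: bool):
            qidx_cache: dict[int, np.ndarray] = {}

            def qidx(grid: GridDescriptor) -> np.ndarray:
                key = id(grid)
                if key not in qidx_cache:
                    qidx_cache[key] = np.stack(
                        [
                            (pts[a] + u[a] - grid.origin[a]) / grid.spacing[a]
                            for a in range(3)
                        ]
                    )
                return qidx_cache[key]

            out = {}
            gvox = np.zeros_like(u) if want_grad else None
            for t in terms + sdm_terms:
                idx = qidx(t.moving.grid)
                mv = sample_volume(t.moving, idx, mode="linear", edge="nearest")
                res = mv - f_vals[t.name]
                out[t.name] = float((res**2).sum() / n_pts)
                if want_grad and t.weight > 0:
                    coef = t.weight * 2.0 / n_pts
                    for a in range(3):
                        gk = sample_volume(t.moving_grad[a], idx, mode="linear", edge="nearest")
                        gvox[a] += coef * res * gk
            return out, gvox

        # per-term normalization: unit initial magnitude for each cost family
        raw0, _ = data_terms(u_base, want_grad=False)
        c0_int = sum(v for k, v in raw0.items() if k == "intensity")
        c0_sdm = sum(v for k, v in raw0.items() if k.startswith("sdm:"))
        w_int = cfg.intensity_weight / max(c0_int, 1e-12)
        w_sdm = cfg.contour_weight / max(c0_sdm, 1e-12)
        for t in terms:
            t.weight = w_int
        for t in sdm_terms:
            t.weight = w_sdm

        def cost_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
            theta = x.reshape(3, *knots.counts)
            u = u_base + _eval_bspline(theta, *basis)
            vals, gvox = data_terms(u, want_grad=True)
            c = w_int * sum(v for k, v in vals.items() if k == "intensity")
            c += w_sdm * sum(v for k, v in vals.items() if k.startswith("sdm:"))
            g_theta = _adjoint_bspline(gvox, *basis)
            if cfg.regularization_weight > 0:
                b, gb = _bending(theta)
                c += cfg.regularization_weight * b
                g_theta += cfg.regularization_weight * gb
            return c, g_theta.ravel()

        trace: list[float] = []
        cache: dict[bytes, float] = {}

        def fun(x: np.ndarray):
            c, g = cost_grad(x)
            cache[x.tobytes()] = c
            if len(cache) > 8:
                cache.pop(next(iter(cache)))
            return c, g

        def callback(xk: np.ndarray) -> None:
            c = cache.get(xk.tobytes())
            if c is None:
                c = cost_grad(xk)[0]
            trace.append(c)

        c_start, _ = cost_grad(theta0.ravel())
        trace.append(c_start)
        res = optimize.minimize(
            fun,
            theta0.ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={
                "maxiter": cfg.iterations(level),
                "ftol": cfg.convergence_tol,
                "gtol": 1e-12,
            },
        )
        if res.fun > c_start + 1e-12:
            raise RegistrationError(
                f"cost diverged at pyramid level {level}: {c_start:.6g} -> {res.fun:.6g}"
            )
        cost_trace.append(trace)
        levels.append((knots, res.x.reshape(3, *knots.counts)))

    # assemble the full-resolution field on the planning grid
    full_axes = [fixed.grid.axis_coords(a) for a in range(3)]
    pts_full = np.stack(np.meshgrid(*full_axes, indexing="ij"))
    u_full = u_rigid(pts_full)
    for knots_l, theta_l in levels:
        ax = [knots_l.basis(full_axes[a], a) for a in range(3)]
        u_full = u_full + _eval_bspline(theta_l, *ax)
    if np.abs(u_full).max() < 0.01:  # numerically-identity result: snap exact
        u_full = np.zeros_like(u_full)
    fld = DisplacementField(u_full, fixed.grid)
    if fld.max_magnitude_mm > cfg.max_displacement_mm:
        raise RegistrationError(
            f"field magnitude {fld.max_magnitude_mm:.1f} mm exceeds the configured "
            f"cap {cfg.max_displacement_mm:.1f} mm"
        )
    return DeformableResult(
        field=fld,
        cost_trace=cost_trace,
        diagnostics={
            "structures": common,
            "final_cost": float(cost_trace[-1][-1]),
            "max_displacement_mm": fld.max_magnitude_mm,
        },
    )


# ---------------------------------------------------------------------------
# warping


def _warp(field: DisplacementField, vol: ImageVolume, mode: str) -> np.ndarray:
    if field.grid.same_geometry(vol.grid) and not field.vectors_mm.any():
        return np.asarray(vol.data, dtype=float).copy()  # identity: bit-exact
    idx = field.mapped_points_index(vol.grid)
    return sample_volume(vol, idx, mode=mode, edge="constant", cval=0.0)


def warp_image(field: DisplacementField, image: ImageVolume) -> ImageVolume:
    """Resample a daily-frame image onto the planning grid through the field."""
    return ImageVolume(_warp(field, image, "linear"), field.grid)


def warp_mask(field: DisplacementField, mask: np.ndarray, grid: GridDescriptor) -> np.ndarray:
    """Warp a daily-frame binary mask onto the planning grid (linear
    interpolation of the indicator, thresholded at 0.5)."""
    vol = ImageVolume(np.asarray(mask, dtype=float), grid)
    return _warp(field, vol, "linear") >= 0.5
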