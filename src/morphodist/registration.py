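"""Symmetric log-domain diffeomorphic demons registration.

The deformable transform is parameterised entirely by a stationary velocity
field v: the forward map is phi = exp(v) (computed by scaling and squaring),
the inverse is exp(-v).  Each iteration computes intensity-driven demons
update forces in both directions (fixed->moving and moving->fixed),
fluid-smooths them, combines them into a single symmetric update u, and folds
u into v through a Baker-Campbell-Hausdorff approximation of
log(exp(v) o exp(u)), followed by diffusion smoothing of v.  Optimisation runs
over a Gaussian image pyramid, coarse to fine.

Because a single velocity field encodes both directions of the registration,
the pairwise shape distance downstream is read off one registration per
subject pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .volumes import DeformationField, Grid, ImageVolume, VelocityField

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "RegistrationError",
    "affine_align",
    "demons_update",
    "compose_velocity",
    "exp_field",
    "warp",
    "register_symmetric",
]


class RegistrationError(RuntimeError):
    """Registration failed (divergence, non-finite energy, bad input)."""


@dataclass
class RegistrationParams:
    """Tunable knobs of the demons optimiser.

    sigma_fluid / sigma_diffusion are Gaussian kernel widths in mm applied to
    the update field and the velocity field respectively.  sigma_x (intensity
    units) bounds the per-voxel step length of the demons force; images are
    jointly rescaled to [0, 1] before optimisation so sigma_x = 1 is a
    sensible default.  exp_steps = None selects the number of
    scaling-and-squaring steps automatically from the field magnitude.
    """

    pyramid_levels: int = 3
    iters_per_level: tuple[int, ...] = (30, 30, 20)
    sigma_fluid: float = 1.0
    sigma_diffusion: float = 1.5
    force_type: str = "symmetric"  # or "thirion"
    bch_order: str = "zeroth"  # or "first"
    exp_steps: int | None = None
    stop_tol: float = 1e-4
    intensity_sigma_x: float = 1.0

    def __post_init__(self) -> None:
        self.iters_per_level = tuple(int(i) for i in self.iters_per_level)
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if len(self.iters_per_level) != self.pyramid_levels:
            raise ValueError("iters_per_level must have one entry per pyramid level")
        if self.sigma_fluid < 0 or self.sigma_diffusion < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.force_type not in ("thirion", "symmetric"):
            raise ValueError(f"unknown force_type {self.force_type!r}")
        if self.bch_order not in ("zeroth", "first"):
            raise ValueError(f"unknown bch_order {self.bch_order!r}")

    def to_dict(self) -> dict:
        return {
            "pyramid_levels": self.pyramid_levels,
            "iters_per_level": list(self.iters_per_level),
            "sigma_fluid": self.sigma_fluid,
            "sigma_diffusion": self.sigma_diffusion,
            "force_type": self.force_type,
            "bch_order": self.bch_order,
            "exp_steps": self.exp_steps,
            "stop_tol": self.stop_tol,
            "intensity_sigma_x": self.intensity_sigma_x,
        }


@dataclass
class RegistrationResult:
    velocity: VelocityField
    forward: DeformationField
    inverse: DeformationField
    energy_trace: list = dc_field(default_factory=list)
    converged: bool = False


# ---------------------------------------------------------------------------
# sampling primitives


def _identity_coords(dims: tuple[int, int, int]) -> np.ndarray:
    """Voxel-index identity grid, shape (3, nx, ny, nz)."""
    return np.mgrid[0 : dims[0], 0 : dims[1], 0 : dims[2]].astype(np.float64)


def _sample_scalar(arr: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def _sample_vector(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    out = np.empty(coords.shape[1:] + (3,), dtype=np.float64)
    for i in range(3):
        out[..., i] = ndimage.map_coordinates(
            field[..., i], coords, order=1, mode="nearest"
        )
    return out


def _warp_coords(disp_mm: np.ndarray, grid: Grid) -> np.ndarray:
    coords = _identity_coords(grid.dims)
    for i in range(3):
        coords[i] += disp_mm[..., i] / grid.spacing[i]
    return coords


def _compose_disp(a: np.ndarray, b: np.ndarray, grid: Grid) -> np.ndarray:
    """Displacement of the composed map x -> x + b(x) + a(x + b(x)) (mm)."""
    coords = _warp_coords(b, grid)
    return b + _sample_vector(a, coords)


def _smooth_vec(field: np.ndarray, sigma_mm: float, grid: Grid) -> np.ndarray:
    if sigma_mm <= 0:
        return field
    sigmas = [sigma_mm / s for s in grid.spacing]
    out = np.empty_like(field)
    for i in range(3):
        out[..., i] = ndimage.gaussian_filter(field[..., i], sigmas, mode="nearest")
    return out


def _gradient_mm(arr: np.ndarray, grid: Grid) -> np.ndarray:
    gx, gy, gz = np.gradient(arr, *grid.spacing)
    return np.stack([gx, gy, gz], axis=-1)


# ---------------------------------------------------------------------------
# core operations


def warp(image, phi: DeformationField, interpolation: str = "linear"):
    """Pull-back resampling: output(x) = image(x + displacement(x)).

    Out-of-grid samples take the nearest edge value.  Nearest-neighbour
    interpolation preserves the set of values, so label volumes stay integral.
    """
    from .volumes import LabelVolume, _check_same_grid

    _check_same_grid(image, phi)
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    coords = _warp_coords(phi.data, image.grid)
    out = _sample_scalar(np.asarray(image.data, dtype=np.float64), coords, order)
    if isinstance(image, LabelVolume):
        return LabelVolume(np.rint(out).astype(np.int32), image.grid)
    return ImageVolume(out, image.grid)


def exp_field(v: VelocityField, exp_steps: int | None = None) -> DeformationField:
    """Exponentiate a stationary velocity field by scaling and squaring.

    Picks the smallest N with max voxel displacement of v / 2^N below half a
    voxel (unless exp_steps is given), then squares d <- d o d N times using
    trilinear, edge-clamped composition.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValueError("velocity field contains non-finite values")
    grid = v.grid
    vox = v.data / np.asarray(grid.spacing)
    max_vox = float(np.sqrt((vox**2).sum(axis=-1)).max())
    if exp_steps is None:
        n = 0 if max_vox == 0 else max(0, math.ceil(math.log2(max_vox / 0.5)))
    else:
        n = int(exp_steps)
    d = v.data / (2.0**n)
    for _ in range(n):
        d = _compose_disp(d, d, grid)
    return DeformationField(d, grid)


def demons_update(
    fixed: ImageVolume, warped_moving: ImageVolume, params: RegistrationParams
) -> VelocityField:
    """Voxelwise demons force  u = diff * J / (|J|^2 + diff^2 / sigma_x^2).

    J is the fixed-image gradient (thirion) or the mean of the fixed and
    warped-moving gradients (symmetric).  Where the denominator vanishes the
    update is zero.
    """
    from .volumes import _check_same_grid

    _check_same_grid(fixed, warped_moving)
    grid = fixed.grid
    diff = fixed.data - warped_moving.data
    if params.force_type == "thirion":
        J = _gradient_mm(fixed.data, grid)
    else:
        J = 0.5 * (_gradient_mm(fixed.data, grid) + _gradient_mm(warped_moving.data, grid))
    denom = (J**2).sum(axis=-1) + diff**2 / params.intensity_sigma_x**2
    ok = denom > 1e-12
    scale = np.where(ok, diff / np.where(ok, denom, 1.0), 0.0)
    return VelocityField(J * scale[..., None], grid)


def compose_velocity(
    v: VelocityField, u: VelocityField, bch_order: str = "zeroth"
) -> VelocityField:
    """BCH approximation Z(v, u) of log(exp(v) o exp(u)).

    zeroth: Z = v + u.  first: Z = v + u + [v, u] / 2 with the Lie bracket
    [v,u]_i = sum_j (d_j v_i) u_j - (d_j u_i) v_j by central differences.
    """
    from .volumes import _check_same_grid

    _check_same_grid(v, u)
    if bch_order == "zeroth":
        return VelocityField(v.data + u.data, v.grid)
    if bch_order != "first":
        raise ValueError(f"unknown bch_order {bch_order!r}")
    grid = v.grid
    bracket = np.zeros_like(v.data)
    for i in range(3):
        Jv = _gradient_mm(v.data[..., i], grid)  # d_j v_i
        Ju = _gradient_mm(u.data[..., i], grid)
        bracket[..., i] = (Jv * u.data).sum(axis=-1) - (Ju * v.data).sum(axis=-1)
    return VelocityField(v.data + u.data + 0.5 * bracket, v.grid)


# ---------------------------------------------------------------------------
# intensity normalisation and pyramids


def _joint_normalize(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale both images jointly to [0, 1] by the 1st-99th percentile."""
    pooled = np.concatenate([a.ravel(), b.ravel()])
    lo, hi = np.percentile(pooled, [1.0, 99.0])
    if hi <= lo:
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            return np.zeros_like(a), np.zeros_like(b)
    return (np.clip((a - lo) / (hi - lo), 0, 1), np.clip((b - lo) / (hi - lo), 0, 1))


def _downsample(arr: np.ndarray, grid: Grid, factor: int) -> tuple[np.ndarray, Grid]:
    if factor == 1:
        return arr, grid
    smoothed = ndimage.gaussian_filter(arr, sigma=factor / 2.0, mode="nearest")
    dims = tuple(max(4, int(round(d / factor))) for d in grid.dims)
    zoom = [nd / d for nd, d in zip(dims, grid.dims)]
    out = ndimage.zoom(smoothed, zoom, order=1, mode="nearest", grid_mode=False)
    spacing = tuple(s / z for s, z in zip(grid.spacing, zoom))
    return out, Grid(out.shape, spacing, grid.origin)


def _upsample_velocity(v: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    zoom = [nd / d for nd, d in zip(dst.dims, src.dims)]
    out = np.empty(dst.dims + (3,), dtype=np.float64)
    for i in range(3):
        out[..., i] = ndimage.zoom(v[..., i], zoom, order=1, mode="nearest")
    return out


def register_symmetric(
    fixed: ImageVolume, moving: ImageVolume, params: RegistrationParams | None = None
) -> RegistrationResult:
    """Inverse-consistent demons: optimise v so exp(v) warps moving onto fixed
    and exp(-v) warps fixed onto moving, minimising the symmetrised SSD energy.
    """
    from .volumes import _check_same_grid

    params = params or RegistrationParams()
    _check_same_grid(fixed, moving)
    grid = fixed.grid
    f_norm, m_norm = _joint_normalize(fixed.data, moving.data)

    levels = []  # coarse -> fine
    for lev in range(params.pyramid_levels - 1, -1, -1):
        factor = 2**lev
        f_l, g_l = _downsample(f_norm, grid, factor)
        m_l, _ = _downsample(m_norm, grid, factor)
        levels.append((f_l, m_l, g_l))

    v = None
    energy_trace: list[float] = []
    converged = False
    for lev_idx, (f_l, m_l, g_l) in enumerate(levels):
        if v is None:
            v = np.zeros(g_l.dims + (3,), dtype=np.float64)
        else:
            v = _upsample_velocity(v, prev_grid, g_l)
        prev_grid = g_l
        fixed_l = ImageVolume(f_l, g_l)
        moving_l = ImageVolume(m_l, g_l)
        n_iter = params.iters_per_level[lev_idx]
        prev_energy = None
        for _ in range(n_iter):
            vf = VelocityField(v, g_l)
            phi_f = exp_field(vf, params.exp_steps)
            phi_b = exp_field(vf.negate(), params.exp_steps)
            warped_m = warp(moving_l, phi_f)
            warped_f = warp(fixed_l, phi_b)
            energy = 0.5 * (
                float(np.mean((f_l - warped_m.data) ** 2))
                + float(np.mean((m_l - warped_f.data) ** 2))
            )
            if not np.isfinite(energy):
                raise RegistrationError(
                    f"non-finite energy at level {lev_idx}; trace={energy_trace}"
                )
            energy_trace.append(energy)
            if prev_energy is not None:
                rel = abs(prev_energy - energy) / max(prev_energy, 1e-30)
                if rel < params.stop_tol:
                    converged = True
                    break
            prev_energy = energy
            u_f = demons_update(fixed_l, warped_m, params).data
            u_b = demons_update(moving_l, warped_f, params).data
            u_f = _smooth_vec(u_f, params.sigma_fluid, g_l)
            u_b = _smooth_vec(u_b, params.sigma_fluid, g_l)
            u = VelocityField(0.5 * (u_f - u_b), g_l)
            z = compose_velocity(VelocityField(v, g_l), u, params.bch_order)
            v = _smooth_vec(z.data, params.sigma_diffusion, g_l)

    velocity = VelocityField(v, grid)
    forward = exp_field(velocity, params.exp_steps)
    inverse = exp_field(velocity.negate(), params.exp_steps)
    return RegistrationResult(velocity, forward, inverse, energy_trace, converged)


# ---------------------------------------------------------------------------
# affine pre-alignment


def _affine_matrix(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12-parameter affine: translation, rotation (rad), log-scale, shear."""
    t = p[0:3]
    rx, ry, rz = p[3:6]
    scale = np.exp(p[6:9])
    kxy, kxz, kyz = p[9:12]
    Rx = np.array(
        [[1, 0, 0], [0, math.cos(rx), -math.sin(rx)], [0, math.sin(rx), math.cos(rx)]]
    )
    Ry = np.array(
        [[math.cos(ry), 0, math.sin(ry)], [0, 1, 0], [-math.sin(ry), 0, math.cos(ry)]]
    )
    Rz = np.array(
        [[math.cos(rz), -math.sin(rz), 0], [math.sin(rz), math.cos(rz), 0], [0, 0, 1]]
    )
    shear = np.array([[1, kxy, kxz], [0, 1, kyz], [0, 0, 1]], dtype=float)
    A = Rz @ Ry @ Rx @ shear @ np.diag(scale)
    return A, t


def _resample_affine(
    moving: np.ndarray, grid: Grid, A: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Sample moving at A (x - c) + c + t for each fixed-grid point x (mm)."""
    center = 0.5 * (np.asarray(grid.dims) - 1) * np.asarray(grid.spacing)
    coords = _identity_coords(grid.dims)
    mm = coords * np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    mm_c = mm - center.reshape(3, 1, 1, 1)
    mapped = np.einsum("ij,jxyz->ixyz", A, mm_c) + (t + center).reshape(3, 1, 1, 1)
    vox = mapped / np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    return _sample_scalar(moving, vox, order=1)


def affine_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    skip: bool = False,
    max_iter: int = 500,
) -> tuple[np.ndarray, ImageVolume]:
    """12-parameter affine pre-alignment minimising mean squared intensity
    error by multi-resolution derivative-free descent (Powell).

    Returns the homogeneous 4x4 transform (world mm, about the grid centre)
    and the moving image resampled onto the fixed grid.  With ``skip=True``
    the inputs pass through unchanged (pre-aligned data, e.g. phantoms).
    """
    from .volumes import _check_same_grid

    if skip:
        return np.eye(4), moving
    _check_same_grid(moving, fixed)
    grid = fixed.grid
    f_norm, m_norm = _joint_normalize(fixed.data, moving.data)
    p = np.zeros(12)
    level_trace: list[tuple[float, float]] = []
    for factor in (4, 2, 1):
        f_l, g_l = _downsample(f_norm, grid, factor)
        m_l, _ = _downsample(m_norm, grid, factor)

        def cost(q: np.ndarray) -> float:
            A, t = _affine_matrix(q)
            res = _resample_affine(m_l, g_l, A, t)
            return float(np.mean((f_l - res) ** 2))

        start = cost(p)
        res = optimize.minimize(
            cost,
            p,
            method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-7, "ftol": 1e-10},
        )
        end = cost(res.x)
        level_trace.append((start, end))
        if end > start + 1e-12:
            raise RegistrationError(
                f"affine optimiser diverged at pyramid factor {factor}: "
                f"MSE {start:.3e} -> {end:.3e}; trace={level_trace}"
            )
        p = res.x
    A, t = _affine_matrix(p)
    resampled = ImageVolume(_resample_affine(moving.data, grid, A, t), grid)
    center = 0.5 * (np.asarray(grid.dims) - 1) * np.asarray(grid.spacing)
    T = np.eye(4)
    T[:3, :3] = A
    T[:3, 3] = t + center - A @ center
    return T, resampled
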