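"""Affine and low-frequency nonlinear registration of scalar volumes.

The nonlinear deformation model is the classical small-deformation
parameterization used for spatial normalisation of brain images: each
component of the displacement field (in mm) is a separable expansion in
the lowest 7 x 9 x 7 discrete cosine modes per axis,

    u_a(x, y, z) = sum_ijk  c_a[i,j,k] * Bx_i(x) * By_j(y) * Bz_k(z),

with B_k(t) = cos(pi * k * t) on the normalized grid coordinate
t = (v + 0.5) / N.  The objective is the sum of squared differences
between the warped, smoothed, (optionally masked) source and the smoothed
template, plus a bending-energy penalty on the displacement field.  The
source is masked *before* smoothing so the non-smooth brain edge of the
selection mask does not drive the fit.

Optimization is deterministic Gauss-Newton on the basis coefficients with
step-halving line search and a two-stage coarse-to-fine schedule (strided
voxel subset + truncated basis first, then the full problem).  The
separable structure of the basis lets the normal matrix J'J be accumulated
with small tensor contractions instead of forming the (nvox x ncoef)
Jacobian.

The affine stage estimates 12 parameters (translations mm, rotations rad,
scales, shears) by the same Gauss-Newton machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage

from .volio import (
    BinaryMask,
    VolumetricImage,
    smooth_array,
)

__all__ = [
    "AffineParams",
    "DctWarp",
    "RegistrationConfig",
    "RegistrationResult",
    "affine_register",
    "nonlinear_register",
    "apply_transform",
    "displacement_field",
    "invert_displacement",
    "save_warp",
    "load_warp",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def affine_matrix_from_params(p: np.ndarray) -> np.ndarray:
    """Compose T * Rx * Ry * Rz * Shear * Scale from 12 parameters."""
    tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz = p
    T = np.eye(4)
    T[:3, 3] = (tx, ty, tz)
    cx, sx_ = np.cos(rx), np.sin(rx)
    cy, sy_ = np.cos(ry), np.sin(ry)
    cz, sz_ = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0, 0], [0, cx, sx_, 0], [0, -sx_, cx, 0], [0, 0, 0, 1]])
    Ry = np.array([[cy, 0, sy_, 0], [0, 1, 0, 0], [-sy_, 0, cy, 0], [0, 0, 0, 1]])
    Rz = np.array([[cz, sz_, 0, 0], [-sz_, cz, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
    H = np.eye(4)
    H[0, 1], H[0, 2], H[1, 2] = hxy, hxz, hyz
    S = np.diag([sx, sy, sz, 1.0])
    return T @ Rx @ Ry @ Rz @ H @ S


@dataclass(eq=False)
class AffineParams:
    """12-parameter affine: 3 translations (mm), 3 rotations (rad),
    3 scales, 3 shears, plus the composed 4x4 matrix (template world ->
    source world)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.shape != (12,):
            raise ValueError("expected 12 affine parameters")
        if np.linalg.det(self.matrix[:3, :3]) <= 0:
            raise ValueError("affine must have positive determinant")

    @classmethod
    def identity(cls) -> "AffineParams":
        p = np.zeros(12)
        p[6:9] = 1.0
        return cls(p)

    @property
    def matrix(self) -> np.ndarray:
        return affine_matrix_from_params(self.params)

    @property
    def translation(self) -> np.ndarray:
        return self.params[:3]

    @property
    def scales(self) -> np.ndarray:
        return self.params[6:9]


@dataclass(eq=False)
class DctWarp:
    """Separable cosine-basis displacement field on a template grid.

    ``coeff_*`` are the per-axis coefficient blocks in mm (default shape
    7 x 9 x 7); ``grid_shape``/``grid_affine`` describe the template grid
    the warp is defined on; ``affine`` is the affine it composes with
    (applied to world coordinates after adding the displacement).
    """

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    coeff_z: np.ndarray
    grid_shape: tuple
    grid_affine: np.ndarray
    affine: AffineParams | None = None

    def __post_init__(self) -> None:
        self.coeff_x = np.asarray(self.coeff_x, dtype=np.float64)
        self.coeff_y = np.asarray(self.coeff_y, dtype=np.float64)
        self.coeff_z = np.asarray(self.coeff_z, dtype=np.float64)
        if not (self.coeff_x.shape == self.coeff_y.shape == self.coeff_z.shape):
            raise ValueError("coefficient blocks must share one shape")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.grid_affine = np.asarray(self.grid_affine, dtype=np.float64)

    @property
    def basis_dims(self) -> tuple:
        return self.coeff_x.shape

    @classmethod
    def zero(cls, grid_shape, grid_affine, basis_dims=(7, 9, 7)) -> "DctWarp":
        z = np.zeros(basis_dims)
        return cls(z.copy(), z.copy(), z.copy(), grid_shape, grid_affine)


@dataclass(eq=False)
class RegistrationConfig:
    """Tunable knobs of the registration engine.

    ``source_fwhm_mm``/``template_fwhm_mm`` default to 8 mm (template
    smoothing matched to the source).  ``basis_dims`` defaults to the
    7 x 9 x 7 cosine modes per axis.  ``regularization_weight`` scales the
    bending-energy penalty relative to the mean-squared intensity
    residual.
    """

    source_fwhm_mm: float = 8.0
    template_fwhm_mm: float = 8.0
    regularization_weight: float = 0.05
    max_iterations: int = 16
    objective_tolerance: float = 1e-4
    basis_dims: tuple = (7, 9, 7)
    refine: bool = True  # add a half-FWHM refinement stage
    refine_fwhm_factor: float = 0.5
    refine_reg_factor: float = 0.4
    affine_max_iterations: int = 32

    def __post_init__(self) -> None:
        if self.source_fwhm_mm < 0 or self.template_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")
        if min(self.basis_dims) < 2:
            raise ValueError("basis_dims must each be >= 2")
        if self.max_iterations < 1 or self.objective_tolerance <= 0:
            raise ValueError("invalid iteration settings")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")

    def stages(self) -> list:
        """(source fwhm, template fwhm, regularization weight) per stage."""
        out = [
            (self.source_fwhm_mm, self.template_fwhm_mm, self.regularization_weight)
        ]
        if self.refine and self.source_fwhm_mm > 0:
            out.append(
                (
                    self.source_fwhm_mm * self.refine_fwhm_factor,
                    self.template_fwhm_mm * self.refine_fwhm_factor,
                    self.regularization_weight * self.refine_reg_factor,
                )
            )
        return out


@dataclass(eq=False)
class RegistrationResult:
    warp: DctWarp
    objective_trace: list = field(default_factory=list)  # final stage, monotone
    stage_traces: list = field(default_factory=list)  # per-stage traces
    converged: bool = False


# ---------------------------------------------------------------------------
# basis machinery
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA_LOCAL = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_BASIS_CACHE: dict = {}


def _dct_basis(n: int, k: int, deriv: int = 0, spacing: float = 1.0) -> np.ndarray:
    """Cosine basis matrix (n x k): B[v, j] = cos(pi j (v+0.5)/n).

    ``deriv`` returns the first/second derivative with respect to mm
    (spacing converts the normalized coordinate to world units).
    """
    key = (n, k, deriv, float(spacing))
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    t = (np.arange(n) + 0.5) / n
    j = np.arange(k)
    arg = np.pi * np.outer(t, j)
    scale = np.pi * j / (n * spacing)
    if deriv == 0:
        b = np.cos(arg)
    elif deriv == 1:
        b = -np.sin(arg) * scale
    elif deriv == 2:
        b = -np.cos(arg) * scale**2
    else:  # pragma: no cover
        raise ValueError("deriv must be 0, 1 or 2")
    _BASIS_CACHE[key] = b
    return b


def displacement_field(warp: DctWarp, stride: int = 1) -> np.ndarray:
    """Reconstruct the dense displacement field (mm), shape (3, nx, ny, nz)."""
    nx, ny, nz = warp.grid_shape
    kx, ky, kz = warp.basis_dims
    Bx = _dct_basis(nx, kx)[::stride]
    By = _dct_basis(ny, ky)[::stride]
    Bz = _dct_basis(nz, kz)[::stride]
    out = np.empty((3, Bx.shape[0], By.shape[0], Bz.shape[0]))
    for a, c in enumerate((warp.coeff_x, warp.coeff_y, warp.coeff_z)):
        t = np.tensordot(Bx, c, axes=(1, 0))  # (nx, ky, kz)
        t = np.tensordot(t, By, axes=(1, 1))  # (nx, kz, ny)
        t = np.tensordot(t, Bz, axes=(1, 1))  # (nx, ny, nz)
        out[a] = t
    return out


def _field_from_coeffs(coeffs: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """coeffs shape (3, kx, ky, kz) -> field (3, nx, ny, nz)."""
    out = np.empty((3, Bx.shape[0], By.shape[0], Bz.shape[0]))
    for a in range(3):
        t = np.tensordot(Bx, coeffs[a], axes=(1, 0))
        t = np.tensordot(t, By, axes=(1, 1))
        t = np.tensordot(t, Bz, axes=(1, 1))
        out[a] = t
    return out


def _bending_matrix(shape, basis_dims, voxel_size) -> np.ndarray:
    """Bending-energy quadratic form on one axis' coefficient block.

    Mean over grid voxels of the squared second derivatives of the
    displacement (mixed terms counted twice), expressed as a
    (prod(basis_dims) x prod(basis_dims)) matrix via Kronecker products of
    small per-axis Gram matrices.
    """
    n = tuple(shape)
    k = tuple(basis_dims)
    h = tuple(float(v) for v in voxel_size)
    grams = []
    for ax in range(3):
        g = []
        for d in range(3):
            b = _dct_basis(n[ax], k[ax], deriv=d, spacing=h[ax])
            g.append(b.T @ b / n[ax])
        grams.append(g)
    terms = [
        ((2, 0, 0), 1.0),
        ((0, 2, 0), 1.0),
        ((0, 0, 2), 1.0),
        ((1, 1, 0), 2.0),
        ((1, 0, 1), 2.0),
        ((0, 1, 1), 2.0),
    ]
    nk = k[0] * k[1] * k[2]
    R = np.zeros((nk, nk))
    for (dx, dy, dz), w in terms:
        R += w * np.kron(
            grams[0][dx], np.kron(grams[1][dy], grams[2][dz])
        )
    return R


def _jtj_block(w: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """sum_v w(v) * (Bx_i By_j Bz_k)(v) * (Bx_l By_m Bz_n)(v) as a matrix.

    Exploits separability; cost is linear in the voxel count.
    """
    A1 = np.einsum("xyz,xi,xl->yzil", w, Bx, Bx, optimize=True)
    A2 = np.einsum("yzil,yj,ym->ziljm", A1, By, By, optimize=True)
    A3 = np.einsum("ziljm,zk,zn->iljmkn", A2, Bz, Bz, optimize=True)
    kx, ky, kz = Bx.shape[1], By.shape[1], Bz.shape[1]
    # reorder (i,l,j,m,k,n) -> (i,j,k, l,m,n)
    A3 = A3.transpose(0, 2, 4, 1, 3, 5).reshape(kx * ky * kz, kx * ky * kz)
    return A3


def _jt_vec(w: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """sum_v w(v) * Bx_i By_j Bz_k, flattened."""
    t = np.tensordot(Bx.T, w, axes=(1, 0))  # (kx, ny, nz)
    t = np.tensordot(t, By, axes=(1, 0))  # (kx, nz, ky)
    t = np.tensordot(t, Bz, axes=(1, 0))  # (kx, ky, kz)
    return t.ravel()


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _sample(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(volume, coords, order=1, mode="grid-constant", cval=0.0)


def _intensity_scale(sw: np.ndarray, t: np.ndarray) -> float:
    denom = float((sw * sw).sum())
    if denom <= 0:
        return 1.0
    return float((sw * t).sum() / denom)


def _masked_source(source: VolumetricImage, template: VolumetricImage,
                   selection_mask) -> np.ndarray:
    if not source.same_grid(template):
        raise ValueError("source must be resampled to the template grid first")
    src = source.data
    if selection_mask is not None:
        mdata = selection_mask.data if isinstance(selection_mask, BinaryMask) else np.asarray(selection_mask)
        if mdata.sum() == 0:
            raise ValueError("selection mask is empty")
        src = src * mdata  # mask applied to the source BEFORE smoothing
    if float(np.ptp(src)) <= 1e-12:
        raise ValueError("degenerate (constant) source image")
    return src


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------


def affine_register(
    source: VolumetricImage,
    template: VolumetricImage,
    config: RegistrationConfig | None = None,
) -> AffineParams:
    """Estimate the 12-parameter affine mapping template world coordinates
    to source world coordinates by minimizing smoothed SSD.

    Deterministic (identity initialization, Gauss-Newton with
    step-halving); source and template may live on different grids.
    """
    config = config or RegistrationConfig()
    if float(np.ptp(source.data)) <= 1e-12:
        raise ValueError("degenerate (constant) source image")
    vs_s = source.voxel_size
    vs_t = template.voxel_size
    ss = smooth_array(source.data, config.source_fwhm_mm, vs_s)
    ts = smooth_array(template.data, config.template_fwhm_mm, vs_t)
    grads = np.stack(np.gradient(ss, *vs_s))
    inv_src = np.linalg.inv(source.affine)

    params = AffineParams.identity().params.copy()

    for stride in (2, 1):
        tsub = ts[::stride, ::stride, ::stride]
        # world coords of the strided template voxels
        idx = np.stack(
            np.meshgrid(
                np.arange(0, template.shape[0], stride),
                np.arange(0, template.shape[1], stride),
                np.arange(0, template.shape[2], stride),
                indexing="ij",
            )
        ).reshape(3, -1)
        world = template.affine[:3, :3] @ idx + template.affine[:3, 3:4]
        worldh = np.vstack([world, np.ones(world.shape[1])])
        tvec = tsub.ravel()
        n = tvec.size

        def objective(p):
            # inv_src maps world -> source voxel, so pos is in voxels
            m = inv_src @ affine_matrix_from_params(p)
            pos = (m @ worldh)[:3]
            sw = _sample(ss, pos)
            s = _intensity_scale(sw, tvec)
            r = s * sw - tvec
            return float((r * r).sum() / n), sw, s, pos

        obj, sw, s, pos = objective(params)
        for _ in range(config.affine_max_iterations):
            # Jacobian: dr/dp_j = s * grad_vox(pos) . d(pos)/dp_j
            gx = _sample(grads[0], pos)
            gy = _sample(grads[1], pos)
            gz = _sample(grads[2], pos)
            # grads are d/dmm of the source volume on its own grid; convert
            # the world-space step into voxel steps inside d(pos)/dp below.
            J = np.empty((n, 12))
            eps = 1e-6
            m0 = affine_matrix_from_params(params)
            for j in range(12):
                pj = params.copy()
                pj[j] += eps
                dm = (affine_matrix_from_params(pj) - m0) / eps
                dpos = (inv_src @ dm) @ worldh  # voxel-space velocity
                # chain with intensity gradient (per-mm) * voxel size
                # gradients are per-mm; convert voxel velocity to mm
                J[:, j] = s * (
                    gx * dpos[0] * vs_s[0]
                    + gy * dpos[1] * vs_s[1]
                    + gz * dpos[2] * vs_s[2]
                )
            r = s * sw - tvec
            g = 2.0 * J.T @ r / n
            H = 2.0 * J.T @ J / n
            H += np.eye(12) * (1e-8 * np.trace(H) / 12 + 1e-12)
            try:
                step = -np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            improved = False
            for _half in range(8):
                cand = params + step
                try:
                    new_obj, new_sw, new_s, new_pos = objective(cand)
                except Exception:
                    new_obj = np.inf
                if new_obj < obj and np.linalg.det(
                    affine_matrix_from_params(cand)[:3, :3]
                ) > 0:
                    improved = True
                    break
                step = step / 2.0
            if not improved:
                break
            rel = (obj - new_obj) / max(obj, 1e-30)
            params, obj, sw, s, pos = cand, new_obj, new_sw, new_s, new_pos
            if rel < config.objective_tolerance:
                break
    return AffineParams(params)


# ---------------------------------------------------------------------------
# nonlinear registration
# ---------------------------------------------------------------------------


def nonlinear_register(
    source: VolumetricImage,
    template: VolumetricImage,
    selection_mask: BinaryMask | np.ndarray | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate a DCT-parameterized displacement field warping the source
    onto the template.

    The source must already be affine-aligned onto the template grid.  The
    selection mask (whole brain / single hemisphere) is applied to the
    source before smoothing.  The objective per stage is the mean squared
    difference between the Gaussian-smoothed warped source and the
    smoothed template plus the weighted bending energy of the
    displacement; stages go from the configured FWHM to its refinement
    (half FWHM, lighter penalty) so coarse alignment precedes detail.
    The source is sampled with cubic splines, the Gauss-Newton normal
    matrix is accumulated through the separable basis structure, and a
    step-halving line search keeps every stage's objective trace
    monotone.  ``objective_trace`` reports the final stage.
    """
    config = config or RegistrationConfig()
    src = _masked_source(source, template, selection_mask)
    vs = template.voxel_size
    shape = template.shape
    kx, ky, kz = config.basis_dims
    Bx = _dct_basis(shape[0], kx)
    By = _dct_basis(shape[1], ky)
    Bz = _dct_basis(shape[2], kz)
    R = _bending_matrix(shape, config.basis_dims, vs)
    nk = kx * ky * kz

    base_coords = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )
    src_spline = ndimage.spline_filter(src, order=3)
    grads = np.stack(np.gradient(src, *vs))  # d/dmm of the raw source

    def warp_source(coords):
        return ndimage.map_coordinates(
            src_spline, coords, order=3, mode="grid-constant", cval=0.0,
            prefilter=False,
        )

    coeffs = np.zeros((3, kx, ky, kz))
    stage_traces: list[list] = []
    converged = False

    for s_fwhm, t_fwhm, lam in config.stages():
        ts = smooth_array(template.data, t_fwhm, vs)
        sigma_vox = None
        if s_fwhm > 0:
            sigma_vox = s_fwhm * FWHM_TO_SIGMA_LOCAL / vs

        def smooth_k(x):
            if sigma_vox is None:
                return x
            return ndimage.gaussian_filter(x, sigma_vox, mode="reflect")

        def objective(c):
            u = _field_from_coeffs(c, Bx, By, Bz)
            coords = base_coords + u / vs[:, None, None, None]
            sw = smooth_k(warp_source(coords))
            s = _intensity_scale(sw, ts)
            r = s * sw - ts
            data = float((r * r).sum() / r.size)
            cf = c.reshape(3, -1)
            reg = float(sum(cf[a] @ R @ cf[a] for a in range(3)))
            return data + lam * reg, coords, s, r

        obj, coords, s, r = objective(coeffs)
        trace = [obj]
        converged = False
        for _it in range(config.max_iterations):
            n = r.size
            rs = smooth_k(r)  # adjoint of the smoothing operator
            g3 = [_sample(grads[a], coords) for a in range(3)]
            H = np.zeros((3 * nk, 3 * nk))
            gvec = np.zeros(3 * nk)
            for a in range(3):
                gvec[a * nk : (a + 1) * nk] = (
                    2.0 * s * _jt_vec(rs * g3[a], Bx, By, Bz) / n
                )
                for b in range(a, 3):
                    blk = 2.0 * s * s * _jtj_block(g3[a] * g3[b], Bx, By, Bz) / n
                    H[a * nk : (a + 1) * nk, b * nk : (b + 1) * nk] = blk
                    if b != a:
                        H[b * nk : (b + 1) * nk, a * nk : (a + 1) * nk] = blk.T
            cact = coeffs.reshape(3, -1)
            for a in range(3):
                gvec[a * nk : (a + 1) * nk] += 2.0 * lam * (R @ cact[a])
                H[a * nk : (a + 1) * nk, a * nk : (a + 1) * nk] += 2.0 * lam * R
            H[np.diag_indices_from(H)] += 1e-7 * np.trace(H) / H.shape[0] + 1e-14
            try:
                step = -linalg.solve(H, gvec, assume_a="pos")
            except Exception:
                break
            if not np.all(np.isfinite(step)):
                raise FloatingPointError("non-finite Gauss-Newton step")
            step3 = step.reshape(3, kx, ky, kz)
            improved = False
            for _half in range(8):
                cand = coeffs + step3
                new_obj, ncoords, ns, nr = objective(cand)
                if np.isfinite(new_obj) and new_obj < obj:
                    improved = True
                    break
                step3 = step3 / 2.0
            if not improved:
                converged = True  # no further descent possible
                break
            rel = (obj - new_obj) / max(obj, 1e-30)
            coeffs, obj, coords, s, r = cand, new_obj, ncoords, ns, nr
            trace.append(obj)
            if rel < config.objective_tolerance:
                converged = True
                break
        stage_traces.append(trace)

    warp = DctWarp(coeffs[0], coeffs[1], coeffs[2], shape, template.affine)
    return RegistrationResult(
        warp=warp,
        objective_trace=stage_traces[-1] if stage_traces else [],
        stage_traces=stage_traces,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# transform application
# ---------------------------------------------------------------------------


def apply_transform(
    image: VolumetricImage,
    affine: AffineParams | np.ndarray | None,
    warp: DctWarp | None,
    target_shape=None,
    target_affine=None,
    order: str = "trilinear",
    space_tag: str = "template",
) -> VolumetricImage:
    """Pull-back resampling through (warp, affine).

    For each target voxel v: world position p = A_t v + u(v) (u from the
    warp, zero when absent), then p' = M p (identity when affine absent),
    then source voxel = A_s^-1 p'.  A single interpolation is performed.
    """
    if warp is not None:
        if target_shape is None:
            target_shape = warp.grid_shape
        if target_affine is None:
            target_affine = warp.grid_affine
        if tuple(target_shape) != tuple(warp.grid_shape) or not np.allclose(
            target_affine, warp.grid_affine
        ):
            raise ValueError("target grid does not match the warp descriptor")
    if target_shape is None:
        target_shape = image.shape
    if target_affine is None:
        target_affine = image.affine
    target_affine = np.asarray(target_affine, dtype=np.float64)

    m = np.eye(4) if affine is None else (
        affine.matrix if isinstance(affine, AffineParams) else np.asarray(affine)
    )
    nx, ny, nz = target_shape
    idx = np.stack(
        np.meshgrid(
            np.arange(nx, dtype=float),
            np.arange(ny, dtype=float),
            np.arange(nz, dtype=float),
            indexing="ij",
        )
    )
    world = np.einsum("ab,bxyz->axyz", target_affine[:3, :3], idx) + target_affine[
        :3, 3
    ].reshape(3, 1, 1, 1)
    if warp is not None:
        world = world + displacement_field(warp)
    world = np.einsum("ab,bxyz->axyz", m[:3, :3], world) + m[:3, 3].reshape(3, 1, 1, 1)
    inv_src = np.linalg.inv(image.affine)
    vox = np.einsum("ab,bxyz->axyz", inv_src[:3, :3], world) + inv_src[:3, 3].reshape(
        3, 1, 1, 1
    )
    interp_order = {"nearest": 0, "trilinear": 1}[order]
    out = ndimage.map_coordinates(
        image.data, vox, order=interp_order, mode="grid-constant", cval=0.0
    )
    return VolumetricImage(out, target_affine, space_tag)


def invert_displacement(
    u: np.ndarray, voxel_size, n_iter: int = 20, tol: float = 1e-3
) -> np.ndarray:
    """Numerical fixed-point inverse of a dense displacement field (mm).

    Solves u_inv(v) = -u(v + u_inv(v)/h) by iteration; adequate for the
    small, smooth deformations used here.
    """
    vs = np.asarray(voxel_size, dtype=float)[:, None, None, None]
    shape = u.shape[1:]
    base = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    )
    uinv = -u.copy()
    for _ in range(n_iter):
        coords = base + uinv / vs
        sampled = np.stack([_sample(u[a], coords) for a in range(3)])
        new = -sampled
        if float(np.abs(new - uinv).max()) < tol:
            uinv = new
            break
        uinv = new
    return uinv


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_warp(warp: DctWarp, path) -> None:
    """Serialize coefficients + grid descriptor as JSON."""
    payload = {
        "basis_dims": list(warp.basis_dims),
        "grid_shape": list(warp.grid_shape),
        "grid_affine": warp.grid_affine.tolist(),
        "coeff_x": warp.coeff_x.tolist(),
        "coeff_y": warp.coeff_y.tolist(),
        "coeff_z": warp.coeff_z.tolist(),
        "affine_params": None
        if warp.affine is None
        else warp.affine.params.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_warp(path) -> DctWarp:
    with open(path) as fh:
        payload = json.load(fh)
    aff = payload.get("affine_params")
    return DctWarp(
        np.asarray(payload["coeff_x"]),
        np.asarray(payload["coeff_y"]),
        np.asarray(payload["coeff_z"]),
        tuple(payload["grid_shape"]),
        np.asarray(payload["grid_affine"]),
        None if aff is None else AffineParams(np.asarray(aff)),
    )


def export_displacement_nifti(warp: DctWarp, path) -> None:
    """Write the dense displacement field as a 4D NIfTI (3 volumes, mm)."""
    import nibabel as nib

    u = displacement_field(warp)
    img = nib.Nifti1Image(
        np.moveaxis(u, 0, -1).astype(np.float32), warp.grid_affine
    )
    nib.save(img, str(path))
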