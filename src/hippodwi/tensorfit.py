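"""Diffusion tensor estimation and scalar map derivation.

Per-voxel apparent diffusion coefficients and symmetric diffusion tensors
are estimated from a diffusion-weighted stack by weighted least squares on
log-signals, then eigendecomposed into fractional anisotropy (FA), mean
diffusivity (MD) and the primary in-plane diffusion orientation.

Conventions
-----------
Tensors live in image (x, y, z) coordinates where x is the left-right
(column) axis and y the dorso-ventral (row) axis.  Orientations are axial:
the angle of the principal eigenvector measured counterclockwise from +x,
reported in degrees on [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorField",
    "ScalarMaps",
    "FitConfigurationError",
    "adc_from_signal",
    "fit_tensor",
    "tensor_metrics",
    "otsu_mask",
]

# column order of the 6 unique tensor entries
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


class FitConfigurationError(ValueError):
    """Raised when the acquisition scheme cannot support a tensor fit."""


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s).

    ``d6`` holds the unique entries (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in the
    trailing axis; ``mask`` flags voxels that participated in the fit and
    ``n_clamped`` counts voxels whose negative eigenvalues were clamped.
    """

    d6: np.ndarray  # (..., 6)
    mask: np.ndarray  # (...), bool
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.d6 = np.asarray(self.d6, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.d6.shape[-1] != 6:
            raise ValueError("tensor field needs 6 components per voxel")
        if self.d6.shape[:-1] != self.mask.shape:
            raise ValueError("mask and tensor grids disagree")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def to_matrices(self) -> np.ndarray:
        """Expand to full (..., 3, 3) symmetric matrices."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.d6, -1, 0)
        out = np.empty(self.d6.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = xx
        out[..., 1, 1] = yy
        out[..., 2, 2] = zz
        out[..., 0, 1] = out[..., 1, 0] = xy
        out[..., 0, 2] = out[..., 2, 0] = xz
        out[..., 1, 2] = out[..., 2, 1] = yz
        return out

    @classmethod
    def from_matrices(cls, mats: np.ndarray, mask: np.ndarray | None = None,
                      n_clamped: int = 0) -> "TensorField":
        mats = np.asarray(mats, dtype=float)
        if mats.shape[-2:] != (3, 3):
            raise ValueError("expected trailing (3, 3) matrices")
        d6 = np.stack(
            [mats[..., 0, 0], mats[..., 1, 1], mats[..., 2, 2],
             mats[..., 0, 1], mats[..., 0, 2], mats[..., 1, 2]], axis=-1)
        if mask is None:
            mask = np.ones(mats.shape[:-2], dtype=bool)
        return cls(d6=d6, mask=mask, n_clamped=n_clamped)


@dataclass
class ScalarMaps:
    """FA, MD and primary in-plane orientation derived from a tensor field."""

    fa: np.ndarray           # dimensionless, [0, 1]
    md: np.ndarray           # mm^2/s
    theta_deg: np.ndarray    # degrees in [0, 180)
    valid: np.ndarray        # bool: voxel carries a fitted tensor
    theta_valid: np.ndarray = field(default=None)  # bool: orientation defined

    def __post_init__(self) -> None:
        if self.theta_valid is None:
            self.theta_valid = np.asarray(self.valid, dtype=bool).copy()


def adc_from_signal(signal, s0, b, eps: float = 1e-6):
    """Pointwise apparent diffusion coefficient, ADC = -ln(S/S0)/b.

    The signal ratio is clamped to (eps, 1] before the logarithm so that
    noise-floor voxels (S <= 0) and noise excursions above S0 yield finite
    values instead of exceptions.  Returns ``(adc, clamped)`` where
    ``clamped`` flags voxels whose ratio was clipped.
    """
    signal = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("S0 must be positive")
    if not b > 0:
        raise ValueError("b-value must be positive")
    ratio = signal / s0
    clamped = (ratio <= eps) | (ratio > 1.0)
    ratio = np.clip(ratio, eps, 1.0)
    return -np.log(ratio) / b, clamped


def design_matrix(bvecs: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    """Rows b_i * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)
    gx, gy, gz = g.T
    cols = np.stack([gx ** 2, gy ** 2, gz ** 2,
                     2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1)
    return b[:, None] * cols


def otsu_mask(stack) -> np.ndarray:
    """Foreground mask from an Otsu threshold on the mean b=0 image.

    Suited to acquisitions where background (air) is dark; the phantom
    pipeline instead masks from its known label map.
    """
    from skimage.filters import threshold_otsu

    b0 = stack.mean_b0()
    thr = threshold_otsu(b0)
    return b0 > thr


def fit_tensor(stack, mask: np.ndarray | None = None,
               eps: float = 1e-6) -> TensorField:
    """Weighted least-squares tensor fit of a diffusion-weighted stack.

    Solves ``B d = y`` per voxel with ``y_i = ln(S0 / S_i)`` and weights
    ``S_i^2`` -- the standard one-pass WLS for log-transformed magnitude
    data.  Negative eigenvalues are clamped to zero afterwards and counted
    in ``n_clamped``.
    """
    dwi = stack.dwi_data()              # (..., n_dirs)
    s0 = stack.mean_b0()                # (...)
    scheme = stack.scheme
    B = design_matrix(scheme.bvecs, scheme.bvals)
    if np.linalg.matrix_rank(B) < 6:
        raise FitConfigurationError(
            "gradient scheme is rank-deficient: need >= 6 non-collinear "
            "directions")

    grid_shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & (s0 > 0)

    d6 = np.zeros(grid_shape + (6,), dtype=float)
    idx = np.flatnonzero(mask.ravel())
    if idx.size:
        S = dwi.reshape(-1, dwi.shape[-1])[idx]
        S0v = s0.ravel()[idx][:, None]
        ratio = np.clip(S / S0v, eps, 1.0)
        y = -np.log(ratio)
        w = S ** 2
        # batched normal equations: (B' W B) d = B' W y
        A = np.einsum("vd,di,dj->vij", w, B, B, optimize=True)
        rhs = np.einsum("vd,di->vi", w * y, B, optimize=True)
        d6.reshape(-1, 6)[idx] = np.linalg.solve(A, rhs[..., None])[..., 0]

    field_ = TensorField(d6=d6, mask=mask)
    # clamp negative eigenvalues (rare at tissue diffusivities, logged)
    mats = field_.to_matrices()[mask]
    if mats.size:
        evals, evecs = np.linalg.eigh(mats)
        bad = evals[..., 0] < 0
        n_bad = int(bad.sum())
        if n_bad:
            ev = np.clip(evals[bad], 0.0, None)
            fixed = np.einsum("vij,vj,vkj->vik", evecs[bad], ev, evecs[bad])
            mats[bad] = fixed
            full = field_.to_matrices()
            full[mask] = mats
            field_ = TensorField.from_matrices(full, mask=mask,
                                               n_clamped=n_bad)
    return field_


def tensor_metrics(tensors: TensorField, degen_tol: float = 1e-12) -> ScalarMaps:
    """FA, MD and axial in-plane orientation from a tensor field.

    Eigenvalues are sorted descending; FA uses the standard normalized
    eigenvalue-dispersion formula.  The orientation theta is the in-plane
    angle of the principal eigenvector and is masked where the two leading
    eigenvalues are degenerate (within ``degen_tol`` mm^2/s) or the
    eigenvector has no in-plane component.
    """
    mats = tensors.to_matrices()
    mask = tensors.mask
    evals, evecs = np.linalg.eigh(mats)          # ascending
    evals = evals[..., ::-1]
    e1 = evecs[..., ::-1][..., :, 0]             # principal eigenvector

    md = evals.mean(axis=-1)
    dev = evals - md[..., None]
    num = np.sqrt((dev ** 2).sum(axis=-1))
    den = np.sqrt((evals ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    ex, ey = e1[..., 0], e1[..., 1]
    inplane = np.hypot(ex, ey)
    theta = np.degrees(np.arctan2(ey, ex)) % 180.0
    theta_valid = mask & (evals[..., 0] - evals[..., 1] > degen_tol) \
        & (inplane > 1e-8)
    theta = np.where(theta_valid, theta, np.nan)

    fa = np.where(mask, fa, np.nan)
    md = np.where(mask, md, np.nan)
    return ScalarMaps(fa=fa, md=md, theta_deg=theta, valid=mask.copy(),
                      theta_valid=theta_valid)
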