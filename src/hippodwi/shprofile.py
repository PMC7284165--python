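"""Spherical-harmonic ADC profiles and axis diffusivities.

The per-direction apparent diffusion coefficient of each voxel is expanded
in a real, even-order spherical harmonic basis (antipodally symmetric, as
ADC profiles must be) and evaluated along the two in-plane anatomical
axes: dorso-ventral (0, 1, 0) and left-right (1, 0, 0).  The resulting
dvD, lrD and their ratio are the axis-diffusivity measures used by the
region statistics.

A tensor ADC profile g -> g' D g is an exactly degree-2 even polynomial on
the sphere, so an order-2 fit reproduces tensor-derived axis diffusivities
to machine precision, which makes the tensor and SH routes mutually
consistent oracles on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .tensorfit import adc_from_signal

__all__ = [
    "ADCProfile",
    "AxisDiffusivities",
    "SHConfigurationError",
    "DV_AXIS",
    "LR_AXIS",
    "n_coefficients",
    "sh_basis",
    "fit_sh",
    "evaluate_axis",
    "axis_maps",
]

DV_AXIS = np.array([0.0, 1.0, 0.0])
LR_AXIS = np.array([1.0, 0.0, 0.0])

_MAX_ORDER = 8
_LR_FLOOR = 1e-6  # mm^2/s: ratio undefined below this left-right diffusivity


class SHConfigurationError(ValueError):
    """Invalid order or underdetermined spherical-harmonic fit."""


def n_coefficients(order: int) -> int:
    """Number of real even-order SH coefficients up to ``order``."""
    return (order + 1) * (order + 2) // 2


def _check_order(order: int) -> None:
    if order % 2 or order < 0 or order > _MAX_ORDER:
        raise SHConfigurationError(
            f"SH order must be even and in [0, {_MAX_ORDER}], got {order}")


def sh_basis(order: int, dirs: np.ndarray) -> np.ndarray:
    """Real even-order spherical harmonic design matrix.

    Rows are directions, columns run over (l, m) with l = 0, 2, ..., order
    and m = -l..l using the standard real combination of complex harmonics
    (sqrt(2) times the imaginary/real part for m < 0 / m > 0).
    """
    _check_order(order)
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / norms
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])            # azimuth
    cols = []
    for ell in range(0, order + 1, 2):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            cols.append(col)
    return np.stack(cols, axis=1)


@dataclass
class ADCProfile:
    """Even-order SH expansion of per-voxel ADC profiles (mm^2/s)."""

    coeffs: np.ndarray      # (..., n_coefficients)
    order: int
    condition_number: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[-1] != n_coefficients(self.order):
            raise ValueError("coefficient count does not match order")


@dataclass
class AxisDiffusivities:
    """Diffusivity along the dorso-ventral and left-right axes (mm^2/s)."""

    dvd: np.ndarray
    lrd: np.ndarray
    ratio: np.ndarray       # dvD / lrD, NaN where undefined
    valid: np.ndarray       # bool
    ratio_valid: np.ndarray  # bool: valid and lrD above floor


def fit_sh(adc_samples: np.ndarray, scheme, order: int = 4) -> ADCProfile:
    """Least-squares even-order SH fit of per-direction ADC samples.

    ``adc_samples`` has the gradient direction on its trailing axis and is
    fit against the scheme's unit directions.  Deterministic; raises if
    the system is underdetermined.
    """
    _check_order(order)
    adc = np.asarray(adc_samples, dtype=float)
    B = sh_basis(order, scheme.bvecs)
    if adc.shape[-1] != B.shape[0]:
        raise ValueError("ADC samples do not match scheme directions")
    if B.shape[0] < B.shape[1]:
        raise SHConfigurationError(
            f"underdetermined fit: {B.shape[0]} directions for "
            f"{B.shape[1]} coefficients")
    cond = float(np.linalg.cond(B))
    pinv = np.linalg.pinv(B)
    coeffs = adc @ pinv.T
    return ADCProfile(coeffs=coeffs, order=order, condition_number=cond)


def evaluate_axis(profile: ADCProfile, axis: np.ndarray) -> np.ndarray:
    """Evaluate the SH expansion along one axis (antipodally symmetric)."""
    b = sh_basis(profile.order, np.asarray(axis, dtype=float))[0]
    return profile.coeffs @ b


def axis_maps(stack, mask: np.ndarray | None = None,
              order: int = 4) -> AxisDiffusivities:
    """Per-voxel dvD / lrD / ratio maps from a diffusion-weighted stack.

    ADC is computed per direction against the mean b=0 image, expanded in
    SH per voxel, and evaluated along the two anatomical axes.  The ratio
    is masked where lrD falls below 1e-6 mm^2/s.
    """
    grid_shape = stack.grid_shape
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    dvd = np.full(grid_shape, np.nan)
    lrd = np.full(grid_shape, np.nan)
    idx = np.flatnonzero(mask.ravel())
    if idx.size:
        b = float(stack.scheme.bvals[0])
        dwi = stack.dwi_data().reshape(-1, stack.scheme.n_dirs)[idx]
        s0 = stack.mean_b0().ravel()[idx][:, None]
        adc, _ = adc_from_signal(dwi, s0, b)
        profile = fit_sh(adc, stack.scheme, order=order)
        dvd.ravel()[idx] = np.clip(evaluate_axis(profile, DV_AXIS), 0.0, None)
        lrd.ravel()[idx] = np.clip(evaluate_axis(profile, LR_AXIS), 0.0, None)

    ratio_valid = mask & (lrd > _LR_FLOOR)
    ratio = np.full(grid_shape, np.nan)
    ratio[ratio_valid] = dvd[ratio_valid] / lrd[ratio_valid]
    return AxisDiffusivities(dvd=dvd, lrd=lrd, ratio=ratio, valid=mask.copy(),
                             ratio_valid=ratio_valid)
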