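"""Parametric hippocampal-slice phantoms.

A phantom is a stylized 2D transverse hippocampal section built from
concentric arcs and wedges: an outer C-shaped CA1 pyramidal band continuing
into CA3, a stratum-radiatum band interior to CA1, a V-shaped granule cell
layer (DG) and a hilar wedge between the DG blades.  Each region carries an
axial orientation field (von Mises on doubled angles), a cell-density proxy
map and an anisotropic diffusion tensor whose radial/tangential
diffusivities are coupled to density, so that the group-level contrasts and
density-diffusion correlations seen in kainate-model epilepsy (pyramidal
cell loss in CA1/CA3, granule-cell dispersion, mossy-fiber sprouting into
the hilus) are reproduced with controllable effect sizes.

Conditions
----------
``control`` slices use the baseline tissue parameters.  ``ipsilateral``
slices (kainate-injected side) lose CA1/CA3 cells (density down, tensors
more isotropic, orientations uniform), disperse the granule cell layer
(band twice as wide, diffusivities up) and gain coherent mossy fibers in
the hilus (FA up).  ``contralateral`` slices show a mild partial CA1 cell
loss only.  Epileptic slices draw a per-slice severity scalar in [0.5, 1]
that scales every effect, creating the within-group spread needed for
intra-group density-diffusion correlations.

Geometry: row index = dorso-ventral (y) axis, column index = left-right
(x) axis, angles counterclockwise from +x, 0-based indexing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .tensorfit import TensorField

__all__ = [
    "ROI_NAMES",
    "ROI_LABELS",
    "CONDITIONS",
    "TissueParams",
    "ConditionEffect",
    "PhantomSpec",
    "ROISet",
    "DensityMap",
    "Phantom",
    "GeometryError",
    "PhantomConfigurationError",
    "generate_geometry",
    "generate_orientation_field",
    "build_tensor_field",
    "generate_density",
    "measure_gcl_width",
    "generate_phantom",
]

ROI_NAMES = ("CA1", "CA3", "DG", "hilus", "srCA1")
ROI_LABELS = {"background": 0, "CA1": 1, "CA3": 2, "DG": 3, "hilus": 4,
              "srCA1": 5}
CONDITIONS = ("control", "ipsilateral", "contralateral")

#: free-water (saline) diffusivity used for background voxels, mm^2/s
SALINE_DIFFUSIVITY = 2.0e-3

_MD_BOUNDS = (0.1e-3, 2.0e-3)


class GeometryError(ValueError):
    """Grid too small (or otherwise unable) to place all five ROIs."""


class PhantomConfigurationError(ValueError):
    """Tissue/coupling parameters produce a non-physical phantom."""


@dataclass(frozen=True)
class TissueParams:
    """Per-ROI microstructural parameters.

    mu_deg
        mean axial orientation, degrees in [0, 180) counterclockwise from
        the left-right (+x) image axis.
    kappa
        von Mises concentration applied on doubled angles (axial data);
        0 means uniform axial orientations.
    lam_par, lam_perp
        axial/radial tensor eigenvalues, mm^2/s (lam_par >= lam_perp > 0).
    baseline_density
        cell-density proxy in arbitrary units, [0, 1].
    """

    mu_deg: float
    kappa: float
    lam_par: float
    lam_perp: float
    baseline_density: float

    def __post_init__(self) -> None:
        if not (self.lam_par >= self.lam_perp > 0):
            raise PhantomConfigurationError(
                "need lam_par >= lam_perp > 0, got "
                f"({self.lam_par}, {self.lam_perp})")
        if self.kappa < 0:
            raise PhantomConfigurationError("kappa must be >= 0")
        md = (self.lam_par + 2 * self.lam_perp) / 3
        if not (_MD_BOUNDS[0] <= md <= _MD_BOUNDS[1]):
            raise PhantomConfigurationError(
                f"mean diffusivity {md:.2e} outside fixed-tissue range "
                f"{_MD_BOUNDS}")
        if not (0 <= self.baseline_density <= 1):
            raise PhantomConfigurationError("baseline_density must be in [0,1]")


# Baseline (control) tissue: fixed-tissue diffusivities around 0.5e-3 mm^2/s,
# orientations per the layered dendrite/axon architecture: dorso-ventral
# (90 deg) dendrites in CA1 and the GCL, oblique (45 deg) dendrites in CA3,
# left-right (0 deg) mossy fibers in the hilus and Schaffer collaterals in
# the CA1 stratum radiatum.
DEFAULT_TISSUE: dict[str, TissueParams] = {
    "CA1": TissueParams(90.0, 12.0, 0.90e-3, 0.30e-3, 0.80),
    "CA3": TissueParams(45.0, 10.0, 0.84e-3, 0.33e-3, 0.75),
    "DG": TissueParams(90.0, 14.0, 0.80e-3, 0.35e-3, 0.90),
    "hilus": TissueParams(0.0, 7.0, 0.72e-3, 0.39e-3, 0.45),
    "srCA1": TissueParams(0.0, 10.0, 0.85e-3, 0.325e-3, 0.35),
}


@dataclass(frozen=True)
class ConditionEffect:
    """Severity-scaled modification of one ROI under one condition.

    density_loss
        fractional density reduction at severity 1 (density factor is
        ``1 - density_loss * severity``).
    kappa
        orientation concentration override (None keeps the baseline);
        0 models complete loss of directional conformity.
    diff_scale
        both eigenvalues scaled by ``1 + diff_scale * severity`` (bulk
        diffusivity increase, e.g. dispersed GCL).
    par_scale / perp_scale
        additional axial / radial scaling, same severity law (anisotropy
        increase, e.g. mossy-fiber sprouting into the hilus).
    """

    density_loss: float = 0.0
    kappa: float | None = None
    diff_scale: float = 0.0
    par_scale: float = 0.0
    perp_scale: float = 0.0


DEFAULT_CONDITION_EFFECTS: dict[str, dict[str, ConditionEffect]] = {
    "control": {},
    "ipsilateral": {
        # pyramidal cell loss: fewer cells, near-isotropic, no preferred axis
        "CA1": ConditionEffect(density_loss=0.75, kappa=0.0),
        "CA3": ConditionEffect(density_loss=0.60, kappa=0.0),
        # granule cell dispersion: wider, less dense GCL, higher diffusivity
        "DG": ConditionEffect(density_loss=0.20, diff_scale=0.45),
        # mossy fiber sprouting: coherent left-right fibers, FA and MD up
        "hilus": ConditionEffect(par_scale=0.60, perp_scale=0.15, kappa=12.0),
        "srCA1": ConditionEffect(density_loss=0.20),
    },
    "contralateral": {
        # partial CA1 pyramidal cell loss only
        "CA1": ConditionEffect(density_loss=0.12),
    },
}

#: GCL band-width multiplier per condition (granule cell dispersion)
DEFAULT_GCL_DISPERSION = {"control": 1.0, "ipsilateral": 2.0,
                          "contralateral": 1.0}


@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic hippocampal slice."""

    grid_shape: tuple[int, int] = (128, 102)   # rows (dv) x cols (lr)
    voxel_size: float = 0.04                    # mm, in-plane
    condition: str = "control"
    tissue: dict[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE))
    condition_effects: dict[str, dict[str, ConditionEffect]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CONDITION_EFFECTS))
    # density -> diffusivity coupling: for a density deficit
    # d = baseline - observed, lam_perp += b_md * d and lam_par -= b_fa * d
    # (cell loss raises radial diffusivity and lowers anisotropy).
    b_md: float = 0.25e-3
    b_fa: float = 0.50e-3
    gcl_dispersion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GCL_DISPERSION))
    severity: float | None = None       # drawn in [0.5, 1] if None (epileptic)
    tissue_jitter_cv: float = 0.05      # per-slice biological variability
    density_jitter_cv: float = 0.05     # per-slice ROI density variability
    density_noise_cv: float = 0.10      # per-voxel density noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PhantomConfigurationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not (self.voxel_size > 0):
            raise PhantomConfigurationError("voxel_size must be > 0")
        ny, nx = self.grid_shape
        if ny < 32 or nx < 32:
            raise GeometryError("grid_shape must be at least 32 x 32")
        missing = set(ROI_NAMES) - set(self.tissue)
        if missing:
            raise PhantomConfigurationError(f"tissue params missing for {missing}")

    def effect(self, roi: str) -> ConditionEffect:
        return self.condition_effects.get(self.condition, {}).get(
            roi, ConditionEffect())

    def effective_kappa(self, roi: str) -> float:
        eff = self.effect(roi)
        return self.tissue[roi].kappa if eff.kappa is None else eff.kappa


@dataclass
class ROISet:
    """Named integer label map partitioning the grid."""

    labels: np.ndarray                  # (ny, nx) int
    voxel_size: float
    names: dict[str, int] = field(default_factory=lambda: dict(ROI_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        known = set(self.names.values())
        if not set(np.unique(self.labels)) <= known:
            raise ValueError("label map contains unknown labels")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.names[name]

    def tissue_mask(self) -> np.ndarray:
        return self.labels != self.names["background"]

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == lab).sum())
                for name, lab in self.names.items()}


@dataclass
class DensityMap:
    """Cell-density proxy (arbitrary units >= 0) plus slice summaries."""

    values: np.ndarray                  # (ny, nx), background = 0
    roi_means: dict[str, float]
    gcl_width_mm: float
    severity: float


@dataclass
class Phantom:
    """A fully generated slice: geometry, orientations, density, tensors."""

    spec: PhantomSpec
    roiset: ROISet
    orientations: np.ndarray            # degrees in [0, 180)
    density: DensityMap
    tensors: TensorField
    roi_lambdas: dict[str, tuple[float, float]]  # effective (par, perp)


# ---------------------------------------------------------------------------
# geometry

def _band_widths(spec: PhantomSpec) -> dict[str, float]:
    m = min(spec.grid_shape)
    disp = spec.gcl_dispersion.get(spec.condition, 1.0)
    return {
        "ca1": max(3.0, 0.055 * m),
        "sr": max(3.0, 0.050 * m),
        "gcl": max(2.0, 0.045 * m) * disp,
    }


def generate_geometry(spec: PhantomSpec) -> ROISet:
    """Build the stylized label map of one hippocampal section.

    Concentric arcs around the grid center: CA1 occupies the upper arc of
    an outer annulus, CA3 continues it around the left/lower-left side,
    srCA1 lines the inside of CA1, the DG/GCL is a thinner U-shaped band
    near the center opening upward, and the hilus fills the wedge the DG
    encloses.  Band widths scale with grid size; the GCL width is
    multiplied by the condition's dispersion factor.
    """
    ny, nx = spec.grid_shape
    m = min(ny, nx)
    w = _band_widths(spec)

    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rows, cols = np.indices((ny, nx))
    x = cols - cx
    y = cy - rows                       # y points dorsally (up in the image)
    r = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0

    r1o = 0.46 * m
    r1i = r1o - w["ca1"]
    rso = r1i
    rsi = rso - w["sr"]
    rdo = 0.24 * m
    rdi = rdo - w["gcl"]
    if rdi <= 1.0 or rsi <= rdo:
        raise GeometryError(
            f"grid {spec.grid_shape} too small for the configured band widths")

    annulus = (r >= r1i) & (r < r1o)
    ca1 = annulus & (ang >= 30.0) & (ang <= 150.0)
    ca3 = annulus & (ang > 150.0) & (ang <= 270.0)
    sr = (r >= rsi) & (r < rso) & (ang >= 30.0) & (ang <= 150.0)
    dg_wedge = (ang >= 190.0) & (ang <= 350.0)
    dg = (r >= rdi) & (r < rdo) & dg_wedge
    hilus = (r < rdi) & dg_wedge

    labels = np.zeros((ny, nx), dtype=np.int16)
    for name, mask in (("CA1", ca1), ("CA3", ca3), ("srCA1", sr),
                       ("DG", dg), ("hilus", hilus)):
        labels[mask] = ROI_LABELS[name]

    roiset = ROISet(labels=labels, voxel_size=spec.voxel_size)
    counts = roiset.counts()
    empty = [name for name in ROI_NAMES if counts[name] == 0]
    if empty:
        raise GeometryError(f"grid too small: empty ROIs {empty}")
    return roiset


# ---------------------------------------------------------------------------
# orientations

def generate_orientation_field(roiset: ROISet, spec: PhantomSpec,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-voxel axial orientations, degrees in [0, 180).

    Axial von Mises sampling by angle doubling: phi ~ vonMises(2 mu, kappa),
    orientation = (phi / 2) mod 180.  kappa = 0 yields uniform axial
    orientations (used to model loss of directional conformity).
    Background voxels get uniform orientations (their tensors are isotropic
    so the value is immaterial).
    """
    if roiset.grid_shape != tuple(spec.grid_shape):
        raise ValueError("roiset and spec grids disagree")
    theta = rng.uniform(0.0, 180.0, size=roiset.grid_shape)
    for roi in ROI_NAMES:
        if roi not in spec.tissue:
            raise PhantomConfigurationError(f"no TissueParams for ROI {roi}")
        mask = roiset.mask(roi)
        n = int(mask.sum())
        mu2 = np.radians(2.0 * spec.tissue[roi].mu_deg)
        kappa = spec.effective_kappa(roi)
        phi = rng.vonmises(mu2, kappa, size=n) if kappa > 0 \
            else rng.uniform(-np.pi, np.pi, size=n)
        theta[mask] = (np.degrees(phi) / 2.0) % 180.0
    return theta


# ---------------------------------------------------------------------------
# tensors

def build_tensor_field(roiset: ROISet, orientations: np.ndarray,
                       spec: PhantomSpec,
                       roi_lambdas: dict[str, tuple[float, float]] | None = None,
                       ) -> TensorField:
    """Axially symmetric tensors with the in-plane principal axis.

    D = lam_perp I + (lam_par - lam_perp) e e^T with e = (cos t, sin t, 0)
    at each voxel's orientation angle t.  Background voxels get an
    isotropic saline-like tensor (trace/3 = 2.0e-3 mm^2/s).  ``roi_lambdas``
    overrides the baseline eigenvalues per ROI (used for density coupling
    and condition effects).
    """
    if roiset.grid_shape != np.shape(orientations):
        raise ValueError("orientation map and label map grids disagree")
    ny, nx = roiset.grid_shape
    lam_par = np.full((ny, nx), SALINE_DIFFUSIVITY)
    lam_perp = np.full((ny, nx), SALINE_DIFFUSIVITY)
    for roi in ROI_NAMES:
        tp = spec.tissue[roi]
        lp, lq = (roi_lambdas or {}).get(roi, (tp.lam_par, tp.lam_perp))
        if not (lp >= lq > 0):
            raise PhantomConfigurationError(
                f"effective eigenvalues for {roi} are non-physical: ({lp}, {lq})")
        mask = roiset.mask(roi)
        lam_par[mask] = lp
        lam_perp[mask] = lq

    t = np.radians(np.asarray(orientations, dtype=float))
    c, s = np.cos(t), np.sin(t)
    d6 = np.zeros((ny, nx, 6))
    delta = lam_par - lam_perp
    d6[..., 0] = lam_perp + delta * c * c      # xx
    d6[..., 1] = lam_perp + delta * s * s      # yy
    d6[..., 2] = lam_perp                      # zz
    d6[..., 3] = delta * c * s                 # xy
    return TensorField(d6=d6, mask=np.ones((ny, nx), dtype=bool))


# ---------------------------------------------------------------------------
# density and coupling

def generate_density(roiset: ROISet, spec: PhantomSpec,
                     rng: np.random.Generator) -> DensityMap:
    """Cell-density proxy map with condition- and severity-scaled loss.

    Slice-level ROI mean = baseline * (1 - density_loss * severity) with a
    multiplicative per-slice jitter; voxel values add multiplicative noise.
    Background density is 0.  The severity scalar (uniform in [0.5, 1] for
    epileptic slices, 0 for controls) creates slice-to-slice variation in
    lesion severity so intra-group density-diffusion correlations are
    recoverable.
    """
    if spec.severity is not None:
        severity = float(spec.severity)
    elif spec.condition == "control":
        severity = 0.0
    else:
        severity = float(rng.uniform(0.5, 1.0))

    values = np.zeros(roiset.grid_shape)
    roi_means: dict[str, float] = {}
    for roi in ROI_NAMES:
        tp = spec.tissue[roi]
        eff = spec.effect(roi)
        mean = tp.baseline_density * (1.0 - eff.density_loss * severity)
        mean *= 1.0 + spec.density_jitter_cv * rng.standard_normal()
        mean = max(mean, 0.0)
        mask = roiset.mask(roi)
        vox = mean * (1.0 + spec.density_noise_cv
                      * rng.standard_normal(int(mask.sum())))
        values[mask] = np.clip(vox, 0.0, None)
        roi_means[roi] = float(values[mask].mean()) if mask.any() else 0.0

    return DensityMap(values=values, roi_means=roi_means,
                      gcl_width_mm=measure_gcl_width(roiset),
                      severity=severity)


def effective_lambdas(spec: PhantomSpec, roi: str, roi_density: float,
                      severity: float,
                      jitter: tuple[float, float] = (1.0, 1.0),
                      ) -> tuple[float, float]:
    """Density-coupled, condition-scaled tensor eigenvalues for one ROI.

    A density deficit d = baseline - observed raises the radial eigenvalue
    (lam_perp += b_md * d: fewer membranes hindering diffusion) and lowers
    the axial one (lam_par -= b_fa * d: fewer coherent processes), so
    higher density means lower diffusivity and higher FA in layered ROIs.
    Condition scale factors then apply multiplicatively.
    """
    tp = spec.tissue[roi]
    eff = spec.effect(roi)
    deficit = tp.baseline_density - roi_density
    lam_perp = tp.lam_perp + spec.b_md * deficit
    lam_par = tp.lam_par - spec.b_fa * deficit
    scale = 1.0 + eff.diff_scale * severity
    lam_par *= scale * (1.0 + eff.par_scale * severity) * jitter[0]
    lam_perp *= scale * (1.0 + eff.perp_scale * severity) * jitter[1]
    if lam_perp <= 0 or lam_par <= 0:
        raise PhantomConfigurationError(
            f"density coupling drove eigenvalues non-positive in {roi}")
    lam_par = max(lam_par, lam_perp)    # keep axial >= radial under jitter
    return float(lam_par), float(lam_perp)


# ---------------------------------------------------------------------------
# measurement

def measure_gcl_width(roiset: ROISet) -> float:
    """Average granule-cell-layer band width in mm.

    Models the GCL as a ribbon of length L and width w, so that
    area = L w and perimeter = 2 L + 2 w; the Crofton perimeter estimate
    of the DG mask then yields w as the smaller root of
    w^2 - (P/2) w + A = 0, i.e. band area / centerline length without
    needing an explicit centerline.  Deterministic.
    """
    from skimage.measure import perimeter_crofton

    mask = roiset.mask("DG")
    area_vox = float(mask.sum())
    if area_vox == 0:
        raise ValueError("empty DG region")
    perim = float(perimeter_crofton(mask, directions=4))
    disc = (perim / 2.0) ** 2 - 4.0 * area_vox
    # degenerate (near-square) band: fall back to the isotropic estimate
    width = np.sqrt(area_vox) if disc < 0 \
        else (perim / 2.0 - np.sqrt(disc)) / 2.0
    return float(width * roiset.voxel_size)


# ---------------------------------------------------------------------------
# orchestration

def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a complete slice phantom; bit-identical for equal specs."""
    rng = np.random.default_rng(spec.rng_seed)
    roiset = generate_geometry(spec)
    orientations = generate_orientation_field(roiset, spec, rng)
    density = generate_density(roiset, spec, rng)
    roi_lambdas = {}
    for roi in ROI_NAMES:
        jit = tuple(1.0 + spec.tissue_jitter_cv * rng.standard_normal(2))
        roi_lambdas[roi] = effective_lambdas(
            spec, roi, density.roi_means[roi], density.severity, jitter=jit)
    tensors = build_tensor_field(roiset, orientations, spec, roi_lambdas)
    return Phantom(spec=spec, roiset=roiset, orientations=orientations,
                   density=density, tensors=tensors, roi_lambdas=roi_lambdas)
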