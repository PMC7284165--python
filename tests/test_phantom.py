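"""Phantom geometry, orientation fields, density coupling and tensors."""

import numpy as np
import pytest
from scipy import stats as sps

from hippodwi import phantom as ph
from hippodwi.stats import axial_mean, vtest


def _spec(**kw):
    return ph.PhantomSpec(**kw)


# ---------------------------------------------------------------------------
# geometry

@pytest.mark.parametrize("condition", ph.CONDITIONS)
def test_labels_partition_grid_with_all_rois(condition):
    roiset = ph.generate_geometry(_spec(condition=condition, rng_seed=3))
    counts = roiset.counts()
    assert sum(counts.values()) == np.prod(roiset.grid_shape)
    for roi in ph.ROI_NAMES:
        assert counts[roi] > 0


def test_small_grid_raises_geometry_error():
    with pytest.raises(ph.GeometryError):
        _spec(grid_shape=(20, 20))


def test_phantom_is_deterministic():
    a = ph.generate_phantom(_spec(condition="ipsilateral", rng_seed=42))
    b = ph.generate_phantom(_spec(condition="ipsilateral", rng_seed=42))
    np.testing.assert_array_equal(a.roiset.labels, b.roiset.labels)
    np.testing.assert_array_equal(a.orientations, b.orientations)
    np.testing.assert_array_equal(a.density.values, b.density.values)
    np.testing.assert_array_equal(a.tensors.d6, b.tensors.d6)
    assert a.density.severity == b.density.severity


# ---------------------------------------------------------------------------
# GCL width

def test_gcl_width_straight_band():
    """A straight 5-voxel band at 0.04 mm/voxel measures 0.20 mm +- half voxel."""
    labels = np.zeros((40, 60), dtype=np.int16)
    labels[18:23, 5:55] = ph.ROI_LABELS["DG"]
    roiset = ph.ROISet(labels=labels, voxel_size=0.04)
    assert ph.measure_gcl_width(roiset) == pytest.approx(0.20, abs=0.02)


def test_gcl_width_matches_configured_band():
    spec = _spec(rng_seed=0)
    configured = max(2.0, 0.045 * min(spec.grid_shape)) * spec.voxel_size
    width = ph.measure_gcl_width(ph.generate_geometry(spec))
    assert abs(width - configured) <= spec.voxel_size


def test_gcl_dispersion_doubles_width():
    ctrl = ph.measure_gcl_width(ph.generate_geometry(_spec()))
    ipsi = ph.measure_gcl_width(
        ph.generate_geometry(_spec(condition="ipsilateral")))
    factor = ph.DEFAULT_GCL_DISPERSION["ipsilateral"]
    assert ipsi / ctrl == pytest.approx(factor, rel=0.10)
    assert ipsi > ctrl  # granule cell dispersion widens the ipsilateral GCL


# ---------------------------------------------------------------------------
# orientation field

def test_orientation_concentrated_near_mu(rng):
    spec = _spec()
    spec.tissue["CA1"] = ph.TissueParams(90.0, 20.0, 0.9e-3, 0.3e-3, 0.8)
    roiset = ph.generate_geometry(spec)
    theta = ph.generate_orientation_field(roiset, spec, rng)
    ca1 = theta[roiset.mask("CA1")]
    delta = abs(axial_mean(ca1) - 90.0)
    assert min(delta, 180.0 - delta) < 5.0


def test_orientation_kappa_zero_is_uniform(rng):
    spec = _spec(grid_shape=(128, 128))
    for roi in ph.ROI_NAMES:
        tp = spec.tissue[roi]
        spec.tissue[roi] = ph.TissueParams(tp.mu_deg, 0.0, tp.lam_par,
                                           tp.lam_perp, tp.baseline_density)
    roiset = ph.generate_geometry(spec)
    samples = ph.generate_orientation_field(roiset, spec, rng).ravel()
    samples = rng.choice(samples, 10_000, replace=False)
    counts, _ = np.histogram(samples, bins=18, range=(0.0, 180.0))
    assert sps.chisquare(counts).pvalue > 0.01


def test_orientation_degenerate_dispersion(rng):
    spec = _spec()
    spec.tissue["DG"] = ph.TissueParams(90.0, 1e6, 0.8e-3, 0.35e-3, 0.9)
    roiset = ph.generate_geometry(spec)
    theta = ph.generate_orientation_field(roiset, spec, rng)
    dg = theta[roiset.mask("DG")]
    assert np.max(np.minimum(np.abs(dg - 90.0), 180 - np.abs(dg - 90.0))) < 0.1


def test_orientation_missing_tissue_params_raises(rng):
    spec = _spec()
    roiset = ph.generate_geometry(spec)
    del spec.tissue["hilus"]
    with pytest.raises(ph.PhantomConfigurationError):
        ph.generate_orientation_field(roiset, spec, rng)


def test_generated_orientations_pass_vtest(rng):
    """Axial samples at kappa >= 5, n >= 50 align with their own mean."""
    for mu, kappa in ((90.0, 5.0), (45.0, 12.0), (0.0, 7.0)):
        phi = rng.vonmises(np.radians(2 * mu), kappa, size=200)
        theta = (np.degrees(phi) / 2.0) % 180.0
        assert vtest(theta, mu).significant


# ---------------------------------------------------------------------------
# tensors

def test_tensor_axis_aligned_rotations():
    labels = np.full((32, 32), ph.ROI_LABELS["CA1"], dtype=np.int16)
    roiset = ph.ROISet(labels=labels, voxel_size=0.04)
    spec = _spec(grid_shape=(32, 32))
    lam = {"CA1": (1.5e-3, 0.3e-3)}
    for mu, expected in [
        (0.0, np.diag([1.5e-3, 0.3e-3, 0.3e-3])),
        (90.0, np.diag([0.3e-3, 1.5e-3, 0.3e-3])),
        # at 45 degrees: Dxx = Dyy = 0.9e-3, Dxy = 0.6e-3 (hand evaluation
        # of R diag(1.5, 0.3, 0.3) R^T at alpha = 45 deg)
        (45.0, np.array([[0.9e-3, 0.6e-3, 0.0],
                         [0.6e-3, 0.9e-3, 0.0],
                         [0.0, 0.0, 0.3e-3]])),
    ]:
        field = ph.build_tensor_field(roiset, np.full((32, 32), mu), spec,
                                      roi_lambdas=lam)
        np.testing.assert_allclose(field.to_matrices()[0, 0], expected,
                                   atol=1e-18)


def test_all_tensors_positive_definite(control_phantom, ipsi_phantom):
    for p in (control_phantom, ipsi_phantom):
        evals = np.linalg.eigvalsh(p.tensors.to_matrices())
        assert evals.min() > 0


def test_background_tensors_are_saline(control_phantom):
    bg = control_phantom.roiset.labels == 0
    md = control_phantom.tensors.to_matrices()[bg].trace(axis1=-2, axis2=-1) / 3
    np.testing.assert_allclose(md, ph.SALINE_DIFFUSIVITY, rtol=1e-12)


# ---------------------------------------------------------------------------
# density and coupling

def test_ipsilateral_ca1_density_below_control(control_phantom, ipsi_phantom):
    assert (ipsi_phantom.density.roi_means["CA1"]
            < control_phantom.density.roi_means["CA1"])


def test_density_background_zero_and_nonnegative(ipsi_phantom):
    values = ipsi_phantom.density.values
    assert values.min() >= 0
    assert np.all(values[ipsi_phantom.roiset.labels == 0] == 0)


def _ipsi_cohort_stats(seed, n=9, **spec_kw):
    """Per-slice (density, MD, FA) for CA1 over one ipsilateral mini-cohort."""
    dens, mds, fas = [], [], []
    for i in range(n):
        spec = _spec(grid_shape=(64, 64), condition="ipsilateral",
                     rng_seed=seed * 1000 + i, **spec_kw)
        p = ph.generate_phantom(spec)
        lp, lq = p.roi_lambdas["CA1"]
        md = (lp + 2 * lq) / 3
        lam = np.array([lp, lq, lq])
        fa = np.sqrt(1.5) * np.linalg.norm(lam - md) / np.linalg.norm(lam)
        dens.append(p.density.roi_means["CA1"])
        mds.append(md)
        fas.append(fa)
    return np.array(dens), np.array(mds), np.array(fas)


def test_zero_coupling_makes_density_and_md_independent():
    rs = []
    for seed in range(100):
        dens, mds, _ = _ipsi_cohort_stats(seed, b_md=0.0, b_fa=0.0)
        rs.append(sps.pearsonr(dens, mds).statistic)
    assert abs(np.mean(rs)) < 0.2


def test_default_coupling_gives_positive_density_fa_correlation():
    hits = 0
    for seed in range(100):
        dens, _, fas = _ipsi_cohort_stats(seed)
        hits += sps.pearsonr(dens, fas).statistic > 0
    assert hits >= 95


def test_stronger_coupling_strictly_raises_md_in_cell_loss_roi():
    """With cell loss (density deficit), a larger b_md raises lambda_perp and
    hence mean MD monotonically."""
    mds = []
    for b_md in (0.0, 0.25e-3, 0.5e-3):
        _, md, _ = _ipsi_cohort_stats(0, n=6, b_md=b_md)
        mds.append(md.mean())
    assert mds[0] < mds[1] < mds[2]


def test_coupling_driving_lambda_nonpositive_raises():
    spec = _spec(grid_shape=(64, 64), condition="ipsilateral", rng_seed=0,
                 b_fa=5e-3, severity=1.0)
    with pytest.raises(ph.PhantomConfigurationError):
        ph.generate_phantom(spec)


def test_invalid_tissue_params_rejected():
    with pytest.raises(ph.PhantomConfigurationError):
        ph.TissueParams(90.0, 5.0, 0.3e-3, 0.9e-3, 0.5)   # perp > par
    with pytest.raises(ph.PhantomConfigurationError):
        ph.TissueParams(90.0, -1.0, 0.9e-3, 0.3e-3, 0.5)  # negative kappa
    with pytest.raises(ph.PhantomConfigurationError):
        ph.TissueParams(90.0, 5.0, 5e-3, 4e-3, 0.5)       # MD out of range
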