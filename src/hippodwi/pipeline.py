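"""End-to-end experiment orchestration.

Generates a cohort of slice phantoms (default 6 control / 9 ipsilateral /
6 contralateral, matching the study design this package emulates),
simulates the HARDI acquisition per slice, fits tensors and SH profiles,
assembles the tidy per-slice ROI parameter table and runs the full
statistical report.  All randomness derives deterministically from one
master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .dwisim import GradientScheme, add_rician_noise, make_scheme, simulate_signal
from .phantom import CONDITIONS, ROI_NAMES, PhantomSpec, generate_phantom
from .shprofile import axis_maps
from .stats import (DWI_PARAMETERS, StatsReport, TestResult, anova_tukey,
                    build_report, correlate, paired_test, vtest)
from .tensorfit import fit_tensor, otsu_mask, tensor_metrics

__all__ = [
    "RunConfig",
    "SliceResult",
    "CohortResult",
    "slice_seed",
    "run_slice",
    "run_cohort",
    "run_paired_cohort",
    "cohort_report",
    "fit_external",
    "orientation_pattern_ok",
    "group_pattern_flags",
    "ipsilateral_density_fa_corr",
    "run_pattern_study",
]

logger = logging.getLogger("hippodwi")

#: hypothesized mean axial orientations per ROI (degrees from left-right axis)
HYPOTHESIZED_MU = {"CA1": 90.0, "DG": 90.0, "CA3": 45.0, "hilus": 0.0,
                   "srCA1": 0.0}

#: group contrasts expected from the condition effects: (roi, parameter,
#: lower group, higher group) -- the Tukey contrast must be significant
#: with this sign.
EXPECTED_GROUP_CONTRASTS = (
    ("CA1", "FA", "ipsilateral", "contralateral"),
    ("CA1", "FA", "ipsilateral", "control"),
    ("DG", "MD", "contralateral", "ipsilateral"),
    ("DG", "dvD", "contralateral", "ipsilateral"),
    ("DG", "lrD", "contralateral", "ipsilateral"),
    ("hilus", "MD", "contralateral", "ipsilateral"),
    ("hilus", "lrD", "contralateral", "ipsilateral"),
    ("hilus", "FA", "control", "ipsilateral"),
)

_HISTOLOGY_ROIS = {"density_CA1": "CA1", "density_CA3": "CA3",
                   "density_GCL": "DG"}


@dataclass
class SchemeConfig:
    n_dirs: int = 60
    b: float = 1000.0
    n_b0: int = 6
    seed: int = 0


@dataclass
class RunConfig:
    """Configuration of one cohort experiment."""

    n_control: int = 6
    n_ipsilateral: int = 9
    n_contralateral: int = 6
    grid_shape: tuple[int, int] = (128, 102)
    voxel_size: float = 0.04
    snr: float | None = 15.0            # None = noise-free
    s0: float = 1000.0
    sh_order: int = 4
    alpha: float = 0.05
    master_seed: int = 0
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    vtest_max_n: int = 300              # cap on pooled orientation samples
    vtest_per_slice: int = 150
    b_md: float = 0.25e-3
    b_fa: float = 0.50e-3
    out_dir: str | None = None
    write_images: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.scheme, dict):
            self.scheme = SchemeConfig(**self.scheme)
        self.grid_shape = tuple(self.grid_shape)
        for n in (self.n_control, self.n_ipsilateral, self.n_contralateral):
            if n < 0:
                raise ValueError("cohort sizes must be >= 0")
        if self.sh_order % 2:
            raise ValueError("sh_order must be even")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def slice_seed(master_seed: int, slice_id: str) -> int:
    """Deterministic 31-bit per-slice seed from the master seed."""
    h = hashlib.blake2b(f"{master_seed}:{slice_id}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


@dataclass
class SliceResult:
    slice_id: str
    group: str
    seed: int
    severity: float
    roi_means: dict            # roi -> {parameter -> value}
    orientations: dict         # roi -> subsampled fitted theta (deg)
    densities: dict            # roi -> mean density
    gcl_width_mm: float
    n_clamped: int = 0


@dataclass
class CohortResult:
    config: RunConfig
    table: pd.DataFrame                    # tidy ROITable
    orientations: dict                     # (group, roi) -> pooled angles
    slices: list
    manifest: pd.DataFrame


def _make_spec(config: RunConfig, condition: str, seed: int,
               severity: float | None = None) -> PhantomSpec:
    return PhantomSpec(grid_shape=config.grid_shape,
                       voxel_size=config.voxel_size, condition=condition,
                       b_md=config.b_md, b_fa=config.b_fa,
                       severity=severity, rng_seed=seed)


def run_slice(spec: PhantomSpec, scheme: GradientScheme, config: RunConfig,
              slice_id: str, out_dir: Path | None = None) -> SliceResult:
    """Phantom -> simulation -> fitting -> per-ROI means for one slice."""
    phantom = generate_phantom(spec)
    stack = simulate_signal(phantom.tensors, scheme, s0=config.s0,
                            voxel_size=config.voxel_size)
    noise_rng = np.random.default_rng(slice_seed(spec.rng_seed, "noise"))
    if config.snr is not None and np.isfinite(config.snr):
        stack = add_rician_noise(stack, config.snr, noise_rng)

    mask = phantom.roiset.tissue_mask()
    tensors = fit_tensor(stack, mask)
    maps = tensor_metrics(tensors)
    axes = axis_maps(stack, mask, order=config.sh_order)

    sub_rng = np.random.default_rng(slice_seed(spec.rng_seed, "subsample"))
    roi_means: dict = {}
    orientations: dict = {}
    for roi in ROI_NAMES:
        rmask = phantom.roiset.mask(roi)
        valid = rmask & maps.valid
        roi_means[roi] = {
            "FA": float(np.nanmean(maps.fa[valid])),
            "MD": float(np.nanmean(maps.md[valid])),
            "dvD": float(np.nanmean(axes.dvd[rmask & axes.valid])),
            "lrD": float(np.nanmean(axes.lrd[rmask & axes.valid])),
            "dvlr_ratio": float(np.nanmean(axes.ratio[rmask
                                                      & axes.ratio_valid])),
        }
        theta = maps.theta_deg[rmask & maps.theta_valid]
        if theta.size > config.vtest_per_slice:
            theta = sub_rng.choice(theta, config.vtest_per_slice,
                                   replace=False)
        orientations[roi] = theta

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        hio.save_stack(stack, out_dir / f"{slice_id}_dwi.nii",
                       out_dir / f"{slice_id}.bval",
                       out_dir / f"{slice_id}.bvec")
        hio.save_labels(phantom.roiset.labels, config.voxel_size,
                        out_dir / f"{slice_id}_labels.nii")
        for name, arr in (("fa", maps.fa), ("md", maps.md),
                          ("theta", maps.theta_deg), ("dvd", axes.dvd),
                          ("lrd", axes.lrd), ("ratio", axes.ratio),
                          ("density", phantom.density.values)):
            hio.save_map(arr, config.voxel_size,
                         out_dir / f"{slice_id}_{name}.nii")

    return SliceResult(slice_id=slice_id, group=spec.condition,
                       seed=spec.rng_seed, severity=phantom.density.severity,
                       roi_means=roi_means, orientations=orientations,
                       densities=dict(phantom.density.roi_means),
                       gcl_width_mm=phantom.density.gcl_width_mm,
                       n_clamped=tensors.n_clamped)


def _table_from_slices(slices: list, animals: dict | None = None
                       ) -> pd.DataFrame:
    rows = []
    for sl in slices:
        hist = {"density_CA1": sl.densities["CA1"],
                "density_CA3": sl.densities["CA3"],
                "density_GCL": sl.densities["DG"],
                "gcl_width": sl.gcl_width_mm}
        animal = (animals or {}).get(sl.slice_id, sl.slice_id)
        for roi in ROI_NAMES:
            for param in DWI_PARAMETERS:
                rows.append({"slice_id": sl.slice_id, "animal": animal,
                             "group": sl.group, "roi": roi,
                             "parameter": param,
                             "value": sl.roi_means[roi][param],
                             "severity": sl.severity, **hist})
    return pd.DataFrame(rows)


def _pool_orientations(slices: list, config: RunConfig) -> dict:
    pool_rng = np.random.default_rng(slice_seed(config.master_seed, "vpool"))
    pooled: dict = {}
    groups = sorted({sl.group for sl in slices})
    for group in list(groups) + ["all"]:
        members = [sl for sl in slices if group in ("all", sl.group)]
        for roi in ROI_NAMES:
            angles = np.concatenate([sl.orientations[roi] for sl in members]) \
                if members else np.empty(0)
            if angles.size > config.vtest_max_n:
                angles = pool_rng.choice(angles, config.vtest_max_n,
                                         replace=False)
            pooled[(group, roi)] = angles
    return pooled


def run_cohort(config: RunConfig) -> CohortResult:
    """Generate and measure the full slice cohort."""
    scheme = make_scheme(config.scheme.n_dirs, config.scheme.b,
                         config.scheme.n_b0, seed=config.scheme.seed)
    counts = {"control": config.n_control,
              "ipsilateral": config.n_ipsilateral,
              "contralateral": config.n_contralateral}
    n_total = sum(counts.values())
    if 0 < min(c for c in counts.values() if c) < 3:
        logger.warning("cohort sizes %s are underpowered for group tests",
                       counts)
    out_dir = Path(config.out_dir) if (config.out_dir
                                       and config.write_images) else None

    slices = []
    for condition in CONDITIONS:
        for i in range(counts[condition]):
            slice_id = f"{condition}_{i + 1:02d}"
            seed = slice_seed(config.master_seed, slice_id)
            spec = _make_spec(config, condition, seed)
            slices.append(run_slice(spec, scheme, config, slice_id,
                                    out_dir=out_dir))
    logger.info("cohort of %d slices complete", n_total)

    table = _table_from_slices(slices)
    manifest = pd.DataFrame(
        [{"slice_id": sl.slice_id, "condition": sl.group, "seed": sl.seed,
          "severity": sl.severity} for sl in slices])
    result = CohortResult(config=config, table=table,
                          orientations=_pool_orientations(slices, config),
                          slices=slices, manifest=manifest)
    if config.out_dir:
        root = Path(config.out_dir)
        root.mkdir(parents=True, exist_ok=True)
        table.to_csv(root / "roi_table.csv", index=False)
        manifest.assign(config_hash=config.config_hash()).to_csv(
            root / "manifest.csv", index=False)
        config.to_yaml(root / "config.yaml")
    return result


def run_paired_cohort(config: RunConfig, n_pairs: int = 5) -> pd.DataFrame:
    """Paired ipsilateral/contralateral slices sharing per-animal severity.

    Emulates whole-brain sections where both hippocampi of one animal are
    measured in the same slice, the setting for paired t-tests.
    """
    scheme = make_scheme(config.scheme.n_dirs, config.scheme.b,
                         config.scheme.n_b0, seed=config.scheme.seed)
    slices, animals = [], {}
    for i in range(n_pairs):
        animal = f"animal_{i + 1:02d}"
        sev_rng = np.random.default_rng(
            slice_seed(config.master_seed, f"{animal}:severity"))
        severity = float(sev_rng.uniform(0.5, 1.0))
        for condition in ("ipsilateral", "contralateral"):
            slice_id = f"{animal}_{condition}"
            seed = slice_seed(config.master_seed, slice_id)
            spec = _make_spec(config, condition, seed, severity=severity)
            slices.append(run_slice(spec, scheme, config, slice_id))
            animals[slice_id] = animal
    return _table_from_slices(slices, animals=animals)


# ---------------------------------------------------------------------------
# statistics over a cohort

def cohort_report(result: CohortResult) -> StatsReport:
    """V-tests, ANOVA/Tukey, and correlation grid for one cohort."""
    config = result.config
    alpha = config.alpha
    tests: list[TestResult] = []

    groups_present = sorted(result.table["group"].unique())
    for (group, roi), angles in sorted(result.orientations.items()):
        if angles.size < 5:
            continue
        res = vtest(angles, HYPOTHESIZED_MU[roi], alpha=alpha,
                    name=f"vtest[{roi}]")
        res.contrast = f"group={group},mu0={HYPOTHESIZED_MU[roi]:g}"
        res.extra.update({"group": group, "roi": roi})
        tests.append(res)

    # across-ROI comparisons on the pooled cohort
    for param in DWI_PARAMETERS:
        tests.extend(anova_tukey(result.table, param, across="roi",
                                 alpha=alpha))
    # across-group comparisons within each ROI
    if len(groups_present) >= 2:
        for roi in ROI_NAMES:
            for param in DWI_PARAMETERS:
                tests.extend(anova_tukey(result.table, param, across="group",
                                         within={"roi": roi}, alpha=alpha))
    # DWI-histology correlation grid, pooled and ipsilateral-only
    subsets = ["all"] + (["ipsilateral"]
                         if "ipsilateral" in groups_present else [])
    for hist_col, roi in _HISTOLOGY_ROIS.items():
        for param in ("FA", "MD"):
            for subset in subsets:
                try:
                    tests.append(correlate(result.table, param, roi,
                                           hist_col, subset=subset,
                                           alpha=alpha))
                except ValueError:
                    pass
    for param in ("FA", "MD"):
        for subset in subsets:
            try:
                tests.append(correlate(result.table, param, "DG", "gcl_width",
                                       subset=subset, alpha=alpha))
            except ValueError:
                pass
    return build_report(tests, result.table, alpha=alpha)


def orientation_pattern_ok(result: CohortResult, alpha: float = 0.05) -> bool:
    """Check the per-group orientation hypothesis pattern.

    Control slices: CA1 and DG significant against 90 degrees, CA3 against
    45, hilus and srCA1 against 0.  Ipsilateral slices: CA1 and CA3
    non-significant (loss of directional conformity).
    """
    def sig(group, roi):
        angles = result.orientations[(group, roi)]
        return vtest(angles, HYPOTHESIZED_MU[roi], alpha=alpha).significant

    expected_sig = [("control", r) for r in ROI_NAMES]
    expected_ns = [("ipsilateral", "CA1"), ("ipsilateral", "CA3")]
    return (all(sig(g, r) for g, r in expected_sig)
            and not any(sig(g, r) for g, r in expected_ns))


def group_pattern_flags(result: CohortResult,
                        alpha: float = 0.05) -> dict[tuple, bool]:
    """Tukey significance-with-direction flags for the expected contrasts."""
    flags = {}
    for roi, param, lo, hi in EXPECTED_GROUP_CONTRASTS:
        res = anova_tukey(result.table, param, across="group",
                          within={"roi": roi}, alpha=alpha)
        ok = False
        for r in res[1:]:
            pair = {r.extra["level_a"], r.extra["level_b"]}
            if pair == {lo, hi} and r.significant:
                # statistic is level_b - level_a
                diff = r.statistic if r.extra["level_b"] == hi \
                    else -r.statistic
                ok = diff > 0
        flags[(roi, param, lo, hi)] = ok
    return flags


def ipsilateral_density_fa_corr(result: CohortResult,
                                alpha: float = 0.05) -> TestResult:
    """Pearson r between CA1 density and CA1 FA within ipsilateral slices."""
    return correlate(result.table, "FA", "CA1", "density_CA1",
                     subset="ipsilateral", alpha=alpha)


def run_pattern_study(n_replicates: int, config: RunConfig,
                      base_seed: int = 0) -> pd.DataFrame:
    """Replicate cohorts under fresh seeds and score the expected patterns.

    Returns one row per replicate with boolean columns: the orientation
    pattern, each expected group contrast (and their conjunction), and the
    ipsilateral density-FA correlation being significantly positive.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, master_seed=slice_seed(base_seed, f"rep{rep}"),
                      out_dir=None, write_images=False)
        result = run_cohort(cfg)
        flags = group_pattern_flags(result, alpha=cfg.alpha)
        corr = ipsilateral_density_fa_corr(result, alpha=cfg.alpha)
        row = {"replicate": rep,
               "orientation_pattern": orientation_pattern_ok(result,
                                                             cfg.alpha),
               "group_pattern": all(flags.values()),
               "corr_sig_positive": corr.significant and corr.statistic > 0,
               "corr_r": corr.statistic}
        row.update({f"{roi}.{param}.{lo}<{hi}": v
                    for (roi, param, lo, hi), v in flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def run_null_coupling_study(n_replicates: int, config: RunConfig,
                            base_seed: int = 0) -> pd.DataFrame:
    """Ipsilateral-only cohorts with density-diffusion coupling switched off.

    With b_md = b_fa = 0 the severity scalar still spreads cell density
    across slices but no longer moves the tensors, so the CA1 density-FA
    correlation is null: its rejection rate calibrates the false-positive
    level of the correlation analysis.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, n_control=0, n_contralateral=0,
                      b_md=0.0, b_fa=0.0, out_dir=None, write_images=False,
                      master_seed=slice_seed(base_seed, f"null{rep}"))
        result = run_cohort(cfg)
        corr = ipsilateral_density_fa_corr(result, alpha=cfg.alpha)
        rows.append({"replicate": rep, "r": corr.statistic,
                     "p": corr.pvalue, "significant": corr.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# external data path

def fit_external(dwi_path, bvals_path, bvecs_path, labels_path=None,
                 out_dir=None, sh_order: int = 4) -> pd.DataFrame:
    """Apply the quantification stack to user-supplied NIfTI data.

    Masking uses the supplied label map when given, otherwise an Otsu
    threshold on the mean b=0 image.  Returns the per-ROI parameter table
    (label integers as ROI names when no name table applies); writes maps
    when ``out_dir`` is given.  No group statistics are computed.
    """
    stack = hio.load_stack(dwi_path, bvals_path, bvecs_path)
    if labels_path is not None:
        labels, _ = hio.load_labels(labels_path)
        mask = labels > 0
    else:
        labels = None
        mask = otsu_mask(stack)

    tensors = fit_tensor(stack, mask)
    maps = tensor_metrics(tensors)
    axes = axis_maps(stack, mask, order=sh_order)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, arr in (("fa", maps.fa), ("md", maps.md),
                          ("theta", maps.theta_deg), ("dvd", axes.dvd),
                          ("lrd", axes.lrd), ("ratio", axes.ratio)):
            hio.save_map(arr, stack.voxel_size, out / f"{name}.nii")

    rows = []
    regions = [(str(lab), labels == lab)
               for lab in np.unique(labels) if lab > 0] \
        if labels is not None else [("foreground", mask)]
    for name, rmask in regions:
        valid = rmask & maps.valid
        values = {"FA": np.nanmean(maps.fa[valid]),
                  "MD": np.nanmean(maps.md[valid]),
                  "dvD": np.nanmean(axes.dvd[rmask & axes.valid]),
                  "lrD": np.nanmean(axes.lrd[rmask & axes.valid]),
                  "dvlr_ratio": np.nanmean(axes.ratio[rmask
                                                      & axes.ratio_valid])}
        for param, value in values.items():
            rows.append({"roi": name, "parameter": param,
                         "value": float(value)})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "roi_table.csv", index=False)
    return table
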