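"""Synthetic imaging phantoms and cohort tables.

Two generators make every downstream stage testable without patient data:

* a geometric diffusion phantom that mimics the periventricular anatomy the
  ALPS measurement relies on — projection fibers running cranio-caudally,
  association fibers running antero-posteriorly, and a perivascular-space
  diffusivity component along the left-right axis, mutually perpendicular —
  with optional global diffusivity elevation (emulating white-matter
  hyperintensity) and Rician magnitude noise;
* a cohort simulator producing per-subject demographics, vascular risk
  factors, small-vessel-disease imaging markers, raw neuropsychological
  scores, and an ALPS index + episodic-memory outcome tied together by a
  linear mediation chain (WMH -> ALPS -> memory) with configurable path
  coefficients.

Default calibration constants reproduce the group structure of a published
four-group CSVD cohort (normal controls, CSVD without cognitive impairment,
CSVD with mild cognitive impairment, CSVD with vascular dementia).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dti import AXIS_LABELS, DiffusionVolume, TensorField, design_matrix

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GROUPS",
    "REFERENCE_GENDER_COUNTS",
    "REFERENCE_EPVS_COUNTS",
    "REFERENCE_AGE_SUMMARY",
    "REFERENCE_EDUCATION_SUMMARY",
    "default_phantom_spec",
    "generate_tensor_field",
    "make_gradient_scheme",
    "generate_dwi",
    "generate_cohort",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

# ---------------------------------------------------------------------------
# Imaging phantom
# ---------------------------------------------------------------------------

REGION_LABELS = {"background": 0, "projection": 1, "association": 2, "subcortical_other": 3}


def _check_spd(d: np.ndarray, name: str) -> None:
    d = np.asarray(d, dtype=float)
    if d.shape != (3, 3) or not np.allclose(d, d.T):
        raise ValueError(f"{name} base tensor must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(d).min() <= 0:
        raise ValueError(f"{name} base tensor is not positive definite")


@dataclass
class PhantomSpec:
    """Geometry and tissue model of the diffusion phantom.

    ``region_map`` labels each voxel with an integer from ``REGION_LABELS``.
    ``pvs_axis_boost`` is added to the left-right (Dxx) diagonal element of
    the projection- and association-region tensors, emulating perivascular
    diffusion; ``wmh_scale`` multiplies every tensor globally, emulating
    white-matter-hyperintensity diffusivity elevation in all directions.
    Units: mm^2/s for tensors and boost.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    region_map: np.ndarray | None = None
    base_tensor_per_region: dict[str, np.ndarray] = field(default_factory=dict)
    pvs_axis_boost: float = 0.46e-3
    wmh_scale: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        defaults = {
            # principal axis cranio-caudal (z)
            "projection": np.diag([0.6e-3, 0.6e-3, 1.7e-3]),
            # principal axis anterior-posterior (y)
            "association": np.diag([0.6e-3, 1.7e-3, 0.6e-3]),
            "subcortical_other": np.diag([0.8e-3, 0.8e-3, 0.8e-3]),
            "background": np.diag([0.8e-3, 0.8e-3, 0.8e-3]),
        }
        for k, v in defaults.items():
            self.base_tensor_per_region.setdefault(k, v)
        for name, d in self.base_tensor_per_region.items():
            _check_spd(np.asarray(d), name)
        if self.wmh_scale < 1:
            raise ValueError("wmh_scale must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.region_map is None:
            self.region_map = _default_region_map(self.grid_shape)
        self.region_map = np.asarray(self.region_map)
        if self.region_map.shape != tuple(self.grid_shape):
            raise ValueError("region_map shape must equal grid_shape")

    @property
    def projection_center(self) -> tuple[int, int, int]:
        return _region_center(self.region_map, REGION_LABELS["projection"])

    @property
    def association_center(self) -> tuple[int, int, int]:
        return _region_center(self.region_map, REGION_LABELS["association"])


def _default_region_map(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Two fiber slabs separated along the anterior-posterior axis.

    The projection slab sits anterior, the association slab posterior, at
    the same left-right and cranio-caudal coordinates ("parallel" ROIs on
    the same axial plane), surrounded by isotropic background.
    """
    nx, ny, nz = grid_shape
    if min(nx, ny, nz) < 12:
        raise ValueError("grid must be at least 12 voxels per axis to hold both ROIs")
    rm = np.zeros(grid_shape, dtype=np.int8)
    x0, x1 = nx // 2 - 4, nx // 2 + 4
    z0, z1 = nz // 2 - 4, nz // 2 + 4
    gap = max(1, ny // 10)
    half = ny // 2
    rm[x0:x1, gap : half - 1, z0:z1] = REGION_LABELS["projection"]
    rm[x0:x1, half + 1 : ny - gap, z0:z1] = REGION_LABELS["association"]
    return rm


def _region_center(region_map: np.ndarray, label: int) -> tuple[int, int, int]:
    idx = np.argwhere(region_map == label)
    if idx.size == 0:
        raise ValueError(f"region label {label} absent from region_map")
    return tuple(int(round(c)) for c in idx.mean(axis=0))


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Default phantom whose noiseless ALPS index sits in the healthy range."""
    return PhantomSpec(**overrides)


def generate_tensor_field(spec: PhantomSpec) -> TensorField:
    """Build the per-voxel tensor field implied by a :class:`PhantomSpec`.

    The perivascular boost adds to the left-right diagonal element within
    both fiber regions; ``wmh_scale`` then multiplies every tensor.
    """
    shape = tuple(spec.grid_shape)
    tensor = np.empty(shape + (3, 3), dtype=float)
    for name, label in REGION_LABELS.items():
        base = np.asarray(spec.base_tensor_per_region[name], dtype=float).copy()
        if name in ("projection", "association"):
            base[0, 0] += spec.pvs_axis_boost
        tensor[spec.region_map == label] = base
    tensor *= spec.wmh_scale

    evals, evecs = np.linalg.eigh(tensor.reshape(-1, 3, 3))
    fa_num = ((evals - evals.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    fa_den = (evals**2).sum(axis=-1)
    fa = np.where(fa_den > 0, np.sqrt(1.5 * fa_num / np.maximum(fa_den, 1e-300)), 0.0)
    principal = evecs[..., -1]

    return TensorField(
        tensor=tensor,
        fa=fa.reshape(shape),
        dxx=tensor[..., 0, 0],
        dyy=tensor[..., 1, 1],
        dzz=tensor[..., 2, 2],
        principal_direction=principal.reshape(shape + (3,)),
        mask=np.ones(shape, dtype=bool),
        voxel_size_mm=spec.voxel_size_mm,
        axis_convention=AXIS_LABELS,
    )


def make_gradient_scheme(n_directions: int = 32, b: float = 1000.0, n_b0: int = 1):
    """Deterministic quasi-uniform gradient scheme (Fibonacci sphere).

    Returns ``(bvals, bvecs)`` with ``n_b0`` leading b = 0 frames.
    """
    if n_directions < 6:
        raise ValueError("at least 6 diffusion directions are required")
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def generate_dwi(
    tf: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DiffusionVolume:
    """Forward-simulate diffusion-weighted signals from a tensor field.

    The noiseless signal is the monoexponential tensor model
    ``S = S0 * exp(-b g^T D g)``. Magnitude noise is Rician: independent
    Gaussians of standard deviation ``noise_sigma * S0`` are added to the
    real and imaginary channels before taking the magnitude, so SNR on the
    b = 0 signal is ``1 / noise_sigma``.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    # forward simulation is well defined for any scheme; direction-count and
    # rank requirements are the tensor fit's concern, not the simulator's
    # b g^T D g for every voxel and gradient
    bq = np.einsum("gi,...ij,gj->...g", bvecs, tf.tensor, bvecs) * bvals
    signal = s0 * np.exp(-bq)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sig = noise_sigma * s0
        re = signal + rng.normal(0.0, sig, signal.shape)
        im = rng.normal(0.0, sig, signal.shape)
        signal = np.hypot(re, im)

    return DiffusionVolume(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size_mm=tf.voxel_size_mm,
        axis_convention=tf.axis_convention,
    )


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

GROUPS = ("NC", "CSVD-non-CI", "CSVD-MCI", "CSVD-VaD")

# contingency tables of the calibration cohort (rows: category, cols: group)
REFERENCE_GENDER_COUNTS = {"female": (25, 28, 26, 15), "male": (27, 28, 26, 14)}
REFERENCE_EPVS_COUNTS = {"present": (0, 19, 19, 11), "absent": (52, 37, 33, 18)}
REFERENCE_AGE_SUMMARY = {
    "ns": (52, 56, 52, 29),
    "means": (58.88, 66.28, 67.48, 66.07),
    "sds": (6.41, 9.25, 6.74, 8.75),
}
REFERENCE_EDUCATION_SUMMARY = {
    "ns": (52, 56, 52, 29),
    "means": (14.48, 12.96, 10.19, 9.41),
    "sds": (3.58, 3.46, 3.07, 3.19),
}

# raw neuropsychological scales: (per-group means, common sd, timed?)
# timed scales are completion times in seconds (lower is better)
_DEFAULT_TEST_PARAMS: dict[str, tuple[tuple[float, float, float, float], float, bool]] = {
    "wms_vr_dr": ((11.5, 11.0, 8.5, 5.0), 2.0, False),
    "avlt_dr": ((8.5, 8.0, 5.5, 3.0), 2.0, False),
    "bnt": ((26.0, 25.0, 22.0, 18.0), 3.0, False),
    "cvf": ((18.0, 17.0, 13.0, 10.0), 3.5, False),
    "tmt_a": ((45.0, 55.0, 75.0, 110.0), 15.0, True),
    "tmt_b": ((100.0, 120.0, 160.0, 220.0), 30.0, True),
    "scwt_b": ((55.0, 65.0, 85.0, 110.0), 15.0, True),
    "scwt_c": ((90.0, 100.0, 130.0, 170.0), 25.0, True),
    "cdt": ((9.0, 8.8, 7.5, 4.5), 1.5, False),
    "vrt": ((10.0, 9.5, 7.5, 4.0), 2.0, False),
}


def _tuple4(x) -> tuple[float, float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 4:
        raise ValueError("per-group parameters must have length 4")
    return t  # type: ignore[return-value]


@dataclass
class CohortSpec:
    """Statistical blueprint of the simulated four-group cohort.

    The mediation chain operates on transformed scales: the exposure is
    ``log10(WMH volume + 1)``, the mediator is the ALPS index, and the
    outcome is the episodic-memory composite. ``path_a`` is the
    within-group slope of ALPS on log-WMH, ``path_b`` the slope of memory
    on ALPS given log-WMH, ``path_c_prime`` the direct slope of memory on
    log-WMH; the implied indirect effect is ``path_a * path_b``.

    ``label_noise`` is the fraction of subjects whose screening scores
    (MMSE/MoCA) are drawn unconstrained rather than consistent with their
    generated group label; downstream reclassification recovers the label
    for the remaining subjects, so agreement is about ``1 - label_noise``.
    """

    n_per_group: tuple[int, int, int, int] = (52, 56, 52, 29)
    age_mean: tuple = (58.88, 66.28, 67.48, 66.07)
    age_sd: tuple = (6.41, 9.25, 6.74, 8.75)
    education_mean: tuple = (14.48, 12.96, 10.19, 9.41)
    education_sd: tuple = (3.58, 3.46, 3.07, 3.19)
    female_prevalence: tuple = (25 / 52, 28 / 56, 26 / 52, 15 / 29)
    risk_factor_prevalences: dict[str, tuple] = field(
        default_factory=lambda: {
            "hypertension": (0.462, 0.714, 0.750, 0.655),
            "diabetes": (0.154, 0.214, 0.314, 0.207),
            "hyperlipidemia": (0.250, 0.214, 0.157, 0.069),
            "smoking": (0.192, 0.179, 0.235, 0.172),
            "alcohol": (0.192, 0.167, 0.216, 0.034),
        }
    )
    # WMH volume (mL): log-normal, parameterised by median and log-sd
    wmh_median: tuple = (0.93, 6.65, 8.00, 13.14)
    wmh_log_sd: tuple = (0.6, 0.8, 0.9, 1.0)
    # lacunes / microbleeds: zero-inflated Poisson (P(zero inflation), rate)
    li_zip: tuple = ((1.0, 0.0), (0.60, 1.2), (0.35, 1.8), (0.30, 2.0))
    cmb_zip: tuple = ((1.0, 0.0), (0.65, 2.5), (0.55, 4.0), (0.35, 12.0))
    epvs_prevalence: tuple = (0.0, 0.339, 0.365, 0.379)
    alps_mean: tuple = (1.76, 1.64, 1.52, 1.44)
    memory_mean: tuple = (0.34, 0.44, -0.23, -1.03)
    mmse_mean: tuple = (29.36, 28.84, 27.48, 20.24)
    mmse_sd: tuple = (0.77, 1.06, 1.39, 2.73)
    moca_mean: tuple = (27.40, 26.87, 21.07, 14.52)
    moca_sd: tuple = (1.30, 1.41, 2.60, 3.42)
    test_params: dict = field(default_factory=lambda: dict(_DEFAULT_TEST_PARAMS))
    # mediation chain on transformed scales
    path_a: float = -0.30
    path_b: float = 0.50
    path_c_prime: float = -0.05
    alps_residual_sd: float = 0.15
    memory_residual_sd: float = 0.60
    age_effect_on_alps: float = -0.004  # ALPS units per year, within group
    memory_test_loading: float = 0.7  # correlation of raw memory tests with outcome
    label_noise: float = 0.02
    # project residual noise orthogonal to the regressors within group so the
    # generating path coefficients are recovered exactly by least squares
    # (useful for exact-arithmetic checks; leave False for realistic sampling)
    orthogonalize_residuals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if len(self.n_per_group) != 4 or any(n < 2 for n in self.n_per_group):
            raise ValueError("n_per_group must be four integers >= 2")
        for name in ("age_sd", "education_sd", "mmse_sd", "moca_sd", "wmh_log_sd"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be > 0")
        for name, prev in {
            "female_prevalence": self.female_prevalence,
            "epvs_prevalence": self.epvs_prevalence,
            **self.risk_factor_prevalences,
        }.items():
            if any(not 0 <= p <= 1 for p in prev):
                raise ValueError(f"prevalence {name} must lie in [0, 1]")
        if self.alps_residual_sd < 0 or self.memory_residual_sd < 0:
            raise ValueError("residual standard deviations must be >= 0")


def _mmse_dementia_cutoff(education_years: np.ndarray) -> np.ndarray:
    """Education-adjusted MMSE dementia cutoff (score <= cutoff -> dementia)."""
    return np.select(
        [education_years <= 0, education_years <= 6], [17, 20], default=24
    ).astype(float)


def _moca_normal_cutoff(education_years: np.ndarray) -> np.ndarray:
    """Education-adjusted MoCA normality cutoff (score > cutoff -> normal)."""
    return np.select(
        [education_years <= 0, education_years <= 6], [13, 19], default=24
    ).astype(float)


def _zip_draw(rng: np.random.Generator, n: int, p_zero: float, lam: float) -> np.ndarray:
    counts = rng.poisson(lam, n)
    counts[rng.random(n) < p_zero] = 0
    return counts


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the per-subject cohort table.

    Within each group, ALPS is linear in the group-centered log-WMH
    exposure (slope ``path_a``) and age; the episodic-memory outcome is
    linear in group-centered ALPS (``path_b``) and log-WMH
    (``path_c_prime``). Group means of every numeric field therefore
    converge to their spec values as n grows. Raw WMS-VR-DR and AVLT-DR
    scores load on the memory outcome so the scored composite tracks it.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g, group in enumerate(GROUPS):
        n = spec.n_per_group[g]
        df = pd.DataFrame(index=range(n))
        df["group"] = group
        df["gender"] = np.where(rng.random(n) < spec.female_prevalence[g], "F", "M")
        df["age"] = rng.normal(spec.age_mean[g], spec.age_sd[g], n)
        edu = np.clip(np.rint(rng.normal(spec.education_mean[g], spec.education_sd[g], n)), 0, None)
        df["education"] = edu
        for rf, prev in spec.risk_factor_prevalences.items():
            df[rf] = rng.random(n) < prev[g]

        # imaging markers
        wmh = np.exp(rng.normal(np.log(spec.wmh_median[g]), spec.wmh_log_sd[g], n))
        df["wmh_volume"] = wmh
        df["li_count"] = _zip_draw(rng, n, *spec.li_zip[g])
        df["cmb_count"] = _zip_draw(rng, n, *spec.cmb_zip[g])
        df["epvs_bg"] = rng.random(n) < spec.epvs_prevalence[g]

        # mediation chain on transformed scales, group-centered so group
        # means of ALPS and memory hit their targets in expectation
        lw = np.log10(wmh + 1.0)
        lw_c = lw - lw.mean()
        age_c = df["age"].to_numpy() - df["age"].mean()

        def _resid(eps: np.ndarray, *regressors: np.ndarray) -> np.ndarray:
            if not spec.orthogonalize_residuals or eps.size == 0:
                return eps
            d = np.column_stack([np.ones(len(eps)), *regressors])
            coef, *_ = np.linalg.lstsq(d, eps, rcond=None)
            return eps - d @ coef

        eps_a = _resid(rng.normal(0.0, spec.alps_residual_sd, n), lw_c, age_c)
        alps = (
            spec.alps_mean[g]
            + spec.path_a * lw_c
            + spec.age_effect_on_alps * age_c
            + eps_a
        )
        df["alps_index"] = alps
        alps_c = alps - alps.mean()
        eps_m = _resid(rng.normal(0.0, spec.memory_residual_sd, n), alps_c, lw_c, age_c)
        memory = (
            spec.memory_mean[g]
            + spec.path_b * alps_c
            + spec.path_c_prime * lw_c
            + eps_m
        )
        df["episodic_memory"] = memory

        # screening scores consistent with the intended label except for a
        # label_noise fraction of unconstrained draws
        cut_mmse = _mmse_dementia_cutoff(edu)
        cut_moca = _moca_normal_cutoff(edu)
        mmse = np.rint(rng.normal(spec.mmse_mean[g], spec.mmse_sd[g], n))
        moca = np.rint(rng.normal(spec.moca_mean[g], spec.moca_sd[g], n))
        consistent = rng.random(n) >= spec.label_noise
        if group == "CSVD-VaD":
            mmse = np.where(consistent, np.clip(mmse, 0, cut_mmse), mmse)
            cdr = np.where(rng.random(n) < 0.7, 1.0, 2.0)
            adl = np.clip(np.rint(rng.normal(12, 3, n)), 8, None)
        else:
            mmse = np.where(consistent, np.clip(mmse, cut_mmse + 1, 30), mmse)
            cdr = np.full(n, 0.5 if group == "CSVD-MCI" else 0.0)
            adl = np.full(n, 8.0)
            if group == "CSVD-MCI":
                moca = np.where(consistent, np.clip(moca, 0, cut_moca), moca)
            else:
                moca = np.where(consistent, np.clip(moca, cut_moca + 1, 30), moca)
        df["mmse"] = np.clip(mmse, 0, 30)
        df["moca"] = np.clip(moca, 0, 30)
        df["cdr"] = cdr
        df["adl"] = adl

        # raw neuropsychological scales; memory scales load on the outcome
        mem_sd = np.hypot(spec.path_b * alps_c.std() if n > 1 else 0.0, spec.memory_residual_sd)
        mem_std = (memory - spec.memory_mean[g]) / mem_sd if mem_sd > 0 else np.zeros(n)
        lam = spec.memory_test_loading
        for test, (means, sd, timed) in spec.test_params.items():
            if test in ("wms_vr_dr", "avlt_dr"):
                noise = rng.normal(0.0, 1.0, n)
                val = means[g] + sd * (lam * mem_std + np.sqrt(1 - lam**2) * noise)
            else:
                val = rng.normal(means[g], sd, n)
            if timed:
                val = np.clip(val, 5.0, None)  # completion times stay positive
            df[test] = val
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"S{i:04d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def _spec_to_jsonable(spec) -> dict:
    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return {k: conv(v) for k, v in dataclasses.asdict(spec).items()}


def write_fixture_bundle(
    out_dir,
    phantom: PhantomSpec | None = None,
    cohort: CohortSpec | None = None,
    n_directions: int = 32,
    b: float = 1000.0,
    s0: float = 1000.0,
) -> dict:
    """Write a self-describing bundle of simulated inputs.

    Produces a NIfTI DWI with FSL-dialect ``.bval``/``.bvec`` text files
    (when ``phantom`` is given), a cohort CSV (when ``cohort`` is given),
    and a JSON manifest recording seeds and parameters so the bundle can
    be regenerated bit-identically.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}

    if phantom is not None:
        tf = generate_tensor_field(phantom)
        bvals, bvecs = make_gradient_scheme(n_directions=n_directions, b=b)
        dwi = generate_dwi(tf, bvals, bvecs, s0=s0, noise_sigma=phantom.noise_sigma, seed=phantom.seed)
        affine = np.diag(list(phantom.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(dwi.signal, affine), out / "dwi.nii.gz")
        np.savetxt(out / "dwi.bval", bvals[None, :], fmt="%.17g")
        np.savetxt(out / "dwi.bvec", bvecs.T, fmt="%.17g")
        manifest["files"]["dwi"] = "dwi.nii.gz"
        manifest["files"]["bval"] = "dwi.bval"
        manifest["files"]["bvec"] = "dwi.bvec"
        manifest["phantom"] = _spec_to_jsonable(phantom)
        manifest["phantom"].pop("region_map", None)  # regenerable from grid_shape
        manifest["gradient_scheme"] = {"n_directions": n_directions, "b": b, "s0": s0}
        manifest["roi_centers"] = {
            "projection": list(phantom.projection_center),
            "association": list(phantom.association_center),
        }

    if cohort is not None:
        df = generate_cohort(cohort)
        df.to_csv(out / "cohort.csv", index=False)
        manifest["files"]["cohort"] = "cohort.csv"
        manifest["cohort"] = _spec_to_jsonable(cohort)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest_path = out / "manifest.json"
    manifest["files"]["manifest"] = manifest_path.name
    return manifest


def read_fixture_bundle(bundle_dir) -> dict:
    """Load a fixture bundle back into in-memory objects.

    Returns a dict with keys among ``dwi`` (:class:`DiffusionVolume`),
    ``cohort`` (DataFrame), ``manifest`` and ``roi_centers``.
    """
    import nibabel as nib

    bundle = Path(bundle_dir)
    with open(bundle / "manifest.json") as fh:
        manifest = json.load(fh)
    out: dict = {"manifest": manifest}
    files = manifest.get("files", {})
    if "dwi" in files:
        img = nib.load(bundle / files["dwi"])
        bvals = np.loadtxt(bundle / files["bval"]).ravel()
        bvecs = np.loadtxt(bundle / files["bvec"])
        voxel = manifest["phantom"]["voxel_size_mm"]
        out["dwi"] = DiffusionVolume(
            signal=np.asarray(img.dataobj, dtype=float),
            bvals=bvals,
            bvecs=bvecs,
            voxel_size_mm=tuple(voxel),
        )
        out["roi_centers"] = manifest.get("roi_centers")
    if "cohort" in files:
        out["cohort"] = pd.read_csv(bundle / files["cohort"])
    return out
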