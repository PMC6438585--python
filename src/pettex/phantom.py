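"""Synthetic FDG-PET phantom cohort generator.

Emulates the statistical structure of a head-and-neck PET cohort so the
full segmentation -> texture -> agreement pipeline can be exercised without
patient data: ellipsoidal tumors of 1-60 ml in a low-uptake background,
signal-to-background ratio (SBR) centered on 23.5 +/- 7.4, textured
intratumoral uptake with an optional necrotic core, Gaussian partial-volume
blur, additive noise, and two simulated observers who differ only in the
jitter of their segmentation seed click.

The construction order for one phantom is fixed: ellipsoid indicator at the
peak SUV, multiplicative textured heterogeneity (smoothed, standardized
Gaussian random field), necrotic core carved toward background, background
plateau outside the tumor, Gaussian blur, additive Gaussian noise, clamp
at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volumes import PETVolume, VOIMask, save_volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic PET phantom.

    ``target_sbr``, when set, overrides ``background_suv`` with
    ``suv_peak / target_sbr`` so that the pre-blur peak-to-background
    ratio equals the target.
    """

    grid_shape: tuple[int, int, int] = (44, 44, 48)
    spacing: tuple[float, float, float] = (4.07, 4.07, 2.0)
    tumor_center: tuple[float, float, float] | None = None  # voxel coords
    tumor_radii_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    suv_peak: float = 23.5
    background_suv: float = 1.0
    target_sbr: float | None = None
    heterogeneity_amp: float = 0.0
    texture_corr_len_mm: float = 8.0
    necrotic_fraction: float = 0.0
    blur_fwhm_mm: float = 6.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_sbr is not None:
            object.__setattr__(self, "background_suv", self.suv_peak / self.target_sbr)
        if not (self.suv_peak > self.background_suv > 0):
            raise ValueError("need suv_peak > background_suv > 0")
        if any(r <= 0 for r in self.tumor_radii_mm) or any(s <= 0 for s in self.spacing):
            raise ValueError("geometric fields must be positive")
        if self.blur_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("blur and noise must be non-negative")
        if not (0.0 <= self.heterogeneity_amp <= 1.0):
            raise ValueError("heterogeneity_amp must lie in [0, 1]")
        if not (0.0 <= self.necrotic_fraction < 1.0):
            raise ValueError("necrotic_fraction must lie in [0, 1)")

    @property
    def center(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return tuple((n - 1) / 2.0 for n in self.grid_shape)


@dataclass(frozen=True)
class ObserverAction:
    """A simulated observer's segmentation-initiating click."""

    observer: str
    seed_point: tuple[int, int, int]
    jitter_mm: float


@dataclass
class PhantomCase:
    """One cohort member: volume, ground-truth support and nominal click."""

    patient_id: str
    volume: PETVolume
    true_mask: VOIMask
    seed_point: tuple[int, int, int]
    true_volume_ml: float
    spec: PhantomSpec


def _ellipsoid_distance(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoidal radius: <= 1 inside the tumor support."""
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    c = spec.center
    d2 = sum(
        ((g - c[ax]) * spec.spacing[ax] / spec.tumor_radii_mm[ax]) ** 2
        for ax, g in enumerate(grids)
    )
    return np.sqrt(d2)


def tumor_support(spec: PhantomSpec) -> np.ndarray:
    """Boolean pre-blur tumor support (the ellipsoid indicator)."""
    return _ellipsoid_distance(spec) <= 1.0


def _check_inside_grid(spec: PhantomSpec) -> None:
    c = spec.center
    for ax in range(3):
        extent_vox = spec.tumor_radii_mm[ax] / spec.spacing[ax]
        if c[ax] - extent_vox < 0.5 or c[ax] + extent_vox > spec.grid_shape[ax] - 1.5:
            raise ValueError(
                f"tumor (semi-axis {spec.tumor_radii_mm[ax]} mm) does not fit "
                f"inside the grid along axis {ax}"
            )


def generate_phantom(spec: PhantomSpec) -> PETVolume:
    """Render one phantom volume; deterministic given ``spec.seed``."""
    _check_inside_grid(spec)
    rng = np.random.default_rng(spec.seed)
    rho = _ellipsoid_distance(spec)
    inside = rho <= 1.0

    img = np.full(spec.grid_shape, spec.background_suv, dtype=np.float64)
    tumor = np.full(spec.grid_shape, spec.suv_peak, dtype=np.float64)

    if spec.heterogeneity_amp > 0:
        white = rng.standard_normal(spec.grid_shape)
        sigma_vox = [
            spec.texture_corr_len_mm * _FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        grf = gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        vals = grf[inside]
        grf = (grf - vals.mean()) / max(vals.std(), 1e-12)
        tumor *= np.clip(1.0 + spec.heterogeneity_amp * grf, 0.05, None)
    else:
        # keep the RNG stream aligned whether or not texture is drawn
        rng.standard_normal(spec.grid_shape)

    if spec.necrotic_fraction > 0:
        core = rho <= spec.necrotic_fraction
        tumor[core] = spec.background_suv

    img[inside] = tumor[inside]

    if spec.blur_fwhm_mm > 0:
        sigma_vox = [spec.blur_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.spacing]
        img = gaussian_filter(img, sigma=sigma_vox, mode="nearest")

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    np.clip(img, 0.0, None, out=img)
    return PETVolume(values=img, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))


def _radii_for_volume(volume_ml: float, elong: np.ndarray) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (mm) with given volume and axis ratios."""
    base = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi * float(np.prod(elong)))) ** (1 / 3)
    return tuple(float(base * e) for e in elong)


def generate_cohort(
    n_patients: int,
    base_spec: PhantomSpec | None = None,
    size_range_ml: tuple[float, float] = (3.0, 60.0),
    small_fraction: float = 0.3,
    seed: int = 0,
    small_size_range_ml: tuple[float, float] = (0.5, 2.0),
    sbr_mean: float = 23.5,
    sbr_sd: float = 7.4,
    necrosis_prob: float = 0.3,
) -> list[PhantomCase]:
    """Draw a seeded phantom cohort.

    Tumor volumes are log-uniform over ``size_range_ml``; a ``small_fraction``
    of patients instead receive a tumor below the 64-voxel analyzability
    floor (drawn log-uniformly over ``small_size_range_ml``), mirroring the
    exclusion pattern of clinical cohorts.  Per-patient SBR is Gaussian
    around 23.5 +/- 7.4 (clipped to [8, 45]); a ``necrosis_prob`` fraction of
    tumors carries a necrotic core.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not (0.0 <= small_fraction < 1.0):
        raise ValueError("small_fraction must lie in [0, 1)")
    if base_spec is None:
        base_spec = PhantomSpec(heterogeneity_amp=0.4, noise_sd=0.1)

    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_patients)
    cases: list[PhantomCase] = []
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        small = rng.random() < small_fraction
        lo, hi = small_size_range_ml if small else size_range_ml
        vol_ml = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elong = rng.uniform(0.85, 1.18, size=3)
        radii = _radii_for_volume(vol_ml, elong)
        sbr = float(np.clip(rng.normal(sbr_mean, sbr_sd), 8.0, 45.0))
        necro = float(rng.uniform(0.2, 0.5)) if rng.random() < necrosis_prob else 0.0
        center = tuple(
            (n - 1) / 2.0 + float(rng.uniform(-1.0, 1.0)) for n in base_spec.grid_shape
        )
        spec = replace(
            base_spec,
            tumor_center=center,
            tumor_radii_mm=radii,
            suv_peak=base_spec.background_suv * sbr,
            target_sbr=sbr,
            necrotic_fraction=necro,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        _check_inside_grid(spec)  # raises if size range incompatible with grid
        volume = generate_phantom(spec)
        support = tumor_support(spec)
        true_mask = VOIMask(mask=support, spacing=spec.spacing)
        seed_point = tuple(int(round(c)) for c in spec.center)
        cases.append(
            PhantomCase(
                patient_id=f"P{i + 1:03d}",
                volume=volume,
                true_mask=true_mask,
                seed_point=seed_point,
                true_volume_ml=vol_ml,
                spec=spec,
            )
        )
    return cases


def simulate_observer(
    nominal_seed_point: tuple[int, int, int],
    jitter_mm: float,
    observer_seed: int,
    support: np.ndarray,
    spacing: tuple[float, float, float],
    observer: str = "obs",
    max_retries: int = 50,
) -> ObserverAction:
    """Jitter the nominal click by a random displacement of magnitude
    <= ``jitter_mm``, constrained to stay inside the tumor support."""
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    point = tuple(int(p) for p in nominal_seed_point)
    if jitter_mm == 0:
        return ObserverAction(observer=observer, seed_point=point, jitter_mm=0.0)
    rng = np.random.default_rng(observer_seed)
    for _ in range(max_retries):
        direction = rng.standard_normal(3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        magnitude = rng.uniform(0.0, jitter_mm)
        disp_vox = direction * magnitude / np.asarray(spacing)
        cand = tuple(int(round(p + d)) for p, d in zip(point, disp_vox))
        if all(0 <= c < s for c, s in zip(cand, support.shape)) and support[cand]:
            return ObserverAction(observer=observer, seed_point=cand, jitter_mm=jitter_mm)
    raise RuntimeError("could not place a jittered seed point inside the tumor support")


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Write one NIfTI per phantom plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        vol_path = out_dir / f"{case.patient_id}.nii.gz"
        save_volume(case.volume, vol_path)
        rows.append(
            {
                "patient_id": case.patient_id,
                "seed": case.spec.seed,
                "true_volume_ml": case.true_volume_ml,
                "seed_point_x": case.seed_point[0],
                "seed_point_y": case.seed_point[1],
                "seed_point_z": case.seed_point[2],
                "sbr": case.spec.target_sbr,
                "necrotic_fraction": case.spec.necrotic_fraction,
                "file": vol_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
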