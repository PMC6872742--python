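"""Phantom PET/CT cohort generator with known survival signal.

Each phantom is a lung-like background volume holding one lobulated,
texturally heterogeneous tumor blob and an optional set of vessel-like
tubes in the peritumoral region. CT and PET renderings share the same
geometry (the modalities are co-registered by construction). Binary
survival labels are drawn from a logistic model over latent tumor
properties (volume, heterogeneity, vessel proximity), so that signal
recovery by the downstream pipeline is checkable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import SegmentationMask, VolumeImage

# Rendering constants. HU values are lung-window plausible; SUV values sit
# inside the [0.01, 20] PET clip window.
CT_BACKGROUND_HU = -800.0
CT_VESSEL_HU = 50.0
CT_TUMOR_HU = 40.0
CT_TEXTURE_HU = 60.0  # heterogeneity contrast at heterogeneity=1
PET_BACKGROUND_SUV = 0.4
PET_VESSEL_SUV = 1.2
PET_TUMOR_SUV = 6.0
PET_TEXTURE_SUV = 3.5
VESSEL_RADIUS_VOX = 1.5
TEXTURE_SMOOTHNESS_VOX = 3.0  # Gaussian sigma of the band-limited fields


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of a single phantom."""

    volume_shape: tuple[int, int, int] = (48, 48, 24)
    spacing_mm: float = 1.0
    tumor_center: tuple[float, float, float] | None = None
    tumor_radii: tuple[float, float, float] = (8.0, 8.0, 5.0)
    lobularity: float = 0.2
    heterogeneity: float = 0.5
    vessel_count: int = 2
    noise_sd_ct: float = 15.0
    noise_sd_pet: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if self.tumor_center is None:
            self.tumor_center = tuple(s / 2.0 for s in self.volume_shape)
        self.tumor_center = tuple(float(c) for c in self.tumor_center)
        self.tumor_radii = tuple(float(r) for r in self.tumor_radii)

    def validate(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError("all tumor radii must be positive")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity must lie in [0, 1]")
        if self.lobularity < 0:
            raise ValueError("lobularity must be nonnegative")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be nonnegative")
        if self.noise_sd_ct < 0 or self.noise_sd_pet < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        # Conservative bound: boundary perturbation rarely exceeds 2 sigma of
        # the unit-variance field; require a 2-voxel margin beyond that.
        grow = 1.0 + 2.0 * self.lobularity
        for c, r, s in zip(self.tumor_center, self.tumor_radii, self.volume_shape):
            if c - r * grow < 2 or c + r * grow > s - 3:
                raise ValueError(
                    f"tumor (center {self.tumor_center}, radii {self.tumor_radii}, "
                    f"lobularity {self.lobularity}) exceeds volume bounds "
                    f"{self.volume_shape} with the required 2-voxel margin"
                )


@dataclass
class SurvivalGenerator:
    """Logistic label model over latent tumor properties.

    ``betas`` maps latent-property names (``volume``, ``heterogeneity``,
    ``vessel_proximity``) to coefficients applied to cohort-standardized
    latents. Labels are 1 = alive at the horizon, 0 = dead.
    """

    beta0: float = 0.0
    betas: dict[str, float] = field(
        default_factory=lambda: {"volume": -2.0, "heterogeneity": -1.2}
    )
    horizon_label: str = "2OS"
    seed: int = 0

    def scaled(self, factor: float) -> "SurvivalGenerator":
        """Return a copy with every slope multiplied by ``factor``."""
        return replace(self, betas={k: v * factor for k, v in self.betas.items()})


@dataclass
class CohortDistribution:
    """Per-patient parameter ranges for :func:`generate_cohort`.

    All ranges are inclusive ``(low, high)``; zero-width ranges pin the
    parameter. Radii are drawn as a base radius times per-axis anisotropy
    factors so tumor volume varies over roughly an order of magnitude.
    """

    volume_shape: tuple[int, int, int] = (48, 48, 24)
    spacing_mm: float = 1.0
    base_radius_range: tuple[float, float] | None = None
    anisotropy_range: tuple[float, float] = (0.75, 1.15)
    lobularity_range: tuple[float, float] = (0.05, 0.3)
    heterogeneity_range: tuple[float, float] = (0.0, 1.0)
    vessel_count_range: tuple[int, int] = (0, 4)
    center_jitter_vox: float | None = None
    noise_sd_ct: float = 15.0
    noise_sd_pet: float = 0.2

    def __post_init__(self) -> None:
        # scale-aware defaults: tumor radii span ~2x (volume ~8x) and stay
        # inside the volume with margin at any ROI scale
        m = max(self.volume_shape)
        if self.base_radius_range is None:
            self.base_radius_range = (0.075 * m, 0.155 * m)
        if self.center_jitter_vox is None:
            self.center_jitter_vox = max(1.0, 0.03 * m)

    def validate(self) -> None:
        for name in (
            "base_radius_range",
            "anisotropy_range",
            "lobularity_range",
            "heterogeneity_range",
            "vessel_count_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} has negative width: ({lo}, {hi})")
        if self.base_radius_range[0] <= 0:
            raise ValueError("base radius must be positive")


@dataclass
class PhantomRecord:
    """One cohort member: paired images, truth mask, label, and latents."""

    patient_id: str
    ct: VolumeImage
    pet: VolumeImage
    mask: SegmentationMask
    label: int
    latents: dict[str, float]
    p_survival: float
    spec: PhantomSpec


def _smooth_field(shape, rng, sigma=TEXTURE_SMOOTHNESS_VOX):
    """Band-limited Gaussian random field, normalized to zero mean unit SD."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = field.std()
    if sd == 0:
        return np.zeros(shape)
    return (field - field.mean()) / sd


def _grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def generate_tumor_mask(spec: PhantomSpec) -> SegmentationMask:
    """Lobulated ellipsoid mask: radii perturbed by smooth boundary noise.

    With ``lobularity=0`` this is the exact discrete ellipsoid
    ``sum(((x_i - c_i)/r_i)^2) <= 1``. The result is the largest connected
    component of the perturbed region, deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    gx, gy, gz = _grid(spec.volume_shape)
    cx, cy, cz = spec.tumor_center
    rx, ry, rz = spec.tumor_radii
    q = ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 + ((gz - cz) / rz) ** 2
    if spec.lobularity > 0:
        s = _smooth_field(spec.volume_shape, rng)
        bound = np.maximum(1.0 + spec.lobularity * s, 0.2) ** 2
    else:
        bound = 1.0
    region = q <= bound
    labels, n = ndimage.label(region)
    if n == 0:
        raise ValueError("tumor mask is empty; check radii against volume shape")
    if n > 1:
        sizes = ndimage.sum_labels(region, labels, index=np.arange(1, n + 1))
        region = labels == (1 + int(np.argmax(sizes)))
    mask = SegmentationMask(region, (spec.spacing_mm,) * 3)
    edge = np.zeros(spec.volume_shape, bool)
    edge[:2], edge[-2:], edge[:, :2], edge[:, -2:] = True, True, True, True
    edge[..., :2] = edge[..., -2:] = True
    if (mask.data & edge).any():
        raise ValueError("tumor exceeds volume bounds: mask touches the 2-voxel margin")
    return mask


def _sample_vessels(spec: PhantomSpec):
    """Deterministic vessel-line geometry shared by both modalities.

    Each vessel is an infinite line (point, unit direction) passing at a
    random standoff outside the tumor surface.
    """
    rng = np.random.default_rng([spec.seed, 2])
    center = np.asarray(spec.tumor_center)
    r_eff = float(np.mean(spec.tumor_radii))
    vessels = []
    for _ in range(spec.vessel_count):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        standoff = r_eff + rng.uniform(2.0, 8.0)
        p0 = center + standoff * v
        vessels.append((p0, u))
    return vessels


def _vessel_distance_field(spec: PhantomSpec):
    """Per-voxel distance (vox) to the nearest vessel axis; inf when none."""
    if spec.vessel_count == 0:
        return np.full(spec.volume_shape, np.inf)
    gx, gy, gz = _grid(spec.volume_shape)
    pts = np.stack([gx, gy, gz], axis=-1)
    dist = np.full(spec.volume_shape, np.inf)
    for p0, u in _sample_vessels(spec):
        d = pts - p0
        along = d @ u
        perp = d - along[..., None] * u
        dist = np.minimum(dist, np.linalg.norm(perp, axis=-1))
    return dist


def vessel_proximity(spec: PhantomSpec, mask: SegmentationMask) -> float:
    """Latent in [0, 1]: 1 when a vessel grazes the tumor surface, 0 if none."""
    if spec.vessel_count == 0:
        return 0.0
    dist = _vessel_distance_field(spec)
    surface = mask.data & ~ndimage.binary_erosion(mask.data)
    gap = float(dist[surface].min()) if surface.any() else float(dist[mask.data].min())
    return float(np.exp(-max(gap, 0.0) / 5.0))


def _texture(spec: PhantomSpec):
    """Intratumoral heterogeneity field, shared across modalities."""
    rng = np.random.default_rng([spec.seed, 3])
    return _smooth_field(spec.volume_shape, rng, sigma=2.0)


def render_ct(mask: SegmentationMask, spec: PhantomSpec) -> VolumeImage:
    """CT rendering: lung background, vessel tubes, soft-tissue tumor."""
    if mask.shape != tuple(spec.volume_shape):
        raise ValueError(f"mask shape {mask.shape} != spec shape {spec.volume_shape}")
    img = np.full(spec.volume_shape, CT_BACKGROUND_HU)
    if spec.vessel_count > 0:
        img[_vessel_distance_field(spec) <= VESSEL_RADIUS_VOX] = CT_VESSEL_HU
    tumor = CT_TUMOR_HU + spec.heterogeneity * CT_TEXTURE_HU * _texture(spec)
    img[mask.data] = tumor[mask.data]
    if spec.noise_sd_ct > 0:
        rng = np.random.default_rng([spec.seed, 4])
        img = img + rng.normal(0.0, spec.noise_sd_ct, spec.volume_shape)
    return VolumeImage(img, (spec.spacing_mm,) * 3, "CT")


def render_pet(mask: SegmentationMask, spec: PhantomSpec) -> VolumeImage:
    """PET rendering: low background, mild vessel uptake, hot tumor.

    SUV is nonnegative everywhere; heterogeneity scales hot/cold subregions
    inside the tumor.
    """
    if mask.shape != tuple(spec.volume_shape):
        raise ValueError(f"mask shape {mask.shape} != spec shape {spec.volume_shape}")
    img = np.full(spec.volume_shape, PET_BACKGROUND_SUV)
    if spec.vessel_count > 0:
        img[_vessel_distance_field(spec) <= VESSEL_RADIUS_VOX] = PET_VESSEL_SUV
    tumor = PET_TUMOR_SUV + spec.heterogeneity * PET_TEXTURE_SUV * _texture(spec)
    img[mask.data] = tumor[mask.data]
    if spec.noise_sd_pet > 0:
        rng = np.random.default_rng([spec.seed, 5])
        img = img + rng.normal(0.0, spec.noise_sd_pet, spec.volume_shape)
    return VolumeImage(np.maximum(img, 0.0), (spec.spacing_mm,) * 3, "PET")


def _draw_spec(dist: CohortDistribution, rng) -> PhantomSpec:
    base = rng.uniform(*dist.base_radius_range)
    # radii shrink along flattened axes so tumors fit volumes with the
    # 2:2:1 aspect of the clinical ROI
    aspect = np.asarray(dist.volume_shape) / max(dist.volume_shape)
    radii = tuple(base * rng.uniform(*dist.anisotropy_range) * a for a in aspect)
    jitter = rng.uniform(-dist.center_jitter_vox, dist.center_jitter_vox, 3)
    center = tuple(s / 2.0 + j for s, j in zip(dist.volume_shape, jitter))
    return PhantomSpec(
        volume_shape=dist.volume_shape,
        spacing_mm=dist.spacing_mm,
        tumor_center=center,
        tumor_radii=radii,
        lobularity=rng.uniform(*dist.lobularity_range),
        heterogeneity=rng.uniform(*dist.heterogeneity_range),
        vessel_count=int(rng.integers(dist.vessel_count_range[0], dist.vessel_count_range[1] + 1)),
        noise_sd_ct=dist.noise_sd_ct,
        noise_sd_pet=dist.noise_sd_pet,
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n_patients: int,
    spec_distribution: CohortDistribution,
    survival_gen: SurvivalGenerator,
    seed: int = 0,
) -> list[PhantomRecord]:
    """Simulate a phantom cohort with labels from the latent logistic model.

    Latents (mask volume in voxels, heterogeneity, vessel proximity) are
    z-scored across the cohort before entering the logistic model, so the
    generator's coefficients are in per-SD units. Fully reproducible from
    ``seed`` and ``survival_gen.seed``.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    spec_distribution.validate()
    rng = np.random.default_rng(seed)
    records: list[tuple[PhantomSpec, SegmentationMask, VolumeImage, VolumeImage, dict]] = []
    for _ in range(n_patients):
        spec = _draw_spec(spec_distribution, rng)
        mask = generate_tumor_mask(spec)
        ct = render_ct(mask, spec)
        pet = render_pet(mask, spec)
        latents = {
            "volume": float(mask.voxel_count),
            "heterogeneity": float(spec.heterogeneity),
            "vessel_proximity": vessel_proximity(spec, mask),
        }
        records.append((spec, mask, ct, pet, latents))

    latents_list = [r[4] for r in records]
    labels, p = labels_from_latents(latents_list, survival_gen)

    cohort = []
    for i, (spec, mask, ct, pet, latents) in enumerate(records):
        cohort.append(
            PhantomRecord(
                patient_id=f"P{i:03d}",
                ct=ct,
                pet=pet,
                mask=mask,
                label=int(labels[i]),
                latents=latents,
                p_survival=float(p[i]),
                spec=spec,
            )
        )
    return cohort


def labels_from_latents(
    latents: list[dict], survival_gen: SurvivalGenerator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Bernoulli survival labels from cohort latents.

    Latents are z-scored across the cohort so generator coefficients are in
    per-SD units; returns (labels, survival probabilities). Different
    generators applied to the same latents yield alternative label sets for
    identical images (e.g. a stronger planted effect or another horizon).
    """
    names = sorted(survival_gen.betas)
    lat = np.array([[d[n] for n in names] for d in latents])
    sd = lat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (lat - lat.mean(axis=0)) / sd
    eta = survival_gen.beta0 + z @ np.array([survival_gen.betas[n] for n in names])
    p = 1.0 / (1.0 + np.exp(-eta))
    label_rng = np.random.default_rng([survival_gen.seed, 11])
    labels = (label_rng.random(len(latents)) < p).astype(int)
    return labels, p


def cohort_manifest(cohort: list[PhantomRecord]):
    """Cohort summary as a DataFrame (id, label, survival prob, latents)."""
    import pandas as pd

    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id, "label": rec.label, "p_survival": rec.p_survival}
        row.update(rec.latents)
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(cohort: list[PhantomRecord], out_dir) -> "object":
    """Write NIfTI volumes/masks plus a CSV manifest; returns the manifest."""
    from pathlib import Path

    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(cohort)
    paths = {"ct_path": [], "pet_path": [], "mask_path": []}
    for rec in cohort:
        for key, obj, name in (
            ("ct_path", rec.ct, "ct"),
            ("pet_path", rec.pet, "pet"),
            ("mask_path", rec.mask, "mask"),
        ):
            path = out / f"{rec.patient_id}_{name}.nii.gz"
            write_volume(obj, path)
            paths[key].append(str(path))
    for key, vals in paths.items():
        manifest[key] = vals
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
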