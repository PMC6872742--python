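"""End-to-end pipeline driver: simulate -> preprocess -> train segmentation
-> extract features -> cross-validate survival (-> visualize).

Stages communicate through in-memory objects; artifacts (models, feature
table, CV report, manifest) are written under the configured output
directory so a rerun with the same config resumes from completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .features import build_feature_table, read_feature_table, write_feature_table
from .preprocess import clip_intensities, crop_mask, crop_roi, mask_centroid, augment
from .survival import CVReport, cross_validate
from .synthetic import CohortDistribution, SurvivalGenerator, generate_cohort
from .unet import UNet, UNetConfig, dice, load_model, save_model, segment, train_unet

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, stage artifacts, summaries."""

    config_hash: str
    artifacts: dict[str, str] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, path: Path | None, summary: dict) -> None:
        if path is not None:
            self.artifacts[stage] = str(path)
            self.checksums[stage] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.summaries[stage] = summary
        self.timestamps[stage] = time.time()

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "artifacts": self.artifacts,
                    "summaries": self.summaries,
                    "timestamps": self.timestamps,
                    "checksums": self.checksums,
                },
                indent=2,
                default=float,
            )
        )

    def verify(self) -> bool:
        """Every recorded artifact exists and matches its checksum."""
        for stage, path in self.artifacts.items():
            p = Path(path)
            if not p.exists():
                return False
            if hashlib.sha256(p.read_bytes()).hexdigest() != self.checksums[stage]:
                return False
        return True


def _config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict

    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest()[:16]


def preprocess_cohort(cohort, roi_shape, modalities=("CT", "PET")):
    """Crop, clip, and pair up every patient's ROI images and mask."""

    @dataclass
    class PatientROIs:
        patient_id: str
        rois: dict
        mask: object
        label: int
        latents: dict

    out = []
    for rec in cohort:
        center = mask_centroid(rec.mask)
        rois = {}
        for m in modalities:
            vol = rec.ct if m == "CT" else rec.pet
            rois[m] = clip_intensities(crop_roi(vol, rec.mask, roi_shape))
        msk = crop_mask(rec.mask, roi_shape, center)
        out.append(PatientROIs(rec.patient_id, rois, msk, rec.label, rec.latents))
    return out


def train_segmentation_models(
    patients, config: PipelineConfig
) -> tuple[dict[str, UNet], dict[str, float]]:
    """Train one segmentation network per modality; returns models + test DSC."""
    n_tr, n_val = config.n_seg_train, config.n_seg_val
    models, test_dsc = {}, {}
    for modality in config.modalities:
        pairs = [(p.rois[modality], p.mask) for p in patients]
        train = pairs[:n_tr]
        if config.n_aug:
            aug = []
            for i, (img, msk) in enumerate(train):
                aug.extend(augment(img, msk, config.n_aug, seed=config.stage_seed(f"aug{modality}{i}")))
            train = train + aug
        val = pairs[n_tr : n_tr + n_val]
        test = pairs[n_tr + n_val :]
        ucfg = UNetConfig(
            in_shape=config.roi_shape,
            base_channels=config.base_channels,
            n_levels=config.n_levels,
            modality=modality,
            epochs=config.epochs,
            lr=config.lr,
            weight_decay=config.weight_decay,
            seed=config.stage_seed(f"train-{modality}"),
        )
        model = UNet(ucfg)
        train_unet(model, train, val, ucfg)
        models[modality] = model
        if test:
            test_dsc[modality] = float(np.mean([dice(segment(model, i), k) for i, k in test]))
    return models, test_dsc


def run_pipeline(config: PipelineConfig, labels_override=None) -> tuple[RunManifest, CVReport]:
    """Execute the full analysis under one config; resumable per stage.

    ``labels_override`` substitutes the cohort's survival labels (used for
    permutation nulls and alternative planted-effect label sets) without
    touching images or segmentation training.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config))
    config.to_yaml(out / "config.yaml")

    # simulate
    dist = CohortDistribution(volume_shape=config.volume_shape)
    gen = SurvivalGenerator(
        beta0=config.survival_beta0,
        betas=dict(config.survival_betas),
        horizon_label=config.horizon_label,
        seed=config.stage_seed("labels"),
    )
    cohort = generate_cohort(config.n_patients, dist, gen, seed=config.stage_seed("simulate"))
    labels = np.array([r.label for r in cohort])
    if labels_override is not None:
        labels = np.asarray(labels_override, dtype=int)
    manifest.record("simulate", None, {"n_patients": len(cohort), "prevalence": float(labels.mean())})

    # preprocess
    patients = preprocess_cohort(cohort, config.roi_shape, config.modalities)
    manifest.record("preprocess", None, {"roi_shape": list(config.roi_shape)})

    # segmentation training (resumable from saved checkpoints)
    models = {}
    model_paths = {m: out / f"unet_{m.lower()}.npz" for m in config.modalities}
    if all(p.exists() for p in model_paths.values()):
        models = {m: load_model(p) for m, p in model_paths.items()}
        test_dsc = manifest.summaries.get("train_seg", {})
        log.info("resumed segmentation models from %s", out)
    else:
        models, test_dsc = train_segmentation_models(patients, config)
        for m, model in models.items():
            save_model(model, model_paths[m])
    manifest.record("train_seg", None, {f"dsc_{m}": v for m, v in (test_dsc or {}).items()})

    # feature extraction
    table_path = out / "features.csv"
    if table_path.exists():
        table = read_feature_table(table_path)
    else:
        table = build_feature_table(models, patients)
        write_feature_table(table, table_path)
    manifest.record("extract", table_path, {"n_features": table.n_features})

    # survival cross-validation
    report = cross_validate(
        table,
        labels,
        horizon_label=config.horizon_label,
        n_folds=config.n_folds,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_init=config.n_init,
        seed=config.stage_seed("cv"),
    )
    cv_path = out / "cv_report.json"
    cv_path.write_text(
        json.dumps(
            {
                "per_fold": report.metrics.to_dict(orient="list"),
                "summary": report.summary.to_dict(orient="index"),
                "horizon": report.horizon_label,
            },
            indent=2,
        )
    )
    report.metrics.to_csv(out / "cv_metrics.csv", index=False)
    manifest.record("cross_validate", cv_path, {k: float(v) for k, v in report.metrics.mean().items()})

    manifest.save(out / "manifest.json")
    return manifest, report
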