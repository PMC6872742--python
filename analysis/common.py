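"""Shared configuration and cached artifacts for the numbered analysis scripts.

All computation lives in the seg2surv package; these helpers only decide
where artifacts are cached (scratch/analysis_run) and which small summaries
land in results/. Rerunning a script reuses every cached upstream artifact,
so the scripts can be run in any order.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

sys.path.insert(0, str(ROOT / "src"))

from seg2surv.config import PipelineConfig  # noqa: E402
from seg2surv.features import build_feature_table, read_feature_table, write_feature_table  # noqa: E402
from seg2surv.pipeline import preprocess_cohort, train_segmentation_models  # noqa: E402
from seg2surv.synthetic import CohortDistribution, SurvivalGenerator, generate_cohort  # noqa: E402
from seg2surv.unet import load_model, save_model  # noqa: E402

#: Study configuration: 120-phantom desk-scale cohort, CT+PET, 4-level nets.
CONFIG = PipelineConfig(
    out_dir=str(SCRATCH),
    n_patients=120,
    volume_shape=(48, 48, 24),
    roi_shape=(48, 48, 24),
    base_channels=4,
    n_levels=4,
    epochs=14,
    n_seg_train=25,
    n_seg_val=5,
    k_range=(2, 15),
    n_init=10,
    n_folds=6,
    seed=20,
)


def get_cohort():
    cfg = CONFIG
    dist = CohortDistribution(volume_shape=cfg.volume_shape)
    gen = SurvivalGenerator(
        beta0=cfg.survival_beta0, betas=dict(cfg.survival_betas),
        horizon_label=cfg.horizon_label, seed=cfg.stage_seed("labels"),
    )
    return generate_cohort(cfg.n_patients, dist, gen, seed=cfg.stage_seed("simulate")), gen


def get_patients(cohort=None):
    if cohort is None:
        cohort, _ = get_cohort()
    return preprocess_cohort(cohort, CONFIG.roi_shape, CONFIG.modalities)


def get_models(patients=None):
    SCRATCH.mkdir(parents=True, exist_ok=True)
    paths = {m: SCRATCH / f"unet_{m.lower()}.npz" for m in CONFIG.modalities}
    if all(p.exists() for p in paths.values()):
        return {m: load_model(p) for m, p in paths.items()}, None
    if patients is None:
        patients = get_patients()
    models, test_dsc = train_segmentation_models(patients, CONFIG)
    for m, model in models.items():
        save_model(model, paths[m])
    return models, test_dsc


def get_feature_table(models=None, patients=None):
    path = SCRATCH / "features.csv"
    if path.exists():
        return read_feature_table(path)
    if patients is None:
        patients = get_patients()
    if models is None:
        models, _ = get_models(patients)
    table = build_feature_table(models, patients)
    write_feature_table(table, path)
    return table


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
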