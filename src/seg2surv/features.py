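"""Bottleneck feature harvesting and conventional PET baseline metrics.

The encoder's most-compressed activations (post-ReLU) are flattened into a
fixed, documented order — x fastest, then y, then z, then channel — and
stacked into a patients x features table, the CT block before the PET
block. Each column carries provenance (modality, bottleneck position,
channel) so that single-modality tables are column subsets of dual-modality
tables and selected features can be traced back to bottleneck neurons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ROIVolume, SegmentationMask
from .unet import UNet

log = logging.getLogger(__name__)

MODALITY_ORDER = ("CT", "PET")


@dataclass
class FeatureTable:
    """Patients x features matrix with per-column provenance."""

    values: np.ndarray  # (n_patients, n_features)
    feature_index: pd.DataFrame  # columns: modality, x, y, z, channel
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.patient_ids), len(self.feature_index)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.patient_ids)} patients x {len(self.feature_index)} features"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_names(self) -> list[str]:
        return [
            f"{r.modality}_c{r.channel:04d}_x{r.x}y{r.y}z{r.z}"
            for r in self.feature_index.itertuples()
        ]

    def subset_columns(self, cols) -> "FeatureTable":
        cols = np.asarray(cols, dtype=int)
        return FeatureTable(
            self.values[:, cols],
            self.feature_index.iloc[cols].reset_index(drop=True),
            list(self.patient_ids),
        )

    def modality_block(self, modality: str) -> "FeatureTable":
        cols = np.flatnonzero((self.feature_index["modality"] == modality).to_numpy())
        return self.subset_columns(cols)


def bottleneck_index(model: UNet, modality: str) -> pd.DataFrame:
    """Provenance rows in flattening order (x fastest, ... channel slowest)."""
    bx, by, bz, ch = model.bottleneck_shape
    m, z, y, x = np.meshgrid(
        np.arange(ch), np.arange(bz), np.arange(by), np.arange(bx), indexing="ij"
    )
    return pd.DataFrame(
        {
            "modality": modality,
            "x": x.ravel(),
            "y": y.ravel(),
            "z": z.ravel(),
            "channel": m.ravel(),
        }
    )


def flatten_bottleneck(activations: np.ndarray) -> np.ndarray:
    """Flatten a (channels, x, y, z) activation tensor x-fastest, channel-slowest."""
    return np.ascontiguousarray(activations.transpose(0, 3, 2, 1)).ravel()


def unflatten_gradient(vec: np.ndarray, bottleneck_shape) -> np.ndarray:
    """Inverse of :func:`flatten_bottleneck` back to (channels, x, y, z)."""
    bx, by, bz, ch = bottleneck_shape
    return vec.reshape(ch, bz, by, bx).transpose(0, 3, 2, 1)


def extract_bottleneck(model: UNet, image: ROIVolume | np.ndarray) -> np.ndarray:
    """Flattened bottleneck activation vector for one image.

    Deterministic for fixed weights and input; length equals
    ``prod(model.bottleneck_shape)`` (55,296 at full scale).
    """
    return flatten_bottleneck(model.encoder_forward(image).astype(np.float64))


def build_feature_table(models: dict[str, UNet], cohort) -> FeatureTable:
    """Per-patient bottleneck features, CT block then PET block.

    ``cohort`` is a sequence of objects with ``patient_id`` and per-modality
    ROI images exposed either as a ``rois`` dict or as ``ct``/``pet``
    attributes. Patients missing a required modality are dropped with a
    logged warning; a single-modality model dict yields the corresponding
    single block (the external-validation path).
    """
    if not models:
        raise ValueError("need at least one per-modality model")
    modalities = [m for m in MODALITY_ORDER if m in models]
    rows, ids = [], []
    for rec in cohort:
        images = getattr(rec, "rois", None)
        if images is None:
            images = {"CT": getattr(rec, "ct", None), "PET": getattr(rec, "pet", None)}
        if any(images.get(m) is None for m in modalities):
            log.warning("patient %s missing a modality; dropped", rec.patient_id)
            continue
        rows.append(
            np.concatenate([extract_bottleneck(models[m], images[m]) for m in modalities])
        )
        ids.append(rec.patient_id)
    if not rows:
        raise ValueError("no patients with all required modalities")
    index = pd.concat(
        [bottleneck_index(models[m], m) for m in modalities], ignore_index=True
    )
    return FeatureTable(np.vstack(rows), index, ids)


@dataclass
class BaselineMetrics:
    """Conventional PET burden metrics over the tumor mask."""

    suv_max: float
    suv_mean: float
    mtv: float  # mm^3
    tlg: float  # = mtv * suv_mean


def baseline_metrics(pet: ROIVolume, mask: SegmentationMask) -> BaselineMetrics:
    """SUV_max / SUV_mean over the mask, MTV, and TLG = MTV x SUV_mean."""
    if pet.modality != "PET":
        raise ValueError("baseline metrics require a PET volume")
    if pet.data.shape != mask.data.shape:
        raise ValueError("PET and mask shapes disagree")
    if not mask.data.any():
        raise ValueError("empty mask: no tumor voxels to summarize")
    vals = pet.data[mask.data]
    spacing = pet.spacing if isinstance(pet.spacing, tuple) else (pet.spacing,) * 3
    voxel_mm3 = float(np.prod(spacing))
    suv_mean = float(vals.mean())
    mtv = float(mask.voxel_count * voxel_mm3)
    return BaselineMetrics(
        suv_max=float(vals.max()), suv_mean=suv_mean, mtv=mtv, tlg=mtv * suv_mean
    )


def write_feature_table(table: FeatureTable, csv_path) -> None:
    """Persist as CSV (full precision) plus a JSON provenance sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(table.values, index=table.patient_ids, columns=table.feature_names())
    df.index.name = "patient_id"
    df.to_csv(csv_path)  # pandas default writes shortest round-trip repr
    sidecar = csv_path.with_suffix(".index.json")
    sidecar.write_text(
        json.dumps(
            {"flatten_order": "x fastest, then y, z, channel; CT block before PET",
             "feature_index": table.feature_index.to_dict(orient="list")}
        )
    )


def read_feature_table(csv_path) -> FeatureTable:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col="patient_id", float_precision="round_trip")
    sidecar = json.loads(csv_path.with_suffix(".index.json").read_text())
    index = pd.DataFrame(sidecar["feature_index"])
    return FeatureTable(df.to_numpy(), index, [str(i) for i in df.index])
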