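"""Model interpretation: activation-maximization feature templates and
guided-backpropagation risk maps.

Templates synthesize the input pattern that maximally excites a chosen
bottleneck neuron by gradient ascent (step length 1/sd(gradient), 20
iterations, N(128, 1) initialization). Risk maps score each voxel's
contribution to the predicted death probability P = 1 - y (y being the
predicted survival probability): per-channel coefficients alpha^(m) are the
rectified gradients of P w.r.t. the bottleneck activation maps, reduced
over bottleneck positions, and weight the (upsampled) activation maps in a
nonnegative linear combination R(X) = sum_m alpha^(m) A^(m)(X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .survival import SurvivalModel
from .types import ROIVolume
from .unet import UNet

log = logging.getLogger(__name__)


@dataclass
class FeatureTemplate:
    """Synthesized input maximizing one bottleneck neuron's activation."""

    volume: np.ndarray
    neuron: tuple  # (modality, x, y, z, channel)
    trajectory: list[float]
    n_iters: int


@dataclass
class RiskMap:
    """Nonnegative voxel field scoring contribution to predicted death."""

    volume: np.ndarray
    alpha: np.ndarray  # per-channel coefficients, >= 0
    modality: str
    patient_id: str = ""
    origin_offset: tuple[int, int, int] = (0, 0, 0)


def activation_maximization(
    encoder,
    neuron: tuple[int, int, int, int],
    n_iters: int = 20,
    seed: int = 0,
    init_mean: float = 128.0,
    init_sd: float = 1.0,
) -> FeatureTemplate:
    """Gradient-ascent synthesis of a neuron's preferred input pattern.

    ``encoder`` is any object with ``encoder_forward``/``encoder_backward``
    (a :class:`~seg2surv.unet.UNet` or a toy stand-in); ``neuron`` indexes
    the bottleneck as (x, y, z, channel). The ascent starts from N(128, 1)
    voxel noise and steps by gamma = 1/sd(gradient); iterations with an
    all-zero or degenerate gradient are skipped with a warning. Voxel values
    are not clipped during the ascent.
    """
    rng = np.random.default_rng(seed)
    in_shape = getattr(getattr(encoder, "config", None), "in_shape", None)
    if in_shape is None:
        in_shape = encoder.in_shape
    x = rng.normal(init_mean, init_sd, in_shape)
    nx, ny, nz, ch = neuron
    trajectory = []
    for _ in range(n_iters):
        bt = encoder.encoder_forward(x)
        trajectory.append(float(bt[ch, nx, ny, nz]))
        dbt = np.zeros_like(bt)
        dbt[ch, nx, ny, nz] = 1.0
        grad = encoder.encoder_backward(dbt)
        sd = float(grad.std())
        if not np.isfinite(sd) or sd == 0:
            log.warning("dead neuron %s: zero gradient, ascent stopped", (neuron,))
            break
        x = x + grad / sd
    bt = encoder.encoder_forward(x)
    trajectory.append(float(bt[ch, nx, ny, nz]))
    return FeatureTemplate(volume=x, neuron=neuron, trajectory=trajectory, n_iters=n_iters)


@dataclass
class PredictionChain:
    """Trained encoders + survival model, differentiable end to end."""

    encoders: dict[str, UNet]
    model: SurvivalModel

    def __post_init__(self) -> None:
        if self.model.feature_provenance is None:
            raise ValueError("survival model lacks feature provenance; cannot trace neurons")

    def _features(self, bottlenecks: dict[str, np.ndarray]) -> np.ndarray:
        feats = np.empty(len(self.model.feature_provenance))
        for i, row in enumerate(self.model.feature_provenance.itertuples()):
            feats[i] = bottlenecks[row.modality][row.channel, row.x, row.y, row.z]
        return feats

    def death_probability(self, images: dict[str, ROIVolume]) -> float:
        """P(death) = 1 - predicted survival probability."""
        bts = {m: self.encoders[m].encoder_forward(img) for m, img in images.items()}
        y = float(self.model.predict_survival(self._features(bts))[0])
        return 1.0 - y

    def feature_gradients(self, images: dict[str, ROIVolume]):
        """dP/d(selected feature), with the bottlenecks and y cached."""
        bts = {m: self.encoders[m].encoder_forward(img) for m, img in images.items()}
        from scipy.special import expit

        feats = self._features(bts)
        z = (feats - self.model.mean) / self.model.scale
        y = expit(self.model.beta0 + z @ self.model.betas)
        # dP/dfeat = -dy/dfeat = -y(1-y) * beta / scale
        dP = -y * (1.0 - y) * self.model.betas / self.model.scale
        return dP, bts, float(y)


def death_gradient(chain: PredictionChain, images: dict[str, ROIVolume]) -> dict[str, np.ndarray]:
    """End-to-end gradient of the death probability w.r.t. every input voxel.

    Returns one gradient field per supplied modality. With an intercept-only
    survival model the gradient is identically zero.
    """
    for m in images:
        if m not in chain.encoders:
            raise ValueError(f"no encoder for modality {m!r}")
    dP, bts, _ = chain.feature_gradients(images)
    grads = {}
    for m, img in images.items():
        dbt = np.zeros_like(bts[m])
        if chain.model.betas.size:
            prov = chain.model.feature_provenance
            for i, row in enumerate(prov.itertuples()):
                if row.modality == m:
                    dbt[row.channel, row.x, row.y, row.z] += dP[i]
        # encoder caches hold this modality's forward pass only if re-run
        chain.encoders[m].encoder_forward(images[m])
        grads[m] = chain.encoders[m].encoder_backward(dbt)
    return grads


def risk_map(
    chain: PredictionChain,
    images: dict[str, ROIVolume],
    modality: str,
    reduction: str = "mean",
) -> RiskMap:
    """Guided-backprop risk map for one modality's image.

    Per-channel coefficients rectify the gradient of the death probability
    w.r.t. each bottleneck activation position (``max(dP/dA, 0)``) and
    reduce over positions (mean by default, sum optionally); channels
    holding no selected feature get alpha = 0 exactly. The map is the
    alpha-weighted sum of the channel activation maps, trilinearly
    upsampled to the ROI grid — nonnegative since activations are post-ReLU.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    dP, bts, _ = chain.feature_gradients(images)
    bt = bts[modality]
    ch = bt.shape[0]
    n_pos = int(np.prod(bt.shape[1:]))
    rect = np.zeros_like(bt)
    if chain.model.betas.size:
        for i, row in enumerate(chain.model.feature_provenance.itertuples()):
            if row.modality == modality:
                rect[row.channel, row.x, row.y, row.z] = max(dP[i], 0.0)
    alpha = rect.reshape(ch, -1).sum(axis=1)
    if reduction == "mean":
        alpha = alpha / n_pos
    weighted = np.tensordot(alpha, bt, axes=(0, 0))
    roi_shape = images[modality].data.shape
    zoom = [t / s for t, s in zip(roi_shape, weighted.shape)]
    vol = ndimage.zoom(weighted.astype(np.float64), zoom, order=1)
    vol = np.maximum(vol, 0.0)
    return RiskMap(
        volume=vol,
        alpha=alpha.astype(np.float64),
        modality=modality,
        origin_offset=getattr(images[modality], "origin_offset", (0, 0, 0)),
    )


def overlay_export(
    image: ROIVolume,
    rmap: RiskMap,
    slices,
    out_dir,
    prefix: str = "overlay",
    alpha_blend: float = 0.45,
) -> list[str]:
    """Export transversal slices with the risk map blended over anatomy.

    The risk map is normalized to its per-volume maximum (a zero map stays
    zero, leaving pure grayscale); heat uses the 'hot' colormap. Returns the
    written PNG paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if image.data.shape != rmap.volume.shape:
        raise ValueError("image and risk map shapes disagree")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vmax = rmap.volume.max()
    heat = rmap.volume / vmax if vmax > 0 else rmap.volume
    paths = []
    for z in slices:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(image.data[:, :, z].T, cmap="gray", origin="lower")
        ax.imshow(
            heat[:, :, z].T, cmap="hot", origin="lower",
            alpha=alpha_blend * (heat[:, :, z].T > 0), vmin=0.0, vmax=1.0,
        )
        ax.set_axis_off()
        path = out / f"{prefix}_z{z:03d}.png"
        fig.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
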