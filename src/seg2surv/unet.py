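"""3D encoder-decoder segmentation network (U-Net) built on the numpy engine.

The encoder halves each spatial dimension between levels while doubling the
channel width (32, 64, 128, 256, 512 at full scale); the most-compressed
output — the bottleneck — is the feature layer harvested downstream. A
symmetric decoder with skip connections reconstructs a per-voxel tumor
probability map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .types import CLIP_WINDOWS, ROIVolume, SegmentationMask

log = logging.getLogger(__name__)


@dataclass
class UNetConfig:
    in_shape: tuple[int, int, int] = (96, 96, 48)
    base_channels: int = 32
    n_levels: int = 5
    modality: str | None = None
    loss: str = "dice+bce"  # "dice+bce" (default), "dice", or "bce"
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 1
    weight_decay: float = 0.0
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.in_shape = tuple(int(s) for s in self.in_shape)

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.n_levels))

    @property
    def input_window(self) -> tuple[float, float] | None:
        return CLIP_WINDOWS.get(self.modality) if self.modality else None


def _effective_levels(in_shape, n_levels: int) -> int:
    """Largest legal depth <= n_levels: every dim divisible by 2^(L-1)."""
    L = n_levels
    while L > 1 and any(s % 2 ** (L - 1) for s in in_shape):
        L -= 1
    return L


class UNet:
    """Segmentation network with explicit forward/backward passes.

    Input volumes are min-max normalized to [0, 1] using the modality clip
    window when the config names a modality; gradients returned by
    ``encoder_backward``/``backward`` are w.r.t. the raw (unnormalized)
    input so they compose with finite differences on raw voxel values.
    """

    def __init__(self, config: UNetConfig, dtype=np.float32):
        L = _effective_levels(config.in_shape, config.n_levels)
        if L != config.n_levels:
            if L < 3:
                raise ValueError(
                    f"in_shape {config.in_shape} supports only {L} levels (< 3); rejected"
                )
            log.warning(
                "in_shape %s not divisible for %d levels; auto-reduced to %d",
                config.in_shape, config.n_levels, L,
            )
            config = UNetConfig(**{**asdict(config), "n_levels": L})
        self.config = config
        self.dtype = dtype
        self.history: dict[str, list[float]] = {"loss": [], "val_dsc": []}
        ch = config.channel_schedule
        rng = np.random.default_rng(config.seed)

        self.enc_blocks = []
        prev = 1
        for c in ch:
            self.enc_blocks.append(
                [nn.Conv3d(prev, c, 3, rng, dtype), nn.ReLU(), nn.Conv3d(c, c, 3, rng, dtype), nn.ReLU()]
            )
            prev = c
        self.pools = [nn.MaxPool3d() for _ in range(len(ch) - 1)]

        self.dec_blocks = []
        for lvl in range(len(ch) - 2, -1, -1):
            self.dec_blocks.append(
                {
                    "up": nn.Upsample3d(),
                    "upconv": nn.Conv3d(ch[lvl + 1], ch[lvl], 3, rng, dtype),
                    "uprelu": nn.ReLU(),
                    "conv1": nn.Conv3d(2 * ch[lvl], ch[lvl], 3, rng, dtype),
                    "relu1": nn.ReLU(),
                    "conv2": nn.Conv3d(ch[lvl], ch[lvl], 3, rng, dtype),
                    "relu2": nn.ReLU(),
                }
            )
        self.final = nn.Conv3d(ch[0], 1, 1, rng, dtype)
        self._prob = None

    # -- plumbing ---------------------------------------------------------
    def layers(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        for blk in self.dec_blocks:
            out.extend(blk.values())
        out.append(self.final)
        return out

    def conv_layers(self):
        return [l for l in self.layers() if isinstance(l, nn.Conv3d)]

    @property
    def bottleneck_shape(self) -> tuple[int, int, int, int]:
        """(x, y, z, channels) of the bottleneck activation tensor."""
        f = 2 ** (self.config.n_levels - 1)
        sx, sy, sz = (s // f for s in self.config.in_shape)
        return (sx, sy, sz, self.config.channel_schedule[-1])

    @property
    def n_bottleneck_features(self) -> int:
        return int(np.prod(self.bottleneck_shape))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"conv{i}_{name}": layer.params[name]
            for i, layer in enumerate(self.conv_layers())
            for name in ("W", "b")
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.conv_layers()):
            layer.W[...] = state[f"conv{i}_W"]
            layer.b[...] = state[f"conv{i}_b"]

    # -- passes -----------------------------------------------------------
    def _as_input(self, image) -> np.ndarray:
        x = image.data if isinstance(image, (ROIVolume, SegmentationMask)) else np.asarray(image)
        if x.shape != self.config.in_shape:
            raise ValueError(f"input shape {x.shape} != configured {self.config.in_shape}")
        x = x.astype(self.dtype)
        win = self.config.input_window
        if win is not None:
            x = (x - win[0]) / (win[1] - win[0])
        return x[None]

    def encoder_forward(self, image) -> np.ndarray:
        """Run the encoder; returns bottleneck activations (C, bx, by, bz)."""
        x = self._as_input(image)
        self._skips = []
        for lvl, blk in enumerate(self.enc_blocks):
            for layer in blk:
                x = layer.forward(x)
            if lvl < len(self.pools):
                self._skips.append(x)
                x = self.pools[lvl].forward(x)
        self._bottleneck = x
        return x

    def encoder_backward(self, dbottleneck: np.ndarray) -> np.ndarray:
        """Backprop a bottleneck gradient to the raw input volume."""
        dx = dbottleneck.astype(self.dtype)
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            if lvl < len(self.pools):
                dx = self.pools[lvl].backward(dx)
            for layer in reversed(self.enc_blocks[lvl]):
                dx = layer.backward(dx)
        dx = dx[0]
        win = self.config.input_window
        if win is not None:
            dx = dx / (win[1] - win[0])
        return dx

    def forward(self, image) -> np.ndarray:
        """Full forward pass; returns the voxelwise tumor probability map."""
        x = self.encoder_forward(image)
        for blk, skip in zip(self.dec_blocks, reversed(self._skips)):
            x = blk["up"].forward(x)
            x = blk["uprelu"].forward(blk["upconv"].forward(x))
            x = np.concatenate([skip, x], axis=0)
            x = blk["relu1"].forward(blk["conv1"].forward(x))
            x = blk["relu2"].forward(blk["conv2"].forward(x))
        logits = self.final.forward(x)
        self._prob = nn.sigmoid(logits)
        return self._prob[0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backprop dLoss/dprob through the whole network (training only)."""
        p = self._prob
        dz = (dprob[None] * p * (1.0 - p)).astype(self.dtype)
        dx = self.final.backward(dz)
        dskips = []
        for blk in reversed(self.dec_blocks):
            dx = blk["conv2"].backward(blk["relu2"].backward(dx))
            dx = blk["conv1"].backward(blk["relu1"].backward(dx))
            n_skip = dx.shape[0] // 2
            dskips.append(dx[:n_skip])
            dx = blk["up"].backward(blk["upconv"].backward(blk["uprelu"].backward(dx[n_skip:])))
        # dec_blocks run deep->shallow, so the reversed walk above visits
        # shallow->deep and dskips is already indexed by encoder level
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            if lvl < len(self.pools):
                dx = self.pools[lvl].backward(dx)
                dx = dx + dskips[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                dx = layer.backward(dx)


def build_unet(config: UNetConfig, dtype=np.float32) -> UNet:
    """Instantiate an (untrained) segmentation network from a config."""
    return UNet(config, dtype=dtype)


def dice(pred: SegmentationMask | np.ndarray, truth: SegmentationMask | np.ndarray) -> float:
    """Sorensen-Dice coefficient 2|A.B| / (|A|+|B|); 1.0 when both empty."""
    a = (pred.data if isinstance(pred, SegmentationMask) else np.asarray(pred)).astype(bool)
    b = (truth.data if isinstance(truth, SegmentationMask) else np.asarray(truth)).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes disagree: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def segment(model: UNet, image) -> SegmentationMask:
    """Binary segmentation: threshold 0.5 on the tumor probability map."""
    prob = model.forward(image)
    spacing = getattr(image, "spacing", 1.0)
    if isinstance(spacing, (int, float)):
        spacing = (float(spacing),) * 3
    return SegmentationMask(prob > 0.5, spacing)


def _val_dsc(model: UNet, val_pairs) -> float:
    return float(np.mean([dice(segment(model, img), msk) for img, msk in val_pairs]))


def train_unet(model: UNet, pairs, val_pairs=None, config: UNetConfig | None = None) -> UNet:
    """Train with Adam (mini-batch 1) on soft-Dice (or BCE) loss.

    Keeps the checkpoint with the best validation DSC (training loss when no
    validation pairs are given) and stops early after
    ``early_stop_patience`` epochs without improvement. Deterministic under
    the config seed. Returns the same model object with best weights
    restored and ``model.history`` filled in.
    """
    cfg = config or model.config
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    loss_fn = {"dice": nn.soft_dice_loss, "bce": nn.bce_loss, "dice+bce": nn.dice_bce_loss}[cfg.loss]
    opt = nn.Adam(model.conv_layers(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([cfg.seed, 17])
    best_score, best_state, patience = -np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for i in order:
            img, msk = pairs[i]
            prob = model.forward(img)
            target = msk.data if isinstance(msk, SegmentationMask) else np.asarray(msk)
            loss, dprob = loss_fn(prob, target)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dprob)
            opt.step()
            epoch_loss += loss
        epoch_loss /= len(pairs)
        score = _val_dsc(model, val_pairs) if val_pairs else -epoch_loss
        model.history["loss"].append(epoch_loss)
        model.history["val_dsc"].append(score if val_pairs else float("nan"))
        if score > best_score:
            best_score = score
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            patience = 0
        else:
            patience += 1
            if patience >= cfg.early_stop_patience:
                log.info("early stop at epoch %d (best score %.4f)", epoch, best_score)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def save_model(model: UNet, path) -> None:
    """Persist weights + config in a single .npz archive."""
    meta = json.dumps(asdict(model.config))
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.state_dict())


def load_model(path) -> UNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        meta["in_shape"] = tuple(meta["in_shape"])
        model = UNet(UNetConfig(**meta))
        model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
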