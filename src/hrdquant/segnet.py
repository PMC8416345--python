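"""Improved U-shaped segmentation network for hyperreflective dots.

Architecture
------------
A 2D encoder–decoder with *three* down/upsampling steps (one fewer than
the classic four-level U-Net, matching the small scale of the target
lesions). Each encoder stage is a multi-scale convolution module (MSCM):
three parallel 3x3 convolutions with dilation rates 1, 2 and 3, fused by
concatenation and a 1x1 convolution. The two deepest encoder stages add a
channel attention module (CAM): global average pooling followed by a
fully connected bottleneck whose sigmoid output gates the channels. The
decoder mirrors the encoder with nearest-neighbour upsampling and skip
connections; a 1x1 head emits two class scores (background / HRD) per
pixel.

Training uses SGD (lr 0.01, momentum 0.9, weight decay 1e-4), batch size
2, 60 epochs, and online augmentation (flips, small rotations, additive
Gaussian noise; 2–4 of these per sample), with a summed cross-entropy +
soft-Dice loss. A 4-fold cross-validation harness and a deterministic
threshold segmenter (network-free reference path) round out the module.
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .volume_io import OCTVolume

AUGMENTATIONS = ("lr_flip", "ud_flip", "rotation", "gaussian_noise")


@dataclasses.dataclass
class NetConfig:
    """Structural hyperparameters of the improved U-shaped network."""

    levels: int = 3
    dilation_rates: tuple[int, int, int] = (1, 2, 3)
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 2
    cam_reduction: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.levels != 3:
            raise ValueError("the improved network has exactly 3 down/upsampling steps")
        if tuple(self.dilation_rates) != (1, 2, 3):
            raise ValueError("MSCM uses exactly three parallel branches at dilations 1, 2, 3")


TINY = NetConfig(base_channels=8)


@dataclasses.dataclass
class TrainConfig:
    """Optimisation protocol. Defaults are the reference settings."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0001
    batch_size: int = 2
    epochs: int = 60
    augment: bool = True
    augmentations: tuple[str, ...] = AUGMENTATIONS
    rotation_deg: float = 15.0
    noise_sigma_range: tuple[float, float] = (0.01, 0.05)
    dice_loss_weight: float = 1.0
    seed: int = 0


@dataclasses.dataclass
class FoldPlan:
    """Assignment of volume ids to cross-validation folds f1..fn."""

    folds: list[list]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_ids(self, k: int):
        return self.folds[k]

    def train_ids(self, k: int):
        return [i for j, f in enumerate(self.folds) if j != k for i in f]


class MSCM(nn.Module):
    """Three parallel dilated 3x3 conv branches fused by a 1x1 conv."""

    def __init__(self, rng, c_in, c_out, dilations=(1, 2, 3)):
        self.branches = [nn.ConvBNReLU(rng, c_in, c_out, 3, d) for d in dilations]
        self.fuse = nn.ConvBNReLU(rng, c_out * len(dilations), c_out, 1)

    def __call__(self, x):
        return self.fuse(nn.concat_channels([br(x) for br in self.branches]))


class CAM(nn.Module):
    """Channel attention: global average pool -> FC bottleneck -> sigmoid gate."""

    def __init__(self, rng, c, reduction=4):
        self.fc1 = nn.Linear(rng, c, max(1, c // reduction))
        self.fc2 = nn.Linear(rng, max(1, c // reduction), c)
        self.last_gate: np.ndarray | None = None

    def __call__(self, x):
        gate = nn.sigmoid(self.fc2(nn.relu(self.fc1(nn.global_avg_pool(x)))))
        self.last_gate = gate.data
        return nn.channel_gate(x, gate)


class DecoderStage(nn.Module):
    def __init__(self, rng, c_in, c_skip, c_out):
        self.up_conv = nn.ConvBNReLU(rng, c_in, c_skip, 3)
        self.conv1 = nn.ConvBNReLU(rng, 2 * c_skip, c_out, 3)
        self.conv2 = nn.ConvBNReLU(rng, c_out, c_out, 3)

    def __call__(self, x, skip):
        x = self.up_conv(nn.upsample2x(x))
        return self.conv2(self.conv1(nn.concat_channels([x, skip])))


class ImprovedUNet(nn.Module):
    """The 3-level MSCM/CAM U-shaped network."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.enc1 = MSCM(rng, config.in_channels, c, config.dilation_rates)
        self.enc2 = MSCM(rng, c, 2 * c, config.dilation_rates)
        self.cam2 = CAM(rng, 2 * c, config.cam_reduction)
        self.enc3 = MSCM(rng, 2 * c, 4 * c, config.dilation_rates)
        self.cam3 = CAM(rng, 4 * c, config.cam_reduction)
        self.bott1 = nn.ConvBNReLU(rng, 4 * c, 8 * c, 3)
        self.bott2 = nn.ConvBNReLU(rng, 8 * c, 8 * c, 3)
        self.dec3 = DecoderStage(rng, 8 * c, 4 * c, 4 * c)
        self.dec2 = DecoderStage(rng, 4 * c, 2 * c, 2 * c)
        self.dec1 = DecoderStage(rng, 2 * c, c, c)
        self.head = nn.Conv2d(rng, c, config.out_channels, 1)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        H, W = x.shape[2], x.shape[3]
        if H % 8 or W % 8:
            raise ValueError(f"input spatial dims must be divisible by 8, got {H}x{W}")
        s1 = self.enc1(x)
        s2 = self.cam2(self.enc2(nn.maxpool2x2(s1)))
        s3 = self.cam3(self.enc3(nn.maxpool2x2(s2)))
        b = self.bott2(self.bott1(nn.maxpool2x2(s3)))
        d = self.dec3(b, s3)
        d = self.dec2(d, s2)
        d = self.dec1(d, s1)
        return self.head(d)

    def cam_gates(self) -> list[np.ndarray]:
        """Gate activations of the two CAMs from the last forward pass."""
        return [g for g in (self.cam2.last_gate, self.cam3.last_gate) if g is not None]


class BaselineUNet(nn.Module):
    """Plain 4-level double-conv U-Net, used as the parameter-count baseline."""

    def __init__(self, base_channels=16, in_channels=1, out_channels=2, seed=0):
        rng = np.random.default_rng(seed)
        c = base_channels
        widths = [c, 2 * c, 4 * c, 8 * c]

        def double(ci, co):
            return [nn.ConvBNReLU(rng, ci, co, 3), nn.ConvBNReLU(rng, co, co, 3)]

        self.encoders = [m for i, w in enumerate(widths)
                         for m in double(in_channels if i == 0 else widths[i - 1], w)]
        self.bottleneck = double(widths[-1], 16 * c)
        self.decoders = []
        prev = 16 * c
        for w in reversed(widths):
            self.decoders.append(DecoderStage(rng, prev, w, w))
            prev = w
        self.head = nn.Conv2d(rng, c, out_channels, 1)


def build_network(config: NetConfig | None = None) -> ImprovedUNet:
    """Construct the improved U-shaped network from a :class:`NetConfig`."""
    return ImprovedUNet(config or NetConfig())


# ------------------------------------------------------------- inference


def _pad_to_multiple(img: np.ndarray, mult: int = 8) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph, pw = (-h) % mult, (-w) % mult
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    return img, (h, w)


def segment_probability(network: ImprovedUNet, volume: OCTVolume) -> np.ndarray:
    """Per-pixel HRD foreground probability for every b-scan of a volume.

    Input b-scans are edge-padded to the nearest multiple of 8 internally
    and cropped back, so the output has exactly the input's (b, z, x) shape.
    """
    network.set_training(False)
    maps = []
    for b in range(volume.n_bscans):
        img, (h, w) = _pad_to_multiple(volume.bscan(b).astype(np.float32))
        logits = network(nn.Tensor(img[None, None]))
        probs = nn.softmax_channels(logits).data[0, 1, :h, :w]
        maps.append(probs)
    return np.stack(maps).astype(np.float64)


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground iff probability >= threshold."""
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    return prob_map >= threshold


def threshold_segment(volume: OCTVolume, threshold: float = 0.45,
                      band: tuple[float, float] = (0.2, 0.72)) -> np.ndarray:
    """Deterministic reference segmenter: bright pixels inside the retina band.

    ``band`` gives the axial window as fractions of depth; outside it
    (vitreous, NFL, RPE, choroid) nothing is segmented. Network-free, so
    the classification/quantification stages are testable without training.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    nz = volume.shape[1]
    lo, hi = int(band[0] * nz), int(band[1] * nz)
    out = np.zeros(volume.shape, dtype=bool)
    out[:, lo:hi, :] = volume.voxels[:, lo:hi, :] > threshold
    return out


# -------------------------------------------------------------- training


def augment_sample(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                   config: TrainConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Apply 2–4 distinct augmentations, chosen uniformly, to one pair.

    Spatial transforms hit image and mask identically (nearest-neighbour
    interpolation for the mask keeps labels integral); Gaussian noise is
    image-only.
    """
    config = config or TrainConfig()
    k = int(rng.integers(2, 5))
    chosen = rng.choice(len(config.augmentations), size=k, replace=False)
    image, mask = np.array(image), np.array(mask)
    for idx in chosen:
        name = config.augmentations[idx]
        if name == "lr_flip":
            image, mask = image[:, ::-1], mask[:, ::-1]
        elif name == "ud_flip":
            image, mask = image[::-1, :], mask[::-1, :]
        elif name == "rotation":
            angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
            image = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
            mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
        elif name == "gaussian_noise":
            sigma = float(rng.uniform(*config.noise_sigma_range))
            image = np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)
        else:
            raise ValueError(f"unknown augmentation {name!r}")
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def _foreground_dice(pred: np.ndarray, target: np.ndarray) -> float:
    a, b = pred > 0, target > 0
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom


def train(network: ImprovedUNet, pairs: Sequence[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig | None = None, log=None) -> list[dict]:
    """Optimise the network on (image, mask) b-scan pairs.

    Returns the per-epoch trace (mean loss, training foreground Dice).
    Aborts with a RuntimeError naming the epoch if the loss diverges.
    """
    config = config or TrainConfig()
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(network.parameters(), config.learning_rate,
                 config.momentum, config.weight_decay)
    trace = []
    for epoch in range(config.epochs):
        network.set_training(True)
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            imgs, masks = [], []
            for i in batch:
                img, msk = pairs[i]
                if config.augment:
                    img, msk = augment_sample(img, msk, rng, config)
                imgs.append(img)
                masks.append(msk)
            x = nn.Tensor(np.stack(imgs)[:, None])
            t = (np.stack(masks) > 0).astype(np.int64)
            logits = network(x)
            loss = nn.add(nn.cross_entropy_with_logits(logits, t),
                          nn.scale(nn.soft_dice_loss(logits, t), config.dice_loss_weight))
            if not np.isfinite(loss.data):
                raise RuntimeError(f"loss diverged (NaN/Inf) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        # training Dice on un-augmented pairs
        network.set_training(False)
        dices = []
        for img, msk in pairs:
            logits = network(nn.Tensor(np.asarray(img, dtype=np.float32)[None, None]))
            pred = nn.softmax_channels(logits).data[0, 1] >= 0.5
            dices.append(_foreground_dice(pred, msk))
        rec = {"epoch": epoch, "loss": float(np.mean(losses)), "dice": float(np.mean(dices))}
        trace.append(rec)
        if log:
            log(f"epoch={epoch},loss={rec['loss']:.4f},dice={rec['dice']:.4f}")
    return trace


def make_folds(ids: Sequence, n_folds: int = 4, seed: int = 0) -> FoldPlan:
    """Shuffle ids and split them into n folds with sizes differing by <= 1."""
    ids = list(ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [order[k::n_folds] for k in range(n_folds)]
    return FoldPlan(folds=folds)


def cross_validate(pairs_by_id: dict, net_config: NetConfig, train_config: TrainConfig,
                   plan: FoldPlan, log=None) -> dict:
    """k-fold cross-validation: train one model per fold, evaluate on its
    held-out fold only, report per-fold and mean +/- SD foreground Dice."""
    fold_dice = []
    for k in range(plan.n_folds):
        net = build_network(dataclasses.replace(net_config, seed=net_config.seed + k))
        train_pairs = [p for i in plan.train_ids(k) for p in pairs_by_id[i]]
        train(net, train_pairs, train_config, log=log)
        net.set_training(False)
        dices = []
        for i in plan.test_ids(k):
            for img, msk in pairs_by_id[i]:
                logits = net(nn.Tensor(np.asarray(img, dtype=np.float32)[None, None]))
                pred = nn.softmax_channels(logits).data[0, 1] >= 0.5
                dices.append(_foreground_dice(pred, msk))
        fold_dice.append(float(np.mean(dices)))
        if log:
            log(f"fold={k},test_dice={fold_dice[-1]:.4f}")
    return {
        "per_fold_dice": fold_dice,
        "mean_dice": float(np.mean(fold_dice)),
        "sd_dice": float(np.std(fold_dice, ddof=1)) if len(fold_dice) > 1 else 0.0,
        "tested_ids": [list(plan.test_ids(k)) for k in range(plan.n_folds)],
    }


# ------------------------------------------------------------ checkpoints


def save_checkpoint(network: ImprovedUNet, path: str | Path):
    """Single-file archive with the NetConfig embedded."""
    payload = {"config": dataclasses.asdict(network.config),
               "state": network.state_arrays()}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path) -> ImprovedUNet:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    net = build_network(NetConfig(**payload["config"]))
    net.load_state_arrays(payload["state"])
    return net
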