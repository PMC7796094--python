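"""Res BCDU-Net: a U-shaped segmentation network with a ResNet-34 encoder,
densely connected bottleneck, and bidirectional ConvLSTM skip fusion.

The encoder is the ResNet-34 layout (7x7/2 stem + 3x3/2 max-pool, then
residual stages of 3/4/6/3 basic blocks at 64/128/256/512 channels, five
spatial halvings in total). The deepest feature feeds a bottleneck of three
convolutional blocks whose inputs concatenate all previous block outputs
(two dense connections) instead of summing them. The decoder repeats
{upsample x2 -> projection conv -> batch norm -> BConvLSTM fusion with the
same-resolution encoder feature -> conv}, with the stem-level skip joined by
plain concatenation, and ends in a 1-channel sigmoid head. The BConvLSTM and
dense-bottleneck components can each be switched off (ablation arms), in
which case fusion degrades to plain concatenation and the bottleneck to
stacked convolutions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit

from . import nn
from .evaluation import dice as _dice

SKIP_CHANNELS = (64, 128, 256, 512)
RESNET34_BLOCKS = (3, 4, 6, 3)


@dataclass(frozen=True)
class NetworkConfig:
    input_size: tuple = (256, 256)
    in_channels: int = 3
    encoder: str = "resnet34"
    encoder_pretrained: bool = False
    base_filters: int = 64
    channel_schedule: tuple = SKIP_CHANNELS
    bottleneck_blocks: int = 3
    bottleneck_dense_connections: int = 2
    use_bconvlstm: bool = True
    use_dense_bottleneck: bool = True
    bconvlstm_kernel: int = 3
    out_activation: str = "sigmoid"

    def validate(self) -> None:
        h, w = self.input_size
        if h % 32 or w % 32 or h <= 0 or w <= 0:
            raise ValueError(
                f"input_size must be positive and divisible by 32 (five "
                f"spatial halvings), got {self.input_size}"
            )
        if self.encoder != "resnet34":
            raise ValueError(f"unsupported encoder {self.encoder!r}")
        sched = tuple(self.channel_schedule)
        if sched[0] != self.base_filters or any(
            b != 2 * a for a, b in zip(sched, sched[1:])
        ):
            raise ValueError(
                "channel_schedule must start at base_filters and double at "
                f"each stage, got {sched}"
            )
        if self.bconvlstm_kernel % 2 != 1 or self.bconvlstm_kernel < 1:
            raise ValueError("bconvlstm_kernel must be an odd positive integer")
        if self.bottleneck_blocks != self.bottleneck_dense_connections + 1:
            raise ValueError(
                "bottleneck needs exactly one more block than dense connections"
            )
        if self.out_activation != "sigmoid":
            raise ValueError("only the sigmoid output head is supported")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    loss: str = "bce"  # bce | dice | bce_dice
    learning_rate: float = 1e-4
    seed: int = 0
    pred_threshold: float = 0.5
    #: optional early stop: end training after the first epoch whose mean
    #: validation Dice reaches this value (None = train all epochs)
    early_stop_dice: float | None = None

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.loss not in ("bce", "dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not (0.0 < self.pred_threshold < 1.0):
            raise ValueError("pred_threshold must lie in (0, 1)")


# --------------------------------------------------------------------------
# building blocks

class _BasicBlock(nn.Module):
    """ResNet basic block: two 3x3 convs with an identity (or projected)
    shortcut added to the block output."""

    def __init__(self, cin, cout, stride, rng, dtype):
        self.conv1 = nn.Conv2D(cin, cout, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2D(cout, dtype=dtype)
        self.conv2 = nn.Conv2D(cout, cout, 3, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2D(cout, dtype=dtype)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2D(cin, cout, 1, stride=stride, padding=0,
                                  rng=rng, dtype=dtype)
            self.proj_bn = nn.BatchNorm2D(cout, dtype=dtype)
        else:
            self.proj = None

    def __call__(self, x):
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return nn.relu(nn.add(y, shortcut))


class _ResNet34Encoder(nn.Module):
    def __init__(self, in_channels, schedule, rng, dtype):
        c0 = schedule[0]
        self.stem_conv = nn.Conv2D(in_channels, c0, 7, stride=2, rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2D(c0, dtype=dtype)
        self.stages = []
        cin = c0
        for stage, (cout, n_blocks) in enumerate(zip(schedule, RESNET34_BLOCKS)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                blocks.append(_BasicBlock(cin, cout, stride, rng, dtype))
                cin = cout
            self.stages.append(blocks)

    def __call__(self, x):
        """Returns (stem_feature, [four stage features])."""
        f_stem = nn.relu(self.stem_bn(self.stem_conv(x)))  # H/2
        y = nn.maxpool2d(f_stem, kernel=3, stride=2, padding=1)  # H/4
        feats = []
        for blocks in self.stages:
            for block in blocks:
                y = block(y)
            feats.append(y)
        return f_stem, feats


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, rng, dtype, kernel=3):
        self.conv = nn.Conv2D(cin, cout, kernel, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2D(cout, dtype=dtype)

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _Bottleneck(nn.Module):
    """Three conv blocks; dense mode concatenates all previous outputs."""

    def __init__(self, channels, n_blocks, dense, rng, dtype):
        self.dense = dense
        self.blocks = []
        for i in range(n_blocks):
            cin = channels * (i + 1) if dense else channels
            self.blocks.append(_ConvBNReLU(cin, channels, rng, dtype))

    def __call__(self, x):
        outputs = [x]
        for block in self.blocks:
            xin = nn.concat(outputs, axis=1) if self.dense else outputs[-1]
            outputs.append(block(xin))
        return outputs[-1]


class _DecoderLevel(nn.Module):
    """{upsample -> projection conv -> BN -> fusion with skip -> conv}."""

    def __init__(self, cin, channels, use_bconvlstm, lstm_kernel, upsample,
                 rng, dtype):
        self.upsample = upsample
        self.proj = nn.Conv2D(cin, channels, 3, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2D(channels, dtype=dtype)
        self.fusion = (
            nn.BConvLSTMFusion(channels, lstm_kernel, rng=rng, dtype=dtype)
            if use_bconvlstm
            else None
        )
        self.conv = _ConvBNReLU(2 * channels, channels, rng, dtype)

    def __call__(self, x, skip):
        if self.upsample:
            x = nn.upsample2x(x)
        x = nn.relu(self.bn(self.proj(x)))
        if self.fusion is not None:
            fused = self.fusion(skip, x)
        else:
            fused = nn.concat([skip, x], axis=1)
        return self.conv(fused)


class _ResBCDUNet(nn.Module):
    def __init__(self, config: NetworkConfig, rng, dtype):
        sched = tuple(config.channel_schedule)
        self.encoder = _ResNet34Encoder(config.in_channels, sched, rng, dtype)
        self.bottleneck = _Bottleneck(
            sched[3], config.bottleneck_blocks, config.use_dense_bottleneck,
            rng, dtype,
        )
        k = config.bconvlstm_kernel
        use = config.use_bconvlstm
        # deepest level fuses at the bottleneck resolution (no upsample)
        self.level4 = _DecoderLevel(sched[3], sched[3], use, k, False, rng, dtype)
        self.level3 = _DecoderLevel(sched[3], sched[2], use, k, True, rng, dtype)
        self.level2 = _DecoderLevel(sched[2], sched[1], use, k, True, rng, dtype)
        self.level1 = _DecoderLevel(sched[1], sched[0], use, k, True, rng, dtype)
        # stem-level skip: plain concatenation (no BConvLSTM)
        self.stem_proj = _ConvBNReLU(sched[0], sched[0], rng, dtype)
        self.stem_conv = _ConvBNReLU(2 * sched[0], sched[0], rng, dtype)
        self.head_conv = _ConvBNReLU(sched[0], sched[0] // 2, rng, dtype)
        self.head_out = nn.Conv2D(sched[0] // 2, 1, 1, padding=0, rng=rng, dtype=dtype)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        f_stem, (f1, f2, f3, f4) = self.encoder(x)
        y = self.bottleneck(f4)
        y = self.level4(y, f4)
        y = self.level3(y, f3)
        y = self.level2(y, f2)
        y = self.level1(y, f1)
        y = nn.upsample2x(y)
        y = self.stem_proj(y)
        y = self.stem_conv(nn.concat([f_stem, y], axis=1))
        y = nn.upsample2x(y)
        y = self.head_conv(y)
        return self.head_out(y)  # logits; sigmoid applied at the interface


class SegmentationModel:
    """Trained-network handle with a forward-prediction contract."""

    def __init__(self, net: _ResBCDUNet, config: NetworkConfig, seed: int):
        self.net = net
        self.config = config
        self.seed = seed

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    @property
    def skip_channels(self) -> tuple:
        return tuple(self.config.channel_schedule)

    def forward_logits(self, batch_nchw: np.ndarray, training: bool) -> nn.Tensor:
        self.net.train(training)
        return self.net(nn.Tensor(batch_nchw))

    def predict_proba(self, batch_nchw: np.ndarray) -> np.ndarray:
        logits = self.forward_logits(batch_nchw, training=False)
        return expit(logits.data)[:, 0]


def build_model(config: NetworkConfig, seed: int = 0,
                pretrained_weights: str | None = None,
                dtype=np.float32) -> SegmentationModel:
    """Construct the network with seeded He initialization.

    ``encoder_pretrained`` requires an explicit weight file (``.npz`` holding
    the encoder parameter arrays in traversal order); nothing is downloaded.
    """
    config.validate()
    if config.encoder_pretrained and pretrained_weights is None:
        raise ValueError(
            "encoder_pretrained=True requires a pretrained_weights file; "
            "no weights are downloaded"
        )
    rng = np.random.default_rng(seed)
    net = _ResBCDUNet(config, rng, dtype)
    if config.encoder_pretrained:
        arrays = np.load(pretrained_weights)
        enc_params = net.encoder.parameters()
        keys = sorted(arrays.files, key=lambda k: int(k.split("_")[-1]))
        if len(keys) != len(enc_params):
            raise ValueError(
                f"weight file holds {len(keys)} arrays, encoder has "
                f"{len(enc_params)} parameters"
            )
        for key, p in zip(keys, enc_params):
            if arrays[key].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.data = arrays[key].astype(p.data.dtype)
    return SegmentationModel(net, config, seed)


# --------------------------------------------------------------------------
# training / inference

def _stack_pairs(pairs, config):
    h, w = config.input_size
    xs, ys = [], []
    for img, mask in pairs:
        img = np.asarray(img, dtype=np.float32)
        mask = np.asarray(mask)
        if img.shape != (h, w, config.in_channels) or mask.shape != (h, w):
            raise ValueError(
                f"sample shape {img.shape}/{mask.shape} does not match the "
                f"configured size {(h, w, config.in_channels)}"
            )
        xs.append(img.transpose(2, 0, 1))
        ys.append(mask.astype(np.float32))
    return np.stack(xs), np.stack(ys)


def _loss(logits: nn.Tensor, target: np.ndarray, kind: str) -> nn.Tensor:
    if kind == "bce":
        return nn.bce_with_logits(logits, target)
    if kind == "dice":
        return nn.soft_dice_loss(nn.sigmoid(logits), target)
    bce = nn.bce_with_logits(logits, target)
    dsc = nn.soft_dice_loss(nn.sigmoid(logits), target)
    return nn.add(bce, dsc)


def train(model: SegmentationModel, train_set, val_set, tc: TrainConfig):
    """Seeded gradient training; returns (model, per-epoch history).

    ``train_set``/``val_set`` yield (H x W x 3 image, H x W mask) pairs of
    the configured size. History records train/val loss and pixel accuracy
    plus the mean validation Dice per epoch.
    """
    tc.validate()
    train_pairs = list(train_set)
    if not train_pairs:
        raise ValueError("training set is empty")
    x_train, y_train = _stack_pairs(train_pairs, model.config)
    val_pairs = list(val_set) if val_set is not None else []
    if val_pairs:
        x_val, y_val = _stack_pairs(val_pairs, model.config)

    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.net.parameters(), lr=tc.learning_rate)
    target = y_train[:, None]  # NCHW with one channel
    n = len(train_pairs)
    history = []
    for epoch in range(tc.epochs):
        perm = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, tc.batch_size):
            idx = perm[start : start + tc.batch_size]
            logits = model.forward_logits(x_train[idx], training=True)
            loss = _loss(logits, target[idx], tc.loss)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}, batch start "
                    f"{start}; aborting training"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append((lval, len(idx)))
            pred = logits.data[:, 0] >= 0.0  # sigmoid(z) >= 0.5  <=>  z >= 0
            correct += int(np.sum(pred == (y_train[idx] >= 0.5)))
            seen += pred.size
        entry = {
            "epoch": epoch,
            "train_loss": sum(l * k for l, k in losses) / n,
            "train_acc": correct / seen,
        }
        if val_pairs:
            entry.update(_validate(model, x_val, y_val, tc))
        history.append(entry)
        if (
            tc.early_stop_dice is not None
            and val_pairs
            and entry["val_dice"] >= tc.early_stop_dice
        ):
            break
    return model, history


def _validate(model, x_val, y_val, tc):
    losses, correct, seen, dices = [], 0, 0, []
    for start in range(0, len(x_val), tc.batch_size):
        xb, yb = x_val[start : start + tc.batch_size], y_val[start : start + tc.batch_size]
        logits = model.forward_logits(xb, training=False)
        losses.append((float(_loss(logits, yb[:, None], tc.loss).data), len(xb)))
        probs = expit(logits.data[:, 0])
        pred = probs >= tc.pred_threshold
        correct += int(np.sum(pred == (yb >= 0.5)))
        seen += pred.size
        for p, t in zip(pred, yb):
            dices.append(_dice(p.astype(np.uint8), (t >= 0.5).astype(np.uint8)))
    return {
        "val_loss": sum(l * k for l, k in losses) / len(x_val),
        "val_acc": correct / seen,
        "val_dice": float(np.mean(dices)),
    }


def predict(model: SegmentationModel, image: np.ndarray, threshold: float = 0.5):
    """Probability map in (0,1) and thresholded {0,1} mask for one image."""
    h, w = model.config.input_size
    image = np.asarray(image, dtype=np.float32)
    if image.shape != (h, w, model.config.in_channels):
        raise ValueError(
            f"image shape {image.shape} does not match configured size "
            f"{(h, w, model.config.in_channels)}"
        )
    probs = model.predict_proba(image.transpose(2, 0, 1)[None])[0]
    return probs, (probs >= threshold).astype(np.uint8)


# --------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: SegmentationModel, path: str) -> None:
    """Write parameters (+ batch-norm stats) as .npz with a JSON sidecar."""
    arrays = {
        f"param_{i}": p.data for i, p in enumerate(model.net.parameters())
    }
    for i, bn in enumerate(_iter_batchnorms(model.net)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, **arrays)
    sidecar = {"config": asdict(model.config), "seed": model.seed}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)


def load_checkpoint(path: str) -> SegmentationModel:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    cfg = dict(sidecar["config"])
    for key in ("input_size", "channel_schedule"):
        cfg[key] = tuple(cfg[key])
    config = NetworkConfig(**cfg)
    model = build_model(config, seed=int(sidecar["seed"]))
    arrays = np.load(path if str(path).endswith(".npz") else str(path))
    for i, p in enumerate(model.net.parameters()):
        p.data = arrays[f"param_{i}"].astype(p.data.dtype)
    for i, bn in enumerate(_iter_batchnorms(model.net)):
        bn.running_mean = arrays[f"bn_mean_{i}"]
        bn.running_var = arrays[f"bn_var_{i}"]
    return model


def _iter_batchnorms(module):
    if isinstance(module, nn.BatchNorm2D):
        yield module
    for sub in module._submodules():
        yield from _iter_batchnorms(sub)
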