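"""Fully-convolutional segmentation networks with skip fusion.

Two backbones share one topology: class scores predicted from the coarsest
feature map are upsampled x2 and fused (added) with scores from the next
finer stride, twice, before a final upsampling chain back to the input
resolution -- the FCN-8s pattern.

* ``mini`` -- three downsampling stages (score fusion at strides 8, 4, 2)
  with a small channel budget; the backbone used for desk-scale training
  and all tests.
* ``vgg16-fcn8s`` -- the full VGG16-derived topology (five stages, fused at
  strides 32, 16, 8, with the fully-connected layers turned into 7x7 / 1x1
  convolutions).  Provided for field-scale use; pretrained weights are
  optional and never required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import DTYPE, Conv2D, MaxPool2, ReLU, Upsample2

_MINI_CHANNELS = (8, 16, 32)
_VGG_BLOCKS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))


@dataclass(frozen=True)
class SegmentationOutput:
    """Per-pixel class probabilities over (background, PSEP)."""

    probabilities: np.ndarray  # (H, W, 2), rows sum to 1

    def __post_init__(self):
        p = np.asarray(self.probabilities)
        if p.ndim != 3 or p.shape[2] != 2:
            raise ValueError("probabilities must have shape (H, W, 2)")
        object.__setattr__(self, "probabilities", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probabilities.shape[:2]

    @property
    def psep(self) -> np.ndarray:
        """(H, W) probability of the PSEP class."""
        return self.probabilities[..., 1]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``skip_strides`` are the strides at which class scores are fused,
    coarse to fine; ``None`` resolves to the backbone's native pyramid
    ((8, 4, 2) for ``mini``, (32, 16, 8) for ``vgg16-fcn8s``).
    """

    backbone: str = "mini"
    skip_strides: tuple[int, ...] | None = None
    num_classes: int = 2
    min_input: int = 32
    channels: tuple[int, ...] = _MINI_CHANNELS  # mini backbone only
    fc_channels: int = 4096  # vgg16-fcn8s fully-connected-as-conv width
    psep_prior_logit: float = -4.0  # initial PSEP-vs-background logit offset

    def __post_init__(self):
        if self.backbone not in ("mini", "vgg16-fcn8s"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.skip_strides is None:
            native = (8, 4, 2) if self.backbone == "mini" else (32, 16, 8)
            object.__setattr__(self, "skip_strides", native)


class FCNModel:
    """Single-image fully-convolutional network (NumPy forward/backward)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.blocks: list[list] = []
        self.head: list = []

        if spec.backbone == "mini":
            plan = [(c, 2) for c in spec.channels]
            slope = 0.1  # leaky: small nets trained from scratch must not die
        else:
            plan = list(_VGG_BLOCKS)
            slope = 0.0  # classic ReLU, matching the VGG16 layer stack
        c_in = 3
        for c_out, n_convs in plan:
            block = []
            for _ in range(n_convs):
                block += [Conv2D(c_in, c_out, 3, rng), ReLU(slope)]
                c_in = c_out
            block.append(MaxPool2())
            self.blocks.append(block)

        if spec.backbone == "vgg16-fcn8s":
            fc = spec.fc_channels
            self.head = [Conv2D(c_in, fc, 7, rng), ReLU(), Conv2D(fc, fc, 1, rng), ReLU()]
            c_in = fc

        # score heads: coarse stream, then the two skip taps (finer strides)
        n_skips = len(spec.skip_strides) - 1
        self._skip_taps = [len(self.blocks) - 2 - i for i in range(n_skips)]
        tap_channels = [plan[i][0] for i in self._skip_taps]
        k = spec.num_classes
        self.scores = [Conv2D(c_in, k, 1, rng)] + [Conv2D(c, k, 1, rng) for c in tap_channels]
        # PSEP pixels are rare (~1-2%), so the fused class scores start at a
        # background-favouring prior; otherwise early updates can lock the
        # net into predicting pure background.
        if spec.num_classes == 2:
            for conv in self.scores:
                conv.params["b"][1] = DTYPE(spec.psep_prior_logit / len(self.scores))
        self._fuse_ups = [Upsample2() for _ in range(n_skips)]
        finest_tap = self._skip_taps[-1] if self._skip_taps else len(self.blocks) - 1
        self._final_ups = [Upsample2() for _ in range(finest_tap + 1)]

    # -- parameter access ---------------------------------------------------

    def _layers(self):
        for b, block in enumerate(self.blocks):
            for i, layer in enumerate(block):
                yield f"block{b}.{i}", layer
        for i, layer in enumerate(self.head):
            yield f"head.{i}", layer
        for i, layer in enumerate(self.scores):
            yield f"score{i}", layer

    def named_params(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": arr
            for name, layer in self._layers()
            for key, arr in layer.params.items()
        }

    def named_grads(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": arr
            for name, layer in self._layers()
            for key, arr in layer.grads.items()
        }

    # -- forward / backward -------------------------------------------------

    def _check_size(self, h: int, w: int):
        m = self.spec.min_input
        if h < m or w < m:
            raise ValueError(f"input {h}x{w} smaller than minimum {m}x{m}")

    def forward_logits(self, image: np.ndarray) -> np.ndarray:
        """Map an (H, W, 3) image in [0, 1] to (num_classes, H, W) logits."""
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        h, w = image.shape[:2]
        self._check_size(h, w)
        x = np.ascontiguousarray(image.transpose(2, 0, 1), dtype=DTYPE) - DTYPE(0.5)

        sizes = [(h, w)]
        feats = []
        for block in self.blocks:
            for layer in block:
                x = layer.forward(x)
            feats.append(x)
            sizes.append(x.shape[1:])
        self._feats = feats
        hx = feats[-1]
        for layer in self.head:
            hx = layer.forward(hx)
        s = self.scores[0].forward(hx)
        for i, tap in enumerate(self._skip_taps):
            s = self._fuse_ups[i].forward(s, feats[tap].shape[1:])
            s = s + self.scores[i + 1].forward(feats[tap])
        finest_tap = self._skip_taps[-1] if self._skip_taps else len(self.blocks) - 1
        for up, target in zip(self._final_ups, reversed(sizes[: finest_tap + 1])):
            s = up.forward(s, target)
        return s

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        ds = dlogits.astype(DTYPE)
        for up in reversed(self._final_ups):
            ds = up.backward(ds)
        dfeat = [None] * len(self.blocks)
        for i in reversed(range(len(self._skip_taps))):
            tap = self._skip_taps[i]
            d = self.scores[i + 1].backward(ds)
            dfeat[tap] = d if dfeat[tap] is None else dfeat[tap] + d
            ds = self._fuse_ups[i].backward(ds)
        d = self.scores[0].backward(ds)
        for layer in reversed(self.head):
            d = layer.backward(d)
        last = len(self.blocks) - 1
        dfeat[last] = d if dfeat[last] is None else dfeat[last] + d
        dx = None
        for b in reversed(range(len(self.blocks))):
            if dfeat[b] is not None:
                dx = dfeat[b] if dx is None else dx + dfeat[b]
            for layer in reversed(self.blocks[b]):
                dx = layer.backward(dx)

    def copy(self) -> "FCNModel":
        """Fresh model with identical architecture and weights (used to
        warm-start the penalty retraining pass from the baseline)."""
        clone = FCNModel(self.spec, seed=0)
        src = self.named_params()
        for name, arr in clone.named_params().items():
            arr[...] = src[name]
        return clone

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Forward pass to per-pixel class probabilities (softmax)."""
        logits = self.forward_logits(image).astype(np.float64)
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=0, keepdims=True)
        return SegmentationOutput(probs.transpose(1, 2, 0))


def build_model(spec: ModelSpec, seed: int = 0) -> FCNModel:
    """Instantiate a randomly initialized model for the given architecture."""
    return FCNModel(spec, seed=seed)


def save_model(model: FCNModel, path) -> None:
    """Write weights (``.npz``) plus a JSON sidecar with the architecture."""
    path = Path(path)
    np.savez(path, **model.named_params())
    meta = {"spec": asdict(model.spec)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> FCNModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    for key in ("skip_strides", "channels"):
        if spec_d.get(key) is not None:
            spec_d[key] = tuple(spec_d[key])
    model = FCNModel(ModelSpec(**spec_d))
    stored = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    params = model.named_params()
    for name, arr in params.items():
        arr[...] = stored[name]
    return model
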