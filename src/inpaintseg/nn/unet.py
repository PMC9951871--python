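"""2D U-Net partitioned into encoder / decoder / post-processing scopes.

The same topology serves both tasks: an *inpainting* head reproduces the
input channel count, a *segmentation* head emits 4 channels (one per tissue
class).  Only the final ("post-processing") 1x1 convolution differs between
the two heads, so pretrained encoder/decoder weights transfer directly.

Every parameter belongs to exactly one scope -- ``encoder``, ``decoder`` or
``post_processing`` -- determined by the first component of its name
(e.g. ``encoder/level0/conv1/W``).  Transfer-learning strategies move and/or
freeze whole scopes; the post-processing layer is never transferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from inpaintseg.nn.layers import Conv2d, ConvTranspose2x2, GroupNorm, MaxPool2x2, ReLU

__all__ = [
    "ModelConfig",
    "WeightBundle",
    "UNet",
    "build_model",
    "transfer_weights",
    "set_trainable",
    "save_checkpoint",
    "load_checkpoint",
    "SCOPES",
]

SCOPES = ("encoder", "decoder", "post_processing")

Head = Literal["inpainting", "segmentation"]
N_SEG_CLASSES = 4


@dataclass(frozen=True)
class ModelConfig:
    """U-Net hyperparameters.

    ``base_filters`` doubles at every deeper level; ``groupnorm_groups`` must
    divide every layer's channel count (i.e. divide ``base_filters``).
    """

    in_channels: int = 1
    depth: int = 3
    base_filters: int = 8
    groupnorm_groups: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_filters % self.groupnorm_groups != 0:
            raise ValueError(
                f"groupnorm_groups {self.groupnorm_groups} must divide "
                f"base_filters {self.base_filters} (and hence every level width)"
            )

    @property
    def out_channels_inpaint(self) -> int:
        return self.in_channels

    @property
    def out_channels_seg(self) -> int:
        return N_SEG_CLASSES


@dataclass
class WeightBundle:
    """Named tensors partitioned into scopes, with provenance.

    ``tensors`` maps full parameter names to arrays; ``scopes`` maps each
    name to its scope.  The partition is total and disjoint by construction
    (scope = first path component of the name).
    """

    tensors: dict[str, np.ndarray]
    scopes: dict[str, str]
    provenance: Literal["random", "pretrained"] = "random"

    def scope_names(self, scope: str) -> list[str]:
        return [n for n, s in self.scopes.items() if s == scope]


class UNet:
    """Plain-numpy U-Net; see module docstring for the scope partition.

    Per level: two (conv 3x3 -> GroupNorm -> ReLU) blocks; 2x2 max-pool
    between encoder levels; transposed-conv upsampling and skip-connection
    concatenation in the decoder.  Weight standardization is applied to all
    3x3 convolutions; the 1x1 post-processing head is a plain convolution.
    """

    def __init__(self, config: ModelConfig, head: Head):
        if head not in ("inpainting", "segmentation"):
            raise ValueError(f"unknown head {head!r}")
        self.config = config
        self.head = head
        self.out_channels = (
            config.out_channels_inpaint if head == "inpainting" else config.out_channels_seg
        )
        self.frozen_scopes: set[str] = set()
        self.dtype = np.float32
        self.layers: dict[str, object] = {}
        rng = np.random.default_rng(config.seed)
        ch = [config.base_filters * 2**i for i in range(config.depth)]
        g = config.groupnorm_groups

        def block(prefix, cin, cout):
            self.layers[f"{prefix}/conv1"] = Conv2d(cin, cout, 3, rng)
            self.layers[f"{prefix}/gn1"] = GroupNorm(cout, g)
            self.layers[f"{prefix}/relu1"] = ReLU()
            self.layers[f"{prefix}/conv2"] = Conv2d(cout, cout, 3, rng)
            self.layers[f"{prefix}/gn2"] = GroupNorm(cout, g)
            self.layers[f"{prefix}/relu2"] = ReLU()

        for i in range(config.depth):
            cin = config.in_channels if i == 0 else ch[i - 1]
            block(f"encoder/level{i}", cin, ch[i])
            if i < config.depth - 1:
                self.layers[f"encoder/level{i}/pool"] = MaxPool2x2()
        for i in range(config.depth - 2, -1, -1):
            self.layers[f"decoder/level{i}/up"] = ConvTranspose2x2(ch[i + 1], ch[i], rng)
            block(f"decoder/level{i}", 2 * ch[i], ch[i])
        self.layers["post_processing/conv"] = Conv2d(
            ch[0], self.out_channels, 1, rng, weight_standardize=False
        )

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self) -> Iterator[tuple[str, object, str]]:
        """Yield (full_param_name, layer, layer_param_key)."""
        for lname, layer in self.layers.items():
            for pname in getattr(layer, "params", {}):
                yield f"{lname}/{pname}", layer, pname

    @staticmethod
    def scope_of(param_name: str) -> str:
        return param_name.split("/", 1)[0]

    def get_weights(self) -> WeightBundle:
        tensors = {n: layer.params[p].copy() for n, layer, p in self.parameters()}
        return WeightBundle(tensors, {n: self.scope_of(n) for n in tensors}, "random")

    def set_weights(self, tensors: dict[str, np.ndarray]) -> None:
        for n, layer, p in self.parameters():
            if n in tensors:
                if layer.params[p].shape != tensors[n].shape:
                    raise ValueError(
                        f"shape mismatch for {n}: {layer.params[p].shape} vs {tensors[n].shape}"
                    )
                layer.params[p] = tensors[n].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            if getattr(layer, "params", None):
                layer.zero_grad()

    def is_trainable(self, param_name: str) -> bool:
        return self.scope_of(param_name) not in self.frozen_scopes

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        d = self.config.depth
        size = min(x.shape[2], x.shape[3])
        if size % 2 ** (d - 1):
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2^{d-1} for depth {d}"
            )
        skips = {}
        for i in range(d):
            for part in ("conv1", "gn1", "relu1", "conv2", "gn2", "relu2"):
                x = self.layers[f"encoder/level{i}/{part}"].forward(x)
            if i < d - 1:
                skips[i] = x
                x = self.layers[f"encoder/level{i}/pool"].forward(x)
        for i in range(d - 2, -1, -1):
            x = self.layers[f"decoder/level{i}/up"].forward(x)
            x = np.concatenate([skips[i], x], axis=1)
            for part in ("conv1", "gn1", "relu1", "conv2", "gn2", "relu2"):
                x = self.layers[f"decoder/level{i}/{part}"].forward(x)
        self._skip_channels = {i: skips[i].shape[1] for i in skips}
        return self.layers["post_processing/conv"].forward(x)

    def backprop(self, gy: np.ndarray) -> None:
        """Backpropagate the loss gradient through the whole network."""
        d = self.config.depth
        g = self.layers["post_processing/conv"].backward(gy)
        # decoder ran levels d-2 .. 0 in forward; reverse: 0 .. d-2
        skip_grads = {}
        for i in range(d - 1):
            for part in ("relu2", "gn2", "conv2", "relu1", "gn1", "conv1"):
                g = self.layers[f"decoder/level{i}/{part}"].backward(g)
            cs = self._skip_channels[i]
            skip_grads[i] = g[:, :cs]
            g = self.layers[f"decoder/level{i}/up"].backward(g[:, cs:])
        # encoder ran levels 0 .. d-1; reverse: d-1 .. 0
        for i in range(d - 1, -1, -1):
            if i < d - 1:
                g = self.layers[f"encoder/level{i}/pool"].backward(g)
                g = g + skip_grads[i]
            for part in ("relu2", "gn2", "conv2", "relu1", "gn1", "conv1"):
                g = self.layers[f"encoder/level{i}/{part}"].backward(g)

    __call__ = forward


def build_model(config: ModelConfig, head: Head) -> UNet:
    """Build a U-Net with the given head; He-initialized under ``config.seed``.

    Both heads share an identical topology except for the post-processing
    layer's output channel count (``in_channels`` for inpainting, 4 for
    segmentation).
    """
    return UNet(config, head)


def transfer_weights(
    source: WeightBundle,
    target: UNet,
    scope: Literal["encoder_only", "encoder_and_decoder"],
) -> UNet:
    """Copy pretrained weights into ``target`` for the requested scopes.

    ``encoder_only`` transfers the encoder; ``encoder_and_decoder`` transfers
    both.  The post-processing layer is never transferred (its shape differs
    between heads); non-transferred scopes keep their fresh initialization.
    Raises on the first mismatched/missing tensor, naming it.
    """
    if scope == "encoder_only":
        wanted = {"encoder"}
    elif scope == "encoder_and_decoder":
        wanted = {"encoder", "decoder"}
    else:
        raise ValueError(f"unknown transfer scope {scope!r}")
    for name, layer, p in target.parameters():
        if target.scope_of(name) not in wanted:
            continue
        if name not in source.tensors:
            raise ValueError(f"source bundle is missing tensor {name!r}")
        src = source.tensors[name]
        if src.shape != layer.params[p].shape:
            raise ValueError(
                f"topology mismatch at {name!r}: source {src.shape} vs target {layer.params[p].shape}"
            )
        layer.params[p] = src.astype(np.float32).copy()
    return target


def set_trainable(model: UNet, scopes, frozen: bool) -> UNet:
    """Freeze or unfreeze whole scopes; a training step never changes a
    frozen tensor (the optimizer skips them)."""
    if isinstance(scopes, str):
        scopes = [scopes]
    for s in scopes:
        if s not in SCOPES:
            raise ValueError(f"unknown scope {s!r}; expected one of {SCOPES}")
    if frozen:
        model.frozen_scopes |= set(scopes)
    else:
        model.frozen_scopes -= set(scopes)
    return model


def save_checkpoint(bundle: WeightBundle, path) -> None:
    """Write a named-tensor archive (.npz) plus a JSON scope manifest."""
    path = Path(path)
    np.savez(path, **bundle.tensors)
    manifest = {
        "provenance": bundle.provenance,
        "tensors": {
            n: {"scope": bundle.scopes[n], "shape": list(bundle.tensors[n].shape)}
            for n in bundle.tensors
        },
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(path) -> WeightBundle:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as npz:
        tensors = {n: npz[n] for n in npz.files}
    for n, meta in manifest["tensors"].items():
        if n not in tensors or list(tensors[n].shape) != meta["shape"]:
            raise ValueError(f"checkpoint tensor {n!r} missing or wrong shape")
    scopes = {n: manifest["tensors"][n]["scope"] for n in tensors}
    return WeightBundle(tensors, scopes, manifest["provenance"])
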