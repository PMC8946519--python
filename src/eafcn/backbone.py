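"""FCN/CNN architecture declaration, shape and receptive-field arithmetic,
patch sampling, and the patch-level training loop.

The patch classifier is a fully convolutional network of four conv blocks
(3D conv, 3D max-pool, batch norm, Leaky ReLU, dropout) and two 1x1-output
"fully connected" layers realized as convolutions, so the trained patch
model can be applied densely to whole volumes.  Its receptive field is
47 voxels per axis and its cumulative stride is 4, which fixes the
geometry of every probability map downstream.  Training patches of 47^3
voxels are sampled uniformly from subject volumes and inherit the subject
label (weak supervision: no voxel-level labels exist).

A whole-volume CNN with the same block structure but a flattening head is
declared as a baseline; its layer table is used for shape checking.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .attention import ExternalAttention3d, SelfAttention3d
from .volume_io import LABEL_TO_INDEX, BrainVolume, SubjectRecord

__all__ = [
    "ConvBlockSpec",
    "NetworkSpec",
    "TrainConfig",
    "PatchSample",
    "PATCH_SIZE",
    "fcn_spec_default",
    "cnn_spec_default",
    "output_shapes",
    "receptive_field",
    "network_stride",
    "network_offset",
    "sample_patches",
    "build_network",
    "FCNModel",
    "train_fcn",
    "save_checkpoint",
    "load_checkpoint",
]

PATCH_SIZE = 47


@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block: conv -> max-pool -> batch norm -> Leaky ReLU -> dropout."""

    out_channels: int
    conv_kernel: int
    conv_stride: int = 1
    conv_pad: int = 0
    pool_kernel: int = 2
    pool_stride: int = 1
    pool_pad: int = 0
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    leaky_slope: float = 0.01
    dropout_p: float = 0.1

    def __post_init__(self):
        if self.conv_kernel < 1 or self.conv_stride < 1 or self.pool_kernel < 1 or self.pool_stride < 1:
            raise ValueError("kernels and strides must be >= 1")
        if self.conv_pad < 0 or self.pool_pad < 0:
            raise ValueError("pads must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network description from which the model, its output
    shapes, and its receptive field are all derived."""

    blocks: tuple
    head_channels: int = 30
    fc1_kernel: int = 6
    n_classes: int = 2
    flatten_head: bool = False        # True for the whole-volume CNN baseline
    attention: str = "none"           # none | self | external
    attention_kwargs: tuple = ()      # sorted (key, value) pairs
    in_channels: int = 1
    name: str = "fcn"

    def __post_init__(self):
        if self.attention not in ("none", "self", "external"):
            raise ValueError(f"unknown attention mode {self.attention!r}")

    @property
    def attn_kwargs(self) -> dict:
        return dict(self.attention_kwargs)


_FCN_CHANNELS = {"full": (20, 40, 80, 160), "desk": (4, 8, 16, 32)}
_FCN_HEAD = {"full": 30, "desk": 8}


def fcn_spec_default(profile: str = "full", attention: str = "none",
                     attention_kwargs: dict | None = None) -> NetworkSpec:
    """The patch FCN: four conv blocks then two conv-realized FC layers.

    ``profile='full'`` reproduces the full-scale layer table
    (channels 20/40/80/160, head 30->2); ``profile='desk'`` is a thin
    CPU-friendly profile (4/8/16/32, head 8->2) with identical geometry.
    """
    if profile not in _FCN_CHANNELS:
        raise ValueError(f"unknown profile {profile!r}")
    c1, c2, c3, c4 = _FCN_CHANNELS[profile]
    blocks = (
        ConvBlockSpec(c1, conv_kernel=4, pool_kernel=2, pool_stride=1),
        ConvBlockSpec(c2, conv_kernel=4, pool_kernel=2, pool_stride=2),
        ConvBlockSpec(c3, conv_kernel=3, pool_kernel=2, pool_stride=2),
        ConvBlockSpec(c4, conv_kernel=3, pool_kernel=2, pool_stride=1),
    )
    kw = tuple(sorted((attention_kwargs or {}).items()))
    return NetworkSpec(blocks=blocks, head_channels=_FCN_HEAD[profile], fc1_kernel=6,
                       attention=attention, attention_kwargs=kw,
                       name=f"fcn-{profile}")


def cnn_spec_default() -> NetworkSpec:
    """The whole-volume CNN baseline (flattening head, input 182x218x182)."""
    blocks = (
        ConvBlockSpec(20, conv_kernel=7, conv_stride=2, pool_kernel=3, pool_stride=2),
        ConvBlockSpec(40, conv_kernel=4, pool_kernel=2, pool_stride=2),
        ConvBlockSpec(80, conv_kernel=3, pool_kernel=2, pool_stride=2),
        ConvBlockSpec(160, conv_kernel=3, pool_kernel=2, pool_stride=1),
    )
    return NetworkSpec(blocks=blocks, head_channels=30, flatten_head=True, name="cnn")


def _conv_out(size, kernel, stride, pad, layer_name):
    out = (size + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError(f"shape error at {layer_name}: extent {size} too small "
                         f"for kernel {kernel} stride {stride} pad {pad}")
    return out


def output_shapes(spec: NetworkSpec, input_shape) -> list:
    """Per-layer output shapes, floor-division convolution arithmetic.

    Returns a list of (layer_name, shape) pairs, starting from the input.
    Raises a shape error naming the first layer whose output would be empty.
    """
    C, *spatial = input_shape
    shapes = [("input", tuple(input_shape))]
    for i, b in enumerate(spec.blocks, start=1):
        spatial = [_conv_out(s, b.conv_kernel, b.conv_stride, b.conv_pad, f"conv{i}") for s in spatial]
        shapes.append((f"conv{i}", (b.out_channels, *spatial)))
        spatial = [_conv_out(s, b.pool_kernel, b.pool_stride, b.pool_pad, f"pool{i}") for s in spatial]
        shapes.append((f"pool{i}", (b.out_channels, *spatial)))
    c_last = spec.blocks[-1].out_channels
    if spec.flatten_head:
        flat = int(c_last * np.prod(spatial))
        shapes.append(("flatten", (flat,)))
        shapes.append(("fc1", (spec.head_channels,)))
        shapes.append(("fc2", (spec.n_classes,)))
    else:
        spatial = [_conv_out(s, spec.fc1_kernel, 1, 0, "fc1") for s in spatial]
        shapes.append(("fc1", (spec.head_channels, *spatial)))
        shapes.append(("fc2", (spec.n_classes, *spatial)))
    return shapes


def _conv_pool_layers(spec: NetworkSpec):
    """(kernel, stride) pairs of the conv/pool cascade through fc1."""
    layers = []
    for b in spec.blocks:
        layers.append((b.conv_kernel, b.conv_stride))
        layers.append((b.pool_kernel, b.pool_stride))
    layers.append((spec.fc1_kernel, 1))
    return layers


def receptive_field(spec: NetworkSpec) -> int:
    """Receptive field (voxels per axis) of one output unit at fc1.

    Standard recursion rf <- rf + (kernel - 1) * jump; jump <- jump * stride
    over the conv/pool cascade.  Only defined for the fully convolutional
    head (the flattening CNN sees the whole image by construction).
    """
    if spec.flatten_head:
        raise ValueError("receptive_field is defined for the fully convolutional head only")
    rf, jump = 1, 1
    for k, s in _conv_pool_layers(spec):
        rf += (k - 1) * jump
        jump *= s
    return rf


def network_stride(spec: NetworkSpec) -> int:
    """Cumulative stride (voxels per output-lattice step)."""
    jump = 1
    for _, s in _conv_pool_layers(spec):
        jump *= s
    return jump


def network_offset(spec: NetworkSpec) -> int:
    """Voxel coordinate (0-based) of the first lattice site's window center."""
    return receptive_field(spec) // 2


@dataclass(frozen=True)
class PatchSample:
    """A 47^3 training cube with its source-volume center and inherited label."""

    voxels: np.ndarray
    center: tuple
    label: str


def sample_patches(volume: BrainVolume, record: SubjectRecord, n: int,
                   rng: np.random.Generator, patch: int | None = None) -> list:
    """Uniformly sample ``n`` fully interior cubes from a volume."""
    patch = PATCH_SIZE if patch is None else patch
    shape = volume.shape
    if any(s < patch for s in shape):
        raise ValueError(f"volume {shape} smaller than patch size {patch}")
    half = patch // 2
    out = []
    for _ in range(n):
        start = tuple(int(rng.integers(0, s - patch + 1)) for s in shape)
        cube = volume.voxels[start[0]:start[0] + patch,
                             start[1]:start[1] + patch,
                             start[2]:start[2] + patch]
        out.append(PatchSample(voxels=np.ascontiguousarray(cube, dtype=np.float32),
                               center=tuple(st + half for st in start),
                               label=record.label))
    return out


class FCNModel:
    """A built network plus the spec it was derived from."""

    def __init__(self, spec: NetworkSpec, net: _nn.Sequential):
        self.spec = spec
        self.net = net

    def forward(self, x, training=False, rng=None):
        return self.net.forward(x, training=training, rng=rng)

    def forward_exact(self, x):
        """Evaluation-mode forward in float64 on the bit-reproducible GEMM
        convolution path (used where dense/patchwise agreement is asserted)."""
        convs = [l for l in self.net.layers if isinstance(l, _nn.Conv3d)]
        old = [c.method for c in convs]
        for c in convs:
            c.method = "gemm"
        try:
            return self.net.forward(np.asarray(x, dtype=np.float64), training=False)
        finally:
            for c, m in zip(convs, old):
                c.method = m

    def params(self):
        return self.net.params()

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)

    @property
    def stride(self):
        return network_stride(self.spec)

    @property
    def offset(self):
        return network_offset(self.spec)


def build_network(spec: NetworkSpec, seed: int = 0) -> FCNModel:
    """Instantiate the network with seeded fan-in-scaled uniform weights.

    The optional attention block is applied to the complete block-4 output
    (after pooling, normalization, activation and dropout), immediately
    before fc1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 901]))
    layers = []
    c_in = spec.in_channels
    for i, b in enumerate(spec.blocks):
        layers.append(_nn.Conv3d(c_in, b.out_channels, b.conv_kernel, stride=b.conv_stride,
                                 pad=b.conv_pad, rng=rng, need_dx=(i > 0)))
        layers.append(_nn.MaxPool3d(b.pool_kernel, b.pool_stride))
        layers.append(_nn.BatchNorm3d(b.out_channels, eps=b.bn_eps, momentum=b.bn_momentum))
        layers.append(_nn.LeakyReLU(b.leaky_slope))
        layers.append(_nn.Dropout(b.dropout_p))
        c_in = b.out_channels
    if spec.attention == "self":
        layers.append(SelfAttention3d(c_in, rng=rng, **spec.attn_kwargs))
    elif spec.attention == "external":
        layers.append(ExternalAttention3d(c_in, rng=rng, **spec.attn_kwargs))
    if spec.flatten_head:
        shapes = dict(output_shapes(spec, (spec.in_channels, 182, 218, 182)))
        layers.append(_nn.Flatten())
        layers.append(_nn.Dropout(0.1))
        layers.append(_nn.Linear(shapes["flatten"][0], spec.head_channels, rng=rng))
        layers.append(_nn.LeakyReLU(0.01))
        layers.append(_nn.Dropout(0.1))
        layers.append(_nn.Linear(spec.head_channels, spec.n_classes, rng=rng))
    else:
        layers.append(_nn.Conv3d(c_in, spec.head_channels, spec.fc1_kernel, rng=rng))
        layers.append(_nn.LeakyReLU(0.01))
        layers.append(_nn.Dropout(0.1))
        layers.append(_nn.Conv3d(spec.head_channels, spec.n_classes, 1, rng=rng))
    return FCNModel(spec, _nn.Sequential(layers))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for both network stages (Adam + cross-entropy)."""

    batch_size: int = 10
    learning_rate: float = 1e-4
    iterations: int = 3000
    validate_every: int = 20
    seed: int = 0
    patches_per_subject: int = 8

    def __post_init__(self):
        if self.batch_size < 1 or self.validate_every < 1 or self.patches_per_subject < 1:
            raise ValueError("counts must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def _patch_batch(subjects, rng, batch_size):
    """One patch from each of ``batch_size`` randomly chosen subjects."""
    n = len(subjects)
    if n >= batch_size:
        idx = rng.choice(n, size=batch_size, replace=False)
    else:
        idx = rng.choice(n, size=batch_size, replace=True)
    xs, ys = [], []
    for i in idx:
        rec, vol = subjects[i]
        p = sample_patches(vol, rec, 1, rng)[0]
        xs.append(p.voxels[None])
        ys.append(LABEL_TO_INDEX[p.label])
    return np.stack(xs), np.array(ys)


def _eval_patch_accuracy(model, patches, labels, chunk=20):
    correct = 0
    for i in range(0, len(patches), chunk):
        x = np.stack([p[None] for p in patches[i:i + chunk]])
        logits = model.forward(x, training=False).reshape(len(x), -1)
        correct += int(np.sum(np.argmax(logits, axis=1) == labels[i:i + chunk]))
    return correct / len(patches)


def train_fcn(model: FCNModel, train_subjects, val_subjects, cfg: TrainConfig):
    """Patch-level training with Adam and cross-entropy.

    Each step draws ``batch_size`` patches from as many distinct training
    subjects; validation patch accuracy is measured every
    ``validate_every`` steps on a fixed patch set drawn once from the
    validation subjects, and the best-scoring weights (ties: earliest) are
    restored at the end.

    Returns (model, history) where history rows are dicts with keys
    iteration, train_loss, val_accuracy.
    """
    if not train_subjects or not val_subjects:
        raise ValueError("both subject lists must be non-empty")
    history = []
    if cfg.iterations == 0:
        return model, history
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2 ** 31), 373]))
    # fixed validation patch set
    val_patches, val_labels = [], []
    for rec, vol in val_subjects:
        for p in sample_patches(vol, rec, cfg.patches_per_subject, rng):
            val_patches.append(p.voxels)
            val_labels.append(LABEL_TO_INDEX[p.label])
    val_labels = np.array(val_labels)
    opt = _nn.Adam(model.params(), lr=cfg.learning_rate)
    best_acc, best_state = -1.0, None
    for it in range(1, cfg.iterations + 1):
        x, y = _patch_batch(train_subjects, rng, cfg.batch_size)
        opt.zero_grad()
        logits = model.forward(x, training=True, rng=rng).reshape(len(x), -1)
        loss, dlogits = _nn.softmax_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        model.net.backward(dlogits.reshape(logits.shape[0], logits.shape[1], 1, 1, 1))
        opt.step()
        if it % cfg.validate_every == 0 or it == cfg.iterations:
            acc = _eval_patch_accuracy(model, val_patches, val_labels)
            history.append({"iteration": it, "train_loss": loss, "val_accuracy": acc})
            if acc > best_acc:
                best_acc, best_state = acc, model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def save_checkpoint(model: FCNModel, cfg: TrainConfig | None, path):
    """Weights + spec + train config in one .npz archive."""
    meta = {"spec": asdict(model.spec), "cfg": asdict(cfg) if cfg else None}
    arrays = {f"arr_{i}": a for i, a in enumerate(model.get_state())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, seed: int = 0) -> tuple:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    spec_d = meta["spec"]
    spec_d["blocks"] = tuple(ConvBlockSpec(**b) for b in spec_d["blocks"])
    spec_d["attention_kwargs"] = tuple(tuple(p) for p in spec_d["attention_kwargs"])
    spec = NetworkSpec(**spec_d)
    model = build_network(spec, seed=seed)
    model.set_state(arrays)
    cfg = TrainConfig(**meta["cfg"]) if meta["cfg"] else None
    return model, cfg
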