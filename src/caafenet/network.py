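"""Assembly of the full classifier and its ablation variants.

The backbone is a modified ResNet18: a 7x7 stem, four stages of two
residual units with 64/128/256/512 channels (stride-2 projection entry for
stages 2-4), global average pooling and a LogSoftmax head.  A CAAFE block
(or an SE / CBAM substitute for the architecture-controlled baselines) can
be inserted after each stage's second residual unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .blocks import (
    CAAFEBlock,
    CAAFEBlockSpec,
    CAMConfig,
    CBAMBlock,
    CBRM,
    ClassifierHead,
    ConfigurationError,
    ResidualUnit,
    SEBlock,
    Module,
)

STAGE_CHANNELS = (64, 128, 256, 512)

#: Ablation variants: which stages carry a CAAFE block, or which
#: substitute attention block is used at the same four insertion points.
VARIANTS = {
    "resnet18*": (),
    "+B1": (0,),
    "+B1B2": (0, 1),
    "+B1B2B3": (0, 1, 2),
    "full": (0, 1, 2, 3),
    "se": "se",
    "cbam": "cbam",
}


@dataclass
class StageConfig:
    channels: int
    n_residual_units: int = 2
    caafe_enabled: bool = False
    downsample_on_entry: bool = False


@dataclass
class ModelConfig:
    """Complete architecture description of one classifier variant."""

    stem_variant: str = "standard"
    input_channels: int = 1
    stages: tuple[StageConfig, ...] = field(default_factory=lambda: tuple(
        StageConfig(channels=c, downsample_on_entry=i > 0)
        for i, c in enumerate(STAGE_CHANNELS)))
    cam_reduction: int = 16
    n_classes: int = 2
    variant_name: str = "full"
    preadd_relu: bool = True
    inter_conv_activation: bool = True
    branch1_include_input: bool = False
    attention_kind: str = "caafe"  # caafe | se | cbam

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ConfigurationError("exactly 4 stages are required")
        if tuple(s.channels for s in self.stages) != STAGE_CHANNELS:
            raise ConfigurationError(
                f"stage channels must follow {STAGE_CHANNELS}")


def config_for_variant(name: str, **overrides) -> ModelConfig:
    if name not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {name!r}; valid variants: "
            + ", ".join(sorted(VARIANTS)))
    selector = VARIANTS[name]
    if isinstance(selector, str):
        stages = tuple(
            StageConfig(channels=c, caafe_enabled=True,
                        downsample_on_entry=i > 0)
            for i, c in enumerate(STAGE_CHANNELS))
        return ModelConfig(stages=stages, variant_name=name,
                           attention_kind=selector, **overrides)
    stages = tuple(
        StageConfig(channels=c, caafe_enabled=(i in selector),
                    downsample_on_entry=i > 0)
        for i, c in enumerate(STAGE_CHANNELS))
    return ModelConfig(stages=stages, variant_name=name, **overrides)


class Stage(Module):
    """Two residual units, optionally followed by an attention block."""

    def __init__(self, in_channels: int, cfg: StageConfig, model_cfg:
                 ModelConfig, *, rng: np.random.Generator):
        stride = 2 if cfg.downsample_on_entry else 1
        self.units = [
            ResidualUnit(in_channels, cfg.channels, stride=stride,
                         preadd_relu=model_cfg.preadd_relu, rng=rng),
            ResidualUnit(cfg.channels, cfg.channels,
                         preadd_relu=model_cfg.preadd_relu, rng=rng),
        ]
        self.attention: Module | None = None
        if cfg.caafe_enabled:
            if model_cfg.attention_kind == "caafe":
                spec = CAAFEBlockSpec(
                    channels=cfg.channels,
                    inter_conv_activation=model_cfg.inter_conv_activation,
                    branch1_include_input=model_cfg.branch1_include_input,
                    cam=CAMConfig(cfg.channels, model_cfg.cam_reduction))
                self.attention = CAAFEBlock(spec, rng=rng)
            elif model_cfg.attention_kind == "se":
                self.attention = SEBlock(
                    cfg.channels, model_cfg.cam_reduction, rng=rng)
            elif model_cfg.attention_kind == "cbam":
                self.attention = CBAMBlock(
                    cfg.channels, model_cfg.cam_reduction, rng=rng)
            else:
                raise ConfigurationError(
                    f"unknown attention kind {model_cfg.attention_kind!r}")

    def forward(self, x, training=False):
        for unit in self.units:
            x = unit.forward(x, training)
        if self.attention is not None:
            x = self.attention.forward(x, training)
        return x

    def backward(self, grad):
        if self.attention is not None:
            grad = self.attention.backward(grad)
        for unit in reversed(self.units):
            grad = unit.backward(grad)
        return grad


class CAAFEResNet(Module):
    """The assembled classifier: stem, four stages, LogSoftmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.stem = CBRM(config.input_channels, STAGE_CHANNELS[0],
                         variant=config.stem_variant, rng=rng)
        self.stages = [
            Stage(STAGE_CHANNELS[max(0, i - 1)], stage_cfg, config, rng=rng)
            for i, stage_cfg in enumerate(config.stages)
        ]
        self.head = ClassifierHead(STAGE_CHANNELS[-1], config.n_classes,
                                   rng=rng)

    def forward(self, x, training=False):
        h = self.stem.forward(x, training)
        for stage in self.stages:
            h = stage.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, grad):
        grad = self.head.backward(grad)
        for stage in reversed(self.stages):
            grad = stage.backward(grad)
        return self.stem.backward(grad)

    def features(self, x, training=False):
        """Feature map entering the head (output of the last stage)."""
        h = self.stem.forward(x, training)
        for stage in self.stages:
            h = stage.forward(h, training)
        return h


def build_model(config: ModelConfig, seed: int = 0) -> CAAFEResNet:
    return CAAFEResNet(config, seed=seed)


def build_variant(name: str, seed: int = 0, **overrides) -> CAAFEResNet:
    """Build one of the named ablation/baseline variants."""
    return CAAFEResNet(config_for_variant(name, **overrides), seed=seed)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars (running stats excluded)."""
    return int(sum(p.size for p in model.parameters()))


def save_checkpoint(model: Module, path, extra: dict | None = None) -> None:
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["__version__"] = np.array(__version__)
    if extra:
        for k, v in extra.items():
            state[f"extra/{k}"] = np.asarray(v)
    np.savez(path, **state)


def load_checkpoint(model: Module, path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        state = {k[len("param/"):]: data[k]
                 for k in data.files if k.startswith("param/")}
        extras = {k[len("extra/"):]: data[k]
                  for k in data.files if k.startswith("extra/")}
        version = str(data["__version__"]) if "__version__" in data else None
    model.load_state_dict(state)
    return {"version": version, **extras}


def receptive_field_probe(block: Module, channels: int, input_size: int = 41,
                          dtype=np.float64) -> int:
    """Side length of the input window one output pixel is sensitive to.

    The block is probed in linearised form: every convolution weight is set
    to one and batch-norm is forced to identity (inference mode, zero
    running mean, unit variance).  The gradient of the centre output pixel
    w.r.t. the input then marks the receptive field exactly.  The probe is
    repeated on a larger input; if the measured window grows, the requested
    ``input_size`` clipped the field and a ``ValueError`` is raised.
    """
    for name, p in block.named_parameters():
        if p.data.ndim >= 2:          # conv / linear weights
            p.data[...] = 1.0
        else:                          # biases, BN gamma/beta
            p.data[...] = 1.0 if name.endswith("gamma") else 0.0
    for name, buf in block.named_buffers():
        buf[...] = 1.0 if name.endswith("running_var") else 0.0

    def measure(size: int) -> int:
        x = np.zeros((1, channels, size, size), dtype=dtype)
        out = block.forward(x, training=False)
        grad = np.zeros_like(out)
        centre = size // 2
        grad[0, :, centre, centre] = 1.0
        gx = block.backward(grad)
        support = np.abs(gx[0]).sum(axis=0) > 0
        rows = np.flatnonzero(support.any(axis=1))
        cols = np.flatnonzero(support.any(axis=0))
        if rows.size == 0:
            return 0
        return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))

    width = measure(input_size)
    if measure(input_size + 12) != width:
        raise ValueError(
            f"receptive field clipped by input_size={input_size}; "
            "probe with a larger input")
    return width
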