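"""Multi-path U-Net: configuration, validation, assembly and inference.

The architecture runs several complete encoder--decoder "receptive field
pathways" over the same input, each with its own pooling window p and depth d,
so each pathway sees the scene through a different sequence of resolutions.
All pathways must reach the same total downsampling factor F = p**d
(coherence), so their bottleneck feature maps can be concatenated along the
channel axis.  The concatenated stack is normalized across channels per pixel
(cross-channel Layer Normalization with a learned per-position gain/bias) and
regularized with Spatial Dropout before feeding every pathway's decoder.
Full-resolution decoder outputs are concatenated and reduced by a 1x1
convolution to per-pixel class probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn


class CoherenceError(ValueError):
    """Raised when receptive field pathways disagree on the downsampling factor."""


@dataclass(frozen=True)
class PathwaySpec:
    """One receptive field pathway.

    Parameters
    ----------
    pool_window
        Side p of the square max-pooling window; the deconvolution kernel and
        stride on the way up equal p as well.
    encoder_filters
        Filters of the successive encoder convolution blocks; the decoder
        filter list is its reverse.
    bottleneck_filters
        Filters of the pathway's bottleneck convolution block.
    """

    pool_window: int
    encoder_filters: tuple[int, ...]
    bottleneck_filters: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoder_filters",
                           tuple(int(f) for f in self.encoder_filters))
        if self.pool_window < 2:
            raise ValueError(f"pool_window must be >= 2, got {self.pool_window}")
        if len(self.encoder_filters) < 1:
            raise ValueError("encoder_filters must be nonempty")
        if any(f < 1 for f in self.encoder_filters):
            raise ValueError("encoder filters must be positive")
        if self.bottleneck_filters < 1:
            raise ValueError("bottleneck_filters must be positive")

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        return self.encoder_filters[::-1]

    @property
    def downsampling_factor(self) -> int:
        return self.pool_window ** self.depth


#: The two-pathway configuration evaluated in the reference experiments:
#: a 4x4-pooling pathway with filters [40, 240] and a 2x2-pooling pathway
#: with filters [40, 80, 160, 220]; both reach factor 16 (4**2 == 2**4).
REFERENCE_PATHWAYS = (
    PathwaySpec(pool_window=4, encoder_filters=(40, 240),
                bottleneck_filters=240),
    PathwaySpec(pool_window=2, encoder_filters=(40, 80, 160, 220),
                bottleneck_filters=220),
)


def validate_pathway_coherence(pathways) -> int:
    """Return the common downsampling factor F of a pathway list.

    Every pathway must satisfy pool_window**depth == F; otherwise the
    bottleneck feature maps would have incompatible spatial dimensions.

    Raises
    ------
    CoherenceError
        Naming the first pathway whose factor differs from the first one's.
    """
    pathways = list(pathways)
    if not pathways:
        raise ValueError("pathway list is empty")
    factor = pathways[0].downsampling_factor
    for i, pw in enumerate(pathways[1:], start=1):
        if pw.downsampling_factor != factor:
            raise CoherenceError(
                f"pathway {i} (pool {pw.pool_window}, depth {pw.depth}) has "
                f"downsampling factor {pw.downsampling_factor}, but pathway 0 "
                f"has {factor}")
    return factor


@dataclass(frozen=True)
class ModelConfig:
    """Full declarative description of a multi-path U-Net."""

    input_height: int
    input_width: int
    input_channels: int
    pathways: tuple[PathwaySpec, ...]
    num_classes: int = 2
    conv_kernel: int = 3
    conv_stride: int = 1
    leaky_slope: float = 0.1
    dropout_rate: float = 0.1
    norm_epsilon: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple(self.pathways))
        if self.input_height < 1 or self.input_width < 1:
            raise ValueError("input dimensions must be positive")
        if self.input_channels < 1:
            raise ValueError("input_channels must be positive")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be a positive odd integer")
        if self.conv_stride != 1:
            raise ValueError("only stride 1 convolutions are supported")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in (0,1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.norm_epsilon <= 0:
            raise ValueError("norm_epsilon must be positive")
        factor = validate_pathway_coherence(self.pathways)
        if self.input_height % factor or self.input_width % factor:
            raise ValueError(
                f"input dimensions {self.input_height}x{self.input_width} "
                f"must be divisible by the common downsampling factor {factor}")

    @property
    def downsampling_factor(self) -> int:
        return validate_pathway_coherence(self.pathways)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathways"] = [
            {"pool_window": p.pool_window,
             "encoder_filters": list(p.encoder_filters),
             "bottleneck_filters": p.bottleneck_filters}
            for p in self.pathways]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["pathways"] = tuple(
            PathwaySpec(pool_window=p["pool_window"],
                        encoder_filters=tuple(p["encoder_filters"]),
                        bottleneck_filters=p["bottleneck_filters"])
            for p in d["pathways"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "ModelConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reference_config(input_size: int = 512, input_channels: int = 3,
                     num_classes: int = 2, **kwargs) -> ModelConfig:
    """The two-pathway configuration at its published scale (512x512x3)."""
    return ModelConfig(input_height=input_size, input_width=input_size,
                       input_channels=input_channels, num_classes=num_classes,
                       pathways=REFERENCE_PATHWAYS, **kwargs)


@dataclass
class NormParams:
    """Adaptive gain/bias of the bottleneck interconnect (spatial shape)."""

    gain: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.gain.shape != self.bias.shape:
            raise ValueError("gain and bias must share a shape")


def interconnect_layer_norm(stack: np.ndarray, params: NormParams,
                            epsilon: float = 1e-5) -> np.ndarray:
    """Cross-channel layer normalization of a concatenated feature stack.

    For each example n and spatial position, the mean and mean squared
    deviation are taken over all channels; the normalized value is scaled and
    shifted by the per-position gain/bias, broadcast over examples and
    channels.  No statistics are shared across examples.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must have axes (example, channel, row, column)")
    if params.gain.shape != stack.shape[2:]:
        raise ValueError(
            f"norm parameter shape {params.gain.shape} does not match stack "
            f"spatial shape {stack.shape[2:]}")
    mu = stack.mean(axis=1, keepdims=True)
    var = stack.var(axis=1, keepdims=True)
    xhat = (stack - mu) / np.sqrt(var + epsilon)
    return params.gain[None, None] * xhat + params.bias[None, None]


def spatial_dropout(x: np.ndarray, rate: float, training: bool = True,
                    seed: int = 0) -> np.ndarray:
    """Channel-wise dropout: whole feature maps zeroed with probability rate.

    Survivors are scaled by 1/(1-rate); identity at inference or rate 0.
    """
    layer = nn.SpatialDropout2d(rate)
    return layer.forward(np.asarray(x, dtype=float), training=training,
                         rng=np.random.default_rng(seed))


class ConvBlock(nn.Layer):
    """Two (conv 3x3 -> instance norm -> leaky ReLU) stages.

    Convolutions preserve spatial size and carry no bias (the instance norm
    shift absorbs it).
    """

    def __init__(self, in_channels: int, filters: int, config: ModelConfig,
                 rng: np.random.Generator, name: str = "block") -> None:
        self.filters = filters
        self.layers: list[nn.Layer] = []
        c = in_channels
        for s in (1, 2):
            self.layers += [
                nn.Conv2d(c, filters, kernel=config.conv_kernel, bias=False,
                          rng=rng, name=f"{name}.conv{s}"),
                nn.InstanceNorm2d(filters, eps=config.norm_epsilon,
                                  name=f"{name}.inorm{s}"),
                nn.LeakyReLU(config.leaky_slope),
            ]
            c = filters

    def parameters(self) -> list[nn.Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, *, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def conv_block(x: np.ndarray, filters: int, config: ModelConfig,
               seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized ConvBlock to a feature stack (functional form)."""
    block = ConvBlock(x.shape[1], filters, config, np.random.default_rng(seed))
    return block.forward(np.asarray(x, dtype=float))


class DeconvBlock(nn.Layer):
    """Transposed conv (kernel = stride = pool) -> instance norm -> leaky ReLU."""

    def __init__(self, in_channels: int, filters: int, pool: int,
                 config: ModelConfig, rng: np.random.Generator,
                 name: str = "up") -> None:
        self.filters = filters
        self.layers: list[nn.Layer] = [
            nn.ConvTranspose2d(in_channels, filters, pool, bias=False,
                               rng=rng, name=f"{name}.deconv"),
            nn.InstanceNorm2d(filters, eps=config.norm_epsilon,
                              name=f"{name}.inorm"),
            nn.LeakyReLU(config.leaky_slope),
        ]

    def parameters(self) -> list[nn.Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, *, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class MultiPathUNet:
    """Assembled multi-path U-Net with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        factor = validate_pathway_coherence(config.pathways)
        self.downsampling_factor = factor
        self.bottleneck_spatial = (config.input_height // factor,
                                   config.input_width // factor)
        self.bottleneck_channels = sum(p.bottleneck_filters
                                       for p in config.pathways)

        rng = np.random.default_rng(config.seed)
        rate = config.dropout_rate
        self.encoders = []   # per pathway: list of (ConvBlock, MaxPool, Dropout)
        self.bottlenecks = []
        self.decoders = []   # per pathway: list of (DeconvBlock, ConvBlock, Dropout)
        for i, pw in enumerate(config.pathways):
            enc, c = [], config.input_channels
            for lv, f in enumerate(pw.encoder_filters):
                enc.append((
                    ConvBlock(c, f, config, rng, name=f"p{i}.enc{lv}"),
                    nn.MaxPool2d(pw.pool_window),
                    nn.SpatialDropout2d(rate),
                ))
                c = f
            self.encoders.append(enc)
            self.bottlenecks.append(
                ConvBlock(c, pw.bottleneck_filters, config, rng,
                          name=f"p{i}.bottleneck"))
        self.interconnect = nn.CrossChannelLayerNorm(
            *self.bottleneck_spatial, eps=config.norm_epsilon,
            name="interconnect")
        self.interconnect_dropout = nn.SpatialDropout2d(rate)
        for i, pw in enumerate(config.pathways):
            dec, c = [], self.bottleneck_channels
            for lv, f in enumerate(pw.decoder_filters):
                skip_f = pw.encoder_filters[pw.depth - 1 - lv]
                dec.append((
                    DeconvBlock(c, f, pw.pool_window, config, rng,
                                name=f"p{i}.up{lv}"),
                    ConvBlock(f + skip_f, f, config, rng,
                              name=f"p{i}.dec{lv}"),
                    nn.SpatialDropout2d(rate),
                ))
                c = f
            self.decoders.append(dec)
        out_c = sum(pw.decoder_filters[-1] for pw in config.pathways)
        self.out_conv = nn.Conv2d(out_c, config.num_classes, kernel=1,
                                  bias=True, rng=rng, name="output")
        self.softmax = nn.Softmax()
        self._split_cache: dict | None = None

    # -- parameter bookkeeping -------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        ps: list[nn.Parameter] = []
        for enc in self.encoders:
            for block, _pool, _drop in enc:
                ps += block.parameters()
        for b in self.bottlenecks:
            ps += b.parameters()
        ps += self.interconnect.parameters()
        for dec in self.decoders:
            for up, block, _drop in dec:
                ps += up.parameters() + block.parameters()
        ps += self.out_conv.parameters()
        return ps

    @property
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the network; returns per-pixel class probabilities (N,K,H,W)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        if x.shape[1] != cfg.input_channels or \
                x.shape[2] != cfg.input_height or x.shape[3] != cfg.input_width:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configuration "
                f"({cfg.input_channels},{cfg.input_height},{cfg.input_width})")
        if training and rng is None:
            rng = np.random.default_rng(cfg.seed)

        bott_outs = []
        all_skips = []  # per pathway: encoder conv-block outputs (the skips)
        for enc, bott in zip(self.encoders, self.bottlenecks):
            h = x
            skips = []
            for block, pool, drop in enc:
                h = block.forward(h, training=training, rng=rng)
                skips.append(h)
                h = pool.forward(h)
                h = drop.forward(h, training=training, rng=rng)
            all_skips.append(skips)
            bott_outs.append(bott.forward(h, training=training, rng=rng))
        stack = np.concatenate(bott_outs, axis=1)
        stack = self.interconnect.forward(stack)
        stack = self.interconnect_dropout.forward(stack, training=training,
                                                  rng=rng)
        path_outs = []
        skip_channels = []  # per pathway, per level: (deconv, skip) channels
        for pw, skips, dec in zip(self.config.pathways, all_skips,
                                  self.decoders):
            h = stack
            chans = []
            for lv, (up, block, drop) in enumerate(dec):
                skip = skips[pw.depth - 1 - lv]
                h = up.forward(h, training=training, rng=rng)
                chans.append((h.shape[1], skip.shape[1]))
                h = np.concatenate([h, skip], axis=1)
                h = block.forward(h, training=training, rng=rng)
                h = drop.forward(h, training=training, rng=rng)
            path_outs.append(h)
            skip_channels.append(chans)
        out = np.concatenate(path_outs, axis=1)
        logits = self.out_conv.forward(out)
        probs = self.softmax.forward(logits)
        self._split_cache = {
            "bott_channels": [b.filters for b in self.bottlenecks],
            "out_channels": [o.shape[1] for o in path_outs],
            "skip_channels": skip_channels,
        }
        return probs

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the probability map; accumulates
        parameter gradients and returns the gradient w.r.t. the input."""
        cache = self._split_cache
        if cache is None:
            raise RuntimeError("backward called before forward")
        dy = self.softmax.backward(dprobs)
        dy = self.out_conv.backward(dy)
        d_path = _split_channels(dy, cache["out_channels"])

        d_stack = 0.0
        skip_grads: list[list[np.ndarray]] = []
        for pi, (pw, dec, g) in enumerate(zip(self.config.pathways,
                                              self.decoders, d_path)):
            sgrads: list[np.ndarray | None] = [None] * pw.depth
            for lv in range(pw.depth - 1, -1, -1):
                up, block, drop = dec[lv]
                f, _skip_f = cache["skip_channels"][pi][lv]
                g = drop.backward(g)
                g = block.backward(g)
                g, d_skip = g[:, :f], g[:, f:]
                sgrads[pw.depth - 1 - lv] = d_skip
                g = up.backward(g)
            skip_grads.append(sgrads)
            d_stack = d_stack + g
        d_stack = self.interconnect_dropout.backward(d_stack)
        d_stack = self.interconnect.backward(d_stack)
        d_botts = _split_channels(d_stack, cache["bott_channels"])

        d_input = 0.0
        for enc, bott, g, sgrads in zip(self.encoders, self.bottlenecks,
                                        d_botts, skip_grads):
            g = bott.backward(g)
            for lv in range(len(enc) - 1, -1, -1):
                block, pool, drop = enc[lv]
                g = drop.backward(g)
                g = pool.backward(g)
                g = g + sgrads[lv]
                g = block.backward(g)
            d_input = d_input + g
        return d_input

    # -- inference helpers -------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 4) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return np.concatenate([self.forward(x[i:i + batch_size])
                               for i in range(0, len(x), batch_size)])

    def predict(self, x: np.ndarray, threshold: float = 0.5,
                batch_size: int = 4) -> np.ndarray:
        return predict_mask(self.predict_proba(x, batch_size), threshold)

    # -- reporting ---------------------------------------------------------

    def summary_lines(self) -> list[str]:
        """Per-pathway layer shape summary plus the parameter count."""
        cfg = self.config
        lines = [f"input: ({cfg.input_channels}, {cfg.input_height}, "
                 f"{cfg.input_width})"]
        for i, pw in enumerate(cfg.pathways):
            h, w = cfg.input_height, cfg.input_width
            lines.append(f"pathway {i}: pool {pw.pool_window}x{pw.pool_window}"
                         f", depth {pw.depth}")
            for lv, f in enumerate(pw.encoder_filters):
                lines.append(f"  enc{lv}: conv_block -> ({f}, {h}, {w})")
                h, w = h // pw.pool_window, w // pw.pool_window
                lines.append(f"  enc{lv}: maxpool+dropout -> ({f}, {h}, {w})")
            lines.append(f"  bottleneck: conv_block -> "
                         f"({pw.bottleneck_filters}, {h}, {w})")
        hb, wb = self.bottleneck_spatial
        lines.append(f"interconnect: concat+layernorm+dropout -> "
                     f"({self.bottleneck_channels}, {hb}, {wb})")
        for i, pw in enumerate(cfg.pathways):
            h, w = hb, wb
            for lv, f in enumerate(pw.decoder_filters):
                h, w = h * pw.pool_window, w * pw.pool_window
                lines.append(f"  dec{lv} (pathway {i}): deconv+skip+conv_block"
                             f" -> ({f}, {h}, {w})")
        lines.append(f"output: 1x1 conv + softmax -> ({cfg.num_classes}, "
                     f"{cfg.input_height}, {cfg.input_width})")
        n = self.num_parameters
        lines.append(f"trainable parameters: {n:,} ({n / 1e6:.2f} M)")
        return lines

    # -- weights persistence ----------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {f"{i:04d}:{p.name}": p.value
                  for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        data = np.load(path)
        params = self.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint does not match the model")
        for key in sorted(data.files):
            i = int(key.split(":", 1)[0])
            if params[i].value.shape != data[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            params[i].value = data[key].astype(np.float64)


def _split_channels(x: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    out, start = [], 0
    for s in sizes:
        out.append(x[:, start:start + s])
        start += s
    return out


def build_multipath_unet(config: ModelConfig) -> MultiPathUNet:
    """Assemble a multi-path U-Net from its declarative configuration."""
    return MultiPathUNet(config)


def count_trainable_parameters(model) -> int:
    """Exact number of trainable scalars in a model, block, or layer."""
    if hasattr(model, "parameters"):
        return int(sum(p.size for p in model.parameters()))
    raise TypeError("object exposes no parameters()")


def parameters_in_millions(model) -> float:
    """Parameter count in millions, rounded to two decimals (report form)."""
    return round(count_trainable_parameters(model) / 1e6, 2)


def predict_mask(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map: foreground where P(fg) strictly exceeds
    the threshold (ties resolve to background).  Channel 1 is foreground."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 3:
        return (p[1] > threshold).astype(np.uint8)
    if p.ndim == 4:
        return (p[:, 1] > threshold).astype(np.uint8)
    raise ValueError("probability map must have 3 or 4 axes")
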