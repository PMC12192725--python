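"""The segmentation network: conv stages + shifted tokenized-MLP bottleneck.

Architecture overview
---------------------
A five-stage encoder-decoder.  The encoder applies three residual
convolution blocks (channels C1, C2, C3, each followed by 2x2 max pooling)
and then two tokenized-MLP stages (C4, C5), each entered through a learned
3x3 overlapped patch embedding with stride 2.  The decoder mirrors the
encoder: two tokenized-MLP stages back up to C3, then three convolutional
stages to C1, every stage doubling the resolution with bilinear
upsampling; encoder features join the decoder at equal resolution through
additive skip connections (concatenation optional).  A final 1x1
convolution produces per-pixel logits.

Inside a tokenized-MLP block the feature map is shifted along one spatial
axis in channel partitions, flattened to tokens of width E, passed through
a token MLP, positionally encoded by a depthwise 3x3 convolution, then the
second (height) pass repeats shift/tokenize and a GELU-MLP whose output is
added back to the stage-entry tokens and layer-normalised.  GELU is used
as the block activation throughout.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, concat, no_grad
from . import nn
from .nn import Module, Conv2d, Linear, DWConv2d, BatchNorm2d, LayerNorm, gelu_t

__all__ = [
    "ModelConfig",
    "TokenGrid",
    "axial_shift",
    "tokenize",
    "detokenize",
    "gelu",
    "bilinear_upsample",
    "Tokenizer",
    "TokMLPBlock",
    "ConvBlock",
    "RMISNet",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

SHIFT_AXES = ("none", "W", "H", "WH")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``channels`` are the per-stage widths C1..C5 (default the lightweight
    configuration C1=16 ... C5=256 used for the headline results; the
    original wider setting is (32, 64, 128, 160, 256)).  ``shift_axes``
    selects which axial shifts the tokenized blocks apply; ``n_partitions``
    channel groups are translated by ``shift_offsets``.  ``mlp_ratio``
    scales the hidden width of the token MLPs relative to the embedding
    dimension.
    """

    channels: tuple[int, int, int, int, int] = (16, 32, 64, 128, 256)
    in_channels: int = 3
    num_classes: int = 1
    use_tok_mlp: bool = True
    use_pe: bool = True
    shift_axes: str = "WH"
    n_partitions: int = 5
    shift_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)
    token_stride: int = 2
    mlp_ratio: float = 1.0
    skip_mode: str = "add"

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        object.__setattr__(
            self, "shift_offsets", tuple(int(o) for o in self.shift_offsets)
        )
        if len(self.channels) != 5:
            raise ValueError("channels must list the five stage widths C1..C5")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channels must be strictly positive")
        if self.in_channels <= 0 or self.num_classes <= 0:
            raise ValueError("in_channels and num_classes must be positive")
        if self.shift_axes not in SHIFT_AXES:
            raise ValueError(f"shift_axes must be one of {SHIFT_AXES}")
        if len(self.shift_offsets) != self.n_partitions:
            raise ValueError("shift_offsets must have length n_partitions")
        if self.token_stride < 1:
            raise ValueError("token_stride must be >= 1")
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")
        if self.skip_mode not in ("add", "concat"):
            raise ValueError("skip_mode must be 'add' or 'concat'")
        if not self.use_tok_mlp and self.shift_axes != "none":
            raise ValueError("shift_axes requires use_tok_mlp=True")
        if not self.use_tok_mlp and self.use_pe:
            raise ValueError("use_pe requires use_tok_mlp=True")

    # ---- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["shift_offsets"] = list(self.shift_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        if "shift_offsets" in d:
            d["shift_offsets"] = tuple(d["shift_offsets"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TokenGrid:
    """Tokens of width E plus the spatial grid they came from."""

    tokens: np.ndarray  # (batch, n_tokens, embed_dim)
    grid_shape: tuple[int, int]

    def __post_init__(self):
        rows, cols = self.grid_shape
        if self.tokens.ndim != 3:
            raise ValueError("tokens must be (batch, token, embedding)")
        if rows * cols != self.tokens.shape[1]:
            raise ValueError(
                f"grid_shape {self.grid_shape} inconsistent with "
                f"{self.tokens.shape[1]} tokens"
            )

    @property
    def embed_dim(self) -> int:
        return self.tokens.shape[2]


# ---------------------------------------------------------------------------
# array-level operations (NumPy in / NumPy out)
# ---------------------------------------------------------------------------

def _partition_channels(n_channels: int, n_partitions: int) -> list[slice]:
    """Split channels into n groups; the remainder joins the last group."""
    base = n_channels // n_partitions if n_channels >= n_partitions else 1
    bounds = [min(i * base, n_channels) for i in range(n_partitions)] + [n_channels]
    return [slice(bounds[i], bounds[i + 1]) for i in range(n_partitions)]


def _shift1d(arr: np.ndarray, offset: int, axis: int) -> np.ndarray:
    """Translate along ``axis`` by ``offset``, zero-filling vacated positions."""
    if offset == 0:
        return arr.copy()
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if offset > 0:
        dst[axis] = slice(offset, None)
        src[axis] = slice(None, -offset)
    else:
        dst[axis] = slice(None, offset)
        src[axis] = slice(-offset, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def axial_shift(
    grid: np.ndarray,
    axis: str,
    offsets: tuple[int, ...] = (-2, -1, 0, 1, 2),
    n_partitions: int | None = None,
) -> np.ndarray:
    """Shift channel partitions along one spatial axis, zero-filling.

    ``grid`` is (batch, channel, row, col); ``axis`` is ``"W"`` (columns)
    or ``"H"`` (rows).  Channels are split into ``len(offsets)`` groups and
    group k is translated by ``offsets[k]``; positions shifted in from
    outside the map are zero.
    """
    grid = np.asarray(grid)
    if grid.ndim != 4:
        raise ValueError("grid must be (batch, channel, row, col)")
    if axis not in ("W", "H"):
        raise ValueError(f"axis must be 'W' or 'H', got {axis!r}")
    if n_partitions is None:
        n_partitions = len(offsets)
    if len(offsets) != n_partitions:
        raise ValueError("offsets must have length n_partitions")
    ax = 3 if axis == "W" else 2
    extent = grid.shape[ax]
    if any(abs(o) >= extent for o in offsets):
        raise ValueError(
            f"|offset| must be < spatial extent {extent} along axis {axis}"
        )
    out = np.empty_like(grid)
    for sl, off in zip(_partition_channels(grid.shape[1], n_partitions), offsets):
        out[:, sl] = _shift1d(grid[:, sl], off, ax)
    return out


def _axial_shift_t(x: Tensor, axis: str, offsets, n_partitions) -> Tensor:
    """Tape-recorded axial shift; the adjoint is the shift by negated offsets."""
    neg = tuple(-o for o in offsets)
    out_data = axial_shift(x.data, axis, offsets, n_partitions)

    def backward(g):
        return (axial_shift(g, axis, neg, n_partitions),)

    return Tensor._make(out_data, (x,), backward)


def gelu(x):
    """Gaussian error linear unit x * Phi(x), via the error function."""
    return nn.gelu_array(x)


def bilinear_upsample(grid: np.ndarray, scale: float) -> np.ndarray:
    """Resample (B, C, H, W) (or (H, W)) by bilinear interpolation.

    Input and output corners are aligned, so grid points (u = v = 0)
    reproduce source pixels exactly and each output pixel is the
    four-neighbour weighted sum with weights (1-u)(1-v), u(1-v), v(1-u), uv.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    grid = np.asarray(grid, dtype=float)
    squeeze = grid.ndim == 2
    if squeeze:
        grid = grid[None, None]
    if grid.ndim != 4:
        raise ValueError("grid must be 2-D or (batch, channel, row, col)")
    h, w = grid.shape[2], grid.shape[3]
    ho, wo = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    lh = nn.interp_matrix(h, ho)
    lw = nn.interp_matrix(w, wo)
    out = lh @ grid @ lw.T
    return out[0, 0] if squeeze else out


def _bilinear_upsample_t(x: Tensor, scale: float) -> Tensor:
    h, w = x.shape[2], x.shape[3]
    ho, wo = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    lh = Tensor(nn.interp_matrix(h, ho, dtype=x.dtype))
    lwt = Tensor(nn.interp_matrix(w, wo, dtype=x.dtype).T)
    return lh @ x @ lwt


def _to_tokens_t(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, H*W, C), row-major token order."""
    b, c, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape(b, h * w, c)


def _to_grid_t(tokens: Tensor, grid_shape, channels: int) -> Tensor:
    b = tokens.shape[0]
    rows, cols = grid_shape
    return tokens.reshape(b, rows, cols, channels).transpose(0, 3, 1, 2)


class Tokenizer(Module):
    """Learned overlapped patch embedding: 3x3 windowed linear map.

    Maps a (B, C, H, W) grid to (H/stride)*(W/stride) tokens of width
    ``embed_dim``.  With stride 1, embed_dim = C and a centred identity
    kernel it is the plain flattening of the grid.
    """

    def __init__(self, in_ch: int, embed_dim: int, stride: int = 1, *, rng):
        super().__init__()
        self.stride = stride
        self.conv = self.add_child(
            "conv", Conv2d(in_ch, embed_dim, 3, stride=stride, pad=1, rng=rng)
        )

    def __call__(self, grid) -> TokenGrid:
        x = grid if isinstance(grid, Tensor) else Tensor(grid)
        h, w = x.shape[2], x.shape[3]
        if h % self.stride or w % self.stride:
            raise ValueError(
                f"spatial dims {h}x{w} not divisible by stride {self.stride}"
            )
        out = self.conv(x)
        rows, cols = out.shape[2], out.shape[3]
        tokens = _to_tokens_t(out)
        return TokenGrid(tokens=tokens, grid_shape=(rows, cols))


def tokenize(grid, weight, bias, stride: int = 1) -> TokenGrid:
    """Functional form of the learned tokenizer (NumPy in / out)."""
    with no_grad():
        x = Tensor(np.asarray(grid, dtype=np.float32))
        h, w = x.shape[2], x.shape[3]
        if h % stride or w % stride:
            raise ValueError(f"spatial dims {h}x{w} not divisible by stride {stride}")
        cols, (ho, wo) = x.im2col(3, stride, 1)
        wmat = np.asarray(weight).reshape(weight.shape[0], -1)
        out = np.matmul(wmat, cols.data) + np.asarray(bias)[None, :, None]
        tokens = out.reshape(x.shape[0], weight.shape[0], ho * wo).transpose(0, 2, 1)
    return TokenGrid(tokens=np.ascontiguousarray(tokens), grid_shape=(ho, wo))


def detokenize(tokens: TokenGrid) -> np.ndarray:
    """Rearrange a TokenGrid back to (batch, E, rows, cols)."""
    rows, cols = tokens.grid_shape
    t = np.asarray(tokens.tokens)
    b, n, e = t.shape
    if n != rows * cols:
        raise ValueError("grid_shape inconsistent with token count")
    return np.ascontiguousarray(t.reshape(b, rows, cols, e).transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class TokMLPBlock(Module):
    """Shifted tokenized-MLP block (resolution preserving).

    Width pass:   X -> Shift_W -> tokens T_W -> MLP1 -> DWConv (PE) -> GELU
    Height pass:  -> Shift_H -> tokens T_H -> GELU -> MLP2
                  -> + stage-entry tokens T -> LayerNorm -> GELU
    """

    def __init__(self, embed_dim: int, config: ModelConfig, *, rng):
        super().__init__()
        self.embed_dim = embed_dim
        self.hidden = max(1, int(round(config.mlp_ratio * embed_dim)))
        self.config = config
        self.mlp1 = self.add_child("mlp1", Linear(embed_dim, self.hidden, rng=rng))
        self.mlp2 = self.add_child("mlp2", Linear(self.hidden, embed_dim, rng=rng))
        self.norm = self.add_child("norm", LayerNorm(embed_dim))
        if config.use_pe:
            self.dwconv = self.add_child("dwconv", DWConv2d(self.hidden, rng=rng))
        else:
            self.dwconv = None

    def _maybe_shift(self, x: Tensor, axis: str) -> Tensor:
        if axis not in self.config.shift_axes:
            return x
        # On very small grids (deep bottleneck of small inputs) the nominal
        # offsets may reach the spatial extent; clamp them, sign preserved,
        # so the block stays total for every input the network accepts.
        extent = x.shape[3] if axis == "W" else x.shape[2]
        offsets = tuple(
            int(np.clip(o, -(extent - 1), extent - 1))
            for o in self.config.shift_offsets
        )
        return _axial_shift_t(x, axis, offsets, self.config.n_partitions)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        entry_tokens = _to_tokens_t(x)  # residual T
        # width pass
        xs = self._maybe_shift(x, "W")
        t_w = _to_tokens_t(xs)
        z = self.mlp1(t_w)
        if self.dwconv is not None:
            z = _to_tokens_t(self.dwconv(_to_grid_t(z, (h, w), self.hidden)))
        y = gelu_t(z)
        # height pass
        ys = self._maybe_shift(_to_grid_t(y, (h, w), self.hidden), "H")
        t_h = _to_tokens_t(ys)
        z2 = self.mlp2(gelu_t(t_h))
        out = gelu_t(self.norm(entry_tokens + z2))
        return _to_grid_t(out, (h, w), self.embed_dim)

    def macs(self, in_hw) -> int:
        n_tok = in_hw[0] * in_hw[1]
        total = n_tok * (self.mlp1.macs_per_token() + self.mlp2.macs_per_token())
        if self.dwconv is not None:
            total += self.dwconv.macs(in_hw)
        return total


class ConvBlock(Module):
    """3x3 conv -> BN -> ReLU plus a residual shortcut from the block input.

    The shortcut is the identity when channel counts match, a learned 1x1
    projection otherwise.  Encoder role appends 2x2 max pooling (and
    rejects odd spatial dims, which would misalign skip shapes); decoder
    role is used after x2 bilinear upsampling.
    """

    def __init__(self, in_ch: int, out_ch: int, role: str = "encoder", *, rng):
        super().__init__()
        if role not in ("encoder", "decoder"):
            raise ValueError("role must be 'encoder' or 'decoder'")
        self.role = role
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv = self.add_child("conv", Conv2d(in_ch, out_ch, 3, rng=rng))
        self.bn = self.add_child("bn", BatchNorm2d(out_ch))
        if in_ch != out_ch:
            self.proj = self.add_child(
                "proj", Conv2d(in_ch, out_ch, 1, pad=0, rng=rng)
            )
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if self.role == "encoder" and (h % 2 or w % 2):
            raise ValueError(
                f"encoder ConvBlock requires even spatial dims, got {h}x{w}"
            )
        out = self.bn(self.conv(x)).relu()
        short = self.proj(x) if self.proj is not None else x
        out = out + short
        if self.role == "encoder":
            out = out.maxpool2x2()
        return out

    def macs(self, in_hw) -> int:
        total = self.conv.macs(in_hw)
        if self.proj is not None:
            total += self.proj.macs(in_hw)
        return total


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class RMISNet(Module):
    """Five-stage encoder-decoder with a tokenized-MLP bottleneck."""

    DOWNSAMPLE_FACTOR = 32  # five successive halvings

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        c1, c2, c3, c4, c5 = config.channels
        cin = config.in_channels
        self.enc1 = self.add_child("enc1", ConvBlock(cin, c1, "encoder", rng=rng))
        self.enc2 = self.add_child("enc2", ConvBlock(c1, c2, "encoder", rng=rng))
        self.enc3 = self.add_child("enc3", ConvBlock(c2, c3, "encoder", rng=rng))
        if config.use_tok_mlp:
            s = config.token_stride
            self.embed4 = self.add_child("embed4", Tokenizer(c3, c4, s, rng=rng))
            self.block4 = self.add_child("block4", TokMLPBlock(c4, config, rng=rng))
            self.embed5 = self.add_child("embed5", Tokenizer(c4, c5, s, rng=rng))
            self.block5 = self.add_child("block5", TokMLPBlock(c5, config, rng=rng))
            self.dproj4 = self.add_child(
                "dproj4", Conv2d(c5, c4, 3, rng=rng)
            )
            self.dblock4 = self.add_child("dblock4", TokMLPBlock(c4, config, rng=rng))
            self.dproj3 = self.add_child(
                "dproj3", Conv2d(self._skip_in(c4), c3, 3, rng=rng)
            )
            self.dblock3 = self.add_child("dblock3", TokMLPBlock(c3, config, rng=rng))
        else:
            self.enc4 = self.add_child("enc4", ConvBlock(c3, c4, "encoder", rng=rng))
            self.enc5 = self.add_child("enc5", ConvBlock(c4, c5, "encoder", rng=rng))
            self.dec4 = self.add_child(
                "dec4", ConvBlock(c5, c4, "decoder", rng=rng)
            )
            self.dec3 = self.add_child(
                "dec3", ConvBlock(self._skip_in(c4), c3, "decoder", rng=rng)
            )
        self.dec2 = self.add_child(
            "dec2", ConvBlock(self._skip_in(c3), c2, "decoder", rng=rng)
        )
        self.dec1 = self.add_child(
            "dec1", ConvBlock(self._skip_in(c2), c1, "decoder", rng=rng)
        )
        self.dec0 = self.add_child(
            "dec0", ConvBlock(self._skip_in(c1), c1, "decoder", rng=rng)
        )
        self.head = self.add_child(
            "head", Conv2d(c1, config.num_classes, 1, pad=0, rng=rng)
        )

    def _skip_in(self, ch: int) -> int:
        return 2 * ch if self.config.skip_mode == "concat" else ch

    def _join(self, x: Tensor, skip: Tensor) -> Tensor:
        if self.config.skip_mode == "concat":
            return concat([x, skip], axis=1)
        return x + skip

    def _check_input(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        f = self.DOWNSAMPLE_FACTOR
        if h % f or w % f:
            raise ValueError(
                f"input spatial dims must be multiples of {f}, got {h}x{w}"
            )
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )

    def __call__(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        self._check_input(x)
        cfg = self.config
        c1, c2, c3, c4, c5 = cfg.channels
        s1 = self.enc1(x)
        s2 = self.enc2(s1)
        s3 = self.enc3(s2)
        if cfg.use_tok_mlp:
            tg4 = self.embed4(s3)
            s4 = self.block4(_to_grid_t(tg4.tokens, tg4.grid_shape, c4))
            tg5 = self.embed5(s4)
            b = self.block5(_to_grid_t(tg5.tokens, tg5.grid_shape, c5))
            d4 = self._join(
                self.dblock4(self.dproj4(_bilinear_upsample_t(b, 2.0))), s4
            )
            d3 = self._join(
                self.dblock3(self.dproj3(_bilinear_upsample_t(d4, 2.0))), s3
            )
        else:
            s4 = self.enc4(s3)
            b = self.enc5(s4)
            d4 = self._join(self.dec4(_bilinear_upsample_t(b, 2.0)), s4)
            d3 = self._join(self.dec3(_bilinear_upsample_t(d4, 2.0)), s3)
        d2 = self._join(self.dec2(_bilinear_upsample_t(d3, 2.0)), s2)
        d1 = self._join(self.dec1(_bilinear_upsample_t(d2, 2.0)), s1)
        d0 = self.dec0(_bilinear_upsample_t(d1, 2.0))
        return self.head(d0)

    forward = __call__

    # ---- analytic MAC walk (mirrors the forward graph) ---------------------
    def macs(self, input_hw: tuple[int, int]) -> int:
        cfg = self.config
        h, w = input_hw
        self_check = (h % self.DOWNSAMPLE_FACTOR, w % self.DOWNSAMPLE_FACTOR)
        if any(self_check):
            raise ValueError(
                f"input dims must be multiples of {self.DOWNSAMPLE_FACTOR}"
            )
        total = 0
        hw = (h, w)
        for blk in (self.enc1, self.enc2, self.enc3):
            total += blk.macs(hw)
            hw = (hw[0] // 2, hw[1] // 2)
        if cfg.use_tok_mlp:
            s = cfg.token_stride
            total += self.embed4.conv.macs(hw)
            hw4 = (hw[0] // s, hw[1] // s)
            total += self.block4.macs(hw4)
            total += self.embed5.conv.macs(hw4)
            hw5 = (hw4[0] // s, hw4[1] // s)
            total += self.block5.macs(hw5)
            total += self.dproj4.macs(hw4) + self.dblock4.macs(hw4)
            total += self.dproj3.macs(hw) + self.dblock3.macs(hw)
        else:
            total += self.enc4.macs(hw)
            hw4 = (hw[0] // 2, hw[1] // 2)
            total += self.enc5.macs(hw4)
            hw5 = (hw4[0] // 2, hw4[1] // 2)
            total += self.dec4.macs(hw4) + self.dec3.macs(hw)
        h3 = hw
        total += self.dec2.macs((h3[0] * 2, h3[1] * 2))
        total += self.dec1.macs((h3[0] * 4, h3[1] * 4))
        total += self.dec0.macs((h3[0] * 8, h3[1] * 8))
        total += self.head.macs((h3[0] * 8, h3[1] * 8))
        return int(total)

    # ---- weights IO --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={missing}, extra={extra}")
        for name, t in own.items():
            arr = np.asarray(state[name], dtype=t.data.dtype)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = arr.copy()
        # running statistics travel separately
        return self

    def norm_stats(self) -> dict[str, np.ndarray]:
        stats = {}
        def walk(mod, prefix):
            if isinstance(mod, BatchNorm2d):
                stats[prefix + "running_mean"] = mod.running_mean.copy()
                stats[prefix + "running_var"] = mod.running_var.copy()
            for name, child in mod._children.items():
                walk(child, prefix + name + ".")
        walk(self, "")
        return stats

    def load_norm_stats(self, stats: dict[str, np.ndarray]):
        def walk(mod, prefix):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.asarray(
                    stats[prefix + "running_mean"], dtype=np.float32
                ).copy()
                mod.running_var = np.asarray(
                    stats[prefix + "running_var"], dtype=np.float32
                ).copy()
            for name, child in mod._children.items():
                walk(child, prefix + name + ".")
        walk(self, "")
        return self


def build_model(config: ModelConfig, seed: int = 0) -> RMISNet:
    """Construct the network (or an ablation variant) from its config."""
    return RMISNet(config, seed=seed)


def save_checkpoint(model: RMISNet, path):
    """Weights + exact config + norm running stats; round-trips bit-exactly."""
    path = Path(path)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload.update({f"stat/{k}": v for k, v in model.norm_stats().items()})
    buf = io.BytesIO()
    np.savez(buf, **payload)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(model.config.to_dict(), indent=2)
    )


def load_checkpoint(path) -> RMISNet:
    path = Path(path)
    config = ModelConfig.from_dict(
        json.loads(path.with_suffix(path.suffix + ".json").read_text())
    )
    model = RMISNet(config, seed=0)
    with np.load(path) as data:
        params = {k[6:]: data[k] for k in data.files if k.startswith("param/")}
        stats = {k[5:]: data[k] for k in data.files if k.startswith("stat/")}
    model.load_state_dict(params)
    model.load_norm_stats(stats)
    return model
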