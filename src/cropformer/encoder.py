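"""The Cropformer encoder: a Transformer trunk with a convolution module
embedded downstream of the attention layer in every block.

Each timestep of an irregular series is embedded as the concatenation of a
sinusoidal day-of-year position encoding (temporal half first) and an affine
token embedding of its band reflectances.  A stack of blocks follows, each
applying — with three residual stages —

    x~ = x  + LN(MHA(x))
    x' = x~ + CM(x~)
    y  = x' + LN(FFN(x'))

where CM is LayerNorm -> repeated Crop Residual units -> Dropout, and each
Crop Residual unit is a depthwise-separable temporal convolution stack with
its own internal shortcut:

    CR(u) = u + PW2(BN(Swish(DW(GLU(PW1(u))))))

Attention logits at padded keys are forced to effectively -inf and all
convolutions see zeroed padding, so outputs at valid positions are invariant
to how much padding a batch carries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .data import Batch, ValidationError
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "position_encode",
    "MultiHeadAttention",
    "CropResidual",
    "ConvModule",
    "FeedForward",
    "CropformerBlock",
    "CropformerEncoder",
    "EncoderWeights",
    "save_checkpoint",
    "load_checkpoint",
    "SMALL_PROFILE",
]

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-size network: 3 blocks, 8 heads, width 256
    (128 spectral + 128 temporal), FFN width 1024, width-7 depthwise
    temporal convolutions with 2 Crop Residual units per block.
    """

    n_bands: int = 4
    d_spec: int = 128
    d_time: int = 128
    n_blocks: int = 3
    n_heads: int = 8
    d_ffn: int = 1024
    kernel_size: int = 7
    conv_padding: int = 3
    conv_stride: int = 1
    n_crop_residual: int = 2
    dropout: float = 0.1
    pe_base: float = 10000.0
    attn_scale_mode: str = "head_dim"   # or "model_dim"
    pe_mode: str = "concat"             # or "additive"

    def __post_init__(self):
        if self.pe_mode not in ("concat", "additive"):
            raise ValidationError("pe_mode must be 'concat' or 'additive'")
        if self.pe_mode == "additive" and self.d_spec != self.d_time:
            raise ValidationError("additive position encoding needs d_spec == d_time")
        if self.d_time % 2 != 0:
            raise ValidationError("d_time must be even")
        if self.d_model % self.n_heads != 0:
            raise ValidationError("d_model must be divisible by n_heads")
        if self.kernel_size % 2 != 1:
            raise ValidationError("kernel_size must be odd")
        if self.conv_stride != 1 or self.conv_padding != (self.kernel_size - 1) // 2:
            raise ValidationError("convolution must be length-preserving "
                                  "(stride 1, padding (kernel_size-1)/2)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.attn_scale_mode not in ("head_dim", "model_dim"):
            raise ValidationError("attn_scale_mode must be 'head_dim' or 'model_dim'")

    @property
    def d_model(self) -> int:
        if self.pe_mode == "additive":
            return self.d_spec
        return self.d_spec + self.d_time


#: Desk-scale profile for CPU runs: one block, width 32, 4 heads.
SMALL_PROFILE = ModelConfig(d_spec=16, d_time=16, n_blocks=1, n_heads=4,
                            d_ffn=64, n_crop_residual=2)


def position_encode(doy: np.ndarray, d_time: int, pe_base: float = 10000.0) -> np.ndarray:
    """Sinusoidal encoding of day-of-year stamps.

    Entry ``(i, 2k)`` is ``sin(doy_i / pe_base**(2k/d_time))`` and
    ``(i, 2k+1)`` the matching cosine; parameter-free and deterministic.
    Accepts any leading shape; appends an axis of size ``d_time``.
    """
    if d_time % 2 != 0:
        raise ValidationError("d_time must be even")
    doy = np.asarray(doy, dtype=np.float64)
    k = np.arange(d_time // 2)
    freq = pe_base ** (2.0 * k / d_time)          # (d_time/2,)
    arg = doy[..., None] / freq                   # (..., d_time/2)
    out = np.empty(doy.shape + (d_time,))
    out[..., 0::2] = np.sin(arg)
    out[..., 1::2] = np.cos(arg)
    return out


class MultiHeadAttention(nn.Module):
    """Scaled dot-product attention over timesteps, with key padding mask.

    Per head: ``softmax(L1(x) L2(x)^T / scale) L3(x)``; heads are
    concatenated and output-projected.  ``scale`` is sqrt(head width) by
    default, or sqrt(model width) when ``attn_scale_mode='model_dim'``.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.n_heads = config.n_heads
        self.d_head = d // config.n_heads
        self.scale = np.sqrt(self.d_head if config.attn_scale_mode == "head_dim" else d)
        self.l1 = nn.Linear(d, d, rng)   # query
        self.l2 = nn.Linear(d, d, rng)   # key
        self.l3 = nn.Linear(d, d, rng)   # value
        self.out = nn.Linear(d, d, rng)

    def _weights(self, x: Tensor, valid_mask: np.ndarray) -> Tensor:
        n, T, d = x.shape
        if not np.all(valid_mask.sum(axis=1) >= 1):
            raise ValidationError("a sample has no valid key positions")

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(n, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k = split_heads(self.l1(x)), split_heads(self.l2(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / self.scale)  # n,h,T,T
        key_mask = valid_mask[:, None, None, :]
        # -1e30 underflows to exactly zero weight after the stable softmax
        logits = nn.where(key_mask, logits, Tensor(np.full(logits.shape, -1e30)))
        return nn.softmax(logits, axis=-1)

    def attention_weights(self, x: Tensor, valid_mask: np.ndarray) -> np.ndarray:
        """Attention weight array (n, heads, T_query, T_key) for inspection."""
        return self._weights(x, valid_mask).data

    def __call__(self, x: Tensor, valid_mask: np.ndarray) -> Tensor:
        n, T, d = x.shape
        attn = self._weights(x, valid_mask)
        v = self.l3(x).reshape(n, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        ctx = attn @ v                                    # n,h,T,dh
        ctx = ctx.transpose(0, 2, 1, 3).reshape(n, T, d)
        return self.out(ctx)


class CropResidual(nn.Module):
    """Depthwise-separable convolution unit with an internal shortcut.

    Pointwise expansion to twice the width, GLU gate back down, depthwise
    temporal convolution, Swish, batch norm (over valid positions only),
    pointwise projection, plus the input.  Padding is zeroed before and
    after the depthwise convolution so it never leaks into valid positions.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.pw1 = nn.Linear(d, 2 * d, rng)
        self.dw = nn.DepthwiseConv1d(d, config.kernel_size, config.conv_padding, rng)
        self.bn = nn.MaskedBatchNorm(d)
        self.pw2 = nn.Linear(d, d, rng)

    def __call__(self, u: Tensor, valid_mask: np.ndarray) -> Tensor:
        m = Tensor(valid_mask[:, :, None].astype(float))
        v = nn.glu(self.pw1(u))
        v = self.dw(v * m) * m
        v = self.bn(nn.swish(v), valid_mask)
        return u + self.pw2(v)


class ConvModule(nn.Module):
    """LayerNorm -> n Crop Residual units -> Dropout."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.ln = nn.LayerNorm(config.d_model)
        self.crs = nn.ModuleList(
            [CropResidual(config, rng) for _ in range(config.n_crop_residual)]
        )
        self.drop = nn.Dropout(config.dropout)

    def __call__(self, x: Tensor, valid_mask: np.ndarray) -> Tensor:
        h = self.ln(x)
        for cr in self.crs:
            h = cr(h, valid_mask)
        return self.drop(h)


class FeedForward(nn.Module):
    """Position-wise two-layer perceptron, width d_model -> d_ffn -> d_model."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.lin1 = nn.Linear(config.d_model, config.d_ffn, rng)
        self.lin2 = nn.Linear(config.d_ffn, config.d_model, rng)
        self.drop = nn.Dropout(config.dropout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.drop(nn.swish(self.lin1(x))))


class CropformerBlock(nn.Module):
    """Attention + convolution + feed-forward with three residual stages."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadAttention(config, rng)
        self.ln_attn = nn.LayerNorm(config.d_model)
        self.cm = ConvModule(config, rng)
        self.ffn = FeedForward(config, rng)
        self.ln_ffn = nn.LayerNorm(config.d_model)
        self.drop = nn.Dropout(config.dropout)

    def __call__(self, x: Tensor, valid_mask: np.ndarray) -> Tensor:
        x1 = x + self.ln_attn(self.drop(self.mha(x, valid_mask)))
        x2 = x1 + self.cm(x1, valid_mask)
        return x2 + self.ln_ffn(self.ffn(x2))


class CropformerEncoder(nn.Module):
    """Embedding plus a stack of Cropformer blocks.

    The parameter count depends only on the configuration, never on the
    sequence length: the temporal coordinate enters through the
    parameter-free position encoding.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.token = nn.Linear(config.n_bands, config.d_spec, rng)
        self.blocks = nn.ModuleList(
            [CropformerBlock(config, rng) for _ in range(config.n_blocks)]
        )

    def seed_dropout(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng

    def embed(self, batch: Batch) -> Tensor:
        """Per-timestep joint embedding: Concat(position, token) rows."""
        cfg = self.config
        if batch.spectra.shape[2] != cfg.n_bands:
            raise ValidationError(
                f"batch has {batch.spectra.shape[2]} bands, model expects {cfg.n_bands}"
            )
        pe = Tensor(position_encode(batch.doy, cfg.d_time, cfg.pe_base))
        s = self.token(Tensor(batch.spectra))
        if cfg.pe_mode == "additive":
            return s + pe
        return nn.concat([pe, s], axis=-1)

    def __call__(self, batch: Batch) -> Tensor:
        x = self.embed(batch)
        for block in self.blocks:
            x = block(x, batch.valid_mask)
        return x


@dataclass
class EncoderWeights:
    """Serialized encoder parameters with their configuration."""

    state: dict[str, np.ndarray]
    config: ModelConfig
    format_version: str = FORMAT_VERSION

    @classmethod
    def from_encoder(cls, enc: CropformerEncoder) -> "EncoderWeights":
        return cls(state=enc.state_dict(), config=enc.config)

    def build(self) -> CropformerEncoder:
        enc = CropformerEncoder(self.config, np.random.default_rng(0))
        enc.load_state_dict(self.state)
        return enc


def _normalize_ckpt_path(path: str | Path) -> Path:
    path = Path(path)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def save_checkpoint(weights: EncoderWeights, path: str | Path,
                    extra_state: Optional[dict[str, np.ndarray]] = None,
                    extra_meta: Optional[dict] = None) -> None:
    """Write a parameter archive (.npz) plus a JSON config sidecar."""
    path = _normalize_ckpt_path(path)
    state = dict(weights.state)
    if extra_state:
        state.update({f"extra.{k}": v for k, v in extra_state.items()})
    np.savez(path, **state)
    meta = {"format_version": weights.format_version,
            "config": asdict(weights.config)}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> tuple[EncoderWeights, dict[str, np.ndarray], dict]:
    """Read a checkpoint; returns (weights, extra arrays, metadata)."""
    path = _normalize_ckpt_path(path)
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["format_version"] != FORMAT_VERSION:
        raise ValidationError(f"unsupported checkpoint version {meta['format_version']}")
    config = ModelConfig(**meta["config"])
    state = {k: v for k, v in arrays.items() if not k.startswith("extra.")}
    extra = {k[len("extra."):]: v for k, v in arrays.items() if k.startswith("extra.")}
    return EncoderWeights(state=state, config=config), extra, meta
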