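"""Model variants for paired (object, condition) data.

Four variants share one latent geometry. The bidirectional model (``biaae``)
encodes each view into an exclusive code plus a shared code,
``(z_x, s_x) = E_x(x)`` and ``(z_y, s_y) = E_y(y)``, decodes each view from
its exclusive code and a shared code, and uses three discriminators: one
pushing the triple (z_x, s, z_y) toward an independent standard-normal
prior, and two scoring whether an exclusive code of one view carries
information about the other view. The unidirectional model (``uniaae``)
drops s_x and reuses s_y everywhere s_x would appear. The supervised AAE
(``saae``) has a single latent code with the raw condition fed to the
decoder; its latent variant (``latent_saae``) feeds an autoencoded condition
code instead.

All encoders and decoders are deterministic; the prior is fixed at N(0, I).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .autograd import Tensor, concat

__all__ = [
    "ArchSpec", "ModelConfig", "ConditionEncoderConfig", "LatentPartition",
    "PairedAAE", "ConditionEncoder", "ConditionDecoder",
    "SmilesEncoder", "SmilesDecoder", "build_model",
    "save_checkpoint", "load_checkpoint", "VARIANTS",
]

VARIANTS = ("saae", "latent_saae", "uniaae", "biaae")

_CHECKPOINT_VERSION = "biaae-ckpt-1"


class InputError(ValueError):
    """Raised when an input's shape does not match the model configuration."""


@dataclasses.dataclass(frozen=True)
class ArchSpec:
    """MLP architecture descriptor: hidden widths and layer options."""

    hidden: tuple[int, ...] = (128, 64)
    activation: str = "leaky_relu"
    batchnorm: bool = False
    dropout: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        d["hidden"] = tuple(d["hidden"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    variant: str = "biaae"
    x_dim: int = 16
    y_dim: int = 16
    dim_zx: int = 12
    dim_s: int = 4
    dim_zy: int = 12
    encoder_arch: ArchSpec = ArchSpec()
    decoder_arch: ArchSpec = ArchSpec()
    discriminator_arch: ArchSpec = ArchSpec(hidden=(128, 64))
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if min(self.dim_zx, self.dim_s, self.dim_zy, self.x_dim, self.y_dim) < 1:
            raise ValueError("all dimensions must be >= 1")

    @property
    def triple_dim(self) -> int:
        return self.dim_zx + self.dim_s + self.dim_zy

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("encoder_arch", "decoder_arch", "discriminator_arch"):
            d[key] = ArchSpec.from_dict(d[key])
        return cls(**d)


@dataclasses.dataclass
class LatentPartition:
    """The (z_x, s, z_y) triple with both shared variants.

    Wherever a discriminator consumes a triple the concatenation order is
    fixed as (z_x, s, z_y).
    """

    z_x: Tensor
    s_x: Optional[Tensor]
    z_y: Tensor
    s_y: Tensor

    def triple(self, shared: Tensor) -> Tensor:
        return concat([self.z_x, shared, self.z_y], axis=1)


def _as_tensor(view) -> Tensor:
    if isinstance(view, Tensor):
        return view
    arr = np.asarray(view, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    elif arr.ndim == 3:  # batch of images
        arr = arr.reshape(arr.shape[0], -1)
    elif arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        # ambiguous; treat as batch of vectors (images must be 3-D batches)
        pass
    return Tensor(arr)


def _build_mlp(in_dim, out_dim, arch: ArchSpec, rng) -> nn.Sequential:
    return nn.mlp(
        in_dim, list(arch.hidden), out_dim, rng,
        activation=arch.activation, batchnorm=arch.batchnorm,
        dropout=arch.dropout,
    )


class Discriminator(nn.Module):
    """Per-row sigmoid score in (0, 1) on a latent (z_x, s, z_y) triple.

    Losses consume ``logit`` (pre-sigmoid score) through stable log-sigmoid
    so gradients survive even when the discriminator saturates.
    """

    def __init__(self, in_dim: int, arch: ArchSpec, rng):
        super().__init__()
        self.net = _build_mlp(in_dim, 1, arch, rng)

    def logit(self, triple: Tensor) -> Tensor:
        return self.net(triple)

    def forward(self, triple: Tensor) -> Tensor:
        return self.net(triple).sigmoid()


class PairedAAE(nn.Module):
    """Dense-view model covering all four variants.

    ``encode_x`` returns (z_x, s_x); for the unidirectional and supervised
    variants ``s_x`` is ``None`` (no shared code is extracted from x; the
    supervised variants treat the whole code as z_x).
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        v = c.variant
        x_code = c.dim_zx + (c.dim_s if v == "biaae" else 0)
        if v in ("saae", "latent_saae"):
            x_code = c.dim_zx + c.dim_s  # single undivided latent z
        self.encoder_x = _build_mlp(c.x_dim, x_code, c.encoder_arch, rng)
        if v == "saae":
            self.encoder_y = None
            dec_in = x_code + c.y_dim  # condition fed raw to the decoder
        elif v == "latent_saae":
            self.encoder_y = _build_mlp(c.y_dim, c.dim_s, c.encoder_arch, rng)
            self.decoder_y = _build_mlp(c.dim_s, c.y_dim, c.decoder_arch, rng)
            dec_in = x_code + c.dim_s
        else:
            self.encoder_y = _build_mlp(c.y_dim, c.dim_zy + c.dim_s, c.encoder_arch, rng)
            self.decoder_y = _build_mlp(c.dim_zy + c.dim_s, c.y_dim, c.decoder_arch, rng)
            dec_in = c.dim_zx + c.dim_s
        self.decoder_x = _build_mlp(dec_in, c.x_dim, c.decoder_arch, rng)
        if v in ("saae", "latent_saae"):
            self.d_prior = Discriminator(x_code, c.discriminator_arch, rng)
            self.d_info_x = self.d_info_y = None
        else:
            self.d_prior = Discriminator(c.triple_dim, c.discriminator_arch, rng)
            self.d_info_x = Discriminator(c.triple_dim, c.discriminator_arch, rng)
            self.d_info_y = Discriminator(c.triple_dim, c.discriminator_arch, rng)

    # -- encoding -------------------------------------------------------------
    def encode_x(self, x) -> tuple[Tensor, Optional[Tensor]]:
        x = _as_tensor(x)
        if x.shape[1] != self.config.x_dim:
            raise InputError(f"x has width {x.shape[1]}, expected {self.config.x_dim}")
        code = self.encoder_x(x)
        if self.config.variant == "biaae":
            return code[:, : self.config.dim_zx], code[:, self.config.dim_zx:]
        return code, None

    def encode_y(self, y) -> tuple[Optional[Tensor], Tensor]:
        if self.encoder_y is None:
            raise InputError("saae variant has no condition encoder")
        y = _as_tensor(y)
        if y.shape[1] != self.config.y_dim:
            raise InputError(f"y has width {y.shape[1]}, expected {self.config.y_dim}")
        code = self.encoder_y(y)
        if self.config.variant == "latent_saae":
            return None, code
        return code[:, : self.config.dim_zy], code[:, self.config.dim_zy:]

    # -- decoding -------------------------------------------------------------
    def decode_x(self, z_x: Tensor, s_or_y: Tensor) -> Tensor:
        return self.decoder_x(concat([z_x, s_or_y], axis=1))

    def decode_y(self, z_y: Optional[Tensor], s: Tensor) -> Tensor:
        if self.config.variant == "latent_saae":
            return self.decoder_y(s)
        return self.decoder_y(concat([z_y, s], axis=1))

    def partition(self, x, y) -> LatentPartition:
        """Encode both views (biaae/uniaae only)."""
        if self.config.variant not in ("biaae", "uniaae"):
            raise InputError("partition requires a biaae or uniaae model")
        z_x, s_x = self.encode_x(x)
        z_y, s_y = self.encode_y(y)
        return LatentPartition(z_x=z_x, s_x=s_x, z_y=z_y, s_y=s_y)

    # -- submodule groups for alternating optimization -------------------------
    def generator_modules(self) -> list[nn.Module]:
        mods = [self.encoder_x, self.decoder_x]
        if self.encoder_y is not None:
            mods.append(self.encoder_y)
        if getattr(self, "decoder_y", None) is not None:
            mods.append(self.decoder_y)
        return mods

    def discriminator_modules(self) -> list[nn.Module]:
        return [d for d in (self.d_prior, self.d_info_x, self.d_info_y) if d is not None]

    def generator_parameters(self):
        return [p for m in self.generator_modules() for p in m.parameters()]

    def discriminator_parameters(self):
        return [p for m in self.discriminator_modules() for p in m.parameters()]


# -- expression condition branch -------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConditionEncoderConfig:
    """Two-stage encoder for (Δge, η): embed the 978-gene difference, then
    concatenate the log10-molar dose and finish with a small head emitting
    (z_y, s_y)."""

    expr_dim: int = 978
    embed_hidden: tuple[int, ...] = (256,)
    embed_out: int = 128
    head_hidden: tuple[int, ...] = (128,)
    dim_zy: int = 10
    dim_s: int = 10
    batchnorm: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionEncoderConfig":
        d = dict(d)
        d["embed_hidden"] = tuple(d["embed_hidden"])
        d["head_hidden"] = tuple(d["head_hidden"])
        return cls(**d)


class ConditionEncoder(nn.Module):
    """E_y for expression conditions; the dose enters after the embedding,
    so the head input width is embed_out + 1."""

    def __init__(self, config: ConditionEncoderConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        arch = ArchSpec(hidden=config.embed_hidden, batchnorm=config.batchnorm)
        self.embed = _build_mlp(config.expr_dim, config.embed_out, arch, rng)
        head_arch = ArchSpec(hidden=config.head_hidden, batchnorm=config.batchnorm)
        self.head = _build_mlp(config.embed_out + 1, config.dim_zy + config.dim_s, head_arch, rng)

    def forward(self, delta, eta) -> tuple[Tensor, Tensor]:
        delta = _as_tensor(delta)
        if delta.shape[1] != self.config.expr_dim:
            raise InputError(f"expression width {delta.shape[1]}, expected {self.config.expr_dim}")
        if eta is None:
            raise InputError("condition encoder expects a dose (log10 molar)")
        eta_arr = np.atleast_1d(np.asarray(eta, dtype=np.float64)).reshape(-1, 1)
        if eta_arr.shape[0] != delta.shape[0]:
            raise InputError("dose vector length must match batch size")
        emb = self.embed(delta)
        code = self.head(concat([emb, Tensor(eta_arr)], axis=1))
        return code[:, : self.config.dim_zy], code[:, self.config.dim_zy:]


class ConditionDecoder(nn.Module):
    """G_y for expression conditions, mirrored: decode (z_y, s) to an
    embedding, split off the dose, and expand back to Δge."""

    def __init__(self, config: ConditionEncoderConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(1)
        head_arch = ArchSpec(hidden=config.head_hidden, batchnorm=False)
        self.head = _build_mlp(config.dim_zy + config.dim_s, config.embed_out + 1, head_arch, rng)
        arch = ArchSpec(hidden=config.embed_hidden[::-1], batchnorm=False)
        self.expand = _build_mlp(config.embed_out, config.expr_dim, arch, rng)

    def forward(self, z_y: Tensor, s: Tensor) -> tuple[Tensor, Tensor]:
        out = self.head(concat([z_y, s], axis=1))
        emb, eta = out[:, :-1], out[:, -1:]
        return self.expand(emb), eta


# -- SMILES sequence branch ------------------------------------------------------

class SmilesEncoder(nn.Module):
    """Character-level GRU encoder: token ids -> (z_x, s_x)."""

    def __init__(self, vocab_size: int, dim_zx: int, dim_s: int,
                 hidden_size: int = 128, num_layers: int = 2,
                 embed_dim: int = 32, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.embedding = nn.Embedding(vocab_size, embed_dim, rng)
        self.gru = nn.GRU(embed_dim, hidden_size, num_layers, rng)
        self.out = nn.Linear(hidden_size, dim_zx + dim_s, rng)
        self.dim_zx = dim_zx
        self.dim_s = dim_s

    def forward(self, token_ids: np.ndarray) -> tuple[Tensor, Tensor]:
        """token_ids: (batch, time) int array, padded."""
        token_ids = np.asarray(token_ids)
        inputs = [self.embedding(token_ids[:, t]) for t in range(token_ids.shape[1])]
        _, hs = self.gru(inputs)
        code = self.out(hs[-1])
        return code[:, : self.dim_zx], code[:, self.dim_zx:]


class SmilesDecoder(nn.Module):
    """GRU decoder conditioned on (z_x, s) through its initial hidden state.

    ``logits`` runs teacher-forced and returns per-step log-probabilities;
    ``generate`` decodes greedily or by multinomial sampling with a
    temperature.
    """

    def __init__(self, vocab_size: int, dim_zx: int, dim_s: int,
                 hidden_size: int = 128, num_layers: int = 2,
                 embed_dim: int = 32, seed: int = 1):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.embedding = nn.Embedding(vocab_size, embed_dim, rng)
        self.gru = nn.GRU(embed_dim, hidden_size, num_layers, rng)
        self.init_hidden = [
            nn.Linear(dim_zx + dim_s, hidden_size, rng) for _ in range(num_layers)
        ]
        self.out = nn.Linear(hidden_size, vocab_size, rng)
        self.vocab_size = vocab_size

    def _h0(self, latent: Tensor) -> list[Tensor]:
        return [lin(latent).tanh() for lin in self.init_hidden]

    def logits(self, z_x: Tensor, s: Tensor, token_ids: np.ndarray) -> Tensor:
        """Teacher-forced log-softmax scores, shape (time-1, batch, vocab):
        step t predicts token t+1 from tokens ≤ t."""
        from .autograd import stack
        token_ids = np.asarray(token_ids)
        latent = concat([z_x, s], axis=1)
        inputs = [self.embedding(token_ids[:, t]) for t in range(token_ids.shape[1] - 1)]
        outputs, _ = self.gru(inputs, self._h0(latent))
        rows = [self.out(o).log_softmax(axis=-1) for o in outputs]
        return stack(rows, axis=0)

    def generate(self, z_x: Tensor, s: Tensor, start_id: int, end_id: int,
                 max_len: int = 120, mode: str = "greedy",
                 temperature: float = 1.0, rng=None) -> list[list[int]]:
        """Decode token-id sequences (without start/end tokens)."""
        from .autograd import no_grad
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        rng = rng if rng is not None else np.random.default_rng(0)
        latent = concat([z_x, s], axis=1)
        batch = latent.shape[0]
        with no_grad():
            hs = self._h0(latent)
            tokens = np.full(batch, start_id, dtype=int)
            done = np.zeros(batch, dtype=bool)
            sequences: list[list[int]] = [[] for _ in range(batch)]
            for _ in range(max_len):
                x = self.embedding(tokens)
                for layer, cell in enumerate(self.gru.cells):
                    hs[layer] = cell(x, hs[layer])
                    x = hs[layer]
                logits = self.out(x).data
                if mode == "greedy":
                    nxt = logits.argmax(axis=1)
                else:
                    scaled = logits / temperature
                    scaled -= scaled.max(axis=1, keepdims=True)
                    probs = np.exp(scaled)
                    probs /= probs.sum(axis=1, keepdims=True)
                    nxt = np.array([rng.choice(self.vocab_size, p=p) for p in probs])
                for i in range(batch):
                    if not done[i]:
                        if nxt[i] == end_id:
                            done[i] = True
                        else:
                            sequences[i].append(int(nxt[i]))
                tokens = nxt
                if done.all():
                    break
        return sequences


class MolecularBiAAE(nn.Module):
    """Bidirectional model over (SMILES molecule, expression condition) pairs.

    Groups a sequence encoder/decoder for the molecule view with the
    dose-aware condition encoder/decoder and the three discriminators. The
    latent geometry matches the dense model: (z_x, s_x) from the molecule,
    (z_y, s_y) from the condition.
    """

    def __init__(self, vocab_size: int, cond_config: ConditionEncoderConfig,
                 dim_zx: int = 10, hidden_size: int = 128, num_layers: int = 2,
                 discriminator_arch: ArchSpec = ArchSpec(hidden=(128, 64)),
                 seed: int = 0):
        super().__init__()
        dim_s = cond_config.dim_s
        rng = np.random.default_rng(seed)
        self.encoder_x = SmilesEncoder(vocab_size, dim_zx, dim_s,
                                       hidden_size, num_layers, seed=seed)
        self.decoder_x = SmilesDecoder(vocab_size, dim_zx, dim_s,
                                       hidden_size, num_layers, seed=seed + 1)
        self.encoder_y = ConditionEncoder(cond_config, rng)
        self.decoder_y = ConditionDecoder(cond_config, rng)
        triple = dim_zx + dim_s + cond_config.dim_zy
        self.d_prior = Discriminator(triple, discriminator_arch, rng)
        self.d_info_x = Discriminator(triple, discriminator_arch, rng)
        self.d_info_y = Discriminator(triple, discriminator_arch, rng)
        self.dim_zx, self.dim_s, self.dim_zy = dim_zx, dim_s, cond_config.dim_zy

    def encode_x(self, token_batch) -> tuple[Tensor, Tensor]:
        return self.encoder_x(token_batch)

    def encode_y(self, delta, eta) -> tuple[Tensor, Tensor]:
        return self.encoder_y(delta, eta)

    def load_pretrained_molecular_branch(self, encoder: "SmilesEncoder",
                                         decoder: "SmilesDecoder") -> None:
        """Copy pretrained sequence-autoencoder weights into the molecular
        branch only; all other parameters are untouched."""
        for target, source in ((self.encoder_x, encoder), (self.decoder_x, decoder)):
            t_params, s_params = target.parameters(), source.parameters()
            if len(t_params) != len(s_params) or any(
                    t.data.shape != s.data.shape for t, s in zip(t_params, s_params)):
                raise ValueError("pretrained branch does not match model dimensions")
            for t, s in zip(t_params, s_params):
                t.data = s.data.copy()


# -- construction and checkpointing ----------------------------------------------

def build_model(config: ModelConfig) -> PairedAAE:
    """Instantiate a dense-view model from its configuration."""
    return PairedAAE(config)


def save_checkpoint(model: nn.Module, path, config=None, extra: dict | None = None) -> None:
    """One-archive checkpoint: weights + config + format version."""
    path = Path(path)
    meta = {
        "version": _CHECKPOINT_VERSION,
        "config": config.to_dict() if config is not None else
                  (model.config.to_dict() if hasattr(model, "config") else None),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[PairedAAE, dict]:
    """Rebuild a PairedAAE from a checkpoint; validates dimensions."""
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
    config = ModelConfig.from_dict(meta["config"])
    model = build_model(config)
    model.load_state_dict(state)  # shape mismatches raise here
    return model, meta
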