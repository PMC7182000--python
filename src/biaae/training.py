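"""Alternating minimax training loop with seeding, checkpointing and logging.

Each step performs (i) a discriminator ascent on the adversarial objectives
with the encoder outputs detached, then (ii) an encoder/decoder descent on
the full weighted objective with the discriminator weights frozen, so that
neither phase routes gradient into the other's parameters. Prior samples and
batch shuffles are redrawn every step from the run's own generator, making a
run a pure function of (model init, dataset, config seed).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import chem, nn, objectives
from .autograd import Tensor, no_grad
from .models import (LatentPartition, PairedAAE, SmilesDecoder, SmilesEncoder,
                     save_checkpoint)
from .objectives import BatchLosses, LossWeights
from .synthetic import PairedSample

__all__ = ["TrainConfig", "TrainingState", "train", "pretrain_autoencoder",
           "SmilesAutoencoder"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 3e-4
    adam_betas_adversarial: tuple[float, float] = (0.5, 0.9)
    adam_betas_plain: tuple[float, float] = (0.99, 0.999)
    disc_updates_per_ae_update: int = 1
    disc_learning_rate: Optional[float] = None   # None -> learning_rate
    # Polyak tail-averaging of encoder/decoder weights, applied at the end of
    # the run; damps the oscillation of the adversarial equilibrium. None
    # disables it.
    generator_ema_decay: Optional[float] = None
    epochs: int = 10
    seed: int = 0
    weights: LossWeights = LossWeights()
    checkpoint_every: int = 0        # steps; 0 disables periodic checkpoints
    keep_checkpoints: int = 2
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch shuffles)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")
        for beta in (*self.adam_betas_adversarial, *self.adam_betas_plain):
            if not 0.0 < beta < 1.0:
                raise ValueError("Adam betas must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class TrainingState:
    step: int = 0
    history: list[dict] = dataclasses.field(default_factory=list)
    rng_state: Optional[dict] = None

    def log_row(self, losses: dict[str, float]) -> None:
        self.history.append({"step": self.step, **losses})


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        x, y = dataset
    else:
        samples: Sequence[PairedSample] = dataset
        if len(samples) == 0:
            raise ValueError("dataset is empty")
        x = np.stack([s.x for s in samples])
        y = np.stack([s.y for s in samples])
    x = np.asarray(x, dtype=np.float64).reshape(len(x), -1)
    y = np.asarray(y, dtype=np.float64).reshape(len(y), -1)
    return x, y


def _detached(partition: LatentPartition) -> LatentPartition:
    return LatentPartition(
        z_x=partition.z_x.detach(),
        s_x=partition.s_x.detach() if partition.s_x is not None else None,
        z_y=partition.z_y.detach(),
        s_y=partition.s_y.detach(),
    )


def _write_log(history: list[dict], path: Path) -> None:
    if not history:
        return
    fields = list(history[0].keys())
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(history)


def train(model: PairedAAE, dataset, config: TrainConfig,
          state: TrainingState | None = None) -> tuple[PairedAAE, TrainingState]:
    """Run alternating minimax training; returns the model and its state.

    Aborts with :class:`FloatingPointError` naming the offending term if any
    loss becomes non-finite.
    """
    x_all, y_all = _as_arrays(dataset)
    n = len(x_all)
    state = state or TrainingState()
    if state.rng_state is not None:
        rng = np.random.default_rng()
        rng.bit_generator.state = state.rng_state
    else:
        rng = np.random.default_rng(config.seed)
    weights = config.weights

    opt_eg = nn.Adam(model.generator_parameters(), lr=config.learning_rate,
                     betas=config.adam_betas_adversarial)
    opt_d = nn.Adam(model.discriminator_parameters(),
                    lr=config.disc_learning_rate or config.learning_rate,
                    betas=config.adam_betas_adversarial)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    checkpoints: list[Path] = []
    gen_params = model.generator_parameters()
    ema = ([p.data.copy() for p in gen_params]
           if config.generator_ema_decay else None)

    model.train()
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start: start + config.batch_size]
            x, y = x_all[idx], y_all[idx]

            # (i) discriminator ascent on detached latents
            for _ in range(config.disc_updates_per_ae_update):
                d_losses = _disc_step(model, x, y, weights, rng, opt_d)

            # (ii) encoder/decoder descent with discriminators frozen
            for d in model.discriminator_modules():
                d.requires_grad_(False)
            losses = objectives.total_objective(x, y, model, weights, rng)
            try:
                losses.assert_finite()
            except FloatingPointError as err:
                raise FloatingPointError(f"step {state.step}: {err}") from err
            opt_eg.zero_grad()
            losses.total.backward()
            opt_eg.step()
            for d in model.discriminator_modules():
                d.requires_grad_(True)
            if ema is not None:
                decay = config.generator_ema_decay
                for avg, p in zip(ema, gen_params):
                    avg *= decay
                    avg += (1 - decay) * p.data

            state.step += 1
            row = losses.values()
            row.update({f"d_{k}": v for k, v in d_losses.items()})
            state.log_row(row)

            if out_dir and config.checkpoint_every and \
                    state.step % config.checkpoint_every == 0:
                ckpt = out_dir / f"step{state.step:07d}.npz"
                save_checkpoint(model, ckpt)
                checkpoints.append(ckpt)
                while len(checkpoints) > config.keep_checkpoints:
                    checkpoints.pop(0).unlink(missing_ok=True)

    state.rng_state = rng.bit_generator.state
    if ema is not None:
        for avg, p in zip(ema, gen_params):
            p.data = avg.copy()
    model.eval()
    if out_dir:
        save_checkpoint(model, out_dir / "final.npz")
        _write_log(state.history, out_dir / "train_log.csv")
        (out_dir / "train_config.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=str))
    return model, state


def _disc_step(model: PairedAAE, x, y, weights: LossWeights,
               rng: np.random.Generator, opt_d: nn.Adam) -> dict[str, float]:
    variant = model.config.variant
    if variant in ("saae", "latent_saae"):
        with no_grad():
            z, _ = model.encode_x(x)
        z = Tensor(z.data)
        prior = Tensor(rng.standard_normal(z.shape))
        d_obj = (model.d_prior.logit(prior).log_sigmoid().mean()
                 + (-model.d_prior.logit(z)).log_sigmoid().mean())
        loss = -weights.lambda_adv * d_obj
        opt_d.zero_grad()
        loss.backward()
        opt_d.step()
        return {"adv": float(d_obj.data)}
    with no_grad():
        part = model.partition(x, y)
    part = _detached(part)
    prior = Tensor(rng.standard_normal((part.z_x.shape[0], model.config.triple_dim)))
    adv_d, _ = objectives.adversarial_loss(part, prior, model.d_prior)
    perm = rng.permutation(part.z_x.shape[0])
    info_d, _ = objectives.info_loss(part, perm, model.d_info_x, model.d_info_y)
    loss = -(weights.lambda_adv * adv_d + weights.lambda_info * info_d)
    if not np.isfinite(float(loss.data)):
        raise FloatingPointError("non-finite discriminator objective")
    opt_d.zero_grad()
    loss.backward()
    opt_d.step()
    return {"adv": float(adv_d.data), "info": float(info_d.data)}


# -- SMILES autoencoder pretraining ------------------------------------------------

class SmilesAutoencoder(nn.Module):
    """Plain sequence autoencoder used to initialize a molecular branch."""

    def __init__(self, vocabulary: chem.SmilesVocabulary, dim_zx: int = 12,
                 dim_s: int = 4, hidden_size: int = 128, num_layers: int = 2,
                 seed: int = 0):
        super().__init__()
        self.vocabulary = vocabulary
        self.encoder = SmilesEncoder(len(vocabulary), dim_zx, dim_s,
                                     hidden_size, num_layers, seed=seed)
        self.decoder = SmilesDecoder(len(vocabulary), dim_zx, dim_s,
                                     hidden_size, num_layers, seed=seed + 1)

    def reconstruction_nll(self, token_batch: np.ndarray) -> Tensor:
        z, s = self.encoder(token_batch)
        log_probs = self.decoder.logits(z, s, token_batch)
        return objectives.seq_nll(log_probs, token_batch[:, 1:],
                                  self.vocabulary.pad_id)

    def token_accuracy(self, token_batch: np.ndarray) -> float:
        """Teacher-forced next-token accuracy over non-pad targets."""
        with no_grad():
            z, s = self.encoder(token_batch)
            log_probs = self.decoder.logits(z, s, token_batch)
        predictions = log_probs.data.argmax(axis=2).T  # (batch, time-1)
        targets = token_batch[:, 1:]
        mask = targets != self.vocabulary.pad_id
        return float((predictions[mask] == targets[mask]).mean())


def pretrain_autoencoder(smiles_list: Sequence[str], config: TrainConfig,
                         vocabulary: chem.SmilesVocabulary | None = None,
                         dim_zx: int = 12, dim_s: int = 4,
                         hidden_size: int = 128, num_layers: int = 2,
                         ) -> tuple[SmilesAutoencoder, TrainingState]:
    """Train a plain SMILES sequence autoencoder (reconstruction only).

    Uses the non-adversarial Adam betas. The returned module's encoder and
    decoder weights can initialize the molecular branch of any variant; a
    vocabulary mismatch at load time raises with the unknown tokens listed.
    """
    if len(smiles_list) == 0:
        raise ValueError("dataset is empty")
    vocabulary = vocabulary or chem.SmilesVocabulary.from_smiles(smiles_list)
    unknown: set[str] = set()
    token_ids = []
    for smiles in smiles_list:
        try:
            token_ids.append(vocabulary.tokenize(smiles))
        except chem.TokenizationError as err:
            unknown.add(str(err))
    if unknown:
        raise chem.TokenizationError(
            "vocabulary does not cover the dataset: " + "; ".join(sorted(unknown)))
    batch_all = vocabulary.pad_batch(token_ids)

    model = SmilesAutoencoder(vocabulary, dim_zx=dim_zx, dim_s=dim_s,
                              hidden_size=hidden_size, num_layers=num_layers,
                              seed=config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  betas=config.adam_betas_plain)
    rng = np.random.default_rng(config.seed)
    state = TrainingState()
    n = len(batch_all)
    bs = min(config.batch_size, n)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            if len(idx) < 1:
                continue
            nll = model.reconstruction_nll(batch_all[idx])
            if not np.isfinite(float(nll.data)):
                raise FloatingPointError(f"step {state.step}: non-finite rec_x NLL")
            opt.zero_grad()
            nll.backward()
            opt.step()
            state.step += 1
            state.log_row({"rec_x": float(nll.data)})
    model.eval()
    return model, state
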