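"""Loss terms of the adversarial-autoencoder family as pure functions.

Sign conventions
----------------
Discriminator objectives (``d_objective``) are values the discriminator
*maximizes*: expected log-scores of "real" inputs plus log-(1−score) of
"fake" inputs; they are ≤ 0 with supremum 0. Encoder/decoder ("generator")
counterparts are *losses to minimize* and use the non-saturating label-flip
form: instead of minimizing log(1−D(fake)) the generator maximizes
log D(fake).

Five terms make up the bidirectional objective:

* shared: batch-mean squared distance ‖s_x − s_y‖² pulling the two shared
  codes together;
* rec_x / rec_y: direct plus cross reconstruction, where the cross term
  decodes a view with the *other* view's shared code;
* adv: one discriminator telling encoder triples (z_x, s, z_y) from
  independent standard-normal triples — this both matches the prior and
  factorizes the three parts;
* info: two discriminators telling a genuine triple from one whose
  opposite-view exclusive code was shuffled within the batch, explicitly
  discouraging z of one view from carrying information about the other.

All log-scores are clamped at 1e-8 so every loss is finite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autograd import Tensor, concat
from .models import LatentPartition, PairedAAE

__all__ = [
    "LossWeights", "BatchLosses", "shared_loss", "mse_loss", "seq_nll",
    "reconstruction_losses", "adversarial_loss", "info_loss",
    "saae_objective", "latent_saae_objective", "total_objective",
]

_EPS = 1e-8


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """λ coefficients balancing the five objective terms.

    Defaults follow the image-benchmark profile (reconstruction 10,
    shared 0.1, adversarial and information terms 1). The unidirectional
    profile raises the information weight to 100.
    """

    lambda_shared: float = 0.1
    lambda_rec_x: float = 10.0
    lambda_rec_y: float = 10.0
    lambda_adv: float = 1.0
    lambda_info: float = 1.0

    def __post_init__(self):
        if min(dataclasses.astuple(self)) < 0:
            raise ValueError("loss weights must be nonnegative")

    @classmethod
    def uniaae_profile(cls) -> "LossWeights":
        return cls(lambda_info=100.0)


@dataclasses.dataclass
class BatchLosses:
    """Per-term losses on one batch.

    ``shared``/``rec_x``/``rec_y``/``adv``/``info``/``total`` are the
    encoder/decoder-side tensors (``total`` is the weighted sum to
    minimize); ``disc_adv``/``disc_info`` are the discriminator-side
    objectives to maximize.
    """

    shared: Tensor
    rec_x: Tensor
    rec_y: Tensor
    adv: Tensor
    info: Tensor
    total: Tensor
    disc_adv: Tensor
    disc_info: Tensor

    def values(self) -> dict[str, float]:
        return {name: float(getattr(self, name).data)
                for name in ("shared", "rec_x", "rec_y", "adv", "info",
                             "total", "disc_adv", "disc_info")}

    def assert_finite(self) -> None:
        for name, value in self.values().items():
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss term: {name} = {value}")


def _log_d(disc, t: Tensor) -> Tensor:
    """log D(t); via stable log-sigmoid of the logit when the discriminator
    exposes one, else a clamped log of the probability (constant oracles)."""
    if hasattr(disc, "logit"):
        return disc.logit(t).log_sigmoid()
    return disc(t).clamp_min(_EPS).log()


def _log_1md(disc, t: Tensor) -> Tensor:
    """log(1 − D(t)) = log σ(−logit)."""
    if hasattr(disc, "logit"):
        return (-disc.logit(t)).log_sigmoid()
    return (1.0 - disc(t)).clamp_min(_EPS).log()


def shared_loss(s_x: Tensor, s_y: Tensor) -> Tensor:
    """Batch mean of the squared Euclidean distance between shared codes."""
    if s_x.shape != s_y.shape:
        raise ValueError(f"shared codes differ in shape: {s_x.shape} vs {s_y.shape}")
    return (((s_x - s_y) ** 2).sum(axis=1)).mean()


def mse_loss(target, prediction: Tensor) -> Tensor:
    """Per-element squared error, averaged over batch and elements."""
    target = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float64))
    return ((prediction - target) ** 2).mean()


def seq_nll(log_probs: Tensor, targets: np.ndarray, pad_id: int) -> Tensor:
    """Teacher-forced per-token NLL averaged over non-pad target tokens.

    log_probs: (time, batch, vocab) log-softmax scores where step t predicts
    targets[:, t]; targets: (batch, time) int array.
    """
    targets = np.asarray(targets)
    time, batch, _ = log_probs.shape
    t_idx, b_idx = np.meshgrid(np.arange(time), np.arange(batch), indexing="ij")
    picked = log_probs[t_idx.ravel(), b_idx.ravel(), targets.T.ravel()]
    mask = (targets.T.ravel() != pad_id).astype(np.float64)
    count = max(mask.sum(), 1.0)
    return -(picked * Tensor(mask)).sum() / count


def reconstruction_losses(x, y, model: PairedAAE,
                          partition: LatentPartition | None = None) -> tuple[Tensor, Tensor]:
    """Direct + cross reconstruction for partitioned variants.

    rec_x = l(x, G_x(z_x, s_x)) + l(x, G_x(z_x, s_y)) and symmetrically for
    y; for the unidirectional variant (no s_x) both terms use s_y and the
    cross term coincides with the direct one.
    """
    part = partition if partition is not None else model.partition(x, y)
    s_x = part.s_x if part.s_x is not None else part.s_y
    rec_x = mse_loss(x, model.decode_x(part.z_x, s_x)) + \
        mse_loss(x, model.decode_x(part.z_x, part.s_y))
    rec_y = mse_loss(y, model.decode_y(part.z_y, part.s_y)) + \
        mse_loss(y, model.decode_y(part.z_y, s_x))
    return rec_x, rec_y


def adversarial_loss(partition: LatentPartition, prior_samples: Tensor,
                     d_prior) -> tuple[Tensor, Tensor]:
    """Prior/independence discriminator term.

    d_objective = E log D(z'_x, s', z'_y)
                + ½ E log(1−D(z_x, s_x, z_y)) + ½ E log(1−D(z_x, s_y, z_y)),
    with the primed triple drawn from the factorized standard-normal prior.
    eg_objective is the non-saturating loss −½E[log D] over both encoder
    triples.
    """
    s_x = partition.s_x if partition.s_x is not None else partition.s_y
    t_x = partition.triple(s_x)
    t_y = partition.triple(partition.s_y)
    d_obj = _log_d(d_prior, prior_samples).mean() \
        + 0.5 * _log_1md(d_prior, t_x).mean() \
        + 0.5 * _log_1md(d_prior, t_y).mean()
    eg_obj = -(0.5 * _log_d(d_prior, t_x).mean()
               + 0.5 * _log_d(d_prior, t_y).mean())
    return d_obj, eg_obj


def _permute(t: Tensor, perm: np.ndarray) -> Tensor:
    return t[np.asarray(perm)]


def info_loss(partition: LatentPartition, perm: np.ndarray,
              d_info_x, d_info_y) -> tuple[Tensor, Tensor]:
    """Information-exclusion discriminators.

    Each discriminator scores a genuine triple against the same triple with
    the other view's exclusive code replaced by a within-batch shuffle:
    D_x on (z_x, s_x, z_y) vs (z_x, s_x, z'_y) and D_y on (z_x, s_y, z_y)
    vs (z'_x, s_y, z_y).
    """
    batch = partition.z_x.shape[0]
    if batch < 2:
        raise ValueError("info loss requires batch size >= 2 (shuffle undefined)")
    perm = np.asarray(perm)
    s_x = partition.s_x if partition.s_x is not None else partition.s_y
    real_x = concat([partition.z_x, s_x, partition.z_y], axis=1)
    fake_x = concat([partition.z_x, s_x, _permute(partition.z_y, perm)], axis=1)
    real_y = concat([partition.z_x, partition.s_y, partition.z_y], axis=1)
    fake_y = concat([_permute(partition.z_x, perm), partition.s_y, partition.z_y], axis=1)
    d_obj = _log_d(d_info_x, real_x).mean() + _log_1md(d_info_x, fake_x).mean() \
        + _log_d(d_info_y, real_y).mean() + _log_1md(d_info_y, fake_y).mean()
    # label-flipped generator counterpart
    eg_obj = -(_log_1md(d_info_x, real_x).mean() + _log_d(d_info_x, fake_x).mean()
               + _log_1md(d_info_y, real_y).mean() + _log_d(d_info_y, fake_y).mean())
    return d_obj, eg_obj


def _zeros() -> Tensor:
    return Tensor(0.0)


def saae_objective(x, y, model: PairedAAE, weights: LossWeights,
                   rng: np.random.Generator) -> BatchLosses:
    """Supervised AAE: reconstruct x from (E_x(x), raw y); one discriminator
    pushes z = E_x(x) to the prior."""
    z, _ = model.encode_x(x)
    y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    rec_x = mse_loss(x, model.decode_x(z, y_t))
    prior = Tensor(rng.standard_normal(z.shape))
    d_obj = _log_d(model.d_prior, prior).mean() + _log_1md(model.d_prior, z).mean()
    eg_obj = -_log_d(model.d_prior, z).mean()
    total = weights.lambda_rec_x * rec_x + weights.lambda_adv * eg_obj
    return BatchLosses(shared=_zeros(), rec_x=rec_x, rec_y=_zeros(),
                       adv=eg_obj, info=_zeros(), total=total,
                       disc_adv=d_obj, disc_info=_zeros())


def latent_saae_objective(x, y, model: PairedAAE, weights: LossWeights,
                          rng: np.random.Generator) -> BatchLosses:
    """Latent SAAE: as SAAE, but the decoder receives an autoencoded
    condition code E_y(y) and the condition autoencoder is trained jointly."""
    z, _ = model.encode_x(x)
    _, y_code = model.encode_y(y)
    rec_x = mse_loss(x, model.decode_x(z, y_code))
    rec_y = mse_loss(y, model.decode_y(None, y_code))
    prior = Tensor(rng.standard_normal(z.shape))
    d_obj = _log_d(model.d_prior, prior).mean() + _log_1md(model.d_prior, z).mean()
    eg_obj = -_log_d(model.d_prior, z).mean()
    total = (weights.lambda_rec_x * rec_x + weights.lambda_rec_y * rec_y
             + weights.lambda_adv * eg_obj)
    return BatchLosses(shared=_zeros(), rec_x=rec_x, rec_y=rec_y,
                       adv=eg_obj, info=_zeros(), total=total,
                       disc_adv=d_obj, disc_info=_zeros())


def total_objective(x, y, model: PairedAAE, weights: LossWeights,
                    rng: np.random.Generator,
                    partition: LatentPartition | None = None) -> BatchLosses:
    """Full bidirectional/unidirectional objective on one batch.

    The unidirectional variant is the same objective with s_x ≡ s_y (its
    encoder emits no shared code), which zeroes the shared term and
    collapses each cross term onto its direct counterpart.
    """
    if model.config.variant == "saae":
        return saae_objective(x, y, model, weights, rng)
    if model.config.variant == "latent_saae":
        return latent_saae_objective(x, y, model, weights, rng)

    part = partition if partition is not None else model.partition(x, y)
    s_x = part.s_x if part.s_x is not None else part.s_y
    shared = shared_loss(s_x, part.s_y)
    rec_x, rec_y = reconstruction_losses(x, y, model, partition=part)

    batch = part.z_x.shape[0]
    prior = Tensor(rng.standard_normal((batch, model.config.triple_dim)))
    adv_d, adv_eg = adversarial_loss(part, prior, model.d_prior)
    perm = rng.permutation(batch)
    info_d, info_eg = info_loss(part, perm, model.d_info_x, model.d_info_y)

    total = (weights.lambda_shared * shared
             + weights.lambda_rec_x * rec_x
             + weights.lambda_rec_y * rec_y
             + weights.lambda_adv * adv_eg
             + weights.lambda_info * info_eg)
    return BatchLosses(shared=shared, rec_x=rec_x, rec_y=rec_y,
                       adv=adv_eg, info=info_eg, total=total,
                       disc_adv=adv_d, disc_info=info_d)
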