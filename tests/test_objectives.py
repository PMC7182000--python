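"""Loss-term semantics, checked against independent per-sample oracles.

The oracle implementations below evaluate every expectation as an explicit
Python loop over single samples, sharing nothing with the batched loss code
except the trained/initialized networks they probe.
"""

import dataclasses

import numpy as np
import pytest

from biaae import (LossWeights, adversarial_loss, build_model, info_loss,
                   latent_saae_objective, reconstruction_losses,
                   saae_objective, shared_loss, total_objective)
from biaae.autograd import Tensor
from biaae.models import LatentPartition

RTOL = 1e-5


class ConstantDiscriminator:
    def __init__(self, value: float):
        self.value = value

    def __call__(self, triple):
        return Tensor(np.full((triple.shape[0], 1), self.value))


def _batch(samples, n=16):
    x = np.stack([s.x for s in samples[:n]])
    y = np.stack([s.y for s in samples[:n]])
    return x, y


# -- closed forms -------------------------------------------------------------------

class TestSharedLoss:
    def test_identical_codes_give_zero(self):
        s = Tensor(np.random.default_rng(0).normal(size=(8, 4)))
        assert float(shared_loss(s, s).data) == 0.0

    def test_unit_displacement_gives_one(self):
        s_x = Tensor(np.array([[1.0, 0.0, 0.0, 0.0]]))
        s_y = Tensor(np.zeros((1, 4)))
        assert float(shared_loss(s_x, s_y).data) == pytest.approx(1.0)

    def test_squared_distance_batch_mean(self):
        s_x = Tensor(np.zeros((5, 2)))
        s_y = Tensor(np.full((5, 2), [2.0, 0.0]))
        assert float(shared_loss(s_x, s_y).data) == pytest.approx(4.0)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shared_loss(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4))))


class TestConstantDiscriminatorValues:
    def test_uninformative_prior_discriminator(self, small_model, factor_samples):
        x, y = _batch(factor_samples)
        part = small_model.partition(x, y)
        prior = Tensor(np.zeros((16, small_model.config.triple_dim)))
        d_obj, _ = adversarial_loss(part, prior, ConstantDiscriminator(0.5))
        assert float(d_obj.data) == pytest.approx(2 * np.log(0.5), rel=1e-12)

    def test_perfect_prior_discriminator_attains_supremum(self, small_model,
                                                          factor_samples):
        x, y = _batch(factor_samples)
        part = small_model.partition(x, y)
        prior = Tensor(np.zeros((16, small_model.config.triple_dim)))
        encoded = {part.triple(part.s_x).data.tobytes(),
                   part.triple(part.s_y).data.tobytes()}

        class PerfectD:
            def __call__(self, triple):
                is_fake = triple.data.tobytes() in encoded
                return Tensor(np.full((triple.shape[0], 1),
                                      1e-12 if is_fake else 1.0 - 1e-12))

        d_obj, _ = adversarial_loss(part, prior, PerfectD())
        assert float(d_obj.data) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_info_discriminators(self, small_model, factor_samples):
        x, y = _batch(factor_samples)
        part = small_model.partition(x, y)
        d_obj, _ = info_loss(part, np.roll(np.arange(16), 1),
                             ConstantDiscriminator(0.5), ConstantDiscriminator(0.5))
        assert float(d_obj.data) == pytest.approx(4 * np.log(0.5), rel=1e-12)

    def test_constant_exclusive_code_makes_shuffling_a_no_op(self, small_model):
        rng = np.random.default_rng(3)
        part = LatentPartition(
            z_x=Tensor(rng.normal(size=(8, 3))),
            s_x=Tensor(rng.normal(size=(8, 2))),
            z_y=Tensor(np.ones((8, 3))),          # constant across the batch
            s_y=Tensor(rng.normal(size=(8, 2))),
        )
        d_x = small_model.d_info_x
        real = d_x(Tensor(np.concatenate([part.z_x.data, part.s_x.data,
                                          part.z_y.data], axis=1))).data
        shuffled = d_x(Tensor(np.concatenate(
            [part.z_x.data, part.s_x.data,
             part.z_y.data[np.roll(np.arange(8), 3)]], axis=1))).data
        assert np.allclose(real, shuffled)

    def test_batch_of_one_rejected(self, small_model, factor_samples):
        x, y = _batch(factor_samples, n=1)
        part = small_model.partition(x, y)
        with pytest.raises(ValueError):
            info_loss(part, np.array([0]), small_model.d_info_x,
                      small_model.d_info_y)


# -- oracle-loop equivalence ---------------------------------------------------------

def _oracle_total(x, y, model, weights, prior, perm):
    """Scalar-loop re-computation of every term of the full objective."""
    model.eval()
    n = len(x)
    z_x, s_x, z_y, s_y = [], [], [], []
    for i in range(n):
        zi, si = model.encode_x(x[i])
        z_x.append(zi.data[0])
        s_x.append(si.data[0] if si is not None else None)
        zi, si = model.encode_y(y[i])
        z_y.append(zi.data[0])
        s_y.append(si.data[0])
    if s_x[0] is None:
        s_x = s_y
    shared = np.mean([np.sum((a - b) ** 2) for a, b in zip(s_x, s_y)])

    def dec_x(i, s):
        return model.decode_x(Tensor(z_x[i][None]), Tensor(s[i][None])).data[0]

    def dec_y(i, s):
        return model.decode_y(Tensor(z_y[i][None]), Tensor(s[i][None])).data[0]

    rec_x = np.mean([np.mean((x[i] - dec_x(i, s_x)) ** 2) for i in range(n)]) + \
        np.mean([np.mean((x[i] - dec_x(i, s_y)) ** 2) for i in range(n)])
    rec_y = np.mean([np.mean((y[i] - dec_y(i, s_y)) ** 2) for i in range(n)]) + \
        np.mean([np.mean((y[i] - dec_y(i, s_x)) ** 2) for i in range(n)])

    def d(net, *parts):
        return float(net(Tensor(np.concatenate(parts)[None])).data.ravel()[0])

    log = np.log
    d_adv = np.mean([log(d(model.d_prior, p[:])) for p in prior]) + \
        0.5 * np.mean([log(1 - d(model.d_prior, z_x[i], s_x[i], z_y[i])) for i in range(n)]) + \
        0.5 * np.mean([log(1 - d(model.d_prior, z_x[i], s_y[i], z_y[i])) for i in range(n)])
    adv_eg = -(0.5 * np.mean([log(d(model.d_prior, z_x[i], s_x[i], z_y[i])) for i in range(n)])
               + 0.5 * np.mean([log(d(model.d_prior, z_x[i], s_y[i], z_y[i])) for i in range(n)]))
    d_info = np.mean([log(d(model.d_info_x, z_x[i], s_x[i], z_y[i])) for i in range(n)]) + \
        np.mean([log(1 - d(model.d_info_x, z_x[i], s_x[i], z_y[perm[i]])) for i in range(n)]) + \
        np.mean([log(d(model.d_info_y, z_x[i], s_y[i], z_y[i])) for i in range(n)]) + \
        np.mean([log(1 - d(model.d_info_y, z_x[perm[i]], s_y[i], z_y[i])) for i in range(n)])
    info_eg = -(np.mean([log(1 - d(model.d_info_x, z_x[i], s_x[i], z_y[i])) for i in range(n)])
                + np.mean([log(d(model.d_info_x, z_x[i], s_x[i], z_y[perm[i]])) for i in range(n)])
                + np.mean([log(1 - d(model.d_info_y, z_x[i], s_y[i], z_y[i])) for i in range(n)])
                + np.mean([log(d(model.d_info_y, z_x[perm[i]], s_y[i], z_y[i])) for i in range(n)]))
    total = (weights.lambda_shared * shared + weights.lambda_rec_x * rec_x
             + weights.lambda_rec_y * rec_y + weights.lambda_adv * adv_eg
             + weights.lambda_info * info_eg)
    return {"shared": shared, "rec_x": rec_x, "rec_y": rec_y, "adv": adv_eg,
            "info": info_eg, "total": total, "disc_adv": d_adv, "disc_info": d_info}


@pytest.mark.parametrize("variant", ["biaae", "uniaae"])
def test_every_loss_term_matches_scalar_loop_oracle(variant, small_config,
                                                    factor_samples):
    config = dataclasses.replace(small_config, variant=variant)
    model = build_model(config).eval()
    x, y = _batch(factor_samples, n=12)
    rng = np.random.default_rng(77)
    prior = rng.standard_normal((12, config.triple_dim))
    perm = rng.permutation(12)

    part = model.partition(x, y)
    shared = shared_loss(part.s_x if part.s_x is not None else part.s_y, part.s_y)
    rec_x, rec_y = reconstruction_losses(x, y, model, partition=part)
    adv_d, adv_eg = adversarial_loss(part, Tensor(prior), model.d_prior)
    info_d, info_eg = info_loss(part, perm, model.d_info_x, model.d_info_y)
    weights = LossWeights()
    total = (weights.lambda_shared * shared + weights.lambda_rec_x * rec_x
             + weights.lambda_rec_y * rec_y + weights.lambda_adv * adv_eg
             + weights.lambda_info * info_eg)

    oracle = _oracle_total(x, y, model, weights, prior, perm)
    batched = {"shared": shared, "rec_x": rec_x, "rec_y": rec_y, "adv": adv_eg,
               "info": info_eg, "total": total, "disc_adv": adv_d,
               "disc_info": info_d}
    for name, tensor in batched.items():
        assert float(tensor.data) == pytest.approx(oracle[name], rel=RTOL), name


def test_saae_objective_matches_scalar_oracle(small_config, factor_samples):
    config = dataclasses.replace(small_config, variant="saae")
    model = build_model(config).eval()
    x, y = _batch(factor_samples, n=10)
    weights = LossWeights()
    losses = saae_objective(x, y, model, weights, np.random.default_rng(5))

    # oracle: per-sample reconstruction through (E_x(x), raw y)
    rec = []
    for i in range(10):
        z, _ = model.encode_x(x[i])
        out = model.decode_x(z, Tensor(y[i][None])).data[0]
        rec.append(np.mean((x[i] - out) ** 2))
    assert float(losses.rec_x.data) == pytest.approx(np.mean(rec), rel=RTOL)
    assert float(losses.rec_y.data) == 0.0
    expected_total = weights.lambda_rec_x * float(losses.rec_x.data) + \
        weights.lambda_adv * float(losses.adv.data)
    assert float(losses.total.data) == pytest.approx(expected_total, rel=RTOL)


def test_latent_saae_adds_condition_autoencoder_term(small_config, factor_samples):
    config = dataclasses.replace(small_config, variant="latent_saae")
    model = build_model(config).eval()
    x, y = _batch(factor_samples, n=10)
    losses = latent_saae_objective(x, y, model, LossWeights(),
                                   np.random.default_rng(5))
    rec_y = []
    for i in range(10):
        _, code = model.encode_y(y[i])
        out = model.decode_y(None, code).data[0]
        rec_y.append(np.mean((y[i] - out) ** 2))
    assert float(losses.rec_y.data) == pytest.approx(np.mean(rec_y), rel=RTOL)


# -- structural properties -----------------------------------------------------------

def test_forcing_shared_codes_equal_recovers_unidirectional_objective(
        small_config, factor_samples):
    """With s_x := s_y the bidirectional objective must equal the
    unidirectional one on the same latents, prior draw and shuffle."""
    model = build_model(small_config).eval()
    x, y = _batch(factor_samples, n=12)
    part = model.partition(x, y)
    forced = LatentPartition(z_x=part.z_x, s_x=part.s_y, z_y=part.z_y,
                             s_y=part.s_y)
    as_uni = LatentPartition(z_x=part.z_x, s_x=None, z_y=part.z_y, s_y=part.s_y)
    weights = LossWeights()
    biaae_losses = total_objective(x, y, model, weights,
                                   np.random.default_rng(9), partition=forced)
    uni_losses = total_objective(x, y, model, weights,
                                 np.random.default_rng(9), partition=as_uni)
    for name in ("shared", "rec_x", "rec_y", "adv", "info", "total",
                 "disc_adv", "disc_info"):
        assert float(getattr(biaae_losses, name).data) == \
            float(getattr(uni_losses, name).data), name
    assert float(biaae_losses.shared.data) == 0.0


def test_total_is_linear_in_the_weights(small_model, factor_samples):
    x, y = _batch(factor_samples, n=8)
    weights = LossWeights(lambda_shared=0.3, lambda_rec_x=2.0,
                          lambda_rec_y=5.0, lambda_adv=0.7, lambda_info=1.3)
    losses = total_objective(x, y, small_model, weights, np.random.default_rng(1))
    manual = (0.3 * float(losses.shared.data) + 2.0 * float(losses.rec_x.data)
              + 5.0 * float(losses.rec_y.data) + 0.7 * float(losses.adv.data)
              + 1.3 * float(losses.info.data))
    assert float(losses.total.data) == pytest.approx(manual, rel=1e-12)


def test_only_shared_weight_and_equal_codes_give_zero_total(small_model,
                                                            factor_samples):
    x, y = _batch(factor_samples, n=8)
    part = small_model.partition(x, y)
    forced = LatentPartition(z_x=part.z_x, s_x=part.s_y, z_y=part.z_y,
                             s_y=part.s_y)
    weights = LossWeights(lambda_shared=1.0, lambda_rec_x=0.0,
                          lambda_rec_y=0.0, lambda_adv=0.0, lambda_info=0.0)
    losses = total_objective(x, y, small_model, weights,
                             np.random.default_rng(0), partition=forced)
    assert float(losses.total.data) == 0.0


def test_losses_finite_on_extreme_inputs(small_model):
    rng = np.random.default_rng(0)
    part = LatentPartition(
        z_x=Tensor(rng.normal(size=(8, 3)) * 1e4),
        s_x=Tensor(rng.normal(size=(8, 2)) * 1e4),
        z_y=Tensor(rng.normal(size=(8, 3)) * 1e4),
        s_y=Tensor(rng.normal(size=(8, 2)) * 1e4),
    )
    prior = Tensor(rng.standard_normal((8, small_model.config.triple_dim)))
    d_obj, eg_obj = adversarial_loss(part, prior, small_model.d_prior)
    assert np.isfinite(float(d_obj.data)) and np.isfinite(float(eg_obj.data))
    d_obj, eg_obj = info_loss(part, rng.permutation(8), small_model.d_info_x,
                              small_model.d_info_y)
    assert np.isfinite(float(d_obj.data)) and np.isfinite(float(eg_obj.data))


def test_gradient_routing_between_adversaries(small_model, factor_samples):
    """Discriminator objectives on detached latents leave encoders untouched;
    generator objectives with frozen discriminators leave those untouched."""
    x, y = _batch(factor_samples, n=8)
    part = small_model.partition(x, y)
    detached = LatentPartition(z_x=part.z_x.detach(), s_x=part.s_x.detach(),
                               z_y=part.z_y.detach(), s_y=part.s_y.detach())
    prior = Tensor(np.random.default_rng(0).standard_normal(
        (8, small_model.config.triple_dim)))
    d_obj, _ = adversarial_loss(detached, prior, small_model.d_prior)
    small_model.zero_grad()
    (-d_obj).backward()
    assert all(p.grad is None for m in small_model.generator_modules()
               for p in m.parameters())
    assert any(p.grad is not None for p in small_model.d_prior.parameters())

    for disc in small_model.discriminator_modules():
        disc.requires_grad_(False)
    losses = total_objective(x, y, small_model, LossWeights(),
                             np.random.default_rng(1))
    small_model.zero_grad()
    losses.total.backward()
    assert all(p.grad is None for m in small_model.discriminator_modules()
               for p in m.parameters())
    assert any(p.grad is not None for p in small_model.encoder_x.parameters())
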