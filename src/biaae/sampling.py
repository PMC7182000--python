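"""Conditional and joint generation following the latent graphical model.

To sample x given y: extract the shared code s from y with the condition
encoder, draw the missing view's exclusive code z_x from the standard-normal
prior, and decode G_x(z_x, s). Joint sampling draws s, z_x, z_y
independently from the prior and decodes both views from the same s.
Sampling never mutates model parameters.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .autograd import Tensor, no_grad
from .models import PairedAAE

__all__ = ["GenerationRequest", "GeneratedSet", "sample_conditional", "sample_joint"]


class UnsupportedVariantError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GenerationRequest:
    direction: str = "x_given_y"        # x_given_y | y_given_x | joint
    condition: Optional[np.ndarray] = None
    n_samples: int = 1
    decode_mode: str = "greedy"         # greedy | multinomial (sequence decoders)
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("x_given_y", "y_given_x", "joint"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclasses.dataclass
class GeneratedSet:
    """Generated objects with provenance; ``items`` is an (n, dim) array for
    dense views or a list of SMILES strings for sequence views."""

    items: object
    validity: Optional[np.ndarray] = None
    shared_code: Optional[np.ndarray] = None
    request: Optional[GenerationRequest] = None

    def __len__(self) -> int:
        return len(self.items)


def sample_conditional(model: PairedAAE, request: GenerationRequest) -> GeneratedSet:
    """Generate n_samples of the missing view given the provided one.

    All samples share the code extracted from the condition and differ only
    in their prior-drawn exclusive codes. For the supervised AAE the raw
    condition is fed straight to the decoder (only x given y is defined).
    """
    if request.direction == "joint":
        raise ValueError("use sample_joint for joint generation")
    variant = model.config.variant
    rng = np.random.default_rng(request.seed)
    if request.condition is None:
        raise ValueError("conditional sampling requires a condition")
    cond = np.asarray(request.condition, dtype=np.float64).reshape(1, -1)

    if variant == "saae":
        if request.direction != "x_given_y":
            raise UnsupportedVariantError("saae only supports x given y")
        z = Tensor(rng.standard_normal((request.n_samples,
                                        model.config.dim_zx + model.config.dim_s)))
        y_rep = Tensor(np.repeat(cond, request.n_samples, axis=0))
        with no_grad():
            x = model.decode_x(z, y_rep).data
        return GeneratedSet(items=x, shared_code=cond, request=request)

    with no_grad():
        if request.direction == "x_given_y":
            if variant == "latent_saae":
                _, shared = model.encode_y(cond)
            else:
                _, shared = model.encode_y(cond)
            z = Tensor(rng.standard_normal(
                (request.n_samples,
                 model.config.dim_zx + (model.config.dim_s if variant in ("saae", "latent_saae") else 0))))
            shared_rep = Tensor(np.repeat(shared.data, request.n_samples, axis=0))
            out = model.decode_x(z, shared_rep).data
        else:  # y given x
            if variant != "biaae":
                raise UnsupportedVariantError(
                    f"{variant} cannot generate the condition view")
            _, shared = model.encode_x(cond)
            z = Tensor(rng.standard_normal((request.n_samples, model.config.dim_zy)))
            shared_rep = Tensor(np.repeat(shared.data, request.n_samples, axis=0))
            out = model.decode_y(z, shared_rep).data
    return GeneratedSet(items=out, shared_code=shared.data, request=request)


def sample_joint(model: PairedAAE, n: int, seed: int = 0) -> tuple[GeneratedSet, GeneratedSet]:
    """Draw n (x, y) pairs from the joint model (bidirectional only)."""
    if model.config.variant != "biaae":
        raise UnsupportedVariantError("joint sampling requires the bidirectional variant")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    c = model.config
    s = rng.standard_normal((n, c.dim_s))
    z_x = rng.standard_normal((n, c.dim_zx))
    z_y = rng.standard_normal((n, c.dim_zy))
    with no_grad():
        x = model.decode_x(Tensor(z_x), Tensor(s)).data
        y = model.decode_y(Tensor(z_y), Tensor(s)).data
    request = GenerationRequest(direction="joint", n_samples=n, seed=seed)
    return (GeneratedSet(items=x, shared_code=s, request=request),
            GeneratedSet(items=y, shared_code=s, request=request))


def sample_smiles(decoder, condition_code: np.ndarray, vocabulary, n_samples: int,
                  dim_zx: int, seed: int = 0, mode: str = "greedy",
                  temperature: float = 1.0, max_len: int = 120) -> GeneratedSet:
    """Generate SMILES from a sequence decoder given a shared code.

    The exclusive code is drawn from the prior per sample; strings are
    decoded greedily or by multinomial sampling and truncated at the end
    token. Invalid strings are kept (validity flags are the evaluator's
    concern).
    """
    rng = np.random.default_rng(seed)
    shared = np.repeat(np.asarray(condition_code).reshape(1, -1), n_samples, axis=0)
    z = rng.standard_normal((n_samples, dim_zx))
    sequences = decoder.generate(Tensor(z), Tensor(shared),
                                 start_id=vocabulary.start_id,
                                 end_id=vocabulary.end_id, max_len=max_len,
                                 mode=mode, temperature=temperature, rng=rng)
    smiles = [vocabulary.detokenize(seq) for seq in sequences]
    return GeneratedSet(items=smiles, shared_code=condition_code)
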