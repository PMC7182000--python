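"""Synthetic paired-view datasets with known shared/exclusive structure.

Two generators are provided:

* :func:`generate_factor_pairs` — the latent factors ``s`` (shared), ``z_x``
  and ``z_y`` (exclusive) are drawn independently from a standard normal and
  mixed into two observed views, so ground truth is available for probing
  whether a trained model routes the shared information into its shared code.
* :func:`generate_pattern_pairs` — image pairs that emulate the noisy
  rotated-digit benchmark: both views show a template of the same class,
  each independently rotated within ±rotation_range, the second view
  corrupted with strong additive Gaussian noise. The class is the only
  feature common to both views. Templates are seeded blurred random blobs,
  one per class, so no external image dataset is needed.

Everything is a pure function of (spec, n): the same spec and seed yield a
bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FactorSpec",
    "PatternPairSpec",
    "PairedSample",
    "generate_factor_pairs",
    "generate_pattern_pairs",
    "save_dataset",
    "load_dataset",
]

_FORMAT_VERSION = "1"


class ConfigurationError(ValueError):
    """Raised when a dataset spec violates its invariants."""


@dataclasses.dataclass(frozen=True)
class FactorSpec:
    """Latent-factor dataset spec: dims of shared/exclusive codes and mixing.

    ``x`` has dimension ``dim_s + dim_zx`` and ``y`` dimension
    ``dim_s + dim_zy`` (square mixing), so the noiseless linear case is
    exactly invertible almost surely.
    """

    dim_s: int = 4
    dim_zx: int = 12
    dim_zy: int = 12
    noise_sd: float = 0.1
    mixing: Literal["linear", "mlp-random"] = "linear"
    seed: int = 0

    def __post_init__(self):
        if min(self.dim_s, self.dim_zx, self.dim_zy) < 1:
            raise ConfigurationError("all latent dimensions must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.mixing not in ("linear", "mlp-random"):
            raise ConfigurationError(f"unknown mixing: {self.mixing!r}")

    @property
    def dim_x(self) -> int:
        return self.dim_s + self.dim_zx

    @property
    def dim_y(self) -> int:
        return self.dim_s + self.dim_zy


@dataclasses.dataclass(frozen=True)
class PatternPairSpec:
    """Rotated noisy pattern-pair spec (class is the only shared feature)."""

    n_classes: int = 10
    image_side: int = 28
    rotation_range: float = np.pi / 4
    # strong relative to the smooth templates' pixel contrast, yet low enough
    # that the class stays recoverable from the noisy view (the benchmark's
    # premise is that the class IS a shared feature of both views)
    noise_sd: float = 0.4
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.image_side < 4:
            raise ConfigurationError("image_side must be >= 4")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclasses.dataclass
class PairedSample:
    """One (object view, condition view) observation.

    ``truth`` carries the generating factors (s, z_x, z_y) when known;
    ``label`` the class for pattern pairs.
    """

    x: np.ndarray
    y: np.ndarray
    label: Optional[int] = None
    truth: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None


def _random_mlp(rng: np.random.Generator, in_dim: int, out_dim: int):
    """A frozen random two-layer tanh map used for nonlinear mixing."""
    w1 = rng.normal(0, 1.0 / np.sqrt(in_dim), size=(in_dim, 2 * out_dim))
    w2 = rng.normal(0, 1.0 / np.sqrt(2 * out_dim), size=(2 * out_dim, out_dim))

    def apply(latent: np.ndarray) -> np.ndarray:
        return np.tanh(latent @ w1) @ w2

    return apply


def generate_factor_pairs(spec: FactorSpec, n: int) -> list[PairedSample]:
    """Draw n paired samples from the shared/exclusive factor model.

    s, z_x, z_y ~ N(0, I) independently; x mixes (s, z_x) and y mixes
    (s, z_y), each plus i.i.d. Gaussian observation noise of sd
    ``spec.noise_sd``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    # independent child streams so the factors do not depend on the mixing mode
    mix_rng = np.random.default_rng([spec.seed, 0])
    factor_rng = np.random.default_rng([spec.seed, 1])
    noise_rng = np.random.default_rng([spec.seed, 2])
    # mixing maps drawn once per spec, then frozen
    if spec.mixing == "linear":
        m_x = mix_rng.normal(size=(spec.dim_s + spec.dim_zx, spec.dim_x))
        m_y = mix_rng.normal(size=(spec.dim_s + spec.dim_zy, spec.dim_y))
        map_x = lambda latent: latent @ m_x
        map_y = lambda latent: latent @ m_y
    else:
        map_x = _random_mlp(mix_rng, spec.dim_s + spec.dim_zx, spec.dim_x)
        map_y = _random_mlp(mix_rng, spec.dim_s + spec.dim_zy, spec.dim_y)

    s = factor_rng.standard_normal((n, spec.dim_s))
    z_x = factor_rng.standard_normal((n, spec.dim_zx))
    z_y = factor_rng.standard_normal((n, spec.dim_zy))
    x = map_x(np.concatenate([s, z_x], axis=1))
    y = map_y(np.concatenate([s, z_y], axis=1))
    if spec.noise_sd > 0:
        x = x + noise_rng.normal(0, spec.noise_sd, size=x.shape)
        y = y + noise_rng.normal(0, spec.noise_sd, size=y.shape)
    return [
        PairedSample(x=x[i], y=y[i], truth=(s[i], z_x[i], z_y[i]))
        for i in range(n)
    ]


def class_templates(spec: PatternPairSpec) -> np.ndarray:
    """Deterministic per-class templates: seeded blurred random blobs in [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    templates = np.empty((spec.n_classes, side, side))
    for c in range(spec.n_classes):
        blob = rng.random((side, side))
        blob = ndimage.gaussian_filter(blob, sigma=side / 10.0)
        # stretch to full unit range so classes are well separated
        blob = (blob - blob.min()) / (blob.max() - blob.min() + 1e-12)
        templates[c] = blob
    return templates


def _rotate(image: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate about the image center, bilinear, zeros outside."""
    return ndimage.rotate(
        image, np.degrees(angle_rad), reshape=False, order=1,
        mode="constant", cval=0.0,
    )


def generate_pattern_pairs(spec: PatternPairSpec) -> list[PairedSample]:
    """Draw paired images sharing only their class.

    x: class template rotated by an angle ~ U[−rotation_range, rotation_range];
    y: the SAME class template, independently rotated, plus N(0, noise_sd²)
    pixel noise. Classes drawn uniformly.
    """
    templates = class_templates(spec)
    rng = np.random.default_rng(spec.seed + 1)  # offset: templates use spec.seed
    labels = rng.integers(0, spec.n_classes, size=spec.n_samples)
    angles = rng.uniform(-spec.rotation_range, spec.rotation_range,
                         size=(spec.n_samples, 2))
    samples = []
    for i in range(spec.n_samples):
        c = int(labels[i])
        x = _rotate(templates[c], angles[i, 0])
        y = _rotate(templates[c], angles[i, 1])
        if spec.noise_sd > 0:
            y = y + rng.normal(0, spec.noise_sd, size=y.shape)
        samples.append(PairedSample(x=x, y=y, label=c))
    return samples


# -- persistence ---------------------------------------------------------------

def save_dataset(samples: Sequence[PairedSample], directory, spec=None) -> None:
    """Write a dataset directory: arrays.npz + metadata.json (spec echo)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {
        "x": np.stack([s.x for s in samples]),
        "y": np.stack([s.y for s in samples]),
    }
    if samples[0].label is not None:
        arrays["label"] = np.array([s.label for s in samples])
    if samples[0].truth is not None:
        arrays["truth_s"] = np.stack([s.truth[0] for s in samples])
        arrays["truth_zx"] = np.stack([s.truth[1] for s in samples])
        arrays["truth_zy"] = np.stack([s.truth[2] for s in samples])
    np.savez_compressed(directory / "arrays.npz", **arrays)
    meta = {"version": _FORMAT_VERSION, "n_samples": len(samples)}
    if spec is not None:
        meta["spec_class"] = type(spec).__name__
        meta["spec"] = dataclasses.asdict(spec)
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_dataset(directory) -> tuple[list[PairedSample], dict]:
    """Read a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    with np.load(directory / "arrays.npz") as arrays:
        x, y = arrays["x"], arrays["y"]
        labels = arrays["label"] if "label" in arrays else None
        truth = (
            (arrays["truth_s"], arrays["truth_zx"], arrays["truth_zy"])
            if "truth_s" in arrays
            else None
        )
    samples = []
    for i in range(len(x)):
        samples.append(PairedSample(
            x=x[i], y=y[i],
            label=int(labels[i]) if labels is not None else None,
            truth=(truth[0][i], truth[1][i], truth[2][i]) if truth else None,
        ))
    return samples, meta
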