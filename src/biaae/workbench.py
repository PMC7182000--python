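"""End-to-end experiment driver on the synthetic benchmarks.

``run_experiment`` generates (or loads) a paired dataset, trains each
requested variant for each seed, evaluates the requested metrics and writes
a report aggregating mean ± sd across seeds — one row per variant. Every RNG
stream (data, init, training, sampling, evaluation) derives its own seed, and
each invocation writes into a fresh run-stamped directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import evaluation, sampling, synthetic, training
from .autograd import Tensor, no_grad
from .models import ArchSpec, ModelConfig, build_model
from .objectives import LossWeights

__all__ = ["ExperimentSpec", "run_experiment", "render_report",
           "disentanglement_probe", "conditional_class_fidelity",
           "fit_pattern_probe", "factor_benchmark", "pattern_benchmark",
           "FACTOR_BENCHMARK_SPEC", "PATTERN_BENCHMARK_SPEC"]

REPORT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class ExperimentSpec:
    dataset: object                     # FactorSpec or PatternPairSpec
    variants: tuple[str, ...] = ("biaae",)
    seeds: tuple[int, ...] = (0,)
    n_train: int = 10_000               # factor datasets only
    train: training.TrainConfig = training.TrainConfig()
    metrics: tuple[str, ...] = ("shared_probe_r2", "exclusive_probe_r2")
    encoder_hidden: tuple[int, ...] = (64, 64)
    decoder_hidden: tuple[int, ...] = (64, 64)
    discriminator_hidden: tuple[int, ...] = (64, 64)
    dim_zx: int = 12
    dim_s: int = 4
    dim_zy: int = 12
    weights_by_variant: dict = dataclasses.field(default_factory=dict)
    out_dir: Optional[str] = None

    def __post_init__(self):
        if not self.variants or not self.seeds:
            raise ValueError("need at least one variant and one seed")


def _model_config(spec: ExperimentSpec, variant: str, seed: int) -> ModelConfig:
    data = spec.dataset
    if isinstance(data, synthetic.FactorSpec):
        x_dim, y_dim = data.dim_x, data.dim_y
    else:
        x_dim = y_dim = data.image_side ** 2
    return ModelConfig(
        variant=variant, x_dim=x_dim, y_dim=y_dim,
        dim_zx=spec.dim_zx, dim_s=spec.dim_s, dim_zy=spec.dim_zy,
        encoder_arch=ArchSpec(hidden=spec.encoder_hidden),
        decoder_arch=ArchSpec(hidden=spec.decoder_hidden),
        discriminator_arch=ArchSpec(hidden=spec.discriminator_hidden),
        seed=seed + 1000,
    )


def _generate(spec: ExperimentSpec, seed: int):
    data = spec.dataset
    if isinstance(data, synthetic.FactorSpec):
        data = dataclasses.replace(data, seed=seed)
        return synthetic.generate_factor_pairs(data, spec.n_train), data
    data = dataclasses.replace(data, seed=seed)
    return synthetic.generate_pattern_pairs(data), data


# -- metric helpers ----------------------------------------------------------------

def disentanglement_probe(model, samples) -> dict[str, float]:
    """Linear-probe R² for the true shared factor from the condition
    encoder's shared code (should be high) and exclusive code (should be
    low)."""
    y = np.stack([s.y for s in samples]).reshape(len(samples), -1)
    truth_s = np.stack([s.truth[0] for s in samples])
    with no_grad():
        z_y, s_y = model.encode_y(y)
    return {
        "shared_probe_r2": evaluation.linear_probe_r2(s_y.data, truth_s),
        "exclusive_probe_r2": evaluation.linear_probe_r2(z_y.data, truth_s),
    }


def fit_pattern_probe(pattern_spec: synthetic.PatternPairSpec, n: int = 2000,
                      seed: int = 12345):
    """Train the frozen class probe on an independently drawn labeled set
    (clean x views from the same template family)."""
    probe_spec = dataclasses.replace(pattern_spec, n_samples=n)
    samples = synthetic.generate_pattern_pairs(probe_spec)
    images = np.stack([s.x for s in samples])
    labels = np.array([s.label for s in samples])
    return evaluation.train_probe(images, labels, seed=seed)


def conditional_class_fidelity(model, samples, probe, seed: int = 0) -> float:
    """Generate one x per condition y (prior-drawn exclusive code) and score
    the probe-assigned class against the condition's class."""
    y = np.stack([s.y for s in samples]).reshape(len(samples), -1)
    labels = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    with no_grad():
        if model.config.variant == "saae":
            z = Tensor(rng.standard_normal(
                (len(y), model.config.dim_zx + model.config.dim_s)))
            x = model.decode_x(z, Tensor(y)).data
        else:
            _, s_y = model.encode_y(y)
            dim_z = model.config.dim_zx + (
                model.config.dim_s if model.config.variant == "latent_saae" else 0)
            z = Tensor(rng.standard_normal((len(y), dim_z)))
            x = model.decode_x(z, s_y).data
    return evaluation.probe_accuracy(x, labels, probe)


def _evaluate(model, samples, spec: ExperimentSpec, seed: int,
              probe=None) -> dict[str, float]:
    out: dict[str, float] = {}
    wanted = set(spec.metrics)
    if wanted & {"shared_probe_r2", "exclusive_probe_r2"}:
        out.update(disentanglement_probe(model, samples))
    if "probe_accuracy" in wanted:
        if probe is None:
            raise ValueError("probe_accuracy requested but no probe supplied")
        out["probe_accuracy"] = conditional_class_fidelity(
            model, samples, probe, seed=seed + 7)
    return {k: v for k, v in out.items() if k in wanted}


# -- reference benchmark recipes -----------------------------------------------------

#: factor benchmark conditions: 4-dim shared / 12-dim exclusive factors,
#: linear mixing, observation noise 0.1, n = 10,000
FACTOR_BENCHMARK_SPEC = synthetic.FactorSpec(dim_s=4, dim_zx=12, dim_zy=12,
                                             noise_sd=0.1, mixing="linear",
                                             seed=0)

#: pattern benchmark conditions: 10 classes, 16x16 views, n = 5,000
PATTERN_BENCHMARK_SPEC = synthetic.PatternPairSpec(n_classes=10, image_side=16,
                                                   n_samples=5000, seed=0)

#: two-phase information-weight schedule (epochs, learning rate, info weight):
#: the shared code saturates under weak information pressure first, then the
#: raised weight purges the exclusive codes
FACTOR_SCHEDULE = ((50, 3e-4, 1.0), (130, 3e-4, 10.0))
PATTERN_SCHEDULE = ((20, 6e-4, 1.0), (60, 6e-4, 10.0))


def _train_schedule(model, data, schedule, batch_size, base_seed,
                    tail_ema: float | None = 0.998,
                    shared_weight: float = 0.1):
    """Run the phases of an (epochs, lr, info weight) schedule; the final
    phase tail-averages the generator weights to damp the adversarial
    oscillation."""
    sofar = 0
    for i, (epochs, lr, info_weight) in enumerate(schedule):
        config = training.TrainConfig(
            epochs=epochs, learning_rate=lr, batch_size=batch_size,
            seed=base_seed + sofar,
            weights=LossWeights(lambda_info=info_weight,
                                lambda_shared=shared_weight),
            generator_ema_decay=tail_ema if i == len(schedule) - 1 else None)
        model, _state = training.train(model, data, config)
        model.train()
        sofar += epochs
    model.eval()
    return model


def factor_benchmark(train_seed: int, samples=None) -> dict[str, float]:
    """Train the bidirectional model on the factor benchmark and report the
    linear-probe R² of the true shared factor from s_y (high when
    disentangled) and from z_y (low when disentangled).

    ``train_seed`` seeds the whole pipeline — the dataset draw (mixing
    matrices included), model initialization and training — so repeated
    calls measure run-to-run variability of the benchmark, not of one fixed
    dataset. Linear encoders/decoders: the views are linear mixes, so the
    smallest dense model class is the right one, and any information
    smuggling is a plain linear correlation the discriminators detect.
    """
    spec = dataclasses.replace(FACTOR_BENCHMARK_SPEC, seed=train_seed)
    if samples is None:
        samples = synthetic.generate_factor_pairs(spec, 10_000)
    config = ModelConfig(
        variant="biaae", x_dim=spec.dim_x, y_dim=spec.dim_y,
        dim_zx=spec.dim_zx, dim_s=spec.dim_s, dim_zy=spec.dim_zy,
        encoder_arch=ArchSpec(hidden=()), decoder_arch=ArchSpec(hidden=()),
        discriminator_arch=ArchSpec(hidden=(64, 64)),
        seed=1000 + train_seed)
    model = build_model(config)
    x = np.stack([s.x for s in samples])
    y = np.stack([s.y for s in samples])
    model = _train_schedule(model, (x, y), FACTOR_SCHEDULE, 128,
                            2000 + 7919 * train_seed)
    return disentanglement_probe(model, samples)


def pattern_benchmark(train_seed: int, ablation: bool = False,
                      samples=None, probe=None,
                      n_eval: int = 800) -> dict[str, float]:
    """Train the bidirectional model on the pattern benchmark and report the
    probe accuracy of x sampled given y (chance = 1/n_classes).

    ``ablation=True`` zeroes the shared and information weights, removing
    everything that couples the two views beyond reconstruction.
    ``train_seed`` seeds the whole pipeline (dataset, init, training).

    The exclusive codes are 2-dimensional: the only view-specific factor is
    the rotation angle, and wide exclusive codes let the encoder smuggle the
    class past the discriminators.
    """
    spec = dataclasses.replace(PATTERN_BENCHMARK_SPEC, seed=train_seed)
    if samples is None:
        samples = synthetic.generate_pattern_pairs(spec)
    if probe is None:
        probe = fit_pattern_probe(spec)
    config = ModelConfig(
        variant="biaae", x_dim=spec.image_side**2, y_dim=spec.image_side**2,
        dim_zx=2, dim_s=4, dim_zy=2,
        encoder_arch=ArchSpec(hidden=(256, 128)),
        decoder_arch=ArchSpec(hidden=(128, 256)),
        discriminator_arch=ArchSpec(hidden=(64, 64)),
        seed=1000 + train_seed)
    model = build_model(config)
    schedule = PATTERN_SCHEDULE
    if ablation:
        schedule = tuple((ep, lr, 0.0) for ep, lr, _ in schedule)
    x = np.stack([s.x for s in samples]).reshape(len(samples), -1)
    y = np.stack([s.y for s in samples]).reshape(len(samples), -1)
    # no tail averaging here: the pattern run's purge phase is still drifting
    # at its end, and averaging a drifting trajectory degrades the endpoint
    model = _train_schedule(model, (x, y), schedule, 256,
                            2000 + 7919 * train_seed, tail_ema=None,
                            shared_weight=0.0 if ablation else 0.1)
    accuracy = conditional_class_fidelity(model, samples[:n_eval], probe,
                                          seed=97 + train_seed)
    return {"probe_accuracy": accuracy}


# -- driver ------------------------------------------------------------------------

def _run_dir(base: Optional[str]) -> Optional[Path]:
    if base is None:
        return None
    stamp = time.strftime("%Y%m%d-%H%M%S")
    candidate = Path(base) / f"run-{stamp}"
    counter = 0
    while candidate.exists():   # never overwrite a previous run
        counter += 1
        candidate = Path(base) / f"run-{stamp}-{counter}"
    candidate.mkdir(parents=True)
    return candidate


def run_experiment(spec: ExperimentSpec) -> dict:
    """Train and evaluate every (variant, seed) cell; aggregate per variant.

    A failure in one cell is recorded in the report and the remaining cells
    still run.
    """
    run_dir = _run_dir(spec.out_dir)
    is_pattern = isinstance(spec.dataset, synthetic.PatternPairSpec)
    probe = None
    if is_pattern and "probe_accuracy" in spec.metrics:
        probe = fit_pattern_probe(spec.dataset)

    rows: dict[str, dict] = {}
    errors: dict[str, str] = {}
    for variant in spec.variants:
        per_metric: dict[str, list[float]] = {}
        for seed in spec.seeds:
            try:
                samples, _data_spec = _generate(spec, seed)
                config = _model_config(spec, variant, seed)
                model = build_model(config)
                weights = spec.weights_by_variant.get(
                    variant,
                    LossWeights.uniaae_profile() if variant == "uniaae"
                    else spec.train.weights)
                tconf = dataclasses.replace(
                    spec.train, seed=seed + 2000, weights=weights,
                    out_dir=str(run_dir / f"{variant}-seed{seed}") if run_dir else None)
                model, _state = training.train(model, samples, tconf)
                cell = _evaluate(model, samples, spec, seed, probe=probe)
                for name, value in cell.items():
                    per_metric.setdefault(name, []).append(value)
            except Exception:  # noqa: BLE001 — report and continue
                errors[f"{variant}/seed{seed}"] = traceback.format_exc(limit=3)
        rows[variant] = {
            metric: {
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "values": values,
            }
            for metric, values in per_metric.items()
        }

    report = {
        "version": REPORT_VERSION,
        "dataset": dataclasses.asdict(spec.dataset),
        "variants": list(spec.variants),
        "seeds": list(spec.seeds),
        "rows": rows,
        "errors": errors,
    }
    if run_dir:
        (run_dir / "report.json").write_text(json.dumps(report, indent=2))
        (run_dir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Plain-text table: one row per variant, mean ± sd per metric."""
    metrics = sorted({m for row in report["rows"].values() for m in row})
    header = ["variant"] + metrics
    lines = ["\t".join(header)]
    for variant, row in report["rows"].items():
        cells = [variant]
        for metric in metrics:
            if metric in row:
                cells.append(f"{row[metric]['mean']:.4f}±{row[metric]['sd']:.4f}")
            else:
                cells.append("—")
        lines.append("\t".join(cells))
    if report.get("errors"):
        lines.append(f"[{len(report['errors'])} cell(s) failed]")
    return "\n".join(lines)
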