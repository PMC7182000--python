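"""Evaluation metrics: neural mutual-information estimation, classifier-probe
accuracy for conditional generation, per-token sequence NLL, molecular
validity and internal diversity, and expression-prediction metrics (R²,
top-1 precision under a dose window).

The mutual-information estimator maximizes the Donsker–Varadhan bound
E_P[T] − log E_Q[e^T] over a small statistics network T, with the product
marginal Q formed by shuffling one side within the batch; a conditioning
variable, when given, is appended to both the joint and the marginal inputs.
The reported value is the maximum of an exponentially smoothed trace of
full-data bound evaluations, which tempers the estimator's upward noise.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.neural_network import MLPClassifier

from . import nn, objectives
from .autograd import Tensor, no_grad
from .sampling import GeneratedSet

__all__ = [
    "MINESpec", "MIEstimate", "estimate_mi", "train_probe", "probe_accuracy",
    "FingerprintSpec", "internal_diversity", "validity_fraction",
    "conditional_nll", "expression_prediction_metrics", "linear_probe_r2",
    "UndefinedMetricError", "DOSE_WINDOW",
]

#: log10-molar window around 10 μM used when scoring expression predictions
DOSE_WINDOW = (-6.5, -5.5)


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions leave it undefined
    (e.g. fewer than two valid molecules, or an empty dose window)."""


# -- mutual information -----------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MINESpec:
    hidden: tuple[int, ...] = (100, 100)
    learning_rate: float = 5e-4
    batch_size: int = 512
    n_steps: int = 2000
    eval_every: int = 25
    ema_decay: float = 0.9          # smoothing of the evaluation trace
    grad_ema_decay: float = 0.99    # bias-corrected gradient of the log-partition
    seed: int = 0


@dataclasses.dataclass
class MIEstimate:
    value: float                    # nats
    n_steps: int
    spec: MINESpec
    trace: list[float]              # smoothed full-data bound per evaluation


def _dv_bound(t_net, joint: np.ndarray, marginal: np.ndarray) -> float:
    with no_grad():
        t_joint = t_net(Tensor(joint)).data
        t_marg = t_net(Tensor(marginal)).data
    return float(t_joint.mean() - (np.log(np.mean(np.exp(t_marg - t_marg.max())))
                                   + t_marg.max()))


def estimate_mi(samples_a: np.ndarray, samples_b: np.ndarray,
                conditioning: Optional[np.ndarray] = None,
                spec: MINESpec = MINESpec()) -> MIEstimate:
    """Neural lower-bound estimate of MI(a, b) (or MI(a, b | c) inputs) in nats.

    The gradient of the log-partition term uses an exponential moving
    average of E[e^T] so that minibatch noise does not bias the update.
    """
    a = np.atleast_2d(np.asarray(samples_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(samples_b, dtype=np.float64))
    if a.ndim > 2:
        a = a.reshape(len(a), -1)
    if b.ndim > 2:
        b = b.reshape(len(b), -1)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 paired samples")
    cond = None
    if conditioning is not None:
        cond = np.atleast_2d(np.asarray(conditioning, dtype=np.float64))
        cond = cond.reshape(len(cond), -1)

    def assemble(a_rows, idx):
        parts = [a_rows, b[idx]]
        if cond is not None:
            parts.append(cond[idx])
        return np.concatenate(parts, axis=1)

    n = a.shape[0]
    rng = np.random.default_rng(spec.seed)
    in_dim = a.shape[1] + b.shape[1] + (cond.shape[1] if cond is not None else 0)
    t_net = nn.mlp(in_dim, list(spec.hidden), 1, rng, activation="relu")
    opt = nn.Adam(t_net.parameters(), lr=spec.learning_rate)

    ema = None
    trace: list[float] = []
    smoothed = None
    all_idx = np.arange(n)
    full_joint = assemble(a, all_idx)

    for step in range(spec.n_steps):
        idx = rng.integers(0, n, size=min(spec.batch_size, n))
        perm = rng.permutation(len(idx))
        joint = assemble(a[idx], idx)
        marginal = assemble(a[idx][perm], idx)
        t_joint = t_net(Tensor(joint))
        t_marg = t_net(Tensor(marginal))
        exp_t = t_marg.exp()
        batch_mean = float(exp_t.data.mean())
        ema = batch_mean if ema is None else \
            spec.grad_ema_decay * ema + (1 - spec.grad_ema_decay) * batch_mean
        # unbiased-gradient surrogate: d/dθ [mean e^T / ema] == d/dθ log E[e^T]
        loss = -(t_joint.mean() - exp_t.mean() * (1.0 / ema))
        opt.zero_grad()
        loss.backward()
        opt.step()

        if (step + 1) % spec.eval_every == 0:
            perm_full = rng.permutation(n)
            bound = _dv_bound(t_net, full_joint, assemble(a[perm_full], all_idx))
            smoothed = bound if smoothed is None else \
                spec.ema_decay * smoothed + (1 - spec.ema_decay) * bound
            trace.append(smoothed)

    return MIEstimate(value=max(trace), n_steps=spec.n_steps, spec=spec, trace=trace)


# -- classifier probe --------------------------------------------------------------

def train_probe(images: np.ndarray, labels: np.ndarray, seed: int = 0,
                hidden: tuple[int, ...] = (128,), max_iter: int = 300) -> MLPClassifier:
    """Train the frozen evaluation classifier on held-out labeled images."""
    x = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    probe = MLPClassifier(hidden_layer_sizes=hidden, max_iter=max_iter,
                          random_state=seed)
    probe.fit(x, np.asarray(labels))
    return probe


def probe_accuracy(generated, condition_labels, probe: MLPClassifier) -> float:
    """Fraction of generated objects whose probe-argmax class equals the
    class of their condition."""
    items = generated.items if isinstance(generated, GeneratedSet) else generated
    x = np.asarray(items, dtype=np.float64).reshape(len(items), -1)
    if len(x) == 0:
        raise ValueError("empty generated set")
    labels = np.asarray(condition_labels)
    if len(labels) != len(x):
        raise ValueError("one condition label per generated object required")
    predicted = probe.predict(x)
    if not set(np.unique(labels)) <= set(probe.classes_):
        raise ValueError("condition classes outside the probe's class space")
    return float((predicted == labels).mean())


def linear_probe_r2(codes: np.ndarray, targets: np.ndarray) -> float:
    """R² of an ordinary linear regression from latent codes to targets
    (pooled across target dimensions)."""
    reg = LinearRegression().fit(codes, targets)
    return float(r2_score(targets, reg.predict(codes)))


# -- molecular metrics -------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FingerprintSpec:
    """Circular (Morgan-type) substructure fingerprints."""

    radius: int = 2
    n_bits: int = 2048


def _fingerprints(molecules, spec: FingerprintSpec):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                    fpSize=spec.n_bits)
    return [gen.GetFingerprint(m) for m in molecules]


def _parse_valid(smiles_list: Sequence[str]):
    parsed = [Chem.MolFromSmiles(s) for s in smiles_list]
    return [m for m in parsed if m is not None], parsed


def validity_fraction(generated) -> float:
    """Fraction of generated strings parseable as chemically valid."""
    items = generated.items if isinstance(generated, GeneratedSet) else list(generated)
    if len(items) == 0:
        raise ValueError("empty generated set")
    valid, _ = _parse_valid(items)
    return len(valid) / len(items)


def internal_diversity(generated, spec: FingerprintSpec = FingerprintSpec()) -> float:
    """1 − mean pairwise Tanimoto similarity over ordered distinct pairs of
    the valid molecules; 0 signals collapse to a single structure."""
    items = generated.items if isinstance(generated, GeneratedSet) else list(generated)
    valid, _ = _parse_valid(items)
    if len(valid) < 2:
        raise UndefinedMetricError("internal diversity needs >= 2 valid molecules")
    fps = _fingerprints(valid, spec)
    n = len(fps)
    total = 0.0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        total += sum(sims) - sims[i]  # exclude the diagonal
    return 1.0 - total / (n * (n - 1))


# -- sequence NLL -------------------------------------------------------------------

def conditional_nll(model, pairs, vocabulary, z_mode: str = "prior",
                    seed: int = 0) -> float:
    """Per-token NLL of reproducing each molecule from its condition.

    ``pairs`` is a sequence of (smiles, delta, eta). The shared code comes
    from the condition encoder; the molecular exclusive code is drawn once
    per pair from the prior with a fixed evaluation seed (``z_mode="zero"``
    uses a zero vector instead). Teacher-forced, averaged over non-pad
    tokens and over pairs.
    """
    rng = np.random.default_rng(seed)
    total, count = 0.0, 0
    for smiles, delta, eta in pairs:
        token_ids = vocabulary.tokenize(smiles)
        batch = np.asarray([token_ids])
        with no_grad():
            _, s_y = model.encode_y(np.asarray(delta)[None, :], [eta])
            if z_mode == "prior":
                z_x = Tensor(rng.standard_normal((1, model.dim_zx)))
            else:
                z_x = Tensor(np.zeros((1, model.dim_zx)))
            log_probs = model.decoder_x.logits(z_x, s_y, batch)
            nll = objectives.seq_nll(log_probs, batch[:, 1:], vocabulary.pad_id)
        total += float(nll.data)
        count += 1
    if count == 0:
        raise UndefinedMetricError("no pairs supplied")
    return total / count


# -- expression prediction ----------------------------------------------------------

def expression_prediction_metrics(real: np.ndarray, predicted: np.ndarray,
                                  predicted_doses: np.ndarray,
                                  dose_window: tuple[float, float] = DOSE_WINDOW,
                                  ) -> tuple[float, float, float]:
    """Score predicted differential-expression profiles against real ones.

    Generated (Δge, η) tuples with log10 dose outside ``dose_window`` are
    discarded. Over the retained samples: R² is pooled over all (sample,
    gene) entries; top-1 precision is the fraction of samples whose gene of
    largest absolute change matches. Returns (r2, top1, retained_fraction);
    raises :class:`UndefinedMetricError` when nothing is retained.
    """
    real = np.asarray(real, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    doses = np.asarray(predicted_doses, dtype=np.float64)
    if real.shape != predicted.shape or len(doses) != len(real):
        raise ValueError("real/predicted/doses must align")
    keep = (doses >= dose_window[0]) & (doses <= dose_window[1])
    retained = float(keep.mean()) if len(keep) else 0.0
    if not keep.any():
        raise UndefinedMetricError("no generated tuples inside the dose window")
    real_kept, pred_kept = real[keep], predicted[keep]
    r2 = float(r2_score(real_kept.ravel(), pred_kept.ravel()))
    top1 = float((np.abs(real_kept).argmax(axis=1)
                  == np.abs(pred_kept).argmax(axis=1)).mean())
    return r2, top1, retained
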