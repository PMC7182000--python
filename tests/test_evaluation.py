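"""Metric semantics: diversity, validity, probe accuracy, sequence NLL,
expression-prediction scores and the neural MI estimator's basic ordering."""

import numpy as np
import pytest

from biaae.autograd import Tensor
from biaae.evaluation import (DOSE_WINDOW, FingerprintSpec, MINESpec,
                              UndefinedMetricError, estimate_mi,
                              expression_prediction_metrics,
                              internal_diversity, probe_accuracy, train_probe,
                              validity_fraction)
from biaae.objectives import seq_nll


class TestInternalDiversity:
    def test_identical_molecules_give_zero(self):
        assert internal_diversity(["CCO", "CCO", "CCO"]) == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self, toy_smiles):
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator
        spec = FingerprintSpec()
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                        fpSize=spec.n_bits)
        mols = [Chem.MolFromSmiles(s) for s in toy_smiles]
        fps = [gen.GetFingerprint(m) for m in mols]
        n = len(fps)
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    total += DataStructs.TanimotoSimilarity(fps[i], fps[j])
        oracle = 1.0 - total / (n * (n - 1))
        assert internal_diversity(toy_smiles, spec) == pytest.approx(oracle, abs=1e-9)

    def test_invalid_molecules_excluded_before_computation(self):
        with_junk = ["CCO", "CCN", "notasmiles"]
        assert internal_diversity(with_junk) == \
            pytest.approx(internal_diversity(["CCO", "CCN"]), abs=1e-12)

    def test_reordering_invariance(self, toy_smiles):
        assert internal_diversity(toy_smiles) == \
            pytest.approx(internal_diversity(toy_smiles[::-1]), abs=1e-12)

    def test_fewer_than_two_valid_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            internal_diversity(["CCO", "brokenstring"])


class TestValidity:
    def test_counts_parseable_fraction(self):
        assert validity_fraction(["CCO", "CCN", "c1ccccc1", "xx("]) == 0.75

    def test_all_broken_gives_zero(self):
        assert validity_fraction(["xx(", ")yy", "zz"]) == 0.0

    def test_single_valid_molecule(self):
        assert validity_fraction(["CCO"]) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            validity_fraction([])


class TestProbeAccuracy:
    def test_real_images_score_near_probe_accuracy(self, pattern_samples):
        x = np.stack([s.x for s in pattern_samples])
        labels = np.array([s.label for s in pattern_samples])
        half = len(x) // 2
        probe = train_probe(x[:half], labels[:half], seed=0)
        own = probe.score(x[half:].reshape(half, -1)[: len(x) - half], labels[half:])
        acc = probe_accuracy(x[half:], labels[half:], probe)
        assert acc == pytest.approx(own, abs=1e-12)
        assert acc > 0.9

    def test_shuffled_labels_score_near_chance(self, pattern_samples, pattern_spec):
        x = np.stack([s.x for s in pattern_samples])
        labels = np.array([s.label for s in pattern_samples])
        half = len(x) // 2
        probe = train_probe(x[:half], labels[:half], seed=0)
        rng = np.random.default_rng(0)
        chance = np.mean([
            probe_accuracy(x[half:], rng.permutation(labels[half:]), probe)
            for _ in range(20)
        ])
        assert abs(chance - 1.0 / pattern_spec.n_classes) < 0.1

    def test_empty_generated_set_rejected(self, pattern_samples):
        x = np.stack([s.x for s in pattern_samples[:10]])
        labels = np.array([s.label for s in pattern_samples[:10]])
        probe = train_probe(x, labels, seed=0, max_iter=50)
        with pytest.raises(ValueError):
            probe_accuracy(np.zeros((0, x[0].size)), np.zeros(0, dtype=int), probe)


class TestSequenceNLL:
    def test_uniform_distribution_gives_log_vocab_per_token(self):
        vocab_size, time, batch = 7, 4, 3
        log_probs = Tensor(np.full((time, batch, vocab_size),
                                   -np.log(vocab_size)))
        targets = np.ones((batch, time), dtype=int)
        nll = seq_nll(log_probs, targets, pad_id=0)
        assert float(nll.data) == pytest.approx(np.log(vocab_size))

    def test_certain_decoder_gives_zero(self):
        vocab_size, time, batch = 5, 3, 2
        probs = np.full((time, batch, vocab_size), 1e-30)
        probs[:, :, 2] = 1.0
        log_probs = Tensor(np.log(probs))
        targets = np.full((batch, time), 2, dtype=int)
        assert float(seq_nll(log_probs, targets, pad_id=0).data) == \
            pytest.approx(0.0, abs=1e-9)

    def test_pad_positions_excluded(self):
        vocab_size = 4
        log_probs = Tensor(np.log(np.full((2, 1, vocab_size), 0.25)))
        targets = np.array([[1, 0]])  # second position is pad
        nll = seq_nll(log_probs, targets, pad_id=0)
        assert float(nll.data) == pytest.approx(np.log(4))

    def test_matches_scalar_loop_on_seeded_decoder(self):
        from biaae.models import SmilesDecoder
        rng = np.random.default_rng(4)
        decoder = SmilesDecoder(vocab_size=9, dim_zx=3, dim_s=2,
                                hidden_size=12, num_layers=1, seed=2)
        tokens = np.array([[1, 3, 4, 5, 2, 0], [1, 6, 7, 2, 0, 0]])
        z = Tensor(rng.normal(size=(2, 3)))
        s = Tensor(rng.normal(size=(2, 2)))
        log_probs = decoder.logits(z, s, tokens)
        batched = float(seq_nll(log_probs, tokens[:, 1:], pad_id=0).data)
        # oracle: explicit loop over (sample, position)
        total, count = 0.0, 0
        for b in range(2):
            for t in range(tokens.shape[1] - 1):
                target = tokens[b, t + 1]
                if target == 0:
                    continue
                total += -log_probs.data[t, b, target]
                count += 1
        assert batched == pytest.approx(total / count, rel=1e-9)


class TestConditionalNLL:
    def _model_and_vocab(self):
        from biaae.chem import SmilesVocabulary
        from biaae.models import ConditionEncoderConfig, MolecularBiAAE
        vocab = SmilesVocabulary()
        model = MolecularBiAAE(
            vocab_size=len(vocab),
            cond_config=ConditionEncoderConfig(expr_dim=30, embed_hidden=(16,),
                                               embed_out=8, head_hidden=(8,),
                                               dim_zy=3, dim_s=2,
                                               batchnorm=False),
            dim_zx=3, hidden_size=16, num_layers=1).eval()
        return model, vocab

    def test_matches_per_pair_scalar_oracle(self):
        from biaae.autograd import Tensor, no_grad
        from biaae.evaluation import conditional_nll
        model, vocab = self._model_and_vocab()
        rng = np.random.default_rng(3)
        pairs = [("CCO", rng.normal(size=30), -6.0),
                 ("c1ccccc1", rng.normal(size=30), -5.5)]
        batched = conditional_nll(model, pairs, vocab, z_mode="zero")
        # oracle: one pair at a time, explicit token loop
        totals = []
        for smiles, delta, eta in pairs:
            tokens = vocab.tokenize(smiles)
            with no_grad():
                _, s_y = model.encode_y(np.asarray(delta)[None, :], [eta])
                log_probs = model.decoder_x.logits(
                    Tensor(np.zeros((1, 3))), s_y, np.asarray([tokens]))
            nll, count = 0.0, 0
            for t in range(len(tokens) - 1):
                nll -= log_probs.data[t, 0, tokens[t + 1]]
                count += 1
            totals.append(nll / count)
        assert batched == pytest.approx(np.mean(totals), rel=1e-9)

    def test_prior_z_mode_is_seed_reproducible(self):
        from biaae.evaluation import conditional_nll
        model, vocab = self._model_and_vocab()
        rng = np.random.default_rng(4)
        pairs = [("CCN", rng.normal(size=30), -6.0)]
        first = conditional_nll(model, pairs, vocab, z_mode="prior", seed=11)
        second = conditional_nll(model, pairs, vocab, z_mode="prior", seed=11)
        assert first == second

    def test_empty_pairs_rejected(self):
        from biaae.evaluation import UndefinedMetricError, conditional_nll
        model, vocab = self._model_and_vocab()
        with pytest.raises(UndefinedMetricError):
            conditional_nll(model, [], vocab)


class TestExpressionPrediction:
    def _profiles(self, n=6, genes=10, seed=0):
        return np.random.default_rng(seed).normal(size=(n, genes))

    def test_identity_prediction_is_perfect(self):
        real = self._profiles()
        doses = np.full(len(real), -6.0)
        r2, top1, retained = expression_prediction_metrics(real, real, doses)
        assert r2 == 1.0 and top1 == 1.0 and retained == 1.0

    def test_non_argmax_perturbation_keeps_top1(self):
        real = self._profiles()
        predicted = real.copy()
        for row in predicted:
            argmax = np.abs(row).argmax()
            victim = (argmax + 1) % len(row)
            row[victim] += 0.1 * np.sign(row[victim] or 1.0)
        doses = np.full(len(real), -6.0)
        r2, top1, _ = expression_prediction_metrics(real, predicted, doses)
        assert top1 == 1.0 and r2 < 1.0

    def test_dose_window_retains_exactly_the_in_window_tuples(self):
        real = self._profiles(n=5)
        doses = np.array([-7.0, -6.5, -6.0, -5.5, -5.4])
        _, _, retained = expression_prediction_metrics(real, real, doses)
        assert retained == pytest.approx(3 / 5)

    def test_all_doses_outside_window_is_undefined(self):
        real = self._profiles(n=4)
        doses = np.full(4, -7.0)
        with pytest.raises(UndefinedMetricError):
            expression_prediction_metrics(real, real, doses)

    def test_window_bounds_match_ten_micromolar(self):
        assert DOSE_WINDOW == (-6.5, -5.5)


class TestMutualInformation:
    SPEC = MINESpec(hidden=(32, 32), n_steps=300, batch_size=256,
                    eval_every=25, seed=0)

    def test_self_information_exceeds_noisy_information(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, size=2000).astype(float)
        noisy = x + rng.normal(0, 2.0, size=2000)
        mi_self = estimate_mi(x[:, None], x[:, None], spec=self.SPEC).value
        mi_noisy = estimate_mi(x[:, None], noisy[:, None], spec=self.SPEC).value
        assert mi_self > mi_noisy

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi(np.zeros((1, 1)), np.zeros((1, 1)), spec=self.SPEC)

    def test_estimate_records_trace(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(500, 1))
        est = estimate_mi(a, a + rng.normal(size=(500, 1)), spec=self.SPEC)
        assert len(est.trace) == self.SPEC.n_steps // self.SPEC.eval_every
        assert est.value == max(est.trace)
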