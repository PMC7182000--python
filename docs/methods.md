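# Methods

## The model family

`biaae` implements adversarial autoencoders for *paired* observations
(x, y) — in the motivating application x is a drug molecule (SMILES) and y
the differential gene-expression signature (Δge over 978 landmark genes plus
a log10-molar dose η) measured after incubating that molecule. The premise
is that the two views share only part of their information: some
transcriptome variation is caused by the drug, the rest by cellular
processes the drug does not control, and conversely most of a molecule's
structural detail leaves no transcriptional trace.

The generative picture has three independent standard-normal latent blocks:
a shared code `s` and two exclusive codes `z_x`, `z_y`. Each view is decoded
from its exclusive code and the shared code: `x = G_x(z_x, s)`,
`y = G_y(z_y, s)`. Inference uses two deterministic encoders,
`(z_x, s_x) = E_x(x)` and `(z_y, s_y) = E_y(y)`, with separate shared heads
so that either view alone can supply `s`. Conditional generation of x given
y is then: extract `s_y` from y, draw `z_x ~ N(0, I)`, decode
`G_x(z_x, s_y)`; joint generation draws all three blocks from the prior.

The bidirectional objective combines five terms:

* **shared** — batch-mean `‖s_x − s_y‖²`, pulling the two shared codes
  together;
* **rec_x, rec_y** — direct plus *cross* reconstruction, where the decoder
  of one view receives the other view's shared code; the cross terms are
  what force the shared code to carry everything one view can say about the
  other (mean squared error for dense views, teacher-forced per-token NLL
  for token sequences);
* **adv** — a discriminator distinguishing the encoder triple
  `(z_x, s, z_y)` (with either shared variant, each at weight ½) from a
  factorized standard-normal triple, simultaneously matching the prior and
  factorizing the three blocks;
* **info** — two discriminators distinguishing a genuine triple from one
  whose *opposite* view's exclusive code was shuffled within the batch,
  explicitly penalizing any dependence between one view's exclusive code and
  the other view's content.

Training alternates a discriminator ascent step (encoder outputs detached)
with an encoder/decoder descent step (discriminator weights frozen), so each
phase routes gradient only into its own parameters. The default weights are
reconstruction 10, shared 0.1, adversarial and information 1 — the image
benchmark profile; the unidirectional variant's profile raises the
information weight to 100.

Three simplifications of the family are implemented as baselines: the
supervised AAE (single latent code, raw condition concatenated into the
decoder), its latent variant (condition autoencoded first), and the
unidirectional model (no `s_x`; formally the bidirectional objective with
`s_x ≡ s_y`, which the test suite checks as an exact identity).

### Sign conventions and saturation

Discriminators use a sigmoid head, but every loss evaluates log D and
log(1−D) through the *logit* with a numerically stable log-sigmoid.
An earlier revision clamped the probability at 1e-8 before the log; that
variant silently zeroes the encoder gradient precisely when a discriminator
saturates — observed in practice as the prior discriminator pinned at its
supremum while training stalled — and was replaced. Encoder-side adversarial
updates use the non-saturating, label-flipped form (maximize log D of the
triple the discriminator scores as fake) rather than minimizing log(1−D).

### Cross-reconstruction gradients

Gradients of the cross terms flow into *both* encoders (no stop-gradient on
`s_y` when reconstructing x). This maximizes the pressure on the shared code
to become informative; it is also what makes the two-phase schedule below
effective.

## Synthetic benchmarks

Real perturbation data (L1000-style signatures, curated molecule sets) are
deliberately out of scope; two generators provide ground-truth-bearing
substitutes so that every claim the package makes is testable offline.

**Factor pairs.** `s, z_x, z_y ~ N(0, I)` independently
(defaults 4/12/12); `x` mixes `(s, z_x)` and `y` mixes `(s, z_y)` through
frozen random maps (linear by default, optionally a random two-layer tanh
net), plus observation noise (default sd 0.1). Observation dims equal the
latent dims they mix, so the noiseless linear case is exactly invertible.
Disentanglement is scored by ordinary linear regression from the condition
encoder's codes to the true `s`: R² should be high from `s_y` and low from
`z_y`.

**Pattern pairs.** One fixed template per class — seeded random blobs,
Gaussian-blurred at sigma = side/10 and stretched to [0, 1] — each view an
independent uniform rotation in ±π/4 (bilinear, zeros outside), the
condition view with additive Gaussian pixel noise. The class is the only
shared feature. The noise default is 0.4: roughly twice the templates' pixel
standard deviation, yet low enough that a held-out classifier still recovers
the class from the noisy view (~92% at side 16). That calibration is part of
the benchmark's validity, not a tuning knob: at noise 1.0 the class is only
~40% recoverable from y, so no conditional generator — however good — could
place the right class in its samples more than ~40% of the time, and the
benchmark would no longer measure disentanglement. Conditional-generation
fidelity is scored by a frozen MLP classifier probe trained on an
independently generated labeled set.

What these generators do *not* emulate: the covariance structure and batch
effects of real expression data, chemical-validity constraints of real
molecules, and the heavy class imbalance of real screens. Passing the
synthetic benchmarks shows the objective routes information as intended at
realistic dimensionalities; it does not certify performance on LINCS-scale
data.

## Training recipes for the benchmarks

Numbers below are the package's default experiment sizes; they were chosen
so a full benchmark run completes in minutes on one CPU core.

**Factor benchmark** (dims 4/12/12, noise 0.1, n = 10,000): linear encoders
and decoders — the data are linear mixes, and within this model class any
information smuggling is a plain linear correlation the discriminators
detect easily — with 64×64 MLP discriminators, batch 128, Adam(0.5, 0.9) at
lr 3e-4, and a two-phase schedule: information weight 1 for 50 epochs until
the shared code saturates, then 10 for 130 epochs to purge the exclusive
code, with Polyak tail-averaging (decay 0.998) of the encoder/decoder
weights over the end of the purge phase to damp the adversarial oscillation.
The phase split matters: strong information pressure from the start
suppresses the shared code before cross-reconstruction has made it
informative, while without the second phase the exclusive code never sheds
the shared factor. Loss weights of this family are meant to be tuned per
dataset on validation metrics; the schedule was fixed on one seed and is
evaluated on fresh seeds.

**Pattern benchmark** (10 classes, side 16, n = 5,000): here the exclusive
factor is intrinsically tiny (a rotation angle), so the model uses
dim_zx = dim_zy = 2 with dim_s = 4. Wide exclusive codes (e.g. 12) let the
x-encoder smuggle the class past the discriminators and conditional samples
collapse to chance; with 2-dim exclusive codes the reconstruction path
itself prefers routing the class through `s`. Encoders 256→128 (decoders
mirrored), batch 256 at lr 6e-4, information weight 1 for 20 epochs then 10
for 60 epochs, no tail averaging (the purge phase is still drifting at its
end, and averaging a drifting trajectory degrades the endpoint).

## Mutual-information estimation

The MI estimator maximizes the Donsker–Varadhan bound
`E_P[T] − log E_Q[e^T]` over a small ReLU MLP, with the product marginal
formed by shuffling one side within the batch and a conditioning variable
(when present) appended to both joint and marginal inputs. The gradient of
the log-partition term uses an exponential moving average (decay 0.99) of
`E[e^T]`, the usual bias correction. Because the bound estimate is noisy
upward, the reported value is the maximum of an EMA-smoothed (decay 0.9)
trace of full-data bound evaluations taken every 25 steps. Defaults
(100×100 net, batch 512, 2000 steps, lr 5e-4) recover the closed-form
Gaussian MI −½ln(1−ρ²) within a few hundredths of a nat at n = 10,000 for
ρ ∈ {0, 0.5, 0.9}. Values are reported in nats.

## Molecular and expression handling

* SMILES are tokenized per character with `Cl`/`Br` as single tokens plus
  start/end/pad specials; sequence models are stacked GRUs (defaults per the
  expression-experiment configuration: hidden 128, 2 layers) with the latent
  code entering the decoder through its initial hidden state.
* The drug-likeness filter keeps molecules with MW in [250, 550] Da
  (inclusive), at least one O or N, elements within {C,N,S,O,F,Cl,Br,H}, no
  ring of more than eight atoms (SSSR), and no tetracycline scaffold. The
  scaffold is a SMARTS for the linearly fused tetracyclic carbon skeleton
  with any-order bonds (matches tetracycline/doxycycline, rejects
  anthracenes and steroids); it is a parameter, since no canonical
  definition exists. Removal attribution uses the first failing rule in the
  order weight → elements → heteroatom → ring → scaffold; de-duplication is
  by canonical SMILES after all rules.
* Expression conditions carry control and perturbed profiles over 978 genes;
  Δge is always recomputed as perturbed − control. Training pairs draw a
  control uniformly from the same plate as the perturbation (configurable
  augmentation factor); splits are by drug, so no molecule appears in two
  splits.
* Internal diversity of a generated set is 1 minus the mean pairwise
  Tanimoto similarity on 2048-bit radius-2 circular fingerprints over
  ordered distinct pairs, invalid strings excluded first.
* Expression-prediction scoring discards generated (Δge, η) tuples with η
  outside [−6.5, −5.5] log10 molar (a window around 10 μM), then reports R²
  pooled over all retained (sample, gene) entries and top-1 precision (the
  fraction of samples whose largest-|Δge| gene matches). Pooled R² was
  chosen over per-gene averaging because near-constant genes make per-gene
  R² degenerate on small sets.
* For the conditional sequence NLL, the molecular exclusive code is drawn
  once per pair from the prior under a fixed evaluation seed (`z_mode="zero"`
  selects a zero vector instead); the choice is exposed because the NLL is
  mildly z-dependent.

## Numerical core

All models run on a small reverse-mode autodiff engine over numpy arrays
(`biaae.autograd`) with the layer set the models need: dense layers,
batch-norm, dropout, embeddings, stacked GRU cells and Adam. Gradients of
every operation are verified against central finite differences in the test
suite. Double precision throughout; discriminator log-scores are evaluated
in logit space (see above), so no loss term can overflow or lose gradient to
clamping.

## Degenerate inputs and tie-breaks

* Batch shuffles for the information term require batch size ≥ 2; uniform
  random permutations may have fixed points.
* Internal diversity is undefined below two valid molecules; expression
  metrics are undefined when the dose window retains nothing — both raise a
  dedicated `UndefinedMetricError` rather than returning a sentinel.
* Multinomial SMILES decoding at temperature → 0 equals greedy decoding;
  temperature must be positive.
* Checkpoints store weights plus the full model configuration and refuse to
  load on any dimension mismatch.

## Known limitations

* CPU-scale throughput: the numpy engine is intended for the synthetic
  benchmarks and small molecular corpora, not LINCS/MOSES-scale training.
* Adversarial equilibria oscillate; probe metrics on a single seed can move
  a few hundredths between epochs near convergence, and across seeds the
  factor benchmark's probe R² values scatter by roughly ±0.1. On that
  benchmark the two probes are nearly complementary — R²(z_y) tracks
  1.1 − R²(s_y) — so whether a run lands in the high-shared/low-exclusive
  corner is substantially seed luck at this training scale. Benchmarks
  therefore report 3-seed majorities, and the test suite documents the
  scatter rather than hiding it.
* On the pattern benchmark the shared/information terms are only decisive
  when the exclusive codes are wide enough to smuggle the class: at the
  2-dim exclusive codes the benchmark uses, cross-reconstruction together
  with the prior discriminator (neither of which an information-term
  ablation removes) already transfers the class, so the ablation is
  competitive; at 12-dim exclusive codes the ablation collapses toward
  chance but the full model needs more optimization than a CPU-scale run
  provides. Both regimes are exercised by the tests.
* The unidirectional variant shares the bidirectional code path (s_x ≡ s_y)
  rather than a separate reduced architecture; its per-step cost is the same.
* Convolutional architectures are not implemented; image views are flattened
  and handled by MLPs, which is sufficient at the benchmark's image sizes.
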