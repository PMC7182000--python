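"""Recover a known shared factor from paired vector views.

Generates paired observations x, y driven by independent standard-normal
factors (s shared, z_x and z_y exclusive), trains the bidirectional
adversarial autoencoder with the package's two-phase factor-benchmark
recipe, and probes the condition encoder's codes with a linear regression
against the true s. A disentangled model stores s in its shared code (high
R²) and keeps it out of the exclusive code (low R²). Runs in a few minutes
on one CPU core.
"""

from biaae.workbench import FACTOR_BENCHMARK_SPEC, factor_benchmark

spec = FACTOR_BENCHMARK_SPEC
print(f"factor pairs: dim_s={spec.dim_s}, dim_zx={spec.dim_zx}, "
      f"dim_zy={spec.dim_zy}, noise sd {spec.noise_sd}, n=10000")
print("training the bidirectional model (two-phase schedule: information "
      "weight 1, then 10)...")

probe = factor_benchmark(train_seed=2)
print(f"linear probe R² for true s from shared code s_y:    "
      f"{probe['shared_probe_r2']:.3f}")
print(f"linear probe R² for true s from exclusive code z_y: "
      f"{probe['exclusive_probe_r2']:.3f}")
print("high shared / low exclusive R² means the model routed the common "
      "factor into the shared part of the latent code; run-to-run scatter "
      "of the adversarial equilibrium moves both numbers by ~0.1 across seeds")
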