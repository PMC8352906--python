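"""Augment a class of carcasses by within-class combination and by GAN.

Combination sums k distinct same-class carcasses (counts are conserved
exactly); the GAN learns the class distribution and samples 150 artificial
carcasses from its latent space.
"""

import numpy as np

from taphoseries import (
    GanConfig,
    combine_within_class,
    default_profiles,
    gan_generate,
    simulate_dataset,
    train_gan,
)

dataset = simulate_dataset(default_profiles(30, n_samples_per_class=40, seed=7))
primary = dataset.by_class("P")
rng = np.random.default_rng(0)

combined = combine_within_class(primary, k=2, n_new=10, rng=rng)
s = combined[0]
parts = {p.sample_id: p for p in primary}
print(f"combined case {s.sample_id}: {int(s.total_marks)} marks "
      f"= {' + '.join(str(int(parts[i].total_marks)) for i in s.provenance)} "
      f"from {s.provenance}")

generator = train_gan(primary, GanConfig(seed=1, epochs=150))
cases = gan_generate(generator, n=150, rng=rng)
X = np.stack([c.values for c in cases])
real = np.stack([p.values for p in primary])
print(f"GAN: {len(cases)} artificial carcasses, all nonnegative: {(X >= 0).all()}")
print(f"mean total marks: generated {X.sum(axis=1).mean():.1f} "
      f"vs training {real.sum(axis=1).mean():.1f}")
rel = gan_generate(generator, n=3, rng=rng, mode="relative")
print("relative-mode outputs sum to:", [float(round(r.values.sum(), 9)) for r in rel])
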