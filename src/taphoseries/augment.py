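"""Data augmentation of small experimental reference sets.

Two routes, both strictly within-class (labels are never mixed):

* **within-class combination** — each new artificial carcass is the
  element-wise sum of k distinct same-class carcasses; counts are conserved
  exactly and provenance is recorded;
* **GAN sampling** — a small fully-connected adversarial pair (generator +
  discriminator, binary cross-entropy loss, Adam) is trained per class on
  series scaled to [0, 1] by per-bin maxima; sampling the latent space yields
  new cases that are un-scaled back to count space, clipped to be
  nonnegative, and — in relative mode — renormalised to sum to 100.

The adversarial pair is implemented directly on numpy (dense layers, manual
backpropagation); all randomness flows through explicit generators, so
training and sampling are reproducible bit for bit from a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import AssemblageSeries


def combine_within_class(
    samples: Sequence[AssemblageSeries],
    k: int = 2,
    n_new: int = 10,
    rng: np.random.Generator | None = None,
) -> list[AssemblageSeries]:
    """Sum k distinct same-class carcasses into each of n_new artificial ones.

    The k constituents of each new case are drawn without replacement, so a
    sample is never combined with itself; ``total_marks`` adds and the
    constituent sample ids are recorded in ``provenance``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the {len(samples)} available samples")
    lengths = {len(s.values) for s in samples}
    if len(lengths) > 1:
        raise ValueError("samples must share series length")
    modes = {s.mode for s in samples}
    if modes != {"raw"}:
        raise ValueError("combination augmentation operates on raw-mode series")
    if rng is None:
        rng = np.random.default_rng()
    out = []
    for i in range(n_new):
        picks = rng.choice(len(samples), size=k, replace=False)
        parts = [samples[j] for j in picks]
        values = np.sum([p.values for p in parts], axis=0)
        out.append(
            AssemblageSeries(
                sample_id=f"comb{i:04d}",
                values=values,
                mode="raw",
                total_marks=int(sum(p.total_marks for p in parts)),
                provenance=tuple(p.sample_id for p in parts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Minimal dense adversarial pair on numpy


@dataclass
class GanConfig:
    """Architecture and training settings of the per-class GAN."""

    latent_dim: int = 16
    hidden_widths: tuple[int, ...] = (64, 64)
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    n_generate: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generate < 1:
            raise ValueError("n_generate must be >= 1")
        if self.latent_dim < 1 or min(self.hidden_widths, default=1) < 1:
            raise ValueError("network widths must be positive")


class _Mlp:
    """Dense network with manual forward/backward and Adam updates."""

    def __init__(self, sizes, out_activation, rng, leaky=0.0):
        self.leaky = leaky
        self.out_activation = out_activation
        self.W = [
            rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self._m = [np.zeros_like(p) for p in self.W + self.b]
        self._v = [np.zeros_like(p) for p in self.W + self.b]
        self._t = 0

    def forward(self, x):
        acts = [x]
        h = x
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if li < len(self.W) - 1:
                h = np.where(z > 0, z, self.leaky * z)
            elif self.out_activation == "sigmoid":
                h = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
            else:
                h = z
            acts.append(h)
        return h, acts

    def backward(self, acts, grad_out):
        """Backprop; ``grad_out`` is dLoss/d(output). Returns dLoss/d(input)."""
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        g = grad_out
        for li in reversed(range(len(self.W))):
            out = acts[li + 1]
            if li == len(self.W) - 1:
                gz = g * out * (1 - out) if self.out_activation == "sigmoid" else g
            else:
                gz = g * np.where(out > 0, 1.0, self.leaky)
            gW[li] = acts[li].T @ gz
            gb[li] = gz.sum(axis=0)
            g = gz @ self.W[li].T
        self._grads = (gW, gb)
        return g

    def adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        gW, gb = self._grads
        self._t += 1
        params = self.W + self.b
        grads = gW + gb
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** self._t)
            vhat = v / (1 - beta2 ** self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class GanGenerator:
    """Trained generator handle: maps latent vectors to series-length vectors.

    ``scale`` is the per-bin maximum of the training set; generated outputs in
    [0, 1] are multiplied back by it, so bins that were identically zero in
    training (e.g. exclusive zones of the secondary class) stay zero.
    """

    def __init__(self, net: _Mlp, latent_dim: int, scale: np.ndarray):
        self._net = net
        self.latent_dim = latent_dim
        self.scale = scale

    def __call__(self, z: np.ndarray) -> np.ndarray:
        out, _ = self._net.forward(np.atleast_2d(z))
        return np.clip(out, 0.0, None) * self.scale

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self(rng.standard_normal((n, self.latent_dim)))


def train_gan(
    samples: Sequence[AssemblageSeries] | np.ndarray,
    config: GanConfig,
    probe_hook=None,
) -> GanGenerator:
    """Train one adversarial pair on the series of a single class.

    ``probe_hook(epoch, generator)``, if given, is called once per epoch with
    a read-only handle (used to monitor convergence).  Raises on non-finite
    losses.
    """
    if not isinstance(samples, np.ndarray):
        X = np.stack([s.values for s in samples])
    else:
        X = np.asarray(samples, dtype=float)
    if len(X) < 2:
        raise ValueError("GAN training needs at least 2 samples")
    scale = X.max(axis=0)
    safe = np.where(scale == 0, 1.0, scale)
    Xs = X / safe
    rng = np.random.default_rng(config.seed)
    L = X.shape[1]
    gen = _Mlp(
        [config.latent_dim, *config.hidden_widths, L], "sigmoid", rng
    )
    disc = _Mlp(
        [L, *reversed(config.hidden_widths), 1], "sigmoid", rng, leaky=0.2
    )
    handle = GanGenerator(gen, config.latent_dim, scale)
    eps = 1e-7
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xs))
        for start in range(0, len(Xs), config.batch_size):
            real = Xs[order[start : start + config.batch_size]]
            nb = len(real)
            z = rng.standard_normal((nb, config.latent_dim))
            fake, gen_acts = gen.forward(z)
            # discriminator step: real -> 1, fake -> 0
            d_real, acts_r = disc.forward(real)
            d_fake, acts_f = disc.forward(fake)
            loss_d = -np.mean(
                np.log(d_real + eps) + np.log(1 - d_fake + eps)
            )
            if not np.isfinite(loss_d):
                raise FloatingPointError(
                    f"non-finite discriminator loss at epoch {epoch}"
                )
            disc.backward(acts_r, -1.0 / (d_real + eps) / (2 * nb))
            gr = disc._grads
            disc.backward(acts_f, 1.0 / (1 - d_fake + eps) / (2 * nb))
            gf = disc._grads
            disc._grads = (
                [a + b for a, b in zip(gr[0], gf[0])],
                [a + b for a, b in zip(gr[1], gf[1])],
            )
            disc.adam_step(config.learning_rate)
            # generator step: non-saturating loss, fake -> 1
            fake, gen_acts = gen.forward(z)
            d_fake, acts_f = disc.forward(fake)
            loss_g = -np.mean(np.log(d_fake + eps))
            if not np.isfinite(loss_g):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}"
                )
            g_in = disc.backward(acts_f, -1.0 / (d_fake + eps) / nb)
            gen.backward(gen_acts, g_in)
            gen.adam_step(config.learning_rate)
        if probe_hook is not None:
            probe_hook(epoch, handle)
    return handle


def gan_generate(
    generator: GanGenerator,
    n: int,
    rng: np.random.Generator,
    mode: str = "raw",
    prefix: str = "gan",
) -> list[AssemblageSeries]:
    """Sample n artificial carcasses from a trained generator.

    Raw-mode outputs are left real-valued (classifiers consume real vectors);
    relative-mode outputs are renormalised to sum to 100.
    """
    values = generator.sample(n, rng)
    out = []
    for i, v in enumerate(values):
        if mode == "relative":
            total = v.sum()
            if total > 0:
                v = 100.0 * v / total
        out.append(
            AssemblageSeries(
                sample_id=f"{prefix}{i:04d}",
                values=v,
                mode=mode,
                total_marks=int(round(v.sum())) if mode == "raw" else 0,
            )
        )
    return out
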