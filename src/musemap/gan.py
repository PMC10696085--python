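"""Unpaired modality translation between unfixed (A) and FFPE (B) domains.

A CycleGAN: two generators (``G_AB``: unfixed -> FFPE-like, ``G_BA``: the
reverse) and two least-squares patch discriminators, trained jointly under

``l_total = l_adv + alpha * l_cycle + beta * l_identity``

with ``alpha = 10`` (cycle-consistency weight) and ``beta = 1`` (identity
weight) by default.  Expectations are batch means and the L1 norm is the
mean absolute difference, so every loss is resolution-independent.

Patches are scaled to [-1, 1] by ``x / 127.5 - 1`` before entering a
generator and mapped back with the exact inverse afterwards.

The trainable front-end is :class:`CycleGANTranslator`, a scikit-learn
style estimator (``fit(X_a, X_b)`` / ``transform`` / ``inverse_transform``);
:func:`train_cyclegan` and :func:`translate_image` are thin functional
wrappers used by the command-line pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .synthetic import PatchDataset, SyntheticImage


# --------------------------------------------------------------------------
# normalisation


def normalize_gan(patch: np.ndarray) -> np.ndarray:
    """Scale [0, 255] intensities to [-1, 1] (divide by 127.5, subtract 1)."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.min() < 0 or patch.max() > 255:
        raise ValueError("input values must lie in [0, 255]")
    return patch / np.float32(127.5) - np.float32(1.0)


def denormalize_gan(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_gan`: [-1, 1] back to [0, 255]."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.min() < -1 - 1e-5 or arr.max() > 1 + 1e-5:
        raise ValueError("input values must lie in [-1, 1]")
    return np.clip((arr + np.float32(1.0)) * np.float32(127.5), 0.0, 255.0)


# --------------------------------------------------------------------------
# losses (least-squares adversarial form; L1 terms are means)


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 10.0  # cycle-consistency weight
    beta: float = 1.0    # identity weight

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be >= 0")


def adversarial_loss_d(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """Discriminator objective: mean((real - 1)^2) + mean(fake^2)."""
    real_scores = np.asarray(real_scores, dtype=np.float64)
    fake_scores = np.asarray(fake_scores, dtype=np.float64)
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("score sets must be non-empty")
    return float(((real_scores - 1.0) ** 2).mean() + (fake_scores ** 2).mean())


def adversarial_loss_g(fake_scores: np.ndarray) -> float:
    """Generator objective: mean((fake - 1)^2)."""
    fake_scores = np.asarray(fake_scores, dtype=np.float64)
    if fake_scores.size == 0:
        raise ValueError("score set must be non-empty")
    return float(((fake_scores - 1.0) ** 2).mean())


def _mean_l1(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.abs(x - y).mean())


def cycle_loss(x_a: np.ndarray, x_a_rec: np.ndarray,
               x_b: np.ndarray, x_b_rec: np.ndarray) -> float:
    """Round-trip reconstruction error: mean|rec_a - a| + mean|rec_b - b|."""
    return _mean_l1(x_a_rec, x_a) + _mean_l1(x_b_rec, x_b)


def identity_loss(x_a: np.ndarray, g_ba_of_a: np.ndarray,
                  x_b: np.ndarray, g_ab_of_b: np.ndarray) -> float:
    """Same-domain fidelity: mean|G_BA(a) - a| + mean|G_AB(b) - b|."""
    return _mean_l1(g_ba_of_a, x_a) + _mean_l1(g_ab_of_b, x_b)


def total_loss(l_adv: float, l_cycle: float, l_identity: float,
               w: LossWeights = LossWeights()) -> float:
    """Weighted sum l_adv + alpha * l_cycle + beta * l_identity."""
    if min(l_adv, l_cycle, l_identity) < 0:
        raise ValueError("loss components must be >= 0")
    return float(l_adv + w.alpha * l_cycle + w.beta * l_identity)


# --------------------------------------------------------------------------
# networks


def build_generator(ngf: int = 8, n_res: int = 2,
                    rng: np.random.Generator | None = None,
                    downsample: bool = True) -> nn.Layer:
    """Correction-field generator: out = clip(x + tanh(f(x)), -1, 1).

    The conv stack ``f`` predicts a bounded residual, so the generator is
    near-identity at initialisation — identity and cycle objectives are
    well-conditioned from the first step, and translation is learned as a
    correction (background removal, contrast restoration, edge sharpening)
    on top of the input.  ``downsample=True`` swaps the full-resolution
    stack for the classic stride-2 encoder/decoder shape (cheaper per
    pixel, but it low-passes fine nuclear texture).
    """
    rng = rng or np.random.default_rng(0)
    if downsample:
        # two stride-2 levels: residual blocks at quarter resolution give the
        # correction head a ~50 px receptive field, enough to estimate the
        # smooth out-of-focus background it must subtract
        body = nn.Sequential(
            nn.Conv2d(3, ngf, 3, rng=rng), nn.InstanceNorm(ngf), nn.ReLU(),
            nn.Conv2d(ngf, 2 * ngf, 3, stride=2, rng=rng),
            nn.InstanceNorm(2 * ngf), nn.ReLU(),
            nn.Conv2d(2 * ngf, 4 * ngf, 3, stride=2, rng=rng),
            nn.InstanceNorm(4 * ngf), nn.ReLU(),
            *[nn.ResBlock(4 * ngf, rng=rng) for _ in range(n_res)],
            nn.Upsample2x(), nn.Conv2d(4 * ngf, 2 * ngf, 3, rng=rng),
            nn.InstanceNorm(2 * ngf), nn.ReLU(),
            nn.Upsample2x(), nn.Conv2d(2 * ngf, ngf, 3, rng=rng),
            nn.InstanceNorm(ngf), nn.ReLU(),
            nn.Conv2d(ngf, 3, 3, rng=rng), nn.Tanh(),
        )
    else:
        body = nn.Sequential(
            nn.Conv2d(3, ngf, 3, rng=rng), nn.InstanceNorm(ngf), nn.ReLU(),
            *[nn.ResBlock(ngf, rng=rng) for _ in range(n_res)],
            nn.Conv2d(ngf, 3, 3, rng=rng), nn.Tanh(),
        )
    # moderate-init correction head: starts close to identity without
    # throttling gradient flow into the body
    final_conv = [l for l in body.layers() if isinstance(l, nn.Conv2d)][-1]
    final_conv.params["w"] *= np.float32(0.3)
    return nn.ResidualAdd(body)


def build_discriminator(ndf: int = 8,
                        rng: np.random.Generator | None = None) -> nn.Sequential:
    """Strided patch discriminator producing a grid of realness scores.

    Deliberately *unnormalised*: the two domains differ chiefly in
    low-frequency brightness (haze, contrast), and per-patch normalisation
    layers would blind the discriminator to exactly those cues.
    """
    rng = rng or np.random.default_rng(0)
    return nn.Sequential(
        nn.Conv2d(3, ndf, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(0.2),
        nn.Conv2d(ndf, 2 * ndf, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(0.2),
        nn.Conv2d(2 * ndf, 4 * ndf, 4, stride=2, pad=1, rng=rng),
        nn.LeakyReLU(0.2),
        nn.Conv2d(4 * ndf, 1, 3, rng=rng),
    )


@dataclass
class TranslatorPair:
    """The two generators: g_ab maps unfixed -> FFPE-like, g_ba the reverse."""

    g_ab: nn.Layer
    g_ba: nn.Layer


@dataclass
class DiscriminatorPair:
    """d_a scores domain-A realness, d_b domain-B realness."""

    d_a: nn.Sequential
    d_b: nn.Sequential


@dataclass(frozen=True)
class GanTrainConfig:
    learning_rate: float = 0.0002
    epochs: int = 12           # paper-scale runs use 48
    batch_size: int = 4
    patch_size: int = 64       # paper-scale runs use 256
    alpha: float = 10.0
    beta: float = 1.0
    ngf: int = 8
    ndf: int = 8
    n_res: int = 2
    downsample: bool = True
    max_patches: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _to_nchw(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)), dtype=np.float32)


def _to_nhwc(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(x, (0, 2, 3, 1)))


class CycleGANTranslator(BaseEstimator, TransformerMixin):
    """Unpaired two-domain image translator (CycleGAN), scikit-learn style.

    ``fit(X_a, X_b)`` takes two *unpaired* stacks of S x S x 3 patches in
    [0, 255] (domain A = unfixed-like, domain B = FFPE-like); ``transform``
    maps A -> B and ``inverse_transform`` maps B -> A, both in [0, 255].

    Fitted attributes: ``pair_`` (generators), ``discriminators_``,
    ``history_`` (per-epoch loss components) and, when ``keep_last_batch``
    is set, ``last_batch_`` with the final step's tensors and logged loss
    values for external cross-checking.
    """

    def __init__(self, epochs: int = 6, batch_size: int = 4,
                 learning_rate: float = 0.0002, alpha: float = 10.0,
                 beta: float = 1.0, ngf: int = 8, ndf: int = 8, n_res: int = 2,
                 downsample: bool = True, max_patches: int = 2000,
                 random_state: int = 0, keep_last_batch: bool = False):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.beta = beta
        self.ngf = ngf
        self.ndf = ndf
        self.n_res = n_res
        self.downsample = downsample
        self.max_patches = max_patches
        self.random_state = random_state
        self.keep_last_batch = keep_last_batch

    # -- fitting ----------------------------------------------------------

    def fit(self, X_a: np.ndarray, X_b: np.ndarray) -> "CycleGANTranslator":
        a = np.asarray(X_a, dtype=np.float32)
        b = np.asarray(X_b, dtype=np.float32)
        if a.size == 0 or b.size == 0:
            raise ValueError("both domains must contain patches")
        if a.shape[1:] != b.shape[1:]:
            raise ValueError(f"patch shapes differ: {a.shape[1:]} vs {b.shape[1:]}")
        rng = np.random.default_rng(self.random_state)
        if len(a) > self.max_patches:
            a = a[rng.choice(len(a), self.max_patches, replace=False)]
        if len(b) > self.max_patches:
            b = b[rng.choice(len(b), self.max_patches, replace=False)]
        a = _to_nchw(normalize_gan(a))
        b = _to_nchw(normalize_gan(b))

        g_ab = build_generator(self.ngf, self.n_res, rng, self.downsample)
        g_ba = build_generator(self.ngf, self.n_res, rng, self.downsample)
        d_a = build_discriminator(self.ndf, rng)
        d_b = build_discriminator(self.ndf, rng)
        opt_d = nn.Adam([d_a, d_b], self.learning_rate)
        opt_g = nn.Adam([g_ab, g_ba], self.learning_rate)
        weights = LossWeights(self.alpha, self.beta)

        n_batches = max(1, min(len(a), len(b)) // self.batch_size)
        history: list[dict[str, float]] = []
        for epoch in range(self.epochs):
            ia = rng.permutation(len(a))
            ib = rng.permutation(len(b))
            sums = {k: 0.0 for k in ("l_adv_A", "l_adv_B", "l_cycle",
                                     "l_identity", "l_total", "d_a_loss",
                                     "d_b_loss")}
            for step in range(n_batches):
                xa = a[ia[step * self.batch_size:(step + 1) * self.batch_size]]
                xb = b[ib[step * self.batch_size:(step + 1) * self.batch_size]]
                rec = self._train_step(xa, xb, g_ab, g_ba, d_a, d_b,
                                       opt_d, opt_g, weights)
                for k in sums:
                    sums[k] += rec[k]
            entry = {"epoch": float(epoch)}
            entry.update({k: v / n_batches for k, v in sums.items()})
            history.append(entry)

        self.pair_ = TranslatorPair(g_ab, g_ba)
        self.discriminators_ = DiscriminatorPair(d_a, d_b)
        self.history_ = history
        return self

    def _train_step(self, xa, xb, g_ab, g_ba, d_a, d_b, opt_d, opt_g, w):
        # generator forwards (each call owns its cache)
        fake_b, c_fb = g_ab.forward(xa)
        rec_a, c_ra = g_ba.forward(fake_b)
        fake_a, c_fa = g_ba.forward(xb)
        rec_b, c_rb = g_ab.forward(fake_a)
        id_a, c_ia = g_ba.forward(xa)
        id_b, c_ib = g_ab.forward(xb)

        # discriminator step (fakes detached)
        nn.zero_grads(d_a), nn.zero_grads(d_b)
        s, c = d_b.forward(xb)
        l_db, g = nn.mse_to(s, 1.0)
        d_b.backward(c, g)
        s, c = d_b.forward(fake_b)
        l_db_f, g = nn.mse_to(s, 0.0)
        d_b.backward(c, g)
        s, c = d_a.forward(xa)
        l_da, g = nn.mse_to(s, 1.0)
        d_a.backward(c, g)
        s, c = d_a.forward(fake_a)
        l_da_f, g = nn.mse_to(s, 0.0)
        d_a.backward(c, g)
        opt_d.step()

        # generator step
        for net in (g_ab, g_ba, d_a, d_b):
            nn.zero_grads(net)
        s_fb, c_dfb = d_b.forward(fake_b)
        l_gadv_b, gs = nn.mse_to(s_fb, 1.0)
        grad_fake_b = d_b.backward(c_dfb, gs)
        s_fa, c_dfa = d_a.forward(fake_a)
        l_gadv_a, gs = nn.mse_to(s_fa, 1.0)
        grad_fake_a = d_a.backward(c_dfa, gs)

        l_cyc_a, g_rec_a = nn.l1_to(rec_a, xa)
        l_cyc_b, g_rec_b = nn.l1_to(rec_b, xb)
        l_id_a, g_id_a = nn.l1_to(id_a, xa)
        l_id_b, g_id_b = nn.l1_to(id_b, xb)

        grad_fake_b = grad_fake_b + g_ba.backward(c_ra, w.alpha * g_rec_a)
        g_ab.backward(c_fb, grad_fake_b.astype(np.float32))
        grad_fake_a = grad_fake_a + g_ab.backward(c_rb, w.alpha * g_rec_b)
        g_ba.backward(c_fa, grad_fake_a.astype(np.float32))
        g_ba.backward(c_ia, w.beta * g_id_a)
        g_ab.backward(c_ib, w.beta * g_id_b)
        opt_g.step()

        l_cycle = l_cyc_a + l_cyc_b
        l_identity = l_id_a + l_id_b
        l_adv = l_gadv_a + l_gadv_b
        rec = {
            "l_adv_A": l_gadv_a, "l_adv_B": l_gadv_b, "l_cycle": l_cycle,
            "l_identity": l_identity,
            "l_total": total_loss(l_adv, l_cycle, l_identity, w),
            "d_a_loss": l_da + l_da_f, "d_b_loss": l_db + l_db_f,
        }
        if self.keep_last_batch:
            self.last_batch_ = {
                "x_a": xa.copy(), "x_b": xb.copy(),
                "rec_a": rec_a.copy(), "rec_b": rec_b.copy(),
                "id_a": id_a.copy(), "id_b": id_b.copy(),
                "logged": dict(rec),
            }
        return rec

    # -- inference --------------------------------------------------------

    def _apply(self, net: nn.Layer, X: np.ndarray,
               chunk: int = 32) -> np.ndarray:
        x = _to_nchw(normalize_gan(np.asarray(X, dtype=np.float32)))
        outs = []
        for i in range(0, len(x), chunk):
            y, _ = net.forward(x[i:i + chunk])
            outs.append(y)
        return denormalize_gan(_to_nhwc(np.concatenate(outs)))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Translate domain-A (unfixed-like) patches to domain B (FFPE-like)."""
        return self._apply(self.pair_.g_ab, X)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        """Translate domain-B patches back to domain A."""
        return self._apply(self.pair_.g_ba, X)


def train_cyclegan(set_a: PatchDataset | np.ndarray,
                   set_b: PatchDataset | np.ndarray,
                   cfg: GanTrainConfig = GanTrainConfig()
                   ) -> tuple[TranslatorPair, DiscriminatorPair, list[dict]]:
    """Functional wrapper around :class:`CycleGANTranslator`."""
    xa = set_a.as_arrays()[0] if isinstance(set_a, PatchDataset) else np.asarray(set_a)
    xb = set_b.as_arrays()[0] if isinstance(set_b, PatchDataset) else np.asarray(set_b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both domains must contain patches")
    if xa.shape[1] != cfg.patch_size or xb.shape[1] != cfg.patch_size:
        raise ValueError(
            f"patch size mismatch: data {xa.shape[1]}/{xb.shape[1]} "
            f"vs config {cfg.patch_size}")
    est = CycleGANTranslator(
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, alpha=cfg.alpha, beta=cfg.beta,
        ngf=cfg.ngf, ndf=cfg.ndf, n_res=cfg.n_res, downsample=cfg.downsample,
        max_patches=cfg.max_patches, random_state=cfg.rng_seed,
    ).fit(xa, xb)
    return est.pair_, est.discriminators_, est.history_


def save_translator(path, pair: TranslatorPair,
                    discriminators: DiscriminatorPair | None = None,
                    ngf: int = 8, ndf: int = 8, n_res: int = 2,
                    downsample: bool = True) -> None:
    """Checkpoint generators (and optionally discriminators) to one .npz."""
    nets: dict[str, nn.Layer] = {"g_ab": pair.g_ab, "g_ba": pair.g_ba}
    if discriminators is not None:
        nets.update(d_a=discriminators.d_a, d_b=discriminators.d_b)
    payload = {"_arch": np.array([ngf, ndf, n_res, int(downsample)])}
    for name, net in nets.items():
        for i, layer in enumerate(net.layers()):
            for k, v in layer.params.items():
                payload[f"{name}/{i}/{k}"] = v
    np.savez(path, **payload)


def load_translator(path) -> TranslatorPair:
    with np.load(path) as archive:
        arch = [int(v) for v in archive["_arch"]]
        ngf, _ndf, n_res = arch[:3]
        downsample = bool(arch[3]) if len(arch) > 3 else True
        pair = TranslatorPair(build_generator(ngf, n_res, downsample=downsample),
                              build_generator(ngf, n_res, downsample=downsample))
        for name, net in (("g_ab", pair.g_ab), ("g_ba", pair.g_ba)):
            for i, layer in enumerate(net.layers()):
                for k in layer.params:
                    layer.params[k][...] = archive[f"{name}/{i}/{k}"]
    return pair


def translate_patches(net: nn.Layer, patches: np.ndarray,
                      chunk: int = 32) -> np.ndarray:
    """Run (N, S, S, 3) patches in [0, 255] through a generator, batched."""
    x = _to_nchw(normalize_gan(np.asarray(patches, dtype=np.float32)))
    outs = []
    for i in range(0, len(x), chunk):
        y, _ = net.forward(x[i:i + chunk])
        outs.append(y)
    return denormalize_gan(_to_nhwc(np.concatenate(outs)))


def apply_generator(net: nn.Layer, tile: np.ndarray) -> np.ndarray:
    """Run one S x S x 3 tile in [0,255] through a generator."""
    return translate_patches(net, tile[None])[0]


def translate_image(pair: TranslatorPair, image: SyntheticImage,
                    tile: int) -> SyntheticImage:
    """Translate a whole image tile-by-tile and stitch the result.

    The image is reflect-padded to a tile multiple, cut into non-overlapping
    tiles, each translated by the generator matching the image's domain
    (unfixed -> FFPE via g_ab, FFPE -> unfixed via g_ba), stitched back and
    cropped to the original size.  The domain tag is flipped; mask and label
    are untouched.
    """
    h, w = image.pixels.shape[:2]
    if tile > min(h, w):
        raise ValueError(f"tile {tile} larger than image {h}x{w}")
    net = pair.g_ab if image.domain == "unfixed" else pair.g_ba
    pad_h = (-h) % tile
    pad_w = (-w) % tile
    padded = np.pad(image.pixels, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    out = np.empty_like(padded)
    for r in range(0, padded.shape[0], tile):
        for c in range(0, padded.shape[1], tile):
            out[r:r + tile, c:c + tile] = apply_generator(
                net, padded[r:r + tile, c:c + tile])
    return SyntheticImage(
        pixels=out[:h, :w].astype(np.float32),
        domain="ffpe" if image.domain == "unfixed" else "unfixed",
        label=image.label,
        mask=image.mask.copy(),
        image_id=image.image_id + "-translated",
    )
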