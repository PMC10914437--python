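"""Expression-conditioned style-based GAN for 2-channel cell crops.

Architecture (desk scale).  The generator follows the style-based recipe: a
mapping network turns the (standardized) expression vector plus a class
embedding into a latent ``w``, which modulates every layer of a synthesis
network seeded by a learned constant, with per-layer noise as the only other
stochasticity — the expression table *is* the latent input, there is no
separate random ``z``.  At this package's scale the synthesis layers are
style-modulated fully-connected transforms rather than convolutions: the
crops are small (32x32, 2 channels) and this keeps single-CPU training in
the seconds-to-minutes range while preserving the mapping-network / style /
noise structure that editing relies on.

The discriminator is conditioned by projection: its penultimate features are
scored against a binary-class embedding *and* a linear embedding of the
expression vector.  Conditioning on the expression (not only the class label)
ties the generator to the joint (expression, image) distribution, which is
what makes feeding *edited* expression vectors move the generated morphology
in the intended direction.

Objective: non-saturating logistic adversarial loss, plus lazily applied R1
gradient penalty on real samples and path-length regularization on the
generator, with weights ``lambda_r1`` and ``lambda_path``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .nn import Tensor, grad, softplus, leaky_relu, Module, Linear, Embedding, MLP, Adam
from .metrics import ToyFeatureExtractor, dfid

__all__ = [
    "GanConfig",
    "StyleLatent",
    "ExprStandardizer",
    "Generator",
    "Discriminator",
    "adversarial_loss_g",
    "adversarial_loss_d",
    "loss_r1",
    "loss_path",
    "PathLengthState",
    "train_gan",
    "generate_edited",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GanConfig:
    p: int
    image_size: int = 32
    channels: int = 2
    latent: int = 64
    mapping_layers: int = 2
    synth_widths: tuple[int, ...] = (128, 256, 256)
    lambda_r1: float = 10.0
    lambda_path: float = 2.0
    r1_every: int = 16
    path_every: int = 8
    path_decay: float = 0.99
    batch: int = 16
    iters: int = 1200
    ckpt_every: int = 400
    lr: float = 2e-3
    seed: int = 0

    def __post_init__(self):
        if self.lambda_r1 < 0 or self.lambda_path < 0:
            raise ValueError("loss weights must be nonnegative")
        s = self.image_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 16")

    @property
    def n_styles(self) -> int:
        return len(self.synth_widths)


@dataclass
class StyleLatent:
    """Per-layer style vectors (n, n_styles, latent) plus the class labels."""

    w: Tensor
    c: np.ndarray


class ExprStandardizer:
    """Per-gene z-scoring of sign-preserving log1p expression.

    ``sign(x) * log1p(|x|)`` equals log1p on counts but stays defined on the
    real-valued vectors produced by editing.  Statistics come from the
    training split and are frozen afterwards.
    """

    def __init__(self):
        self.mu = None
        self.sd = None

    @staticmethod
    def _link(x: np.ndarray) -> np.ndarray:
        return np.sign(x) * np.log1p(np.abs(x))

    def fit(self, G: np.ndarray) -> "ExprStandardizer":
        z = self._link(np.asarray(G, dtype=np.float64))
        self.mu = z.mean(axis=0)
        self.sd = np.maximum(z.std(axis=0), 1e-6)
        return self

    def transform(self, G: np.ndarray) -> np.ndarray:
        if self.mu is None:
            raise RuntimeError("standardizer not fitted")
        G = np.atleast_2d(np.asarray(G, dtype=np.float64))
        if G.shape[1] != self.mu.shape[0]:
            raise ValueError(f"expected {self.mu.shape[0]} genes, got {G.shape[1]}")
        return (self._link(G) - self.mu) / self.sd

    def state(self):
        return {"std_mu": self.mu, "std_sd": self.sd}

    def load(self, state):
        self.mu = np.asarray(state["std_mu"], dtype=np.float64)
        self.sd = np.asarray(state["std_sd"], dtype=np.float64)
        return self


class MappingNetwork(Module):
    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        self.in_proj = Linear(cfg.p, cfg.latent, rng)
        self.class_emb = Embedding(2, cfg.latent, rng)
        self.mlp = MLP([cfg.latent] * (cfg.mapping_layers + 1), rng)

    def forward(self, expr_z: np.ndarray, c: np.ndarray) -> Tensor:
        h = self.in_proj(Tensor(expr_z)) + self.class_emb(c)
        return self.mlp(leaky_relu(h))


class SynthesisNetwork(Module):
    """Learned-constant input, style-modulated dense layers, per-layer noise,
    tanh output in (-1, 1)."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        widths = list(cfg.synth_widths)
        self.cfg_shape = (cfg.channels, cfg.image_size, cfg.image_size)
        self.const = Tensor(rng.normal(0.0, 1.0, size=(widths[0],)), requires_grad=True)
        self.styles = [Linear(cfg.latent, wi, rng, gain=0.3) for wi in widths]
        self.hidden = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.noise_strength = [Tensor(np.zeros(()), requires_grad=True)
                               for _ in range(len(widths) - 1)]
        out_dim = int(np.prod(self.cfg_shape))
        self.to_img = Linear(widths[-1], out_dim, rng)

    def forward(self, w: Tensor, noise: list[np.ndarray] | None) -> Tensor:
        n = w.shape[0]
        h = self.const.reshape(1, -1).broadcast_to((n, self.const.shape[0]))
        for l, layer in enumerate(self.hidden):
            s = 1.0 + self.styles[l](w[:, l, :])
            h = layer(h * s)
            if noise is not None:
                h = h + self.noise_strength[l] * Tensor(noise[l])
            h = leaky_relu(h)
        s = 1.0 + self.styles[-1](w[:, -1, :])
        img = self.to_img(h * s).tanh()
        return img.reshape((n,) + self.cfg_shape)


class Generator(Module):
    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.mapping = MappingNetwork(cfg, rng)
        self.synthesis = SynthesisNetwork(cfg, rng)
        self.standardizer = ExprStandardizer()

    # -- mapping -----------------------------------------------------------
    def mapping_forward(self, expr: np.ndarray, c: np.ndarray) -> StyleLatent:
        """Expression (raw scale, real-valued allowed) + class -> per-layer
        style latents.  Deterministic given parameters."""
        expr_z = self.standardizer.transform(expr)
        c = np.atleast_1d(np.asarray(c, dtype=np.intp))
        if len(c) != expr_z.shape[0]:
            raise ValueError("expression rows and labels differ in length")
        w = self.mapping(expr_z, c)
        n, latent = w.shape
        w_layers = w.reshape(n, 1, latent).broadcast_to((n, self.cfg.n_styles, latent))
        return StyleLatent(w=w_layers, c=c)

    def make_noise(self, n: int, noise_seed: int) -> list[np.ndarray]:
        widths = self.cfg.synth_widths
        return [np.random.default_rng([noise_seed, l]).standard_normal((n, widths[l + 1]))
                for l in range(len(widths) - 1)]

    def generator_forward(self, latent: StyleLatent, noise_seed: int = 0) -> Tensor:
        """Synthesis pass: (n, 2, S, S) images in (-1, 1)."""
        noise = self.make_noise(latent.w.shape[0], noise_seed)
        return self.synthesis(latent.w, noise)

    def forward(self, expr: np.ndarray, c: np.ndarray, noise_seed: int = 0) -> Tensor:
        return self.generator_forward(self.mapping_forward(expr, c), noise_seed)


class Discriminator(Module):
    """MLP trunk with projection conditioning on class and expression."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        in_dim = cfg.channels * cfg.image_size**2
        self.trunk = MLP([in_dim, 256, 128, 64], rng)
        self.out = Linear(64, 1, rng)
        self.class_emb = Embedding(2, 64, rng)
        self.expr_proj = Linear(cfg.p, 64, rng, gain=0.3)

    def forward(self, images: Tensor, expr_z: np.ndarray, c: np.ndarray) -> Tensor:
        n = images.shape[0]
        feat = leaky_relu(self.trunk(images.reshape(n, -1)))
        logit = self.out(feat)
        logit = logit + (feat * self.class_emb(c)).sum(axis=1, keepdims=True)
        logit = logit + (feat * self.expr_proj(Tensor(expr_z))).sum(axis=1, keepdims=True)
        return logit.reshape(n)


# ---------------------------------------------------------------- losses
def adversarial_loss_g(fake_logits: Tensor) -> Tensor:
    """Non-saturating generator loss: mean softplus(-D(fake))."""
    return softplus(-fake_logits).mean()


def adversarial_loss_d(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """Discriminator loss: mean softplus(-D(real)) + mean softplus(D(fake))."""
    return softplus(-real_logits).mean() + softplus(fake_logits).mean()


def loss_r1(disc, images: np.ndarray, expr_z: np.ndarray, c: np.ndarray) -> Tensor:
    """R1 penalty: (1/2) E[ ||grad_x D(x)||^2 ] over a real batch.

    Differentiable w.r.t. the discriminator parameters (double backprop).
    """
    x = Tensor(np.asarray(images, dtype=np.float64))
    logits = disc(x, expr_z, c)
    gx = grad(logits.sum(), [x])[0]
    n = x.shape[0]
    return 0.5 * (gx.reshape(n, -1) ** 2).sum(axis=1).mean()


@dataclass
class PathLengthState:
    a: float = 0.0
    decay: float = 0.99


def loss_path(gen: Generator, expr: np.ndarray, c: np.ndarray,
              noise_seed: int, state: PathLengthState,
              rng: np.random.Generator) -> tuple[Tensor, PathLengthState]:
    """Path-length penalty: squared deviation of ||J_w^T y|| from the running
    mean ``a``; ``y`` is unit-variance image-shaped noise scaled by
    1/sqrt(pixels).  Returns the penalty and the EMA-updated state."""
    latent = gen.mapping_forward(expr, c)
    w_leaf = Tensor(latent.w.data.copy(), requires_grad=True)
    img = gen.synthesis(w_leaf, gen.make_noise(w_leaf.shape[0], noise_seed))
    y = rng.standard_normal(img.shape) / np.sqrt(np.prod(img.shape[1:]))
    val = (img * Tensor(y)).sum()
    gw = grad(val, [w_leaf])[0]
    n, L = gw.shape[0], gw.shape[1]
    norms = (((gw ** 2).reshape(n, -1).sum(axis=1) * (1.0 / L)) + 1e-24) ** 0.5
    penalty = ((norms - state.a) ** 2).mean()
    new_a = state.a + (1.0 - state.decay) * (float(norms.data.mean()) - state.a)
    return penalty, PathLengthState(a=new_a, decay=state.decay)


# ---------------------------------------------------------------- training
@dataclass
class GanTrainResult:
    generator: Generator
    discriminator: Discriminator
    trace: pd.DataFrame
    checkpoints: dict[int, dict]
    best_iter: int
    config: GanConfig


def _unpack_dataset(dataset):
    if hasattr(dataset, "images"):
        expr = dataset.counts if hasattr(dataset, "counts") else dataset.G
        return np.asarray(dataset.images, dtype=np.float64), \
            np.asarray(expr, dtype=np.float64), np.asarray(dataset.labels)
    images, expr, labels = dataset
    return (np.asarray(images, dtype=np.float64),
            np.asarray(expr, dtype=np.float64), np.asarray(labels))


def train_gan(dataset, cfg: GanConfig, extractor=None,
              progress: bool = False) -> GanTrainResult:
    """Alternating D/G optimization of the full objective with lazy
    regularization; logs dFID (toy extractor, subsampled) at every checkpoint
    and selects the checkpoint with the lowest dFID."""
    images, expr, labels = _unpack_dataset(dataset)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    n = len(images)
    rng = np.random.default_rng([cfg.seed, 1])
    gen = Generator(cfg, np.random.default_rng([cfg.seed, 2]))
    gen.standardizer.fit(expr)
    disc = Discriminator(cfg, np.random.default_rng([cfg.seed, 3]))
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=(0.0, 0.99))
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=(0.0, 0.99))
    pl_state = PathLengthState(decay=cfg.path_decay)
    extractor = extractor or ToyFeatureExtractor(in_channels=cfg.channels)

    trace_rows = []
    checkpoints: dict[int, dict] = {}
    eval_idx = np.random.default_rng([cfg.seed, 4]).choice(
        n, size=min(n, 256), replace=False)

    for it in range(cfg.iters):
        idx = rng.integers(0, n, size=cfg.batch)
        real = images[idx] * 2.0 - 1.0
        expr_b, c_b = expr[idx], labels[idx].astype(np.intp)
        expr_z = gen.standardizer.transform(expr_b)

        # --- discriminator step (generator frozen via detach) -------------
        fake = gen.forward(expr_b, c_b, noise_seed=_seed(cfg.seed, it, 0)).detach()
        d_loss = adversarial_loss_d(disc(Tensor(real), expr_z, c_b),
                                    disc(fake, expr_z, c_b))
        if cfg.lambda_r1 > 0 and it % cfg.r1_every == 0:
            d_loss = d_loss + (cfg.lambda_r1 * cfg.r1_every) * loss_r1(
                disc, real, expr_z, c_b)
        opt_d.step(d_loss)

        # --- generator step ------------------------------------------------
        fake = gen.forward(expr_b, c_b, noise_seed=_seed(cfg.seed, it, 1))
        g_loss = adversarial_loss_g(disc(fake, expr_z, c_b))
        if cfg.lambda_path > 0 and it % cfg.path_every == 0:
            pl, pl_state = loss_path(gen, expr_b, c_b,
                                     _seed(cfg.seed, it, 2), pl_state, rng)
            g_loss = g_loss + (cfg.lambda_path * cfg.path_every) * pl
        opt_g.step(g_loss)

        if (it + 1) % cfg.ckpt_every == 0 or (it + 1) == cfg.iters:
            gen_imgs = generate_edited(gen, expr[eval_idx],
                                       labels[eval_idx], noise_seed=_seed(cfg.seed, it, 3))
            score, _ = dfid(gen_imgs, images[eval_idx], extractor=extractor,
                            repeats=2, subsample=128, seed=cfg.seed)
            trace_rows.append({"iter": it + 1, "d_loss": d_loss.item(),
                               "g_loss": g_loss.item(), "dfid": score})
            checkpoints[it + 1] = gen.state_dict()
            if progress:
                print(f"[{it + 1}/{cfg.iters}] dFID={score:.4f}")

    trace = pd.DataFrame(trace_rows)
    best_iter = int(trace.loc[trace["dfid"].idxmin(), "iter"])
    gen.load_state_dict(checkpoints[best_iter])
    return GanTrainResult(generator=gen, discriminator=disc, trace=trace,
                          checkpoints=checkpoints, best_iter=best_iter,
                          config=cfg)


def _seed(base: int, it: int, stream: int) -> int:
    return int((base * 1_000_003 + it * 7 + stream) % (2**31 - 1))


def generate_edited(gen: Generator, expr: np.ndarray, labels: np.ndarray,
                    noise_seed: int = 0) -> np.ndarray:
    """Generate one image per expression row (possibly edited), mapped back to
    [0, 1].  Deterministic given parameters and ``noise_seed``."""
    expr = np.atleast_2d(np.asarray(expr, dtype=np.float64))
    if expr.shape[0] == 0:
        return np.zeros((0, gen.cfg.channels, gen.cfg.image_size, gen.cfg.image_size))
    out = gen.forward(expr, labels, noise_seed=noise_seed)
    return np.clip((out.data + 1.0) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------- checkpoints
_CKPT_VERSION = "stedit-gan-1"


def save_checkpoint(path, gen: Generator) -> None:
    state = {f"param:{k}": v for k, v in gen.state_dict().items()}
    state.update({f"std:{k}": v for k, v in gen.standardizer.state().items()})
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(gen.cfg).items()}
    np.savez(path, __version__=_CKPT_VERSION, __config__=np.array([repr(cfg)]), **state)


def load_checkpoint(path) -> Generator:
    with np.load(path, allow_pickle=False) as z:
        version = str(z["__version__"])
        if version != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version!r}")
        import ast

        cfg_dict = ast.literal_eval(str(z["__config__"][0]))
        cfg_dict["synth_widths"] = tuple(cfg_dict["synth_widths"])
        cfg = GanConfig(**cfg_dict)
        gen = Generator(cfg)
        gen.load_state_dict({k[6:]: z[k] for k in z.files if k.startswith("param:")})
        gen.standardizer.load({k[4:]: z[k] for k in z.files if k.startswith("std:")})
    return gen
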