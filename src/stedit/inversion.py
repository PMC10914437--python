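"""Dual-encoder GAN inversion: reconstruct real crops through the frozen
generator, then edit reconstructions by substituting edited expression.

Two encoders with complementary roles are trained while the generator stays
frozen:

* ``EncoderC`` ("editability" pathway): maps the image to a single global
  latent shared by all style layers, plus an L2-normalized embedding used by
  the contrastive loss.  A momentum copy of this encoder provides the
  contrastive keys (InfoNCE with temperature ``tau``), keeping the embedding
  space slowly moving and consistent.
* ``EncoderP`` ("reconstruction" pathway): predicts per-layer style offsets,
  tanh-bounded so offsets cannot run away from the mapping-network base.

Latent fusion is additive: ``w = mapping(expr, c) + global + offsets``.
Additive fusion keeps expression substitution well-defined at inference:
editing replaces only the mapping-network term while both image-derived
terms are computed from the ORIGINAL image.

Objective: ``lambda1 * L_moco + lambda2 * L2 + lambda3 * L_perc`` where
``L_perc`` is a perceptual distance over the feature stack of a fixed
random-weight convolutional network (pluggable; any callable image->features
list works, e.g. a pretrained stack at full scale).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gan import Generator, StyleLatent
from .metrics import psnr, ssim
from .nn import Tensor, Adam, Module, Linear, MLP, leaky_relu, logsumexp

__all__ = [
    "InversionConfig",
    "EncoderC",
    "EncoderP",
    "PerceptualStack",
    "encode",
    "loss_reconstruction",
    "loss_contrastive",
    "train_inversion",
    "reconstruct",
    "reconstruct_edited",
]


@dataclass
class InversionConfig:
    lambda1: float = 0.1      # contrastive (moco) weight
    lambda2: float = 1.0      # l2 reconstruction weight
    lambda3: float = 0.2      # perceptual weight
    tau: float = 0.07
    emb_dim: int = 32
    global_scale: float = 2.0
    enc_hidden: tuple[int, ...] = (256, 128)
    offset_scale: float = 1.0
    momentum: float = 0.99
    batch: int = 8
    iters: int = 400
    ckpt_every: int = 100
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be nonnegative")


def _conv3x3_s2(x: Tensor, k: np.ndarray) -> Tensor:
    """Valid 3x3 stride-2 convolution built from slice + matmul primitives,
    so it is differentiable w.r.t. the input."""
    n, c, h, w = x.shape
    ho, wo = (h - 3) // 2 + 1, (w - 3) // 2 + 1
    out = None
    for dy in range(3):
        for dx in range(3):
            sub = x[:, :, dy:dy + 2 * (ho - 1) + 1:2, dx:dx + 2 * (wo - 1) + 1:2]
            v = sub.transpose(0, 2, 3, 1).reshape(n * ho * wo, c) @ Tensor(k[dy, dx])
            out = v if out is None else out + v
    cout = k.shape[3]
    return out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)


class PerceptualStack:
    """Fixed random-weight convolutional feature stack used as the perceptual
    distance for inversion training.  Weights are frozen at construction."""

    def __init__(self, in_channels: int = 2, seed: int = 12345):
        rng = np.random.default_rng([seed, 77])
        widths = [in_channels, 8, 16]
        self.kernels = [
            rng.normal(0.0, 1.0 / np.sqrt(9 * a), size=(3, 3, a, b))
            for a, b in zip(widths[:-1], widths[1:])
        ]

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = []
        for k in self.kernels:
            x = leaky_relu(_conv3x3_s2(x, k))
            feats.append(x)
        return feats


class EncoderC(Module):
    """Global-latent encoder plus contrastive embedding head."""

    def __init__(self, gen_cfg, inv_cfg: InversionConfig, rng: np.random.Generator):
        in_dim = gen_cfg.channels * gen_cfg.image_size**2
        self.trunk = MLP([in_dim, *inv_cfg.enc_hidden], rng)
        self.head_latent = Linear(inv_cfg.enc_hidden[-1], gen_cfg.latent, rng, gain=0.1)
        self.head_emb = Linear(inv_cfg.enc_hidden[-1], inv_cfg.emb_dim, rng)
        self.global_scale = inv_cfg.global_scale

    def forward(self, images: Tensor) -> tuple[Tensor, Tensor]:
        n = images.shape[0]
        h = leaky_relu(self.trunk(images.reshape(n, -1)))
        emb = self.head_emb(h)
        emb = emb * ((emb * emb).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        return self.head_latent(h).tanh() * self.global_scale, emb


class EncoderP(Module):
    """Per-layer style-offset encoder; offsets are tanh-bounded."""

    def __init__(self, gen_cfg, inv_cfg: InversionConfig, rng: np.random.Generator):
        in_dim = gen_cfg.channels * gen_cfg.image_size**2
        self.n_styles = gen_cfg.n_styles
        self.latent = gen_cfg.latent
        self.offset_scale = inv_cfg.offset_scale
        self.net = MLP([in_dim, *inv_cfg.enc_hidden, self.n_styles * self.latent], rng)

    def forward(self, images: Tensor) -> Tensor:
        n = images.shape[0]
        raw = self.net(images.reshape(n, -1))
        return raw.reshape(n, self.n_styles, self.latent).tanh() * self.offset_scale


def encode(images: np.ndarray, expr: np.ndarray, c: np.ndarray,
           gen: Generator, enc_c: EncoderC, enc_p: EncoderP) -> StyleLatent:
    """Fuse the mapping-network base with the image-derived global latent and
    per-layer offsets.  ``images`` are in [0, 1]; the networks see (-1, 1)."""
    x = Tensor(np.asarray(images, dtype=np.float64) * 2.0 - 1.0)
    base = gen.mapping_forward(expr, c)
    global_lat, _ = enc_c(x)
    offsets = enc_p(x)
    n, latent = global_lat.shape
    w = base.w + global_lat.reshape(n, 1, latent).broadcast_to(base.w.shape) + offsets
    return StyleLatent(w=w, c=base.c)


def loss_reconstruction(x: Tensor, xhat: Tensor,
                        perceptual: PerceptualStack) -> tuple[Tensor, Tensor]:
    """(mean squared pixel error, perceptual feature distance)."""
    if x.shape != xhat.shape:
        raise ValueError("shapes differ")
    l2 = ((x - xhat) ** 2).mean()
    fx, fy = perceptual(x), perceptual(xhat)
    lpip = None
    for a, b in zip(fx, fy):
        term = ((a - b) ** 2).mean()
        lpip = term if lpip is None else lpip + term
    return l2, lpip * (1.0 / len(fx))


def loss_contrastive(query_emb: Tensor, key_emb: np.ndarray, tau: float = 0.07) -> Tensor:
    """InfoNCE over a batch: positives are matching (reconstruction, input)
    pairs, negatives the other batch members.  Keys are stop-gradient
    (momentum-encoder) embeddings."""
    n = query_emb.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a batch of at least 2 (no negatives)")
    logits = (query_emb @ Tensor(np.asarray(key_emb, dtype=np.float64).T)) * (1.0 / tau)
    diag = logits[np.arange(n), np.arange(n)]
    return (logsumexp(logits, axis=1) - diag).mean()


@dataclass
class InversionResult:
    enc_c: EncoderC
    enc_p: EncoderP
    trace: pd.DataFrame
    best_iter: int
    config: InversionConfig


def train_inversion(dataset, gen: Generator, cfg: InversionConfig) -> InversionResult:
    """Optimize the two encoders against the frozen generator; logs PSNR and
    SSIM on a held-out split at every checkpoint and selects the checkpoint
    with the best SSIM."""
    from .gan import _unpack_dataset

    images, expr, labels = _unpack_dataset(dataset)
    n = len(images)
    if n < 4:
        raise ValueError("need at least 4 cells to train inversion")
    rng = np.random.default_rng([cfg.seed, 11])
    perm = np.random.default_rng([cfg.seed, 12]).permutation(n)
    n_val = max(2, min(64, n // 10))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    enc_c = EncoderC(gen.cfg, cfg, np.random.default_rng([cfg.seed, 13]))
    enc_p = EncoderP(gen.cfg, cfg, np.random.default_rng([cfg.seed, 14]))
    key_enc = copy.deepcopy(enc_c)
    perceptual = PerceptualStack(in_channels=gen.cfg.channels)
    opt = Adam(enc_c.parameters() + enc_p.parameters(), lr=cfg.lr, betas=(0.5, 0.999))

    def eval_metrics() -> tuple[float, float]:
        recon = reconstruct(images[val_idx], expr[val_idx], labels[val_idx],
                            gen, enc_c, enc_p)
        ps = np.mean([psnr(images[i2], recon[j]) for j, i2 in enumerate(val_idx)])
        ss = np.mean([ssim(images[i2], recon[j]) for j, i2 in enumerate(val_idx)])
        return float(ps), float(ss)

    trace_rows = []
    checkpoints: dict[int, tuple[dict, dict]] = {}
    ps0, ss0 = eval_metrics()
    trace_rows.append({"iter": 0, "loss": np.nan, "psnr": ps0, "ssim": ss0})
    checkpoints[0] = (enc_c.state_dict(), enc_p.state_dict())

    for it in range(cfg.iters):
        idx = train_idx[rng.integers(0, len(train_idx), size=cfg.batch)]
        x = Tensor(images[idx] * 2.0 - 1.0)
        latent = encode(images[idx], expr[idx], labels[idx], gen, enc_c, enc_p)
        xhat = gen.synthesis(latent.w, noise=None)
        loss = Tensor(0.0)
        if cfg.lambda2 > 0 or cfg.lambda3 > 0:
            l2, lpip = loss_reconstruction(x, xhat, perceptual)
            loss = loss + cfg.lambda2 * l2 + cfg.lambda3 * lpip
        if cfg.lambda1 > 0:
            _, q_emb = enc_c(xhat)
            _, k_emb = key_enc(x)
            loss = loss + cfg.lambda1 * loss_contrastive(q_emb, k_emb.data, cfg.tau)
        opt.step(loss)
        # momentum update of the key encoder
        for kp, qp in zip(key_enc.parameters(), enc_c.parameters()):
            kp.data = cfg.momentum * kp.data + (1.0 - cfg.momentum) * qp.data

        if (it + 1) % cfg.ckpt_every == 0 or (it + 1) == cfg.iters:
            ps, ss = eval_metrics()
            trace_rows.append({"iter": it + 1, "loss": loss.item(), "psnr": ps, "ssim": ss})
            checkpoints[it + 1] = (enc_c.state_dict(), enc_p.state_dict())

    trace = pd.DataFrame(trace_rows)
    fit_rows = trace[trace["iter"] > 0]
    best_iter = int(fit_rows.loc[fit_rows["ssim"].idxmax(), "iter"])
    best_c, best_p = checkpoints[best_iter]
    enc_c.load_state_dict(best_c)
    enc_p.load_state_dict(best_p)
    return InversionResult(enc_c=enc_c, enc_p=enc_p, trace=trace,
                           best_iter=best_iter, config=cfg)


def reconstruct(images: np.ndarray, expr: np.ndarray, c: np.ndarray,
                gen: Generator, enc_c: EncoderC, enc_p: EncoderP) -> np.ndarray:
    """Plain reconstruction: encode each crop and decode through the frozen
    generator (noise-free synthesis).  Returns images in [0, 1]."""
    latent = encode(images, expr, c, gen, enc_c, enc_p)
    out = gen.synthesis(latent.w, noise=None)
    return np.clip((out.data + 1.0) / 2.0, 0.0, 1.0)


_ENC_VERSION = "stedit-encoders-1"


def save_encoders(path, result: InversionResult) -> None:
    from dataclasses import asdict

    state = {f"c:{k}": v for k, v in result.enc_c.state_dict().items()}
    state.update({f"p:{k}": v for k, v in result.enc_p.state_dict().items()})
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(result.config).items()}
    np.savez(path, __version__=_ENC_VERSION, __config__=np.array([repr(cfg)]), **state)


def load_encoders(path, gen: Generator) -> tuple[EncoderC, EncoderP, InversionConfig]:
    import ast

    with np.load(path, allow_pickle=False) as z:
        if str(z["__version__"]) != _ENC_VERSION:
            raise ValueError("unsupported encoder checkpoint version")
        cfg_dict = ast.literal_eval(str(z["__config__"][0]))
        cfg_dict["enc_hidden"] = tuple(cfg_dict["enc_hidden"])
        cfg = InversionConfig(**cfg_dict)
        enc_c = EncoderC(gen.cfg, cfg, np.random.default_rng(0))
        enc_p = EncoderP(gen.cfg, cfg, np.random.default_rng(0))
        enc_c.load_state_dict({k[2:]: z[k] for k in z.files if k.startswith("c:")})
        enc_p.load_state_dict({k[2:]: z[k] for k in z.files if k.startswith("p:")})
    return enc_c, enc_p, cfg


def reconstruct_edited(images: np.ndarray, expr_edited: np.ndarray,
                       c: np.ndarray, gen: Generator,
                       enc_c: EncoderC, enc_p: EncoderP) -> np.ndarray:
    """Edited reconstruction: image-derived latent terms come from the
    ORIGINAL image while the mapping pathway consumes the EDITED expression.
    With ``expr_edited`` equal to the original expression this is exactly
    ``reconstruct``."""
    images = np.asarray(images, dtype=np.float64)
    expr_edited = np.atleast_2d(np.asarray(expr_edited, dtype=np.float64))
    if len(images) != len(expr_edited):
        raise ValueError("image and expression counts differ")
    return reconstruct(images, expr_edited, c, gen, enc_c, enc_p)
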