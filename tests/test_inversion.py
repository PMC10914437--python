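"""Inversion encoders: fusion contracts, loss closed forms, smoke training
and edited reconstruction."""

import numpy as np
import pytest

from stedit.gan import Generator
from stedit.inversion import (EncoderC, EncoderP, InversionConfig,
                              PerceptualStack, encode, load_encoders,
                              loss_contrastive, loss_reconstruction,
                              reconstruct, reconstruct_edited, save_encoders,
                              train_inversion)
from stedit.metrics import psnr, ssim
from stedit.nn import Tensor


@pytest.fixture(scope="module")
def encoders(trained_gan):
    icfg = InversionConfig(seed=2)
    gen = trained_gan.generator
    ec = EncoderC(gen.cfg, icfg, np.random.default_rng(1))
    ep = EncoderP(gen.cfg, icfg, np.random.default_rng(2))
    return gen, ec, ep, icfg


class TestEncode:
    def test_zeroed_encoders_reduce_to_mapping_base(self, encoders, small_dataset):
        gen, ec, ep, icfg = encoders
        ec0 = EncoderC(gen.cfg, icfg, np.random.default_rng(1))
        ep0 = EncoderP(gen.cfg, icfg, np.random.default_rng(2))
        for _, p in ec0.named_parameters():
            p.data[...] = 0.0
        for _, p in ep0.named_parameters():
            p.data[...] = 0.0
        imgs = small_dataset.images[:3]
        expr = small_dataset.counts[:3].astype(float)
        c = small_dataset.labels[:3]
        fused = encode(imgs, expr, c, gen, ec0, ep0)
        base = gen.mapping_forward(expr, c)
        np.testing.assert_array_equal(fused.w.data, base.w.data)

    def test_same_image_same_latent(self, encoders, small_dataset):
        gen, ec, ep, _ = encoders
        imgs = small_dataset.images[:2]
        expr = small_dataset.counts[:2].astype(float)
        c = small_dataset.labels[:2]
        w1 = encode(imgs, expr, c, gen, ec, ep).w.data
        w2 = encode(imgs, expr, c, gen, ec, ep).w.data
        np.testing.assert_array_equal(w1, w2)

    def test_offsets_bounded_by_scale(self, encoders, small_dataset):
        gen, _, ep, icfg = encoders
        x = Tensor(small_dataset.images[:8] * 2.0 - 1.0)
        off = ep(x).data
        assert np.abs(off).max() <= icfg.offset_scale


class TestReconstructionLoss:
    def test_zero_at_identity(self, rng):
        x = Tensor(rng.uniform(size=(2, 2, 16, 16)))
        perc = PerceptualStack()
        l2, lp = loss_reconstruction(x, x, perc)
        assert l2.item() == 0.0
        assert lp.item() == 0.0

    def test_constant_offset_l2_closed_form(self, rng):
        x = Tensor(rng.uniform(size=(2, 2, 16, 16)))
        l2, _ = loss_reconstruction(x, x + 0.1, PerceptualStack())
        assert l2.item() == pytest.approx(0.01, rel=1e-12)

    def test_perceptual_distance_symmetric(self, rng):
        perc = PerceptualStack()
        x = Tensor(rng.uniform(size=(1, 2, 16, 16)))
        y = Tensor(rng.uniform(size=(1, 2, 16, 16)))
        _, dxy = loss_reconstruction(x, y, perc)
        _, dyx = loss_reconstruction(y, x, perc)
        assert dxy.item() == pytest.approx(dyx.item(), rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            loss_reconstruction(Tensor(np.zeros((1, 2, 16, 16))),
                                Tensor(np.zeros((1, 2, 8, 8))),
                                PerceptualStack())


class TestContrastiveLoss:
    def test_orthogonal_embeddings_closed_form(self):
        """Matched pairs at similarity 1, orthogonal negatives, tau = 1:
        loss = ln(1 + (B-1) e^{-1})."""
        B = 4
        emb = np.eye(B)
        loss = loss_contrastive(Tensor(emb), emb, tau=1.0)
        assert loss.item() == pytest.approx(np.log(1 + (B - 1) * np.exp(-1.0)),
                                            rel=1e-12)

    def test_identical_embeddings_give_log_batch(self):
        B = 5
        emb = np.tile(np.eye(1, 8), (B, 1))
        loss = loss_contrastive(Tensor(emb), emb, tau=1.0)
        assert loss.item() == pytest.approx(np.log(B), rel=1e-12)

    def test_loss_decreases_with_positive_similarity(self):
        key = np.eye(3)
        q_lo = key.copy()
        q_lo[0] = [0.6, 0.8, 0.0]   # positive pair similarity 0.6
        q_hi = key.copy()
        q_hi[0] = [0.8, 0.6, 0.0]   # positive pair similarity 0.8
        assert (loss_contrastive(Tensor(q_hi), key, tau=1.0).item()
                < loss_contrastive(Tensor(q_lo), key, tau=1.0).item())

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            loss_contrastive(Tensor(np.ones((1, 4))), np.ones((1, 4)))


class TestTraining:
    def test_smoke_training_improves_psnr(self, small_dataset, trained_gan):
        cfg = InversionConfig(iters=300, ckpt_every=100, seed=4)
        res = train_inversion(small_dataset, trained_gan.generator, cfg)
        first = res.trace.iloc[0]
        best = res.trace[res.trace["iter"] == res.best_iter].iloc[0]
        assert best.psnr > first.psnr
        assert best.ssim > first.ssim

    def test_degenerate_zero_weight_config_is_noop(self, small_dataset,
                                                   trained_gan):
        cfg = InversionConfig(lambda1=0, lambda2=0, lambda3=0,
                              iters=30, ckpt_every=15, seed=4)
        gen = trained_gan.generator
        ec_before = EncoderC(gen.cfg, cfg, np.random.default_rng([4, 13]))
        res = train_inversion(small_dataset, gen, cfg)
        for (_, p0), (_, p1) in zip(ec_before.named_parameters(),
                                    res.enc_c.named_parameters()):
            np.testing.assert_array_equal(p0.data, p1.data)
        assert res.trace.psnr.nunique() == 1  # flat trace

    def test_deterministic_replay(self, small_dataset, trained_gan):
        cfg = InversionConfig(iters=40, ckpt_every=20, seed=6)
        t1 = train_inversion(small_dataset, trained_gan.generator, cfg).trace
        t2 = train_inversion(small_dataset, trained_gan.generator, cfg).trace
        np.testing.assert_allclose(t1.loss[1:], t2.loss[1:], rtol=1e-10)


@pytest.fixture(scope="module")
def trained_inversion(small_dataset, trained_gan):
    cfg = InversionConfig(iters=500, ckpt_every=125, seed=4)
    return train_inversion(small_dataset, trained_gan.generator, cfg)


class TestReconstruction:
    def test_no_edit_identity_bit_exact(self, small_dataset, trained_gan,
                                        trained_inversion):
        inv = trained_inversion
        imgs = small_dataset.images[:5]
        expr = small_dataset.counts[:5].astype(float)
        c = small_dataset.labels[:5]
        plain = reconstruct(imgs, expr, c, trained_gan.generator,
                            inv.enc_c, inv.enc_p)
        via_edit = reconstruct_edited(imgs, expr, c, trained_gan.generator,
                                      inv.enc_c, inv.enc_p)
        np.testing.assert_array_equal(plain, via_edit)

    def test_cardinality_mismatch_rejected(self, small_dataset, trained_gan,
                                           trained_inversion):
        inv = trained_inversion
        with pytest.raises(ValueError):
            reconstruct_edited(small_dataset.images[:3],
                               small_dataset.counts[:2].astype(float),
                               small_dataset.labels[:3],
                               trained_gan.generator, inv.enc_c, inv.enc_p)

    def test_reconstruction_beats_random_pair_baseline(self, small_dataset,
                                                       trained_gan,
                                                       trained_inversion):
        """SSIM(reconstruction, input) exceeds the SSIM of random real image
        pairs after smoke training."""
        ds = small_dataset
        inv = trained_inversion
        rng = np.random.default_rng(0)
        sel = rng.choice(ds.n, 60, replace=False)
        rec = reconstruct(ds.images[sel], ds.counts[sel].astype(float),
                          ds.labels[sel], trained_gan.generator,
                          inv.enc_c, inv.enc_p)
        s_rec = np.mean([ssim(ds.images[s], rec[j]) for j, s in enumerate(sel)])
        pairs = rng.choice(ds.n, size=(60, 2))
        s_rand = np.mean([ssim(ds.images[a], ds.images[b]) for a, b in pairs])
        assert s_rec > s_rand

    def test_edited_reconstruction_moves_nuclear_area(self, small_dataset,
                                                      trained_gan,
                                                      trained_inversion):
        from stedit.expr_edit import EditSpec, edit_population
        from stedit.metrics import features_table
        from stedit.st_io import ExpressionMatrix

        ds = small_dataset
        inv = trained_inversion
        em = ExpressionMatrix(G=ds.counts.astype(float), labels=ds.labels,
                              subtypes=ds.subtypes, panel=ds.panel)
        edited = edit_population(em, EditSpec(mode="full", source=1, target=0))
        tum = ds.labels == 1
        rec_un = reconstruct(ds.images[tum], ds.counts[tum].astype(float),
                             ds.labels[tum], trained_gan.generator,
                             inv.enc_c, inv.enc_p)
        rec_ed = reconstruct_edited(ds.images[tum], edited.edited.G[tum],
                                    ds.labels[tum], trained_gan.generator,
                                    inv.enc_c, inv.enc_p)
        target = features_table(ds.images[~tum]).nuclear_area.mean()
        a_un = features_table(rec_un).nuclear_area.mean()
        a_ed = features_table(rec_ed).nuclear_area.mean()
        assert abs(a_ed - target) < abs(a_un - target)


def test_encoder_checkpoint_roundtrip(tmp_path, small_dataset, trained_gan,
                                      trained_inversion):
    path = tmp_path / "enc.npz"
    save_encoders(path, trained_inversion)
    ec, ep, cfg = load_encoders(path, trained_gan.generator)
    imgs = small_dataset.images[:3]
    expr = small_dataset.counts[:3].astype(float)
    c = small_dataset.labels[:3]
    np.testing.assert_array_equal(
        reconstruct(imgs, expr, c, trained_gan.generator,
                    trained_inversion.enc_c, trained_inversion.enc_p),
        reconstruct(imgs, expr, c, trained_gan.generator, ec, ep))
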