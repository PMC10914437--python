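"""Conditional GAN: loss-term analytics, determinism contracts, smoke
training, and editing-direction behavior of the generator."""

import numpy as np
import pytest

from stedit.expr_edit import EditSpec, edit_population
from stedit.gan import (Discriminator, GanConfig, Generator, PathLengthState,
                        adversarial_loss_d, adversarial_loss_g,
                        generate_edited, load_checkpoint, loss_path, loss_r1,
                        save_checkpoint, train_gan)
from stedit.metrics import ToyFeatureExtractor, dfid, features_table
from stedit.nn import Module, Tensor
from stedit.st_io import ExpressionMatrix


@pytest.fixture(scope="module")
def gen(small_dataset):
    cfg = GanConfig(p=small_dataset.cfg.p, seed=3)
    g = Generator(cfg, np.random.default_rng(3))
    g.standardizer.fit(small_dataset.counts)
    return g


class TestMapping:
    def test_deterministic(self, gen, small_dataset):
        e = small_dataset.counts[:4].astype(float)
        c = small_dataset.labels[:4]
        w1 = gen.mapping_forward(e, c).w.data
        w2 = gen.mapping_forward(e, c).w.data
        np.testing.assert_array_equal(w1, w2)

    def test_non_driver_genes_still_reach_latent(self, gen, small_dataset):
        """No masking inside the network: any gene perturbs the latent."""
        e1 = small_dataset.counts[:1].astype(float)
        e2 = e1.copy()
        e2[0, -1] += 5.0  # a non-driver gene
        w1 = gen.mapping_forward(e1, [0]).w.data
        w2 = gen.mapping_forward(e2, [0]).w.data
        assert np.abs(w1 - w2).max() > 0

    def test_zero_vector_finite(self, gen):
        w = gen.mapping_forward(np.zeros((1, gen.cfg.p)), [1]).w.data
        assert np.isfinite(w).all()

    def test_wrong_length_rejected(self, gen):
        with pytest.raises(ValueError):
            gen.mapping_forward(np.zeros((1, gen.cfg.p + 3)), [0])


class TestGeneratorForward:
    def test_shape_and_range(self, gen):
        out = gen.forward(np.ones((3, gen.cfg.p)), [0, 1, 0], noise_seed=1)
        assert out.shape == (3, 2, 32, 32)
        assert np.abs(out.data).max() < 1.0

    def test_bit_reproducible(self, gen):
        e = np.ones((2, gen.cfg.p))
        a = gen.forward(e, [0, 1], noise_seed=9).data
        b = gen.forward(e, [0, 1], noise_seed=9).data
        np.testing.assert_array_equal(a, b)

    def test_batch_order_preserved(self, gen, rng):
        e = rng.gamma(2.0, size=(5, gen.cfg.p))
        c = np.array([0, 1, 0, 1, 0])
        batch = gen.forward(e, c, noise_seed=2).data
        single = gen.forward(e[2:3], c[2:3], noise_seed=2).data
        # same row through the network; noise differs by batch position, so
        # compare pre-noise determinism via the full-batch rerun instead
        rerun = gen.forward(e, c, noise_seed=2).data
        np.testing.assert_array_equal(batch, rerun)
        assert single.shape == (1, 2, 32, 32)

    def test_untrained_output_varies(self, gen, rng):
        out = gen.forward(rng.gamma(2.0, size=(4, gen.cfg.p)), [0, 0, 1, 1],
                          noise_seed=0).data
        assert np.isfinite(out).all()
        assert out.std() > 0


class TestLosses:
    def test_generator_loss_at_zero_logit_is_ln2(self):
        assert adversarial_loss_g(Tensor(np.zeros(4))).item() == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_confident_discriminator_loss_vanishes(self):
        d = adversarial_loss_d(Tensor(np.full(4, 50.0)), Tensor(np.full(4, -50.0)))
        assert d.item() == pytest.approx(0.0, abs=1e-12)

    def test_monotonicity_in_logits(self):
        base = adversarial_loss_d(Tensor([1.0]), Tensor([-1.0])).item()
        assert adversarial_loss_d(Tensor([1.1]), Tensor([-1.0])).item() < base
        assert adversarial_loss_d(Tensor([1.0]), Tensor([-0.9])).item() > base
        g = adversarial_loss_g(Tensor([0.5])).item()
        assert adversarial_loss_g(Tensor([0.6])).item() < g

    def test_r1_linear_discriminator_closed_form(self, rng):
        class LinearD(Module):
            def __init__(self):
                self.w = Tensor(rng.normal(size=(32, 1)), requires_grad=True)

            def forward(self, x, expr_z, c):
                return (x.reshape(x.shape[0], -1) @ self.w).reshape(x.shape[0])

        d = LinearD()
        batch = rng.normal(size=(6, 2, 4, 4))
        r1 = loss_r1(d, batch, None, None)
        assert r1.item() == pytest.approx(0.5 * float((d.w.data ** 2).sum()),
                                          rel=1e-12)
        # homogeneity: doubling the weights quadruples the penalty
        d.w.data *= 2.0
        assert loss_r1(d, batch, None, None).item() == pytest.approx(
            4.0 * r1.item(), rel=1e-12)

    def test_r1_constant_discriminator_zero(self, rng):
        class ConstD(Module):
            def __init__(self):
                self.b = Tensor(np.zeros(1), requires_grad=True)

            def forward(self, x, expr_z, c):
                return (x.reshape(x.shape[0], -1) * 0.0).sum(axis=1) + self.b

        assert loss_r1(ConstD(), rng.normal(size=(3, 2, 4, 4)), None, None
                       ).item() == pytest.approx(0.0, abs=1e-15)

    def test_path_penalty_zero_jacobian_gives_a_squared(self, gen, rng):
        """A generator frozen at a constant output has zero Jacobian, so the
        penalty collapses to the running mean squared."""
        frozen = Generator(gen.cfg, np.random.default_rng(0))
        frozen.standardizer.fit(np.ones((4, gen.cfg.p)))
        for name, p in frozen.synthesis.named_parameters():
            if "styles" in name or name == "const":
                p.data[...] = 0.0
        state = PathLengthState(a=0.7)
        pen, _ = loss_path(frozen, np.ones((2, gen.cfg.p)), np.array([0, 1]),
                           noise_seed=0, state=state, rng=rng)
        assert pen.item() == pytest.approx(0.49, abs=1e-6)

    def test_path_running_mean_ema_arithmetic(self, gen):
        """One EMA step from a = 0 with observed mean norm m gives a = (1 -
        decay) * m; checked by comparing two decays on identical draws."""
        args = dict(expr=np.ones((3, gen.cfg.p)), c=np.array([0, 1, 0]),
                    noise_seed=1)
        pen1, s1 = loss_path(gen, args["expr"], args["c"], args["noise_seed"],
                             PathLengthState(a=0.0, decay=0.99),
                             np.random.default_rng(1))
        pen2, s2 = loss_path(gen, args["expr"], args["c"], args["noise_seed"],
                             PathLengthState(a=0.0, decay=0.50),
                             np.random.default_rng(1))
        assert pen1.item() >= 0.0
        assert pen1.item() == pytest.approx(pen2.item(), rel=1e-12)
        assert s1.a > 0.0
        assert s2.a == pytest.approx(50.0 * s1.a, rel=1e-12)


class TestTraining:
    def test_single_class_rejected(self, small_dataset):
        ds = small_dataset
        sel = ds.labels == 0
        with pytest.raises(ValueError, match="both classes"):
            train_gan((ds.images[sel], ds.counts[sel].astype(float),
                       ds.labels[sel]),
                      GanConfig(p=ds.cfg.p, iters=10, ckpt_every=10))

    def test_loss_trace_reproducible(self, small_dataset):
        ds = small_dataset
        cfg = GanConfig(p=ds.cfg.p, iters=40, ckpt_every=20, seed=12)
        t1 = train_gan(ds, cfg).trace
        t2 = train_gan(ds, cfg).trace
        np.testing.assert_allclose(t1.d_loss, t2.d_loss, rtol=1e-10)
        np.testing.assert_allclose(t1.dfid, t2.dfid, rtol=1e-10)

    def test_smoke_training_improves_dfid(self, small_dataset, trained_gan):
        """dFID of the selected checkpoint beats the untrained generator."""
        ds = small_dataset
        cfg = trained_gan.config
        virgin = Generator(cfg, np.random.default_rng([cfg.seed, 2]))
        virgin.standardizer.fit(ds.counts)
        ext = ToyFeatureExtractor()
        imgs0 = generate_edited(virgin, ds.counts[:256].astype(float),
                                ds.labels[:256], noise_seed=0)
        d0, _ = dfid(imgs0, ds.images[:256], extractor=ext, repeats=2,
                     subsample=128, seed=0)
        assert trained_gan.trace.dfid.min() < d0

    def test_checkpoint_roundtrip_identical_outputs(self, trained_gan, tmp_path,
                                                    small_dataset):
        path = tmp_path / "g.npz"
        save_checkpoint(path, trained_gan.generator)
        reloaded = load_checkpoint(path)
        e = small_dataset.counts[:4].astype(float)
        c = small_dataset.labels[:4]
        np.testing.assert_array_equal(
            trained_gan.generator.forward(e, c, noise_seed=3).data,
            reloaded.forward(e, c, noise_seed=3).data)


class TestGenerateEdited:
    def test_empty_matrix_gives_empty_set(self, gen):
        out = generate_edited(gen, np.zeros((0, gen.cfg.p)), np.zeros(0, int))
        assert out.shape[0] == 0

    def test_deterministic_given_seed(self, gen, rng):
        e = rng.gamma(2.0, size=(3, gen.cfg.p))
        c = np.array([0, 1, 1])
        np.testing.assert_array_equal(generate_edited(gen, e, c, noise_seed=4),
                                      generate_edited(gen, e, c, noise_seed=4))

    def test_edited_expression_moves_morphology(self, trained_gan, small_dataset):
        """Tumor cells edited toward the normal second-moment structure
        generate smaller, darker-marker cells (directional)."""
        ds = small_dataset
        em = ExpressionMatrix(G=ds.counts.astype(float), labels=ds.labels,
                              subtypes=ds.subtypes, panel=ds.panel)
        edited = edit_population(em, EditSpec(mode="full", source=1, target=0))
        tum = ds.labels == 1
        gen_un = generate_edited(trained_gan.generator,
                                 ds.counts[tum].astype(float), ds.labels[tum], 7)
        gen_ed = generate_edited(trained_gan.generator,
                                 edited.edited.G[tum], ds.labels[tum], 7)
        f_un = features_table(gen_un)
        f_ed = features_table(gen_ed)
        f_norm = features_table(ds.images[~tum])
        target_area = f_norm.nuclear_area.mean()
        target_marker = f_norm.marker_mean.mean()
        assert (abs(f_ed.nuclear_area.mean() - target_area)
                < abs(f_un.nuclear_area.mean() - target_area))
        assert (abs(f_ed.marker_mean.mean() - target_marker)
                < abs(f_un.marker_mean.mean() - target_marker))
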