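"""Loss-function oracles: gradient-field identities, direction-weighted TV
homogeneity, consistency self-match, Sobel hand-convolution values, analytic
gradient-penalty cases and composite-loss bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svct import autodiff as ad
from svct.geometry import FanBeamProjector
from svct.losses import (LossWeights, consistency_loss, ddpm_loss,
                         gradient_penalty, hf_regularizer,
                         residual_gradient_field, sobel_edges,
                         wgan_objectives)


class _LinearCritic:
    """D(y) = scale * <u, y> with ||u||_2 = 1; analytic input gradient."""

    def __init__(self, u, scale=1.0):
        self.u = u / np.linalg.norm(u)
        self.scale = scale

    def __call__(self, y):
        flat = y.reshape(y.shape[0], -1)
        w = ad.constant(self.scale * self.u.reshape(-1, 1))
        return (flat @ w).reshape(y.shape[0])

    def input_grad(self, y):
        g = np.broadcast_to(self.scale * self.u[None], y.shape)
        return ad.constant(np.ascontiguousarray(g))


class TestGradientField:
    def test_constant_image_has_zero_field(self):
        gf = residual_gradient_field(np.full((12, 12), 2.3))
        assert np.all(gf.g_h == 0) and np.all(gf.g_w == 0)
        assert np.all(gf.nor == 0) and np.all(gf.alpha == 0)

    def test_horizontal_ramp(self):
        z = np.tile(np.arange(10.0), (10, 1))
        gf = residual_gradient_field(z)
        assert np.allclose(gf.g_w[2:, 2:], 1.0)
        assert np.allclose(gf.g_h[2:, 2:], 0.0)
        assert np.allclose(gf.nor[2:, 2:], 1.0)

    def test_magnitude_is_hypotenuse(self):
        rng = np.random.default_rng(0)
        gf = residual_gradient_field(rng.standard_normal((16, 16)))
        assert np.allclose(gf.nor ** 2, gf.g_h ** 2 + gf.g_w ** 2)
        assert np.all(gf.nor >= 0) and np.all(gf.alpha >= 0)

    def test_scaling_leaves_alpha_unchanged(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((16, 16))
        a1 = residual_gradient_field(z)
        a5 = residual_gradient_field(5.0 * z)
        assert np.allclose(a5.nor, 5.0 * a1.nor)
        interior = (slice(2, -2), slice(2, -2))
        assert np.allclose(a5.alpha[interior], a1.alpha[interior], atol=1e-6)

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            residual_gradient_field(np.zeros(5))


class TestHFRegularizer:
    def test_zero_and_constant_residuals_give_zero(self):
        y = np.random.default_rng(0).random((16, 16))
        assert hf_regularizer(y, y) == 0.0
        # (y + c) - y re-rounds per element, so "constant" holds to ulp only
        assert hf_regularizer(y + 3.7, y) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(0.1, 10.0))
    def test_positive_homogeneity_degree_one(self, c):
        """R(y_L + c z0) = c R(y_L + z0) for interior-supported z0."""
        rng = np.random.default_rng(2)
        z0 = np.zeros((16, 16))
        z0[4:12, 4:12] = rng.standard_normal((8, 8))
        y_label = np.zeros((16, 16))
        r1 = hf_regularizer(y_label + z0, y_label)
        rc = hf_regularizer(y_label + c * z0, y_label)
        assert rc == pytest.approx(c * r1, rel=1e-6)

    def test_matches_bruteforce_weighted_tv(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((16, 16))
        gf = residual_gradient_field(z)
        expected = float(np.mean(gf.alpha * gf.nor))
        assert hf_regularizer(z, np.zeros_like(z)) == pytest.approx(
            expected, rel=1e-9)

    def test_gradient_matches_frozen_weight_functional(self):
        rng = np.random.default_rng(4)
        yp = ad.parameter(rng.standard_normal((8, 8)))
        y_label = np.zeros((8, 8))
        r = hf_regularizer(yp, y_label)
        r.backward()
        alpha0 = residual_gradient_field(yp.data).alpha

        def frozen(zd):
            gf = residual_gradient_field(zd)
            return float(np.mean(alpha0 * np.sqrt(gf.g_h ** 2 + gf.g_w ** 2
                                                  + 1e-24)))

        d = rng.standard_normal((8, 8))
        eps = 1e-7
        num = (frozen(yp.data + eps * d) - frozen(yp.data - eps * d)) / (2 * eps)
        assert float(np.vdot(yp.grad, d)) == pytest.approx(num, rel=1e-4)

    def test_noise_vs_oriented_texture_descriptor(self):
        """alpha distinguishes isotropic noise from an oriented line."""
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((32, 32))
        line = np.zeros((32, 32))
        line[16, 4:28] = 1.0
        gf_n = residual_gradient_field(noise)
        gf_l = residual_gradient_field(line)
        # restrict to active pixels and compare mean descriptors
        a_noise = gf_n.alpha[gf_n.nor > 0.1].mean()
        a_line = gf_l.alpha[gf_l.nor > 0.1].mean()
        assert abs(a_noise - a_line) > 0.1

    def test_weight_modes(self):
        z = np.random.default_rng(6).standard_normal((12, 12))
        zero = np.zeros_like(z)
        vals = {m: hf_regularizer(z, zero, weight_mode=m)
                for m in ("alpha", "inverse", "min")}
        assert all(v > 0 for v in vals.values())
        assert vals["min"] <= min(vals["alpha"], vals["inverse"]) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hf_regularizer(np.zeros((8, 8)), np.zeros((9, 9)))


class TestConsistencyLoss:
    @pytest.fixture
    def projector(self, tiny_geometry):
        g = tiny_geometry
        return FanBeamProjector(g, g.view_angles(g.n_views_intermediate), 32)

    def test_self_consistency_is_zero(self, projector):
        img = np.random.default_rng(0).random((32, 32))
        label = projector.project(img)
        assert consistency_loss(img, label, projector) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_constant_offset_gives_its_magnitude(self, projector):
        img = np.random.default_rng(1).random((32, 32))
        label = projector.project(img)
        assert consistency_loss(img, label + 0.37, projector) == \
            pytest.approx(0.37, rel=1e-9)

    def test_matches_bruteforce_mean_abs(self, projector, tiny_geometry):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        label = rng.random((tiny_geometry.n_views_intermediate,
                            tiny_geometry.n_detectors))
        expected = float(np.abs(projector.project(img) - label).mean())
        assert consistency_loss(img, label, projector) == pytest.approx(
            expected, rel=1e-12)

    def test_view_count_mismatch_rejected(self, projector):
        with pytest.raises(ValueError):
            consistency_loss(np.zeros((32, 32)), np.zeros((5, 48)), projector)


class TestDDPMLoss:
    def test_exact_match_gives_zero(self, tiny_geometry):
        g = tiny_geometry
        proj = FanBeamProjector(g, g.view_angles(g.n_views_intermediate), 32)
        y = np.random.default_rng(0).random((32, 32))
        x = proj.project(y)
        total, comps = ddpm_loss(x, x, y, y, LossWeights(), projector=proj)
        assert total.item() == pytest.approx(0.0, abs=1e-9)

    def test_weight_isolation(self):
        rng = np.random.default_rng(1)
        xp, xl = rng.random((12, 48)), rng.random((12, 48))
        yp, yl = rng.random((16, 16)), rng.random((16, 16))
        w = LossWeights(lambda2=0.0, lambda3=0.0, hf_enabled=False)
        total, comps = ddpm_loss(xp, xl, yp, yl, w)
        assert total.item() == pytest.approx(np.abs(xp - xl).mean(), rel=1e-12)

    def test_components_recombine_to_total(self, tiny_geometry):
        g = tiny_geometry
        proj = FanBeamProjector(g, g.view_angles(g.n_views_intermediate), 32)
        rng = np.random.default_rng(2)
        xp, xl = rng.random((12, 48)), rng.random((12, 48))
        yp, yl = rng.random((32, 32)), rng.random((32, 32))
        total, comps = ddpm_loss(xp, xl, yp, yl, LossWeights(), projector=proj)
        assert total.item() == pytest.approx(sum(comps.values()), abs=1e-9)


class TestSobelEdges:
    def test_constant_image_has_zero_interior(self):
        b = sobel_edges(np.full((8, 8), 4.2))
        assert np.allclose(b, 0.0)

    def test_vertical_step_edge_hand_convolution(self):
        """Horizontal Sobel kernel on a step of height h responds 4h."""
        step = 2.0
        img = np.zeros((5, 7))
        img[:, 4:] = step
        b = sobel_edges(img)
        assert b[2, 3] == pytest.approx(4 * step)
        assert b[2, 4] == pytest.approx(4 * step)
        assert b[2, 1] == pytest.approx(0.0)

    def test_nonnegative_everywhere(self):
        b = sobel_edges(np.random.default_rng(0).standard_normal((16, 16)))
        assert np.all(b >= 0)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            sobel_edges(np.zeros((2, 2)))


class TestGradientPenalty:
    def test_unit_gradient_linear_critic_gives_zero(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(16)
        critic = _LinearCritic(u, scale=1.0)
        yr, yf = rng.standard_normal((2, 3, 16)), rng.standard_normal((2, 3, 16))
        pen = gradient_penalty(critic, rng.standard_normal((3, 16)),
                               rng.standard_normal((3, 16)), seed=1)
        assert pen.item() == pytest.approx(0.0, abs=1e-10)

    def test_doubled_critic_gives_one(self):
        rng = np.random.default_rng(1)
        critic = _LinearCritic(rng.standard_normal(16), scale=2.0)
        pen = gradient_penalty(critic, rng.standard_normal((3, 16)),
                               rng.standard_normal((3, 16)), seed=2)
        assert pen.item() == pytest.approx(1.0, rel=1e-9)

    def test_nonnegative_for_conv_critic(self):
        from svct.models import Discriminator

        rng = np.random.default_rng(2)
        critic = Discriminator(rng, 16, widths=(4, 8))
        yr = rng.standard_normal((2, 1, 16, 16))
        yf = rng.standard_normal((2, 1, 16, 16))
        pen = gradient_penalty(critic, yr, yf, seed=3)
        assert np.isfinite(pen.item()) and pen.item() >= 0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        critic = _LinearCritic(rng.standard_normal(16), scale=1.7)
        yr, yf = rng.standard_normal((3, 16)), rng.standard_normal((3, 16))
        assert gradient_penalty(critic, yr, yf, 7).item() == \
            gradient_penalty(critic, yr, yf, 7).item()


class TestWGANObjectives:
    @pytest.fixture
    def setup(self, tiny_geometry):
        from svct.models import Discriminator, HENet

        rng = np.random.default_rng(0)
        henet = HENet(rng, depth=1, base_width=4, n_primitives=3)
        critic = Discriminator(rng, 16, widths=(4, 8))
        y = rng.random((2, 16, 16))
        batch = {"y_prime": y, "b": sobel_edges(y), "y_label": y.copy()}
        return henet, critic, batch

    def test_identity_generator_zeroes_fidelity_terms(self, setup):
        henet, critic, batch = setup
        for p in henet.parameters():
            p.data = np.zeros_like(p.data)
        g_loss, d_loss, comps = wgan_objectives(henet, critic, batch,
                                                LossWeights(), seed=0)
        assert comps["g_mse"] == pytest.approx(0.0, abs=1e-12)
        assert comps["g_hf"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_critic_reduces_d_loss_to_penalty(self, setup):
        henet, critic, batch = setup
        for p in critic.parameters():
            p.data = np.zeros_like(p.data)
        w = LossWeights()
        g_loss, d_loss, comps = wgan_objectives(henet, critic, batch, w, seed=0)
        assert comps["wasserstein"] == pytest.approx(0.0, abs=1e-12)
        assert d_loss.item() == pytest.approx(w.mu_gp * comps["gp"], rel=1e-9)

    def test_generator_components_recombine(self, setup):
        henet, critic, batch = setup
        w = LossWeights()
        g_loss, d_loss, comps = wgan_objectives(henet, critic, batch, w, seed=1)
        expected = comps["g_mse"] + comps["g_hf"] + comps["g_consistency"] \
            - w.lambda_wgan * comps["g_adv"]
        assert g_loss.item() == pytest.approx(expected, abs=1e-9)
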