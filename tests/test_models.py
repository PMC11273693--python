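"""Network-stage contracts: interpolation identities, end-to-end gradient
flow through the reconstruction layer, critic behaviour and checkpointing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svct import autodiff as ad
from svct.geometry import FanBeamProjector
from svct.losses import l1, sobel_edges
from svct.models import (Discriminator, DualDomainModel, HENet, IENet, SINet,
                         angular_interp_matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_stage1(rng, tiny_geometry):
    g = tiny_geometry
    proj = FanBeamProjector(g, g.view_angles(g.n_views_intermediate), 16)
    sinet = SINet(rng, g.n_views_sparse, g.n_views_intermediate,
                  g.n_detectors, depth=1, base_width=4, n_primitives=3)
    ienet = IENet(rng, depth=1, base_width=4, n_primitives=3)
    return DualDomainModel(sinet, ienet, proj)


class TestAngularInterpolation:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n_sparse=st.integers(2, 12), mult=st.integers(1, 6))
    def test_rows_are_distributions_for_any_even_subset(self, n_sparse, mult):
        W = angular_interp_matrix(n_sparse, n_sparse * mult)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert np.all(W >= 0)

    def test_rows_are_convex_and_periodic(self):
        W = angular_interp_matrix(4, 12)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert np.all(W >= 0)
        # the final target rows interpolate between the last and first views
        assert W[11, 3] > 0 and W[11, 0] > 0

    def test_measured_rows_pass_through(self):
        W = angular_interp_matrix(5, 15)
        assert np.allclose(W[::3], np.eye(5))

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            angular_interp_matrix(7, 12)


class TestSINet:
    def test_output_view_count_is_interpolation_target(self, rng):
        net = SINet(rng, 60, 180, 64, depth=2, base_width=4, n_primitives=3)
        out = net(np.random.default_rng(1).random((60, 64)))
        assert out.shape == (180, 64)

    def test_zero_weights_reduce_to_linear_interpolation(self, rng,
                                                         tiny_geometry):
        g = tiny_geometry
        net = SINet(rng, g.n_views_sparse, g.n_views_intermediate,
                    g.n_detectors, depth=1, base_width=4, n_primitives=3)
        for p in net.parameters():
            p.data = np.zeros_like(p.data)
        x = np.random.default_rng(2).random((g.n_views_sparse, g.n_detectors))
        assert np.allclose(net(x).data, net.interpolate(x))

    def test_wrong_view_count_rejected(self, rng, tiny_geometry):
        g = tiny_geometry
        net = SINet(rng, g.n_views_sparse, g.n_views_intermediate,
                    g.n_detectors, depth=1, base_width=4, n_primitives=3)
        with pytest.raises(ValueError):
            net(np.zeros((g.n_views_sparse + 1, g.n_detectors)))

    def test_fidelity_step_moves_measured_rows_toward_data(self, rng,
                                                           tiny_geometry):
        """One Adam step on the sinogram fidelity reduces that loss."""
        g = tiny_geometry
        net = SINet(rng, g.n_views_sparse, g.n_views_intermediate,
                    g.n_detectors, depth=1, base_width=4, n_primitives=3)
        data_rng = np.random.default_rng(3)
        x = data_rng.random((g.n_views_sparse, g.n_detectors))
        target = data_rng.random((g.n_views_intermediate, g.n_detectors))
        opt = ad.Adam(net.parameters(), lr=1e-3)
        before = l1(net(x), target).item()
        loss = l1(net(x), target)
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert l1(net(x), target).item() < before


class TestDualDomain:
    def test_output_shapes(self, tiny_stage1, tiny_geometry):
        g = tiny_geometry
        x = np.random.default_rng(0).random((g.n_views_sparse,
                                             g.n_detectors)) * 0.1
        out = tiny_stage1(x)
        assert out.x_prime.shape == (g.n_views_intermediate, g.n_detectors)
        assert out.y_mid.shape == (16, 16)
        assert out.y_prime.shape == (16, 16)

    def test_equals_manual_stage_composition(self, tiny_stage1, tiny_geometry):
        g = tiny_geometry
        x = np.random.default_rng(1).random((g.n_views_sparse,
                                             g.n_detectors)) * 0.1
        out = tiny_stage1(x)
        xp = tiny_stage1.sinet(x)
        ymid = tiny_stage1.projector.fbp(xp.data)
        yprime = tiny_stage1.ienet(ad.constant(ymid))
        assert np.array_equal(out.x_prime.data, xp.data)
        assert np.array_equal(out.y_mid.data, ymid)
        assert np.array_equal(out.y_prime.data, yprime.data)

    def test_gradient_reaches_sinet_through_fbp(self, tiny_stage1,
                                                tiny_geometry):
        g = tiny_geometry
        x = np.random.default_rng(2).random((g.n_views_sparse,
                                             g.n_detectors)) * 0.1
        out = tiny_stage1(x)
        target = np.random.default_rng(3).random((16, 16))
        loss = l1(out.y_prime, target)
        tiny_stage1.zero_grad()
        loss.backward()
        total = sum(float(np.abs(p.grad).sum())
                    for p in tiny_stage1.sinet.parameters()
                    if p.grad is not None)
        assert total > 0

    def test_identity_networks_give_fbp_of_interpolation(self, tiny_stage1,
                                                         tiny_geometry):
        g = tiny_geometry
        for p in tiny_stage1.parameters():
            p.data = np.zeros_like(p.data)
        x = np.random.default_rng(4).random((g.n_views_sparse,
                                             g.n_detectors)) * 0.1
        out = tiny_stage1(x)
        ref = tiny_stage1.projector.fbp(tiny_stage1.sinet.interpolate(x))
        assert np.allclose(out.y_prime.data, ref)

    def test_inference_deterministic(self, tiny_stage1, tiny_geometry):
        g = tiny_geometry
        x = np.random.default_rng(5).random((g.n_views_sparse, g.n_detectors))
        a = tiny_stage1.reconstruct(x)
        b = tiny_stage1.reconstruct(x)
        assert np.array_equal(a, b)


class TestHENet:
    def test_zero_weights_identity_on_image_channel(self, rng):
        net = HENet(rng, depth=1, base_width=4, n_primitives=3)
        for p in net.parameters():
            p.data = np.zeros_like(p.data)
        y = np.random.default_rng(0).random((8, 8))
        out = net.refine(y, sobel_edges(y))
        assert np.array_equal(out, y)

    def test_input_validation(self, rng):
        net = HENet(rng, depth=1, base_width=4, n_primitives=3)
        with pytest.raises(ValueError):
            net.refine(np.zeros((8, 8)), np.zeros((9, 9)))
        with pytest.raises(ValueError):
            net(ad.constant(np.zeros((1, 3, 8, 8))))


class TestDiscriminator:
    def test_scalar_per_batch_item(self, rng):
        critic = Discriminator(rng, 16, widths=(4, 8))
        scores = critic(ad.constant(rng.standard_normal((3, 1, 16, 16))))
        assert scores.shape == (3,)

    def test_doubling_head_weights_doubles_score(self, rng):
        critic = Discriminator(rng, 16, widths=(4, 8))
        y = ad.constant(rng.standard_normal((2, 1, 16, 16)))
        s1 = critic(y).data.copy()
        critic.head.w.data *= 2.0
        critic.head.b.data *= 2.0
        assert np.allclose(critic(y).data, 2.0 * s1)

    def test_wrong_input_size_rejected(self, rng):
        critic = Discriminator(rng, 16, widths=(4, 8))
        with pytest.raises(ValueError):
            critic(ad.constant(np.zeros((1, 1, 8, 8))))

    def test_input_grad_matches_autodiff(self, rng):
        critic = Discriminator(rng, 16, widths=(4, 8))
        y = ad.parameter(rng.standard_normal((2, 1, 16, 16)))
        critic(y).sum().backward()
        chain = critic.input_grad(ad.constant(y.data))
        assert np.allclose(chain.data, y.grad, atol=1e-12)
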