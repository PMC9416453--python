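"""Network components: shapes, determinism, sampling, KL, gradients."""

import numpy as np
import pytest

from ergoreba.nn import (LatentDistribution, ModelBundle,
                         NetworkConfig, Tensor, kl_to_standard_normal,
                         sample_latent)
from ergoreba.nn.autodiff import set_default_dtype
from ergoreba.nn.models import get_preset


@pytest.fixture(scope="module")
def desk_bundle():
    return ModelBundle(get_preset("desk"), seed=42)


@pytest.fixture
def streams(rng, desk_bundle):
    dims = desk_bundle.cfg.stream_dims
    return {k: rng.normal(size=(4, d)) for k, d in dims.items()}


@pytest.fixture(autouse=True)
def float64_mode():
    """High-precision mode for numeric checks; restored afterwards."""
    set_default_dtype(np.float64)
    yield
    set_default_dtype(np.float32)


class TestConfig:
    def test_full_preset_matches_reference_dims(self):
        cfg = get_preset("full")
        assert cfg.stream_hidden_dims[-1] == 2048
        assert cfg.token_dims == (2048, 512, 128)
        assert (cfg.skel_latent_dim, cfg.reba_latent_dim) == (128, 64)
        assert cfg.transformer_blocks == 3
        assert cfg.layers_per_block == 4
        assert cfg.heads == 4

    def test_validator_rejects_bad_schedules(self):
        with pytest.raises(ValueError, match="decreasing"):
            NetworkConfig(token_dims=(256, 256, 64),
                          stream_hidden_dims=(256, 256, 256, 256)).validate()
        with pytest.raises(ValueError, match="divide"):
            NetworkConfig(token_dims=(2048, 512, 130)).validate()


class TestEncoders:
    def test_stream_embedding_shapes(self, desk_bundle, streams):
        emb = desk_bundle.e_ms(streams)
        assert len(emb) == 3
        d_out = desk_bundle.cfg.stream_hidden_dims[-1]
        for e in emb:
            assert e.shape == (4, d_out)

    def test_stream_dim_mismatch_names_stream(self, desk_bundle, streams):
        streams["arms"] = streams["arms"][:, :-1]
        with pytest.raises(ValueError, match="arms"):
            desk_bundle.e_ms(streams)

    def test_latent_distribution_shape(self, desk_bundle, streams):
        dist = desk_bundle.encode_skel(streams)
        d = desk_bundle.cfg.skel_latent_dim
        assert dist.mu.shape == (4, d)
        assert dist.log_var.shape == (4, d)

    def test_forward_deterministic(self, desk_bundle, streams):
        d1 = desk_bundle.encode_skel(streams)
        d2 = desk_bundle.encode_skel(streams)
        np.testing.assert_array_equal(d1.mu.data, d2.mu.data)
        np.testing.assert_array_equal(d1.log_var.data, d2.log_var.data)

    def test_token_permutation_changes_output(self, desk_bundle, streams):
        emb = desk_bundle.e_ms(streams)
        d1 = desk_bundle.e_t(emb)
        d2 = desk_bundle.e_t([emb[1], emb[2], emb[0]])
        assert not np.allclose(d1.mu.data, d2.mu.data)

    def test_reba_encoder_decoder_shapes(self, desk_bundle, rng):
        x = rng.normal(size=(4, 6))
        dist = desk_bundle.e_reba(x)
        d = desk_bundle.cfg.reba_latent_dim
        assert dist.mu.shape == (4, d)
        out = desk_bundle.d_reba(dist.mu)
        assert out.shape == (4, 6)

    def test_decoder_rejects_wrong_latent_dim(self, desk_bundle, rng):
        z = Tensor(rng.normal(size=(4, 999)))
        with pytest.raises(ValueError, match="latent dim"):
            desk_bundle.d_skel(z)


class TestSampling:
    def test_deterministic_flag_returns_mu(self, rng):
        dist = LatentDistribution(rng.normal(size=(3, 8)),
                                  rng.normal(size=(3, 8)))
        z = sample_latent(dist, rng, deterministic=True)
        np.testing.assert_array_equal(z.data, dist.mu.data)

    def test_fixed_seed_reproducible(self, rng):
        dist = LatentDistribution(rng.normal(size=(3, 8)),
                                  rng.normal(size=(3, 8)))
        z1 = sample_latent(dist, np.random.default_rng(7))
        z2 = sample_latent(dist, np.random.default_rng(7))
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_sample_mean_matches_mu(self, rng):
        mu = rng.normal(size=(1, 6))
        log_var = np.full((1, 6), -1.0)
        dist = LatentDistribution(mu, log_var)
        draws = np.stack([
            sample_latent(dist, rng).data[0] for _ in range(100_000)])
        se = np.exp(-0.5) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mu[0]) < 4 * se)


class TestKL:
    def test_standard_normal_is_zero(self):
        dist = LatentDistribution(np.zeros((1, 16)), np.zeros((1, 16)))
        assert float(kl_to_standard_normal(dist).data) == pytest.approx(0.0)

    def test_unit_mean_one_dim_is_half(self):
        dist = LatentDistribution(np.ones((1, 1)), np.zeros((1, 1)))
        assert float(kl_to_standard_normal(dist).data) == pytest.approx(0.5)

    def test_nonnegative_on_random_distributions(self, rng):
        for _ in range(50):
            dist = LatentDistribution(rng.normal(size=(1, 8)),
                                      rng.normal(scale=0.5, size=(1, 8)))
            assert float(kl_to_standard_normal(dist).data) >= 0.0

    def test_matches_monte_carlo_estimate(self, rng):
        # KL = E_q[log q - log p]; estimate with 10^6 draws
        for _ in range(5):
            mu = rng.normal(size=4)
            log_var = rng.normal(scale=0.5, size=4)
            sigma = np.exp(0.5 * log_var)
            z = mu + sigma * rng.standard_normal((1_000_000, 4))
            log_q = (-0.5 * ((z - mu) / sigma) ** 2
                     - 0.5 * log_var - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            log_p = (-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            diffs = log_q - log_p
            mc = diffs.mean()
            se = diffs.std(ddof=1) / np.sqrt(len(diffs))
            closed = float(kl_to_standard_normal(
                LatentDistribution(mu[None], log_var[None])).data)
            assert abs(closed - mc) < 3 * se + 1e-9


class TestAlignment:
    def test_output_dims_are_skeletal(self, desk_bundle, rng):
        d_skel = desk_bundle.cfg.skel_latent_dim
        d_reba = desk_bundle.cfg.reba_latent_dim
        skel_dist = LatentDistribution(rng.normal(size=(4, d_skel)),
                                       rng.normal(size=(4, d_skel)))
        out = desk_bundle.m_skel(skel_dist)
        assert out.mu.shape == (4, d_skel)
        reba_dist = LatentDistribution(rng.normal(size=(4, d_reba)),
                                       rng.normal(size=(4, d_reba)))
        out = desk_bundle.m_reba(reba_dist)
        assert out.mu.shape == (4, d_skel)

    def test_not_identity_for_random_weights(self, desk_bundle, rng):
        d = desk_bundle.cfg.skel_latent_dim
        dist = LatentDistribution(rng.normal(size=(4, d)),
                                  rng.normal(size=(4, d)))
        out = desk_bundle.m_skel(dist)
        assert not np.allclose(out.mu.data, dist.mu.data)

    def test_input_dim_checked(self, desk_bundle, rng):
        bad = LatentDistribution(rng.normal(size=(4, 5)),
                                 rng.normal(size=(4, 5)))
        with pytest.raises(ValueError, match="alignment input dim"):
            desk_bundle.m_skel(bad)


class TestGradients:
    def test_finite_difference_through_full_path(self, rng):
        """Autodiff gradients along E_MS -> E_T -> D_skel match central
        finite differences on randomly probed parameters."""
        cfg = NetworkConfig(
            stream_hidden_dims=(16, 16, 16, 16), token_dims=(16, 8, 4),
            skel_latent_dim=4, reba_latent_dim=3, decoder_hidden=8,
            reba_hidden=8, align_hidden=8)
        bundle = ModelBundle(cfg, seed=1)
        streams = {k: rng.normal(size=(3, d))
                   for k, d in cfg.stream_dims.items()}
        y = rng.normal(size=(3, 6))

        from ergoreba.training import loss_skel_vae

        def loss_value():
            dist = bundle.encode_skel(streams)
            pred = bundle.d_skel(dist.mu)
            return loss_skel_vae(pred, y, dist, beta=1e-2)

        loss = loss_value()
        loss.backward()
        params = bundle.parameters()
        probed = 0
        for p in params[:: max(1, len(params) // 12)]:
            if p.grad is None:
                continue
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_value().data)
            p.data[idx] = orig - eps
            lm = float(loss_value().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            probed += 1
        assert probed >= 8

    def test_gradient_flows_to_latent_sample(self, rng):
        z = Tensor(rng.normal(size=(2, 4)), requires_grad=True)
        target = rng.normal(size=(2, 6))
        w = Tensor(rng.normal(size=(4, 6)), requires_grad=True)
        pred = z @ w
        loss = ((pred - Tensor(target)) ** 2.0).mean()
        loss.backward()
        assert z.grad is not None and np.any(z.grad != 0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = NetworkConfig(
            stream_hidden_dims=(8, 8, 8, 8), token_dims=(8, 4),
            transformer_blocks=2, layers_per_block=1, heads=2,
            skel_latent_dim=4, reba_latent_dim=3, decoder_hidden=8,
            reba_hidden=8, align_hidden=8)
        bundle = ModelBundle(cfg, seed=5)
        bundle.phase = "phase1"
        streams = {k: rng.normal(size=(2, d))
                   for k, d in cfg.stream_dims.items()}
        before = bundle.predict_scores(streams, use_alignment=False)
        path = tmp_path / "model.bin"
        bundle.save(path)
        again = ModelBundle.load(path)
        assert again.phase == "phase1"
        after = again.predict_scores(streams, use_alignment=False)
        np.testing.assert_allclose(before, after, atol=1e-12)
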