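import math
import warnings

import numpy as np
import pytest
from scipy.stats import norm

from omicsmix.autograd import Tensor
from omicsmix.model import (
    Discriminator,
    MixerEncoder,
    MixerLayer,
    ModelConfig,
    NetworkWeights,
    MixerAutoencoder,
    encode_dataset,
    grid_size,
    inverse_grid,
    patchify,
    reshape_to_grid,
    train,
)
from omicsmix.nn import Adam, BatchNorm1d, bce, gelu, gelu_scalar


TINY = dict(
    latent_dim=16, patch_size=4, embed_channels=8, n_mixer_layers=1,
    token_mlp_width=8, channel_mlp_width=8, per_omics_hidden=16, disc_hidden=8,
    max_epochs=5,
)


class TestGelu:
    def test_center_and_asymptote(self):
        assert gelu_scalar(0.0) == 0.0
        assert gelu_scalar(10.0) == pytest.approx(10.0, abs=1e-6)

    def test_value_at_one(self):
        assert gelu_scalar(1.0) == pytest.approx(0.8412, abs=5e-4)

    def test_close_to_exact_phi_form(self):
        x = np.linspace(-5, 5, 201)
        exact = x * norm.cdf(x)
        assert np.max(np.abs(gelu_scalar(x) - exact)) < 3e-3

    def test_tensor_and_scalar_paths_agree(self, rng):
        x = rng.normal(size=(3, 4))
        np.testing.assert_allclose(gelu(Tensor(x)).data, gelu_scalar(x), rtol=1e-12)


class TestBatchNorm:
    def test_standardizes_in_training_mode(self, rng):
        bn = BatchNorm1d(4)
        out = bn(Tensor(rng.normal(loc=3.0, scale=2.0, size=(500, 4)))).data
        assert np.abs(out.mean(axis=0)).max() < 1e-9
        assert np.abs(out.var(axis=0) - 1).max() < 1e-2

    def test_constant_dimension_maps_to_beta(self):
        bn = BatchNorm1d(2)
        bn.beta.data = np.array([5.0, -1.0])
        out = bn(Tensor(np.full((10, 2), 7.0))).data
        np.testing.assert_allclose(out, np.tile([5.0, -1.0], (10, 1)), atol=1e-6)

    def test_affine_parameters_scale_and_shift(self, rng):
        bn = BatchNorm1d(3)
        bn.gamma.data = np.full(3, 2.0)
        bn.beta.data = np.full(3, 3.0)
        out = bn(Tensor(rng.normal(size=(1000, 3)))).data
        assert np.abs(out.mean(axis=0) - 3.0).max() < 1e-9
        assert np.abs(out.std(axis=0) - 2.0).max() < 1e-4

    def test_inference_uses_running_statistics(self, rng):
        bn = BatchNorm1d(2)
        x = rng.normal(loc=4.0, size=(200, 2))
        bn.running_mean = x.mean(axis=0)
        bn.running_var = x.var(axis=0)
        bn.eval()
        out = bn(Tensor(x)).data
        assert np.abs(out.mean(axis=0)).max() < 1e-6

    def test_single_row_batch_falls_back_to_running_stats(self):
        bn = BatchNorm1d(2)
        out = bn(Tensor(np.array([[1.0, 2.0]]))).data  # would be degenerate batch stats
        np.testing.assert_allclose(out, [[1.0, 2.0]], atol=1e-4)


class TestGrid:
    @pytest.mark.parametrize(
        "D,p,H,n_pad", [(9, 2, 4, 7), (16, 2, 4, 0), (1, 1, 1, 0), (1100, 16, 48, 1204)]
    )
    def test_grid_size_and_padding(self, D, p, H, n_pad):
        grid = reshape_to_grid(np.arange(1.0, D + 1.0), p)
        assert grid.H == grid.W == H == grid_size(D, p)
        flat = grid.cells.ravel()
        assert (flat[D:] == 1.0).all() and flat.size - D == n_pad

    def test_round_trip_restores_input(self, rng):
        xa = rng.normal(size=37)
        grid = reshape_to_grid(xa, 3)
        np.testing.assert_array_equal(inverse_grid(grid), xa)

    def test_patchify_counts_and_single_patch(self):
        grid = reshape_to_grid(np.arange(16.0), 2)
        tokens = patchify(grid, 2)
        assert tokens.N == 4 and tokens.tokens.shape == (4, 4)
        # first tile is the top-left 2x2 block, flattened row-major
        np.testing.assert_array_equal(tokens.tokens[0], [0, 1, 4, 5])
        whole = patchify(grid, 4)
        assert whole.N == 1
        np.testing.assert_array_equal(whole.tokens[0], np.arange(16.0))


class TestMixer:
    def test_zero_weight_layer_is_identity(self, rng):
        layer = MixerLayer(4, 8, 3, 3, rng)
        for p in layer.parameters():
            p.data = np.zeros_like(p.data)
        x = rng.normal(size=(2, 4, 8))
        np.testing.assert_array_equal(layer(Tensor(x)).data, x)

    def test_output_shape_preserved(self, rng):
        layer = MixerLayer(5, 6, 7, 9, rng)
        assert layer(Tensor(rng.normal(size=(3, 5, 6)))).data.shape == (3, 5, 6)

    def test_zero_weight_encoder_pools_raw_patches(self, rng):
        cfg = ModelConfig(**{**TINY, "patch_size": 2, "embed_channels": 4})
        enc = MixerEncoder(D=16, cfg=cfg, rng=rng)
        # identity embedding (C = p*p), zero mixer weights
        enc.embed.weight.data = np.eye(4)
        enc.embed.bias.data = np.zeros(4)
        for layer in enc.layers:
            for p in layer.parameters():
                p.data = np.zeros_like(p.data)
        xa = np.arange(16.0)[None, :]
        za = enc(Tensor(xa)).data[0]
        expected = patchify(reshape_to_grid(xa[0], 2), 2).tokens.mean(axis=0)
        np.testing.assert_allclose(za, expected, atol=1e-12)

    def test_deterministic_for_identical_samples(self, rng):
        cfg = ModelConfig(**TINY)
        enc = MixerEncoder(D=40, cfg=cfg, rng=rng)
        x = rng.normal(size=40)
        out = enc(Tensor(np.stack([x, x]))).data
        np.testing.assert_array_equal(out[0], out[1])
        assert out.shape[1] == cfg.embed_channels


class TestNetwork:
    def _build(self, seed=0, **overrides):
        rng = np.random.default_rng(seed)
        cfg = ModelConfig(**{**TINY, **overrides})
        dims = [10, 8, 6, 4]
        return MixerAutoencoder(dims, cfg, rng), Discriminator(cfg.latent_dim, cfg.disc_hidden, rng), dims

    def test_latent_has_configured_dimension(self, rng):
        net, _, dims = self._build()
        parts = [Tensor(rng.normal(size=(5, d))) for d in dims]
        z = net.encode(parts, Tensor(rng.normal(size=(5, sum(dims)))))
        assert z.data.shape == (5, 16)

    def test_zero_fusion_weights_give_zero_latent_in_eval(self, rng):
        net, _, dims = self._build()
        net.fusion.weight.data = np.zeros_like(net.fusion.weight.data)
        net.fusion.bias.data = np.zeros_like(net.fusion.bias.data)
        net.eval()  # running stats: mean 0, var 1
        parts = [Tensor(rng.normal(size=(5, d))) for d in dims]
        z = net.encode(parts, Tensor(rng.normal(size=(5, sum(dims)))))
        np.testing.assert_allclose(z.data, 0.0, atol=1e-12)

    def test_decoder_output_dimensions(self, rng):
        net, disc, dims = self._build()
        parts = [Tensor(rng.normal(size=(5, d))) for d in dims]
        z = net.encode(parts, Tensor(rng.normal(size=(5, sum(dims)))))
        for dec, d in zip(net.omics_decoders, dims):
            assert dec(z).data.shape == (5, d)
        assert net.combined_decoder(z).data.shape == (5, sum(dims))

    def test_discriminator_score_strictly_inside_unit_interval(self, rng):
        _, disc, _ = self._build()
        scores = disc(Tensor(rng.normal(size=(20, 16)) * 50)).data
        assert ((scores > 0) & (scores < 1)).all()

    def test_loss_weighting_arithmetic(self, rng):
        net, disc, dims = self._build()
        parts = [Tensor(rng.normal(size=(6, d))) for d in dims]
        combined = Tensor(rng.normal(size=(6, sum(dims))))
        l1, l2, l3, total, _ = net.loss_terms(parts, combined, disc)
        cfg = net.cfg
        expected = cfg.lambda1 * l1.data + cfg.lambda2 * l2.data + cfg.lambda3 * l3.data
        assert total.data == pytest.approx(float(expected))

    def test_bce_at_half_is_ln2(self):
        assert float(bce(Tensor(np.full((4, 1), 0.5)), 1.0).data) == pytest.approx(
            math.log(2), abs=1e-9
        )

    def test_ablation_switches_change_fusion_width(self, rng):
        net_m, _, dims = self._build(use_per_omics_stream=False)
        assert net_m.fusion.weight.data.shape[0] == net_m.cfg.embed_channels
        net_o, _, _ = self._build(use_mixer_stream=False)
        assert net_o.fusion.weight.data.shape[0] == net_o.cfg.per_omics_hidden * len(dims)
        with pytest.raises(ValueError, match="stream"):
            ModelConfig(**{**TINY, "use_mixer_stream": False, "use_per_omics_stream": False})


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, small_preprocessed):
        cfg = ModelConfig(**TINY, seed=3)
        w1, r1 = train(small_preprocessed, cfg)
        w2, r2 = train(small_preprocessed, cfg)
        assert r1.total[-1] < r1.total[0]
        assert r1.total == r2.total  # bitwise-identical training trajectory
        z1 = encode_dataset(w1, small_preprocessed)
        z2 = encode_dataset(w2, small_preprocessed)
        np.testing.assert_array_equal(z1, z2)

    def test_patience_zero_stops_at_first_non_improving_epoch(self, small_preprocessed):
        cfg = ModelConfig(**{**TINY, "max_epochs": 50}, seed=3, patience=0, min_delta=1e9)
        _, report = train(small_preprocessed, cfg)
        # epoch 1 sets the baseline; epoch 2 is the first non-improving epoch
        assert report.stopped_epoch == 2

    def test_encode_dataset_shape_and_repeatability(self, small_preprocessed):
        cfg = ModelConfig(**TINY, seed=1)
        weights, _ = train(small_preprocessed, cfg)
        z = encode_dataset(weights, small_preprocessed)
        assert z.shape == (small_preprocessed.n_samples, 16)
        np.testing.assert_array_equal(z, encode_dataset(weights, small_preprocessed))

    def test_latent_separates_planted_clusters(self, small_cohort):
        from omicsmix.io import preprocess_dataset

        dataset, truth = small_cohort
        ds = preprocess_dataset(dataset)
        cfg = ModelConfig(**{**TINY, "max_epochs": 12}, seed=2)
        weights, _ = train(ds, cfg)
        z = encode_dataset(weights, ds)
        labels = truth.true_labels
        centroids = np.stack([z[labels == k].mean(axis=0) for k in np.unique(labels)])
        between = np.linalg.norm(centroids[:, None] - centroids[None], axis=2)
        between = between[np.triu_indices_from(between, 1)].mean()
        within = np.mean(
            [np.linalg.norm(z[labels == k] - centroids[i], axis=1).mean()
             for i, k in enumerate(np.unique(labels))]
        )
        assert between > 0.5 * within  # planted structure is visible in the latent

    def test_weights_round_trip_through_archive(self, small_preprocessed, tmp_path):
        cfg = ModelConfig(**TINY, seed=4)
        weights, _ = train(small_preprocessed, cfg)
        path = tmp_path / "weights.npz"
        weights.save(path)
        loaded = NetworkWeights.load(path)
        assert loaded.version == weights.version
        np.testing.assert_array_equal(
            encode_dataset(loaded, small_preprocessed),
            encode_dataset(weights, small_preprocessed),
        )

    def test_non_finite_loss_aborts_with_diagnostic(self, small_preprocessed):
        cfg = ModelConfig(**TINY, seed=5, learning_rate=1e160)
        with pytest.raises(RuntimeError, match="non-finite"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            train(small_preprocessed, cfg)


class TestAdam:
    def test_minimizes_quadratic(self):
        from omicsmix.nn import Parameter

        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            p.grad = 2 * p.data  # d/dp of ||p||^2
            opt.step()
        assert np.abs(p.data).max() < 1e-3


from hypothesis import given, settings
from hypothesis import strategies as st


@given(D=st.integers(min_value=1, max_value=2000), p=st.integers(min_value=1, max_value=64))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_grid_round_trip_property(D, p):
    """reshape -> patchify geometry -> inverse restores any (D, p) input."""
    xa = np.sin(np.arange(D, dtype=float))  # deterministic, non-constant payload
    grid = reshape_to_grid(xa, p)
    assert grid.H == grid.W and grid.H % p == 0
    assert patchify(grid, p).N == (grid.H // p) ** 2
    np.testing.assert_array_equal(inverse_grid(grid), xa)
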