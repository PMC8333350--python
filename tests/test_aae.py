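"""Adversarial autoencoder: shapes, schedule, training behaviour, artefacts."""

import numpy as np
import pytest

import neuronorm as nn
from neuronorm.aae import MLP, cyclical_learning_rate
from neuronorm.cohort import N_REGIONS
from neuronorm.preprocess import condition_vector


class TestArchitecture:
    def test_decoder_input_width_is_49(self):
        params = nn.build_model(nn.AAEConfig())
        assert params.decoder.dims[0] == 20 + 27 + 2 == 49

    def test_encoder_parameter_count(self):
        # 101*100+100 + 100*100+100 + 100*20+20 = 22,320
        params = nn.build_model(nn.AAEConfig())
        assert params.encoder.n_parameters == 22320

    def test_network_shapes_match_config(self):
        cfg = nn.AAEConfig()
        params = nn.build_model(cfg)
        assert params.encoder.dims == (101, 100, 100, 20)
        assert params.decoder.dims == (49, 100, 100, 101)
        assert params.discriminator.dims == (20, 100, 100, 1)

    def test_same_seed_gives_identical_initial_weights(self):
        a = nn.build_model(nn.AAEConfig(seed=99))
        b = nn.build_model(nn.AAEConfig(seed=99))
        for Wa, Wb in zip(a.encoder.W, b.encoder.W):
            np.testing.assert_array_equal(Wa, Wb)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            nn.AAEConfig(latent_dim=0)


class TestForwardPasses:
    def test_zero_weight_encoder_maps_to_zero(self):
        params = nn.build_model(nn.AAEConfig())
        for W in params.encoder.W:
            W[:] = 0.0
        h = nn.encode(np.random.default_rng(0).normal(size=(5, N_REGIONS)), params)
        assert h.shape == (5, 20)
        np.testing.assert_array_equal(h, 0.0)

    def test_latent_dimension_is_20(self):
        params = nn.build_model(nn.AAEConfig())
        h = nn.encode(np.ones(N_REGIONS), params)
        assert h.shape == (20,)

    def test_encode_is_continuous(self):
        params = nn.build_model(nn.AAEConfig(seed=2))
        x = np.random.default_rng(1).normal(size=N_REGIONS)
        base = nn.encode(x, params)
        for eps in (1e-3, 1e-6):
            moved = nn.encode(x + eps, params)
            assert np.linalg.norm(moved - base) < 1e3 * eps

    def test_decode_output_dimension(self):
        params = nn.build_model(nn.AAEConfig())
        out = nn.decode(np.zeros(20), condition_vector(60, "male"), params)
        assert out.shape == (N_REGIONS,)

    def test_zero_weight_decoder_outputs_zero(self):
        params = nn.build_model(nn.AAEConfig())
        for W in params.decoder.W:
            W[:] = 0.0
        for b in params.decoder.b:
            b[:] = 0.0
        out = nn.decode(np.ones(20), condition_vector(50, "female"), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_malformed_condition_vector_rejected(self):
        params = nn.build_model(nn.AAEConfig())
        with pytest.raises(ValueError):
            nn.decode(np.zeros(20), np.zeros(28), params)

    def test_zero_weight_discriminator_outputs_half(self):
        params = nn.build_model(nn.AAEConfig())
        for W in params.discriminator.W:
            W[:] = 0.0
        for b in params.discriminator.b:
            b[:] = 0.0
        assert nn.discriminate(np.ones(20), params) == pytest.approx(0.5)

    def test_discriminator_output_strictly_in_unit_interval(self):
        params = nn.build_model(nn.AAEConfig(seed=8))
        z = np.random.default_rng(3).normal(size=(50, 20)) * 10
        p = nn.discriminate(z, params)
        assert np.all((p > 0) & (p < 1))


class TestCyclicalLearningRate:
    CFG = nn.AAEConfig(cycle_step_batches=100)

    def test_base_rate_at_step_zero(self):
        assert cyclical_learning_rate(0, self.CFG) == pytest.approx(0.0001)

    def test_first_peak_hits_max(self):
        assert cyclical_learning_rate(100, self.CFG) == pytest.approx(0.005)

    def test_second_peak_decayed_by_gamma(self):
        expected = 0.0001 + 0.98 * (0.005 - 0.0001)
        assert cyclical_learning_rate(300, self.CFG) == pytest.approx(expected)

    def test_cycle_boundaries_return_to_base(self):
        for step in (200, 400, 600):
            assert cyclical_learning_rate(step, self.CFG) == pytest.approx(0.0001)

    def test_triangular_between_anchors(self):
        lr = cyclical_learning_rate(50, self.CFG)
        assert lr == pytest.approx(0.0001 + 0.5 * (0.005 - 0.0001))

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            cyclical_learning_rate(-1, self.CFG)


class TestMLPGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = MLP((4, 6, 3), slope=0.01, rng=rng)
        X = rng.normal(size=(5, 4))
        T = rng.normal(size=(5, 3))

        def loss():
            return 0.5 * np.sum((net.forward(X) - T) ** 2)

        out, cache = net.forward(X, keep_cache=True)
        _, grads = net.backward(out - T, cache)
        flat = net.flat_grads(grads)
        eps = 1e-6
        for p, g in zip(net.params(), flat):
            idx = (0,) * p.ndim
            orig = p[idx]
            p[idx] = orig + eps
            up = loss()
            p[idx] = orig - eps
            down = loss()
            p[idx] = orig
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-7)


class TestTraining:
    def test_rejects_non_hc_subjects(self, graded_clinical, quick_config):
        cohort, _ = graded_clinical
        with pytest.raises(ValueError, match="HC"):
            nn.train(cohort, quick_config)

    def test_training_is_deterministic(self, small_reference):
        cfg = nn.AAEConfig(epochs=2, batch_size=128, seed=33)
        a = nn.train(small_reference, cfg)
        b = nn.train(small_reference, cfg)
        for Wa, Wb in zip(a.encoder.W, b.encoder.W):
            np.testing.assert_array_equal(Wa, Wb)
        assert a.training_log == b.training_log

    def test_loss_descends(self, trained_small_model):
        log = trained_small_model.training_log
        assert log[-1]["reconstruction_loss"] < log[0]["reconstruction_loss"]
        assert all(np.isfinite(e["reconstruction_loss"]) for e in log)

    def test_loss_trend_non_increasing_in_windows(self, trained_small_model):
        losses = np.array([e["reconstruction_loss"]
                           for e in trained_small_model.training_log])
        windows = [np.median(w) for w in np.array_split(losses, 6)]
        assert windows[-1] < windows[0]

    def test_log_has_one_row_per_epoch(self, trained_small_model):
        assert len(trained_small_model.training_log) == 60

    def test_noiseless_cohort_reconstructed_almost_exactly(self, atlas):
        # volumes are a deterministic function of (age, sex): representable,
        # so the reconstruction loss should collapse
        spec = nn.SimulationSpec(group_sizes={"HC": 256}, atlas=atlas,
                                 noise_sd=0.0, seed=9)
        cohort = nn.generate_reference_cohort(spec)
        params = nn.train(cohort, nn.AAEConfig(epochs=200, seed=4))
        assert params.training_log[-1]["reconstruction_loss"] < 1e-3

    def test_conditioning_changes_reconstruction(self, trained_small_model):
        h = np.zeros(20)
        out_young = nn.decode(h, condition_vector(47, "male"), trained_small_model)
        out_old = nn.decode(h, condition_vector(73, "male"), trained_small_model)
        assert np.linalg.norm(out_young - out_old) > 1e-3


class TestReconstructAndArtefacts:
    def test_reconstruct_is_deterministic(self, small_reference, trained_small_model):
        rec = small_reference.records[0]
        x1, xhat1 = nn.reconstruct(rec, trained_small_model)
        x2, xhat2 = nn.reconstruct(rec, trained_small_model)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(xhat1, xhat2)
        assert x1.shape == xhat1.shape == (N_REGIONS,)

    def test_untrained_model_refuses_to_score(self, small_reference):
        params = nn.build_model(nn.AAEConfig())
        with pytest.raises(ValueError, match="scaler"):
            nn.reconstruct(small_reference.records[0], params)

    def test_save_load_round_trip_bit_exact(self, trained_small_model, tmp_path):
        path = tmp_path / "model.npz"
        nn.save_model(trained_small_model, path)
        loaded = nn.load_model(path)
        for net in ("encoder", "decoder", "discriminator"):
            for Wa, Wb in zip(getattr(trained_small_model, net).W,
                              getattr(loaded, net).W):
                np.testing.assert_array_equal(Wa, Wb)
        np.testing.assert_array_equal(loaded.scaler.median,
                                      trained_small_model.scaler.median)
        assert loaded.config == trained_small_model.config
        assert loaded.training_log == trained_small_model.training_log

    def test_tampered_artefact_rejected(self, trained_small_model, tmp_path):
        path = tmp_path / "model.npz"
        nn.save_model(trained_small_model, path)
        data = {k: v for k, v in np.load(path).items()}
        data["encoder_W0"] = data["encoder_W0"] + 1e-3
        np.savez(path, **data)
        with pytest.raises(ValueError, match="checksum"):
            nn.load_model(path)
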