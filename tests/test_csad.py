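import numpy as np
import pytest

from fidgetlab import (CSADConfig, build_csad, csad_losses, train_csad)
from fidgetlab._nn import Tensor, softmax
from fidgetlab.config import ConfigError
from fidgetlab.csad import _kl_gaussian, latent_means
from fidgetlab.mbcnn import MBCNNConfig, ProtocolError, branch_inputs

from test_mbcnn import split_by_subject, toy_windows


def small_config(**kw):
    base = dict(backbone=MBCNNConfig(modality="imu", conv_filters=(4, 8),
                                     dense=(16, 8), pooling="average"),
                latent_dim_m=6, latent_dim_s=6, enc_hidden=16, mlp_hidden=12,
                epochs=2, batch_size=16, learning_rate=1e-3)
    base.update(kw)
    return CSADConfig(**base)


class TestBuild:
    def test_forward_probabilities_are_distributions(self):
        w = toy_windows(20)
        model = build_csad(small_config(), w, seed=0)
        inputs = branch_inputs(w, "imu")
        _, mu_m, _, mu_s, _ = model.encode(inputs)
        p_fm = softmax(model.movement_logits(mu_m).data)
        p_subj = softmax(model.subject_logits(mu_s).data)
        assert np.allclose(p_fm.sum(axis=1), 1.0)
        assert np.allclose(p_subj.sum(axis=1), 1.0)
        assert p_subj.shape[1] == len(model.subjects)

    def test_decoder_reconstructs_backbone_shape(self):
        w = toy_windows(8)
        model = build_csad(small_config(), w, seed=0)
        inputs = branch_inputs(w, "imu")
        feat, mu_m, _, mu_s, _ = model.encode(inputs)
        recon = model.decode(mu_m, mu_s)
        assert recon.shape == feat.shape

    def test_extreme_logvar_is_clipped_to_finite_kl(self):
        w = toy_windows(8)
        model = build_csad(small_config(), w, seed=0)
        model.enc_m.logvar.b.data[:] = -1e9  # degenerate posterior
        report, total = csad_losses(model, branch_inputs(w, "imu"),
                                    w.labels, w.subject_ids)
        assert np.isfinite(report.kl_movement)
        assert np.isfinite(float(total.data))

    def test_unequal_latent_dims_rejected(self):
        with pytest.raises(ConfigError):
            small_config(latent_dim_m=4, latent_dim_s=8).validate()

    def test_unseen_subject_rejected_by_subject_head(self):
        w = toy_windows(12)
        model = build_csad(small_config(), w, seed=0)
        with pytest.raises(ConfigError, match="training subjects"):
            model.subject_targets(["ghost"])


class TestLosses:
    def test_standard_normal_posterior_has_zero_kl(self):
        mu = Tensor(np.zeros((5, 4)))
        logvar = Tensor(np.zeros((5, 4)))
        assert float(_kl_gaussian(mu, logvar).data) == pytest.approx(0.0)

    def test_report_total_is_exact_weighted_sum(self):
        w = toy_windows(16)
        for objective in ("negative_ce", "confusion"):
            model = build_csad(small_config(adv_objective=objective,
                                            lambda_adv=0.7, beta_m=0.3,
                                            lambda_rec=0.5,
                                            task_weight_movement=2.0),
                               w, seed=1)
            report, total = csad_losses(model, branch_inputs(w, "imu"),
                                        w.labels, w.subject_ids)
            assert report.total == pytest.approx(report.recompute_total(),
                                                 abs=1e-12)
            assert report.total == pytest.approx(float(total.data), abs=1e-12)
            if objective == "negative_ce":
                assert report.adv_encoder_term == pytest.approx(
                    -(report.adv_movement_from_zs +
                      report.adv_subject_from_zm), abs=1e-12)

    def test_components_match_independent_recomputation(self):
        """Step-by-step numpy recomputation of every loss component."""
        w = toy_windows(2)
        model = build_csad(small_config(), w, seed=2)
        inputs = branch_inputs(w, "imu")
        report, _ = csad_losses(model, inputs, w.labels, w.subject_ids)

        def dense(layer, x):
            return x @ layer.w.data + layer.b.data

        def rl(x):
            return np.maximum(x, 0.0)

        feat = model.backbone.features(inputs).data
        h_m = rl(dense(model.enc_m.h, feat))
        mu_m = dense(model.enc_m.mu, h_m)
        lv_m = np.clip(dense(model.enc_m.logvar, h_m), -10, 10)
        h_s = rl(dense(model.enc_s.h, feat))
        mu_s = dense(model.enc_s.mu, h_s)
        lv_s = np.clip(dense(model.enc_s.logvar, h_s), -10, 10)

        def ce(logits, y):
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return float(-np.log(p[np.arange(len(y)), y] + 1e-12).mean())

        y_fm = (np.asarray(w.labels) == 1).astype(int)
        y_subj = model.subject_targets(w.subject_ids)
        bce = ce(dense(model.head_fm, rl(dense(model.trunk_m, mu_m))), y_fm)
        cce = ce(dense(model.head_subject, rl(dense(model.trunk_s, mu_s))),
                 y_subj)
        adv_fm = ce(dense(model.adv_fm_from_zs,
                          rl(dense(model.adv_fm_hidden, mu_s))), y_fm)
        adv_subj = ce(dense(model.adv_subject_from_zm,
                            rl(dense(model.adv_subj_hidden, mu_m))), y_subj)
        kl_m = float(0.5 * (mu_m**2 + np.exp(lv_m) - 1 - lv_m).sum(1).mean())
        kl_s = float(0.5 * (mu_s**2 + np.exp(lv_s) - 1 - lv_s).sum(1).mean())
        z = np.concatenate([mu_m, mu_s], axis=1)
        recon = dense(model.dec2, rl(dense(model.dec1, z)))
        rmse = float(np.sqrt(np.mean((recon - feat) ** 2)))

        assert report.movement_bce == pytest.approx(bce, abs=1e-6)
        assert report.subject_cce == pytest.approx(cce, abs=1e-6)
        assert report.adv_movement_from_zs == pytest.approx(adv_fm, abs=1e-6)
        assert report.adv_subject_from_zm == pytest.approx(adv_subj,
                                                           abs=1e-6)
        assert report.kl_movement == pytest.approx(kl_m, abs=1e-6)
        assert report.kl_subject == pytest.approx(kl_s, abs=1e-6)
        assert report.reconstruction_rmse == pytest.approx(rmse, abs=1e-6)


class TestTraining:
    def test_subject_overlap_is_hard_error(self):
        w = toy_windows(30)
        model = build_csad(small_config(), w, seed=0)
        with pytest.raises(ProtocolError):
            train_csad(model, w, w, seed=0)

    def test_same_seed_identical_first_epoch_loss(self):
        w = toy_windows(40)
        train, test = split_by_subject(w, ["S3"])
        losses = []
        for _ in range(2):
            model = build_csad(small_config(epochs=1), train, seed=4)
            h, _, _ = train_csad(model, train, test, seed=4)
            losses.append(h.total_loss[0])
        assert losses[0] == losses[1]

    def test_latents_have_configured_dimensions(self):
        w = toy_windows(24)
        train, test = split_by_subject(w, ["S3"])
        model = build_csad(small_config(epochs=1), train, seed=0)
        _, lat_train, lat_test = train_csad(model, train, test, seed=0)
        assert lat_train.z_m.shape == (len(train), 6)
        assert lat_test.z_s.shape == (len(test), 6)

    def test_without_adversary_subject_stays_decodable_from_zm(
            self, tiny_windows):
        """lambda_adv = 0 reduces to two supervised VAEs: the movement
        code keeps identity information on confounded data."""
        from sklearn.neighbors import KNeighborsClassifier
        w = tiny_windows
        test_subject = w.subjects[-1]
        train, test = split_by_subject(w, [test_subject])
        cfg = small_config(lambda_adv=0.0, beta_m=0.01, beta_s=0.01,
                           epochs=8, learning_rate=1e-3)
        model = build_csad(cfg, train, seed=5)
        _, lat, _ = train_csad(model, train, test, seed=5)
        y = np.array([str(s) for s in train.subject_ids])
        clf = KNeighborsClassifier(5).fit(lat.z_m[::2], y[::2])
        acc = clf.score(lat.z_m[1::2], y[1::2])
        assert acc > 2.0 / len(model.subjects)
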