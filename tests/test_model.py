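"""Structure, determinism and inference behavior of the DLVM."""

import numpy as np
import pytest

from dlvm import (
    DGPParams,
    DLVMConfig,
    elbo,
    fit_dlvm,
    generate_cohort,
    infer_counterfactual,
    reconstruct_factual,
)
from dlvm.model import load_dlvm, save_dlvm


class TestConfig:
    def test_reference_defaults(self):
        cfg = DLVMConfig()
        assert (cfg.dim_Z, cfg.dim_z1, cfg.dim_z2) == (50, 160, 160)
        assert cfg.hidden_sizes == (300, 300, 100)
        assert cfg.batch_size == 10 and cfg.epochs == 300
        assert cfg.learning_rate == 1e-5 and cfg.decay_rate == 1e-5

    @pytest.mark.parametrize("bad", [
        {"dim_Z": 0}, {"learning_rate": 0.0}, {"epochs": -1},
        {"outcome_model": "poisson"}, {"optimizer": "sgd"},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            DLVMConfig(**bad)


class TestFit:
    def test_empty_training_set_rejected(self, small_cohort, tiny_config):
        with pytest.raises(ValueError):
            fit_dlvm(small_cohort.subset([]), small_cohort.subset([0, 1]), tiny_config)

    def test_single_arm_training_warns_not_errors(self, small_cohort, tiny_config):
        idx = np.flatnonzero(small_cohort.treatment == 0)[:40]
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit_dlvm(small_cohort.subset(idx), None, tiny_config)

    def test_same_seed_same_parameters(self, small_cohort, tiny_config):
        train = small_cohort.subset(range(100))
        valid = small_cohort.subset(range(100, 140))
        a = fit_dlvm(train, valid, tiny_config)
        b = fit_dlvm(train, valid, tiny_config)
        assert a.parameter_checksum() == b.parameter_checksum()
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_training_log_has_one_row_per_epoch(self, tiny_model, tiny_config):
        assert len(tiny_model.training_log) == tiny_config.epochs
        assert all(np.isfinite(row[1]) for row in tiny_model.training_log)

    def test_smoothed_objective_trends_upward(self):
        """Moving-average training ELBO is non-decreasing over the final 80%
        of training for most seeds (stochastic ascent on the bound)."""
        ok = 0
        for seed in range(5):
            c = generate_cohort(DGPParams(n=400, seed=20 + seed))
            cfg = DLVMConfig.desk_scale(seed=seed, epochs=25)
            m = fit_dlvm(c.subset(range(300)), c.subset(range(300, 400)), cfg)
            obj = np.array([row[1] for row in m.training_log])
            ma = np.convolve(obj, np.ones(10) / 10, mode="valid")
            tail = ma[int(0.2 * len(ma)):]
            ok += bool((np.diff(tail) >= -1e-6).all())
        assert ok >= 4


class TestElbo:
    def test_finite_and_schema_checked(self, tiny_model, small_cohort):
        val = elbo(tiny_model, small_cohort.subset(range(20)), n_samples=5)
        assert np.isfinite(val)
        other = generate_cohort(DGPParams(n=30, seed=0, n_discrete_proxies=4,
                                          n_continuous_proxies=3))
        with pytest.raises(ValueError, match="schema"):
            elbo(tiny_model, other)

    def test_empty_batch_rejected(self, tiny_model, small_cohort):
        with pytest.raises(ValueError):
            elbo(tiny_model, small_cohort.subset([]))


class TestInference:
    def test_untrained_model_rejected(self, small_cohort, tiny_config):
        from dlvm.model import TrainedDLVM

        bare = TrainedDLVM(config=tiny_config, schema_fingerprint="x")
        with pytest.raises(ValueError):
            infer_counterfactual(bare, small_cohort)

    def test_ice_follows_two_branch_definition(self, tiny_model, small_cohort):
        est = infer_counterfactual(tiny_model, small_cohort, n_samples=10, seed=0)
        t1 = est.t_factual == 1
        assert np.allclose(est.ice[t1], est.y_factual[t1] - est.y_hat_0[t1])
        assert np.allclose(est.ice[~t1], est.y_hat_1[~t1] - est.y_factual[~t1])
        assert np.isfinite(est.y_hat_0).all() and np.isfinite(est.y_hat_1).all()

    def test_reconstruct_factual_equals_matching_arm(self, tiny_model, small_cohort):
        est = infer_counterfactual(tiny_model, small_cohort, n_samples=10, seed=3)
        recon = reconstruct_factual(tiny_model, small_cohort, n_samples=10, seed=3)
        assert np.array_equal(recon, est.y_hat_factual)

    def test_seeded_inference_is_deterministic(self, tiny_model, small_cohort):
        a = infer_counterfactual(tiny_model, small_cohort, n_samples=20, seed=5)
        b = infer_counterfactual(tiny_model, small_cohort, n_samples=20, seed=5)
        assert np.array_equal(a.y_hat_0, b.y_hat_0)
        assert np.array_equal(a.y_hat_1, b.y_hat_1)

    def test_permutation_equivariance(self, tiny_model, small_cohort):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_cohort.n)
        est = infer_counterfactual(tiny_model, small_cohort, n_samples=15, seed=1)
        est_p = infer_counterfactual(tiny_model, small_cohort.subset(perm),
                                     n_samples=15, seed=1)
        assert np.allclose(est_p.y_hat_0, est.y_hat_0[perm], atol=1e-12)
        assert np.allclose(est_p.y_hat_1, est.y_hat_1[perm], atol=1e-12)

    def test_monte_carlo_estimates_converge(self, tiny_model, small_cohort):
        one = small_cohort.subset([0])
        ref = infer_counterfactual(tiny_model, one, n_samples=4000, seed=9)
        errs = []
        for s in (2, 40, 800):
            est = infer_counterfactual(tiny_model, one, n_samples=s, seed=9)
            errs.append(abs(est.y_hat_1[0] - ref.y_hat_1[0])
                        + abs(est.y_hat_0[0] - ref.y_hat_0[0]))
        assert errs[0] >= errs[2]
        assert errs[1] >= errs[2]

    def test_proxies_only_conditioning_available(self, tiny_model, small_cohort):
        est = infer_counterfactual(tiny_model, small_cohort.subset(range(30)),
                                   n_samples=10, seed=2, condition="proxies")
        assert np.isfinite(est.y_hat_0).all()

    def test_effect_sign_recovered_on_positive_effect_dgp(self):
        signs = []
        for seed in range(3):
            c = generate_cohort(DGPParams(n=800, seed=40 + seed, tau=1.0))
            cfg = DLVMConfig.desk_scale(seed=seed, epochs=20)
            m = fit_dlvm(c.subset(range(600)), c.subset(range(600, 800)), cfg)
            est = infer_counterfactual(m, c, n_samples=30)
            signs.append(np.mean(est.ice) > 0)
        assert sum(signs) >= 2


class TestOrdinalOutcome:
    def test_ordinal_head_predicts_within_observed_range(self, small_cohort):
        cfg = DLVMConfig.desk_scale(
            seed=0, dim_Z=6, dim_z1=6, dim_z2=6, hidden_sizes=(24, 12),
            epochs=5, batch_size=64, outcome_model="ordinal-categorical",
        )
        m = fit_dlvm(small_cohort.subset(range(150)),
                     small_cohort.subset(range(150, 200)), cfg)
        est = infer_counterfactual(m, small_cohort.subset(range(40)), n_samples=10)
        lo, hi = small_cohort.outcome.min(), small_cohort.outcome.max()
        assert (est.y_hat_0 >= lo - 1e-9).all() and (est.y_hat_1 <= hi + 1e-9).all()

    def test_softmax_head_outputs_simplex(self, small_cohort):
        from dlvm import nn

        cfg = DLVMConfig.desk_scale(
            seed=1, dim_Z=4, dim_z1=4, dim_z2=4, hidden_sizes=(16,),
            epochs=3, batch_size=64, outcome_model="ordinal-categorical",
        )
        m = fit_dlvm(small_cohort.subset(range(120)),
                     small_cohort.subset(range(120, 160)), cfg)
        rng = np.random.default_rng(0)
        Z = nn.Tensor(rng.standard_normal((50, cfg.dim_Z)))
        t = nn.Tensor(rng.integers(0, 2, (50, 1)).astype(float))
        logits = m.nets["dec_y"](nn.concat([Z, t]))
        logp = logits - nn.logsumexp(logits, axis=1, keepdims=True)
        probs = np.exp(logp.data)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, small_cohort, tmp_path):
        path = tmp_path / "model.npz"
        save_dlvm(tiny_model, path)
        back = load_dlvm(path, small_cohort.schema)
        assert back.parameter_checksum() == tiny_model.parameter_checksum()
        a = infer_counterfactual(tiny_model, small_cohort.subset(range(10)),
                                 n_samples=5, seed=0)
        b = infer_counterfactual(back, small_cohort.subset(range(10)),
                                 n_samples=5, seed=0)
        assert np.array_equal(a.y_hat_1, b.y_hat_1)

    def test_schema_mismatch_refused(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_dlvm(tiny_model, path)
        other = generate_cohort(DGPParams(n=20, seed=0, n_discrete_proxies=4,
                                          n_continuous_proxies=3))
        with pytest.raises(ValueError, match="fingerprint"):
            load_dlvm(path, other.schema)
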