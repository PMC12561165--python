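import numpy as np
import pytest

from rtcn.ddpm import (BalancePlan, DdpmTrainConfig, balance_dataset,
                       forward_chain, forward_sample, make_balance_plan,
                       make_schedule, sample, train_denoiser)
from rtcn.io import Beat

FAST = DdpmTrainConfig(steps=60, batch_size=8, hidden=16, n_pos=8, n_time=4)


def _beats(rng, label="HC", n=4, length=64, patient="p0"):
    return [Beat(rng.normal(size=length), label, patient, r_index=10)
            for _ in range(n)]


class TestSchedule:
    def test_two_step_hand_arithmetic(self):
        s = make_schedule(2, 0.1, 0.2)
        np.testing.assert_allclose(s.alphas, [0.9, 0.8])
        np.testing.assert_allclose(s.alpha_bars, [0.9, 0.72])

    def test_canonical_schedule_destroys_signal(self):
        s = make_schedule(1000, 1e-4, 0.02)
        assert s.alpha_bars[-1] < 1e-4

    def test_alpha_bar_strictly_decreasing(self):
        s = make_schedule(50, 1e-3, 0.3)
        assert np.all(np.diff(s.alpha_bars) < 0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(1, 1e-4, 0.02)
        with pytest.raises(ValueError):
            make_schedule(10, 0.02, 1e-4)  # non-monotone request

    def test_posterior_variance_switch(self):
        s = make_schedule(10, 1e-3, 0.2, sigma_kind="posterior")
        b, abar, abar_prev = s.betas[4], s.alpha_bars[4], s.alpha_bars[3]
        expected = np.sqrt(b * (1 - abar_prev) / (1 - abar))
        assert s.sigma(5) == pytest.approx(expected)
        assert s.sigma(5) < np.sqrt(b)


class TestForwardProcess:
    def test_small_noise_limit_stays_near_x0(self):
        s = make_schedule(10, 1e-6, 1e-4)
        x0 = np.ones(500)
        x1 = forward_sample(x0, 1, s, seed_or_rng=0)
        assert np.max(np.abs(x1 - x0)) < 3 * np.sqrt(1e-6) + 1e-3

    def test_marginal_matches_closed_form_within_3_sigma(self):
        s = make_schedule(20, 1e-3, 0.2)
        x0 = np.array([1.5])
        t = 12
        draws = np.array([forward_sample(x0, t, s, seed_or_rng=k)[0]
                          for k in range(10_000)])
        abar = s.alpha_bars[t - 1]
        se_mean = np.sqrt(1 - abar) / np.sqrt(draws.size)
        assert abs(draws.mean() - np.sqrt(abar) * 1.5) < 3 * se_mean
        # variance: 3 SEs of the sample variance of a normal
        se_var = (1 - abar) * np.sqrt(2 / (draws.size - 1))
        assert abs(draws.var() - (1 - abar)) < 3 * se_var

    def test_iterated_chain_matches_closed_form_variance(self):
        s = make_schedule(15, 1e-3, 0.25)
        rng = np.random.default_rng(0)
        x0 = np.zeros((10_000, 4)) + 0.7
        t = 10
        chain = forward_chain(x0, t, s, rng)
        closed = forward_sample(x0, t, s, seed_or_rng=rng)
        ratio = chain.var(axis=0) / closed.var(axis=0)
        assert np.all((0.95 < ratio) & (ratio < 1.05))

    def test_t_out_of_range_rejected(self):
        s = make_schedule(5, 1e-3, 0.2)
        with pytest.raises(ValueError):
            forward_sample(np.zeros(3), 6, s)


class TestTraining:
    def test_loss_decreases_on_repeated_beat(self, rng):
        s = make_schedule(20, 1e-3, 0.2)
        model, trace = train_denoiser(_beats(rng, n=1) * 8, s,
                                      DdpmTrainConfig(steps=200, batch_size=8,
                                                      hidden=16, n_pos=8,
                                                      n_time=4), seed=0)
        assert np.mean(trace[-20:]) < np.mean(trace[:20])

    def test_zero_learning_rate_freezes_parameters(self, rng):
        s = make_schedule(10, 1e-3, 0.2)
        cfg = DdpmTrainConfig(steps=30, batch_size=4, lr=0.0, hidden=8,
                              n_pos=4, n_time=4)
        model, trace = train_denoiser(_beats(rng), s, cfg, seed=0)
        fresh = type(model)(64, cfg, seed=0)
        for (n1, p1), (n2, p2) in zip(model.named_parameters(),
                                      fresh.named_parameters()):
            np.testing.assert_array_equal(p1.value, p2.value, err_msg=n1)

    def test_same_seed_identical_loss_trace(self, rng):
        s = make_schedule(10, 1e-3, 0.2)
        beats = _beats(rng)
        _, t1 = train_denoiser(beats, s, FAST, seed=3)
        _, t2 = train_denoiser(beats, s, FAST, seed=3)
        np.testing.assert_array_equal(t1, t2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_denoiser([], make_schedule(10, 1e-3, 0.2))


class TestSampling:
    def test_shapes_and_determinism(self, rng):
        s = make_schedule(10, 1e-3, 0.2)
        model, _ = train_denoiser(_beats(rng, length=651), s, FAST, seed=0)
        a = sample(model, s, 3, seed=5)
        b = sample(model, s, 3, seed=5)
        assert a.shape == (3, 651)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            sample(model, s, 0)


class TestBalance:
    def test_downsample_and_synthesize_bookkeeping(self, rng):
        s = make_schedule(10, 1e-3, 0.2)
        a = _beats(rng, "HC", n=100, patient="pa")
        b = _beats(rng, "AMI", n=20, patient="pb")
        model, _ = train_denoiser(b, s, FAST, seed=0)
        out = balance_dataset(a + b, BalancePlan({"HC": 50, "AMI": 50}, seed=1),
                              {"AMI": model}, s)
        hc = [x for x in out if x.label == "HC"]
        ami = [x for x in out if x.label == "AMI"]
        assert len(hc) == 50 and all(x.source == "real" for x in hc)
        assert len(ami) == 50
        assert sum(x.source == "real" for x in ami) == 20
        assert sum(x.source == "synthetic" for x in ami) == 30
        # all original minority beats retained
        real_ids = {id(x) for x in b}
        assert all(id(x) in real_ids for x in ami if x.source == "real")

    def test_identity_plan_keeps_dataset(self, rng):
        beats = _beats(rng, "HC", 5) + _beats(rng, "IMI", 7)
        out = balance_dataset(beats, BalancePlan({"HC": 5, "IMI": 7}), None)
        assert sorted(id(b) for b in out) == sorted(id(b) for b in beats)

    def test_missing_model_for_minority_class_rejected(self, rng):
        beats = _beats(rng, "HC", 2)
        with pytest.raises(ValueError, match="denoiser model"):
            balance_dataset(beats, BalancePlan({"HC": 5}), {},
                            make_schedule(5, 1e-3, 0.2))

    def test_scaled_twelve_class_plan_structure(self, rng):
        # 1/100-scale mirror of a ~5-6k-per-class corpus: near-balance helper
        counts = {"AMI": 60, "ALMI": 63, "ASMI": 62, "ASLMI": 60, "IMI": 53,
                  "ILMI": 58, "IPMI": 52, "IPLMI": 57, "LMI": 55, "PMI": 50,
                  "PLMI": 58, "HC": 59}
        beats = [Beat(rng.normal(size=16), lab, f"{lab}-{i}", r_index=8)
                 for lab, n in counts.items() for i in range(n)]
        plan = make_balance_plan(beats, seed=0)
        assert len(set(plan.targets.values())) == 1
        target = next(iter(plan.targets.values()))
        assert min(counts.values()) <= target <= max(counts.values())
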