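"""Generator: pattern bank geometry, signal model closed forms, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vdac import (
    SimulationConfig,
    generate_attention_schedule,
    make_pattern_bank,
    participant_couplings,
    participant_gains,
    simulate_behavior,
    simulate_cohort,
    simulate_epochs,
    simulate_learning_behavior,
)
from vdac.behavior import condition_summaries, vdac_interaction_effect
from vdac.containers import BehaviorModel, NoiseModel, Seeds
from vdac.schedules import generate_learning_schedule


class TestPatternBank:
    def test_unit_norm_and_mutual_orthogonality(self, small_config):
        bank = make_pattern_bank(small_config)
        M = bank.as_matrix()
        assert np.allclose(np.linalg.norm(M, axis=0), 1.0, atol=1e-12)
        assert np.allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-10)

    def test_deterministic_under_pattern_seed(self, small_config):
        a = make_pattern_bank(small_config).as_matrix()
        b = make_pattern_bank(small_config).as_matrix()
        assert np.array_equal(a, b)
        other = SimulationConfig(n_channels=16, seeds=Seeds(patterns=99))
        assert not np.allclose(a, make_pattern_bank(other).as_matrix())

    def test_location_patterns_contralateral_posterior(self, small_config):
        from vdac.simulate import make_channel_info
        bank = make_pattern_bank(small_config)
        info = make_channel_info(16)
        right_post = ((info["hemisphere"] == "R") & info["posterior"]).to_numpy()
        assert np.all(bank.loc_left[~right_post] == 0)
        assert np.all(bank.loc_left[right_post] != 0)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            make_pattern_bank(SimulationConfig(n_channels=8))


class TestEpochSignalModel:
    def test_pre_onset_silence_without_noise(self, noiseless_config):
        sched = generate_attention_schedule(1, 0).head(20)
        ep = simulate_epochs(sched, noiseless_config, 0)
        pre = ep.data[:, :, ep.times_ms < noiseless_config.location_onset_ms - 40]
        assert np.allclose(pre, 0.0, atol=1e-3)

    def test_location_projection_matches_configured_amplitude(self, noiseless_config):
        cfg = noiseless_config
        bank = make_pattern_bank(cfg)
        sched = generate_attention_schedule(1, 0)
        low_left = sched[(sched["reward_level"] == "low")
                         & (sched["cue_side"] == "left")].head(1)
        ep = simulate_epochs(low_left.reset_index(drop=True), cfg, 0)
        late = ep.times_ms > cfg.value_signal_onset_ms + 3 * cfg.ramp_ms
        proj = ep.data[0, :, late] @ bank.loc_left
        assert np.allclose(proj, cfg.base_amplitude, atol=1e-6)

    def test_high_reward_location_gain_is_one_plus_m(self, noiseless_config):
        cfg = noiseless_config
        bank = make_pattern_bank(cfg)
        m = participant_gains(cfg)[1]
        sched = generate_attention_schedule(1, 0)
        pick = sched[(sched["reward_level"] == "high")
                     & (sched["cue_side"] == "right")].head(1)
        ep = simulate_epochs(pick.reset_index(drop=True), cfg, 1)
        late = ep.times_ms > cfg.value_signal_onset_ms + 3 * cfg.ramp_ms
        proj = ep.data[0, :, late] @ bank.loc_right
        assert np.allclose(proj, cfg.base_amplitude * (1 + m), atol=1e-4)

    def test_identity_amplitude_equal_across_reward_levels(self, noiseless_config):
        cfg = noiseless_config
        bank = make_pattern_bank(cfg)
        sched = generate_attention_schedule(1, 0)
        ep = simulate_epochs(sched.head(200), cfg, 0)
        late = ep.times_ms > cfg.value_signal_onset_ms + 3 * cfg.ramp_ms
        trials = ep.trials
        for level, ident in (("high", "H1"), ("low", "L1")):
            mask = ((trials["reward_level"] == level)
                    & (trials["cue_side"] == "left")
                    & (trials["identity_left"] == ident)).to_numpy()
            if not mask.any():
                continue
            proj = np.einsum("nct,c->nt", ep.data[mask][:, :, late],
                             bank.identity[ident])
            assert np.allclose(proj, cfg.identity_amplitude, atol=1e-6)

    def test_value_axis_sign_by_reward_level(self, noiseless_config):
        cfg = noiseless_config
        bank = make_pattern_bank(cfg)
        sched = generate_attention_schedule(1, 0).head(300)
        ep = simulate_epochs(sched, cfg, 0)
        late = ep.times_ms > cfg.value_signal_onset_ms + 3 * cfg.ramp_ms
        proj = np.einsum("nct,c->nt", ep.data[:, :, :], bank.value)[:, late]
        level = ep.trials["reward_level"].to_numpy()
        assert np.allclose(proj[level == "high"], cfg.value_amplitude, atol=1e-6)
        assert np.allclose(proj[level == "low"], -cfg.value_amplitude, atol=1e-6)
        assert np.allclose(proj[level == "baseline"], 0.0, atol=1e-6)

    def test_learning_high_amplitude_grows_with_trial(self, noiseless_config):
        cfg = noiseless_config
        bank = make_pattern_bank(cfg)
        sched = generate_learning_schedule(1, 0)
        ep = simulate_epochs(sched, cfg, 0)
        t_idx = np.argmin(np.abs(ep.times_ms - 220))  # post-loc, pre-modulation
        high = ep.trials["reward_level"].to_numpy() == "high"
        side = ep.trials["cue_side"].to_numpy()
        pat = np.where(side[:, None] == "left", bank.loc_left, bank.loc_right)
        amp = np.einsum("nc,nc->n", ep.data[:, :, t_idx], pat)
        tn = ep.trials["trial_number"].to_numpy()
        rho = stats.spearmanr(tn[high], amp[high]).statistic
        assert rho > 0.999  # monotone growth law, noiseless

    def test_epochs_bit_reproducible(self, small_config):
        sched = generate_attention_schedule(1, 0).head(30)
        a = simulate_epochs(sched, small_config, 2)
        b = simulate_epochs(sched, small_config, 2)
        assert np.array_equal(a.data, b.data)

    def test_noise_has_requested_marginal_sd(self, small_config):
        sched = generate_attention_schedule(1, 0).head(80)
        cfg = SimulationConfig(n_channels=16, epoch_window_ms=(-100, 500),
                               base_amplitude=0, identity_amplitude=0,
                               value_amplitude=0,
                               noise_model=NoiseModel(noise_sd=3.0))
        ep = simulate_epochs(sched, cfg, 0)
        assert abs(ep.data.std() - 3.0) < 0.15


class TestBehaviorModel:
    def _noiseless_cfg(self, coupling=60.0, coupling_noise=0.0):
        return SimulationConfig(
            n_participants=6, n_channels=16,
            behavior=BehaviorModel(rt_noise_sd_ms=0.0, coupling=coupling,
                                   coupling_noise_sd_ms=coupling_noise,
                                   lapse_rate=0.0, incongruent_lapse_boost=0.0))

    def test_zero_coupling_zero_noise_gives_null_interaction(self):
        cfg = self._noiseless_cfg(coupling=0.0)
        sched = generate_attention_schedule(1, 0)
        beh = simulate_behavior(sched, cfg, 0)
        eff = vdac_interaction_effect(condition_summaries(beh))
        assert eff.interaction_ms == pytest.approx(0.0, abs=1e-9)

    def test_interaction_recovers_latent_b_exactly(self):
        cfg = self._noiseless_cfg()
        b = participant_couplings(cfg)
        for p in (0, 3):
            beh = simulate_behavior(generate_attention_schedule(1, 0), cfg, p)
            eff = vdac_interaction_effect(condition_summaries(beh), p)
            assert eff.interaction_ms == pytest.approx(b[p], abs=1e-9)

    def test_coupling_links_behavior_to_neural_gain(self):
        cfg = SimulationConfig(
            n_participants=30, n_channels=16,
            behavior=BehaviorModel(coupling=80.0, coupling_noise_sd_ms=2.0))
        m = participant_gains(cfg)
        b = participant_couplings(cfg)
        assert stats.spearmanr(m, b).statistic > 0.8

    def test_accuracy_cost_only_in_high_incongruent_long_soa(self):
        cfg = SimulationConfig(n_participants=2, n_channels=16)
        beh = simulate_behavior(generate_attention_schedule(2, 0), cfg, 0)
        acc = beh.groupby(["reward_level", "congruency", "soa_ms"])["accuracy"].mean()
        hi_long = (acc.loc[("high", "incongruent", 500.0)]
                   + acc.loc[("high", "incongruent", 1000.0)]) / 2
        hc_long = (acc.loc[("high", "congruent", 500.0)]
                   + acc.loc[("high", "congruent", 1000.0)]) / 2
        assert hi_long < hc_long

    def test_requires_attention_schedule(self, small_config):
        with pytest.raises(ValueError, match="attention"):
            simulate_behavior(generate_learning_schedule(1, 0), small_config, 0)

    def test_learning_behavior_accuracy_improves(self, small_config):
        sched = generate_learning_schedule(1, 0)
        beh = simulate_learning_behavior(sched, small_config, 0)
        first = beh[beh["trial_number"] <= 50]["accuracy"].mean()
        last = beh[beh["trial_number"] > 334]["accuracy"].mean()
        assert last > first + 0.15


class TestCohort:
    def test_cohort_size_and_determinism(self):
        cfg = SimulationConfig(n_participants=3, n_channels=16,
                               epoch_window_ms=(-100, 500))
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert len(a.epochs) == 3
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert np.array_equal(a.epochs[1].data, b.epochs[1].data)

    def test_minimum_two_participants(self):
        with pytest.raises(ValueError, match="n_participants"):
            simulate_cohort(SimulationConfig(n_participants=1, n_channels=16))
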