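"""Synthetic multichannel epochs with planted, recoverable structure.

The generator emulates what the decoding pipeline needs from a two-phase
reward/attention experiment, at sensor level:

* a *location* signal — a lateralised channel pattern keyed to the side of
  the reward stimulus, rising at ``location_onset_ms`` and, on high-reward
  trials, multiplicatively boosted by ``(1 + m_i)`` from
  ``value_mod_onset_ms`` onward (m_i is the participant's latent neural
  value-modulation gain);
* an *identity* signal — one orthonormal pattern per stimulus identity with
  equal amplitude across reward levels (matching the empirical null of no
  identity value modulation), rising at ``identity_onset_ms``;
* a shared *value* axis — one pattern added with sign +1 on high-reward and
  -1 on low-reward trials from ``value_signal_onset_ms``, so that
  cross-generalisation across stimulus pairs can recover it;
* spatially correlated AR(1) sensor noise from a low-rank factor model.

On learning-task schedules the high-reward location amplitude additionally
grows with trial number as a saturating exponential, emulating the gradual
emergence of spatial selection over learning.

Behavior is generated so that the per-participant RT reward x congruency
interaction b_i is coupled to m_i through ``b_i = kappa * m_i + noise``,
giving a planted brain-behavior relationship for recovery tests.

Everything is reproducible from the config's seed block; latent truths
(m_i, b_i) are returned separately from the data so analysis stages can
never read them by accident.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .containers import (
    EpochSet,
    IDENTITIES,
    IDENTITY_VALUE,
    SimulationConfig,
)
from .schedules import generate_attention_schedule, generate_learning_schedule

__all__ = [
    "PatternBank",
    "make_pattern_bank",
    "make_channel_info",
    "participant_gains",
    "participant_couplings",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_learning_behavior",
    "simulate_cohort",
    "CohortData",
]


# ---------------------------------------------------------------------------
# channel layout and pattern bank
# ---------------------------------------------------------------------------

def make_channel_info(n_channels: int) -> pd.DataFrame:
    """Synthetic sensor layout: hemispheres, posterior subset, planar pairs.

    Channels split into left/right hemisphere halves; within each
    hemisphere the second half is labelled posterior. Consecutive channels
    ``(2k, 2k+1)`` form planar pairs. Requires ``n_channels`` divisible by 8
    so every block pairs up evenly.
    """
    if n_channels % 8 != 0:
        raise ValueError("n_channels must be a multiple of 8")
    half = n_channels // 2
    quarter = n_channels // 4
    hemisphere = np.where(np.arange(n_channels) < half, "L", "R")
    posterior = np.zeros(n_channels, dtype=bool)
    posterior[half - quarter:half] = True      # posterior left
    posterior[n_channels - quarter:] = True    # posterior right
    return pd.DataFrame({
        "channel": [f"ch{i:03d}" for i in range(n_channels)],
        "hemisphere": hemisphere,
        "posterior": posterior,
    })


def planar_pairs_for(n_channels: int) -> list[tuple[int, int]]:
    return [(2 * k, 2 * k + 1) for k in range(n_channels // 2)]


@dataclass
class PatternBank:
    """Unit-norm, mutually orthogonal channel-space patterns."""

    loc_left: np.ndarray      # response pattern when the reward stimulus is left
    loc_right: np.ndarray
    value: np.ndarray         # shared value axis
    identity: dict[str, np.ndarray]

    def as_matrix(self) -> np.ndarray:
        cols = [self.loc_left, self.loc_right, self.value]
        cols += [self.identity[k] for k in IDENTITIES]
        return np.stack(cols, axis=1)


def make_pattern_bank(config: SimulationConfig) -> PatternBank:
    """Construct the planted patterns, deterministic under ``seeds.patterns``.

    Location patterns are supported on contralateral posterior channels
    (left stimulus -> right-hemisphere posterior sensors and vice versa), so
    the univariate lateralised analyses see a physiologically sensible
    layout; disjoint support makes them exactly orthogonal. The value axis
    and the ten identity patterns are drawn at random and orthogonalised
    against the location patterns and each other (QR), then sign-fixed for
    determinism.
    """
    C = config.n_channels
    n_patterns = 3 + len(IDENTITIES)
    if C < n_patterns:
        raise ValueError(f"need at least {n_patterns} channels for the pattern bank, got {C}")
    info = make_channel_info(C)
    rng = np.random.default_rng(np.random.SeedSequence([config.seeds.patterns]))

    post_left = ((info["hemisphere"] == "L") & info["posterior"]).to_numpy()
    post_right = ((info["hemisphere"] == "R") & info["posterior"]).to_numpy()

    def _masked_unit(mask: np.ndarray) -> np.ndarray:
        v = np.zeros(C)
        vals = rng.standard_normal(mask.sum())
        # keep all loadings one sign so the planar RMS envelope is lateralised
        v[mask] = np.abs(vals)
        return v / np.linalg.norm(v)

    loc_left = _masked_unit(post_right)   # contralateral organisation
    loc_right = _masked_unit(post_left)

    raw = rng.standard_normal((C, 1 + len(IDENTITIES)))
    M = np.concatenate([loc_left[:, None], loc_right[:, None], raw], axis=1)
    Q, R = np.linalg.qr(M)
    # sign-fix columns for reproducibility across BLAS implementations
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs

    value = Q[:, 2]
    identity = {name: Q[:, 3 + i] for i, name in enumerate(IDENTITIES)}
    return PatternBank(loc_left=loc_left, loc_right=loc_right,
                       value=value, identity=identity)


# ---------------------------------------------------------------------------
# latent participant parameters
# ---------------------------------------------------------------------------

def participant_gains(config: SimulationConfig) -> np.ndarray:
    """Latent neural value-modulation gains m_i >= 0, one per participant."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seeds.behavior, 101]))
    m = rng.normal(config.value_mod_gain_mean, config.value_mod_gain_sd,
                   size=config.n_participants)
    return np.clip(m, 0.0, None)


def participant_couplings(config: SimulationConfig) -> np.ndarray:
    """Latent behavioral interaction effects b_i = kappa * m_i + noise (ms)."""
    m = participant_gains(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seeds.behavior, 202]))
    beh = config.behavior
    return beh.coupling * m + rng.normal(0.0, beh.coupling_noise_sd_ms, size=m.size)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def _logistic_ramp(times_ms: np.ndarray, onset_ms: float, ramp_ms: float) -> np.ndarray:
    """Logistic rise: ~0 at onset, half-maximal at onset + ramp/2, ~1 at onset + ramp."""
    return expit((times_ms - onset_ms - ramp_ms / 2.0) / (ramp_ms / 8.0))


def _cued_identity(trials: pd.DataFrame) -> np.ndarray:
    return np.where(trials["cue_side"].to_numpy() == "left",
                    trials["identity_left"].to_numpy(),
                    trials["identity_right"].to_numpy())


def _ar1_factor_noise(rng: np.random.Generator, n_trials: int, n_channels: int,
                      n_times: int, spatial_rank: int, ar1: float,
                      noise_sd: float) -> np.ndarray:
    """Spatially mixed stationary AR(1) noise, marginal SD = noise_sd."""
    if noise_sd == 0:
        return np.zeros((n_trials, n_channels, n_times))
    # spatial covariance from a factor model, normalised to unit variances
    B = rng.standard_normal((n_channels, max(spatial_rank, 0)))
    sigma = B @ B.T + np.eye(n_channels)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    L = np.linalg.cholesky(sigma)
    burn = 50  # discard AR(1) spin-up so the series is stationary
    e = rng.standard_normal((n_trials, n_channels, n_times + burn))
    scale = np.sqrt(1.0 - ar1 ** 2)
    u = lfilter([scale], [1.0, -ar1], e, axis=-1)[..., burn:]
    return noise_sd * np.einsum("cd,ndt->nct", L, u)


def simulate_epochs(schedule: pd.DataFrame, config: SimulationConfig,
                    participant: int = 0) -> EpochSet:
    """Generate one participant's epochs for a learning or attention schedule.

    Per trial, ``data = sum_k s_k * a_k(t) * p_k + noise`` with logistic
    ramps ``a_k``; see the module docstring for the planted components. The
    high-reward location gain uses the participant's latent m_i (drawn
    reproducibly from the seed block), so cohort-level value modulation is
    heterogeneous across participants.
    """
    task = schedule["task"].iloc[0]
    if not (schedule["task"] == task).all():
        raise ValueError("schedule mixes tasks; simulate one task at a time")
    if participant < 0 or participant >= config.n_participants:
        raise ValueError(f"participant {participant} outside 0..{config.n_participants - 1}")

    bank = make_pattern_bank(config)
    times = config.times_ms()
    n, C, T = len(schedule), config.n_channels, times.size
    m_i = participant_gains(config)[participant]

    a_loc = _logistic_ramp(times, config.location_onset_ms, config.ramp_ms)
    a_id = _logistic_ramp(times, config.identity_onset_ms, config.ramp_ms)
    a_mod = _logistic_ramp(times, config.value_mod_onset_ms, config.ramp_ms)
    a_val = _logistic_ramp(times, config.value_signal_onset_ms, config.ramp_ms)

    reward = schedule["reward_level"].to_numpy()
    is_high = reward == "high"
    is_low = reward == "low"
    cue_side = schedule["cue_side"].to_numpy()
    cued_id = _cued_identity(schedule)

    data = np.zeros((n, C, T))

    # --- location signal (only when a reward stimulus singles out a side) ---
    has_loc = is_high | is_low
    loc_pattern = np.zeros((n, C))
    loc_pattern[cue_side == "left"] = bank.loc_left
    loc_pattern[cue_side == "right"] = bank.loc_right
    loc_amp = np.where(has_loc, config.base_amplitude, 0.0)
    if task == "learning":
        tn = schedule["trial_number"].to_numpy().astype(float)
        growth = (config.learning_growth_floor
                  + (1.0 - config.learning_growth_floor)
                  * (1.0 - np.exp(-tn / config.learning_growth_tau)))
        loc_amp = np.where(is_high, loc_amp * growth, loc_amp)
    # value modulation of the location signal: (1 + m_i) on high-reward trials
    gain_t = 1.0 + np.where(is_high, m_i, 0.0)[:, None] * a_mod[None, :]  # (n, T)
    data += loc_amp[:, None, None] * loc_pattern[:, :, None] * (a_loc[None, None, :] * gain_t[:, None, :])

    # --- identity signal (equal amplitude across reward levels by default) ---
    id_pattern = np.stack([bank.identity[i] for i in cued_id])
    id_gain_t = 1.0 + np.where(is_high, config.identity_value_gain, 0.0)[:, None] * a_mod[None, :]
    data += config.identity_amplitude * id_pattern[:, :, None] * (a_id[None, None, :] * id_gain_t[:, None, :])

    # --- shared value axis: +1 high, -1 low, 0 otherwise ---
    sign = np.where(is_high, 1.0, np.where(is_low, -1.0, 0.0))
    data += config.value_amplitude * sign[:, None, None] * bank.value[None, :, None] * a_val[None, None, :]

    # --- noise ---
    nm = config.noise_model
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seeds.noise, participant, 0 if task == "learning" else 1]))
    data += _ar1_factor_noise(rng, n, C, T, nm.spatial_rank, nm.ar1_coef, nm.noise_sd)

    info = make_channel_info(C)
    return EpochSet(
        data=data,
        times_ms=times,
        sfreq_hz=config.sfreq_hz,
        channel_ids=list(info["channel"]),
        planar_pairs=planar_pairs_for(C),
        trials=schedule.reset_index(drop=True),
        channel_info=info,
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(schedule: pd.DataFrame, config: SimulationConfig,
                      participant: int = 0) -> pd.DataFrame:
    """Fill ``rt_ms``/``accuracy`` for an attention-task schedule.

    RT = base - soa_benefit * (SOA/1000) + capture term + Gaussian noise,
    where the capture term is +b_i/2 on high-reward incongruent and -b_i/2
    on high-reward congruent trials (b_i the participant's latent coupling),
    with an analogous, config-sized low-reward term (default 0 ms).
    Accuracy has a congruency-dependent error-rate boost only in high-reward
    long-SOA cells, mirroring the accuracy pattern of attentional capture.
    """
    if schedule["task"].iloc[0] != "attention" or not (schedule["task"] == "attention").all():
        raise ValueError("simulate_behavior requires an attention-task schedule")
    beh = config.behavior
    b_i = participant_couplings(config)[participant]
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seeds.behavior, participant, 303]))

    out = schedule.copy()
    reward = out["reward_level"].to_numpy()
    congr = out["congruency"].to_numpy()
    soa = out["soa_ms"].to_numpy().astype(float)

    term = np.zeros(len(out))
    term[(reward == "high") & (congr == "incongruent")] = +b_i / 2.0
    term[(reward == "high") & (congr == "congruent")] = -b_i / 2.0
    term[(reward == "low") & (congr == "incongruent")] = +beh.low_effect_ms / 2.0
    term[(reward == "low") & (congr == "congruent")] = -beh.low_effect_ms / 2.0

    rt = (beh.base_rt_ms - beh.soa_benefit_ms * (soa / 1000.0) + term
          + rng.normal(0.0, beh.rt_noise_sd_ms, size=len(out)))
    out["rt_ms"] = np.clip(rt, 150.0, None)

    p_err = np.full(len(out), beh.lapse_rate)
    boost = (reward == "high") & (congr == "incongruent") & (soa >= 500)
    p_err[boost] += beh.incongruent_lapse_boost
    out["accuracy"] = (rng.random(len(out)) >= p_err).astype(float)
    return out


def simulate_learning_behavior(schedule: pd.DataFrame, config: SimulationConfig,
                               participant: int = 0) -> pd.DataFrame:
    """Fill ``rt_ms``/``accuracy`` for a learning-task schedule.

    Choice accuracy follows a saturating learning curve with an asymptote
    ordered by the value difference between options (high-vs-zero easiest,
    low-vs-zero hardest); RT speeds up over trials and is faster on
    high-value choices. Purely generator plumbing so learning-curve
    analyses have realistic input.
    """
    if not (schedule["task"] == "learning").all():
        raise ValueError("simulate_learning_behavior requires a learning-task schedule")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seeds.behavior, participant, 404]))
    out = schedule.copy()
    tn = out["trial_number"].to_numpy().astype(float)
    sess = out["session"].to_numpy().astype(float)
    # learning carries over sessions: use cumulative trial count
    cum = tn + (sess - 1) * tn.max()
    asym = out["choice_type"].map({"HZ": 0.97, "HL": 0.94, "LZ": 0.88}).to_numpy()
    p_correct = asym - (asym - 0.5) * np.exp(-cum / 60.0)
    out["accuracy"] = (rng.random(len(out)) < p_correct).astype(float)
    base = np.where(out["choice_type"] == "LZ", 1050.0, 950.0)
    rt = base - 250.0 * (1.0 - np.exp(-cum / 80.0)) + rng.normal(0, 180.0, len(out))
    out["rt_ms"] = np.clip(rt, 200.0, None)
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """A simulated cohort plus its latent truth.

    ``epochs[i]`` carries the i-th participant's data with behavior already
    merged into the trial table. ``truth`` holds one row per participant
    with the latent gains (m_i) and couplings (b_i) for recovery tests —
    analysis code must never read it.
    """

    epochs: list[EpochSet]
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig, task: str = "attention",
                    sessions: int = 1) -> CohortData:
    """Simulate ``config.n_participants`` datasets for one task phase.

    All participants share the schedule structure (order re-randomised per
    participant via the schedule seed) and the pattern bank; latent gains
    differ per participant. Fully reproducible from the seed block.
    """
    if config.n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    m = participant_gains(config)
    b = participant_couplings(config)
    epochs = []
    for p in range(config.n_participants):
        if task == "attention":
            sched = generate_attention_schedule(sessions, seed=config.seeds.schedule + p)
            sched = simulate_behavior(sched, config, p)
        elif task == "learning":
            parts = [generate_learning_schedule(s, seed=config.seeds.schedule + p)
                     for s in range(1, sessions + 1)]
            sched = pd.concat(parts, ignore_index=True)
            sched["trial_id"] = np.arange(len(sched))
            sched = simulate_learning_behavior(sched, config, p)
        else:
            raise ValueError(f"unknown task {task!r}")
        epochs.append(simulate_epochs(sched, config, p))
    truth = pd.DataFrame({
        "participant": np.arange(config.n_participants),
        "m_i": m,
        "b_i": b,
    })
    return CohortData(epochs=epochs, truth=truth, config=config)
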