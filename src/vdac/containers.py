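"""Core data containers for the decoding pipeline.

The universal input is an :class:`EpochSet` — a ``trials x channels x time``
array of epoched sensor data with a per-trial metadata table — together with a
:class:`SimulationConfig` describing how synthetic data are generated.

Trial metadata live in a plain :class:`pandas.DataFrame` with a fixed column
contract (see :data:`TRIAL_COLUMNS`); every analysis selects its conditions
from that table rather than from positional conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

#: Required columns of a trial table, in canonical order.
TRIAL_COLUMNS = [
    "trial_id",
    "task",
    "session",
    "trial_number",
    "choice_type",
    "reward_level",
    "cue_side",
    "identity_left",
    "identity_right",
    "soa_ms",
    "congruency",
    "rt_ms",
    "accuracy",
]

REWARD_LEVELS = ("high", "low", "baseline")
IDENTITIES = ("H1", "H2", "L1", "L2", "Z1", "Z2", "Z3", "Z4", "Z5", "Z6")

#: Reward level conveyed by each stimulus identity.
IDENTITY_VALUE = {
    "H1": "high", "H2": "high",
    "L1": "low", "L2": "low",
    "Z1": "zero", "Z2": "zero", "Z3": "zero",
    "Z4": "zero", "Z5": "zero", "Z6": "zero",
}


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the trial-table column contract and basic invariants.

    Raises
    ------
    ValueError
        If a required column is missing, or trial numbers are not strictly
        increasing within a session, or condition labels are inconsistent
        (e.g. an attention trial marked ``baseline`` with a congruency other
        than ``na``).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    for _, sess in trials.groupby("session"):
        tn = sess["trial_number"].to_numpy()
        if not np.all(np.diff(tn) > 0):
            raise ValueError("trial_number must be strictly increasing within a session")
    att = trials[trials["task"] == "attention"]
    if len(att):
        base = att["reward_level"] == "baseline"
        na = att["congruency"] == "na"
        if not (base == na).all():
            raise ValueError("attention task: reward_level=baseline must coincide with congruency=na")
    # identity labels consistent with reward level of the cued stimulus
    cued = np.where(
        trials["cue_side"].to_numpy() == "left",
        trials["identity_left"].to_numpy(),
        trials["identity_right"].to_numpy(),
    )
    level = trials["reward_level"].to_numpy()
    for ident, lev in zip(cued, level):
        if lev in ("high", "low") and IDENTITY_VALUE.get(ident) != lev:
            raise ValueError(
                f"cued identity {ident!r} inconsistent with reward_level {lev!r}"
            )


@dataclass
class EpochSet:
    """Epoched multichannel data: ``data[trial, channel, time]`` plus metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_times)``.
    times_ms
        Strictly increasing, uniformly spaced time axis in ms relative to cue
        onset; spacing must equal ``1000 / sfreq_hz``.
    sfreq_hz
        Sampling rate in Hz.
    channel_ids
        One identifier per channel.
    planar_pairs
        Channel-index pairs that form planar-gradiometer sites; used by the
        RMS combination in the evoked analysis. May be empty.
    trials
        Trial metadata table; its row count must equal ``data.shape[0]``.
    channel_info
        Optional per-channel table with at least ``hemisphere`` ("L"/"R") and
        ``posterior`` (bool) columns; required by sensor-selection routines.
    """

    data: np.ndarray
    times_ms: np.ndarray
    sfreq_hz: float
    channel_ids: list[str]
    planar_pairs: list[tuple[int, int]] = field(default_factory=list)
    trials: pd.DataFrame | None = None
    channel_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[1] != len(self.channel_ids):
            raise ValueError("channel_ids length does not match data")
        dt = np.diff(self.times_ms)
        if self.times_ms.size > 1:
            if not np.all(dt > 0):
                raise ValueError("times_ms must be strictly increasing")
            step = 1000.0 / self.sfreq_hz
            if not np.allclose(dt, step, rtol=0, atol=1e-6):
                raise ValueError("times_ms spacing must equal 1000/sfreq_hz")
        if self.trials is not None and len(self.trials) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but data has "
                f"{self.data.shape[0]} trials"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray | Sequence[int]) -> "EpochSet":
        """Return a new EpochSet restricted to the given trials.

        ``mask`` may be a boolean mask or integer indices; the trial table is
        subset in lockstep (index reset, original order preserved).
        """
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        trials = None
        if self.trials is not None:
            trials = self.trials.iloc[idx].reset_index(drop=True)
        return EpochSet(
            data=self.data[idx],
            times_ms=self.times_ms,
            sfreq_hz=self.sfreq_hz,
            channel_ids=list(self.channel_ids),
            planar_pairs=list(self.planar_pairs),
            trials=trials,
            channel_info=self.channel_info,
        )

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask over the time axis for ``start_ms <= t <= end_ms``."""
        return (self.times_ms >= start_ms) & (self.times_ms <= end_ms)


@dataclass
class NoiseModel:
    """Spatially correlated AR(1) sensor noise.

    ``spatial_rank`` low-rank factors plus a diagonal floor set the spatial
    covariance; ``ar1_coef`` is the lag-one temporal autocorrelation at the
    sampling rate; ``noise_sd`` is the marginal per-channel standard
    deviation.
    """

    spatial_rank: int = 8
    ar1_coef: float = 0.9
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.spatial_rank < 0:
            raise ValueError("spatial_rank must be >= 0")


@dataclass
class BehaviorModel:
    """Generative reaction-time/accuracy model for the attention task.

    ``coupling`` (kappa, ms per unit neural gain) links the per-participant
    RT reward x congruency interaction b_i to the neural value-modulation
    gain m_i: ``b_i = coupling * m_i + N(0, coupling_noise_sd_ms)``. The
    low-reward congruency effect defaults to 0 ms (no reliable low-reward
    capture), so the interaction equals b_i exactly at zero RT noise.
    """

    base_rt_ms: float = 550.0
    soa_benefit_ms: float = 60.0
    coupling: float = 60.0
    coupling_noise_sd_ms: float = 8.0
    low_effect_ms: float = 0.0
    rt_noise_sd_ms: float = 150.0
    lapse_rate: float = 0.06
    incongruent_lapse_boost: float = 0.05


@dataclass
class Seeds:
    """Independent seed block; every stochastic stage draws from its own."""

    schedule: int = 0
    patterns: int = 1
    noise: int = 2
    behavior: int = 3


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic paradigm.

    Onset latencies anchor the planted effects: the location signal rises at
    ``location_onset_ms``, identity at ``identity_onset_ms``; on high-reward
    trials the location signal is additionally scaled by ``(1 + m_i)`` from
    ``value_mod_onset_ms`` (default 260 ms), and a shared value axis appears
    from ``value_signal_onset_ms`` (default 336 ms). All ramps are logistic
    over ``ramp_ms``.

    ``value_mod_gain_mean``/``sd`` set the across-participant distribution of
    the neural gain m_i (truncated at 0). ``identity_value_gain`` defaults to
    0: identity patterns have equal amplitude across reward levels; set it
    positive to plant an identity value modulation for power studies.
    """

    n_participants: int = 30
    n_channels: int = 64
    sfreq_hz: float = 250.0
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    location_onset_ms: float = 100.0
    identity_onset_ms: float = 125.0
    value_mod_onset_ms: float = 260.0
    value_signal_onset_ms: float = 336.0
    ramp_ms: float = 50.0
    base_amplitude: float = 1.0
    identity_amplitude: float = 0.8
    value_amplitude: float = 0.5
    value_mod_gain_mean: float = 0.5
    value_mod_gain_sd: float = 0.25
    identity_value_gain: float = 0.0
    learning_growth_floor: float = 0.4
    learning_growth_tau: float = 128.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window_ms
        for name in ("location_onset_ms", "identity_onset_ms",
                     "value_mod_onset_ms", "value_signal_onset_ms"):
            t = getattr(self, name)
            if not lo <= t <= hi:
                raise ValueError(f"{name}={t} outside epoch window {self.epoch_window_ms}")
        if self.ramp_ms <= 0:
            raise ValueError("ramp_ms must be > 0")

    def times_ms(self) -> np.ndarray:
        """The epoch time axis implied by the window and sampling rate."""
        step = 1000.0 / self.sfreq_hz
        lo, hi = self.epoch_window_ms
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "noise_model" in d and isinstance(d["noise_model"], dict):
            d["noise_model"] = NoiseModel(**d["noise_model"])
        if "behavior" in d and isinstance(d["behavior"], dict):
            d["behavior"] = BehaviorModel(**d["behavior"])
        if "seeds" in d and isinstance(d["seeds"], dict):
            d["seeds"] = Seeds(**d["seeds"])
        if "epoch_window_ms" in d:
            d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
        return cls(**d)
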