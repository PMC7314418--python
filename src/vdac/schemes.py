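"""The three decoding analyses composed from the distance decoder.

* **Location** — left vs right side of the reward stimulus, collapsed over
  identities, run separately for high- and low-reward trials; the high-low
  contrast is the value modulation of spatial selection.
* **Identity** — which of the two same-value stimuli was shown, decoded
  within each cue side and averaged over sides, per reward level.
* **Value (cross-generalised)** — train high-vs-low on one stimulus pair
  (H1/L1), test on the other (H2/L2), and vice versa, collapsing over cue
  side; any decodable signal must generalise across identity and location
  and is attributable only to value.

Plus the trialwise learning correlation: Spearman rank correlation between
trial number and each trial's delta at the group-level peak time,
Fisher-z transformed per participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet
from .decoding import (
    DecodingTimecourse,
    crossval_distance_decode,
    distance_delta,
    fit_class_models,
    smooth_timecourse,
)

__all__ = [
    "select_attention_trials",
    "decode_location",
    "decode_identity",
    "decode_value_crossgen",
    "group_peak_time",
    "trialwise_peak_correlation",
]

_PAIRS = {1: ("H1", "L1"), 2: ("H2", "L2")}


def _cued_identity(trials: pd.DataFrame) -> np.ndarray:
    return np.where(trials["cue_side"].to_numpy() == "left",
                    trials["identity_left"].to_numpy(),
                    trials["identity_right"].to_numpy())


def select_attention_trials(epochs: EpochSet, soa: str = "long") -> EpochSet:
    """Restrict attention-task epochs to one SOA regime.

    ``soa='long'`` pools the 500 and 1000 ms SOA trials (cue-locked epochs,
    free of target processing within the first 500 ms); ``soa='zero'``
    keeps the 0 ms SOA trials. Learning-task epochs pass through untouched.
    """
    t = epochs.trials
    if t is None or (t["task"] == "learning").all():
        return epochs
    if soa == "long":
        mask = t["soa_ms"].isin([500.0, 1000.0])
    elif soa == "zero":
        mask = t["soa_ms"] == 0.0
    else:
        raise ValueError(f"soa must be 'long' or 'zero', got {soa!r}")
    return epochs.select(mask.to_numpy())


def decode_location(epochs: EpochSet, reward_level: str, k: int = 5,
                    repeats: int = 50, seed: int = 0,
                    smooth_sigma_ms: float = 16.0) -> DecodingTimecourse:
    """Decode the reward-stimulus side for one reward level.

    For learning-task data the high condition pools the high-vs-zero and
    high-vs-low choice trials. Labels are ``cue_side``; stimulus identities
    are collapsed.
    """
    trials = epochs.trials
    if reward_level not in ("high", "low"):
        raise ValueError("reward_level must be 'high' or 'low'")
    sub = epochs.select((trials["reward_level"] == reward_level).to_numpy())
    labels = sub.trials["cue_side"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError(f"missing a cue side in {reward_level}-reward trials")
    tc = crossval_distance_decode(sub, labels, k=k, repeats=repeats, seed=seed,
                                  smooth_sigma_ms=smooth_sigma_ms)
    tc.trial_index = np.flatnonzero((trials["reward_level"] == reward_level).to_numpy())
    tc.scheme, tc.condition = "location", reward_level
    return tc


def decode_identity(epochs: EpochSet, reward_level: str, k: int = 5,
                    repeats: int = 50, seed: int = 0,
                    smooth_sigma_ms: float = 16.0) -> DecodingTimecourse:
    """Decode stimulus identity within each cue side, then pool.

    E.g. for the high level: H1 vs H2 among left-cue trials and among
    right-cue trials separately, so the side signal cannot contribute; the
    per-trial deltas from the two side analyses are concatenated (each
    trial is decoded exactly once), which averages the two timecourses at
    the trial-mean level.
    """
    trials = epochs.trials
    if reward_level not in ("high", "low"):
        raise ValueError("reward_level must be 'high' or 'low'")
    level_idx = np.flatnonzero((trials["reward_level"] == reward_level).to_numpy())
    sub = epochs.select(level_idx)
    idents = _cued_identity(sub.trials)
    uniq = np.unique(idents)
    if uniq.size != 2:
        raise ValueError(f"expected two identities at level {reward_level!r}, got {uniq!r}")

    deltas = np.full((len(level_idx), epochs.n_times), np.nan)
    for s_i, side in enumerate(("left", "right")):
        side_mask = sub.trials["cue_side"].to_numpy() == side
        side_labels = idents[side_mask]
        present = np.unique(side_labels)
        if present.size < 2:
            raise ValueError(f"cue side {side!r} has a single identity; cannot decode")
        tc_side = crossval_distance_decode(
            sub.select(side_mask), side_labels, k=k, repeats=repeats,
            seed=seed + s_i, smooth_sigma_ms=smooth_sigma_ms)
        deltas[np.flatnonzero(side_mask)] = tc_side.delta

    return DecodingTimecourse(
        delta=deltas,
        trial_index=level_idx,
        times_ms=epochs.times_ms,
        sfreq_hz=epochs.sfreq_hz,
        scheme="identity",
        condition=reward_level,
        params={"k": k, "repeats": repeats, "seed": seed,
                "smooth_sigma_ms": smooth_sigma_ms},
    )


def _value_pair_mask(trials: pd.DataFrame, pair: int,
                     learning_subsample: str | None) -> np.ndarray:
    """Trials usable for value decoding belonging to stimulus pair 1 or 2."""
    high_id, low_id = _PAIRS[pair]
    cued = _cued_identity(trials)
    level = trials["reward_level"].to_numpy()
    mask = ((level == "high") & (cued == high_id)) | ((level == "low") & (cued == low_id))
    if (trials["task"] == "learning").any():
        # exclude high-vs-low choice trials; equate counts by odd/even
        # subsampling of the (doubled) low-vs-zero trials
        ct = trials["choice_type"].to_numpy()
        mask &= ct != "HL"
        lz = mask & (ct == "LZ")
        lz_pos = np.flatnonzero(lz)
        offset = 0 if (learning_subsample or "odd") == "odd" else 1
        drop = lz_pos[(np.arange(lz_pos.size) + offset) % 2 == 1]
        mask[drop] = False
    return mask


def decode_value_crossgen(epochs: EpochSet, seed: int = 0,
                          smooth_sigma_ms: float = 16.0,
                          learning_subsample: str = "odd") -> DecodingTimecourse:
    """Cross-generalised value decoding (train one stimulus pair, test the other).

    Class means and the noise covariance are fitted on all trials of the
    training pair (high vs low), and every trial of the held-out pair gets a
    delta; both directions are run so each usable trial is tested exactly
    once, and cue sides are collapsed throughout. For learning-task data
    the high-vs-low choice trials are excluded and the doubled low-vs-zero
    trials are subsampled by an odd/even split to equate counts.
    """
    trials = epochs.trials
    masks = {p: _value_pair_mask(trials, p, learning_subsample) for p in (1, 2)}
    for p, m in masks.items():
        lv = trials["reward_level"].to_numpy()[m]
        if not {"high", "low"} <= set(lv):
            raise ValueError(f"stimulus pair {p} lacks a reward level; cannot cross-generalise")

    all_idx: list[np.ndarray] = []
    all_delta: list[np.ndarray] = []
    for train_pair, test_pair in ((1, 2), (2, 1)):
        tr = epochs.select(masks[train_pair])
        te = epochs.select(masks[test_pair])
        tr_labels = tr.trials["reward_level"].to_numpy()
        te_labels = te.trials["reward_level"].to_numpy()
        means, precision, _ = fit_class_models(tr.data, tr_labels)
        classes = np.unique(tr_labels)
        all_delta.append(distance_delta(te.data, te_labels, means, precision, classes))
        all_idx.append(np.flatnonzero(masks[test_pair]))

    idx = np.concatenate(all_idx)
    order = np.argsort(idx)
    tc = DecodingTimecourse(
        delta=np.concatenate(all_delta)[order],
        trial_index=idx[order],
        times_ms=epochs.times_ms,
        sfreq_hz=epochs.sfreq_hz,
        scheme="value",
        condition="crossgen",
        params={"seed": seed, "learning_subsample": learning_subsample},
    )
    if smooth_sigma_ms:
        tc = smooth_timecourse(tc, smooth_sigma_ms)
    return tc


# ---------------------------------------------------------------------------
# trialwise learning correlation
# ---------------------------------------------------------------------------

def group_peak_time(timecourses: list[DecodingTimecourse],
                    window_ms: tuple[float, float] | None = None) -> float:
    """Peak time of the trial- and participant-averaged decoding curve.

    Optionally restricted to ``window_ms`` (e.g. post-onset); ties break to
    the earliest time.
    """
    times = timecourses[0].times_ms
    grand = np.mean([tc.mean_timecourse() for tc in timecourses], axis=0)
    if window_ms is not None:
        mask = (times >= window_ms[0]) & (times <= window_ms[1])
    else:
        mask = np.ones(times.size, dtype=bool)
    sub = np.where(mask, grand, -np.inf)
    return float(times[int(np.argmax(sub))])


def trialwise_peak_correlation(tc: DecodingTimecourse, trials: pd.DataFrame,
                               peak_time_ms: float) -> float:
    """Fisher-z Spearman correlation between trial number and peak-time delta.

    ``peak_time_ms`` must come from group-level decoding results (see
    :func:`group_peak_time`) so the selection is independent of the single
    participant tested. Returns ``atanh(rho)``; NaN when the correlation is
    undefined (constant input).
    """
    if tc.delta.shape[0] < 10:
        raise ValueError("need at least 10 trials for the trialwise correlation")
    t_idx = int(np.argmin(np.abs(tc.times_ms - peak_time_ms)))
    peak_delta = tc.delta[:, t_idx]
    trial_number = trials["trial_number"].to_numpy()[tc.trial_index] \
        if len(trials) != len(peak_delta) else trials["trial_number"].to_numpy()
    if np.all(peak_delta == peak_delta[0]):
        return float("nan")
    rho = stats.spearmanr(trial_number, peak_delta).statistic
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    return float(np.arctanh(rho))
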