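"""Univariate event-related field components: N2pc and P1.

Per-trial data are baseline corrected (200 ms prestimulus window by
default), planar-gradiometer pairs are combined by root mean square, and
lateralised components are measured as the contralateral-minus-ipsilateral
sensor average. Sensors of interest are chosen per participant from a
contrast orthogonal to the tested one (activity averaged across reward
levels): the n posterior sensors per hemisphere with the largest absolute
lateralised difference in the component window. The N2pc amplitude is the
value-averaged difference in a fixed 200-325 ms window; the P1 analysis
finds a per-sensor peak latency in 75-200 ms and averages a 50 ms window
around it.

Baseline correction is applied before the (nonlinear) RMS combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import EpochSet

__all__ = [
    "EvokedWaveform",
    "ComponentMeasure",
    "baseline_correct",
    "combine_planar_rms",
    "evoked_by_side",
    "select_component_sensors",
    "compute_n2pc",
    "find_component_peak",
    "compute_p1",
]


@dataclass
class EvokedWaveform:
    """Trial-averaged (combined-)channel x time waveform for one condition."""

    values: np.ndarray
    times_ms: np.ndarray
    condition: str = ""
    baseline_window_ms: tuple[float, float] | None = None
    channel_info: pd.DataFrame | None = None


@dataclass
class ComponentMeasure:
    component: str                       # "N2pc" or "P1"
    sensors: np.ndarray                  # combined-channel indices
    window_ms: tuple[float, float] | dict
    amplitude_by_condition: dict[str, float] = field(default_factory=dict)


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline window."""
    mask = epochs.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} outside epoch")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    out = epochs.select(np.arange(epochs.n_trials))
    out.data = epochs.data - base
    return out


def combine_planar_rms(epochs: EpochSet) -> EpochSet:
    """Combine planar-gradiometer pairs as sqrt(a^2 + b^2), halving channels.

    The combined channel table keeps the hemisphere/posterior labels of the
    first pair member (pairs never straddle hemispheres in the synthetic
    layout).
    """
    pairs = epochs.planar_pairs
    if not pairs:
        raise ValueError("planar_pairs not defined on this EpochSet")
    used = [i for p in pairs for i in p]
    if sorted(used) != list(range(epochs.n_channels)):
        raise ValueError("planar pairs must cover every channel exactly once")
    a_idx = np.array([p[0] for p in pairs])
    b_idx = np.array([p[1] for p in pairs])
    data = np.sqrt(epochs.data[:, a_idx] ** 2 + epochs.data[:, b_idx] ** 2)
    info = None
    if epochs.channel_info is not None:
        info = epochs.channel_info.iloc[a_idx].reset_index(drop=True)
        info = info.assign(channel=[f"pair{k:03d}" for k in range(len(pairs))])
    return EpochSet(
        data=data,
        times_ms=epochs.times_ms,
        sfreq_hz=epochs.sfreq_hz,
        channel_ids=[f"pair{k:03d}" for k in range(len(pairs))],
        planar_pairs=[],
        trials=epochs.trials,
        channel_info=info,
    )


def evoked_by_side(epochs: EpochSet, condition_mask: np.ndarray | None = None
                   ) -> dict[str, EvokedWaveform]:
    """Trial-averaged, RMS-combined waveforms for left- and right-cue trials."""
    out = {}
    trials = epochs.trials
    base_mask = np.ones(epochs.n_trials, dtype=bool) if condition_mask is None \
        else np.asarray(condition_mask)
    for side in ("left", "right"):
        m = base_mask & (trials["cue_side"].to_numpy() == side)
        if not m.any():
            raise ValueError(f"no {side}-cue trials in selection")
        avg = epochs.select(m)
        comb = combine_planar_rms(
            EpochSet(avg.data.mean(axis=0, keepdims=True), epochs.times_ms,
                     epochs.sfreq_hz, epochs.channel_ids, epochs.planar_pairs,
                     trials=None, channel_info=epochs.channel_info))
        out[side] = EvokedWaveform(comb.data[0], epochs.times_ms, condition=side,
                                   channel_info=comb.channel_info)
    return out


def _lateralized_difference(by_side: dict[str, EvokedWaveform]) -> np.ndarray:
    """Per-sensor contra-minus-ipsi signal: needs hemisphere labels.

    For a left-hemisphere sensor contralateral means right-cue trials and
    vice versa. Shape: combined-channels x time.
    """
    info = by_side["left"].channel_info
    if info is None or "hemisphere" not in info:
        raise ValueError("channel_info with hemisphere labels required")
    hemi = info["hemisphere"].to_numpy()
    left_w, right_w = by_side["left"].values, by_side["right"].values
    contra = np.where((hemi == "L")[:, None], right_w, left_w)
    ipsi = np.where((hemi == "L")[:, None], left_w, right_w)
    return contra - ipsi


def select_component_sensors(by_side: dict[str, EvokedWaveform],
                             window_ms: tuple[float, float] = (200.0, 325.0),
                             n_per_hemisphere: int = 5) -> np.ndarray:
    """Top-n posterior sensors per hemisphere by |contra - ipsi| in window.

    ``by_side`` must come from an orthogonal contrast — reward levels (and
    SOAs) averaged — so selection cannot bias the later high-vs-low test.
    Returns combined-channel indices, left hemisphere first.
    """
    info = by_side["left"].channel_info
    if info is None or not {"hemisphere", "posterior"} <= set(info.columns):
        raise ValueError("channel_info with hemisphere/posterior labels required")
    diff = _lateralized_difference(by_side)
    times = by_side["left"].times_ms
    tmask = (times >= window_ms[0]) & (times <= window_ms[1])
    score = np.abs(diff[:, tmask].mean(axis=1))
    chosen = []
    for hemi in ("L", "R"):
        cand = np.flatnonzero((info["hemisphere"] == hemi).to_numpy()
                              & info["posterior"].to_numpy())
        if cand.size < n_per_hemisphere:
            raise ValueError(f"hemisphere {hemi} has only {cand.size} posterior sensors")
        top = cand[np.argsort(score[cand])[::-1][:n_per_hemisphere]]
        chosen.append(np.sort(top))
    return np.concatenate(chosen)


def _contra_ipsi_average(epochs: EpochSet, sensors: np.ndarray,
                         condition_mask: np.ndarray) -> np.ndarray:
    """Sensor-averaged contra-minus-ipsi waveform for one condition.

    Averages trials separately per cue side, RMS-combines, then averages
    across cue sides within contralateral and ipsilateral sensor sets.
    """
    by_side = evoked_by_side(epochs, condition_mask)
    info = by_side["left"].channel_info
    hemi = info["hemisphere"].to_numpy()[sensors]
    contra, ipsi = [], []
    for side, wf in by_side.items():
        opp = "R" if side == "left" else "L"
        contra.append(wf.values[sensors[hemi == opp]].mean(axis=0))
        ipsi.append(wf.values[sensors[hemi != opp]].mean(axis=0))
    return np.mean(contra, axis=0) - np.mean(ipsi, axis=0)


def compute_n2pc(epochs: EpochSet, sensors: np.ndarray,
                 window_ms: tuple[float, float] = (200.0, 325.0),
                 conditions: tuple[str, ...] = ("high", "low")) -> ComponentMeasure:
    """N2pc amplitude per reward condition on pre-selected sensors.

    Amplitude = contra-minus-ipsi average within the window; input epochs
    should already be baseline corrected.
    """
    trials = epochs.trials
    tmask = epochs.time_mask(*window_ms)
    amps = {}
    for cond in conditions:
        cmask = (trials["reward_level"] == cond).to_numpy()
        if not cmask.any():
            raise ValueError(f"no trials for condition {cond!r}")
        wave = _contra_ipsi_average(epochs, sensors, cmask)
        amps[cond] = float(wave[tmask].mean())
    return ComponentMeasure("N2pc", sensors, window_ms, amps)


def find_component_peak(waveform: np.ndarray, times_ms: np.ndarray,
                        search_window_ms: tuple[float, float] = (75.0, 200.0)
                        ) -> float:
    """Latency of the largest strict local maximum within the window.

    Falls back to the latency of the maximum value when no interior peak
    exists (e.g. a monotone segment). Plateau ties take the earliest
    sample.
    """
    mask = (times_ms >= search_window_ms[0]) & (times_ms <= search_window_ms[1])
    if not mask.any():
        raise ValueError(f"search window {search_window_ms} outside time axis")
    seg = waveform[mask]
    seg_times = times_ms[mask]
    peaks, _ = find_peaks(seg)
    if peaks.size:
        best = peaks[int(np.argmax(seg[peaks]))]
    else:
        best = int(np.argmax(seg))
    return float(seg_times[best])


def compute_p1(epochs: EpochSet, sensors: np.ndarray,
               search_window_ms: tuple[float, float] = (75.0, 200.0),
               peak_halfwidth_ms: float = 25.0,
               conditions: tuple[str, ...] = ("high", "low")) -> ComponentMeasure:
    """P1 lateralisation with per-sensor peak windows.

    For each selected sensor, the peak latency of the all-trial RMS average
    is found in the search window and a 50 ms window centred on it (clipped
    at epoch edges) defines that sensor's measurement window; the
    contra-minus-ipsi difference is then averaged per condition within the
    per-sensor windows.
    """
    trials = epochs.trials
    all_by_side = evoked_by_side(epochs)
    grand = (all_by_side["left"].values + all_by_side["right"].values) / 2.0
    times = epochs.times_ms
    windows: dict[int, tuple[float, float]] = {}
    for s in sensors:
        lat = find_component_peak(grand[s], times, search_window_ms)
        lo = max(lat - peak_halfwidth_ms, times[0])
        hi = min(lat + peak_halfwidth_ms, times[-1])
        windows[int(s)] = (lo, hi)

    info = all_by_side["left"].channel_info
    hemi = info["hemisphere"].to_numpy()
    amps = {}
    for cond in conditions:
        cmask = (trials["reward_level"] == cond).to_numpy()
        if not cmask.any():
            raise ValueError(f"no trials for condition {cond!r}")
        by_side = evoked_by_side(epochs, cmask)
        per_sensor = []
        for s in sensors:
            lo, hi = windows[int(s)]
            wmask = (times >= lo) & (times <= hi)
            contra_side = "right" if hemi[s] == "L" else "left"
            ipsi_side = "left" if contra_side == "right" else "right"
            d = (by_side[contra_side].values[s, wmask].mean()
                 - by_side[ipsi_side].values[s, wmask].mean())
            per_sensor.append(d)
        amps[cond] = float(np.mean(per_sensor))
    return ComponentMeasure("P1", sensors, windows, amps)
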