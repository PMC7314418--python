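"""Decode the reward-stimulus side and show its value modulation.

Runs the cross-validated Mahalanobis distance decoder on high- and
low-reward trials of one simulated participant and prints the trial-mean
distance difference (delta) in three time windows. Positive delta means
the cue side is decodable; the high-low gap after ~260 ms is the planted
value modulation of spatial selection.
"""

import numpy as np

from vdac import (
    SimulationConfig,
    decode_location,
    fit_pca_reduce,
    generate_attention_schedule,
    simulate_epochs,
)
from vdac.schemes import select_attention_trials

config = SimulationConfig(n_participants=2, n_channels=32,
                          epoch_window_ms=(-100.0, 500.0))
schedule = generate_attention_schedule(sessions=1, seed=0)
epochs = simulate_epochs(schedule, config, participant=0)
epochs = select_attention_trials(epochs, soa="long")  # pool 500/1000 ms SOA
epochs = fit_pca_reduce(epochs, n_components=70)

high = decode_location(epochs, "high", repeats=10, seed=0)
low = decode_location(epochs, "low", repeats=10, seed=0)

windows = {"baseline (-100..0 ms)": (-100, 0),
           "early (120..250 ms)": (120, 250),
           "late (300..500 ms)": (300, 500)}
print(f"{'window':<22}{'delta high':>12}{'delta low':>12}{'high-low':>10}")
for name, (lo, hi) in windows.items():
    mask = (high.times_ms >= lo) & (high.times_ms <= hi)
    dh = high.mean_timecourse()[mask].mean()
    dl = low.mean_timecourse()[mask].mean()
    print(f"{name:<22}{dh:>12.3f}{dl:>12.3f}{dh - dl:>10.3f}")
print("\nBoth conditions decode after ~100 ms; only the late window shows")
print("the high>low gap — learned value modulating spatial selection.")
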