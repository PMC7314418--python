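"""Univariate N2pc analysis on simulated epochs.

Baseline-corrects, selects posterior sensors per hemisphere from the
value-averaged (orthogonal) lateralised contrast, and measures the
contralateral-minus-ipsilateral N2pc amplitude per reward condition in the
200-325 ms window. The planted contralateral location signal is boosted on
high-reward trials from 260 ms, so the high-reward N2pc should be larger.
"""

import numpy as np

from vdac import (
    SimulationConfig,
    baseline_correct,
    compute_n2pc,
    generate_attention_schedule,
    select_component_sensors,
    simulate_epochs,
)
from vdac.evoked import evoked_by_side
from vdac.schemes import select_attention_trials

config = SimulationConfig(n_participants=2, n_channels=32,
                          epoch_window_ms=(-200.0, 500.0))
epochs = simulate_epochs(generate_attention_schedule(1, seed=0), config, 0)
epochs = baseline_correct(select_attention_trials(epochs, "long"))

reward_only = epochs.trials["reward_level"].isin(["high", "low"]).to_numpy()
by_side = evoked_by_side(epochs, reward_only)
sensors = select_component_sensors(by_side, window_ms=(200.0, 325.0),
                                   n_per_hemisphere=4)
print("selected combined-gradiometer sensors:", list(sensors))

m = compute_n2pc(epochs, sensors, window_ms=(200.0, 325.0))
hi = m.amplitude_by_condition["high"]
lo = m.amplitude_by_condition["low"]
print(f"N2pc amplitude, high reward: {hi:.3f}")
print(f"N2pc amplitude, low reward:  {lo:.3f}")
print(f"value modulation (high-low): {hi - lo:+.3f}")
print("\nAmplitudes are contra-minus-ipsi averages over the selected")
print("sensors; the positive high-low difference mirrors the value")
print("modulation of spatial attention seen in the decoding.")
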