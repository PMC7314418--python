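"""Group-level cluster permutation test on a small simulated cohort.

Decodes the high-low location contrast for 8 participants, then tests it
against zero with the sign-flip cluster permutation test. The printed
cluster should start near the planted 260 ms modulation onset.
"""

import numpy as np

from vdac import SimulationConfig, simulate_cohort
from vdac.pipeline import decode_cohort
from vdac.group_stats import cluster_sign_permutation

config = SimulationConfig(n_participants=8, n_channels=32,
                          epoch_window_ms=(-100.0, 500.0))
cohort = simulate_cohort(config, task="attention", sessions=1)
dec = decode_cohort(cohort, soa="long", schemes=("location",),
                    repeats=5, seed=0)

contrast = dec.group("location_contrast").crop(0.0)  # drop the baseline
res = cluster_sign_permutation(contrast, alpha_cluster=0.05, n_perm=2000,
                               seed=0)
print(f"{'cluster':<10}{'start ms':>10}{'end ms':>10}{'mass':>10}{'p':>10}")
for i, c in enumerate(res.clusters):
    print(f"{i:<10}{c.t_start_ms:>10.0f}{c.t_end_ms:>10.0f}"
          f"{c.mass:>10.1f}{c.p_value:>10.4f}")
print("\nMass is the summed t statistic; p comes from the max-cluster-mass")
print("permutation null (sign flips of whole participants), so it is")
print("corrected for the number of timepoints tested.")
print(f"earliest significant cluster onset: {res.onset_ms():.0f} ms "
      "(planted modulation onset: 260 ms)")
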