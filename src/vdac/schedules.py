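"""Trial-schedule generators for the two-phase reward/attention paradigm.

The training phase is a two-alternative reward learning task over 10 stimuli
(two high-reward, two low-reward, six zero-reward): 96 high-vs-low, 96
high-vs-zero and 192 low-vs-zero choice trials per session, the last doubled
to equate how often high- and low-reward stimuli are selected. The testing
phase is a cued visual discrimination task with a 3 (reward: high/low/
baseline) x 2 (congruency) x 3 (SOA: 0/500/1000 ms) factorial design, 60
trials per cell per session, congruency undefined for baseline trials.

Counterbalancing of identities and left/right placement within cells is
exact (even integer counts), not Bernoulli, so that no schedule-level
confound can masquerade as a planted effect. Only the presentation order is
randomised, reproducibly from the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import TRIAL_COLUMNS, validate_trial_table

_ZEROS = ["Z1", "Z2", "Z3", "Z4", "Z5", "Z6"]

N_LEARNING_PER_SESSION = 384
N_ATTENTION_PER_SESSION = 900


def _rows_to_table(rows: list[dict], session: int, task: str, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([seed, session]))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    df = pd.DataFrame(rows)
    df["task"] = task
    df["session"] = session
    df["trial_number"] = np.arange(1, len(df) + 1)
    df["trial_id"] = (session - 1) * len(df) + df["trial_number"] - 1
    df["rt_ms"] = np.nan
    df["accuracy"] = np.nan
    return df[TRIAL_COLUMNS].reset_index(drop=True)


def _pair_row(cued: str, other: str, cue_side: str, *, choice_type: str,
              reward_level: str, soa_ms: float, congruency: str) -> dict:
    left, right = (cued, other) if cue_side == "left" else (other, cued)
    return {
        "choice_type": choice_type,
        "reward_level": reward_level,
        "cue_side": cue_side,
        "identity_left": left,
        "identity_right": right,
        "soa_ms": soa_ms,
        "congruency": congruency,
    }


def generate_learning_schedule(session: int, seed: int = 0) -> pd.DataFrame:
    """One session of the reward learning task: 384 choice trials.

    Composition is exact for every seed: 96 high-vs-low (HL), 96
    high-vs-zero (HZ), 192 low-vs-zero (LZ). Within each choice type the two
    relevant reward identities, their zero-reward partners and left/right
    placement are balanced as evenly as integer counts allow. ``cue_side``
    is the side of the higher-reward option and ``reward_level`` its value
    class (high for HZ/HL, low for LZ).
    """
    if session not in (1, 2):
        raise ValueError(f"session must be 1 or 2, got {session!r}")

    rows: list[dict] = []
    zero_cycle = 0

    def next_zero() -> str:
        nonlocal zero_cycle
        z = _ZEROS[zero_cycle % 6]
        zero_cycle += 1
        return z

    # HZ: 96 = 2 high identities x 2 sides x 24
    for high in ("H1", "H2"):
        for side in ("left", "right"):
            for _ in range(24):
                rows.append(_pair_row(high, next_zero(), side,
                                      choice_type="HZ", reward_level="high",
                                      soa_ms=np.nan, congruency="na"))
    # HL: 96 = 2 high x 2 low x 2 sides x 12
    for high in ("H1", "H2"):
        for low in ("L1", "L2"):
            for side in ("left", "right"):
                for _ in range(12):
                    rows.append(_pair_row(high, low, side,
                                          choice_type="HL", reward_level="high",
                                          soa_ms=np.nan, congruency="na"))
    # LZ: 192 = 2 low x 2 sides x 48
    for low in ("L1", "L2"):
        for side in ("left", "right"):
            for _ in range(48):
                rows.append(_pair_row(low, next_zero(), side,
                                      choice_type="LZ", reward_level="low",
                                      soa_ms=np.nan, congruency="na"))

    df = _rows_to_table(rows, session, "learning", seed)
    validate_trial_table(df)
    return df


def generate_attention_schedule(sessions: int, seed: int = 0) -> pd.DataFrame:
    """Attention-task schedule: 900 trials per session (1800 over two).

    Per session, 60 trials per (reward in {high, low}) x congruency x SOA
    cell plus 60 baseline trials (two zero-reward stimuli, congruency
    ``na``) per SOA. Reward identities and cue side are balanced exactly
    within each cell; ``cue_side`` on baseline trials is the target side.
    """
    if sessions < 1:
        raise ValueError(f"sessions must be >= 1, got {sessions!r}")

    frames = []
    for session in range(1, sessions + 1):
        rows: list[dict] = []
        zero_cycle = 0

        def next_zero() -> str:
            nonlocal zero_cycle
            z = _ZEROS[zero_cycle % 6]
            zero_cycle += 1
            return z

        for soa in (0, 500, 1000):
            for reward, idents in (("high", ("H1", "H2")), ("low", ("L1", "L2"))):
                for congruency in ("congruent", "incongruent"):
                    # 60 = 2 identities x 2 sides x 15
                    for ident in idents:
                        for side in ("left", "right"):
                            for _ in range(15):
                                rows.append(_pair_row(
                                    ident, next_zero(), side,
                                    choice_type="none", reward_level=reward,
                                    soa_ms=float(soa), congruency=congruency))
            # baseline: 60 per SOA, two distinct zero stimuli
            for side in ("left", "right"):
                for _ in range(30):
                    z1, z2 = next_zero(), next_zero()
                    if z1 == z2:  # cycle length 6 never repeats adjacently
                        z2 = next_zero()
                    rows.append(_pair_row(z1, z2, side,
                                          choice_type="none", reward_level="baseline",
                                          soa_ms=float(soa), congruency="na"))
        frames.append(_rows_to_table(rows, session, "attention", seed))

    df = pd.concat(frames, ignore_index=True)
    df["trial_id"] = np.arange(len(df))
    validate_trial_table(df)
    return df


def target_side(trials: pd.DataFrame) -> np.ndarray:
    """Side where the target grating appears, derived from congruency.

    Congruent: same side as the reward stimulus; incongruent: opposite;
    baseline: ``cue_side`` itself encodes the target side.
    """
    cue = trials["cue_side"].to_numpy()
    congr = trials["congruency"].to_numpy()
    flip = {"left": "right", "right": "left"}
    return np.array([flip[c] if g == "incongruent" else c for c, g in zip(cue, congr)])
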