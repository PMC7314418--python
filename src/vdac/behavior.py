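"""Behavioral summaries: learning curves, condition medians, VDAC effect.

The central quantity is the per-participant value-driven attentional
capture (VDAC) interaction on reaction time,

    interaction = (high_incongruent - high_congruent)
                - (low_incongruent - low_congruent),

computed from median RTs of correct trials with the four reward x
congruency cells first averaged (unweighted) across the three SOAs. This
effect anchors the median split and every brain-behavior analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VdacEffect",
    "learning_curves",
    "condition_summaries",
    "vdac_interaction_effect",
]


@dataclass
class VdacEffect:
    participant: int | str
    interaction_ms: float
    components: dict[str, float]


def learning_curves(trials: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Trialwise moving-average accuracy and RT curves for the learning task.

    Smoothing is a trailing ``window``-trial moving average within each
    session (shrinking at session starts), sessions concatenated; no
    smoothing leaks across the session boundary. The high-reward curve
    pools the high-vs-zero and high-vs-low choice trials; the low-reward
    curve is the low-vs-zero trials. Returns a tidy frame with columns
    ``condition, session, trial_number, accuracy, rt_ms``.
    """
    t = trials[trials["task"] == "learning"]
    if t.empty or t["accuracy"].isna().all():
        raise ValueError("learning-task trials with accuracy required")
    rows = []
    for cond, mask in (("high", t["choice_type"].isin(["HZ", "HL"])),
                       ("low", t["choice_type"] == "LZ")):
        sub = t[mask].sort_values(["session", "trial_number"])
        for session, sess in sub.groupby("session"):
            if sess.empty:
                raise ValueError(f"empty session {session}")
            acc = sess["accuracy"].rolling(window, min_periods=1).mean()
            rt = sess["rt_ms"].rolling(window, min_periods=1).mean()
            rows.append(pd.DataFrame({
                "condition": cond,
                "session": session,
                "trial_number": sess["trial_number"].to_numpy(),
                "accuracy": acc.to_numpy(),
                "rt_ms": rt.to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


def condition_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Median RT (correct trials) and accuracy per reward x congruency x SOA.

    Also attaches the baseline-subtracted RT difference score per SOA
    (condition minus the baseline cell at the matching SOA). Cells with no
    correct trials yield missing values.
    """
    t = trials[trials["task"] == "attention"].copy()
    if t.empty:
        raise ValueError("attention-task trials required")
    correct = t[t["accuracy"] == 1]
    grp = ["reward_level", "congruency", "soa_ms"]
    med = correct.groupby(grp)["rt_ms"].median().rename("median_rt_ms")
    acc = t.groupby(grp)["accuracy"].mean().rename("accuracy")
    out = pd.concat([med, acc], axis=1).reset_index()
    base = out[out["reward_level"] == "baseline"].set_index("soa_ms")["median_rt_ms"]
    out["rt_diff_ms"] = out.apply(
        lambda r: r["median_rt_ms"] - base.get(r["soa_ms"], np.nan)
        if r["reward_level"] != "baseline" else 0.0, axis=1)
    return out


def vdac_interaction_effect(summary: pd.DataFrame,
                            participant: int | str = 0) -> VdacEffect:
    """The RT reward x congruency interaction from a condition summary.

    The four reward x congruency cells are first averaged (unweighted)
    across the three SOAs, then
    ``(high_incong - high_cong) - (low_incong - low_cong)``.
    """
    cells = {}
    for reward in ("high", "low"):
        for congr in ("congruent", "incongruent"):
            sel = summary[(summary["reward_level"] == reward)
                          & (summary["congruency"] == congr)]
            if sel.empty or sel["median_rt_ms"].isna().any():
                raise ValueError(f"missing cell {reward}/{congr}")
            cells[f"{reward[0:4]}_{'cong' if congr == 'congruent' else 'incong'}"] = \
                float(sel["median_rt_ms"].mean())
    base_sel = summary[summary["reward_level"] == "baseline"]
    components = {
        "high_cong": cells["high_cong"],
        "high_incong": cells["high_incong"],
        "low_cong": cells["low_cong"],
        "low_incong": cells["low_incong"],
        "baseline": float(base_sel["median_rt_ms"].mean()) if not base_sel.empty else np.nan,
    }
    interaction = ((components["high_incong"] - components["high_cong"])
                   - (components["low_incong"] - components["low_cong"]))
    return VdacEffect(participant=participant, interaction_ms=interaction,
                      components=components)
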