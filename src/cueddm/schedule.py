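"""Trial schedules: exact stratified condition counts, seeded shuffle.

Cue-object counts are assigned exactly (probability × total trials must be an
integer — true for all three preset designs at 560 trials), gap sides are
balanced 50/50 within each cue object up to rounding, and cue-target delays
are drawn uniformly from the design's delay set. The only randomness is the
seeded shuffle and the delay draws, so condition-frequency audits are exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CUE_OBJECTS, CUE_VALIDITY, DesignSpec

__all__ = ["build_schedule", "schedule_audit"]

_COUNT_TOL = 1e-9


def build_schedule(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build one session's ordered trial schedule.

    Returns a DataFrame with columns ``cue_object``, ``space_valid``,
    ``feature_valid``, ``delay_ms``, ``gap_side`` and exactly
    ``design.total_trials`` rows.

    Raises
    ------
    ValueError
        If any ``probability × total_trials`` is not an integer (no silent
        rounding).
    """
    total = design.total_trials
    counts: dict[str, int] = {}
    for cue in CUE_OBJECTS:
        exact = design.cue_object_probs[cue] * total
        rounded = round(exact)
        if abs(exact - rounded) > _COUNT_TOL:
            raise ValueError(
                f"cue object {cue}: probability {design.cue_object_probs[cue]} x "
                f"{total} trials = {exact} is not an integer; stratified exact "
                "assignment requires integer counts"
            )
        counts[cue] = int(rounded)

    cues: list[str] = []
    sides: list[str] = []
    for cue in CUE_OBJECTS:
        n = counts[cue]
        cues.extend([cue] * n)
        n_left = n // 2
        n_right = n - n_left
        if n % 2 and rng.random() < 0.5:  # odd count: randomize the extra side
            n_left, n_right = n_right, n_left
        sides.extend(["left"] * n_left + ["right"] * n_right)

    order = rng.permutation(total)
    cue_arr = np.asarray(cues, dtype=object)[order]
    side_arr = np.asarray(sides, dtype=object)[order]
    delays = rng.choice(np.asarray(design.delays_ms), size=total)

    sv = np.asarray([CUE_VALIDITY[c][0] for c in cue_arr])
    fv = np.asarray([CUE_VALIDITY[c][1] for c in cue_arr])
    return pd.DataFrame(
        {
            "cue_object": cue_arr,
            "space_valid": sv,
            "feature_valid": fv,
            "delay_ms": delays.astype(int),
            "gap_side": side_arr,
        }
    )


def schedule_audit(schedule: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Condition-frequency audit: observed vs design counts per cue object."""
    obs = schedule["cue_object"].value_counts()
    total = len(schedule)
    rows = []
    for cue in CUE_OBJECTS:
        n_obs = int(obs.get(cue, 0))
        n_exp = design.cue_object_probs[cue] * design.total_trials
        rows.append(
            {
                "cue_object": cue,
                "n_observed": n_obs,
                "n_expected": n_exp,
                "pct_observed": 100.0 * n_obs / total,
                "pct_design": 100.0 * design.cue_object_probs[cue],
            }
        )
    return pd.DataFrame(rows)
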