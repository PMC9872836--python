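"""Trial exclusion and condition-cell summaries.

Exclusions run in a fixed order that mirrors the human pipeline: practice
block first, then gaze-contaminated trials (blinks, saccades, fixation
breaks), then trials with no designated keypress, then — optionally — fast
responses below a cutoff (0.250 s reproduces the robustness check used for
the drift analysis). The report gives the percentage removed at each stage
relative to the trials entering that stage, which is how such pipelines are
conventionally reported.

Surviving trials are reduced to per-subject x cue-object *condition cells*
carrying the three EZ inputs: proportion correct (Pc), mean correct RT (MRT)
and variance of correct RT (VRT, n-1 denominator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CUE_OBJECTS

__all__ = ["apply_exclusions", "summarize_cells"]

_VALID_RESPONSES = {"left", "right", "none"}


def apply_exclusions(
    log: pd.DataFrame,
    *,
    fast_cutoff_s: float | None = None,
    practice_blocks: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-exclusion stages to a trial log.

    Returns ``(filtered_log, report)`` where the report has one row per
    stage with ``n_before``, ``n_removed``, ``pct_removed`` (of trials
    entering the stage) and ``n_after``.

    Raises
    ------
    ValueError
        If the log contains response codes outside {left, right, none}.
    """
    bad = set(log["response"].unique()) - _VALID_RESPONSES
    if bad:
        raise ValueError(f"unknown response codes: {sorted(bad)}")

    stages = []
    out = log

    def _drop(name: str, mask_keep: pd.Series) -> None:
        nonlocal out
        n_before = len(out)
        kept = out[mask_keep]
        n_removed = n_before - len(kept)
        stages.append(
            {
                "stage": name,
                "n_before": n_before,
                "n_removed": n_removed,
                "pct_removed": 100.0 * n_removed / n_before if n_before else 0.0,
                "n_after": len(kept),
            }
        )
        out = kept

    _drop("practice_block", out["block_index"] >= practice_blocks)
    _drop("gaze_contaminated", ~out["gaze_contaminated"].astype(bool))
    _drop("no_response", out["response"] != "none")
    if fast_cutoff_s is not None:
        _drop("fast_response", out["rt_s"] >= fast_cutoff_s)

    return out.reset_index(drop=True), pd.DataFrame(stages)


def summarize_cells(
    filtered: pd.DataFrame,
    *,
    min_correct: int = 2,
    drop_flagged_subjects: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce a filtered log to per-subject x cue-object condition cells.

    Every retained trial must carry a designated response and RT. A cell
    with fewer than ``min_correct`` correct trials is flagged (MRT/VRT are
    undefined or degenerate there); by default the owning subject is dropped
    from the cell table, mirroring the exclusion of participants with nearly
    empty cells.

    Returns ``(cells, flags)``: cells with columns ``subject_id``,
    ``cue_object``, ``n_total``, ``n_correct``, ``Pc``, ``MRT``, ``VRT``;
    flags listing the offending subject/cell pairs.
    """
    if (filtered["response"] == "none").any():
        raise ValueError("filtered log still contains non-responses; run apply_exclusions first")

    df = filtered.copy()
    df["correct"] = df["response"] == df["gap_side"]

    rows = []
    for (subj, cue), grp in df.groupby(["subject_id", "cue_object"], sort=True):
        correct_rt = grp.loc[grp["correct"], "rt_s"].to_numpy(float)
        n_corr = correct_rt.size
        rows.append(
            {
                "subject_id": subj,
                "cue_object": cue,
                "n_total": len(grp),
                "n_correct": n_corr,
                "Pc": n_corr / len(grp),
                "MRT": correct_rt.mean() if n_corr else np.nan,
                "VRT": correct_rt.var(ddof=1) if n_corr >= 2 else np.nan,
            }
        )
    cells = pd.DataFrame(rows)

    # subjects must contribute every cue object; absent cells count as empty
    flag_rows = []
    for subj, grp in cells.groupby("subject_id"):
        present = set(grp["cue_object"])
        for cue in CUE_OBJECTS:
            if cue not in present:
                flag_rows.append(
                    {"subject_id": subj, "cue_object": cue, "n_correct": 0}
                )
        low = grp[grp["n_correct"] < min_correct]
        for _, r in low.iterrows():
            flag_rows.append(
                {
                    "subject_id": subj,
                    "cue_object": r["cue_object"],
                    "n_correct": int(r["n_correct"]),
                }
            )
    flags = pd.DataFrame(flag_rows, columns=["subject_id", "cue_object", "n_correct"])

    if drop_flagged_subjects and not flags.empty:
        cells = cells[~cells["subject_id"].isin(flags["subject_id"])].reset_index(
            drop=True
        )
    return cells, flags
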