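"""Exclusion stages and condition-cell summaries."""

import numpy as np
import pandas as pd
import pytest

from cueddm import apply_exclusions, summarize_cells
from cueddm.session import TRIAL_LOG_COLUMNS


def _make_log(n=200, gaze_rate=0.1, none_rate=0.0, seed=0, rt=0.5):
    rng = np.random.default_rng(seed)
    n_practice = 40
    df = pd.DataFrame(
        {
            "subject_id": 0,
            "block_index": np.where(np.arange(n) < n_practice, 0, 1),
            "trial_index": np.arange(n),
            "cue_object": np.resize(["SvFv", "SvFi", "SiFv", "SiFi"], n),
            "space_valid": True,
            "feature_valid": True,
            "delay_ms": 500,
            "gap_size_deg": 0.2,
            "gap_side": np.resize(["left", "right"], n),
            "response": np.resize(["left", "right"], n),
            "rt_s": rt,
            "gaze_contaminated": rng.random(n) < gaze_rate,
            "is_guess": False,
        }
    )
    none_mask = rng.random(n) < none_rate
    df.loc[none_mask, "response"] = "none"
    df.loc[none_mask, "rt_s"] = np.nan
    return df[TRIAL_LOG_COLUMNS]


def test_stage_order_and_report_reconciles():
    log = _make_log(n=400, gaze_rate=0.1, none_rate=0.05, seed=1)
    filtered, report = apply_exclusions(log)
    assert list(report["stage"]) == ["practice_block", "gaze_contaminated", "no_response"]
    # counts reconcile exactly with rows removed
    assert report["n_before"].iloc[0] == len(log)
    for i in range(1, len(report)):
        assert report["n_before"].iloc[i] == report["n_after"].iloc[i - 1]
    assert report["n_after"].iloc[-1] == len(filtered)
    assert (report["n_before"] - report["n_removed"] == report["n_after"]).all()
    # gaze stage removes about the contamination rate
    gaze_pct = report.set_index("stage").loc["gaze_contaminated", "pct_removed"]
    assert gaze_pct == pytest.approx(10, abs=4)
    assert not filtered["gaze_contaminated"].any()
    assert (filtered["response"] != "none").all()
    assert (filtered["block_index"] > 0).all()


def test_exclusions_idempotent():
    log = _make_log(n=400, gaze_rate=0.2, none_rate=0.02, seed=2)
    once, _ = apply_exclusions(log)
    twice, report = apply_exclusions(once, practice_blocks=1)
    pd.testing.assert_frame_equal(once, twice)
    assert (report["n_removed"] == 0).all()


def test_fast_cutoff_removes_exactly_sub_threshold_trials():
    log = _make_log(n=100, gaze_rate=0.0)
    log.loc[50:59, "rt_s"] = 0.2
    filtered, report = apply_exclusions(log, fast_cutoff_s=0.25)
    fast = report.set_index("stage").loc["fast_response"]
    assert fast["n_removed"] == 10
    assert (filtered["rt_s"] >= 0.25).all()


def test_unknown_response_codes_rejected():
    log = _make_log(n=50)
    log.loc[3, "response"] = "middle"
    with pytest.raises(ValueError, match="unknown response codes"):
        apply_exclusions(log)


def test_cell_summaries_hand_values():
    rows = []
    for cue in ("SvFv", "SvFi", "SiFv", "SiFi"):
        for i, (rt, resp) in enumerate([(0.4, "left"), (0.6, "left"), (0.7, "right")]):
            rows.append(
                {
                    "subject_id": 0,
                    "block_index": 1,
                    "trial_index": i,
                    "cue_object": cue,
                    "space_valid": True,
                    "feature_valid": True,
                    "delay_ms": 500,
                    "gap_size_deg": 0.2,
                    "gap_side": "left",
                    "response": resp,
                    "rt_s": rt,
                    "gaze_contaminated": False,
                    "is_guess": False,
                }
            )
    log = pd.DataFrame(rows)[TRIAL_LOG_COLUMNS]
    cells, flags = summarize_cells(log, min_correct=2)
    assert flags.empty
    cell = cells.iloc[0]
    # correct RTs {0.4, 0.6}: MRT = 0.5, VRT = 0.02 (n-1 denominator)
    assert cell["Pc"] == pytest.approx(2 / 3)
    assert cell["MRT"] == pytest.approx(0.5)
    assert cell["VRT"] == pytest.approx(0.02)


def test_constant_rt_all_correct_cell():
    log = _make_log(n=120, gaze_rate=0.0, rt=0.5)
    filtered, _ = apply_exclusions(log)
    cells, _ = summarize_cells(filtered)
    assert (cells["Pc"] == 1.0).all()
    assert (cells["MRT"] == 0.5).all()
    assert (cells["VRT"] == 0.0).all()


def test_subject_with_starved_cell_flagged_and_dropped():
    log = _make_log(n=400, gaze_rate=0.0, seed=3)
    # subject 1: SiFi cell has a single correct trial
    sub1 = log.copy()
    sub1["subject_id"] = 1
    starved = sub1["cue_object"] == "SiFi"
    sub1.loc[starved, "response"] = np.where(
        sub1.loc[starved, "gap_side"] == "left", "right", "left"
    )
    first = sub1.index[starved][0]
    sub1.loc[first, "response"] = sub1.loc[first, "gap_side"]
    both = pd.concat([log, sub1], ignore_index=True)
    filtered, _ = apply_exclusions(both)
    cells, flags = summarize_cells(filtered, min_correct=2)
    assert (flags["subject_id"] == 1).all() and len(flags) == 1
    assert set(cells["subject_id"]) == {0}


def test_summaries_reject_unfiltered_log():
    log = _make_log(n=100, none_rate=0.3, seed=4)
    with pytest.raises(ValueError, match="non-responses"):
        summarize_cells(log)
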