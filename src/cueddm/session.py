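"""Simulate full sessions and cohorts of the dual-cue search task.

A session walks the stratified schedule trial by trial: boundary separation
and non-decision time are looked up by whole cue object, drift by the two
validity flags and the current titrated gap, and choices/RTs come from the
two-boundary diffusion sampler. Contamination mirrors the human data
stream — fast uniform guesses, gaze-contaminated trials, and trials with no
designated keypress — and the titration update runs on all trials before any
exclusion, as in the recorded experiments.

All randomness flows from one seed per subject; cohorts spawn independent
per-subject substreams from a master seed, so trial logs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ddm import sample_ddm_trials
from .design import DesignSpec
from .observer import ObserverParams, drift_for_trial
from .schedule import build_schedule
from .titration import titration_step

__all__ = ["simulate_session", "simulate_cohort", "TRIAL_LOG_COLUMNS"]

#: Column order of the trial-log schema (one row per trial).
TRIAL_LOG_COLUMNS = [
    "subject_id",
    "block_index",
    "trial_index",
    "cue_object",
    "space_valid",
    "feature_valid",
    "delay_ms",
    "gap_size_deg",
    "gap_side",
    "response",
    "rt_s",
    "gaze_contaminated",
    "is_guess",
]

_OTHER_SIDE = {"left": "right", "right": "left"}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(
    design: DesignSpec,
    params: ObserverParams,
    seed,
    *,
    subject_id=0,
    titrate: bool = True,
    fixed_gap_deg: float | None = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate one subject's full session (practice block included).

    Parameters
    ----------
    design, params
        Experimental design and generative observer.
    seed
        Integer seed, SeedSequence or Generator for this subject.
    titrate
        If True (default) the gap follows the staircase; if False the gap is
        held at ``fixed_gap_deg`` (default: the observer's reference gap) for
        the whole session, which makes the generating (v, a, ter) per cell
        well defined for parameter-recovery studies.
    dt
        Euler step of the diffusion sampler (s).

    Returns
    -------
    DataFrame with :data:`TRIAL_LOG_COLUMNS`, ``design.total_trials`` rows.
    """
    rng = _as_rng(seed)
    schedule = build_schedule(design, rng)
    total = design.total_trials
    window_s = design.response_window_ms / 1000.0
    tit = design.titration

    if titrate:
        gap = tit.gap_init_deg
    else:
        gap = params.gap_ref_deg if fixed_gap_deg is None else fixed_gap_deg
        if not tit.gap_min_deg <= gap <= tit.gap_max_deg:
            raise ValueError("fixed gap must lie within the titration range")

    a_lookup = schedule["cue_object"].map(params.a_by_object).to_numpy(float)
    ter_lookup = schedule["cue_object"].map(params.ter_by_object).to_numpy(float)
    sv = schedule["space_valid"].to_numpy(bool)
    fv = schedule["feature_valid"].to_numpy(bool)
    sides = schedule["gap_side"].to_numpy(object)

    gap_deg = np.empty(total)
    response = np.empty(total, dtype=object)
    rt_s = np.full(total, np.nan)
    is_guess = np.zeros(total, dtype=bool)

    chunk = tit.window_trials if titrate else total
    outcomes: list[bool] = []
    start = 0
    while start < total:
        stop = min(start + chunk, total)
        sl = slice(start, stop)
        m = stop - start
        gap_deg[sl] = gap

        v = drift_for_trial(params, sv[sl], fv[sl], gap)
        res = sample_ddm_trials(
            v,
            a_lookup[sl],
            ter_lookup[sl],
            s=params.s,
            response_window_s=window_s,
            dt=dt,
            rng=rng,
        )

        resp = np.where(
            res["responded"],
            np.where(
                res["correct"],
                sides[sl],
                np.asarray([_OTHER_SIDE[s_] for s_ in sides[sl]], dtype=object),
            ),
            "none",
        ).astype(object)
        rt = res["rt_s"].copy()

        # fast uniform guesses replace the diffusion outcome wholesale
        guess = rng.random(m) < params.guess_rate
        if np.any(guess):
            n_g = int(guess.sum())
            rt[guess] = rng.uniform(0.0, window_s, size=n_g)
            resp[guess] = np.where(
                rng.random(n_g) < 0.5, "left", "right"
            ).astype(object)

        # independent failure to press a designated key
        none_mask = rng.random(m) < params.nonresponse_rate
        resp[none_mask] = "none"
        rt[resp == "none"] = np.nan

        response[sl] = resp
        rt_s[sl] = rt
        is_guess[sl] = guess & (resp != "none")

        correct_now = resp == sides[sl]  # non-response scores incorrect
        outcomes.extend(correct_now.tolist())
        if titrate and m == tit.window_trials:
            gap = titration_step(gap, outcomes[-tit.window_trials :], tit)
        start = stop

    gaze = rng.random(total) < params.gaze_loss_rate

    log = schedule.copy()
    log.insert(0, "subject_id", subject_id)
    log.insert(1, "block_index", np.arange(total) // design.trials_per_block)
    log.insert(2, "trial_index", np.arange(total))
    log["gap_size_deg"] = gap_deg
    log["response"] = response
    log["rt_s"] = rt_s
    log["gaze_contaminated"] = gaze
    log["is_guess"] = is_guess
    return log[TRIAL_LOG_COLUMNS]


def simulate_cohort(
    design: DesignSpec,
    params: ObserverParams,
    n_subjects: int,
    master_seed,
    *,
    titrate: bool = True,
    fixed_gap_deg: float | None = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` independent sessions from one master seed.

    Per-subject substreams are spawned from a ``SeedSequence``, so cohorts
    are reproducible and subjects statistically independent.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    children = ss.spawn(n_subjects)
    logs = [
        simulate_session(
            design,
            params,
            np.random.default_rng(child),
            subject_id=i,
            titrate=titrate,
            fixed_gap_deg=fixed_gap_deg,
            dt=dt,
        )
        for i, child in enumerate(children)
    ]
    return pd.concat(logs, ignore_index=True)
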