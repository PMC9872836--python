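"""End-to-end analysis and parameter-recovery reports.

`analyze_log` chains the stages exactly as the human data were analyzed:
exclusions -> condition cells -> d' -> robust EZ inversion -> repeated-
measures inference, and returns tidy tables (every reported number is a CSV
cell). `recovery_report` compares generating to recovered DDM parameters on
simulated cohorts with the gap held at the reference size, so each cell has
a well-defined ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CUE_OBJECTS, CUE_VALIDITY, DesignSpec
from .ez import ez_fit_cells
from .observer import ObserverParams
from .preprocess import apply_exclusions, summarize_cells
from .sensitivity import dprime_cells
from .session import simulate_cohort, simulate_session
from .stats import paired_t, rm_anova_2x2, within_subject_sem

__all__ = ["analyze_log", "recovery_report", "titrated_accuracy"]

#: Per-subject measures analyzed with the 2x2 repeated-measures machinery.
MEASURES = ("d_prime", "v", "a", "ter")


def _attach_validity(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["space_valid"] = df["cue_object"].map(lambda c: CUE_VALIDITY[c][0])
    df["feature_valid"] = df["cue_object"].map(lambda c: CUE_VALIDITY[c][1])
    return df


def analyze_log(
    log: pd.DataFrame,
    *,
    fast_cutoff_s: float | None = None,
    practice_blocks: int = 1,
    min_correct: int = 2,
    min_cell_n: int = 10,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis pipeline on a trial log.

    Returns a dict of tidy tables: ``exclusions``, ``cells``, ``flags``,
    ``dprime``, ``ez``, ``measures`` (long per-subject table of all four
    measures), ``effects`` (ANOVA + marginal paired contrasts per measure)
    and ``condition_means`` (per-cue-object means with within-participant
    SEMs).
    """
    if log.empty:
        raise ValueError("empty trial log")
    filtered, report = apply_exclusions(
        log, fast_cutoff_s=fast_cutoff_s, practice_blocks=practice_blocks
    )
    if filtered.empty:
        raise ValueError("no trials survive the exclusion stages")
    cells, flags = summarize_cells(filtered, min_correct=min_correct)
    if cells.empty:
        raise ValueError("no subjects survive the minimum-correct screen")
    kept_subjects = cells["subject_id"].unique()
    filtered = filtered[filtered["subject_id"].isin(kept_subjects)]

    dp = dprime_cells(filtered)
    ez = ez_fit_cells(cells, min_n=min_cell_n)

    measures = dp[["subject_id", "cue_object", "d_prime"]].merge(
        ez[["subject_id", "cue_object", "v", "a", "ter", "low_n"]],
        on=["subject_id", "cue_object"],
    )
    # group statistics use only subjects with valid estimates in all cells
    bad_subj = measures.loc[
        measures["low_n"] | measures[["v", "a", "ter"]].isna().any(axis=1),
        "subject_id",
    ].unique()
    complete = measures[~measures["subject_id"].isin(bad_subj)]
    complete = _attach_validity(complete.drop(columns="low_n"))

    effect_rows = []
    mean_rows = []
    for measure in MEASURES:
        for res in rm_anova_2x2(complete, measure):
            effect_rows.append(
                {
                    "measure": measure,
                    "contrast": res.effect,
                    "kind": "rm_anova",
                    "F": res.F,
                    "t": np.nan,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "eta_g2": res.eta_g2,
                    "dz": np.nan,
                    "bf10": np.nan,
                }
            )
        wide = complete.pivot(
            index="subject_id", columns="cue_object", values=measure
        )[list(CUE_OBJECTS)]
        for factor, valid_cols, invalid_cols in (
            ("space", ["SvFv", "SvFi"], ["SiFv", "SiFi"]),
            ("feature", ["SvFv", "SiFv"], ["SvFi", "SiFi"]),
        ):
            tres = paired_t(
                wide[valid_cols].mean(axis=1), wide[invalid_cols].mean(axis=1)
            )
            effect_rows.append(
                {
                    "measure": measure,
                    "contrast": f"{factor}_valid_vs_invalid",
                    "kind": "paired_t",
                    "F": np.nan,
                    "t": tres.t,
                    "df1": 1,
                    "df2": tres.df,
                    "p": tres.p,
                    "eta_g2": np.nan,
                    "dz": tres.dz,
                    "bf10": tres.bf10,
                }
            )
        sems = within_subject_sem(wide)
        for cue in CUE_OBJECTS:
            mean_rows.append(
                {
                    "measure": measure,
                    "cue_object": cue,
                    "mean": wide[cue].mean(),
                    "within_sem": sems[cue],
                    "n_subjects": wide.shape[0],
                }
            )

    return {
        "exclusions": report,
        "cells": cells,
        "flags": flags,
        "dprime": dp,
        "ez": ez,
        "measures": complete,
        "effects": pd.DataFrame(effect_rows),
        "condition_means": pd.DataFrame(mean_rows),
    }


def titrated_accuracy(
    seed,
    *,
    n_trials: int = 5000,
    burn_in: int = 500,
    observer: ObserverParams | None = None,
    dt: float = 1e-3,
) -> float:
    """Post-burn-in mean accuracy of a DDM observer under the staircase.

    Runs a long titrated session (Experiment-1 cue mix; the default observer
    from :func:`cueddm.band_check_observer` is cue-neutral, spanning roughly
    57% accuracy at the gap floor to 95% at the ceiling), discards the first
    ``burn_in`` trials, and returns the mean pre-exclusion accuracy — the
    quantity the 60-70% titration band is meant to control.
    """
    from .observer import band_check_observer

    if observer is None:
        observer = band_check_observer()
    if n_trials % 50:
        raise ValueError("n_trials must be a multiple of 50 for an exact schedule")
    base = DesignSpec("E1", {"SvFv": 0.70, "SvFi": 0.10, "SiFv": 0.10, "SiFi": 0.10})
    design = DesignSpec(
        base.experiment_id,
        base.cue_object_probs,
        n_blocks=n_trials // 50,
        trials_per_block=50,
        practice_blocks=1,
        titration=base.titration,
    )
    log = simulate_session(design, observer, seed, dt=dt)
    post = log.iloc[burn_in:]
    return float((post["response"] == post["gap_side"]).mean())


def _true_cell_params(params: ObserverParams) -> pd.DataFrame:
    rows = []
    for cue in CUE_OBJECTS:
        sv, fv = CUE_VALIDITY[cue]
        rows.append(
            {
                "cue_object": cue,
                "v_true": params.v_base
                + sv * params.dv_space
                + fv * params.dv_feature,
                "a_true": params.a_by_object[cue],
                "ter_true": params.ter_by_object[cue],
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    design: DesignSpec,
    params: ObserverParams,
    n_subjects: int,
    master_seed: int,
    *,
    n_seeds: int = 1,
    fast_cutoff_s: float | None = 0.25,
    min_cell_n: int = 10,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Generating vs recovered (v, a, T_er) per cue object.

    Simulates ``n_seeds`` cohorts with the gap fixed at the observer's
    reference size (so the generating drift per cell is exact), runs the
    robust pipeline, and reports group-mean recovered values, bias, percent
    bias and across-seed RMSE per parameter and cell. A ``low_n`` column
    flags cells whose per-subject trial counts make single-subject estimates
    unstable (fewer than ~40 analyzed trials).
    """
    truth = _true_cell_params(params)
    ss = np.random.SeedSequence(master_seed)
    per_seed = []
    for rep_ss in ss.spawn(n_seeds):
        log = simulate_cohort(
            design, params, n_subjects, rep_ss, titrate=False, dt=dt
        )
        out = analyze_log(
            log, fast_cutoff_s=fast_cutoff_s, min_cell_n=min_cell_n
        )
        grp = (
            out["measures"]
            .groupby("cue_object")[["v", "a", "ter"]]
            .mean()
            .reindex(list(CUE_OBJECTS))
        )
        per_seed.append(grp)

    rows = []
    analyzed = design.analyzed_trials
    for cue in CUE_OBJECTS:
        n_cell = design.cue_object_probs[cue] * analyzed
        tr = truth[truth["cue_object"] == cue].iloc[0]
        for param in ("v", "a", "ter"):
            est = np.array([g.loc[cue, param] for g in per_seed])
            true_val = tr[f"{param}_true"]
            rows.append(
                {
                    "cue_object": cue,
                    "parameter": param,
                    "true": true_val,
                    "recovered_mean": est.mean(),
                    "bias": est.mean() - true_val,
                    "pct_bias": 100.0 * (est.mean() - true_val) / true_val,
                    "rmse": float(np.sqrt(np.mean((est - true_val) ** 2))),
                    "n_seeds": n_seeds,
                    "n_trials_per_cell": n_cell,
                    "low_n": n_cell < 40,
                }
            )
    return pd.DataFrame(rows)
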