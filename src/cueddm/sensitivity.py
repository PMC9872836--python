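"""2AFC sensitivity (d').

The task is a two-alternative forced choice on the gap side, and the pre-cue
carries no information about the correct response, so accuracy effects are
measured bias-free as d' = z(H) - z(F). "Gap on the right edge" is the
designated signal class (an arbitrary, documented choice: swapping classes
only flips the sign). Extreme rates are handled by the log-linear correction
(add 0.5 to every count, 1 to every denominator) by default; a 1/(2N)
replacement rule is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["DPrimeResult", "dprime_2afc", "dprime_cells"]


@dataclass(frozen=True)
class DPrimeResult:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float


def dprime_2afc(
    n_right_given_right: int,
    n_right_given_left: int,
    n_right_trials: int,
    n_left_trials: int,
    correction: str = "loglinear",
) -> DPrimeResult:
    """d' for a 2AFC cell from response counts.

    Parameters
    ----------
    n_right_given_right
        "Right" responses on gap-right (signal) trials — hits.
    n_right_given_left
        "Right" responses on gap-left (noise) trials — false alarms.
    n_right_trials, n_left_trials
        Trial counts per class (each >= 1).
    correction
        ``"loglinear"`` (default): add 0.5 to all four cells;
        ``"clamp"``: replace rates of 0 or 1 by 1/(2N) or 1 - 1/(2N);
        ``"none"``: no correction (rejects degenerate rates).
    """
    if n_right_trials < 1 or n_left_trials < 1:
        raise ValueError("each response class needs at least one trial")
    if not 0 <= n_right_given_right <= n_right_trials:
        raise ValueError("hit count outside [0, n_right_trials]")
    if not 0 <= n_right_given_left <= n_left_trials:
        raise ValueError("false-alarm count outside [0, n_left_trials]")

    if correction == "loglinear":
        hit = (n_right_given_right + 0.5) / (n_right_trials + 1)
        fa = (n_right_given_left + 0.5) / (n_left_trials + 1)
    elif correction == "clamp":
        hit = n_right_given_right / n_right_trials
        fa = n_right_given_left / n_left_trials
        hit = min(max(hit, 1 / (2 * n_right_trials)), 1 - 1 / (2 * n_right_trials))
        fa = min(max(fa, 1 / (2 * n_left_trials)), 1 - 1 / (2 * n_left_trials))
    elif correction == "none":
        hit = n_right_given_right / n_right_trials
        fa = n_right_given_left / n_left_trials
        if hit in (0.0, 1.0) or fa in (0.0, 1.0):
            raise ValueError(
                "rate of 0 or 1 gives an infinite quantile; choose a correction"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")

    d = float(norm.ppf(hit) - norm.ppf(fa))
    return DPrimeResult(hit_rate=float(hit), false_alarm_rate=float(fa), d_prime=d)


def dprime_cells(filtered: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """d' per subject x cue object from a filtered trial log.

    Signal trials are gap-right; a hit is a "right" response on a gap-right
    trial, a false alarm a "right" response on a gap-left trial.
    """
    rows = []
    for (subj, cue), grp in filtered.groupby(["subject_id", "cue_object"], sort=True):
        right_trials = grp[grp["gap_side"] == "right"]
        left_trials = grp[grp["gap_side"] == "left"]
        res = dprime_2afc(
            int((right_trials["response"] == "right").sum()),
            int((left_trials["response"] == "right").sum()),
            len(right_trials),
            len(left_trials),
            correction=correction,
        )
        rows.append(
            {
                "subject_id": subj,
                "cue_object": cue,
                "hit_rate": res.hit_rate,
                "false_alarm_rate": res.false_alarm_rate,
                "d_prime": res.d_prime,
            }
        )
    return pd.DataFrame(rows)
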