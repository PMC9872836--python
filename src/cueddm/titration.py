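"""Adaptive gap-size staircase.

Mean accuracy over the most recent evaluation window (all cue types pooled,
non-responses scored incorrect) drives multiplicative gap updates: accuracy
above the band shrinks the gap by the step fraction, below the band grows it,
clamped to the configured range. With the default constants (20% steps,
15-trial windows, 60-70% band, gap in [0.05, 0.5] degrees) an always-correct
observer is driven to the 0.05-degree floor and a chance observer to the
0.5-degree ceiling.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

from .design import TitrationSpec

__all__ = ["window_accuracy", "titration_step", "run_staircase"]


def window_accuracy(outcomes: Sequence) -> float:
    """Proportion correct in a trailing window; non-responses count as wrong.

    ``outcomes`` holds per-trial correctness, with ``None`` (no response)
    treated as incorrect.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("titration window is empty")
    return sum(1 for o in outcomes if o) / len(outcomes)


def titration_step(gap: float, outcomes: Sequence, spec: TitrationSpec) -> float:
    """One staircase update from the trailing-window outcomes.

    Accuracy > band_high shrinks the gap by ``step_fraction``; accuracy <
    band_low grows it; otherwise (band edges inclusive) the gap is unchanged.
    The result is clamped to ``[gap_min_deg, gap_max_deg]``.
    """
    acc = window_accuracy(outcomes)
    if acc > spec.band_high:
        return max(gap * (1.0 - spec.step_fraction), spec.gap_min_deg)
    if acc < spec.band_low:
        return min(gap * (1.0 + spec.step_fraction), spec.gap_max_deg)
    return gap


def run_staircase(
    spec: TitrationSpec,
    outcome_fn: Callable[[int, float], object],
    n_trials: int,
) -> list[float]:
    """Drive the staircase with a deterministic/callback observer.

    ``outcome_fn(trial_index, gap)`` returns the trial outcome (truthy =
    correct, ``None``/falsy = incorrect or no response). Returns the per-trial
    gap trajectory (gap in effect on each trial). Used for oracle-observer
    checks of the staircase asymptotes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    gap = spec.gap_init_deg
    trajectory: list[float] = []
    window: list[object] = []
    for i in range(n_trials):
        trajectory.append(gap)
        window.append(outcome_fn(i, gap))
        if len(window) == spec.window_trials:
            gap = titration_step(gap, window, spec)
            window = []
    return trajectory
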