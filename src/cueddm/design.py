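"""Experimental designs for the dual-cue visual-search task.

A single central pre-cue (a colored arrow) carries two components: a spatial
one (the pointing direction) and a feature one (the color). Each component is
independently valid or invalid on a given trial, yielding four *cue objects*
labeled ``SvFv``, ``SvFi``, ``SiFv``, ``SiFi`` (space-valid/invalid ×
feature-valid/invalid). The three experiments differ only in how probability
mass is distributed over the four cue objects:

========== ====== ====== ====== ======
experiment  SvFv   SvFi   SiFv   SiFi
========== ====== ====== ====== ======
E1          70%    10%    10%    10%
E2a         10%    40%    40%    10%
E2b         40%    10%    40%    10%
========== ====== ====== ====== ======

Every session has 7 blocks of 80 trials (560 total); the first block is
practice and is dropped before analysis. The target is a square frame with a
small gap on its left or right edge; observers report the gap side (2AFC)
within a 1500 ms response window. Gap size is titrated online to hold overall
accuracy in a 60-70% band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CUE_OBJECTS",
    "CUE_VALIDITY",
    "TitrationSpec",
    "DesignSpec",
    "EXPERIMENTS",
    "get_design",
]

#: Canonical cue-object order used throughout (tables, CSV output, plots).
CUE_OBJECTS: tuple[str, ...] = ("SvFv", "SvFi", "SiFv", "SiFi")

#: cue_object -> (space_valid, feature_valid)
CUE_VALIDITY: dict[str, tuple[bool, bool]] = {
    "SvFv": (True, True),
    "SvFi": (True, False),
    "SiFv": (False, True),
    "SiFi": (False, False),
}


@dataclass(frozen=True)
class TitrationSpec:
    """Constants of the adaptive gap-size staircase.

    Accuracy pooled over all cue types is evaluated every ``window_trials``
    trials; above ``band_high`` the gap shrinks by ``step_fraction``, below
    ``band_low`` it grows by the same fraction, clamped to
    ``[gap_min_deg, gap_max_deg]``. Accuracy exactly on a band edge leaves
    the gap unchanged.
    """

    gap_min_deg: float = 0.05
    gap_max_deg: float = 0.5
    gap_init_deg: float = 0.5
    step_fraction: float = 0.20
    window_trials: int = 15
    band_low: float = 0.60
    band_high: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.gap_min_deg < self.gap_max_deg:
            raise ValueError("need 0 < gap_min_deg < gap_max_deg")
        if not self.gap_min_deg <= self.gap_init_deg <= self.gap_max_deg:
            raise ValueError("gap_init_deg must lie in [gap_min_deg, gap_max_deg]")
        if not 0.0 < self.step_fraction < 1.0:
            raise ValueError("step_fraction must be in (0, 1)")
        if self.window_trials < 1:
            raise ValueError("window_trials must be >= 1")
        if not 0.0 <= self.band_low <= self.band_high <= 1.0:
            raise ValueError("need 0 <= band_low <= band_high <= 1")


@dataclass(frozen=True)
class DesignSpec:
    """One experiment's cue-object probabilities, block structure and timing."""

    experiment_id: str
    cue_object_probs: dict[str, float]
    n_blocks: int = 7
    trials_per_block: int = 80
    practice_blocks: int = 1
    delays_ms: tuple[int, ...] = (500, 1000, 1500)
    response_window_ms: float = 1500.0
    titration: TitrationSpec = field(default_factory=TitrationSpec)

    def __post_init__(self) -> None:
        if set(self.cue_object_probs) != set(CUE_OBJECTS):
            raise ValueError(f"cue_object_probs must have keys {CUE_OBJECTS}")
        if any(p < 0 for p in self.cue_object_probs.values()):
            raise ValueError("cue-object probabilities must be >= 0")
        if abs(sum(self.cue_object_probs.values()) - 1.0) > 1e-12:
            raise ValueError("cue-object probabilities must sum to 1")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("block structure must be positive")
        if not 0 <= self.practice_blocks < self.n_blocks:
            raise ValueError("practice_blocks must be in [0, n_blocks)")
        if self.response_window_ms <= 0:
            raise ValueError("response_window_ms must be > 0")

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def analyzed_trials(self) -> int:
        """Trials remaining after the practice blocks are dropped."""
        return (self.n_blocks - self.practice_blocks) * self.trials_per_block


EXPERIMENTS: dict[str, DesignSpec] = {
    "E1": DesignSpec(
        "E1", {"SvFv": 0.70, "SvFi": 0.10, "SiFv": 0.10, "SiFi": 0.10}
    ),
    "E2a": DesignSpec(
        "E2a", {"SvFv": 0.10, "SvFi": 0.40, "SiFv": 0.40, "SiFi": 0.10}
    ),
    "E2b": DesignSpec(
        "E2b", {"SvFv": 0.40, "SvFi": 0.10, "SiFv": 0.40, "SiFi": 0.10}
    ),
}


def get_design(experiment_id: str) -> DesignSpec:
    """Return the preset :class:`DesignSpec` for ``E1``, ``E2a`` or ``E2b``."""
    try:
        return EXPERIMENTS[experiment_id]
    except KeyError:
        raise KeyError(
            f"unknown experiment {experiment_id!r}; choose from {sorted(EXPERIMENTS)}"
        ) from None
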