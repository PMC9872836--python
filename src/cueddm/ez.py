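"""EZ-diffusion: closed-form forward equations and exact inversion.

The EZ-diffusion model maps three observables of a condition cell — response
accuracy Pc, mean correct RT (MRT) and variance of correct RT (VRT) — onto
three parameters of an unbiased two-boundary Wiener diffusion: drift rate v,
boundary separation a and non-decision time T_er. With noise scale s and
y = -v*a/s^2:

    Pc  = 1 / (1 + e^y)
    MDT = (a / 2v) * (1 - e^y) / (1 + e^y)            (mean decision time)
    MRT = MDT + T_er
    VRT = (a s^2 / 2 v^3) * (2 y e^y - e^{2y} + 1) / (e^y + 1)^2

and the inversion is closed-form: with L = logit(Pc),

    x   = L (L Pc^2 - L Pc + Pc - 1/2) / VRT
    v   = sign(Pc - 1/2) * s * x^{1/4}
    a   = s^2 L / v
    T_er = MRT - MDT(v, a).

At v -> 0 the analytic limits Pc -> 1/2, MDT -> a^2 / 4 s^2 and
VRT -> a^4 / 24 s^4 apply. Accuracies of exactly 0, 1/2 or 1 make the logit
degenerate and are edge-corrected using the cell's trial count n
(1/(2n) replacement), with a warning.

The "robust" flavor used by the pipeline removes contaminant trials (gaze
losses, non-responses, optionally responses faster than 250 ms) upstream,
before the inversion; see :mod:`cueddm.preprocess`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EZEstimates", "ez_forward", "ez_inverse", "ez_fit_cells"]

_SMALL_Y = 1e-5  # below this |v a / s^2| the closed forms are evaluated by series


@dataclass(frozen=True)
class EZEstimates:
    """Recovered parameters plus inversion diagnostics for one cell."""

    v: float
    a: float
    ter: float
    mdt: float  # mean decision time, MRT - ter
    L: float  # logit(Pc) after any edge correction
    y: float  # -v*a/s^2
    edge_corrected: bool = False


def _mdt(v, a, s):
    """Mean decision time (a/2v)*tanh(v a / 2 s^2); v=0 limit a^2/4s^2."""
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    w = v * a / (2.0 * s * s)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            np.abs(w) < _SMALL_Y,
            (a * a) / (4.0 * s * s) * (1.0 - w * w / 3.0),  # tanh series
            np.divide(a, 2.0 * v, out=np.zeros_like(a), where=v != 0) * np.tanh(w),
        )
    return out


def _vrt(v, a, s):
    """Variance of decision time; stable for either drift sign, v=0 limit a^4/24s^4."""
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    y = -v * a / (s * s)
    small = np.abs(y) < _SMALL_Y
    ysafe = np.where(small, 1.0, y)
    # evaluate with exponentials of -|y| only, to avoid overflow
    yneg = -np.abs(ysafe)
    e = np.exp(yneg)
    num = 2.0 * yneg * e - e * e + 1.0
    den = (e + 1.0) ** 2
    vsafe = np.where(small, 1.0, v)
    core = (a * s * s / (2.0 * np.abs(vsafe) ** 3)) * (num / den)
    limit = a**4 / (24.0 * s**4)
    return np.where(small, limit, core)


def ez_forward(v, a, ter, s: float = 0.1):
    """Closed-form (Pc, MRT, VRT) of the unbiased diffusion.

    Accepts scalars or broadcastable arrays; ``v = 0`` is handled by the
    analytic limit branch, not treated as an error.
    """
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    ter = np.asarray(ter, float)
    if np.any(a <= 0):
        raise ValueError("boundary separation a must be > 0")
    if s <= 0:
        raise ValueError("noise scale s must be > 0")
    y = -v * a / (s * s)
    with np.errstate(over="ignore"):
        pc = np.where(y > 0, np.exp(-y) / (1.0 + np.exp(-y)), 1.0 / (1.0 + np.exp(y)))
    mrt = _mdt(v, a, s) + ter
    vrt = _vrt(v, a, s)
    if pc.ndim == 0:
        return float(pc), float(mrt), float(vrt)
    return pc, mrt, vrt


def ez_inverse(
    pc: float,
    mrt: float,
    vrt: float,
    *,
    n: int | None = None,
    s: float = 0.1,
) -> EZEstimates:
    """Invert (Pc, MRT, VRT) to (v, a, T_er) in closed form.

    ``Pc`` of exactly 0, 1/2 or 1 is replaced using the cell trial count
    ``n`` — 1/(2n), 1/2 + 1/(2n) and 1 - 1/(2n) respectively — with a
    warning; ``n`` is required in that case. The round trip through
    :func:`ez_forward` is exact to double precision on the valid domain.
    """
    if not 0.0 <= pc <= 1.0:
        raise ValueError("Pc must be in [0, 1]")
    if vrt <= 0:
        raise ValueError("VRT must be > 0 for the inversion")
    if s <= 0:
        raise ValueError("noise scale s must be > 0")

    corrected = False
    if pc in (0.0, 0.5, 1.0):
        if n is None or n < 1:
            raise ValueError(
                f"Pc = {pc} needs an edge correction; supply the cell trial count n"
            )
        if pc == 1.0:
            pc = 1.0 - 1.0 / (2.0 * n)
        elif pc == 0.0:
            pc = 1.0 / (2.0 * n)
        else:
            pc = 0.5 + 1.0 / (2.0 * n)
        corrected = True
        warnings.warn(
            f"degenerate accuracy edge-corrected to Pc = {pc:.6g} (n = {n})",
            stacklevel=2,
        )

    L = float(np.log(pc / (1.0 - pc)))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = s * s * L / v
    mdt = float(_mdt(v, a, s))
    ter = mrt - mdt
    return EZEstimates(
        v=v, a=float(a), ter=float(ter), mdt=mdt, L=L, y=-v * a / (s * s),
        edge_corrected=corrected,
    )


def ez_fit_cells(
    cells: pd.DataFrame,
    *,
    min_n: int = 10,
    s: float = 0.1,
) -> pd.DataFrame:
    """Run the EZ inversion on a table of condition cells.

    Cells below ``min_n`` total trials are kept in the output but flagged
    ``low_n`` with NaN estimates (they are excluded from group statistics).
    Edge-corrected cells are flagged ``edge_corrected``.
    """
    rows = []
    for _, cell in cells.iterrows():
        rec = {
            "subject_id": cell["subject_id"],
            "cue_object": cell["cue_object"],
            "n": int(cell["n_total"]),
            "v": np.nan,
            "a": np.nan,
            "ter": np.nan,
            "mdt": np.nan,
            "low_n": False,
            "edge_corrected": False,
        }
        if cell["n_total"] < min_n or not np.isfinite(cell["VRT"]) or cell["VRT"] <= 0:
            rec["low_n"] = True
        else:
            est = ez_inverse(
                float(cell["Pc"]),
                float(cell["MRT"]),
                float(cell["VRT"]),
                n=int(cell["n_total"]),
                s=s,
            )
            rec.update(
                v=est.v, a=est.a, ter=est.ter, mdt=est.mdt,
                edge_corrected=est.edge_corrected,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
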