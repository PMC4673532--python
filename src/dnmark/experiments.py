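"""Canonical sweep experiments: the small-noise / big-noise contrast.

This module freezes the study protocol used throughout the tests and docs:
a quasi-static sweep of the fold model from p = -6 to p = 6 (121 values,
one time unit of dwell per value at dt = 0.01, the last ten states of each
dwell recorded), run at a small (sigma = 0.1) and a big (sigma = 1.0)
noise amplitude. Per replicate the protocol

1. detects the state jump and truncates to the pre-transition segment
   (only data before the transition are assumed observable),
2. evaluates the classical CSD trend criterion on the raw series,
3. embeds the segment (window 10, step 1) into the (u, v) moment series
   and evaluates the same criterion there,
4. runs the DNM detector on the embedded series and records whether a
   warning fires -- which, on pre-transition data, necessarily precedes
   the jump.

With small noise the raw criterion succeeds; with big noise it becomes
unreliable while the embedded criterion and the DNM warning keep working.
The network counterpart sweeps the 18-node model towards its fold at P=0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import dnm, indicators
from .embedding import SlidingWindowSpec, sliding_window_moments
from .simulate import (ParameterSchedule, Trajectory, derive_seed, fold_model,
                       network_model, sweep)

log = logging.getLogger(__name__)

__all__ = [
    "SIGMA_SMALL",
    "SIGMA_BIG",
    "fold_sweep",
    "network_sweep",
    "detect_jump",
    "fold_contrast_replicate",
    "fold_contrast_study",
]

#: default noise amplitudes of the two study regimes
SIGMA_SMALL = 0.1
SIGMA_BIG = 1.0


def lower_branch_state(p: float) -> float:
    """The stable lower equilibrium of the fold skeleton at parameter p."""
    return brentq(lambda x: p + 3 * x - x ** 3, -4.0, -1.0)


def fold_sweep(sigma: float, seed, p_min: float = -6.0, p_max: float = 6.0,
               n_values: int = 121, dwell_time: float = 1.0,
               samples_per_value: int = 10, dt: float = 0.01) -> Trajectory:
    """Quasi-static sweep of the fold model (the packaged fixture protocol)."""
    sched = ParameterSchedule(
        values=np.linspace(p_min, p_max, n_values),
        samples_per_value=samples_per_value,
        dwell_time=dwell_time,
    )
    x0 = lower_branch_state(p_min)
    return sweep(fold_model(sigma), sched, x0=[x0], dt=dt, seed=seed)


def network_sweep(sigma: float = 0.2, seed=None, p_min: float = -1.0,
                  p_max: float = 0.2, n_values: int = 61,
                  dwell_time: float = 1.0, samples_per_value: int = 10,
                  dt: float = 0.01) -> Trajectory:
    """Quasi-static sweep of the 18-node network towards its fold at P = 0."""
    model = network_model(sigma)
    sched = ParameterSchedule(
        values=np.linspace(p_min, p_max, n_values),
        samples_per_value=samples_per_value,
        dwell_time=dwell_time,
    )
    # settle the deterministic skeleton at p_min for a clean start
    from .simulate import euler_maruyama

    settle = euler_maruyama(
        network_model(0.0), np.zeros(model.n_vars),
        np.arange(0.0, 20.0, dt), p=p_min, seed=0,
    )
    return sweep(model, sched, x0=settle.states[-1], dt=dt, seed=seed)


def detect_jump(X, threshold: float = 1.0, confirm: int = 20) -> int | None:
    """Index of the state transition in a fold-sweep trajectory.

    The jump is the first sample above ``threshold`` whose following
    ``confirm`` samples average above it too (so single noise excursions
    do not count). None if the series never commits to the upper branch.
    """
    x = X.states[:, 0] if hasattr(X, "states") else np.asarray(X, float).ravel()
    for i in np.flatnonzero(x > threshold):
        if x[i: i + confirm].mean() > threshold:
            return int(i)
    return None


@dataclass
class ContrastReplicate:
    raw_csd: bool
    embedded_csd: bool
    dnm_warning: bool
    jump_index: int
    p_jump: float


def fold_contrast_replicate(sigma: float, seed, window: int = 10,
                            epsilon: float = 1e-3) -> ContrastReplicate | None:
    """One replicate of the contrast protocol (see module docstring).

    Returns None when the trajectory jumps too early to leave a usable
    pre-transition segment (fewer than six windows) or never jumps.
    """
    traj = fold_sweep(sigma, seed)
    j = detect_jump(traj)
    if j is None or j < 6 * window:
        log.info("seed %r: unusable replicate (jump index %r)", seed, j)
        return None
    pre = traj.states[:j, :]
    spec = SlidingWindowSpec(length=window, step=1)

    raw_track = indicators.windowed_indicators(pre, spec)
    moments = sliding_window_moments(pre, spec)
    emb_track = indicators.windowed_indicators(moments, spec)
    det = dnm.dominant_group_track(moments, spec, epsilon=epsilon)
    return ContrastReplicate(
        raw_csd=indicators.csd_criterion(raw_track),
        embedded_csd=indicators.csd_criterion(emb_track),
        dnm_warning=det.warning_index is not None,
        jump_index=j,
        p_jump=float(traj.parameter_track[j]),
    )


def fold_contrast_study(sigma: float, seeds, window: int = 10) -> dict:
    """Replicate rates of the contrast protocol over the given seeds."""
    reps = [fold_contrast_replicate(sigma, s, window=window) for s in seeds]
    reps = [r for r in reps if r is not None]
    n = len(reps)
    if n == 0:
        raise RuntimeError("no usable replicates")
    return {
        "n": n,
        "raw_csd_rate": sum(r.raw_csd for r in reps) / n,
        "embedded_csd_rate": sum(r.embedded_csd for r in reps) / n,
        "dnm_warning_rate": sum(r.dnm_warning for r in reps) / n,
        "mean_p_jump": float(np.mean([r.p_jump for r in reps])),
    }
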