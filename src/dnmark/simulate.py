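"""Stochastic differential equation simulators.

Fixed-step Euler--Maruyama integration of additive-noise SDEs

    dx = f(x, p) dt + L dW,      L L^T = noise covariance,

plus the two model systems used throughout the package: the one-dimensional
fold (saddle-node) normal form and an 18-node regulatory-network stand-in.
Quasi-static parameter sweeps and seeded Monte-Carlo ensembles provide the
fixtures and the sampling oracle for the moment-equation machinery in
:mod:`dnmark.embedding`.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "SDEModel",
    "ParameterSchedule",
    "Trajectory",
    "ExplosionError",
    "euler_maruyama",
    "sweep",
    "ensemble",
    "ensemble_moments",
    "fold_model",
    "network_model",
    "NETWORK_CORE_NODES",
    "seed_sequence",
    "derive_seed",
]

_SYM_TOL = 1e-10


class ExplosionError(RuntimeError):
    """Raised when a trajectory leaves the finite range during integration."""


def seed_sequence(seed) -> np.random.SeedSequence:
    """Normalize ``seed`` to a :class:`numpy.random.SeedSequence`.

    Integers are wrapped as ``SeedSequence([seed])``; sub-streams are derived
    by appending indices to the entropy list (see :func:`derive_seed`), so a
    replicate's stream is reproducible from ``(seed, replicate)`` alone.
    """
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (int, np.integer)):
        return np.random.SeedSequence([int(seed)])
    if isinstance(seed, (tuple, list)):
        return np.random.SeedSequence([int(s) for s in seed])
    raise TypeError(f"seed must be an int, sequence of ints or SeedSequence, got {seed!r}")


def derive_seed(seed, *indices: int) -> np.random.SeedSequence:
    """Counter-based sub-seed: entropy ``[seed, *indices]``."""
    if isinstance(seed, np.random.SeedSequence):
        ent = list(np.atleast_1d(seed.entropy)) + [int(i) for i in indices]
        return np.random.SeedSequence(ent)
    base = [int(seed)] if isinstance(seed, (int, np.integer)) else [int(s) for s in seed]
    return np.random.SeedSequence(base + [int(i) for i in indices])


@dataclass
class SDEModel:
    """An additive-noise SDE ``dx = drift(x, p) dt + L dW``.

    Parameters
    ----------
    drift
        Callable ``(x, p) -> dx/dt`` mapping an ``(n,)`` state and a scalar
        control parameter to an ``(n,)`` vector.
    noise_cov
        Symmetric positive-semidefinite ``(n, n)`` noise covariance, in units
        of state**2 / time.
    n_vars
        State dimension ``n``.
    name
        Free-form label.
    """

    drift: Callable[[np.ndarray, float], np.ndarray]
    noise_cov: np.ndarray
    n_vars: int
    name: str = ""

    def __post_init__(self):
        self.noise_cov = np.atleast_2d(np.asarray(self.noise_cov, dtype=float))
        n = int(self.n_vars)
        if n < 1:
            raise ValueError("n_vars must be >= 1")
        self.n_vars = n
        if self.noise_cov.shape != (n, n):
            raise ValueError(
                f"noise_cov has shape {self.noise_cov.shape}, expected ({n}, {n})"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=_SYM_TOL):
            raise ValueError("noise_cov must be symmetric")
        w, V = np.linalg.eigh(self.noise_cov)
        if w.min(initial=0.0) < -_SYM_TOL * max(1.0, w.max(initial=0.0)):
            raise ValueError(f"noise_cov is not positive semidefinite (min eig {w.min():g})")
        # PSD square root; exact Cholesky is unusable for the common singular cases
        self._noise_factor = V * np.sqrt(np.clip(w, 0.0, None))

    @property
    def is_deterministic(self) -> bool:
        return bool(np.all(self.noise_cov == 0.0))


@dataclass
class ParameterSchedule:
    """A quasi-static sweep of the control parameter.

    The simulator dwells ``dwell_time`` time units at each value in
    ``values`` and records the final ``samples_per_value`` states of each
    dwell, emulating slow parameter drift with a burn-in at every level.
    """

    values: np.ndarray
    samples_per_value: int = 10
    dwell_time: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        d = np.diff(self.values)
        if self.values.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("values must be strictly monotone")
        if self.samples_per_value < 1:
            raise ValueError("samples_per_value must be >= 1")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")


@dataclass
class Trajectory:
    """A recorded path: ``states[k]`` is the state at ``times[k]``."""

    times: np.ndarray
    states: np.ndarray
    parameter_track: np.ndarray
    seed: object = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states disagree in length")
        self.parameter_track = np.broadcast_to(
            np.asarray(self.parameter_track, dtype=float), self.times.shape
        ).copy()
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]


def _parameter_values(p, times: np.ndarray) -> np.ndarray:
    if callable(p):
        return np.asarray([float(p(t)) for t in times])
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        return np.full(times.shape, float(p))
    if p.shape != times.shape:
        raise ValueError("parameter track must match the time grid")
    return p


def _check_finite(states: np.ndarray, times: np.ndarray, what: str = "state"):
    bad = ~np.isfinite(states).all(axis=1)
    if bad.any():
        k = int(np.argmax(bad))
        raise ExplosionError(
            f"non-finite {what} at step {k} (t = {times[k]:g}); "
            "the trajectory exploded -- reduce dt or the noise amplitude"
        )


def euler_maruyama(model: SDEModel, x0, times, p=0.0, seed=None) -> Trajectory:
    """Integrate ``model`` over the grid ``times`` with Euler--Maruyama.

    ``p`` may be a scalar, an array aligned with ``times`` or a callable of
    time. The first recorded state is ``x0``; step ``k`` uses the parameter
    value at ``times[k]``. Identical inputs (including ``seed``) produce a
    bitwise-identical trajectory.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must contain at least two points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (model.n_vars,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({model.n_vars},)")
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    p_track = _parameter_values(p, times)
    dt = np.diff(times)

    rng = np.random.default_rng(seed_sequence(seed))
    T, n = times.size, model.n_vars
    # pre-scaled noise increments: L sqrt(dt) z
    z = rng.standard_normal((T - 1, n))
    incr = (z @ model._noise_factor.T) * np.sqrt(dt)[:, None]

    states = np.empty((T, n))
    states[0] = x0
    x = x0
    drift = model.drift
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(T - 1):
            x = x + np.asarray(drift(x, p_track[k])) * dt[k] + incr[k]
            states[k + 1] = x
    _check_finite(states, times)
    return Trajectory(times=times, states=states, parameter_track=p_track, seed=seed)


def sweep(model: SDEModel, schedule: ParameterSchedule, x0, dt: float = 0.01,
          seed=None) -> Trajectory:
    """Quasi-static parameter sweep.

    At each schedule value the system is integrated for ``dwell_time`` and
    the last ``samples_per_value`` states (spaced ``dt``) are recorded; the
    final state seeds the next dwell, so the path is continuous in state.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (model.n_vars,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({model.n_vars},)")
    n_dwell = max(1, round(schedule.dwell_time / dt))
    spv = min(schedule.samples_per_value, n_dwell)
    if spv < schedule.samples_per_value:
        log.warning("samples_per_value truncated to dwell length (%d)", n_dwell)

    rng = np.random.default_rng(seed_sequence(seed))
    n = model.n_vars
    sqdt = np.sqrt(dt)
    drift = model.drift
    rec_states, rec_times, rec_p = [], [], []
    x = x0
    t = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for p in schedule.values:
            z = rng.standard_normal((n_dwell, n))
            incr = (z @ model._noise_factor.T) * sqdt
            for k in range(n_dwell):
                x = x + np.asarray(drift(x, p)) * dt + incr[k]
                t += dt
                if k >= n_dwell - spv:
                    rec_states.append(x)
                    rec_times.append(t)
                    rec_p.append(p)
            if not np.isfinite(x).all():
                raise ExplosionError(
                    f"non-finite state during dwell at p = {p:g} (t = {t:g})"
                )
    return Trajectory(
        times=np.asarray(rec_times),
        states=np.asarray(rec_states),
        parameter_track=np.asarray(rec_p),
        seed=seed,
    )


def ensemble(model: SDEModel, x0, times, p=0.0, n_reps: int = 1, seed=None) -> list[Trajectory]:
    """``n_reps`` independent trajectories; replicate ``r`` uses the
    sub-seed ``derive_seed(seed, r)``, so any single replicate can be
    reproduced in isolation."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    out = []
    for r in range(n_reps):
        try:
            out.append(euler_maruyama(model, x0, times, p=p, seed=derive_seed(seed, r)))
        except ExplosionError as err:
            raise ExplosionError(f"replicate {r}: {err}") from err
    return out


def ensemble_moments(trajectories: Sequence[Trajectory]):
    """Cross-replicate sample mean and covariance at every time point.

    Returns ``(times, U, V)`` with ``U`` of shape ``(T, n)`` and ``V`` of
    shape ``(T, n, n)`` (unbiased, ``ddof=1``). The Monte-Carlo oracle for
    :func:`dnmark.embedding.propagate_moments`.
    """
    times = trajectories[0].times
    X = np.stack([tr.states for tr in trajectories])  # (R, T, n)
    R = X.shape[0]
    U = X.mean(axis=0)
    C = X - U
    V = np.einsum("rti,rtj->tij", C, C) / max(R - 1, 1)
    return times, U, V


# ---------------------------------------------------------------------------
# model zoo


def fold_model(sigma: float) -> SDEModel:
    """The fold (saddle-node) normal form ``dx/dt = p + 3x - x^3 + noise``.

    The deterministic skeleton has saddle-node bifurcations at ``p = -2``
    (upper branch) and ``p = +2`` (lower branch): sweeping p from -6 to 6
    carries the state along the lower branch until it jumps near, or --
    under strong noise -- well before, ``p = 2``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    def drift(x, p):
        return p + 3.0 * x - x ** 3

    return SDEModel(drift=drift, noise_cov=[[sigma ** 2]], n_vars=1, name="fold")


#: indices of the mutually activating core whose equilibrium disappears at P=0
NETWORK_CORE_NODES = (0, 1, 2)


def _load_network_params() -> dict:
    ref = importlib.resources.files("dnmark") / "data" / "network18.yaml"
    return yaml.safe_load(ref.read_text())


def network_model(sigma: float) -> SDEModel:
    """An 18-node regulatory-style network with a fold at ``P = 0``.

    Three mutually activating core genes (Hill activation, linear decay)
    share a saddle-node: their low-expression equilibrium disappears as the
    control parameter P reaches 0, while fifteen downstream genes follow
    stably (triangular Jacobian). Topology and kinetic constants live in the
    packaged ``data/network18.yaml``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    prm = _load_network_params()
    n = int(prm["n_vars"])
    c0 = float(prm["core"]["offset"])
    beta = float(prm["core"]["beta"])
    parents = np.asarray(prm["downstream"]["parents"], dtype=int)
    alpha = np.asarray(prm["downstream"]["alpha"], dtype=float)
    basal = np.asarray(prm["downstream"]["basal"], dtype=float)
    repress = np.asarray(prm["downstream"]["repress"], dtype=bool)
    core = list(NETWORK_CORE_NODES)

    def hill(y):
        return y * y / (1.0 + y * y)

    def drift(x, P):
        dx = np.empty_like(x)
        xc = x[core]
        # shared activation by the core mean: the rank-one coupling keeps all
        # off-symmetric modes at decay rate 1, so only the collective mode
        # softens at the fold
        m = xc.mean()
        dx[core] = P + c0 + beta * hill(m) - xc
        xp = x[parents]
        h = hill(xp)
        act = np.where(repress, 1.0 / (1.0 + xp * xp), h)
        dx[3:] = basal + alpha * act - x[3:]
        return dx

    return SDEModel(drift=drift, noise_cov=(sigma ** 2) * np.eye(n), n_vars=n,
                    name="network18")
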