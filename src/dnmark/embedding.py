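"""Distribution embedding: from state series to moment series.

The central trick of the package: a noisy n-dimensional state series is
mapped through sliding windows to the time series of its first moments
u_i (means) and second central moments v_ij (covariances), i.e. into an
N = n(n+3)/2 dimensional description of the evolving state *distribution*.
Because window statistics average the fluctuations away, the embedded
series carries far less noise than the raw one, and classical
critical-slowing-down indicators become informative again.

The module also provides the deterministic moment differential equations
used to validate the embedding: the exact affine moment system of a linear
SDE (du/dt = A u + b, dV/dt = A V + V A^T + D) and the one-dimensional
Gaussian (second-order) closure of a nonlinear drift, together with an
equilibrium continuation that locates the fold of the moment system -- the
bifurcation that, under strong noise, precedes the fold of the state
equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.integrate import solve_ivp
from scipy.optimize import approx_fprime, root
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = [
    "moment_dimension",
    "MomentIndexMap",
    "SlidingWindowSpec",
    "MomentSeries",
    "MomentEmbedder",
    "sliding_window_moments",
    "noise_reduction_ratio",
    "LinearModel",
    "MomentField",
    "linear_moment_field",
    "gaussian_closure_field_1d",
    "propagate_moments",
    "moment_bifurcation_scan",
    "BifurcationScan",
]


def moment_dimension(n: int) -> int:
    """Number of moment variables of a second-order embedding: n(n+3)/2.

    That is n means plus n(n+1)/2 distinct (co)variances; e.g. 2 for n=1,
    77 for n=11 and 189 for n=18.
    """
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    n = int(n)
    return n * (n + 3) // 2


class MomentIndexMap:
    """Bijection between (i, j) moment labels and packed column positions.

    Packing order is fixed across versions: first the n means ``u_1..u_n``,
    then the upper triangle of the covariance row-major:
    ``v_1_1, v_1_2, .., v_1_n, v_2_2, .., v_n_n`` (indices 1-based in names,
    0-based in code).
    """

    def __init__(self, n: int):
        if int(n) != n or n < 1:
            raise ValueError("n must be a positive integer")
        self.n = int(n)
        self.pairs = [(i, j) for i in range(self.n) for j in range(i, self.n)]
        self._col = {pair: k for k, pair in enumerate(self.pairs)}

    @property
    def n_second(self) -> int:
        return len(self.pairs)

    @property
    def size(self) -> int:
        """Total packed dimension N = n(n+3)/2."""
        return self.n + self.n_second

    def column_of(self, i: int, j: int) -> int:
        """Packed column (within the v block) of central moment v_ij."""
        return self._col[(min(i, j), max(i, j))]

    def names(self) -> list[str]:
        u = [f"u_{i + 1}" for i in range(self.n)]
        v = [f"v_{i + 1}_{j + 1}" for i, j in self.pairs]
        return u + v

    def pack(self, V: np.ndarray) -> np.ndarray:
        """Upper triangle of a symmetric ``(.., n, n)`` matrix, packed."""
        V = np.asarray(V)
        iu, ju = zip(*self.pairs)
        return V[..., list(iu), list(ju)]

    def unpack(self, v: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`pack` (returns the full symmetric matrix)."""
        v = np.asarray(v)
        V = np.zeros(v.shape[:-1] + (self.n, self.n), dtype=v.dtype)
        for k, (i, j) in enumerate(self.pairs):
            V[..., i, j] = v[..., k]
            V[..., j, i] = v[..., k]
        return V


@dataclass
class SlidingWindowSpec:
    """Window geometry: ``length`` consecutive samples, advancing by ``step``.

    ``label_position`` chooses the representative time of a window; the
    default ``right`` stamps a window with its latest sample so that
    anything derived from it is causal.
    """

    length: int = 10
    step: int = 1
    label_position: str = "right"

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if self.step < 1:
            raise ValueError("window step must be >= 1")
        if self.label_position not in ("left", "center", "right"):
            raise ValueError("label_position must be 'left', 'center' or 'right'")

    def label_offset(self) -> int:
        return {"left": 0, "center": self.length // 2, "right": self.length - 1}[
            self.label_position
        ]


@dataclass
class MomentSeries:
    """The embedded series: windowed means and central second moments."""

    window_labels: np.ndarray
    first_moments: np.ndarray           # (W, n)
    second_central_moments: np.ndarray  # (W, n(n+1)/2), packed upper triangle
    n_vars: int
    index_map: MomentIndexMap = None

    def __post_init__(self):
        self.window_labels = np.asarray(self.window_labels, dtype=float)
        self.first_moments = np.atleast_2d(np.asarray(self.first_moments, dtype=float))
        self.second_central_moments = np.atleast_2d(
            np.asarray(self.second_central_moments, dtype=float)
        )
        if self.index_map is None:
            self.index_map = MomentIndexMap(self.n_vars)
        n, m = self.n_vars, self.index_map.n_second
        W = self.window_labels.shape[0]
        if self.first_moments.shape != (W, n):
            raise ValueError("first_moments shape mismatch")
        if self.second_central_moments.shape != (W, m):
            raise ValueError("second_central_moments shape mismatch")

    @property
    def n_moments(self) -> int:
        return self.index_map.size

    @property
    def packed(self) -> np.ndarray:
        """(W, N) array: means then packed covariances."""
        return np.hstack([self.first_moments, self.second_central_moments])

    @property
    def columns(self) -> list[str]:
        return self.index_map.names()

    def covariance_matrices(self) -> np.ndarray:
        """(W, n, n) reconstructed covariance matrices."""
        return self.index_map.unpack(self.second_central_moments)

    def validate(self, tol: float = 1e-8):
        """Check the invariants: non-negative variances, PSD 2x2 minors."""
        V = self.covariance_matrices()
        d = np.diagonal(V, axis1=1, axis2=2)
        scale = max(1.0, float(np.nanmax(np.abs(d), initial=1.0)))
        if np.any(d < -tol * scale):
            raise ValueError("negative variance in moment series")
        off = V ** 2
        outer = d[:, :, None] * d[:, None, :]
        if np.any(off > outer + tol * scale ** 2):
            raise ValueError("a 2x2 covariance minor is negative (|v_ij| too large)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.packed, columns=self.columns)
        df.insert(0, "time", self.window_labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MomentSeries":
        u_cols = [c for c in df.columns if c.startswith("u_")]
        v_cols = [c for c in df.columns if c.startswith("v_")]
        n = len(u_cols)
        imap = MomentIndexMap(n)
        if [*u_cols, *v_cols] != imap.names():
            raise ValueError("columns do not follow the packed moment layout")
        return cls(
            window_labels=df["time"].to_numpy(),
            first_moments=df[u_cols].to_numpy(),
            second_central_moments=df[v_cols].to_numpy(),
            n_vars=n,
            index_map=imap,
        )


def _series_values(X) -> tuple[np.ndarray, np.ndarray]:
    """Duck-typed view of a series: (times, values with shape (T, ..) )."""
    if hasattr(X, "states"):           # simulate.Trajectory
        return np.asarray(X.times, float), np.asarray(X.states, float)
    if hasattr(X, "packed"):           # MomentSeries
        return np.asarray(X.window_labels, float), X.packed
    if hasattr(X, "values") and hasattr(X, "times"):  # io.TimeSeriesMatrix
        return np.asarray(X.times, float), np.asarray(X.values, float)
    V = np.asarray(X, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    return np.arange(V.shape[0], dtype=float), V


class MomentEmbedder(TransformerMixin, BaseEstimator):
    """Sliding-window moment transformer (scikit-learn style).

    Maps a ``(T, n)`` state series to the ``(W, n(n+3)/2)`` packed series of
    windowed means and unbiased (co)variances. If the input carries a
    replicate axis ``(T, S, n)``, each window pools the ``length * S``
    samples it spans (replicate moments aggregated over the window); with a
    single trajectory the within-window time samples act as the ergodic
    surrogate. Both cases run through the same pooled-sample code path.

    Parameters
    ----------
    window : int, default 10
        Samples per window.
    step : int, default 1
        Advance between consecutive windows (1 = maximally overlapping).
    label_position : {'left', 'center', 'right'}, default 'right'
        Which sample time stamps a window ('right' keeps labels causal).
    """

    def __init__(self, window: int = 10, step: int = 1, label_position: str = "right"):
        self.window = window
        self.step = step
        self.label_position = label_position

    def _spec(self) -> SlidingWindowSpec:
        return SlidingWindowSpec(self.window, self.step, self.label_position)

    def fit(self, X, y=None):
        _, V = _series_values(X)
        self._spec()  # validates the parameters
        self.n_features_in_ = V.shape[-1]
        self.index_map_ = MomentIndexMap(self.n_features_in_)
        self.n_moments_ = self.index_map_.size
        return self

    def transform(self, X) -> np.ndarray:
        return self.embed(X).packed

    def embed(self, X) -> MomentSeries:
        """Full embedding with window labels (richer than ``transform``)."""
        spec = self._spec()
        times, V = _series_values(X)
        if V.ndim == 2:
            V = V[:, None, :]          # (T, 1, n): a single trajectory
        T, S, n = V.shape
        if T < spec.length:
            raise ValueError(
                f"series of length {T} is shorter than the window ({spec.length})"
            )
        if not np.isfinite(V).all():
            raise ValueError("series contains non-finite values")
        W = sliding_window_view(V, spec.length, axis=0)[:: spec.step]
        # (W, S, n, L) -> pooled samples (W, L*S, n)
        W = np.moveaxis(W, -1, 1).reshape(W.shape[0], spec.length * S, n)
        m = W.shape[1]
        u = W.mean(axis=1)
        C = W - u[:, None, :]
        cov = np.einsum("wli,wlj->wij", C, C) / (m - 1)
        imap = MomentIndexMap(n)
        starts = np.arange(0, T - spec.length + 1, spec.step)
        labels = times[starts + spec.label_offset()]
        self.n_features_in_ = n
        self.index_map_ = imap
        self.n_moments_ = imap.size
        return MomentSeries(
            window_labels=labels,
            first_moments=u,
            second_central_moments=imap.pack(cov),
            n_vars=n,
            index_map=imap,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.index_map_.names(), dtype=object)


def sliding_window_moments(X, spec: SlidingWindowSpec | None = None) -> MomentSeries:
    """Functional form of :class:`MomentEmbedder` (see its docstring)."""
    spec = spec or SlidingWindowSpec()
    emb = MomentEmbedder(spec.length, spec.step, spec.label_position)
    return emb.fit(X).embed(X)


def _detrend_ma(y: np.ndarray, span: int) -> np.ndarray:
    """Residual about a centered moving average of ``span`` samples.

    Only the region where the full-span average exists is returned, so edge
    effects never leak into the residual.
    """
    span = max(2, int(span))
    if y.shape[0] < span:
        raise ValueError("series shorter than the detrending span")
    trend = np.convolve(y, np.ones(span), mode="valid") / span
    lo = (span - 1) // 2
    return y[lo: lo + trend.shape[0]] - trend


def noise_reduction_ratio(X, spec: SlidingWindowSpec | None = None) -> np.ndarray:
    """Per-variable SD(windowed means) / SD(raw series), after detrending.

    Both series are detrended with a centered moving average whose span is
    the window length, so the slow sweep-induced drift does not masquerade
    as fluctuation. For i.i.d. noise and non-overlapping windows the ratio
    approaches 1/sqrt(length). Variables with zero raw SD yield NaN and a
    logged warning.
    """
    spec = spec or SlidingWindowSpec()
    _, V = _series_values(X)
    if V.ndim == 3:
        V = V.reshape(V.shape[0], -1)
    ms = sliding_window_moments(X, spec)
    if ms.first_moments.shape[0] < spec.length + 1:
        raise ValueError("too few windows to detrend the embedded series")
    out = np.empty(V.shape[1])
    for i in range(V.shape[1]):
        sd_raw = _detrend_ma(V[:, i], spec.length).std(ddof=1)
        if sd_raw == 0.0:
            log.warning("variable %d has zero fluctuation; ratio undefined", i)
            out[i] = np.nan
            continue
        out[i] = _detrend_ma(ms.first_moments[:, i], spec.length).std(ddof=1) / sd_raw
    return out


# ---------------------------------------------------------------------------
# analytic moment dynamics


@dataclass
class LinearModel:
    """Affine SDE ``dx = (A x + b) dt + noise`` with noise covariance D."""

    A: np.ndarray
    b: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        self.b = np.broadcast_to(np.asarray(self.b, dtype=float), (n,)).copy()
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if self.D.shape != (n, n):
            raise ValueError("D must match A in shape")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if np.linalg.eigvalsh(self.D).min() < -1e-10:
            raise ValueError("D must be positive semidefinite")

    @property
    def n_vars(self) -> int:
        return self.A.shape[0]


@dataclass
class MomentField:
    """A deterministic vector field on the packed moment vector z = (u, v)."""

    n_vars: int
    fun: Callable[[np.ndarray], np.ndarray]
    index_map: MomentIndexMap = None

    def __post_init__(self):
        if self.index_map is None:
            self.index_map = MomentIndexMap(self.n_vars)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.fun(np.asarray(z, dtype=float))

    @property
    def size(self) -> int:
        return self.index_map.size


def linear_moment_field(model: LinearModel) -> MomentField:
    """Exact moment dynamics of an affine SDE.

    du/dt = A u + b and dV/dt = A V + V A^T + D, returned over the packed
    N = n(n+3)/2 vector. For linear drift the second-order truncation is
    exact -- there is no closure error.
    """
    n = model.n_vars
    imap = MomentIndexMap(n)
    A, b, D = model.A, model.b, model.D

    def fun(z):
        if z.shape[-1] != imap.size:
            raise ValueError(f"packed moment vector must have length {imap.size}")
        u = z[:n]
        V = imap.unpack(z[n:])
        du = A @ u + b
        dV = A @ V + V @ A.T + D
        return np.concatenate([du, imap.pack(dV)])

    return MomentField(n_vars=n, fun=fun, index_map=imap)


def gaussian_closure_field_1d(f, sigma: float, fprime=None, fsecond=None) -> MomentField:
    """Second-order Gaussian closure of a scalar SDE ``dx = f(x) dt + sigma dW``.

    Taylor-expanding the drift about the mean and setting the third central
    moment to zero gives

        du/dt = f(u) + (1/2) f''(u) v,
        dv/dt = 2 f'(u) v + sigma**2.

    Derivatives default to central differences when not supplied. The
    variance is floored at zero inside the field (with a logged warning) so
    an integrator cannot run it negative.
    """
    h = 1e-5

    def fp(u):
        if fprime is not None:
            return fprime(u)
        return (f(u + h) - f(u - h)) / (2 * h)

    def fpp(u):
        if fsecond is not None:
            return fsecond(u)
        return (f(u + h) - 2 * f(u) + f(u - h)) / h ** 2

    warned = [False]

    def fun(z):
        u, v = z[0], z[1]
        if v < 0:
            if not warned[0]:
                log.warning("variance clipped at 0 during closure evaluation")
                warned[0] = True
            v = 0.0
        du = f(u) + 0.5 * fpp(u) * v
        dv = 2.0 * fp(u) * v + sigma ** 2
        return np.array([du, dv])

    return MomentField(n_vars=1, fun=fun)


def propagate_moments(field: MomentField, z0, times) -> np.ndarray:
    """Integrate the moment ODEs over ``times`` (adaptive Runge--Kutta).

    Returns the (T, N) packed moment trajectory; diagonal variance entries
    are clipped at zero on output. Raises on integrator failure, naming the
    last time reached.
    """
    times = np.asarray(times, dtype=float)
    z0 = np.asarray(z0, dtype=float)
    if z0.shape != (field.size,):
        raise ValueError(f"z0 must have packed dimension {field.size}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    sol = solve_ivp(
        lambda t, z: field(z),
        (times[0], times[-1]),
        z0,
        t_eval=times,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else times[0]
        raise RuntimeError(f"moment integration failed after t = {last:g}: {sol.message}")
    Z = sol.y.T
    n = field.n_vars
    diag_cols = [n + field.index_map.column_of(i, i) for i in range(n)]
    neg = Z[:, diag_cols] < 0
    if neg.any():
        log.warning("clipped %d negative variance values to 0", int(neg.sum()))
        Z[:, diag_cols] = np.clip(Z[:, diag_cols], 0.0, None)
    return Z


@dataclass
class BifurcationScan:
    """Continuation result: the equilibrium branch and where it ends."""

    p_branch: np.ndarray
    z_branch: np.ndarray
    stable: np.ndarray
    p_fold: float | None

    @property
    def has_fold(self) -> bool:
        return self.p_fold is not None


def moment_bifurcation_scan(field_factory, p_grid, z0, jump_tol: float = 0.5,
                            ) -> BifurcationScan:
    """Continue an equilibrium of ``field_factory(p)`` along ``p_grid``.

    At each parameter value the root of the moment field is tracked from
    the previous solution (Powell hybrid). The branch ends -- and
    ``p_fold`` is reported as the last continuable parameter -- when the
    root finder stops converging or the solution jumps by more than
    ``jump_tol`` (in the packed norm), which is how a fold manifests in a
    naive continuation. Stability is the sign of the leading Jacobian
    eigenvalue (finite differences).
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.ndim != 1 or p_grid.size < 2:
        raise ValueError("p_grid must be a 1-D grid")
    if np.any(np.diff(p_grid) == 0) or not (
        np.all(np.diff(p_grid) > 0) or np.all(np.diff(p_grid) < 0)
    ):
        raise ValueError("p_grid must be monotone")

    z0 = np.asarray(z0, dtype=float)
    zs, ps, stab = [], [], []
    z_prev = z0
    fold_p = None
    for k, p in enumerate(p_grid):
        fld = field_factory(p)
        sol = root(lambda z: fld(z), z_prev, method="hybr", tol=1e-10)
        ok = sol.success and np.linalg.norm(fld(sol.x)) < 1e-6
        if ok and zs:
            ok = np.linalg.norm(sol.x - z_prev) <= jump_tol
        if not ok:
            if not zs:
                raise RuntimeError(
                    f"no equilibrium found at the first parameter value p = {p:g}"
                )
            fold_p = ps[-1]
            break
        J = np.empty((z0.size, z0.size))
        for i in range(z0.size):
            J[i, :] = approx_fprime(sol.x, lambda z, i=i: fld(z)[i], 1e-7)
        stab.append(bool(np.max(np.linalg.eigvals(J).real) < 0))
        zs.append(sol.x)
        ps.append(p)
        z_prev = sol.x
    return BifurcationScan(
        p_branch=np.asarray(ps),
        z_branch=np.asarray(zs),
        stable=np.asarray(stab, dtype=bool),
        p_fold=fold_p,
    )
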