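"""Critical-slowing-down indicators over sliding windows.

Standard deviation, lag-1 autocorrelation and skewness per window and per
variable, with Kendall-tau trends against time, applicable both to raw
state series and to embedded moment series. Also the signal-to-noise
comparison that quantifies how much quieter the embedded series is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .embedding import SlidingWindowSpec, _detrend_ma, _series_values

log = logging.getLogger(__name__)

__all__ = [
    "IndicatorTrack",
    "SlidingIndicators",
    "windowed_indicators",
    "trend_tau",
    "csd_criterion",
    "snr",
]


@dataclass
class IndicatorTrack:
    """Per-window indicator trajectories and their time trends.

    ``sd``, ``ar1`` and ``skewness`` are (W, k) arrays (NaN where a window
    had zero variance); ``trend_tau`` is a DataFrame indexed by variable
    with one Kendall-tau column per indicator.
    """

    window_labels: np.ndarray
    sd: np.ndarray
    ar1: np.ndarray
    skewness: np.ndarray
    trend_tau: pd.DataFrame
    names: list[str]

    def to_frame(self) -> pd.DataFrame:
        parts = {"time": self.window_labels}
        for ind, arr in (("sd", self.sd), ("ar1", self.ar1), ("skew", self.skewness)):
            for j, nm in enumerate(self.names):
                parts[f"{ind}:{nm}"] = arr[:, j]
        return pd.DataFrame(parts)


def trend_tau(labels: np.ndarray, values: np.ndarray) -> float:
    """Kendall rank correlation of an indicator trajectory against time.

    NaN windows are dropped, never interpolated.
    """
    m = np.isfinite(values)
    if m.sum() < 2:
        return np.nan
    return stats.kendalltau(np.asarray(labels)[m], np.asarray(values)[m]).statistic


class SlidingIndicators(TransformerMixin, BaseEstimator):
    """Windowed CSD indicator transformer (scikit-learn style).

    ``transform`` returns the (W, 3k) array ``[sd | ar1 | skew]``; the
    richer :meth:`track` keeps labels and trend statistics. Within each
    window: unbiased SD; lag-1 Pearson autocorrelation between the window's
    leading and trailing sub-series; adjusted Fisher--Pearson skewness.
    Windows with zero variance yield NaN ar1/skewness and are logged.
    """

    def __init__(self, window: int = 10, step: int = 1, label_position: str = "right"):
        self.window = window
        self.step = step
        self.label_position = label_position

    def fit(self, X, y=None):
        _, V = _series_values(X)
        self.n_features_in_ = V.shape[-1]
        return self

    def transform(self, X) -> np.ndarray:
        tr = self.track(X)
        return np.hstack([tr.sd, tr.ar1, tr.skewness])

    def track(self, X) -> IndicatorTrack:
        spec = SlidingWindowSpec(self.window, self.step, self.label_position)
        if spec.length < 3:
            raise ValueError("indicator windows need at least 3 samples")
        times, V = _series_values(X)
        if V.ndim == 3:
            V = V.reshape(V.shape[0], -1)
        T, k = V.shape
        if T < spec.length:
            raise ValueError("series shorter than the indicator window")
        names = getattr(X, "columns", None) or getattr(X, "names", None)
        if names is None or len(names) != k:
            names = [f"x{j + 1}" for j in range(k)]
        W = sliding_window_view(V, spec.length, axis=0)[:: spec.step]  # (W, k, L)
        sd = W.std(axis=-1, ddof=1)
        a = W[..., :-1]
        b = W[..., 1:]
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        den = np.sqrt((a * a).sum(-1) * (b * b).sum(-1))
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ar1 = np.where(den > 0, (a * b).sum(-1) / den, np.nan)
            skew = stats.skew(W, axis=-1, bias=False)
        ar1 = np.clip(ar1, -1.0, 1.0)
        dead = sd == 0
        if dead.any():
            log.warning("%d windows with zero variance; indicators set to NaN",
                        int(dead.sum()))
            ar1[dead] = np.nan
            skew[dead] = np.nan
        starts = np.arange(0, T - spec.length + 1, spec.step)
        labels = times[starts + spec.label_offset()]
        tau = pd.DataFrame(
            {
                "sd": [trend_tau(labels, sd[:, j]) for j in range(k)],
                "ar1": [trend_tau(labels, ar1[:, j]) for j in range(k)],
                "skewness": [trend_tau(labels, skew[:, j]) for j in range(k)],
            },
            index=list(names),
        )
        return IndicatorTrack(
            window_labels=labels, sd=sd, ar1=ar1, skewness=skew,
            trend_tau=tau, names=list(names),
        )


def windowed_indicators(X, spec: SlidingWindowSpec | None = None) -> IndicatorTrack:
    """Functional form of :class:`SlidingIndicators` (see its docstring)."""
    spec = spec or SlidingWindowSpec()
    return SlidingIndicators(spec.length, spec.step, spec.label_position).fit(X).track(X)


def csd_criterion(track: IndicatorTrack) -> bool:
    """Does the series show the classical pre-transition trend signature?

    True when at least one variable has strictly positive Kendall trends in
    both SD and lag-1 autocorrelation. For a single-variable series this is
    simply "SD and AR trends are positive"; for a multivariate (e.g.
    embedded) series any signaling variable counts, in the same spirit in
    which the network marker looks for a signaling subgroup.
    """
    tau = track.trend_tau
    return bool(((tau["sd"] > 0) & (tau["ar1"] > 0)).any())


def _series_snr(y: np.ndarray, span: int) -> float:
    """Trend power / residual power about a centered moving average."""
    if y.shape[0] < span:
        raise ValueError("series shorter than the SNR smoothing span")
    trend = np.convolve(y, np.ones(span), mode="valid") / span
    lo = (span - 1) // 2
    resid = y[lo: lo + trend.shape[0]] - trend
    p_trend = float(np.mean((trend - trend.mean()) ** 2))
    p_resid = float(np.mean(resid ** 2))
    if p_resid == 0.0:
        log.warning("zero residual power; SNR is infinite")
        return np.inf
    return p_trend / p_resid


def snr(X_raw, X_embedded, spec: SlidingWindowSpec | None = None) -> dict:
    """Signal-to-noise comparison between a raw and an embedded series.

    Per series, SNR = power of a centered moving-average trend (span
    ``2 * window + 1``) over the power of the residual about it. Returns
    per-variable values, the aggregate (median) for each representation and
    their ratio; a ratio above 1 means the embedding raised the SNR.
    """
    spec = spec or SlidingWindowSpec()
    span = 2 * spec.length + 1
    _, R = _series_values(X_raw)
    if R.ndim == 3:
        R = R.reshape(R.shape[0], -1)
    _, E = _series_values(X_embedded)
    raw = np.array([_series_snr(R[:, j], span) for j in range(R.shape[1])])
    emb = np.array([_series_snr(E[:, j], span) for j in range(E.shape[1])])
    agg_raw = float(np.median(raw))
    agg_emb = float(np.median(emb))
    return {
        "raw": raw,
        "embedded": emb,
        "aggregate_raw": agg_raw,
        "aggregate_embedded": agg_emb,
        "ratio": agg_emb / agg_raw if agg_raw > 0 else np.inf,
    }
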