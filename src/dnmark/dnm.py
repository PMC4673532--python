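"""The dynamical network marker (DNM).

Near a critical transition a dominant group of variables emerges whose
members (1) fluctuate ever more strongly, (2) correlate ever more tightly
with each other and (3) decouple from the rest of the system. The
composite score

    I = SD_d * PCC_in / (PCC_out + eps)

(mean member SD times mean within-group |Pearson r|, over the mean
group-to-outside |r| plus a small eps guarding against zero division)
therefore rises sharply as the transition approaches. This module finds
candidate groups from the correlation structure (average-linkage
dendrogram cuts), tracks the best-scoring group window by window, and
turns the score trajectory into a warning time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .embedding import SlidingWindowSpec, _series_values

log = logging.getLogger(__name__)

__all__ = [
    "DNMResult",
    "DNMScore",
    "pcc_matrix",
    "dnm_score",
    "candidate_groups",
    "DNMDetector",
    "dominant_group_track",
    "detect_warning",
    "three_conditions_check",
]


def pcc_matrix(window_data: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation matrix of a (samples, variables) window.

    Zero-variance variables keep their row/column (indices stay stable) but
    their off-diagonal correlations are set to 0 and a warning is logged;
    the diagonal is always 1.
    """
    X = np.atleast_2d(np.asarray(window_data, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    bad = ~np.isfinite(C)
    if bad.any():
        log.warning("zero-variance variables in window; correlations set to 0")
        C[bad] = 0.0
    C = np.abs(C)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, 0.0, 1.0)


@dataclass
class DNMScore:
    I: float
    sd_d: float
    pcc_in: float
    pcc_out: float


def dnm_score(members: Sequence[int], window_data: np.ndarray,
              epsilon: float = 1e-3, corr: np.ndarray | None = None) -> DNMScore:
    """Score a candidate group on one window of data.

    SD_d is the mean unbiased SD over member variables, PCC_in the mean
    absolute Pearson correlation over member pairs, PCC_out the mean over
    (member, non-member) pairs -- zero when the group is the whole system,
    in which case the three conditions still apply. ``corr`` may carry a
    precomputed :func:`pcc_matrix` for speed.
    """
    X = np.atleast_2d(np.asarray(window_data, dtype=float))
    k = X.shape[1]
    members = sorted(set(int(m) for m in members))
    if len(members) < 2:
        raise ValueError("a dominant group needs at least 2 members")
    if members[0] < 0 or members[-1] >= k:
        raise ValueError("member index out of range")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if corr is None:
        corr = pcc_matrix(X)
    outsiders = [j for j in range(k) if j not in members]
    sd_d = float(X[:, members].std(axis=0, ddof=1).mean())
    sub = corr[np.ix_(members, members)]
    iu = np.triu_indices(len(members), 1)
    pcc_in = float(sub[iu].mean())
    pcc_out = float(corr[np.ix_(members, outsiders)].mean()) if outsiders else 0.0
    return DNMScore(I=sd_d * pcc_in / (pcc_out + epsilon),
                    sd_d=sd_d, pcc_in=pcc_in, pcc_out=pcc_out)


def candidate_groups(corr: np.ndarray, min_size: int = 2) -> list[tuple[int, ...]]:
    """Candidate dominant groups from the correlation structure.

    Average-linkage hierarchical clustering on the distance ``1 - |r|``;
    the candidates are every cluster of size >= ``min_size`` appearing at
    any cut height of the dendrogram, deduplicated, plus always the
    all-variables set. Deterministic: sorted by size then lexicographically.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if k < min_size:
        raise ValueError(f"need at least {min_size} variables, got {k}")
    dist = 1.0 - np.clip((corr + corr.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    found: set[tuple[int, ...]] = {tuple(range(k))}
    for h in np.unique(Z[:, 2]):
        labels = fcluster(Z, t=h, criterion="distance")
        for lab in np.unique(labels):
            grp = tuple(int(i) for i in np.flatnonzero(labels == lab))
            if len(grp) >= min_size:
                found.add(grp)
    return sorted(found, key=lambda g: (len(g), g))


def detect_warning(score_track: np.ndarray, baseline_fraction: float = 0.25,
                   z_threshold: float = 2.0) -> int | None:
    """First window whose score exceeds the early-baseline excursion level.

    The baseline is the earliest ``baseline_fraction`` of windows; the
    warning fires at the first later window with
    ``I > mean + z_threshold * SD`` of the baseline. A flat baseline
    (SD = 0) falls back to the ratio rule ``I > 2 * mean``; a track that
    never exceeds it yields None (logged).
    """
    I = np.asarray(score_track, dtype=float)
    W = I.shape[0]
    if W < 5:
        raise ValueError("need at least 5 windows to detect a warning")
    if not 0.0 < baseline_fraction < 1.0:
        raise ValueError("baseline_fraction must be in (0, 1)")
    nb = max(2, int(round(baseline_fraction * W)))
    base = I[:nb]
    base = base[np.isfinite(base)]
    if base.size < 2:
        log.warning("baseline windows all undefined; no warning")
        return None
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    thresh = mu + z_threshold * sd if sd > 0 else 2.0 * mu
    if sd == 0 and mu == 0:
        log.warning("flat zero baseline; no warning possible")
        return None
    later = I[nb:]
    hits = np.flatnonzero(np.isfinite(later) & (later > thresh))
    if hits.size == 0:
        log.info("score never exceeded the baseline threshold; no warning")
        return None
    return int(nb + hits[0])


class DNMDetector(BaseEstimator):
    """Sliding-window dominant-group tracker (scikit-learn style).

    ``fit`` slides windows over a (moment or state) series and, per window,
    clusters the |Pearson| correlation matrix, scores every candidate group
    and keeps the maximizer (ties resolved toward the smaller, then
    lexicographically earlier group). Fitted attributes:

    - ``score_track_``, ``sd_d_track_``, ``pcc_in_track_``, ``pcc_out_track_``
    - ``members_`` -- maximizing group at the peak-score window
    - ``group_track_`` -- per-window maximizing group
    - ``peak_index_`` / ``peak_time_`` and ``warning_index_`` / ``warning_time_``

    Windows where every variable is constant produce NaN scores; if all
    windows are degenerate, ``fit`` raises.
    """

    def __init__(self, window: int = 10, step: int = 1, label_position: str = "right",
                 epsilon: float = 1e-3, min_size: int = 2,
                 baseline_fraction: float = 0.25, z_threshold: float = 2.0):
        self.window = window
        self.step = step
        self.label_position = label_position
        self.epsilon = epsilon
        self.min_size = min_size
        self.baseline_fraction = baseline_fraction
        self.z_threshold = z_threshold

    def fit(self, X, y=None):
        spec = SlidingWindowSpec(self.window, self.step, self.label_position)
        if spec.length < 3:
            raise ValueError("DNM windows need at least 3 samples")
        times, V = _series_values(X)
        if V.ndim == 3:
            V = V.reshape(V.shape[0], -1)
        T, k = V.shape
        if T < spec.length + spec.step:
            raise ValueError("need enough samples for at least 2 windows")
        starts = np.arange(0, T - spec.length + 1, spec.step)
        labels = times[starts + spec.label_offset()]
        W = starts.size

        score = np.full(W, np.nan)
        sd_d = np.full(W, np.nan)
        p_in = np.full(W, np.nan)
        p_out = np.full(W, np.nan)
        groups: list[tuple[int, ...] | None] = [None] * W
        for w, s in enumerate(starts):
            data = V[s: s + spec.length]
            if np.all(data.std(axis=0) == 0):
                continue
            corr = pcc_matrix(data)
            best = None
            for grp in candidate_groups(corr, self.min_size):
                sc = dnm_score(grp, data, self.epsilon, corr=corr)
                if best is None or sc.I > best[0].I:
                    best = (sc, grp)
            score[w] = best[0].I
            sd_d[w] = best[0].sd_d
            p_in[w] = best[0].pcc_in
            p_out[w] = best[0].pcc_out
            groups[w] = best[1]
        if not np.isfinite(score).any():
            raise RuntimeError("all windows degenerate; no DNM score defined")

        self.window_labels_ = labels
        self.score_track_ = score
        self.sd_d_track_ = sd_d
        self.pcc_in_track_ = p_in
        self.pcc_out_track_ = p_out
        self.group_track_ = groups
        self.peak_index_ = int(np.nanargmax(score))
        self.peak_time_ = float(labels[self.peak_index_])
        self.members_ = groups[self.peak_index_]
        self.n_features_in_ = k
        # ranked alternatives at the peak window (multiple DNMs may coexist;
        # only the maximizer is reported as members_)
        s = starts[self.peak_index_]
        data = V[s: s + spec.length]
        corr = pcc_matrix(data)
        ranked = sorted(
            ((dnm_score(g, data, self.epsilon, corr=corr).I, g)
             for g in candidate_groups(corr, self.min_size)),
            key=lambda t: (-t[0], len(t[1]), t[1]),
        )
        self.runner_ups_ = [(g, I) for I, g in ranked[1:6]]
        if W >= 5:
            wi = detect_warning(score, self.baseline_fraction, self.z_threshold)
        else:
            wi = None
        self.warning_index_ = wi
        self.warning_time_ = float(labels[wi]) if wi is not None else None
        return self

    def result(self) -> "DNMResult":
        return DNMResult(
            members=self.members_,
            window_labels=self.window_labels_,
            score_track=self.score_track_,
            sd_d_track=self.sd_d_track_,
            pcc_in_track=self.pcc_in_track_,
            pcc_out_track=self.pcc_out_track_,
            epsilon=self.epsilon,
            warning_index=self.warning_index_,
            warning_time=self.warning_time_,
            peak_index=self.peak_index_,
            peak_time=self.peak_time_,
        )


@dataclass
class DNMResult:
    """Dominant group, score trajectory and detection times."""

    members: tuple[int, ...]
    window_labels: np.ndarray
    score_track: np.ndarray
    sd_d_track: np.ndarray
    pcc_in_track: np.ndarray
    pcc_out_track: np.ndarray
    epsilon: float
    warning_index: int | None
    warning_time: float | None
    peak_index: int
    peak_time: float

    def tracks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.window_labels,
                "score": self.score_track,
                "sd_d": self.sd_d_track,
                "pcc_in": self.pcc_in_track,
                "pcc_out": self.pcc_out_track,
            }
        )

    def summary(self) -> dict:
        return {
            "members": [int(m) for m in self.members],
            "epsilon": self.epsilon,
            "warning_index": self.warning_index,
            "warning_time": self.warning_time,
            "peak_index": self.peak_index,
            "peak_time": self.peak_time,
            "n_windows": int(self.score_track.shape[0]),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def dominant_group_track(M, spec: SlidingWindowSpec | None = None,
                         epsilon: float = 1e-3, min_size: int = 2,
                         baseline_fraction: float = 0.25,
                         z_threshold: float = 2.0) -> DNMResult:
    """Functional form of :class:`DNMDetector` (see its docstring)."""
    spec = spec or SlidingWindowSpec()
    det = DNMDetector(
        window=spec.length, step=spec.step, label_position=spec.label_position,
        epsilon=epsilon, min_size=min_size,
        baseline_fraction=baseline_fraction, z_threshold=z_threshold,
    )
    return det.fit(M).result()


def three_conditions_check(members: Sequence[int], early_windows: np.ndarray,
                           late_windows: np.ndarray) -> tuple[bool, bool, bool]:
    """Test the three dominant-group conditions between two data segments.

    Given (samples, variables) arrays for an early and a late segment,
    returns whether, from early to late, (1) the mean member SD increased,
    (2) PCC_in increased and (3) PCC_out decreased -- all strictly.
    """
    early = np.atleast_2d(np.asarray(early_windows, dtype=float))
    late = np.atleast_2d(np.asarray(late_windows, dtype=float))
    if early.size == 0 or late.size == 0:
        raise ValueError("both window sets must be non-empty")
    # epsilon is irrelevant here; reuse the score computation for the parts
    s_early = dnm_score(members, early)
    s_late = dnm_score(members, late)

    def gt(a, b):  # strictly greater, ignoring float rounding noise
        return a > b and not np.isclose(a, b, rtol=1e-10, atol=1e-12)

    return (
        gt(s_late.sd_d, s_early.sd_d),
        gt(s_late.pcc_in, s_early.pcc_in),
        gt(s_early.pcc_out, s_late.pcc_out),
    )
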