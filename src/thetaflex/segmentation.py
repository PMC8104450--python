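"""Boundary derivation from population spiking and Victor-Purpura scoring.

The segmentation pipeline turns the spiking of 16 unconnected model copies
(driven by 16 auditory channels) into candidate syllable boundaries via a
sum-and-threshold "postsynaptic" trace, then scores the boundaries against
transcription-derived syllable midpoints with a normalized Victor-Purpura
point-process distance D_VP,tau: the minimal edit cost where moving a
boundary by delta < tau costs delta/tau and moving it further, inserting, or
deleting costs 1, log-normalized by the number of sub-unit-cost (matched)
moves.  Negative D means every model boundary matched a distinct midpoint
within tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .synthetic_speech import PHONEME_CLASSES, Transcription

REFRACTORY_BOUNDARY = 25.0   # ms between retained boundaries
GAUSS_SIGMA = 25.0 / 4.0     # ms, smoothing of the postsynaptic trace
DEFAULT_TAU = 50.0           # ms, Victor-Purpura timescale

W_S_GRID = tuple(range(25, 76, 5))                       # 11 values
R_THRESH_GRID = (1.0 / 3.0, 0.4, 0.45, 0.5, 0.55, 0.6, 2.0 / 3.0)


@dataclass
class BoundarySet:
    """Model-derived segmental boundaries (ms, strictly increasing)."""

    times: np.ndarray
    w_s: float
    r_thresh: float
    threshold: float
    refractory: float = REFRACTORY_BOUNDARY


class DegenerateBaselineError(ValueError):
    """Postsynaptic trace is identically zero over the baseline window."""


def postsynaptic_trace(spike_trains, duration: float, w_s: float,
                       dt: float = 1.0, sigma: float = GAUSS_SIGMA) -> tuple:
    """Sum-and-threshold drive to a putative downstream boundary detector.

    Each train is convolved with a causal exponential kernel of decay time
    w_s / 5 ms, summed over cells, and smoothed with a unit-area Gaussian
    (sigma = 25/4 ms).  Returns (t, P) sampled at ``dt`` ms.
    """
    n = int(round(duration / dt)) + 1
    counts = np.zeros(n)
    for train in spike_trains:
        train = np.asarray(train, dtype=float)
        idx = np.round(train / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    decay = w_s / 5.0
    n_kernel = int(10.0 * decay / dt) + 1
    kernel = np.exp(-np.arange(n_kernel) * dt / decay)
    P = np.convolve(counts, kernel)[:n]
    P = gaussian_filter1d(P, sigma / dt, mode="constant")
    t = np.arange(n) * dt
    return t, P


def derive_boundaries(t: np.ndarray, P: np.ndarray, r_thresh: float,
                      w_s: float = math.nan,
                      baseline_window: tuple = (0.0, 1000.0),
                      refractory: float = REFRACTORY_BOUNDARY) -> BoundarySet:
    """Threshold crossings of P(t) as candidate boundaries.

    The threshold is r_thresh times the maximum of P over the pre-stimulus
    baseline window; candidates are upward crossings, and any candidate
    following the previously *retained* boundary by less than the 25 ms
    refractory period is removed.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    lo, hi = baseline_window
    base = P[(t >= lo) & (t <= hi)]
    if base.size == 0 or base.max() <= 0.0:
        raise DegenerateBaselineError(
            "baseline window has no positive postsynaptic activity; "
            "threshold undefined")
    p_star = r_thresh * base.max()
    above = P >= p_star
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    retained = []
    for i in idx:
        if not retained or t[i] - retained[-1] >= refractory:
            retained.append(t[i])
    return BoundarySet(times=np.asarray(retained), w_s=w_s,
                       r_thresh=r_thresh, threshold=p_star,
                       refractory=refractory)


def syllable_midpoints(boundaries) -> np.ndarray:
    """Midpoints of successive boundary pairs: t_i = (t*_i + t*_{i+1}) / 2."""
    b = np.asarray(boundaries, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 boundaries to form midpoints")
    return 0.5 * (b[:-1] + b[1:])


# -- Victor-Purpura boundary distance ---------------------------------------

@dataclass
class SegmentationScore:
    """Victor-Purpura edit distance between boundary sets.

    ``matches`` counts sub-unit-cost shift moves on an optimal path (ties
    broken toward more matches).  ``D`` = log(d / matches); -inf flags an exact
    coincidence (d = 0), +inf flags an optimal path with no matches.
    """

    d: float
    matches: int
    D: float
    tau: float
    n_m: int
    n_t: int

    @property
    def finite(self) -> bool:
        return math.isfinite(self.D)


def vp_distance(m, t, tau: float = DEFAULT_TAU) -> SegmentationScore:
    """Minimal-cost alignment of boundary sets ``m`` and ``t``.

    Dynamic program over order-preserving alignments; shifting a boundary by
    |delta| costs |delta|/tau, insertion and deletion cost 1 each (so a far
    shift is never cheaper than deleting and re-inserting, which caps its
    effective cost at 2).  In the tau -> inf limit d -> |n_m - n_t|; in the
    tau -> 0 limit d -> n_m + n_t.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    m = np.sort(np.asarray(getattr(m, "times", m), dtype=float))
    t = np.sort(np.asarray(t, dtype=float))
    nm, nt = m.size, t.size
    EPS = 1e-12
    # cost[i][j], match[i][j]: best (min cost, max matches) aligning m[:i], t[:j]
    cost = np.empty((nm + 1, nt + 1))
    match = np.zeros((nm + 1, nt + 1), dtype=int)
    cost[:, 0] = np.arange(nm + 1)
    cost[0, :] = np.arange(nt + 1)
    for i in range(1, nm + 1):
        for j in range(1, nt + 1):
            shift = abs(m[i - 1] - t[j - 1]) / tau
            cands = (
                (cost[i - 1, j] + 1.0, match[i - 1, j]),
                (cost[i, j - 1] + 1.0, match[i, j - 1]),
                (cost[i - 1, j - 1] + shift,
                 match[i - 1, j - 1] + (1 if shift < 1.0 else 0)),
            )
            best = min(c for c, _ in cands)
            cost[i, j] = best
            match[i, j] = max(mm for c, mm in cands if c <= best + EPS)
    d = float(cost[nm, nt])
    n_match = int(match[nm, nt])
    if d <= EPS:
        D = -math.inf
    elif n_match == 0:
        D = math.inf
    else:
        D = math.log(d / n_match)
    return SegmentationScore(d=d, matches=n_match, D=D, tau=tau,
                             n_m=nm, n_t=nt)


# -- parameter optimization -------------------------------------------------

def optimize_parameters(sentence_runs, w_s_grid=W_S_GRID,
                        r_thresh_grid=R_THRESH_GRID, tau: float = DEFAULT_TAU,
                        dt: float = 1.0,
                        baseline_window: tuple = (0.0, 1000.0)):
    """Exhaustive grid search for the (w_s, r_thresh) minimizing mean D.

    ``sentence_runs`` is a list of dicts with keys ``spike_trains`` (list of
    16 spike-time arrays), ``duration`` (ms), ``midpoints`` (ground-truth
    syllable midpoints), and optionally ``group`` (e.g. a gain or sub-band
    label).  The objective is the minimum over groups of the mean finite
    D_VP,tau, as in the segmentation protocol.  Returns (w_s*, r_thresh*,
    surface DataFrame).
    """
    rows = []
    for w_s in w_s_grid:
        # postsynaptic traces depend on w_s only; reuse across r_thresh
        traces = []
        for run in sentence_runs:
            t, P = postsynaptic_trace(run["spike_trains"], run["duration"],
                                      w_s, dt=dt)
            traces.append((t, P, run))
        for r_thresh in r_thresh_grid:
            per_group: dict = {}
            for t, P, run in traces:
                try:
                    bset = derive_boundaries(t, P, r_thresh, w_s=w_s,
                                             baseline_window=baseline_window)
                except DegenerateBaselineError:
                    continue
                score = vp_distance(bset.times, run["midpoints"], tau)
                per_group.setdefault(run.get("group", 0), []).append(score)
            means = []
            for grp, scores in per_group.items():
                finite = [s.D for s in scores if s.finite]
                perfect = [s for s in scores if s.D == -math.inf]
                if finite:
                    means.append(float(np.mean(finite)))
                elif perfect:
                    means.append(-math.inf)
            if means:
                rows.append(dict(w_s=w_s, r_thresh=r_thresh,
                                 score=min(means), n_groups=len(means)))
    if not rows:
        raise ValueError("no grid cell produced a finite score")
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["score"].idxmin()]
    return float(best["w_s"]), float(best["r_thresh"]), surface


def phoneme_distribution(boundaries, transcription: Transcription) -> pd.Series:
    """Proportion of boundaries falling in each of the 7 phoneme classes."""
    times = np.asarray(getattr(boundaries, "times", boundaries), dtype=float)
    counts = {cls: 0 for cls in PHONEME_CLASSES}
    for b in times:
        counts[transcription.phoneme_class_at(b)] += 1
    total = max(sum(counts.values()), 1)
    return pd.Series({cls: counts[cls] / total for cls in PHONEME_CLASSES})
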