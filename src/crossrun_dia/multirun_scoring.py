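"""Consensus multi-run peak picking and weight-decayed score aggregation.

Aligned single-run scoring profiles are averaged into a cross-run
profile whose signal-to-noise ratio grows with the number of runs
because independent noise cancels while the shared peak reinforces.
The top candidate peak groups are picked once on the averaged profile
and applied to every run (consensus picking), so peak selection is
uniform across the dataset.

Each candidate's multi-run score in a target run is a normalized
weighted combination of the aligned single-run scores of all runs,
with weights given by the global run similarity passed through the
exponential weight-decay function

    phi(w) = (k**w - 1) / (k - 1),

which leaves weights near 1 almost untouched while crushing small
weights toward 0, so distant runs cannot inflate a peak's evidence.
``k`` is the weight-decay coefficient (k = 0 disables decay; k -> 1 is
the identity limit). The decay coefficient can be chosen automatically
from the elbow of the identification-count-versus-k curve on a
downsampled library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema

from crossrun_dia.alignment import SynchronizedPeptide

__all__ = [
    "CrossRunProfile",
    "PeakCandidate",
    "average_profiles",
    "snr",
    "pick_peaks",
    "weight_decay",
    "multirun_score",
    "find_elbow",
    "auto_select_k",
]


@dataclass
class CrossRunProfile:
    """Averaged main-score profile over the aligned per-run stack."""

    precursor_id: str
    grid_rt: np.ndarray
    averaged_main: np.ndarray
    n_runs_averaged: np.ndarray  # per grid point

    @classmethod
    def from_synchronized(cls, sync: SynchronizedPeptide) -> "CrossRunProfile":
        return average_profiles(sync)


def average_profiles(sync: SynchronizedPeptide) -> CrossRunProfile:
    """Element-wise mean of the aligned main-score profiles over non-NaN runs."""
    stack = sync.profiles["main_score"]
    available = ~np.all(np.isnan(stack), axis=1)
    if not available.any():
        raise ValueError(f"all runs are NaN for {sync.precursor_id!r}; peptide skipped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(stack, axis=0)
    n = np.sum(~np.isnan(stack), axis=0)
    avg = np.where(n > 0, avg, 0.0)
    return CrossRunProfile(sync.precursor_id, sync.grid_rt, avg, n)


def snr(values: np.ndarray, rt: np.ndarray, region: tuple[float, float]) -> float:
    """Peak-region SNR: max score inside the region / max score outside.

    Returns ``inf`` when the outside maximum is 0.
    """
    left, right = region
    inside = (rt >= left) & (rt <= right)
    if not inside.any():
        raise ValueError("annotated region contains no grid points")
    peak = float(np.nanmax(values[inside]))
    outside = values[~inside]
    if outside.size == 0:
        raise ValueError("region covers the whole grid; SNR undefined")
    noise = float(np.nanmax(outside))
    if noise == 0.0:
        return np.inf
    return peak / noise


@dataclass
class PeakCandidate:
    """A consensus candidate peak on the common grid."""

    rank: int
    apex_idx: int
    apex_rt: float
    left_idx: int
    right_idx: int
    left_rt: float
    right_rt: float
    apex_score: float


def _boundaries(values: np.ndarray, apex: int, floor_frac: float = 0.1) -> tuple[int, int]:
    """Walk outward to the nearest valley or to score < floor_frac * apex."""
    floor = floor_frac * values[apex]
    left = apex
    while left > 0 and values[left - 1] <= values[left] and values[left - 1] >= floor:
        left -= 1
    right = apex
    n = len(values)
    while right < n - 1 and values[right + 1] <= values[right] and values[right + 1] >= floor:
        right += 1
    return left, right


def pick_peaks(
    profile: CrossRunProfile, top_n: int = 10, min_separation: float = 24.0
) -> list[PeakCandidate]:
    """Pick up to ``top_n`` consensus candidates from the averaged profile.

    Local maxima are ranked by averaged score (ties to the lower RT) and
    greedily accepted when at least ``min_separation`` seconds away from
    every already-accepted apex. The same candidate RTs apply to every
    run. Boundaries extend to the nearest valley or to 10% of the apex
    score.
    """
    v = profile.averaged_main
    rt = profile.grid_rt
    if v.size == 0:
        return []
    maxima = list(argrelextrema(v, np.greater_equal, order=1)[0])
    # drop plateau duplicates: keep the first index of equal-valued neighbours
    maxima = [i for i in maxima if i == 0 or v[i] != v[i - 1] or i - 1 not in maxima]
    maxima = [i for i in maxima if v[i] > 0]
    if not maxima:
        return []
    maxima.sort(key=lambda i: (-v[i], rt[i]))

    accepted: list[int] = []
    for i in maxima:
        if all(abs(rt[i] - rt[j]) >= min_separation for j in accepted):
            accepted.append(i)
        if len(accepted) == top_n:
            break

    out = []
    for rank, i in enumerate(accepted, start=1):
        li, ri = _boundaries(v, i)
        out.append(
            PeakCandidate(rank, int(i), float(rt[i]), li, ri, float(rt[li]), float(rt[ri]), float(v[i]))
        )
    return out


def weight_decay(w, k: float):
    """Exponential weight decay phi(w) = (k**w - 1)/(k - 1) on [0, 1].

    phi(0) = 0 and phi(1) = 1 for every k; k = 0 disables decay
    (phi(w) = w) and k = 1 is handled as its analytic limit, also the
    identity. For k > 1 phi is strictly increasing, convex, and
    phi(w) <= w.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any((w_arr < 0) | (w_arr > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if k < 0:
        raise ValueError("decay coefficient k must be >= 0")
    if k == 0 or abs(k - 1.0) < 1e-12:
        out = w_arr.copy()
    else:
        out = (np.power(k, w_arr) - 1.0) / (k - 1.0)
    return float(out) if np.isscalar(w) else out


def multirun_score(
    scores: np.ndarray,
    weights: np.ndarray,
    k: float,
    target_index: int,
) -> float:
    """Similarity-weighted, decay-penalized combination of aligned scores.

    ``scores[j]`` is run j's single-run score at the candidate position
    (NaN when unavailable) and ``weights[j]`` the global similarity of
    run j to the target run (1 for the target itself). Weights pass
    through :func:`weight_decay` and are normalized to sum 1, so the
    result is a convex combination bounded by the per-run scores. If
    every decayed weight vanishes the target run's own score is
    returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    valid = ~np.isnan(scores)
    phi = np.zeros_like(weights)
    phi[valid] = weight_decay(weights[valid], k)
    denom = phi[valid].sum()
    if denom <= 0:
        warnings.warn("all decayed weights are zero; falling back to the target run's score")
        own = scores[target_index]
        return float(own) if np.isfinite(own) else 0.0
    return float(np.nansum(phi * np.where(valid, scores, 0.0)) / denom)


# ---------------------------------------------------------------------------
# Automated selection of the decay coefficient


def find_elbow(
    k_grid: Sequence[float], counts: Sequence[float], gaussian_sigma: float = 1.0
) -> float:
    """First elbow of the identification-count-versus-k curve.

    The curve is Gaussian-smoothed, restricted to its initial descending
    segment, both axes are min-max normalized, and the elbow is the
    point with maximum perpendicular distance to the chord from the
    segment's first to last point. A flat or strictly linear decline has
    no elbow; the smallest k is returned with a warning.
    """
    k = np.asarray(k_grid, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(k) != len(c) or len(k) < 3:
        raise ValueError("need matching k grid and counts with >= 3 points")
    smooth = gaussian_filter1d(c, sigma=gaussian_sigma, mode="nearest")

    # initial descending segment (first local minimum of the smoothed curve)
    end = len(smooth) - 1
    for i in range(1, len(smooth)):
        if smooth[i] > smooth[i - 1]:
            end = i - 1
            break
    if end < 2 or smooth[0] == smooth[end]:
        warnings.warn("count curve is flat; no elbow, returning the smallest k")
        return float(k[0])

    x = (k[: end + 1] - k[0]) / (k[end] - k[0])
    y = (smooth[: end + 1] - smooth[end]) / (smooth[0] - smooth[end])
    # distance to chord y = 1 - x, i.e. |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1.0)
    if np.all(dist < 1e-9):
        warnings.warn("count curve declines linearly; no elbow, returning the smallest k")
        return float(k[0])
    return float(k[int(np.argmax(dist))])


def auto_select_k(
    id_count_fn: Callable[[float], int],
    k_grid: Sequence[float] = (0, 5, 10, 25, 50, 100, 200),
    gaussian_sigma: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Run the pipeline at each k and return (k*, counts).

    ``id_count_fn(k)`` must return the number of identifications at the
    fixed q-value cutoff for decay coefficient k — typically the full
    workflow on a downsampled library. The k grid must be increasing
    and include 0 (decay disabled baseline).
    """
    k = np.asarray(k_grid, dtype=float)
    if k[0] != 0 or np.any(np.diff(k) <= 0):
        raise ValueError("k_grid must be increasing and include 0 first")
    counts = np.array([float(id_count_fn(float(kk))) for kk in k])
    return find_elbow(k, counts, gaussian_sigma), counts
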