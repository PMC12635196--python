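"""Sliding-window peak scoring of extracted chromatograms.

A window of fixed length slides along each peptide's chromatogram time
point by time point and a pluggable scorer maps the fragment-trace
window matrix to a peak-quality score in [0, 1], producing a continuous
*scoring profile* per run. Alongside the main score, three auxiliary
profiles are computed: the spectral cosine similarity between observed
fragment intensities and the library spectrum, and the MS1 / MS2
trapezoidal window areas.

The default scorer is a deterministic composite (fragment co-elution,
Gaussian shape, spectral cosine); any model with the same signature —
e.g. a trained neural scorer — can be injected through
:class:`ScorerSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from crossrun_dia.data_model_io import Chromatogram, LibraryEntry

__all__ = ["ScoringProfile", "ScorerSpec", "default_scorer", "score_profile", "spectral_cosine_profile"]


@dataclass
class ScoringProfile:
    """Continuous per-time-point score traces for one (run, precursor)."""

    run_id: str
    precursor_id: str
    rt: np.ndarray
    main_score: np.ndarray
    spectral_cosine: np.ndarray
    ms1_area: np.ndarray
    ms2_area: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "main_score": self.main_score,
            "spectral_cosine": self.spectral_cosine,
            "ms1_area": self.ms1_area,
            "ms2_area": self.ms2_area,
        }


Scorer = Callable[[np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class ScorerSpec:
    """Sliding-window configuration: window length (odd, centred) and scorer."""

    window_length: int = 17
    scorer: Scorer | None = None  # None selects the vectorised default

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 3")


def _gaussian_template(length: int) -> np.ndarray:
    x = np.arange(length) - (length - 1) / 2.0
    return np.exp(-0.5 * (x / (length / 6.0)) ** 2)


def default_scorer(window_matrix: np.ndarray, library_intensities: np.ndarray) -> float:
    """Deterministic composite peak-quality score for one window.

    Mean of three components, each in [0, 1]:

    * co-elution — mean pairwise Pearson correlation between fragment
      traces, mapped to [0, 1] by clamping negative values (anti-
      correlation is no co-elution evidence);
    * shape — Pearson correlation of the summed trace with a centred
      Gaussian template, mapped to [0, 1] the same way;
    * spectral cosine between the window-centre intensities and the
      library spectrum.

    Degenerate windows (every trace constant) score 0.
    """
    w = np.atleast_2d(np.asarray(window_matrix, dtype=float))
    res = _default_scorer_batch(w[None, :, :], np.asarray(library_intensities, dtype=float))
    return float(res[0])


def _pearson_rows(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centred traces and their L2 norms, per window. w: (T, f, L)."""
    c = w - w.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(c, axis=2)
    return c, norms


def _default_scorer_batch(windows: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Vectorised default scorer over a stack of windows (T, f, L)."""
    T, f, L = windows.shape
    centred, norms = _pearson_rows(windows)
    valid = norms > 0.0

    # co-elution: mean pairwise Pearson over fragment pairs with variance
    safe = np.where(valid[:, :, None], centred / np.where(norms[:, :, None] == 0, 1.0, norms[:, :, None]), 0.0)
    corr = np.einsum("tfl,tgl->tfg", safe, safe)
    n_valid = valid.sum(axis=1)
    pair_counts = n_valid * (n_valid - 1)
    off_diag_sum = corr.sum(axis=(1, 2)) - np.einsum("tff->t", corr)
    # negative correlation carries no co-elution evidence: clamp at 0
    coelution = np.where(
        pair_counts > 0,
        np.clip(off_diag_sum / np.where(pair_counts == 0, 1, pair_counts), 0.0, 1.0),
        0.0,
    )

    # shape: correlation of summed trace with a Gaussian template
    summed = windows.sum(axis=1)
    tmpl = _gaussian_template(L)
    tmpl_c = tmpl - tmpl.mean()
    s_c = summed - summed.mean(axis=1, keepdims=True)
    s_norm = np.linalg.norm(s_c, axis=1)
    denom = s_norm * np.linalg.norm(tmpl_c)
    shape = np.where(denom > 0, (s_c @ tmpl_c) / np.where(denom == 0, 1.0, denom), -1.0)
    shape = np.clip(shape, 0.0, 1.0)
    shape = np.where(s_norm > 0, shape, 0.0)

    # spectral cosine at window centre
    centre = windows[:, :, L // 2]
    cosine = _cosine_to_library(centre, lib)

    score = (coelution + shape + cosine) / 3.0
    degenerate = ~valid.any(axis=1)
    score = np.where(degenerate, 0.0, score)
    return np.clip(score, 0.0, 1.0)


def _cosine_to_library(columns: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Cosine similarity of each row of ``columns`` (T, f) to the library spectrum."""
    lib_norm = np.linalg.norm(lib)
    col_norm = np.linalg.norm(columns, axis=1)
    denom = col_norm * lib_norm
    out = np.where(denom > 0, columns @ lib / np.where(denom == 0, 1.0, denom), 0.0)
    return np.clip(out, 0.0, 1.0)


def spectral_cosine_profile(chrom: Chromatogram, entry: LibraryEntry) -> np.ndarray:
    """Per-time-point cosine between observed fragment intensities and the library."""
    return _cosine_to_library(chrom.ms2_traces.T, entry.library_intensities)


def _window_area(trace: np.ndarray, half: int, step: float) -> np.ndarray:
    """Trapezoidal area of ``trace`` within the window at each centre (edge-replicated)."""
    padded = np.pad(trace, half, mode="edge")
    kernel = np.ones(2 * half + 1)
    kernel[0] = kernel[-1] = 0.5
    return np.convolve(padded, kernel, mode="valid") * step


def score_profile(
    chrom: Chromatogram, entry: LibraryEntry, spec: ScorerSpec = ScorerSpec()
) -> ScoringProfile:
    """Slide the scoring window along a chromatogram.

    Edges are handled by replicating the first/last time point so the
    profile has the same length as the RT grid. The MS1 area profile is
    zero when no MS1 trace was extracted.
    """
    L = spec.window_length
    if chrom.n_points < L:
        raise ValueError(
            f"chromatogram has {chrom.n_points} points, fewer than window_length={L}"
        )
    half = L // 2
    lib = entry.library_intensities
    if lib.shape[0] != chrom.ms2_traces.shape[0]:
        raise ValueError("library fragment count does not match chromatogram traces")

    padded = np.pad(chrom.ms2_traces, ((0, 0), (half, half)), mode="edge")
    windows = sliding_window_view(padded, L, axis=1)  # (f, T, L)
    windows = np.ascontiguousarray(windows.transpose(1, 0, 2))  # (T, f, L)

    if spec.scorer is None:
        main = _default_scorer_batch(windows, lib)
    else:
        main = np.array(
            [np.clip(spec.scorer(w, lib), 0.0, 1.0) for w in windows], dtype=float
        )

    step = float(np.median(np.diff(chrom.rt)))
    ms2_area = _window_area(chrom.ms2_traces.sum(axis=0), half, step)
    if chrom.ms1_trace is not None:
        ms1_area = _window_area(chrom.ms1_trace, half, step)
    else:
        ms1_area = np.zeros(chrom.n_points)

    return ScoringProfile(
        run_id=chrom.run_id,
        precursor_id=chrom.precursor_id,
        rt=chrom.rt.copy(),
        main_score=main,
        spectral_cosine=spectral_cosine_profile(chrom, entry),
        ms1_area=ms1_area,
        ms2_area=ms2_area,
    )
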