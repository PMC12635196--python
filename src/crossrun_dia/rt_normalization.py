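"""Retention-time normalization and global run-similarity metrics.

Anchor peptides are sub-sampled from the spectral library across the
iRT range (equal-width bins with 20% edge oversampling), located in each
run by the highest-scoring position of their scoring profile (the *best
RT*), and validated by spectral cosine (> 0.95 by default). A linear or
lowess model of RT against library iRT is fitted per run; anchors whose
residual (converted to seconds through the local slope) falls below a
threshold are *inliers*. Inlier sets drive four global run-similarity
metrics — NC (Dice overlap of inlier IDs), total-intensity cosine, mean
XIC cosine, and aligned XIC cosine — collected into a symmetric
similarity matrix that downstream alignment uses to build its spanning
tree and the multi-run scorer uses as combination weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from crossrun_dia.data_model_io import Chromatogram, LibraryEntry
from crossrun_dia.peak_scoring import ScoringProfile

__all__ = [
    "AnchorRecord",
    "RunAnchors",
    "GlobalRTModel",
    "SimilarityMatrix",
    "select_anchor_peptides",
    "find_best_rt",
    "validate_anchor",
    "fit_global_model",
    "nc_similarity",
    "intensity_similarity",
    "xic_cosine_similarity",
    "aligned_xic_cosine_similarity",
    "build_similarity_matrix",
    "build_run_anchors",
]

DEFAULT_COSINE_THRESHOLD = 0.95
DEFAULT_RESIDUAL_THRESHOLD_S = 60.0


@dataclass
class AnchorRecord:
    precursor_id: str
    best_rt: float
    irt: float
    cosine_at_best: float
    residual_s: float = np.nan
    inlier: bool = False


@dataclass
class RunAnchors:
    """Anchor identifications of one run, with inlier flags."""

    run_id: str
    records: list[AnchorRecord]

    @property
    def inlier_ids(self) -> set[str]:
        return {r.precursor_id for r in self.records if r.inlier}

    def inlier_points(self) -> tuple[np.ndarray, np.ndarray]:
        pts = [(r.best_rt, r.irt) for r in self.records if r.inlier]
        if not pts:
            return np.empty(0), np.empty(0)
        a = np.array(pts)
        return a[:, 0], a[:, 1]


# ---------------------------------------------------------------------------
# Anchor selection


def select_anchor_peptides(
    library: list[LibraryEntry],
    n_anchors: int = 4000,
    n_bins: int = 10,
    oversample_edge: float = 0.20,
    seed: int = 0,
) -> list[str]:
    """Sample anchor peptides stratified across the iRT range.

    The iRT range is split into ``n_bins`` equal-width bins and peptides
    are drawn uniformly within each; the first and last bins receive an
    ``oversample_edge`` larger quota (rounded up) to stabilise the RT
    model at the gradient boundaries. Decoys are never anchors. If the
    library holds fewer targets than ``n_anchors``, all are returned
    with a warning.
    """
    rng = np.random.default_rng(seed)
    targets = [e for e in library if not e.is_decoy]
    if len(targets) <= n_anchors:
        if len(targets) < n_anchors:
            warnings.warn(
                f"library has only {len(targets)} target peptides; using all as anchors"
            )
        return [e.precursor_id for e in targets]

    irts = np.array([e.irt for e in targets])
    lo, hi = irts.min(), irts.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, irts, side="right") - 1, 0, n_bins - 1)

    base = n_anchors / n_bins
    edge_quota = int(np.ceil((1.0 + oversample_edge) * base))
    inner_bins = max(n_bins - 2, 0)
    remaining = n_anchors - 2 * edge_quota
    inner_quota = remaining // inner_bins if inner_bins else 0
    leftover = remaining - inner_quota * inner_bins

    quotas = np.full(n_bins, inner_quota)
    quotas[0] = quotas[-1] = edge_quota
    for b in range(1, 1 + leftover):
        quotas[b] += 1

    selected: list[str] = []
    shortfall = 0
    pool_left: list[str] = []
    for b in range(n_bins):
        members = [targets[i].precursor_id for i in np.where(bin_idx == b)[0]]
        take = min(quotas[b], len(members))
        shortfall += quotas[b] - take
        chosen = rng.choice(len(members), size=take, replace=False)
        selected.extend(members[i] for i in sorted(chosen))
        pool_left.extend(m for i, m in enumerate(members) if i not in set(chosen))
    if shortfall > 0 and pool_left:
        extra = rng.choice(len(pool_left), size=min(shortfall, len(pool_left)), replace=False)
        selected.extend(pool_left[i] for i in sorted(extra))
    return selected


# ---------------------------------------------------------------------------
# Best RT and validation


def find_best_rt(profile: ScoringProfile) -> tuple[float, float, float]:
    """Return (best_rt, main score, spectral cosine) at the profile argmax.

    Ties break to the smallest RT.
    """
    if profile.main_score.size == 0 or np.all(np.isnan(profile.main_score)):
        raise ValueError(f"profile for {profile.precursor_id!r} is empty or all-NaN")
    idx = int(np.nanargmax(profile.main_score))
    return float(profile.rt[idx]), float(profile.main_score[idx]), float(profile.spectral_cosine[idx])


def validate_anchor(cosine_at_best: float, cosine_threshold: float = DEFAULT_COSINE_THRESHOLD) -> bool:
    """An anchor is valid iff its spectral cosine is strictly above the threshold."""
    return bool(cosine_at_best > cosine_threshold)


# ---------------------------------------------------------------------------
# Global RT models


@dataclass
class GlobalRTModel:
    """A fitted RT mapping (RT -> iRT, or run_i RT -> run_j RT).

    Lowess fits are made monotone by isotonic post-correction so the
    mapping stays invertible for synchronization.
    """

    kind: str
    grid_x: np.ndarray
    grid_y: np.ndarray

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        # linear extrapolation beyond the fitted grid
        y = np.interp(x, self.grid_x, self.grid_y)
        slopes = np.gradient(self.grid_y, self.grid_x)
        left = x < self.grid_x[0]
        right = x > self.grid_x[-1]
        y[left] = self.grid_y[0] + slopes[0] * (x[left] - self.grid_x[0])
        y[right] = self.grid_y[-1] + slopes[-1] * (x[right] - self.grid_x[-1])
        return float(y[0]) if scalar else y

    def local_slope(self, x: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        slopes = np.gradient(self.grid_y, self.grid_x)
        s = np.interp(x, self.grid_x, slopes)
        return float(s[0]) if scalar else s

    def residuals_seconds(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """|prediction error| converted to seconds through the local slope."""
        pred = self.predict(np.asarray(x, dtype=float))
        slope = np.atleast_1d(self.local_slope(x))
        slope = np.where(np.abs(slope) < 1e-12, 1e-12, np.abs(slope))
        return np.abs(pred - np.asarray(y, dtype=float)) / slope


def fit_global_model(
    x: np.ndarray,
    y: np.ndarray,
    kind: str = "linear",
    lowess_frac: float = 0.3,
    run_id: str = "?",
) -> GlobalRTModel:
    """Fit a linear or lowess mapping y(x) from anchor points.

    Requires >= 10 points for linear and >= 30 for lowess fits; raises
    naming the run otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_pts = 10 if kind == "linear" else 30
    if len(x) < min_pts:
        raise ValueError(
            f"run {run_id!r}: {len(x)} anchor points are insufficient for a {kind} RT model "
            f"(need >= {min_pts})"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if kind == "linear":
        slope, intercept = np.polyfit(xs, ys, 1)
        gx = np.array([xs[0], xs[-1]])
        return GlobalRTModel("linear", gx, slope * gx + intercept)
    if kind != "lowess":
        raise ValueError(f"unknown model kind {kind!r}")
    smoothed = sm_lowess(ys, xs, frac=lowess_frac, return_sorted=True)
    gx, gy = smoothed[:, 0], smoothed[:, 1]
    gx, idx = np.unique(gx, return_index=True)
    gy = gy[idx]
    increasing = bool(np.polyfit(xs, ys, 1)[0] >= 0)
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    gy = iso.fit_transform(gx, gy)
    return GlobalRTModel("lowess", gx, gy)


def build_run_anchors(
    run_id: str,
    profiles: dict[str, ScoringProfile],
    library_by_id: dict[str, LibraryEntry],
    anchor_ids: list[str],
    kind: str = "linear",
    cosine_threshold: float = DEFAULT_COSINE_THRESHOLD,
    residual_threshold_s: float = DEFAULT_RESIDUAL_THRESHOLD_S,
    lowess_frac: float = 0.3,
) -> tuple[RunAnchors, GlobalRTModel]:
    """Locate, validate and inlier-filter anchors for one run; fit its RT model."""
    records = []
    for pid in anchor_ids:
        prof = profiles.get(pid)
        if prof is None:
            continue
        best_rt, _, cosine = find_best_rt(prof)
        records.append(AnchorRecord(pid, best_rt, library_by_id[pid].irt, cosine))

    valid = [r for r in records if validate_anchor(r.cosine_at_best, cosine_threshold)]
    if len(valid) < (10 if kind == "linear" else 30):
        raise ValueError(
            f"run {run_id!r}: only {len(valid)} validated anchors; cannot fit {kind} RT model"
        )
    x = np.array([r.best_rt for r in valid])
    y = np.array([r.irt for r in valid])
    model = fit_global_model(x, y, kind=kind, lowess_frac=lowess_frac, run_id=run_id)
    residuals = model.residuals_seconds(x, y)
    for r, res in zip(valid, residuals):
        r.residual_s = float(res)
        r.inlier = bool(res <= residual_threshold_s)
    return RunAnchors(run_id, records), model


# ---------------------------------------------------------------------------
# Run-pair similarity metrics


def nc_similarity(inliers_i: set[str], inliers_j: set[str]) -> float:
    """Dice-style overlap of inlier peptide IDs: 2*N_common / (N_i + N_j)."""
    n_i, n_j = len(inliers_i), len(inliers_j)
    if n_i + n_j == 0:
        warnings.warn("both inlier sets are empty; NC similarity undefined, returning 0")
        return 0.0
    return 2.0 * len(inliers_i & inliers_j) / (n_i + n_j)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


def intensity_similarity(
    intensities_i: dict[str, float], intensities_j: dict[str, float], inlier_union: set[str]
) -> float:
    """Cosine of total MS2 intensities over the inlier union (missing -> 0)."""
    if not inlier_union:
        warnings.warn("no shared inliers; intensity similarity undefined, returning 0")
        return 0.0
    ids = sorted(inlier_union)
    u = np.array([intensities_i.get(p, 0.0) for p in ids])
    v = np.array([intensities_j.get(p, 0.0) for p in ids])
    return _cosine(u, v)


def xic_cosine_similarity(
    chroms_i: dict[str, Chromatogram], chroms_j: dict[str, Chromatogram], inlier_union: set[str]
) -> float:
    """Mean cosine of flattened XICs over the inlier union (missing skipped)."""
    vals = []
    for pid in sorted(inlier_union):
        ci, cj = chroms_i.get(pid), chroms_j.get(pid)
        if ci is None or cj is None:
            continue
        n = min(ci.n_points, cj.n_points)
        vals.append(_cosine(ci.ms2_traces[:, :n].ravel(), cj.ms2_traces[:, :n].ravel()))
    if not vals:
        warnings.warn("no shared inlier XICs; similarity undefined, returning 0")
        return 0.0
    return float(np.mean(vals))


def aligned_xic_cosine_similarity(
    chroms_i: dict[str, Chromatogram],
    chroms_j: dict[str, Chromatogram],
    inlier_union: set[str],
    pair_model: GlobalRTModel | None = None,
    band_width: float = 3.0 * DEFAULT_RESIDUAL_THRESHOLD_S,
    gap_penalty: float = 0.05,
) -> float:
    """Mean XIC cosine after per-peptide pairwise alignment."""
    from crossrun_dia.alignment import align_pair_dp  # local import avoids a cycle

    vals = []
    for pid in sorted(inlier_union):
        ci, cj = chroms_i.get(pid), chroms_j.get(pid)
        if ci is None or cj is None:
            continue
        path = align_pair_dp(ci, cj, pair_model, band_width=band_width, gap_penalty=gap_penalty)
        matched = [(a, b) for a, b in path.pairs if a >= 0 and b >= 0]
        if not matched:
            continue
        ai = np.array([a for a, _ in matched])
        bj = np.array([b for _, b in matched])
        vals.append(_cosine(ci.ms2_traces[:, ai].ravel(), cj.ms2_traces[:, bj].ravel()))
    if not vals:
        warnings.warn("no shared inlier XICs; similarity undefined, returning 0")
        return 0.0
    return float(np.mean(vals))


@dataclass
class SimilarityMatrix:
    """Symmetric run-by-run global-RT-similarity matrix (diagonal 1)."""

    runs: list[str]
    W: np.ndarray
    metric: str = "nc"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.runs), len(self.runs)):
            raise ValueError("similarity matrix shape does not match run list")

    def weight(self, run_i: str, run_j: str) -> float:
        return float(self.W[self.runs.index(run_i), self.runs.index(run_j)])

    def row(self, run_id: str) -> np.ndarray:
        return self.W[self.runs.index(run_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.runs, columns=self.runs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def build_similarity_matrix(
    runs: list[str],
    metric: str = "nc",
    inlier_sets: dict[str, set[str]] | None = None,
    intensities: dict[str, dict[str, float]] | None = None,
    chromatograms: dict[str, dict[str, Chromatogram]] | None = None,
    pair_models: dict[tuple[str, str], GlobalRTModel] | None = None,
) -> SimilarityMatrix:
    """Assemble the symmetric global similarity matrix for one metric.

    ``inlier_sets`` is always required; the intensity and XIC metrics
    additionally need per-run total intensities or chromatograms.
    """
    if len(runs) < 2:
        raise ValueError("similarity matrix needs at least 2 runs")
    if inlier_sets is None:
        raise ValueError("inlier_sets are required for every metric")
    n = len(runs)
    W = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = runs[i], runs[j]
            union = inlier_sets[ri] | inlier_sets[rj]
            if metric == "nc":
                w = nc_similarity(inlier_sets[ri], inlier_sets[rj])
            elif metric == "intensity":
                w = intensity_similarity(intensities[ri], intensities[rj], union)
            elif metric == "xic_cosine":
                w = xic_cosine_similarity(chromatograms[ri], chromatograms[rj], union)
            elif metric == "aligned_xic_cosine":
                model = pair_models.get((ri, rj)) if pair_models else None
                w = aligned_xic_cosine_similarity(
                    chromatograms[ri], chromatograms[rj], union, pair_model=model
                )
            else:
                raise ValueError(f"unknown similarity metric {metric!r}")
            W[i, j] = W[j, i] = w
    return SimilarityMatrix(runs, W, metric)
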