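"""Match-between-runs alignment of chromatograms and scoring profiles.

Runs are connected by a minimum spanning tree over the global
similarity matrix (edge weight 1 - w_ij), so each peptide needs exactly
n_runs - 1 pairwise alignments instead of all pairs — linear rather
than quadratic in the number of runs — and signal transfer is confined
to directly connected, highly similar runs.

Pairwise alignment is either a fitted global RT model (linear or
lowess, assuming preserved elution order) or a per-peptide
Needleman-Wunsch dynamic program over the point-pair fragment-cosine
similarity, constrained to a band around the global model's prediction.
Mappings are composed along tree paths to a root run and the per-run
scoring profiles are interpolated onto the root grid, yielding a
synchronized RT matrix per peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from crossrun_dia.data_model_io import Chromatogram
from crossrun_dia.rt_normalization import (
    GlobalRTModel,
    RunAnchors,
    SimilarityMatrix,
    fit_global_model,
)

__all__ = [
    "RunTree",
    "AlignmentPath",
    "AlignmentResult",
    "SynchronizedPeptide",
    "build_mst",
    "align_pair_dp",
    "fit_pairwise_models",
    "align_all",
    "synchronize",
]

DEFAULT_GAP_PENALTY = 0.05
GAP = -1  # gap marker in alignment paths


# ---------------------------------------------------------------------------
# Minimum spanning tree over runs


@dataclass
class RunTree:
    """Spanning tree over runs; edges carry distance 1 - similarity."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("a spanning tree has exactly n - 1 edges")

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b, _ in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out

    def parents_from(self, root: str) -> dict[str, str]:
        """BFS parent pointers from ``root``; raises if disconnected."""
        parents: dict[str, str] = {}
        seen = {root}
        queue = [root]
        while queue:
            cur = queue.pop(0)
            for nb in self.neighbors(cur):
                if nb not in seen:
                    seen.add(nb)
                    parents[nb] = cur
                    queue.append(nb)
        if len(seen) != len(self.nodes):
            raise ValueError("run tree is disconnected")
        return parents

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.edges, columns=["run_i", "run_j", "distance"]).to_csv(
            path, sep="\t", index=False
        )


def build_mst(sim: SimilarityMatrix) -> RunTree:
    """Kruskal MST on distances 1 - w_ij with lexicographic tie-breaks."""
    runs = sim.runs
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to build a spanning tree")
    if not np.all(np.isfinite(sim.W)):
        raise ValueError("similarity matrix contains non-finite entries")
    candidates = sorted(
        (1.0 - float(sim.W[i, j]), runs[i], runs[j])
        for i in range(len(runs))
        for j in range(i + 1, len(runs))
    )
    parent = {r: r for r in runs}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    edges: list[tuple[str, str, float]] = []
    for w, a, b in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, w))
            if len(edges) == len(runs) - 1:
                break
    return RunTree(list(runs), edges)


def choose_root(sim: SimilarityMatrix) -> str:
    """The most central run: maximal total similarity to all others."""
    totals = sim.W.sum(axis=1)
    return sim.runs[int(np.argmax(totals))]


# ---------------------------------------------------------------------------
# Pairwise dynamic-programming alignment


@dataclass
class AlignmentPath:
    """Monotone alignment path between two chromatograms.

    ``pairs`` holds (index_i, index_j) with ``GAP`` (-1) marking a gap
    on one side; ``score`` is the DP optimum.
    """

    pairs: list[tuple[int, int]]
    score: float
    used_fallback: bool = False

    @property
    def matched(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.pairs if a != GAP and b != GAP]


def _pointwise_cosine_matrix(ti: np.ndarray, tj: np.ndarray) -> np.ndarray:
    """Intensity-weighted cosine similarity between time points of two runs.

    S[a, b] is the cosine of the fragment-intensity vectors at time a
    (run i) and b (run j), scaled by the geometric mean of the two
    points' relative intensities (each column norm divided by its run's
    maximum). The magnitude term gives the DP contrast: matches between
    low-intensity baseline points score near zero, so the optimal path
    is driven by actual peak correspondence rather than by the high
    baseline cosine of non-negative noise.
    """
    ni = np.linalg.norm(ti, axis=0)
    nj = np.linalg.norm(tj, axis=0)
    S = ti.T @ tj
    denom = np.outer(ni, nj)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, S / np.where(denom == 0, 1.0, denom), 0.0)
    mi = ni / ni.max() if ni.max() > 0 else ni
    mj = nj / nj.max() if nj.max() > 0 else nj
    S = S * np.sqrt(np.outer(mi, mj))
    return np.clip(S, 0.0, 1.0)


def align_pair_dp(
    chrom_i: Chromatogram,
    chrom_j: Chromatogram,
    global_model: GlobalRTModel | None = None,
    band_width: float | None = 180.0,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> AlignmentPath:
    """Needleman-Wunsch alignment of two chromatograms.

    The match score of cell (a, b) is the cosine between the two runs'
    fragment-intensity vectors at those time points; matches are only
    allowed within ``band_width`` seconds of the global model's
    prediction (identity mapping when no model is given). Gaps cost
    ``gap_penalty`` per step. Tie-breaks prefer diagonal, then a gap in
    run j, then a gap in run i. If the band excludes every match the
    global mapping is returned as a fallback path with a warning.
    """
    n, m = chrom_i.n_points, chrom_j.n_points
    S = _pointwise_cosine_matrix(chrom_i.ms2_traces, chrom_j.ms2_traces)

    if band_width is not None:
        pred = (
            np.asarray(global_model.predict(chrom_i.rt), dtype=float)
            if global_model is not None
            else chrom_i.rt
        )
        in_band = np.abs(chrom_j.rt[None, :] - pred[:, None]) <= band_width
        if not in_band.any():
            warnings.warn(
                f"alignment band empty for {chrom_i.precursor_id}; "
                "falling back to the global RT mapping"
            )
            return _fallback_path(chrom_i, chrom_j, global_model)
        S = np.where(in_band, S, -np.inf)

    NEG = -np.inf
    D = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 up (gap in j), 3 left (gap in i)
    cols = np.arange(m + 1)
    D[0, :] = -gap_penalty * cols
    D[:, 0] = -gap_penalty * np.arange(n + 1)
    ptr[0, 1:] = 3
    ptr[1:, 0] = 2

    gap_cost = gap_penalty * cols[1:]
    for a in range(1, n + 1):
        diag = D[a - 1, :-1] + S[a - 1, :]
        up = D[a - 1, 1:] - gap_penalty
        # tie-break order: diagonal beats up
        M = np.where(diag >= up, diag, up)
        Mptr = np.where(diag >= up, 1, 2).astype(np.uint8)
        # left gaps are a decayed prefix-max: D[a,b] = max_c<=b (V[c] - gap*(b-c))
        shifted = np.concatenate(([D[a, 0]], M + gap_cost))
        run_max = np.maximum.accumulate(shifted)[1:]
        row = run_max - gap_cost
        # left is the last tie-break preference; the tolerance absorbs the
        # rounding introduced by the add-then-subtract prefix trick
        left_wins = row > M + 1e-9
        D[a, 1:] = np.maximum(row, M)
        ptr[a, 1:] = np.where(left_wins, np.uint8(3), Mptr)

    if not np.isfinite(D[n, m]):
        warnings.warn(
            f"no feasible banded alignment for {chrom_i.precursor_id}; "
            "falling back to the global RT mapping"
        )
        return _fallback_path(chrom_i, chrom_j, global_model)

    pairs: list[tuple[int, int]] = []
    a, b = n, m
    while a > 0 or b > 0:
        p = ptr[a, b]
        if p == 1:
            pairs.append((a - 1, b - 1))
            a, b = a - 1, b - 1
        elif p == 2:
            pairs.append((a - 1, GAP))
            a -= 1
        else:
            pairs.append((GAP, b - 1))
            b -= 1
    pairs.reverse()
    return AlignmentPath(pairs, float(D[n, m]))


def _fallback_path(
    chrom_i: Chromatogram, chrom_j: Chromatogram, model: GlobalRTModel | None
) -> AlignmentPath:
    pred = (
        np.asarray(model.predict(chrom_i.rt), dtype=float) if model is not None else chrom_i.rt
    )
    idx_j = np.clip(np.searchsorted(chrom_j.rt, pred), 0, chrom_j.n_points - 1)
    pairs = [(a, int(b)) for a, b in enumerate(idx_j)]
    return AlignmentPath(pairs, 0.0, used_fallback=True)


def path_mapping(path: AlignmentPath, rt_i: np.ndarray, rt_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matched-anchor RT pairs of a path, many-to-one collapsed by averaging."""
    matched = path.matched
    if not matched:
        raise ValueError("alignment path has no matched pairs")
    xs = np.array([rt_i[a] for a, _ in matched])
    ys = np.array([rt_j[b] for _, b in matched])
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.bincount(inverse)
    np.add.at(uy, inverse, ys)
    uy = uy / counts
    uy = np.maximum.accumulate(uy)  # guard monotonicity after collapsing
    return ux, uy


# ---------------------------------------------------------------------------
# Tree-wide alignment and synchronization


def fit_pairwise_models(
    anchors: dict[str, RunAnchors],
    edges: list[tuple[str, str, float]],
    kind: str = "linear",
    lowess_frac: float = 0.3,
) -> dict[tuple[str, str], GlobalRTModel]:
    """Direct pairwise rt_i -> rt_j models on shared inlier best RTs, per tree edge.

    Both directions of every edge are fitted.
    """
    models: dict[tuple[str, str], GlobalRTModel] = {}
    for a, b, _ in edges:
        rec_a = {r.precursor_id: r.best_rt for r in anchors[a].records if r.inlier}
        rec_b = {r.precursor_id: r.best_rt for r in anchors[b].records if r.inlier}
        shared = sorted(set(rec_a) & set(rec_b))
        x = np.array([rec_a[p] for p in shared])
        y = np.array([rec_b[p] for p in shared])
        models[(a, b)] = fit_global_model(x, y, kind=kind, lowess_frac=lowess_frac, run_id=f"{a}->{b}")
        models[(b, a)] = fit_global_model(y, x, kind=kind, lowess_frac=lowess_frac, run_id=f"{b}->{a}")
    return models


@dataclass
class AlignmentResult:
    """Per-run RT vectors mapped onto the root run's time scale."""

    precursor_id: str
    root: str
    mapped_rt: dict[str, np.ndarray]  # run_id -> root-equivalent RT per local grid index
    n_pairwise_alignments: int
    mode: str


def align_all(
    precursor_id: str,
    chroms: dict[str, Chromatogram],
    tree: RunTree,
    root: str,
    pair_models: dict[tuple[str, str], GlobalRTModel],
    mode: str = "dialignr",
    band_width: float | None = 180.0,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> AlignmentResult:
    """Map each run's RT grid onto the root run's time scale.

    Exactly one pairwise alignment is executed per tree edge
    (n_runs - 1 in total); mappings are composed along tree paths by
    piecewise-linear interpolation between the matched anchors of each
    edge. ``mode`` selects global models only (``global_linear`` /
    ``global_lowess``), per-peptide DP on top of the global constraint
    (``dialignr``), or the identity (``none``).
    """
    if mode not in {"none", "global_linear", "global_lowess", "dialignr"}:
        raise ValueError(f"unknown alignment mode {mode!r}")
    runs = tree.nodes
    mapped: dict[str, np.ndarray] = {}
    root_chrom = chroms.get(root)
    if root_chrom is None:
        raise ValueError(f"root run {root!r} has no chromatogram for {precursor_id!r}")
    mapped[root] = root_chrom.rt.copy()
    if mode == "none":
        for r in runs:
            if r in chroms:
                mapped[r] = chroms[r].rt.copy()
        return AlignmentResult(precursor_id, root, mapped, 0, mode)

    parents = tree.parents_from(root)
    order = [root]
    while len(order) < len(runs):
        for r in runs:
            if r not in order and parents.get(r) in order:
                order.append(r)

    n_alignments = 0
    for run in order[1:]:
        par = parents[run]
        child_chrom = chroms.get(run)
        if child_chrom is None:
            continue
        model = pair_models[(run, par)]
        if mode == "dialignr":
            par_chrom = chroms.get(par)
            if par_chrom is None:
                to_parent = np.asarray(model.predict(child_chrom.rt), dtype=float)
            else:
                path = align_pair_dp(
                    child_chrom, par_chrom, model, band_width=band_width, gap_penalty=gap_penalty
                )
                ux, uy = path_mapping(path, child_chrom.rt, par_chrom.rt)
                to_parent = np.interp(child_chrom.rt, ux, uy)
        else:
            to_parent = np.asarray(model.predict(child_chrom.rt), dtype=float)
        n_alignments += 1
        if par == root:
            mapped[run] = to_parent
        else:
            # compose with the parent's already-computed map to the root scale
            par_rt = chroms[par].rt if par in chroms else None
            if par_rt is None or par not in mapped:
                mapped[run] = to_parent
            else:
                mapped[run] = np.interp(to_parent, par_rt, mapped[par])
        mapped[run] = np.maximum.accumulate(mapped[run])
    return AlignmentResult(precursor_id, root, mapped, n_alignments, mode)


@dataclass
class SynchronizedPeptide:
    """Scoring profiles of all runs interpolated onto the root grid.

    ``run_rt_at_grid[r, g]`` is run r's local RT corresponding to root
    grid point g (NaN where the run lacks a trace), i.e. the
    synchronized RT matrix; ``profiles[score][r, g]`` are the aligned
    score traces.
    """

    precursor_id: str
    root: str
    runs: list[str]
    grid_rt: np.ndarray
    run_rt_at_grid: np.ndarray
    profiles: dict[str, np.ndarray]


def synchronize(
    result: AlignmentResult,
    profiles: dict[str, dict[str, np.ndarray]],
    chroms: dict[str, Chromatogram],
    runs: list[str],
) -> SynchronizedPeptide:
    """Interpolate every run's profiles onto the root run's RT grid.

    Non-monotone composed mappings are repaired by a running-maximum
    (isotonic) projection with a warning; many-to-one points collapse by
    linear interpolation averaging. Runs without a trace become NaN rows
    that downstream operations skip.
    """
    root_rt = chroms[result.root].rt
    G = len(root_rt)
    score_types = next(iter(profiles.values())).keys() if profiles else []
    stacks = {s: np.full((len(runs), G), np.nan) for s in score_types}
    rt_matrix = np.full((len(runs), G), np.nan)

    for ri, run in enumerate(runs):
        if run not in result.mapped_rt or run not in profiles:
            continue
        m = result.mapped_rt[run]
        if np.any(np.diff(m) < 0):
            warnings.warn(f"non-monotone mapping for run {run}; applying isotonic repair")
            m = np.maximum.accumulate(m)
        local_rt = chroms[run].rt
        rt_matrix[ri] = np.interp(root_rt, m, local_rt)
        for s, values in profiles[run].items():
            stacks[s][ri] = np.interp(root_rt, m, values)
    return SynchronizedPeptide(
        result.precursor_id, result.root, list(runs), root_rt.copy(), rt_matrix, stacks
    )
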