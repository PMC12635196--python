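import itertools
from functools import lru_cache

import numpy as np
import pytest

from crossrun_dia.alignment import (
    DEFAULT_GAP_PENALTY,
    AlignmentPath,
    RunTree,
    _pointwise_cosine_matrix,
    align_all,
    align_pair_dp,
    build_mst,
    choose_root,
    fit_pairwise_models,
    path_mapping,
    synchronize,
)
from crossrun_dia.data_model_io import Chromatogram
from crossrun_dia.rt_normalization import SimilarityMatrix


def _chrom(traces, run="r", pid="p", step=2.0):
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    rt = np.arange(traces.shape[1], dtype=float) * step
    return Chromatogram(run, pid, rt, traces)


def reference_dp_score(S: np.ndarray, gap: float) -> float:
    """Independent recursive optimum over all monotone paths."""
    n, m = S.shape

    @lru_cache(maxsize=None)
    def f(a, b):
        if a == 0 and b == 0:
            return 0.0
        best = -np.inf
        if a > 0 and b > 0 and np.isfinite(S[a - 1, b - 1]):
            best = max(best, f(a - 1, b - 1) + S[a - 1, b - 1])
        if a > 0:
            best = max(best, f(a - 1, b) - gap)
        if b > 0:
            best = max(best, f(a, b - 1) - gap)
        return best

    return f(n, m)


class TestMST:
    def _sim(self, W, runs=None):
        W = np.asarray(W, dtype=float)
        runs = runs or [f"r{i}" for i in range(len(W))]
        return SimilarityMatrix(runs, W)

    def test_two_runs_single_edge(self):
        tree = build_mst(self._sim([[1, 0.5], [0.5, 1]]))
        assert len(tree.edges) == 1

    def test_replicates_pair_up_before_crossing_groups(self):
        # two replicate pairs: (0,1) and (2,3) highly similar
        W = np.array(
            [
                [1.0, 0.9, 0.2, 0.3],
                [0.9, 1.0, 0.25, 0.2],
                [0.2, 0.25, 1.0, 0.95],
                [0.3, 0.2, 0.95, 1.0],
            ]
        )
        tree = build_mst(self._sim(W))
        edge_pairs = {frozenset((a, b)) for a, b, _ in tree.edges}
        assert frozenset(("r0", "r1")) in edge_pairs
        assert frozenset(("r2", "r3")) in edge_pairs

    def test_equal_similarities_still_valid_tree(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 1.0)
        tree = build_mst(self._sim(W))
        assert len(tree.edges) == 3
        tree.parents_from("r0")  # connected

    def test_matches_brute_force_on_small_matrices(self):
        """MST total weight equals the brute-force minimum over all spanning trees."""
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = int(rng.integers(3, 6))
            W = rng.uniform(0, 1, (n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            sim = self._sim(W)
            tree = build_mst(sim)
            all_edges = [
                (i, j, 1.0 - W[i, j]) for i in range(n) for j in range(i + 1, n)
            ]
            best = np.inf
            for combo in itertools.combinations(all_edges, n - 1):
                parent = list(range(n))

                def find(x):
                    while parent[x] != x:
                        x = parent[x]
                    return x

                ok = True
                for a, b, _ in combo:
                    ra, rb = find(a), find(b)
                    if ra == rb:
                        ok = False
                        break
                    parent[ra] = rb
                if ok:
                    best = min(best, sum(w for _, _, w in combo))
            assert tree.total_weight() == pytest.approx(best)


class TestAlignPairDP:
    def test_identity_gives_pure_diagonal(self):
        rng = np.random.default_rng(1)
        tr = rng.uniform(0, 10, (4, 25))
        path = align_pair_dp(_chrom(tr), _chrom(tr.copy()), None, band_width=None)
        assert all(a == b for a, b in path.pairs)
        assert len(path.matched) == 25

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(2)
        tr = rng.uniform(0, 10, (4, 30))
        shifted = np.roll(tr, 3, axis=1)
        path = align_pair_dp(_chrom(tr), _chrom(shifted), None, band_width=None)
        offsets = [b - a for a, b in path.matched]
        vals, counts = np.unique(offsets, return_counts=True)
        assert vals[np.argmax(counts)] == 3

    def test_dp_equals_recursive_oracle(self):
        """DP optimum equals exhaustive recursion on 100 random short instances."""
        for s in range(100):
            rng = np.random.default_rng(s)
            n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            ti = rng.uniform(0, 5, (3, n))
            tj = rng.uniform(0, 5, (3, m))
            path = align_pair_dp(_chrom(ti), _chrom(tj), None, band_width=None)
            S = _pointwise_cosine_matrix(ti, tj)
            assert path.score == pytest.approx(reference_dp_score(S, DEFAULT_GAP_PENALTY), abs=1e-9)

    def test_band_restriction_falls_back_when_empty(self):
        rng = np.random.default_rng(3)
        ti = rng.uniform(0, 5, (2, 10))
        tj = rng.uniform(0, 5, (2, 10))
        ci = _chrom(ti)
        cj = Chromatogram("r", "p", np.arange(10) * 2.0 + 1e5, tj)  # far away grid
        with pytest.warns(UserWarning, match="band"):
            path = align_pair_dp(ci, cj, None, band_width=10.0)
        assert path.used_fallback

    def test_path_monotone(self):
        for s in range(20):
            rng = np.random.default_rng(s)
            ti = rng.uniform(0, 5, (3, 12))
            tj = rng.uniform(0, 5, (3, 15))
            path = align_pair_dp(_chrom(ti), _chrom(tj), None, band_width=None)
            matched = path.matched
            assert all(
                m2[0] >= m1[0] and m2[1] >= m1[1] for m1, m2 in zip(matched, matched[1:])
            )

    def test_path_mapping_collapses_many_to_one_by_average(self):
        path = AlignmentPath([(0, 0), (0, 1), (1, 2)], 0.0)
        rt_i = np.array([0.0, 2.0])
        rt_j = np.array([0.0, 2.0, 4.0])
        ux, uy = path_mapping(path, rt_i, rt_j)
        assert ux.tolist() == [0.0, 2.0]
        assert uy.tolist() == [1.0, 4.0]  # (0+2)/2 then 4


def _make_sim_and_tree(ds):
    runs = ds.run_ids
    n = len(runs)
    W = np.full((n, n), 0.8)
    np.fill_diagonal(W, 1.0)
    sim = SimilarityMatrix(runs, W)
    return sim, build_mst(sim)


class TestAlignAllAndSynchronize:
    def test_alignment_count_is_runs_minus_one(self, shifted_dataset):
        ds = shifted_dataset
        sim, tree = _make_sim_and_tree(ds)
        root = choose_root(sim)
        pid = ds.library[0].precursor_id
        chroms = {r: ds.chromatograms[r][pid] for r in ds.run_ids}
        # identity-ish pairwise models from true apexes are unnecessary: use DP without models
        res = align_all(pid, chroms, tree, root, _identity_models(tree), mode="dialignr")
        assert res.n_pairwise_alignments == len(ds.run_ids) - 1

    def test_global_linear_reduces_apex_spread(self, shifted_dataset):
        """Aligned apex RTs are tighter than raw apex RTs on linearly shifted data."""
        ds = shifted_dataset
        gt = ds.ground_truth
        sim, tree = _make_sim_and_tree(ds)
        root = choose_root(sim)
        models = _true_shift_models(ds, tree)
        spreads_pre, spreads_post = [], []
        for e in ds.library[:10]:
            pid = e.precursor_id
            chroms = {r: ds.chromatograms[r][pid] for r in ds.run_ids}
            res = align_all(pid, chroms, tree, root, models, mode="global_linear")
            sub = gt[(gt.precursor_id == pid) & gt.present]
            apexes = dict(zip(sub.run_id, sub.apex_rt))
            if len(apexes) < 3:
                continue
            mapped = [
                np.interp(apexes[r], chroms[r].rt, res.mapped_rt[r])
                for r in apexes
                if r in res.mapped_rt
            ]
            spreads_pre.append(np.std(list(apexes.values())))
            spreads_post.append(np.std(mapped))
        assert np.median(spreads_post) < np.median(spreads_pre)

    def test_synchronize_identical_runs_preserves_profiles(self, clean_dataset):
        ds = clean_dataset
        sim, tree = _make_sim_and_tree(ds)
        root = choose_root(sim)
        pid = ds.library[0].precursor_id
        chroms = {r: ds.chromatograms[r][pid] for r in ds.run_ids}
        res = align_all(pid, chroms, tree, root, _identity_models(tree), mode="none")
        values = {r: {"x": chroms[r].ms2_traces[0]} for r in ds.run_ids}
        sync = synchronize(res, values, chroms, ds.run_ids)
        ri = ds.run_ids.index(root)
        assert np.allclose(sync.profiles["x"][ri], chroms[root].ms2_traces[0])

    def test_missing_run_yields_nan_row(self, clean_dataset):
        ds = clean_dataset
        sim, tree = _make_sim_and_tree(ds)
        root = choose_root(sim)
        pid = ds.library[0].precursor_id
        chroms = {r: ds.chromatograms[r][pid] for r in ds.run_ids}
        dropped = ds.run_ids[-1] if ds.run_ids[-1] != root else ds.run_ids[0]
        sub = {r: c for r, c in chroms.items() if r != dropped}
        res = align_all(pid, sub, tree, root, _identity_models(tree), mode="none")
        values = {r: {"x": sub[r].ms2_traces[0]} for r in sub}
        sync = synchronize(res, values, sub, ds.run_ids)
        assert np.all(np.isnan(sync.profiles["x"][ds.run_ids.index(dropped)]))


def _identity_models(tree):
    from crossrun_dia.rt_normalization import GlobalRTModel

    models = {}
    for a, b, _ in tree.edges:
        g = np.array([0.0, 1e4])
        models[(a, b)] = GlobalRTModel("linear", g, g)
        models[(b, a)] = GlobalRTModel("linear", g, g)
    return models


def _true_shift_models(ds, tree):
    """Pairwise linear models fitted on the generator's true apex RTs."""
    from crossrun_dia.rt_normalization import fit_global_model

    gt = ds.ground_truth[ds.ground_truth.present]
    by_run = {r: dict(zip(g.precursor_id, g.apex_rt)) for r, g in gt.groupby("run_id")}
    models = {}
    for a, b, _ in tree.edges:
        shared = sorted(set(by_run[a]) & set(by_run[b]))
        x = np.array([by_run[a][p] for p in shared])
        y = np.array([by_run[b][p] for p in shared])
        models[(a, b)] = fit_global_model(x, y, "linear")
        models[(b, a)] = fit_global_model(y, x, "linear")
    return models
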