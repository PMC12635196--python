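import numpy as np
import pandas as pd
import pytest

from crossrun_dia.quant_metrics import (
    completeness,
    dispersion,
    filter_valid,
    median_bias,
    species_ratios,
    ssa,
    top3_protein_quant,
    total_bias,
)


def _groups(n_a=3, n_b=3):
    runs = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return runs, {r: r[0] for r in runs}


def brute_force_auroc(x, y):
    """O(n^2) pairwise comparison with half credit for ties."""
    wins = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    return wins / (len(x) * len(y))


class TestFilterValid:
    def test_three_runs_each_side_retained(self):
        runs, groups = _groups()
        m = pd.DataFrame([[200.0] * 6], index=["p1"], columns=runs)
        assert list(filter_valid(m, groups).index) == ["p1"]

    def test_two_runs_one_side_removed(self):
        runs, groups = _groups()
        m = pd.DataFrame([[200, 200, np.nan, 200, 200, 200]], index=["p1"], columns=runs)
        assert filter_valid(m, groups).empty

    def test_low_intensity_entry_nulled_then_row_reevaluated(self):
        runs, groups = _groups()
        m = pd.DataFrame([[99, 200, 200, 200, 200, 200]], index=["p1"], columns=runs)
        out = filter_valid(m, groups)
        assert out.empty  # only 2 valid A entries remain

    def test_idempotent(self):
        runs, groups = _groups(4, 4)
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.uniform(50, 500, (10, 8)), columns=runs, index=[f"p{i}" for i in range(10)]
        )
        once = filter_valid(m, groups)
        twice = filter_valid(once, groups)
        pd.testing.assert_frame_equal(once, twice)

    def test_constructed_matrix_survivor_count(self):
        """10x12 toy matrix with a known number of surviving rows."""
        runs, groups = _groups(6, 6)
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.uniform(150, 400, (10, 12)), columns=runs, index=[f"p{i}" for i in range(10)]
        )
        # rows 0-2: fail min_runs in B; row 3: all below intensity; rows 4-9 pass
        m.iloc[0:3, 6:10] = np.nan
        m.iloc[3, :] = 50.0
        out = filter_valid(m, groups)
        assert len(out) == 6
        assert set(out.index) == {f"p{i}" for i in range(4, 10)}


class TestSpeciesRatios:
    def test_equal_means_zero_ratio(self):
        runs, groups = _groups()
        m = pd.DataFrame([[10.0] * 6], index=["p1"], columns=runs)
        out = species_ratios(m, groups, pd.Series({"p1": "human"}))
        assert out.loc["p1", "log2_ratio"] == pytest.approx(0.0)

    def test_tenfold_ratio(self):
        runs, groups = _groups()
        m = pd.DataFrame([[10.0, 10, 10, 1, 1, 1]], index=["p1"], columns=runs)
        out = species_ratios(m, groups, pd.Series({"p1": "yeast"}))
        assert out.loc["p1", "log2_ratio"] == pytest.approx(np.log2(10))

    def test_nan_excluded_from_means(self):
        runs, groups = _groups()
        m = pd.DataFrame([[10.0, np.nan, 10, 5, 5, np.nan]], index=["p1"], columns=runs)
        out = species_ratios(m, groups, pd.Series({"p1": "h"}))
        assert out.loc["p1", "log2_ratio"] == pytest.approx(1.0)


class TestSSA:
    def test_perfect_separation(self):
        r = pd.DataFrame(
            {"log2_ratio": [1.0, 1.1, 1.2, -1.0, -1.1], "species": ["y"] * 3 + ["h"] * 2}
        )
        assert ssa(r, ("y", "h")) == 1.0

    def test_identical_distributions_near_half(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            r = pd.DataFrame(
                {"log2_ratio": rng.normal(0, 1, 40), "species": ["y"] * 20 + ["h"] * 20}
            )
            vals.append(ssa(r, ("y", "h")))
        assert 0.5 <= np.mean(vals) < 0.58  # folded AUROC is >= 0.5 by definition

    def test_matches_pairwise_oracle_with_ties(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 5, rng.integers(3, 20)).astype(float)
            y = rng.integers(0, 5, rng.integers(3, 20)).astype(float)
            r = pd.DataFrame(
                {"log2_ratio": np.concatenate([x, y]), "species": ["a"] * len(x) + ["b"] * len(y)}
            )
            auc = brute_force_auroc(x, y)
            assert ssa(r, ("a", "b")) == pytest.approx(max(auc, 1 - auc), abs=1e-12)

    def test_one_species_missing_rejected(self):
        r = pd.DataFrame({"log2_ratio": [1.0], "species": ["a"]})
        with pytest.raises(ValueError):
            ssa(r, ("a", "b"))


class TestBiasAndDispersion:
    def test_exact_truth_gives_zero_mb_and_disp(self):
        ratios = np.full(10, np.log2(2.0))
        assert median_bias(ratios, 2.0) == 0.0
        assert dispersion(ratios) == 0.0

    def test_median_of_bracketing_ratios(self):
        # ratios {1, 4} on log2: {0, 2}; median 1 = log2(2) -> MB 0
        assert median_bias(np.array([0.0, 2.0]), 2.0) == pytest.approx(0.0)

    def test_symmetric_noise_raises_disp_not_mb(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.3, 4001)
        noise -= np.median(noise)  # symmetrize exactly
        ratios = np.log2(2.0) + noise
        assert median_bias(ratios, 2.0) < 1e-9
        assert dispersion(ratios) > 0.25


class TestTotalBias:
    def test_baseline_identity(self):
        comps = {"one_minus_ssa": 0.1, "mb": 0.2, "disp": 0.3}
        assert total_bias(comps, dict(comps)) == pytest.approx(1.0)

    def test_geometric_mean_of_reciprocal_pair(self):
        comps = {"mb": 0.5, "disp": 2.0}
        base = {"mb": 1.0, "disp": 1.0}
        assert total_bias(comps, base) == pytest.approx(1.0)

    def test_two_vs_three_component_modes_differ_by_ssa_term(self):
        base = {"one_minus_ssa": 0.2, "mb": 0.1, "disp": 0.1}
        comps = {"one_minus_ssa": 0.4, "mb": 0.1, "disp": 0.1}
        three = total_bias(comps, base)
        two = total_bias(
            {k: comps[k] for k in ("mb", "disp")}, {k: base[k] for k in ("mb", "disp")}
        )
        assert two == pytest.approx(1.0)
        assert three > two


class TestCompleteness:
    def test_full_matrix_is_one(self):
        m = pd.DataFrame(np.ones((4, 4)))
        assert completeness(m) == 1.0

    def test_half_nan_after_row_filter(self):
        m = pd.DataFrame(np.ones((4, 4)))
        m.iloc[0, :2] = np.nan  # row still in >= 3 runs but 2 NaN... wait 2 left
        m.iloc[0, :] = [1, 1, 1, np.nan]
        assert completeness(m) == pytest.approx(15 / 16)

    def test_row_filter_shrinks_numerator_and_denominator(self):
        m = pd.DataFrame(np.ones((4, 4)))
        m.iloc[3, :] = [1, np.nan, np.nan, np.nan]  # row seen in 1 run: dropped
        assert completeness(m) == pytest.approx(1.0)


class TestTop3:
    def _matrix(self):
        runs = ["r1", "r2"]
        return pd.DataFrame(
            {
                "r1": [100.0, 50, 10, 5, 1, 30, 20],
                "r2": [110.0, 60, 20, 6, 2, 40, 10],
            },
            index=[f"p{i}" for i in range(7)],
        )

    def test_top3_by_global_mean(self):
        m = self._matrix()
        prot = pd.Series({f"p{i}": "X" for i in range(5)} | {"p5": "Y", "p6": "Y"})
        out = top3_protein_quant(m, prot)
        assert out.loc["X", "r1"] == pytest.approx(100 + 50 + 10)
        assert out.loc["Y", "r1"] == pytest.approx(30 + 20)  # only 2 precursors: both

    def test_order_invariance(self):
        m = self._matrix()
        prot = pd.Series({f"p{i}": "X" for i in range(7)})
        out1 = top3_protein_quant(m, prot)
        perm = m.sample(frac=1, random_state=1)
        out2 = top3_protein_quant(perm, prot.reindex(perm.index))
        pd.testing.assert_frame_equal(out1, out2)
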