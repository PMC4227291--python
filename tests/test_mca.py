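import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from multicorr import (
    MCA,
    SubpopulationSpec,
    compute_surface,
    count_mca_plots,
    default_resolution,
    enumerate_grid,
    find_outlier_candidates,
    pearson,
    subset_by_quantile,
)
from multicorr.mca import in_omega, window_row_indices

from _oracles import surface_oracle, window_oracle


def toy_frame(m=10):
    return pd.DataFrame(
        {"s": np.arange(1.0, m + 1), "a": np.arange(m, dtype=float),
         "b": np.arange(m, dtype=float) ** 2}
    )


class TestGrid:
    def test_coarsest_grid_is_single_apex(self):
        assert enumerate_grid(1, 10) == [(0.5, 0.5)]

    def test_resolution_five(self):
        got = set(enumerate_grid(5, 100))
        expected = {
            (0.2, 0.2), (0.4, 0.2), (0.6, 0.2), (0.8, 0.2),
            (0.4, 0.4), (0.6, 0.4), (0.5, 0.5),
        }
        assert {(round(a, 12), round(b, 12)) for a, b in got} == expected

    @pytest.mark.parametrize("r", [1, 3, 5, 7, 9, 11, 13, 15])
    def test_size_matches_double_loop_and_all_admissible(self, r):
        grid = enumerate_grid(r, 100)
        # independent count: beta row j has R - 2j + 1 alphas, plus the apex
        assert len(grid) == sum(r - 2 * j + 1 for j in range(1, r // 2 + 1)) + 1
        assert len(set(grid)) == len(grid)
        assert all(in_omega(a, b) for a, b in grid)

    @pytest.mark.parametrize("r, m", [(2, 10), (0, 10), (11, 9)])
    def test_invalid_resolution(self, r, m):
        with pytest.raises(ValueError):
            enumerate_grid(r, m)


class TestWindowing:
    def test_full_window_returns_everything(self):
        df = toy_frame(10)
        sub = subset_by_quantile(df, SubpopulationSpec("s", 0.5, 0.5))
        pd.testing.assert_frame_equal(sub, df)

    def test_bottom_window_takes_smallest_ranks(self):
        df = toy_frame(10)
        sub = subset_by_quantile(df, SubpopulationSpec("s", 0.15, 0.15))
        assert sub["s"].tolist() == [1.0, 2.0, 3.0]

    def test_row_order_preserved(self, rng):
        df = pd.DataFrame({"s": rng.permutation(20).astype(float),
                           "a": np.arange(20.0)})
        sub = subset_by_quantile(df, SubpopulationSpec("s", 0.3, 0.2))
        assert list(sub.index) == sorted(sub.index)

    def test_outside_omega_rejected(self):
        with pytest.raises(ValueError):
            SubpopulationSpec("s", 0.1, 0.3)  # alpha < beta
        with pytest.raises(ValueError):
            window_row_indices(np.arange(5.0), 0.9, 0.2)  # alpha > 1 - beta

    def test_unknown_sorter(self):
        with pytest.raises(KeyError, match="nope"):
            subset_by_quantile(toy_frame(), SubpopulationSpec("nope", 0.5, 0.5))

    def test_matches_enumeration_oracle(self, rng):
        vals = rng.normal(size=23)
        for alpha, beta in enumerate_grid(7, 23):
            got = window_row_indices(vals, alpha, beta).tolist()
            assert got == window_oracle(list(vals), alpha, beta)

    def test_window_nesting(self, rng):
        vals = rng.normal(size=40)
        for alpha in (0.3, 0.5, 0.6):
            inner, outer = None, None
            for beta in sorted(b for b in (0.1, 0.2, 0.3) if in_omega(alpha, b)):
                outer = set(window_row_indices(vals, alpha, beta))
                if inner is not None:
                    assert inner <= outer
                inner = outer

    def test_ties_broken_by_row_order(self):
        vals = np.array([2.0, 2.0, 2.0, 2.0])
        got = window_row_indices(vals, 0.25, 0.25).tolist()
        # all values tie, so the stable order is the row order: ranks 1..2
        assert got == [0, 1]


class TestSurface:
    def test_apex_equals_global_correlation(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=["x", "y", "s"])
        surf = compute_surface(df, ("x", "y"), "s", 5)
        apex = surf.apex
        direct = pearson(df["x"], df["y"])
        assert apex.n == 25
        assert apex.estimate.coefficient == pytest.approx(direct.coefficient)

    def test_sorter_in_pair_guard(self):
        df = toy_frame()
        with pytest.raises(ValueError, match="sorting variable"):
            compute_surface(df, ("a", "s"), "s", 3)
        surf = compute_surface(df, ("a", "s"), "s", 3, allow_sorter_in_pair=True)
        assert surf.cells

    def test_small_windows_flagged_invalid(self):
        df = toy_frame(9)
        surf = compute_surface(df, ("a", "b"), "s", 9)
        small = [c for c in surf.cells if c.n < 3]
        assert small and all(not c.estimate.valid for c in small)

    @pytest.mark.parametrize("m, r, seed", [(8, 3, 0), (12, 3, 1), (19, 5, 2),
                                            (30, 7, 3)])
    def test_matches_brute_force_oracle(self, m, r, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(m, 3)), columns=["x", "y", "s"])
        surf = compute_surface(df, ("x", "y"), "s", r)
        ref = surface_oracle(df, ("x", "y"), "s", r)
        assert len(surf.cells) == len(ref)
        for cell in surf.cells:
            n_ref, r_ref, p_ref = ref[(round(cell.alpha, 12), round(cell.beta, 12))]
            assert cell.n == n_ref
            if r_ref is None:
                assert not cell.estimate.valid
            else:
                assert cell.estimate.coefficient == pytest.approx(r_ref, abs=1e-12)
                assert cell.estimate.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_monotone_sorter_relabeling_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x", "y", "s"])
        base = compute_surface(df, ("x", "y"), "s", 7)
        df2 = df.assign(s=np.exp(df["s"]))
        relabeled = compute_surface(df2, ("x", "y"), "s", 7)
        for c1, c2 in zip(base.cells, relabeled.cells):
            assert (c1.alpha, c1.beta, c1.n) == (c2.alpha, c2.beta, c2.n)
            if c1.estimate.valid:
                assert c1.estimate.coefficient == pytest.approx(
                    c2.estimate.coefficient
                )

    def test_export_frame_layout(self, tmp_path):
        surf = compute_surface(toy_frame(12), ("a", "b"), "s", 3)
        frame = surf.to_frame()
        assert list(frame.columns) == [
            "alpha", "beta", "n", "coefficient", "p_value", "valid",
            "median_sorter",
        ]
        assert (frame["beta"].diff().dropna() <= 1e-12).all()
        out = tmp_path / "surface.tsv"
        surf.to_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert len(back) == len(frame)


class TestPlotCount:
    @pytest.mark.parametrize("k, expected", [(0, 0), (2, 0), (3, 1), (9, 84)])
    def test_known_values(self, k, expected):
        assert count_mca_plots(k) == expected

    def test_matches_triple_enumeration(self):
        for k in range(13):
            triples = list(itertools.combinations(range(k), 3))
            assert count_mca_plots(k) == len(triples)


class TestOutlierCandidates:
    def build(self, rng):
        # 40 uncorrelated points plus one extreme observation, placed at the
        # top of the sorting variable, that induces a significant global r
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 1, 40)
        s = rng.uniform(0, 1, 40)
        df = pd.DataFrame({"x": np.append(x, 10.0), "y": np.append(y, 10.0),
                           "s": np.append(s, 2.0)})
        return df

    def test_influential_extreme_point_is_flagged(self, rng):
        df = self.build(rng)
        base = pearson(df.drop(index=40)["x"], df.drop(index=40)["y"])
        assert base.p_value > 0.05  # fixture premise: cloud alone uncorrelated
        assert pearson(df["x"], df["y"]).p_value < 0.05
        surf = compute_surface(df, ("x", "y"), "s", 5)
        assert 40 in find_outlier_candidates(surf, df)

    def test_perfect_correlation_unflagged(self):
        df = pd.DataFrame({"x": np.arange(30.0), "y": np.arange(30.0),
                           "s": np.arange(30.0)})
        surf = compute_surface(df, ("x", "y"), "s", 5)
        assert find_outlier_candidates(surf, df) == []

    def test_degenerate_size_no_crash(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 3, 2], "s": [1.0, 2, 3]})
        surf = compute_surface(df, ("x", "y"), "s", 3)
        assert isinstance(find_outlier_candidates(surf, df), list)


class TestEstimator:
    def test_fit_exposes_surface(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "s"])
        est = MCA(pair=("x", "y"), sorting_variable="s", resolution=7).fit(df)
        assert est.surface_.apex.n == 40
        assert est.n_observations_ == 40
        assert est.resolution_ == 7

    def test_sklearn_params_roundtrip(self):
        est = MCA(pair=("x", "y"), sorting_variable="s", resolution=7,
                  method="spearman")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(resolution=9)
        assert cloned.resolution == 9 and est.resolution == 7

    def test_default_resolution_rule(self):
        assert default_resolution(10) == 9
        assert default_resolution(99) == 99
        assert default_resolution(500) == 99
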