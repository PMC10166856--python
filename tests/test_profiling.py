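"""Binning, profiles, loess smoothing and module scores."""
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axiscope import (
    assign_bins,
    bin_profile,
    loess_fit,
    normalize_counts,
    score_module,
    smooth_profile,
)
from axiscope.errors import (
    EmptyModule,
    InvalidBinCount,
    NoSpots,
    OutOfRange,
    TooFewBins,
)
from conftest import make_count_matrix


class TestAssignBins:
    @pytest.mark.parametrize(
        "p,n_bins,expected",
        [
            (0.0, 10, 1),     # left edge of the first bin
            (1.0, 10, 10),    # right-closed final bin
            (0.35, 10, 4),    # inside [0.3, 0.4)
            (0.3, 10, 4),     # left-closed interior edge
            (0.999999, 10, 10),
            (0.5, 1, 1),
        ],
    )
    def test_edge_conventions(self, p, n_bins, expected):
        assert assign_bins({"s": p}, n_bins)["s"] == expected

    def test_invalid_bin_count(self):
        with pytest.raises(InvalidBinCount):
            assign_bins({"s": 0.5}, 0)

    def test_out_of_range_position(self):
        with pytest.raises(OutOfRange):
            assign_bins({"s": 1.0001}, 10)

    @given(
        positions=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50
        ),
        n_bins=st.integers(min_value=1, max_value=30),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, positions, n_bins):
        """Every in-range position maps to exactly one bin in 1..n_bins,
        and the bin's interval actually contains the position."""
        pos = {f"s{i}": p for i, p in enumerate(positions)}
        bins = assign_bins(pos, n_bins)
        assert set(bins) == set(pos)
        for s, b in bins.items():
            assert 1 <= b <= n_bins
            lo, hi = (b - 1) / n_bins, b / n_bins
            p = pos[s]
            assert lo <= p and (p < hi or (b == n_bins and p <= 1.0))


class TestBinProfile:
    def test_single_member_bins(self):
        prof = bin_profile({"a": 0.1, "b": 0.9}, {"a": 5.0, "b": 7.0}, n_bins=2)
        np.testing.assert_allclose(prof.x, [0.1, 0.9])
        np.testing.assert_allclose(prof.y, [5.0, 7.0])
        np.testing.assert_array_equal(prof.occupancy, [1, 1])

    def test_empty_bins_are_omitted(self):
        pos = {"a": 0.1, "b": 0.6, "c": 0.9}
        prof = bin_profile(pos, {k: 1.0 for k in pos}, n_bins=4)
        assert len(prof.x) == 3  # nothing in [0.25, 0.5)
        assert prof.occupancy.sum() == 3
        np.testing.assert_array_equal(prof.bin_index, [1, 3, 4])

    def test_matches_independent_grouping_oracle(self):
        rng = np.random.default_rng(42)
        pos = {f"s{i}": float(p) for i, p in enumerate(rng.uniform(0, 1, 100))}
        vals = {s: float(v) for s, v in zip(pos, rng.normal(size=100))}
        n_bins = 7
        prof = bin_profile(pos, vals, n_bins=n_bins)
        # oracle: interval arithmetic with open/closed edges, then mean
        for idx, x_i, y_i, occ in zip(
            prof.bin_index, prof.x, prof.y, prof.occupancy
        ):
            members = [
                s
                for s, p in pos.items()
                if (idx - 1) / n_bins <= p
                and (p < idx / n_bins or (idx == n_bins and p <= 1))
            ]
            assert len(members) == occ
            assert x_i == pytest.approx(np.mean([pos[s] for s in members]))
            assert y_i == pytest.approx(np.mean([vals[s] for s in members]))
        assert prof.occupancy.sum() == 100
        assert np.all(np.diff(prof.x) > 0)

    def test_spots_without_feature_are_dropped_with_count(self):
        prof = bin_profile(
            {"a": 0.1, "b": 0.5, "c": 0.9},
            {"a": 1.0, "c": float("nan"), "b": 2.0},
            n_bins=2,
        )
        assert prof.n_dropped == 1
        assert prof.occupancy.sum() == 2

    def test_all_spots_missing_raises(self):
        with pytest.raises(NoSpots):
            bin_profile({"a": 0.1}, {}, n_bins=2)

    def test_orientation_flip_reverses_profile(self):
        rng = np.random.default_rng(3)
        # keep positions off bin edges so the closed-edge convention at the
        # boundary cannot move a spot between mirrored bins
        pos = {f"s{i}": float(p) for i, p in
               enumerate(rng.uniform(0.001, 0.999, 80))}
        vals = {s: float(v) for s, v in zip(pos, rng.normal(size=80))}
        n_bins = 10
        prof = bin_profile(pos, vals, n_bins=n_bins)
        flipped = bin_profile({s: 1 - p for s, p in pos.items()}, vals, n_bins)
        np.testing.assert_array_equal(
            flipped.bin_index, (n_bins + 1 - prof.bin_index)[::-1]
        )
        np.testing.assert_allclose(flipped.x[::-1], 1 - prof.x, atol=1e-12)
        np.testing.assert_allclose(flipped.y[::-1], prof.y, atol=1e-12)


class TestLoess:
    def test_constant_input_reproduced_exactly(self):
        x = np.linspace(0, 1, 12)
        fit = loess_fit(x, np.full(12, 3.25), np.linspace(0, 1, 30))
        np.testing.assert_allclose(fit, 3.25, atol=1e-9)

    @pytest.mark.parametrize("degree", [1, 2])
    @pytest.mark.parametrize("span", [0.3, 0.75, 1.0])
    def test_collinear_input_reproduces_the_line(self, degree, span):
        x = np.linspace(0, 1, 15)
        y = 2.0 * x - 0.5
        grid = np.linspace(0, 1, 40)
        fit = loess_fit(x, y, grid, span=span, degree=degree)
        np.testing.assert_allclose(fit, 2.0 * grid - 0.5, atol=1e-6)

    def test_degree1_matches_statsmodels_lowess(self):
        """Independent oracle: statsmodels' lowess is the same tri-cube
        local-linear estimator; fits must agree to numerical precision."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 1, 20))
        y = np.sin(3 * x) + rng.normal(0, 0.1, 20)
        grid = np.linspace(x.min(), x.max(), 11)
        mine = loess_fit(x, y, grid, span=0.5, degree=1)
        oracle = lowess(y, x, frac=0.5, it=0, xvals=grid)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_degree2_matches_r_loess_at_data_points(self, tmp_path):
        """Independent oracle: R's loess (the reference implementation of
        the smoother) with degree 2, compared where its evaluation is
        exact (the data points)."""
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 1, 20))
        y = np.sin(3 * x) + rng.normal(0, 0.1, 20)
        np.savetxt(
            tmp_path / "xy.csv", np.c_[x, y], delimiter=",",
            header="x,y", comments="",
        )
        script = textwrap.dedent(
            """
            d <- read.csv('xy.csv')
            f <- loess(y ~ x, data=d, span=0.5, degree=2, surface='direct')
            write.csv(data.frame(fit=fitted(f)), 'fit.csv', row.names=FALSE)
            """
        )
        (tmp_path / "fit.R").write_text(script)
        subprocess.run(
            ["Rscript", "fit.R"], cwd=tmp_path, check=True, capture_output=True
        )
        oracle = np.loadtxt(tmp_path / "fit.csv", skiprows=1)
        mine = loess_fit(x, y, x, span=0.5, degree=2)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_monotone_gradient_yields_monotone_fit(self):
        """A noiseless sigmoidal profile smooths to a non-decreasing curve."""
        x = np.linspace(0, 1, 50)
        y = 1.0 / (1.0 + np.exp(-8 * (x - 0.5)))
        fit = loess_fit(x, y, np.linspace(0, 1, 100), span=0.5, degree=2)
        assert np.all(np.diff(fit) >= -1e-3)

    def test_too_few_points_for_degree(self):
        with pytest.raises(TooFewBins):
            loess_fit(np.array([0.0, 1.0]), np.array([1.0, 2.0]),
                      np.array([0.5]), degree=2)

    def test_smooth_profile_constant_feature(self):
        prof = bin_profile(
            {f"s{i}": p for i, p in enumerate(np.linspace(0, 1, 30))},
            {f"s{i}": 4.0 for i in range(30)},
            n_bins=10,
        )
        sm = smooth_profile(prof)
        np.testing.assert_allclose(sm.fitted, 4.0, atol=1e-9)
        assert np.all(np.diff(sm.grid) > 0)
        assert np.all(np.isfinite(sm.fitted))


class TestModuleScore:
    def test_single_gene_module_equals_that_gene(self):
        m = make_count_matrix([[1, 5], [2, 8], [0, 3]], gene_names=["A", "B"])
        scores = score_module(m, ["B"])
        np.testing.assert_allclose(list(scores.values()), [5, 8, 3])

    def test_duplicate_genes_count_once(self):
        m = make_count_matrix([[1, 5], [2, 8]], gene_names=["A", "B"])
        assert score_module(m, ["A", "B", "A"]) == score_module(m, ["A", "B"])

    def test_two_gene_module_is_row_mean(self):
        m = make_count_matrix([[1, 5], [2, 8], [0, 3]], gene_names=["A", "B"])
        scores = score_module(m, ["A", "B"])
        np.testing.assert_allclose(list(scores.values()), [3.0, 5.0, 1.5])

    def test_absent_genes_warn_and_are_listed(self):
        m = make_count_matrix([[1, 5]], gene_names=["A", "B"])
        with pytest.warns(UserWarning, match="ZZZ"):
            scores = score_module(m, ["A", "ZZZ"])
        np.testing.assert_allclose(list(scores.values()), [1.0])

    def test_fully_absent_module_raises(self):
        m = make_count_matrix([[1, 5]], gene_names=["A", "B"])
        with pytest.raises(EmptyModule):
            score_module(m, ["X", "Y"])


class TestNormalization:
    def test_median_library_log1p(self):
        m = make_count_matrix([[10, 0], [20, 20], [5, 5]])
        norm = normalize_counts(m)
        libs = np.array([10, 40, 10])
        expected = np.log1p(
            np.array([[10, 0], [20, 20], [5, 5]]) * (10.0 / libs)[:, None]
        )
        np.testing.assert_allclose(norm.dense(), expected)
        assert norm.kind == "normalized"

    def test_prenormalized_passthrough(self):
        m = make_count_matrix([[1.0, 2.0]])
        m.kind = "normalized"
        assert normalize_counts(m) is m
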