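"""Grids, personalised treatment effects, simultaneous bands and the
subgroup trichotomy, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import expit

import credsub as cs
from credsub.subgroups import _LogOddsPTE

from conftest import make_toy_pte
from oracles import band_oracle, bracket_oracle, classify_oracle, max_level_oracle

TABLE_GAMMA = np.array([-0.22, -0.19, -0.01, -0.07, 0.32])


def _ranges():
    return {"sf36_gh": (30.0, 60.0), "age": (45.0, 75.0), "hba1c": (5.5, 9.5)}


class TestMakeGrid:
    def test_point_count(self, identity_std):
        grid = cs.make_grid(identity_std, _ranges(), resolution=2)
        assert grid.m == 16  # 2 * 2**3

    def test_raw_values_within_ranges(self, small_design, small_cohort):
        cc, _ = cs.complete_cases(small_cohort)
        ranges = {
            name: (cc[name].min(), cc[name].max())
            for name in ("sf36_gh", "age", "hba1c")
        }
        grid = cs.make_grid(small_design.std, ranges, resolution=4)
        for name, (lo, hi) in ranges.items():
            vals = grid.raw[name]
            assert vals.min() >= lo - 1e-9 and vals.max() <= hi + 1e-9

    def test_point_at_means_is_standardized_origin(self, small_design):
        std = small_design.std
        ranges = {
            name: (std.center[name] - std.scale[name], std.center[name] + std.scale[name])
            for name in ("sf36_gh", "age", "hba1c")
        }
        grid = cs.make_grid(std, ranges, resolution=3)  # middle value = mean
        at_mean = np.isclose(grid.points[:, [1, 2, 4]], 0.0).all(axis=1)
        assert at_mean.sum() == 2  # one per sex
        np.testing.assert_allclose(grid.points[at_mean][:, [1, 2, 4]], 0.0, atol=1e-12)

    def test_errors(self, identity_std):
        with pytest.raises(ValueError):
            cs.make_grid(identity_std, _ranges(), resolution=1)
        with pytest.raises(ValueError):
            cs.make_grid(identity_std, {}, resolution=3)
        bad = dict(_ranges(), bmi=(20.0, 40.0))
        with pytest.raises(ValueError, match="unknown"):
            cs.make_grid(identity_std, bad, resolution=3)
        equal = dict(_ranges(), age=(50.0, 50.0))
        with pytest.raises(ValueError, match="equal"):
            cs.make_grid(identity_std, equal, resolution=3)

    def test_structure(self, identity_std):
        grid = cs.make_grid(identity_std, _ranges(), resolution=3)
        assert grid.is_factorial and grid.shape == (3, 3, 2, 3)
        assert np.all(grid.points[:, 0] == 1.0)
        assert set(np.unique(grid.points[:, 3])) == {0.0, 1.0}


class TestComputePTE:
    def _single_draw(self, gamma, beta=None):
        d = np.zeros((1, 10))
        d[0, 5:] = gamma
        if beta is not None:
            d[0, :5] = beta
        return cs.PosteriorDraws(draws=d)

    def test_zero_gamma_zero_effect(self, small_grid):
        draws = self._single_draw(np.zeros(5), beta=np.ones(5))
        for scale in ("log-odds", "risk-difference"):
            pte = cs.compute_pte(draws, small_grid, scale=scale)
            np.testing.assert_allclose(pte.values, 0.0)

    def test_log_odds_at_origin(self, identity_std):
        # female point at the standardized origin: delta = -gamma_0 = 0.22
        grid = cs.CovariateGrid(points=np.array([[1.0, 0.0, 0.0, 0.0, 0.0]]))
        pte = cs.compute_pte(self._single_draw(TABLE_GAMMA), grid)
        assert pte.values[0, 0] == pytest.approx(0.22)

    def test_log_odds_hba1c_plus_one_sd(self):
        grid = cs.CovariateGrid(points=np.array([[1.0, 0.0, 0.0, 0.0, 1.0]]))
        pte = cs.compute_pte(self._single_draw(TABLE_GAMMA), grid)
        assert pte.values[0, 0] == pytest.approx(0.22 - 0.32)

    def test_risk_difference_manual(self):
        beta = np.array([-2.0, 0.1, 0.2, 0.3, 0.4])
        z = np.array([1.0, 0.5, -0.5, 1.0, 0.2])
        grid = cs.CovariateGrid(points=z[None, :])
        pte = cs.compute_pte(
            self._single_draw(TABLE_GAMMA, beta=beta), grid, scale="risk-difference"
        )
        expected = expit(z @ beta) - expit(z @ beta + z @ TABLE_GAMMA)
        assert pte.values[0, 0] == pytest.approx(expected)

    def test_unknown_scale(self, short_draws, small_grid):
        with pytest.raises(ValueError):
            cs.compute_pte(short_draws, small_grid, scale="hazard")

    def test_blocks_consistent_with_values(self, small_pte):
        blocks = np.vstack(list(small_pte.iter_blocks(block_size=97)))
        # BLAS may round differently for different block shapes
        np.testing.assert_allclose(blocks, small_pte.values, rtol=1e-12, atol=1e-14)


class TestSimultaneousBand:
    def test_identical_draws_degenerate(self):
        pte = make_toy_pte(np.tile([0.5, -0.25], (6, 1)))
        band = cs.simultaneous_band(pte, 0.8)
        np.testing.assert_allclose(band.lower, band.mean)
        np.testing.assert_allclose(band.upper, band.mean)
        assert band.multiplier == 0.0

    def test_four_draw_toy_matches_enumeration(self):
        values = np.array([[0.1, 0.9], [0.4, 0.2], [-0.3, 0.5], [0.2, 0.6]])
        for level in (0.3, 0.5, 0.75, 0.9):
            band = cs.simultaneous_band(make_toy_pte(values), level)
            mean_o, sd_o, c_o = band_oracle(values, level)
            np.testing.assert_allclose(band.mean, mean_o)
            np.testing.assert_allclose(band.sd, sd_o)
            assert band.multiplier == c_o

    def test_level_near_one_gives_max(self):
        values = np.random.default_rng(0).normal(size=(4, 3))
        band = cs.simultaneous_band(make_toy_pte(values), 0.999)
        _, _, c_max = band_oracle(values, 0.999999)
        assert band.multiplier == c_max

    def test_streaming_block_size_invariance(self):
        values = np.random.default_rng(5).normal(size=(100, 50))
        a = cs.simultaneous_band(make_toy_pte(values), 0.8, block_size=7)
        b = cs.simultaneous_band(make_toy_pte(values), 0.8, block_size=10_000)
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.sd, b.sd)
        assert a.multiplier == b.multiplier

    def test_validation(self):
        pte = make_toy_pte(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            cs.simultaneous_band(pte, 1.0)
        with pytest.raises(ValueError):
            cs.simultaneous_band(make_toy_pte(np.zeros((1, 2))), 0.8)

    def test_band_ordering(self, small_pte):
        band = cs.simultaneous_band(small_pte, 0.8)
        assert np.all(band.lower <= band.mean + 1e-12)
        assert np.all(band.mean <= band.upper + 1e-12)


class TestClassify:
    def test_toy_band_rule(self):
        # (lower, upper): (0.1, 0.5), (-0.2, 0.3), (-0.6, -0.1)
        mean = np.array([0.3, 0.05, -0.35])
        sd = np.array([0.2, 0.25, 0.25])
        band = cs.SimultaneousBand(
            mean=mean, sd=sd, multiplier=1.0, level=0.8,
            floored=np.zeros(3, dtype=bool),
        )
        pair = cs.classify(band, 0.0)
        np.testing.assert_array_equal(pair.D, [True, False, False])
        np.testing.assert_array_equal(pair.S, [True, True, False])
        np.testing.assert_array_equal(pair.uncertainty, [False, True, False])
        np.testing.assert_array_equal(pair.S_complement, [False, False, True])

    def test_full_grid_D(self):
        band = cs.SimultaneousBand(
            mean=np.array([1.0, 2.0]), sd=np.array([0.1, 0.1]),
            multiplier=1.0, level=0.8, floored=np.zeros(2, dtype=bool),
        )
        pair = cs.classify(band, 0.0)
        assert pair.D.all() and not pair.uncertainty.any()

    def test_empty_S(self):
        band = cs.SimultaneousBand(
            mean=np.array([-1.0, -2.0]), sd=np.array([0.1, 0.1]),
            multiplier=1.0, level=0.8, floored=np.zeros(2, dtype=bool),
        )
        pair = cs.classify(band, 0.0)
        assert not pair.S.any() and pair.S_complement.all()

    def test_trichotomy_partition(self, small_pte):
        pair = cs.classify(cs.simultaneous_band(small_pte, 0.8))
        counts = pair.D.sum() + pair.uncertainty.sum() + pair.S_complement.sum()
        assert counts == small_pte.m
        assert not np.any(pair.D & ~pair.S)

    def test_region_labels(self):
        band = cs.SimultaneousBand(
            mean=np.array([0.3, 0.05, -0.35]), sd=np.array([0.2, 0.25, 0.25]),
            multiplier=1.0, level=0.8, floored=np.zeros(3, dtype=bool),
        )
        labels = cs.classify(band, 0.0).region_labels()
        assert list(labels) == ["D", "S\\D", "Sc"]


class TestBracketProbability:
    def test_vacuous_pair(self):
        values = np.random.default_rng(1).normal(size=(20, 4))
        pair = cs.CredibleSubgroupPair(
            D=np.zeros(4, dtype=bool), S=np.ones(4, dtype=bool),
            level=0.8, threshold=0.0,
        )
        assert cs.bracket_probability(make_toy_pte(values), pair) == 1.0

    def test_guarantee_at_construction_level(self, small_pte):
        for level in (0.5, 0.65, 0.8, 0.95):
            pair = cs.classify(cs.simultaneous_band(small_pte, level))
            assert cs.bracket_probability(small_pte, pair) >= level

    def test_four_draw_enumeration(self):
        values = np.array([[0.1, -0.9], [0.4, 0.2], [-0.3, 0.5], [0.2, 0.6]])
        pte = make_toy_pte(values)
        pair = cs.classify(cs.simultaneous_band(pte, 0.75))
        expected = bracket_oracle(values, pair.D, pair.S, 0.0)
        assert cs.bracket_probability(pte, pair) == expected

    def test_grid_mismatch(self, small_pte):
        pair = cs.CredibleSubgroupPair(
            D=np.zeros(3, dtype=bool), S=np.ones(3, dtype=bool),
            level=0.8, threshold=0.0,
        )
        with pytest.raises(ValueError):
            cs.bracket_probability(small_pte, pair)


class TestMaxCredibleLevel:
    def test_floored_positive_point_at_top(self):
        values = np.column_stack([np.ones(5), np.random.default_rng(0).normal(size=5)])
        surface = cs.max_credible_level(make_toy_pte(values), level_grid=[0.1, 0.5, 0.9])
        assert surface.values[0] == 0.9

    def test_floored_negative_point_at_bottom(self):
        values = np.column_stack([-np.ones(5), np.random.default_rng(0).normal(size=5)])
        surface = cs.max_credible_level(make_toy_pte(values), level_grid=[0.1, 0.5, 0.9])
        assert surface.values[0] == -0.9

    def test_symmetric_straddle_small_magnitude(self):
        values = np.array([[1.0, 0.3], [-1.0, 0.4]])
        surface = cs.max_credible_level(
            make_toy_pte(values), level_grid=np.arange(0.05, 1.0, 0.05)
        )
        assert abs(surface.values[0]) <= 0.5

    def test_four_draw_sweep_matches_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(4, 3))
        level_grid = np.arange(0.05, 1.0, 0.05)
        surface = cs.max_credible_level(make_toy_pte(values), level_grid=level_grid)
        expected = max_level_oracle(values, 0.0, level_grid)
        np.testing.assert_allclose(surface.values, expected)

    def test_consistency_with_classify(self, small_pte):
        level_grid = np.array([0.5, 0.65, 0.8, 0.95])
        surface = cs.max_credible_level(small_pte, level_grid=level_grid)
        for level in level_grid:
            pair = cs.classify(cs.simultaneous_band(small_pte, level))
            np.testing.assert_array_equal(surface.values >= level, pair.D)

    def test_empty_level_grid(self, small_pte):
        with pytest.raises(ValueError):
            cs.max_credible_level(small_pte, level_grid=[])


class TestInvariants:
    def test_nesting_across_levels(self, small_pte):
        levels = [0.5, 0.65, 0.8, 0.95]
        pairs = [cs.classify(cs.simultaneous_band(small_pte, lv)) for lv in levels]
        for lo, hi in zip(pairs[:-1], pairs[1:]):
            assert np.all(hi.D <= lo.D)  # D shrinks as level rises
            assert np.all(hi.S_complement <= lo.S_complement)

    def test_translation_equivariance(self, short_draws, small_grid):
        pte = cs.compute_pte(short_draws, small_grid)
        assert isinstance(pte, _LogOddsPTE)
        shift = 0.37
        pte_shifted = pte.shifted(shift)
        band = cs.simultaneous_band(pte, 0.8)
        band_s = cs.simultaneous_band(pte_shifted, 0.8)
        np.testing.assert_allclose(band_s.mean, band.mean - shift, atol=1e-12)
        np.testing.assert_allclose(band_s.lower, band.lower - shift, atol=1e-12)
        np.testing.assert_allclose(band_s.upper, band.upper - shift, atol=1e-12)
        assert band_s.multiplier == pytest.approx(band.multiplier, abs=1e-12)

    @given(
        values=hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(2, 10), st.integers(1, 5)),
            elements=st.floats(-5, 5, allow_nan=False, width=32),
        ),
        level=st.sampled_from([0.2, 0.5, 0.8, 0.95]),
        threshold=st.sampled_from([0.0, 0.1, -0.2]),
    )
    @settings(max_examples=150)
    def test_oracle_equivalence(self, values, level, threshold):
        pte = make_toy_pte(values, threshold=threshold)
        band = cs.simultaneous_band(pte, level)
        mean_o, sd_o, c_o = band_oracle(values, level)
        np.testing.assert_allclose(band.mean, mean_o)
        np.testing.assert_allclose(band.sd, sd_o)
        assert band.multiplier == c_o

        pair = cs.classify(band, threshold)
        d_o, s_o = classify_oracle(values, level, threshold)
        np.testing.assert_array_equal(pair.D, d_o)
        np.testing.assert_array_equal(pair.S, s_o)
        assert not np.any(pair.D & ~pair.S)

        prob = cs.bracket_probability(pte, pair)
        assert prob == bracket_oracle(values, pair.D, pair.S, threshold)
        assert prob >= level - 1e-12

        level_grid = [0.2, 0.5, 0.8, 0.95]
        surface = cs.max_credible_level(pte, threshold, level_grid)
        np.testing.assert_allclose(
            surface.values, max_level_oracle(values, threshold, level_grid)
        )


class TestApplyToCohort:
    def _grid(self, identity_std):
        ranges = {"sf36_gh": (0.0, 1.0), "age": (0.0, 1.0), "hba1c": (0.0, 1.0)}
        return cs.make_grid(identity_std, ranges, resolution=2)

    def _cohort(self, rows):
        return pd.DataFrame(
            rows, columns=["sf36_gh", "age", "sex", "hba1c"]
        ).assign(treatment=0.0, event=0.0)

    def test_all_subjects_at_single_D_point(self, identity_std):
        grid = self._grid(identity_std)
        D = np.zeros(16, dtype=bool)
        D[0] = True  # point (gh=0, age=0, sex=0, hba1c=0)
        pair = cs.CredibleSubgroupPair(
            D=D, S=np.ones(16, dtype=bool), level=0.8, threshold=0.0, grid=grid
        )
        cohort = self._cohort([[0.1, 0.2, 0.0, 0.1]] * 4)
        frac = cs.apply_to_cohort(pair, cohort, identity_std)
        assert frac == {"D": 1.0, "S\\D": 0.0, "Sc": 0.0}

    def test_empty_D_full_S(self, identity_std):
        grid = self._grid(identity_std)
        pair = cs.CredibleSubgroupPair(
            D=np.zeros(16, dtype=bool), S=np.ones(16, dtype=bool),
            level=0.8, threshold=0.0, grid=grid,
        )
        cohort = self._cohort([[0.9, 0.1, 1.0, 0.5], [0.0, 0.0, 0.0, 0.0]])
        frac = cs.apply_to_cohort(pair, cohort, identity_std)
        assert frac == {"D": 0.0, "S\\D": 1.0, "Sc": 0.0}

    def test_hand_mapped_fractions(self, identity_std):
        grid = self._grid(identity_std)
        # flat index order (gh, age, sex, hba1c), sizes (2, 2, 2, 2)
        D = np.zeros(16, dtype=bool)
        S = np.ones(16, dtype=bool)
        D[0b0000] = True        # (0,0,sex0,0) -> D
        S[0b1111] = False       # (1,1,sex1,1) -> Sc
        pair = cs.CredibleSubgroupPair(D=D, S=S, level=0.8, threshold=0.0, grid=grid)
        cohort = self._cohort(
            [
                [0.1, 0.1, 0.0, 0.2],   # nearest (0,0,0,0) -> D
                [0.4, 0.3, 0.0, 0.1],   # nearest (0,0,0,0) -> D
                [0.9, 0.9, 1.0, 0.8],   # nearest (1,1,1,1) -> Sc
                [0.9, 0.1, 1.0, 0.8],   # nearest (1,0,1,1) -> S\D
                [0.2, 0.9, 0.0, 0.9],   # nearest (0,1,0,1) -> S\D
            ]
        )
        frac = cs.apply_to_cohort(pair, cohort, identity_std)
        assert frac == {"D": 0.4, "S\\D": 0.4, "Sc": 0.2}
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_out_of_range_clipped_with_warning(self, identity_std, caplog):
        grid = self._grid(identity_std)
        pair = cs.CredibleSubgroupPair(
            D=np.zeros(16, dtype=bool), S=np.ones(16, dtype=bool),
            level=0.8, threshold=0.0, grid=grid,
        )
        cohort = self._cohort([[5.0, -3.0, 1.0, 0.5]])
        with caplog.at_level("WARNING"):
            frac = cs.apply_to_cohort(pair, cohort, identity_std)
        assert sum(frac.values()) == pytest.approx(1.0)
        assert any("outside the grid" in r.message for r in caplog.records)

    def test_incomplete_cohort_rejected(self, identity_std):
        grid = self._grid(identity_std)
        pair = cs.CredibleSubgroupPair(
            D=np.zeros(16, dtype=bool), S=np.ones(16, dtype=bool),
            level=0.8, threshold=0.0, grid=grid,
        )
        cohort = self._cohort([[0.1, np.nan, 0.0, 0.1]])
        with pytest.raises(ValueError):
            cs.apply_to_cohort(pair, cohort, identity_std)


class TestClassificationTable:
    def test_columns_and_values(self, small_pte, small_grid):
        band = cs.simultaneous_band(small_pte, 0.8)
        pair = cs.classify(band)
        surface = cs.max_credible_level(small_pte, level_grid=[0.5, 0.8])
        table = cs.classification_table(small_grid, band, pair, surface)
        assert len(table) == small_grid.m
        np.testing.assert_allclose(table["mean_effect"], band.mean)
        np.testing.assert_allclose(table["lower"], band.lower)
        np.testing.assert_allclose(table["upper"], band.upper)
        assert set(table["region"]) <= {"D", "S\\D", "Sc"}
        np.testing.assert_allclose(table["max_credible_level"], surface.values)
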