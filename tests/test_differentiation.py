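"""Reporter threshold logic, differentiation calls and movie alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagemotility import differentiation as diff
from lineagemotility.model import CellLife, FateLabel, Spot

from conftest import forest_from


def make_cell(cell_id, gfp, dt=2.0, label="M"):
    spots = [Spot(spot_id=f"{cell_id}_{i}", cell_id=cell_id, frame=i,
                  t_min=i * dt, pos=(0.0, 0.0, 0.0), gfp_raw=float(g))
             for i, g in enumerate(gfp)]
    return CellLife(cell_id=cell_id, spots=spots, generation_label=label)


class TestNormalize:
    def test_scales_by_movie_maximum(self, worked, worked_forest):
        diff.normalize_gfp(worked_forest, worked.meta)
        norms = [s.gfp_norm for c in worked_forest.cells.values() for s in c.spots]
        assert max(norms) == pytest.approx(1.0)
        assert min(norms) == pytest.approx(10.0 / 40.0)

    def test_all_equal_raws_normalise_to_one(self):
        from lineagemotility.model import LineageForest, MovieMeta
        cell = make_cell("c", [7.0, 7.0, 7.0])
        forest = LineageForest(cells={"c": cell}, movie_id="m")
        meta = MovieMeta(movie_id="m")
        diff.normalize_gfp(forest, meta)
        assert all(s.gfp_norm == pytest.approx(1.0) for s in cell.spots)

    def test_nonpositive_max_rejected(self):
        from lineagemotility.model import LineageForest, MovieMeta
        forest = LineageForest(cells={"c": make_cell("c", [0.0])}, movie_id="m")
        with pytest.raises(diff.DataError):
            diff.normalize_gfp(forest, MovieMeta(movie_id="m"))


class TestBackground:
    def test_midpoint_interpolation(self):
        bg = diff.fit_background([(0.0, 10.0), (100.0, 20.0)])
        assert bg.eval(50.0) == pytest.approx(15.0)

    def test_single_sample_constant(self):
        bg = diff.fit_background([(0.0, 7.0)])
        for t in (0.0, 55.5, 1e6):
            assert bg.eval(t) == pytest.approx(7.0)

    def test_constant_extrapolation_beyond_range(self):
        bg = diff.fit_background([(0.0, 10.0), (100.0, 20.0)])
        assert bg.eval(150.0) == pytest.approx(20.0)
        assert bg.eval(-50.0) == pytest.approx(10.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(diff.DataError):
            diff.fit_background([])


class TestThreshold:
    def test_multiplier_is_worst_endocardial_ratio(self):
        bg = diff.fit_background([(0.0, 10.0)])
        endo = make_cell("e", [9.0, 18.0, 12.0])  # max ratio 1.8
        thr = diff.find_threshold([endo], bg)
        assert thr.multiplier == pytest.approx(1.8, rel=1e-5)
        # by construction every endocardial spot is classified negative
        assert not any(thr.is_positive(s.gfp_raw, s.t_min) for s in endo.spots)

    def test_all_at_background_gives_multiplier_one(self):
        bg = diff.fit_background([(0.0, 10.0)])
        thr = diff.find_threshold([make_cell("e", [10.0, 10.0])], bg)
        assert thr.multiplier == pytest.approx(1.0, rel=1e-5)

    def test_zero_background_at_spot_rejected(self):
        bg = diff.fit_background([(0.0, 0.0)])
        with pytest.raises(diff.DataError):
            diff.find_threshold([make_cell("e", [1.0])], bg)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.0, 50.0))
    def test_raising_an_endocardial_intensity_never_lowers_m(self, bump):
        bg = diff.fit_background([(0.0, 10.0)])
        base = [9.0, 12.0, 11.0]
        m0 = diff.find_threshold([make_cell("e", base)], bg).multiplier
        bumped = [base[0] + bump] + base[1:]
        m1 = diff.find_threshold([make_cell("e", bumped)], bg).multiplier
        assert m1 >= m0 - 1e-12


class TestCalls:
    BG = diff.fit_background([(0.0, 10.0)])

    def test_never_crossing_returns_none(self):
        thr = diff.ThresholdModel(multiplier=1.5, background=self.BG)
        cell = make_cell("c", [10.0] * 20)
        assert diff.call_differentiation(cell, thr).t_diff_min is None

    def test_first_exceedance_time_on_two_minute_frames(self):
        thr = diff.ThresholdModel(multiplier=1.5, background=self.BG)
        gfp = [10.0] * 37 + [40.0] * 5
        cell = make_cell("c", gfp)
        assert diff.call_differentiation(cell, thr).t_diff_min == pytest.approx(74.0)

    def test_persistence_requires_consecutive_frames(self):
        thr = diff.ThresholdModel(multiplier=1.5, background=self.BG)
        gfp = [10, 40, 10, 40, 40, 40]
        cell = make_cell("c", gfp)
        call = diff.call_differentiation(cell, thr, persistence_frames=3)
        assert call.t_diff_min == pytest.approx(3 * 2.0)

    def test_inherited_positivity_excluded_when_required(self):
        thr = diff.ThresholdModel(multiplier=1.5, background=self.BG)
        born_positive = make_cell("c", [40.0] * 10)
        assert diff.call_differentiation(
            born_positive, thr, require_prior_negative=True).t_diff_min is None
        assert diff.call_differentiation(born_positive, thr).t_diff_min == 0.0

    def test_larger_multiplier_never_gives_earlier_call(self, rng):
        gfp = np.abs(rng.normal(15, 8, size=60))
        cell = make_cell("c", gfp)
        prev = -np.inf
        for m in (1.0, 1.5, 2.0, 3.0):
            thr = diff.ThresholdModel(multiplier=m, background=self.BG)
            t = diff.call_differentiation(cell, thr).t_diff_min
            t = np.inf if t is None else t
            assert t >= prev
            prev = t


class TestClassMeansAndAlignment:
    def test_mean_of_two_calls(self):
        from lineagemotility.model import LineageForest
        thr = diff.ThresholdModel(multiplier=1.5,
                                  background=diff.fit_background([(0.0, 10.0)]))
        c1 = make_cell("c1", [10.0] * 5 + [40.0] * 5)    # t_diff 10 min
        c2 = make_cell("c2", [10.0] * 10 + [40.0] * 5)   # t_diff 20 min
        for c in (c1, c2):
            c.fate = FateLabel.LV_AVC
        forest = LineageForest(cells={"c1": c1, "c2": c2}, movie_id="m")
        assert diff.mean_differentiation_time(
            forest, FateLabel.LV_AVC, thr) == pytest.approx(15.0)

    def test_empty_class_rejected(self):
        from lineagemotility.model import LineageForest
        thr = diff.ThresholdModel(multiplier=1.5,
                                  background=diff.fit_background([(0.0, 10.0)]))
        forest = LineageForest(cells={}, movie_id="m")
        with pytest.raises(diff.DataError):
            diff.mean_differentiation_time(forest, FateLabel.LV_AVC, thr)

    def test_identical_class_means_align_to_zero(self):
        means = {"a": {FateLabel.LV_AVC: 1200.0}, "b": {FateLabel.LV_AVC: 1200.0}}
        offsets = diff.align_movies(means, "a")
        assert offsets == {"a": 0.0, "b": 0.0}

    def test_alignment_translation_equivariance(self):
        base = {FateLabel.LV_AVC: 1200.0, FateLabel.ATRIAL: 1700.0}
        shifted = {f: t + 300.0 for f, t in base.items()}
        offsets = diff.align_movies({"ref": base, "late": shifted}, "ref")
        assert offsets["late"] == pytest.approx(-300.0)
        assert offsets["late"] % 2.0 == 0.0  # on the frame grid

    def test_disjoint_class_sets_rejected(self):
        means = {"a": {FateLabel.LV_AVC: 1200.0}, "b": {FateLabel.ATRIAL: 1700.0}}
        with pytest.raises(diff.DataError):
            diff.align_movies(means, "a")


class TestSyntheticRecovery:
    def test_threshold_recovers_configured_endocardial_margin(self, small_movie):
        forest = forest_from(small_movie)
        bg = diff.fit_background(small_movie.meta.background_samples)
        endo = [c for c in forest.cells.values()
                if c.fate is FateLabel.ENDOCARDIUM]
        thr = diff.find_threshold(endo, bg)
        assert thr.multiplier == pytest.approx(small_movie.truth["endo_margin"],
                                               rel=0.01)

    def test_constructed_shift_recovered_as_negative_offset(self):
        base = {FateLabel.LV_AVC: 1000.0, FateLabel.ATRIAL: 1500.0}
        moved = {f: t + 300.0 for f, t in base.items()}
        offsets = diff.align_movies({"ref": base, "m": moved}, "ref")
        assert offsets["m"] == pytest.approx(-300.0)
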