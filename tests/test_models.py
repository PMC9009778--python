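import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somaprf import (
    FWHM,
    HALF_WIDTH,
    FitOptions,
    conventional_field,
    fit_conventional,
    fit_nonrigid,
    goodness_of_fit,
    nonrigid_field,
    predict_timeseries,
    prf_center,
    prf_size,
    select_vertices,
)
from somaprf.models import condition_regressors


class TestNonRigidField:
    @pytest.mark.parametrize(
        "dx, expected",
        [(0.0, 1.0), (1.0, np.exp(-0.5)), (10.0, np.exp(-50.0))],
    )
    def test_gaussian_evaluation(self, dx, expected):
        g = nonrigid_field(np.full(18, dx))
        np.testing.assert_allclose(g, expected, rtol=1e-12)

    def test_field_is_effectively_zero_at_the_distance_bound(self):
        assert nonrigid_field(np.array([10.0]))[0] < 1e-21

    def test_out_of_bounds_distances_rejected(self):
        with pytest.raises(ValueError):
            nonrigid_field(np.array([-0.1]))
        with pytest.raises(ValueError):
            nonrigid_field(np.array([10.1]))


class TestPrediction:
    def test_zero_weights_give_zero_prediction(self, small_protocol):
        _, design, hrf, _ = small_protocol
        p = predict_timeseries(np.zeros(4), design, hrf)
        assert np.all(p == 0)

    def test_prediction_is_linear_in_the_weights(self, small_protocol):
        _, design, hrf, _ = small_protocol
        w = np.array([1.0, 0.3, 0.0, 0.7])
        np.testing.assert_allclose(
            predict_timeseries(2 * w, design, hrf),
            2 * predict_timeseries(w, design, hrf),
        )

    def test_single_event_prediction_is_the_shifted_hrf(self):
        """A one-volume event with unit weight reproduces the HRF kernel
        placed at the event volume."""
        from somaprf import EventSchedule, canonical_hrf, design_matrix

        events = pd.DataFrame(
            {"condition": [1], "onset": [10.0], "duration": [2.0],
             "interval": [10.0], "part": [1], "run": [1]}
        )
        sched = EventSchedule(events, 10.0, 14.7, 0)
        design = design_matrix(sched, volumes_per_run=(40,), tr=2.0, boxcar=2.0,
                               n_conditions=1)
        hrf = canonical_hrf(tr=2.0, duration=30.0)
        p = predict_timeseries(np.array([1.0]), design, hrf)
        assert np.all(p[:5] == 0)
        np.testing.assert_allclose(p[5 : 5 + len(hrf.values)], hrf.values)

    def test_convolution_restarts_at_run_boundaries(self, protocol):
        """No hemodynamic response leaks from one scanner run into the next."""
        _, design, hrf, C = protocol
        for sl in design.run_slices():
            seg = design.s[:, sl]
            first_event = np.flatnonzero(seg.sum(axis=0))[0]
            assert np.all(C[sl][:first_event] == 0)

    def test_tr_mismatch_rejected(self, protocol):
        from somaprf import canonical_hrf

        _, design, _, _ = protocol
        with pytest.raises(ValueError, match="tr"):
            condition_regressors(design, canonical_hrf(tr=1.0))


class TestPRFCenter:
    def test_unique_minimum(self):
        dx = np.full(18, 10.0)
        dx[0], dx[1], dx[2] = 3.0, 0.2, 5.0
        assert prf_center(dx) == 2

    def test_tie_resolves_to_floored_mean_index(self):
        dx = np.full(18, 10.0)
        dx[2] = dx[5] = 0.0  # parts 3 and 6
        assert prf_center(dx) == 4

    def test_all_equal_gives_floor_of_mean_index(self):
        assert prf_center(np.full(18, 2.0)) == 9

    def test_near_tie_within_tolerance_counts_as_tie(self):
        dx = np.full(18, 10.0)
        dx[2], dx[5] = 0.0, 1e-8
        assert prf_center(dx, tie_tol=1e-6) == 4
        assert prf_center(dx, tie_tol=1e-10) == 3


class TestPRFSize:
    def test_single_center_part_is_one_body_part_worth(self):
        dx = np.full(18, 10.0)
        dx[4] = 0.0
        np.testing.assert_allclose(prf_size(dx), HALF_WIDTH)

    def test_maximal_field_counts_all_18_parts(self):
        np.testing.assert_allclose(prf_size(np.zeros(18)), 18 * HALF_WIDTH)

    def test_hand_computed_two_part_field(self):
        dx = np.full(18, 10.0)
        dx[0], dx[1] = 0.0, 1.0
        np.testing.assert_allclose(prf_size(dx), (1.0 + 0.9) * HALF_WIDTH)

    def test_parts_beyond_half_window_do_not_count(self):
        dx = np.full(18, 10.0)
        dx[0], dx[1] = 0.0, HALF_WIDTH + 1e-9
        np.testing.assert_allclose(prf_size(dx), HALF_WIDTH)

    @settings(max_examples=200, deadline=None)
    @given(
        dx=st.lists(st.floats(0.0, 10.0), min_size=18, max_size=18),
        i=st.integers(0, 17),
        outward=st.floats(0.0, 5.0),
    )
    def test_moving_a_part_outward_never_increases_size(self, dx, i, outward):
        dx = np.asarray(dx)
        moved = dx.copy()
        moved[i] = min(10.0, moved[i] + outward)
        assert prf_size(moved) <= prf_size(dx) + 1e-12


class TestGoodnessOfFit:
    def test_perfect_prediction_gives_unit_r2(self):
        y = np.sin(np.linspace(0, 8, 100))
        f, p, r2 = goodness_of_fit(y, y, 19)
        assert r2 == 1.0 and p == 0.0

    def test_hand_computed_f_statistic(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.0, 2.0, 3.0, 0.0])
        # ss_tot=30, sse=16, df=(1, 3): F = ((30-16)/1)/(16/3)
        f, p, r2 = goodness_of_fit(y, pred, 1)
        np.testing.assert_allclose(f, 14.0 / (16.0 / 3.0))
        np.testing.assert_allclose(r2, 1 - 16.0 / 30.0)

    def test_zero_variance_is_degenerate(self):
        f, p, r2 = goodness_of_fit(np.zeros(50), np.zeros(50), 5)
        assert (f, p, r2) == (0.0, 1.0, 0.0)

    def test_too_many_parameters_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(10), np.ones(10), 10)


class TestFitNonRigid:
    def test_noiseless_roundtrip_recovers_center_and_variance(self, small_protocol):
        _, design, hrf, C = small_protocol
        rng = np.random.default_rng(3)
        for _ in range(5):
            dx_true = rng.uniform(0.0, 4.0, 4)
            dx_true[rng.integers(4)] = 0.0
            y = 1.4 * (C @ nonrigid_field(dx_true))
            fit = fit_nonrigid(y, design, hrf, regressors=C)
            assert fit.center == prf_center(dx_true)
            assert fit.r2 >= 0.999

    def test_scale_equivariance(self, small_protocol):
        _, design, hrf, C = small_protocol
        dx_true = np.array([0.0, 1.5, 3.0, 4.5])
        y = C @ nonrigid_field(dx_true)
        a = fit_nonrigid(y, design, hrf, regressors=C)
        b = fit_nonrigid(3.0 * y, design, hrf, regressors=C)
        np.testing.assert_allclose(b.beta, 3.0 * a.beta, rtol=1e-4)
        np.testing.assert_allclose(b.dx[:2], a.dx[:2], atol=1e-3)

    def test_constant_timeseries_is_flagged_degenerate(self, small_protocol):
        _, design, hrf, _ = small_protocol
        fit = fit_nonrigid(np.zeros(design.n_volumes), design, hrf)
        assert fit.degenerate and fit.r2 == 0.0 and fit.p_value == 1.0

    def test_fitted_distances_respect_bounds_exactly(self, small_protocol):
        _, design, hrf, C = small_protocol
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.normal(0, 1, design.n_volumes)
            fit = fit_nonrigid(y, design, hrf, regressors=C)
            assert np.all(fit.dx >= 0.0) and np.all(fit.dx <= 10.0)

    def test_multi_start_matches_exhaustive_grid_search(self, small_protocol):
        """On the tiny 4-condition problem the fit's SSE must not exceed the
        best profiled-amplitude SSE over the full 0.25-step distance lattice."""
        _, design, hrf, C = small_protocol
        rng = np.random.default_rng(11)
        grid = np.arange(0.0, 10.0 + 1e-9, 0.25)
        G = np.exp(-0.5 * np.stack(np.meshgrid(grid, grid, grid, grid,
                                               indexing="ij"), -1).reshape(-1, 4) ** 2)
        P = G @ C.T  # (lattice, T)
        pp = np.einsum("ij,ij->i", P, P)
        for _ in range(3):
            dx_true = rng.uniform(0, 5, 4)
            y = C @ nonrigid_field(dx_true) + rng.normal(0, 0.5, C.shape[0])
            py = P @ y
            with np.errstate(invalid="ignore", divide="ignore"):
                sse_grid = float(np.nanmin(y @ y - py**2 / pp))
            fit = fit_nonrigid(y, design, hrf, regressors=C)
            assert fit.sse <= sse_grid + 1e-6 * (y @ y)

    def test_infinite_input_rejected(self, small_protocol):
        _, design, hrf, _ = small_protocol
        y = np.zeros(design.n_volumes)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_nonrigid(y, design, hrf)


class TestFitConventional:
    def test_noiseless_parameter_recovery(self, protocol):
        _, design, hrf, C = protocol
        y = 1.2 * (C @ conventional_field(7.0, 1.5))
        fit = fit_conventional(y, design, hrf, regressors=C)
        assert abs(fit.x0 - 7.0) < 0.05
        assert abs(fit.sigma - 1.5) < 0.05

    def test_single_condition_response_centers_on_that_part(self, protocol):
        _, design, hrf, C = protocol
        y = C[:, 11].copy()  # respond to the thumb only
        fit = fit_conventional(y, design, hrf, regressors=C)
        assert abs(fit.x0 - 12.0) < 0.5

    def test_symmetric_response_centers_midway(self, protocol):
        _, design, hrf, C = protocol
        w = np.zeros(18)
        w[7], w[8], w[9] = 0.7, 1.0, 0.7  # symmetric profile around part 9
        y = C @ w
        fit = fit_conventional(y, design, hrf, regressors=C)
        assert abs(fit.x0 - 9.0) < 0.2


class TestSelectVertices:
    def test_all_ones_select_nothing(self):
        assert not select_vertices(np.ones(10), 0.05).any()

    def test_hand_worked_benjamini_hochberg_example(self):
        mask = select_vertices(np.array([0.001, 0.02, 0.9]), 0.05)
        assert mask.tolist() == [True, True, False]

    def test_empty_input_gives_empty_mask(self):
        assert select_vertices(np.array([]), 0.05).size == 0

    def test_null_selection_fraction_stays_below_q(self, rng):
        fracs = [
            select_vertices(rng.uniform(0, 1, 200), 0.05).mean()
            for _ in range(200)
        ]
        assert np.mean(fracs) <= 0.05 + 0.01


class TestModelConsistency:
    def test_nonrigid_and_conventional_centers_agree_on_ordered_fields(
        self, protocol, rng
    ):
        """On synthetic vertices whose fields follow the homunculus ordering
        the two models' center maps correlate strongly (R >= 0.8)."""
        from scipy.stats import pearsonr

        from somaprf import SyntheticConfig, make_somatotopic_ground_truth
        from somaprf import simulate_vertex_timeseries

        _, design, hrf, C = protocol
        cfg = SyntheticConfig(
            rois={"M1": __import__("somaprf").RoiProfile(1.5)},
            vertices_per_roi=30,
            n_subjects=1,
        )
        truth = make_somatotopic_ground_truth(cfg, seed=21)
        Y = simulate_vertex_timeseries(truth, design, hrf, noise_sd=0.4, seed=22)
        nr, cv = [], []
        for v in range(Y.shape[0]):
            nr.append(fit_nonrigid(Y[v], design, hrf, regressors=C).center)
            cv.append(fit_conventional(Y[v], design, hrf, regressors=C).x0)
        r, _ = pearsonr(nr, cv)
        assert r >= 0.8
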