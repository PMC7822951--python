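"""Trace linking, frame filtering, z estimation and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from simpler_tirf import (
    IlluminationProfile,
    correct_illumination,
    distortion_alpha,
    frame_filter,
    gaussian_illumination,
    link_traces,
    mislocalization_n0,
    trace_z_statistics,
    z_estimate,
    z_precision,
)

D_F, ALPHA_F, N0 = 87.5, 0.93, 10000.0


def _table(rows):
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons"])


class TestLinkTraces:
    def test_stationary_molecule_forms_one_trace(self):
        table = _table([(f, 0.0, 0.0, 1000.0) for f in range(1, 6)])
        traces = link_traces(table)
        assert len(traces) == 1
        assert list(traces.table["trace_id"]) == [0] * 5
        traces.validate()

    def test_simultaneous_molecules_do_not_cross_link(self):
        rows = []
        for f in range(3):
            rows.append((f, 0.0, 0.0, 1000.0))
            rows.append((f, 100.0, 0.0, 1000.0))
        traces = link_traces(_table(rows), radius_nm=20.0)
        assert len(traces) == 2
        lengths = traces.lengths()
        assert sorted(lengths) == [3, 3]
        traces.validate()

    def test_gap_frame_breaks_the_trace(self):
        table = _table([(0, 0.0, 0.0, 1.0), (1, 0.0, 0.0, 1.0), (3, 0.0, 0.0, 1.0)])
        traces = link_traces(table)
        assert len(traces) == 2

    def test_sparse_scatter_yields_singletons(self, rng):
        """Random single detections far sparser than the linking radius:
        every trace has length 1, verified against a brute-force
        all-pairs distance check."""
        n = 200
        table = _table([
            (f, x, y, 1000.0)
            for f, x, y in zip(
                rng.integers(0, 50, n),
                rng.uniform(0, 50000.0, n),
                rng.uniform(0, 50000.0, n),
            )
        ])
        traces = link_traces(table, radius_nm=20.0)
        # brute force: count pairs in consecutive frames within the radius
        xy = table[["x_nm", "y_nm"]].to_numpy()
        fr = table["frame"].to_numpy()
        expected_links = 0
        for i in range(n):
            for j in range(n):
                if fr[j] == fr[i] + 1:
                    if np.sum((xy[i] - xy[j]) ** 2) < 400.0:
                        expected_links += 1
        assert expected_links == 0
        assert len(traces) == n

    def test_nearest_candidate_wins(self):
        table = _table([
            (0, 0.0, 0.0, 1.0),
            (1, 5.0, 0.0, 1.0),   # nearer successor
            (1, 15.0, 0.0, 1.0),  # farther, starts a new trace
        ])
        traces = link_traces(table, radius_nm=20.0)
        ids = traces.table["trace_id"].to_numpy()
        assert ids[0] == ids[1]
        assert ids[2] != ids[0]

    def test_empty_table(self):
        traces = link_traces(_table([]))
        assert len(traces) == 0


class TestFrameFilter:
    @pytest.mark.parametrize("length,kept", [(5, 3), (4, 2), (3, 1), (2, 0), (1, 0)])
    def test_first_and_last_frames_dropped(self, length, kept):
        table = _table([(f, 0.0, 0.0, float(f)) for f in range(length)])
        out = frame_filter(link_traces(table))
        assert len(out) == kept
        if kept:
            # exactly the interior frames survive
            assert list(out["frame"]) == list(range(1, length - 1))

    def test_conservation_kept_plus_dropped(self, rng):
        rows = []
        x = 0.0
        for trace in range(20):
            length = int(rng.integers(1, 8))
            start = int(rng.integers(0, 1000))
            x += 1000.0
            rows += [(start + k, x, 0.0, 1.0) for k in range(length)]
        table = _table(rows)
        traces = link_traces(table)
        out = frame_filter(traces)
        lengths = traces.lengths()
        expected = int(sum(max(n - 2, 0) for n in lengths))
        assert len(out) == expected
        assert len(out) + (len(table) - expected) == len(table)


class TestIlluminationCorrection:
    def test_uniform_profile_is_identity(self):
        table = _table([(0, 0.0, 0.0, 500.0), (1, 10.0, 5.0, 700.0)])
        out = correct_illumination(table, IlluminationProfile(kind="flat"))
        assert np.allclose(out["photons"], table["photons"])

    def test_half_intensity_doubles_counts(self):
        profile = gaussian_illumination(sigma_nm=1000.0)
        r = 1000.0 * np.sqrt(2.0 * np.log(2.0))  # P = 0.5 at this radius
        table = _table([(0, r, 0.0, 500.0)])
        out = correct_illumination(table, profile)
        assert out["photons"][0] == pytest.approx(1000.0, rel=1e-12)

    def test_nonpositive_profile_flags_record(self):
        img = np.zeros((4, 4))
        img[0, 0] = 1.0
        profile = IlluminationProfile(kind="image", image=img, pixel_size_nm=100.0)
        table = _table([(0, 350.0, 350.0, 500.0)])
        out = correct_illumination(table, profile)
        assert not out["valid"][0]


class TestZEstimate:
    def test_full_signal_maps_to_interface(self):
        assert z_estimate(N0, N0, D_F, ALPHA_F) == pytest.approx(0.0)

    def test_one_decay_constant(self):
        n = N0 * (ALPHA_F * np.exp(-1.0) + (1 - ALPHA_F))
        assert z_estimate(n, N0, D_F, ALPHA_F) == pytest.approx(D_F)

    def test_reference_ratio_maps_to_250nm(self):
        assert z_estimate(0.12341 * N0, N0, D_F, ALPHA_F) == pytest.approx(
            250.0, abs=0.1
        )

    @given(z=hst.floats(0.0, 400.0))
    @settings(max_examples=200, deadline=None)
    def test_algebraic_round_trip(self, z):
        n = N0 * (ALPHA_F * np.exp(-z / D_F) + (1 - ALPHA_F))
        assert z_estimate(n, N0, D_F, ALPHA_F) == pytest.approx(z, abs=1e-9)

    def test_monotone_decreasing_in_photons(self):
        n = np.linspace(0.8 * N0, 1.2 * N0, 50)
        z = z_estimate(n, N0, D_F, ALPHA_F)
        assert np.all(np.diff(z) < 0)

    def test_below_asymptote_is_nan(self):
        assert np.isnan(z_estimate(0.9 * (1 - ALPHA_F) * N0, N0, D_F, ALPHA_F))

    def test_above_n0_gives_negative_z(self):
        assert z_estimate(1.05 * N0, N0, D_F, ALPHA_F) < 0.0


class TestZPrecision:
    def test_zero_uncertainties_give_zero(self):
        assert z_precision(N0, N0, D_F, ALPHA_F, 0.0, 0.0) == pytest.approx(0.0)

    def test_shot_noise_at_interface(self):
        s = z_precision(N0, N0, D_F, ALPHA_F, np.sqrt(N0), 0.0)
        assert s == pytest.approx(0.941, abs=0.002)

    def test_range_end_with_calibration_uncertainty(self):
        n = N0 * (ALPHA_F * np.exp(-250.0 / D_F) + (1 - ALPHA_F))
        s = z_precision(n, N0, D_F, ALPHA_F, np.sqrt(n), 1.0)
        assert s == pytest.approx(6.4, abs=0.1)
        assert s <= 10.0


class TestSensitivity:
    def test_zero_n0_error_bounded_by_approximation_gap(self, paper_response):
        dz = mislocalization_n0(np.array([0.0, 100.0, 200.0]), 0.0, paper_response)
        assert np.all(np.abs(dz) < 0.01)
        dz_approx = mislocalization_n0(100.0, 0.0, paper_response, pathway="approx")
        assert abs(dz_approx) < 1.0

    def test_overestimated_n0_biases_z_up(self, paper_response):
        dz = mislocalization_n0(np.array([0.0, 150.0, 250.0]), 0.10, paper_response)
        assert np.all(dz > 0)
        assert np.all(np.diff(dz) > 0)  # grows with z

    def test_underestimate_mirrors_overestimate(self, paper_response):
        up = mislocalization_n0(100.0, 0.10, paper_response)
        down = mislocalization_n0(100.0, -0.10, paper_response)
        assert np.sign(up) != np.sign(down)

    def test_matched_alpha_has_no_distortion(self, paper_config, paper_response):
        d = distortion_alpha(
            150.0, 0.9, 0.9, paper_config, response_true=paper_response
        )
        assert d.accumulated_nm < 0.05

    def test_distortion_grows_with_range_and_mismatch(
        self, paper_config, paper_response
    ):
        d_small = distortion_alpha(
            150.0, 0.9, 0.89, paper_config, response_true=paper_response
        )
        d_large = distortion_alpha(
            150.0, 0.9, 0.88, paper_config, response_true=paper_response
        )
        d_deep = distortion_alpha(
            250.0, 0.9, 0.88, paper_config, response_true=paper_response
        )
        assert d_small.accumulated_nm < d_large.accumulated_nm
        assert d_large.accumulated_nm < d_deep.accumulated_nm

    def test_alpha_out_of_range_rejected(self, paper_config, paper_response):
        with pytest.raises(ValueError, match="alpha"):
            distortion_alpha(150.0, 0.9, 1.5, paper_config,
                             response_true=paper_response)


class TestTraceStatistics:
    def test_noiseless_trace_has_zero_spread(self):
        df = pd.DataFrame({
            "trace_id": [0] * 4,
            "z_nm": [100.0] * 4,
            "photons": [5000.0] * 4,
        })
        out = trace_z_statistics(df)
        assert len(out) == 1
        assert out["sigma_z_emp_nm"][0] == pytest.approx(0.0)
        assert out["sigma_n_sqrtn"][0] == pytest.approx(0.0)

    def test_short_traces_excluded(self):
        df = pd.DataFrame({
            "trace_id": [0, 0, 1, 1, 1],
            "z_nm": [1.0, 2.0, 3.0, 4.0, 5.0],
            "photons": [10.0] * 5,
        })
        out = trace_z_statistics(df, min_records=3)
        assert list(out["trace_id"]) == [1]

    def test_sigma_n_estimator_centred_near_truth(self, rng):
        """std(N)/sqrt(mean N) over 3-frame traces: centred near the
        generating c = 5 with the documented small-sample bias."""
        c, n_mean, n_traces = 5.0, 20000.0, 4000
        rows = []
        for t in range(n_traces):
            n = rng.normal(n_mean, c * np.sqrt(n_mean), 3)
            rows += [{"trace_id": t, "z_nm": 0.0, "photons": v} for v in n]
        out = trace_z_statistics(pd.DataFrame(rows))
        med = out["sigma_n_sqrtn"].median()
        # 3-sample std underestimates; expect within ~20% below c
        assert 0.8 * c < med < 1.05 * c
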