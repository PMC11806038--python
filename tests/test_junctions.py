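import numpy as np
import pandas as pd
import pytest

from wingshear.junctions import (classify_junction, gradient_stability_correlation,
                                 normalized_density_in_cell, percent_change,
                                 sliding_junction_stability, stable_fraction,
                                 t1_accumulation_profile)
from wingshear.mesh import detect_sliding_junctions, detect_t1_events
from wingshear.synthetic import simulate_scene


class TestClassify:
    def test_pd_band(self):
        assert classify_junction(10.0, 0.0, "PD") == "horizontal"
        assert classify_junction(80.0, 0.0, "PD") == "vertical"

    def test_boundary_goes_to_otherwise(self):
        assert classify_junction(45.0, 0.0, "PD") == "vertical"
        assert classify_junction(45.0, 0.0, "AP") == "horizontal"

    def test_ap_swap(self):
        assert classify_junction(10.0, 0.0, "AP") == "vertical"
        assert classify_junction(80.0, 0.0, "AP") == "horizontal"

    def test_relative_to_flow(self):
        assert classify_junction(40.0, 30.0, "PD") == "horizontal"
        assert classify_junction(40.0, -30.0, "PD") == "vertical"

    def test_partition(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-90, 90, 500)
        classes = classify_junction(angles, 17.0, "PD")
        assert set(classes) <= {"horizontal", "vertical"}
        assert len(classes) == 500


def junction_rows(specs):
    rows = []
    for i, (m1, m2, s1, s2) in enumerate(specs):
        rows.append({"frame": 0, "junction_id": i, "cell_a": 1, "cell_b": 2 + i,
                     "mean_ch1": m1, "mean_ch2": m2, "sum_ch1": s1, "sum_ch2": s2})
    return pd.DataFrame(rows)


class TestStableFraction:
    def test_proportional_channels_all_scopes(self):
        c = 0.5
        df = junction_rows([(10, 10 * c, 40, 40 * c), (25, 25 * c, 75, 75 * c)])
        assert stable_fraction(df, scope="wing") == pytest.approx(c)
        df["class"] = ["horizontal", "vertical"]
        assert all(v == pytest.approx(c)
                   for v in stable_fraction(df, scope="class").values())
        np.testing.assert_allclose(stable_fraction(df, scope="junction"), c)

    def test_pooled_ratio_not_mean_of_ratios(self):
        # sums (mKate, sfGFP) = (10, 20) and (30, 40): pooled 40/60
        df = junction_rows([(2, 1, 20, 10), (4, 3, 40, 30)])
        assert stable_fraction(df) == pytest.approx(40.0 / 60.0)
        mean_of_ratios = np.mean([10 / 20, 30 / 40])
        assert stable_fraction(df) != pytest.approx(mean_of_ratios)

    def test_subdivision_invariance(self):
        whole = junction_rows([(10, 4, 100, 40)])
        halves = junction_rows([(10, 4, 60, 24), (10, 4, 40, 16)])
        assert stable_fraction(whole) == pytest.approx(stable_fraction(halves))

    def test_zero_denominator(self):
        df = junction_rows([(0, 5, 0, 5)])
        with pytest.raises(ValueError, match="zero sfGFP"):
            stable_fraction(df)


class TestPercentChange:
    def test_examples(self):
        assert percent_change(100.0, 150.0) == pytest.approx(50.0)
        assert percent_change(0.50, 0.38) == pytest.approx(-24.0)
        assert percent_change(7.0, 7.0) == 0.0

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    def test_unit_invariance(self):
        assert percent_change(2.0, 3.0) == percent_change(2000.0, 3000.0)


def _new_junction_track(frames, i0, ramp_per_min=0.0, interval=15.0,
                        angle=0.0, l0=1.0):
    rows = []
    for k, t in enumerate(frames):
        rows.append({
            "frame": t, "junction_id": 7, "cell_a": 3, "cell_b": 4,
            "mean_ch1": i0 * (1 + ramp_per_min * k * interval),
            "mean_ch2": 0.0, "sum_ch1": 1.0, "sum_ch2": 0.0,
            "length_um": l0, "angle_deg": angle, "deg_v1": 3, "deg_v2": 3,
        })
    return pd.DataFrame(rows)


def _t1_event():
    return pd.DataFrame([{
        "event_id": 0, "cell_a": 1, "cell_b": 2, "cell_c": 3, "cell_d": 4,
        "frame_lost": 2, "frame_gained": 2, "ambiguous": False,
    }])


class TestT1Profile:
    def test_constant_density_flat(self):
        jt = _new_junction_track(range(2, 10), i0=50.0)
        prof = t1_accumulation_profile(_t1_event(), jt)
        assert np.allclose(prof["mean_pct_density"], 0.0)

    def test_linear_ramp(self):
        # I(t) = I0 (1 + 0.01 t_min) -> +90% at 90 min
        jt = _new_junction_track(range(2, 10), i0=50.0, ramp_per_min=0.01)
        prof = t1_accumulation_profile(_t1_event(), jt)
        at90 = prof[prof["t_min"] == 90.0]["mean_pct_density"].iloc[0]
        assert at90 == pytest.approx(90.0)

    def test_lost_junction_excluded(self):
        jt = _new_junction_track([2], i0=50.0)  # gone before first post frame
        prof = t1_accumulation_profile(_t1_event(), jt)
        assert len(prof) == 0 and prof.attrs["n_excluded"] == 1

    def test_orientation_ordering_from_generator(self):
        # per-class accumulation: vertical junctions painted brighter under a
        # polarity axis along the flow -> class profiles keep their ordering
        scene = simulate_scene(preset="shear", rows=10, cols=10, n_frames=9,
                               seed=31, n_t1=4, beta=20.0,
                               polarity_magnitude=0.3)
        ev = detect_t1_events(scene.adjacency)
        prof = t1_accumulation_profile(ev, scene.junctions, theta_flow_deg=0.0)
        assert set(prof["class"]) <= {"horizontal", "vertical"}
        assert (prof["n"] > 0).all()


class TestSlidingStability:
    def test_no_change_zero(self):
        scene = simulate_scene(preset="uniform", rows=8, cols=8, n_frames=4,
                               seed=32, n_sliding=3, sliding_effect_pct=0.0)
        ev, ctrl = detect_sliding_junctions(scene.junctions)
        res = sliding_junction_stability(ev, scene.junctions, ctrl)
        assert np.allclose(res["pct_stability"], 0.0, atol=1e-9)

    def test_mkate_only_reduction_recovered(self):
        scene = simulate_scene(preset="uniform", rows=12, cols=12, n_frames=5,
                               seed=33, n_sliding=8, sliding_effect_pct=-30.0,
                               polarity_magnitude=0.0)
        ev, ctrl = detect_sliding_junctions(scene.junctions)
        res = sliding_junction_stability(ev, scene.junctions, ctrl)
        slid = res[res["group"] == "sliding"]
        control = res[res["group"] == "control"]
        assert slid["pct_stability"].mean() == pytest.approx(-30.0, abs=1e-6)
        assert control["pct_stability"].mean() == pytest.approx(0.0, abs=1e-6)
        # the reduction is in the slow channel only
        assert slid["pct_ch2"].mean() == pytest.approx(-30.0, abs=1e-6)
        assert abs(slid["pct_ch1"].mean()) < 1e-6

    def test_global_gain_invariance(self):
        scene = simulate_scene(preset="uniform", rows=8, cols=8, n_frames=4,
                               seed=34, n_sliding=3, sliding_effect_pct=-20.0)
        ev, ctrl = detect_sliding_junctions(scene.junctions)
        base = sliding_junction_stability(ev, scene.junctions, ctrl)
        scaled = scene.junctions.copy()
        for col in ("mean_ch1", "mean_ch2", "sum_ch1", "sum_ch2"):
            scaled[col] *= 3.7
        res = sliding_junction_stability(ev, scaled, ctrl)
        np.testing.assert_allclose(res["pct_stability"], base["pct_stability"])


class TestNormalizedDensity:
    def test_equal_intensities(self):
        assert normalized_density_in_cell(10.0, [10.0, 10.0, 10.0]) == 1.0

    def test_dimmer_than_siblings(self):
        assert normalized_density_in_cell(50.0, [100.0, 100.0]) == 0.5

    def test_gain_invariance(self):
        a = normalized_density_in_cell(50.0, [100.0, 80.0])
        b = normalized_density_in_cell(500.0, [1000.0, 800.0])
        assert a == pytest.approx(b)

    def test_needs_siblings(self):
        with pytest.raises(ValueError):
            normalized_density_in_cell(1.0, [2.0])


class TestCorrelation:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r2 = gradient_stability_correlation(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        _, _, r2 = gradient_stability_correlation(x, np.ones(4))
        assert r2 == pytest.approx(0.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            gradient_stability_correlation([1, 2], [1, 2])

    def test_noise_calibrated_r2(self):
        # analytic setup: for S = a + b g + eps with eps sigma chosen so the
        # explained variance fraction is 0.7, the sample R^2 across 20 seeds
        # stays within +/-0.15 of 0.7 on average
        g = np.linspace(0.002, 0.02, 8)
        b, a = -7.0, 0.55
        sigma = abs(b) * g.std() * np.sqrt(0.3 / 0.7)
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = a + b * g + rng.normal(0, sigma, g.size)
            _, _, r2 = gradient_stability_correlation(g, s)
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx(0.7, abs=0.15)
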