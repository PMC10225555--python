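import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcscreen.dose_response import four_param_logistic
from hcscreen.errors import LayoutError, PlacementError
from hcscreen.synthetic_data import (
    FieldImageSpec,
    GroundTruth,
    PlateLayout,
    ScreenScenario,
    render_field,
    simulate_dose_series,
    simulate_flow,
    simulate_qpcr,
    simulate_screen,
)
from hcscreen.validation_assays import rq_ddct


class TestScenarioValidation:
    def test_defaults_valid(self):
        ScreenScenario()

    def test_hits_plus_toxic_must_fit(self):
        with pytest.raises(ValueError):
            ScreenScenario(n_extracts=10, n_true_hits=6, n_cytotoxic=5)

    def test_pos_mean_below_neg_rejected(self):
        with pytest.raises(ValueError):
            ScreenScenario(neg_mean=500.0, pos_mean=100.0)

    def test_hit_effect_must_exceed_threshold(self):
        with pytest.raises(ValueError):
            ScreenScenario(n_true_hits=2, hit_effect=35.0)

    def test_hit_effect_sequence_length_checked(self):
        with pytest.raises(ValueError):
            ScreenScenario(n_true_hits=3, hit_effect=(50.0, 60.0))

    def test_json_round_trip(self):
        s = ScreenScenario(n_true_hits=2, hit_effect=(45.0, 55.0), seed=9)
        assert ScreenScenario.from_json(s.to_json()) == s


class TestSimulateScreen:
    def test_full_library_layout(self):
        scenario = ScreenScenario(
            n_extracts=480, n_true_hits=7, hit_effect=(47, 50, 55, 60, 65, 68, 52),
            n_cytotoxic=20, seed=1,
        )
        sim = simulate_screen(scenario)
        extract_rows = sim.plate_map[sim.plate_map["role"] == "EXTRACT"]
        assert len(extract_rows) == 480
        assert len(sim.truth.true_hits()) == 7
        assert len(sim.truth.cytotoxic()) == 20
        # 6 plates of 8 NEG + 8 POS control wells each
        assert (sim.plate_map["role"] == "NEG").sum() == 48
        assert (sim.plate_map["role"] == "POS").sum() == 48
        # one measurement row per non-empty well
        assert len(sim.measurements) == len(sim.plate_map[sim.plate_map["role"] != "EMPTY"])

    def test_empty_library_gives_control_only_plate(self):
        sim = simulate_screen(ScreenScenario(n_extracts=0, n_true_hits=0, n_cytotoxic=0, seed=2))
        assert len(sim.truth) == 0
        assert set(sim.plate_map["role"]) == {"NEG", "POS", "EMPTY"}

    def test_zero_effect_library_mean_activity_near_zero(self):
        # Monte-Carlo oracle over >= 10^4 extract wells, against the true
        # generative control means; per-well activity SD is 15/800*100.
        scenario = ScreenScenario(n_extracts=10_000, n_true_hits=0, n_cytotoxic=0, seed=3)
        sim = simulate_screen(scenario)
        merged = sim.measurements.merge(sim.plate_map, on=["plate_id", "well"])
        gfp = merged.loc[merged["role"] == "EXTRACT", "avg_gfp"]
        activity = 100.0 * (gfp - scenario.neg_mean) / (scenario.pos_mean - scenario.neg_mean)
        assert abs(activity.mean()) < 0.1

    def test_cytotoxic_wells_lose_cells_and_gfp(self):
        scenario = ScreenScenario(
            n_extracts=40, n_true_hits=0, n_cytotoxic=10,
            cytotoxic_kill_fraction=0.9, seed=4,
        )
        sim = simulate_screen(scenario)
        merged = sim.measurements.merge(sim.plate_map, on=["plate_id", "well"])
        toxic_ids = set(sim.truth.cytotoxic())
        toxic = merged[merged["extract_id"].isin(toxic_ids)]
        healthy = merged[(merged["role"] == "EXTRACT") & ~merged["extract_id"].isin(toxic_ids)]
        assert toxic["cell_count"].max() < healthy["cell_count"].min()
        # 10% survival is below the 25% reporting floor -> GFP withheld
        assert toxic["avg_gfp"].isna().all()
        assert healthy["avg_gfp"].notna().all()

    def test_seed_determinism(self):
        scenario = ScreenScenario(n_extracts=80, n_true_hits=2, hit_effect=50.0, seed=5)
        a, b = simulate_screen(scenario), simulate_screen(scenario)
        pd.testing.assert_frame_equal(a.plate_map, b.plate_map)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.truth.to_frame(), b.truth.to_frame())

    def test_planted_hit_count_conserved(self, small_scenario):
        sim = simulate_screen(small_scenario)
        truth_df = sim.truth.to_frame()
        assert (truth_df["true_activity"] > 40).sum() == small_scenario.n_true_hits
        assert len(sim.truth.true_hits()) == small_scenario.n_true_hits

    def test_expected_activity_matches_planting(self):
        # Average the measured activity of one planted hit over many seeds.
        effect = 60.0
        vals = []
        for seed in range(200):
            scenario = ScreenScenario(
                n_extracts=1, n_true_hits=1, hit_effect=effect, n_cytotoxic=0, seed=seed
            )
            sim = simulate_screen(scenario)
            merged = sim.measurements.merge(sim.plate_map, on=["plate_id", "well"])
            gfp = merged.loc[merged["role"] == "EXTRACT", "avg_gfp"].iloc[0]
            vals.append(100.0 * (gfp - 200.0) / 800.0)
        assert np.mean(vals) == pytest.approx(effect, abs=0.5)

    def test_infeasible_layout_rejected(self):
        layout = PlateLayout(max_plates=1)
        with pytest.raises(LayoutError):
            simulate_screen(ScreenScenario(n_extracts=200, n_true_hits=0, n_cytotoxic=0), layout)

    def test_all_control_columns_rejected(self):
        layout = PlateLayout(neg_columns=tuple(range(1, 7)), pos_columns=tuple(range(7, 13)))
        with pytest.raises(LayoutError):
            simulate_screen(ScreenScenario(n_extracts=5, n_true_hits=0, n_cytotoxic=0), layout)


class TestRenderField:
    def test_zero_cells_blank_channels(self):
        img = render_field(FieldImageSpec(n_cells=0, noise_sd=0.0, seed=0))
        assert np.all(img.dna == img.spec.background)
        assert np.all(img.gfp == img.spec.background)
        assert img.cells == ()

    def test_noiseless_band_mean_exact(self):
        spec = FieldImageSpec(n_cells=50, noise_sd=0.0, cytoplasm_gfp_mean=300.0, seed=1)
        img = render_field(spec)
        assert len(img.cells) == 50
        for cell in img.cells:
            band = img.cytoplasm_band_mask(cell)
            assert float(img.gfp[band].mean()) == cell.true_mean_gfp == 300.0

    def test_noisy_band_mean_within_one_percent(self):
        # 5% pixel noise; direct pixel averaging over the known band.
        spec = FieldImageSpec(n_cells=50, noise_sd=15.0, cytoplasm_gfp_mean=300.0, seed=2)
        img = render_field(spec)
        for cell in img.cells:
            band = img.cytoplasm_band_mask(cell)
            assert float(img.gfp[band].mean()) == pytest.approx(300.0, rel=0.01)

    def test_spacing_invariant(self):
        spec = FieldImageSpec(n_cells=40, seed=3)
        img = render_field(spec)
        centers = [c.centroid for c in img.cells]
        min_d = min(
            math.dist(a, b) for i, a in enumerate(centers) for b in centers[i + 1 :]
        )
        assert min_d >= spec.min_center_distance_px

    def test_placement_error_when_overpacked(self):
        with pytest.raises(PlacementError):
            render_field(FieldImageSpec(image_shape=(64, 64), n_cells=50, seed=0))

    def test_seed_determinism(self):
        spec = FieldImageSpec(n_cells=20, noise_sd=10.0, seed=9)
        a, b = render_field(spec), render_field(spec)
        assert np.array_equal(a.dna, b.dna) and np.array_equal(a.gfp, b.gfp)
        assert a.cells == b.cells


class TestSimulateDoseSeries:
    CONCS = (0.5, 0.167, 0.056, 0.0185, 0.0062, 0.0021, 0.00069)

    def test_noiseless_midpoint_at_ec50(self):
        df = simulate_dose_series((10.0, 90.0, 0.056, 1.3), (0.5, 0.056, 0.001), noise_sd=0.0)
        assert df.loc[1, "activity"] == pytest.approx((10.0 + 90.0) / 2)

    def test_low_concentration_limit_is_bottom(self):
        df = simulate_dose_series((5.0, 95.0, 0.05, 2.0), (0.05, 1e-9), noise_sd=0.0)
        assert df.loc[1, "activity"] == pytest.approx(5.0, abs=1e-6)

    def test_plateau_value_matches_plugin_oracle(self):
        # A plateau of 68.6 reached by the third dilution, noiselessly.
        params = (0.0, 68.6, 0.002, 3.0)
        df = simulate_dose_series(params, self.CONCS, noise_sd=0.0)
        expected = four_param_logistic(0.056, *params)
        assert df.loc[2, "activity"] == expected
        assert df.loc[2, "activity"] == pytest.approx(68.6, abs=0.01)

    def test_cytotoxic_dilutions_missing_activity(self):
        df = simulate_dose_series(
            (0.0, 60.0, 0.005, 2.0), self.CONCS, cytotoxic_above=0.1, seed=1,
            cell_count_mean=3500, kill_fraction=0.7,
        )
        assert df.loc[:1, "activity"].isna().all()
        assert df.loc[2:, "activity"].notna().all()
        assert df.loc[:1, "cell_count"].max() < 0.5 * df.loc[2:, "cell_count"].min()

    def test_increasing_concentrations_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_series((0, 1, 0.1, 1), (0.1, 0.2))

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_series((0, 1, 0.1, 1), (0.5, 0.0))


class TestSimulateFlow:
    def test_zero_sd_constant(self):
        events = simulate_flow(100, 42.0, 0.0, seed=0)
        assert np.all(events == 42.0)

    def test_clt_bound(self):
        events = simulate_flow(100_000, 100.0, 10.0, seed=1)
        assert abs(events.mean() - 100.0) < 0.2  # 3*sd/sqrt(n) ~ 0.095

    @pytest.mark.parametrize("n", [0, -3])
    def test_bad_event_count(self, n):
        with pytest.raises(ValueError):
            simulate_flow(n, 10.0, 1.0)


class TestSimulateQpcr:
    def test_rq_one_all_deltas_equal(self):
        q = simulate_qpcr(1.0, ct_housekeeping=21.0, noise_sd=0.0)
        assert q.ct_target_treated - q.ct_hk_treated == q.ct_target_ref - q.ct_hk_ref

    def test_rq_two_gives_ddct_minus_one(self):
        q = simulate_qpcr(2.0, noise_sd=0.0)
        ddct = (q.ct_target_treated - q.ct_hk_treated) - (q.ct_target_ref - q.ct_hk_ref)
        assert ddct == pytest.approx(-1.0)

    def test_round_trip_to_printed_rq(self):
        q = simulate_qpcr(9.48, noise_sd=0.0)
        assert rq_ddct(*q.as_tuple()).rq == pytest.approx(9.48, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_any_rq(self, true_rq):
        q = simulate_qpcr(true_rq, noise_sd=0.0)
        assert rq_ddct(*q.as_tuple()).rq == pytest.approx(true_rq, rel=1e-9)

    def test_non_positive_rq_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0)
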