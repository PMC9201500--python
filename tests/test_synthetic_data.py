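"""Generator contracts: schedules, pot drydowns, root segments, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootplast.config import ConfigurationError, EffectConfig, ExperimentDesign
from rootplast.synthetic_data import (
    expected_layer_length,
    generate_control_series,
    generate_experiment,
    generate_pot_series,
    generate_root_segments,
    make_schedule,
)


class TestSchedule:
    def test_default_design_is_mon_wed_fri(self):
        days = make_schedule(ExperimentDesign(duration_days=35, weighings_per_week=3))
        expected = sorted({7 * w + o for w in range(5) for o in (0, 2, 4)} | {0, 35})
        assert days.tolist() == expected
        assert len(days) == 16

    @pytest.mark.parametrize(
        "duration,per_week,expected",
        [
            (7, 1, [0, 7]),
            (35, 7, list(range(36))),
        ],
    )
    def test_degenerate_frequencies(self, duration, per_week, expected):
        design = ExperimentDesign(duration_days=duration, weighings_per_week=per_week)
        assert make_schedule(design).tolist() == expected

    @given(duration=st.integers(1, 120), per_week=st.integers(1, 7))
    @settings(max_examples=60, deadline=None)
    def test_sorted_unique_with_forced_endpoints(self, duration, per_week):
        days = make_schedule(
            ExperimentDesign(duration_days=duration, weighings_per_week=per_week)
        )
        assert days[0] == 0 and days[-1] == duration
        assert np.all(np.diff(days) > 0)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentDesign(weighings_per_week=0)


class TestPotSeries:
    def test_ww_no_transpiration_no_noise_is_constant(self, design, rng):
        eff = EffectConfig(weighing_sd=0.0, control_drainage=0.0)
        series = generate_pot_series(
            design, eff, "WW", rng, transpiration=0.0
        )
        assert np.allclose(series.weights, design.field_capacity_weight)

    def test_wd_constant_loss_is_linear(self, design, rng):
        # Infinite decay time constant freezes the daily loss at its base.
        eff = EffectConfig(weighing_sd=0.0, wd_decay_tau=float("inf"))
        series = generate_pot_series(design, eff, "WD", rng)
        expected = design.field_capacity_weight - eff.base_daily_loss * series.days
        assert np.allclose(series.weights, expected)

    def test_wd_default_monotone_and_flattening(self, design, effects, rng):
        series = generate_pot_series(design, effects, "WD", rng)
        assert np.all(np.diff(series.weights) <= 0)
        drops = -np.diff(series.weights)
        # drydown flattens: losses over the last week far below the first
        assert drops[-3:].sum() < 0.2 * drops[:3].sum()
        assert np.all(series.weights > 0)

    def test_ww_refilled_to_field_capacity(self, design, effects, rng):
        series = generate_pot_series(design, effects, "WW", rng)
        refills = series.weights[series.post_irrigation]
        assert np.allclose(refills, design.field_capacity_weight)
        # pre-irrigation weights sit below field capacity
        pre = series.weights[~series.post_irrigation]
        assert np.all(pre < design.field_capacity_weight)

    def test_control_constant_without_drainage(self, design, rng):
        eff = EffectConfig(control_drainage=0.0, weighing_sd=0.0)
        series = generate_control_series(design, eff, rng)
        assert series.is_control
        assert np.allclose(series.weights, design.field_capacity_weight)

    def test_control_declines_at_drainage_rate(self, design, rng):
        eff = EffectConfig(control_drainage=0.05, weighing_sd=0.0)
        series = generate_control_series(design, eff, rng)
        expected = design.field_capacity_weight - 0.05 * series.days
        assert np.allclose(series.weights, expected)

    def test_all_series_share_the_design_schedule(self, design, effects, rng):
        schedule = make_schedule(design)
        control = generate_control_series(design, effects, rng)
        planted = generate_pot_series(design, effects, "WD", rng)
        assert control.days.tolist() == schedule.tolist()
        assert sorted(set(planted.days.tolist())) == schedule.tolist()


class TestRootSegments:
    def test_degenerate_allocation_confines_depths(self, design, effects, rng):
        seg = generate_root_segments(
            design, effects, "GC", "WW", rng,
            layer_allocation=np.array([1.0, 0.0, 0.0, 0.0]),
        )
        assert (seg["depth_cm"] < 10).all()

    def test_bad_allocation_rejected(self, design, effects, rng):
        with pytest.raises(ConfigurationError):
            generate_root_segments(
                design, effects, "GC", "WW", rng,
                layer_allocation=np.array([0.5, 0.2, 0.1, 0.1]),
            )

    def test_expected_wd_ww_ratio_equals_reduction(self, design, noise_free_effects):
        eff = noise_free_effects
        for genotype in design.genotypes:
            ww = expected_layer_length(design, eff, genotype, "WW")
            wd = expected_layer_length(design, eff, genotype, "WD")
            alloc_ww = eff.layer_allocation(genotype, "WW")
            alloc_wd = eff.layer_allocation(genotype, "WD")
            ratio = (wd / alloc_wd) / (ww / alloc_ww)
            assert np.allclose(ratio, eff.root_reduction(genotype))

    def test_sampled_total_ratio_near_reduction(self, design, rng):
        eff = EffectConfig(n_segments_base=4000)
        ww = generate_root_segments(design, eff, "GC", "WW", rng)
        wd = generate_root_segments(design, eff, "GC", "WD", rng)
        ratio = wd["length_mm"].sum() / ww["length_mm"].sum()
        assert ratio == pytest.approx(eff.wd_root_reduction, rel=0.05)

    def test_modal_length_class_is_half_to_one_mm(self, design, effects, rng):
        seg = generate_root_segments(
            design, effects, "GC", "WW", rng, n_segments=10_000
        )
        cls = pd.cut(seg["diameter_mm"], bins=list(design.class_edges) + [np.inf])
        by_class = seg.groupby(cls, observed=True)["length_mm"].sum()
        assert by_class.idxmax().left == 0.5

    def test_segment_validity(self, design, effects, rng):
        seg = generate_root_segments(design, effects, "Illapel", "WD", rng)
        assert (seg["depth_cm"] >= 0).all()
        assert (seg["depth_cm"] < max(design.layer_edges)).all()
        assert (seg["length_mm"] > 0).all()
        assert (seg["diameter_mm"] > 0).all()


class TestExperiment:
    def test_same_seed_gives_identical_tables(self, design, effects):
        a = generate_experiment(design, effects, seed=11)
        b = generate_experiment(design, effects, seed=11)
        pd.testing.assert_frame_equal(a.plants, b.plants)
        pd.testing.assert_frame_equal(a.pot_weights, b.pot_weights)
        pd.testing.assert_frame_equal(a.root_segments, b.root_segments)

    def test_plant_count_follows_design(self, effects):
        design = ExperimentDesign(n_blocks=2)
        data = generate_experiment(design, effects, seed=0)
        assert len(data.plants) == 8 * 2 * 2

    def test_root_shoot_higher_under_deficit(self, design, effects):
        data = generate_experiment(design, effects, seed=3)
        ratio = data.plants["rdw_g"] / data.plants["sdw_g"]
        means = ratio.groupby(data.plants["regime"]).mean()
        assert means["WD"] > means["WW"]

    def test_biomass_density_qc_warning(self, design, effects):
        with pytest.warns(UserWarning, match="pot-binding"):
            generate_experiment(design, effects, seed=0, qc_biomass_bound=2.0)

    def test_biomass_density_configurable_into_guidance_band(self, design):
        eff = EffectConfig(sdw_base=30.0, rdw_base=2.0)
        data = generate_experiment(design, eff, seed=0)
        ww = data.plants[data.plants["regime"] == "WW"]
        density = (ww["rdw_g"] + ww["sdw_g"]) / design.pot_volume
        assert 1.06 <= density.mean() <= 2.58
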