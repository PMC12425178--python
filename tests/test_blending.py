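"""Blend / distill operations and the naive alternative approaches."""

import numpy as np
import pytest

import agemix as am


def _mixing(parameter, density, model, output):
    return am.build_mixing_table(parameter, density, model, output)


class TestBlend:
    def test_constant_parameter_everywhere(self, constant_parameter, uniform_density):
        mx = _mixing(constant_parameter, uniform_density,
                     am.make_partition([0, 3, 7, 10]), am.make_partition([0, 10]))
        np.testing.assert_allclose(am.blend(mx).values, 0.3, atol=1e-9)

    def test_uniform_density_weighted_mean(self, identity_parameter, uniform_density):
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 10]), am.make_partition([0, 10]))
        assert am.blend(mx).values[0] == pytest.approx(5.0, abs=1e-9)

    def test_triangular_density_weighted_mean(self, identity_parameter, triangular_density):
        # ∫ x·(x/50) dx / ∫ x/50 dx over [0,10] = (1000/150)/(1) → 20/3
        mx = _mixing(identity_parameter, triangular_density,
                     am.make_partition([0, 10]), am.make_partition([0, 10]))
        assert am.blend(mx).values[0] == pytest.approx(20 / 3, abs=1e-9)

    def test_value_within_parameter_range_per_group(self, uniform_density):
        wavy = am.FeatureFunction(lambda x: np.sin(np.asarray(x, float)) + 2.0, (0, 10))
        model = am.make_partition([0, 2.5, 6, 10])
        mx = _mixing(wavy, uniform_density, model, am.make_partition([0, 10]))
        blended = am.blend(mx).values
        for j in range(model.n_intervals):
            grid = np.linspace(model.boundaries[j], model.boundaries[j + 1], 500)
            vals = np.asarray(wavy(grid))
            assert vals.min() - 1e-9 <= blended[j] <= vals.max() + 1e-9


class TestRedistributionWeights:
    def test_identity_when_partitions_match(self, identity_parameter, uniform_density):
        part = am.make_partition([0, 3, 7, 10])
        mx = _mixing(identity_parameter, uniform_density, part, part)
        np.testing.assert_array_equal(
            am.redistribution_weights(mx).matrix, np.eye(3)
        )

    def test_linear_parameter_row(self, identity_parameter, uniform_density):
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 10]), am.make_partition([0, 5, 10]))
        np.testing.assert_allclose(
            am.redistribution_weights(mx).matrix, [[0.25, 0.75]], atol=1e-9
        )

    def test_crossing_output_group_draws_from_both_models(
        self, identity_parameter, uniform_density
    ):
        # output [4,8) straddles model boundary at 6: both ω entries nonzero
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 6, 10]), am.make_partition([0, 4, 8, 10]))
        omega = am.redistribution_weights(mx).matrix
        assert omega[0, 1] > 0 and omega[1, 1] > 0

    def test_rows_sum_to_one_and_vanish_off_support(
        self, identity_parameter, triangular_density
    ):
        mx = _mixing(identity_parameter, triangular_density,
                     am.make_partition([0, 4, 10]), am.make_partition([0, 2, 6, 10]))
        omega = am.redistribution_weights(mx).matrix
        np.testing.assert_allclose(omega.sum(axis=1), 1.0, atol=1e-9)
        assert omega[0, 2] == 0.0  # model [0,4) cannot feed output [6,10)

    def test_zero_weight_group_falls_back_to_population(self, uniform_density):
        # parameter ≡ 0 on [0,5): Eq-form weights vanish there
        step = am.FeatureFunction(
            lambda x: np.where(np.asarray(x, float) < 5, 0.0, 1.0), (0, 10)
        )
        mx = _mixing(step, uniform_density,
                     am.make_partition([0, 5, 10]), am.make_partition([0, 2.5, 5, 7.5, 10]))
        with pytest.warns(UserWarning, match="zero total weight"):
            omega = am.redistribution_weights(mx).matrix
        np.testing.assert_allclose(omega[0, :2], [0.5, 0.5], atol=1e-6)


class TestDistill:
    def test_zero_input_gives_zero_output(self, identity_parameter, uniform_density):
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 5, 10]), am.make_partition([0, 2, 10]))
        out = am.distill(mx, am.OutcomeVector(mx.model, [0.0, 0.0]))
        np.testing.assert_array_equal(out.values, [0.0, 0.0])

    def test_symmetric_split(self, constant_parameter, uniform_density):
        mx = _mixing(constant_parameter, uniform_density,
                     am.make_partition([0, 10]), am.make_partition([0, 5, 10]))
        out = am.distill(mx, am.OutcomeVector(mx.model, [100.0]))
        np.testing.assert_allclose(out.values, [50.0, 50.0], atol=1e-7)

    def test_linear_parameter_split(self, identity_parameter, uniform_density):
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 10]), am.make_partition([0, 5, 10]))
        out = am.distill(mx, am.OutcomeVector(mx.model, [100.0]))
        np.testing.assert_allclose(out.values, [25.0, 75.0], atol=1e-6)

    def test_identity_on_matching_partitions(self, identity_parameter, triangular_density):
        part = am.make_partition([0, 2, 6, 10])
        mx = _mixing(identity_parameter, triangular_density, part, part)
        x = am.OutcomeVector(part, [3.0, 1.5, 9.0])
        np.testing.assert_array_equal(am.distill(mx, x).values, x.values)

    def test_union_roundtrip_reproduces_model_outcomes(
        self, identity_parameter, triangular_density
    ):
        model = am.make_partition([0, 4, 10])
        output = am.make_partition([0, 2, 6, 10])
        union = am.union_partition(model, output)
        mx = _mixing(identity_parameter, triangular_density, model, union)
        x = am.OutcomeVector(model, [40.0, 70.0])
        y = am.distill(mx, x)
        resummed = np.zeros(model.n_intervals)
        np.add.at(resummed, model.locate(union.midpoints), y.values)
        np.testing.assert_allclose(resummed, x.values, rtol=1e-12)

    def test_mismatched_outcome_partition_rejected(
        self, identity_parameter, uniform_density
    ):
        mx = _mixing(identity_parameter, uniform_density,
                     am.make_partition([0, 5, 10]), am.make_partition([0, 10]))
        other = am.OutcomeVector(am.make_partition([0, 10]), [1.0])
        with pytest.raises(ValueError):
            am.distill(mx, other)


class TestAggregateAlternatives:
    def test_midpoint_simple(self, identity_parameter):
        agg = am.aggregate_midpoint(identity_parameter, am.make_partition([0, 5, 10]))
        np.testing.assert_allclose(agg.values, [2.5, 7.5])

    def test_midpoint_of_terminal_elderly_group(self):
        # open-ended 65+ group closed at 101 → midpoint 83
        model = am.make_partition([0, 5, 20, 65, 101])
        ifr = am.FeatureFunction(am.covid_ifr, (0, 101))
        agg = am.aggregate_midpoint(ifr, model)
        assert agg.values[-1] == pytest.approx(am.covid_ifr(83.0), rel=1e-12)

    def test_midpoint_constant(self, constant_parameter):
        agg = am.aggregate_midpoint(constant_parameter, am.make_partition([0, 3, 10]))
        np.testing.assert_allclose(agg.values, 0.3)

    def test_mean_age_uniform_density(self, identity_parameter, uniform_density):
        agg = am.aggregate_mean_age(
            identity_parameter, uniform_density, am.make_partition([0, 10])
        )
        assert agg.values[0] == pytest.approx(5.0, abs=1e-9)

    def test_mean_age_triangular_density(self, identity_parameter, triangular_density):
        agg = am.aggregate_mean_age(
            identity_parameter, triangular_density, am.make_partition([0, 10])
        )
        assert agg.values[0] == pytest.approx(20 / 3, abs=1e-9)

    def test_mean_age_equals_blend_for_affine_parameter(self, triangular_density):
        affine = am.FeatureFunction(lambda x: 3.0 * np.asarray(x, float) - 1.0, (0, 10))
        model = am.make_partition([0, 4, 10])
        mean_age = am.aggregate_mean_age(affine, triangular_density, model)
        blended = am.blend(_mixing(affine, triangular_density, model,
                                   am.make_partition([0, 10])))
        np.testing.assert_allclose(mean_age.values, blended.values, rtol=1e-8)


class TestDistributeAlternatives:
    def test_uniform_equal_lengths(self, unit_interval):
        out = am.distribute_uniform(
            am.OutcomeVector(unit_interval, [100.0]), am.make_partition([0, 5, 10])
        )
        np.testing.assert_allclose(out.values, [50.0, 50.0])

    def test_uniform_length_proportional(self, unit_interval):
        out = am.distribute_uniform(
            am.OutcomeVector(unit_interval, [100.0]), am.make_partition([0, 2, 10])
        )
        np.testing.assert_allclose(out.values, [20.0, 80.0])

    def test_uniform_zero_deaths(self, unit_interval):
        out = am.distribute_uniform(
            am.OutcomeVector(unit_interval, [0.0]), am.make_partition([0, 2, 10])
        )
        np.testing.assert_array_equal(out.values, [0.0, 0.0])

    def test_mean_age_boundary_goes_to_upper_interval(
        self, unit_interval, uniform_density
    ):
        # mean of uniform on [0,10) is 5.0 → upper interval under half-open rule
        out = am.distribute_mean_age(
            am.OutcomeVector(unit_interval, [100.0]), uniform_density,
            am.make_partition([0, 5, 10]),
        )
        np.testing.assert_allclose(out.values, [0.0, 100.0])

    def test_mean_age_mass_concentrated_low(self, unit_interval):
        low = am.FeatureFunction(
            lambda x: np.exp(-np.asarray(x, float)), (0, 10), is_density=True
        )
        out = am.distribute_mean_age(
            am.OutcomeVector(unit_interval, [100.0]), low, am.make_partition([0, 5, 10])
        )
        np.testing.assert_allclose(out.values, [100.0, 0.0])

    def test_mean_age_groups_land_independently(self, uniform_density):
        model = am.make_partition([0, 4, 10])
        out = am.distribute_mean_age(
            am.OutcomeVector(model, [10.0, 30.0]), uniform_density,
            am.make_partition([0, 2, 6, 10]),
        )
        np.testing.assert_allclose(out.values, [0.0, 10.0, 30.0])

    def test_density_uniform_reduces_to_length_proportional(
        self, unit_interval, uniform_density
    ):
        deaths = am.OutcomeVector(unit_interval, [100.0])
        output = am.make_partition([0, 2, 10])
        np.testing.assert_allclose(
            am.distribute_density(deaths, uniform_density, output).values,
            am.distribute_uniform(deaths, output).values,
            atol=1e-7,
        )

    def test_density_triangular(self, unit_interval, triangular_density):
        # population integrals of x/50 over [0,5) and [5,10): 0.25 vs 0.75
        out = am.distribute_density(
            am.OutcomeVector(unit_interval, [100.0]), triangular_density,
            am.make_partition([0, 5, 10]),
        )
        np.testing.assert_allclose(out.values, [25.0, 75.0], atol=1e-6)

    def test_density_equals_distill_with_constant_parameter(
        self, constant_parameter, triangular_density
    ):
        model = am.make_partition([0, 4, 10])
        output = am.make_partition([0, 2, 6, 10])
        deaths = am.OutcomeVector(model, [60.0, 40.0])
        mx = _mixing(constant_parameter, triangular_density, model, output)
        np.testing.assert_allclose(
            am.distill(mx, deaths).values,
            am.distribute_density(deaths, triangular_density, output).values,
            rtol=1e-9,
        )


class TestSummaries:
    def test_parameter_summary_shape_and_constant_agreement(
        self, constant_parameter, uniform_density
    ):
        model = am.make_partition([0, 3, 7, 10])
        summary = am.parameter_summary(constant_parameter, uniform_density, model)
        assert len(summary) == model.n_intervals * 3
        np.testing.assert_allclose(summary["value"], 0.3, atol=1e-9)

    def test_parameter_summary_jensen_for_convex_parameter(self, uniform_density):
        convex = am.FeatureFunction(lambda x: np.asarray(x, float) ** 2, (0, 10))
        model = am.make_partition([0, 5, 10])
        summary = am.parameter_summary(convex, uniform_density, model)
        pivot = summary.pivot(index="group_lo", columns="approach", values="value")
        assert (pivot["blend"] >= pivot["mean_age"] - 1e-9).all()

    def test_distill_summary_columns_conserve_total(
        self, identity_parameter, triangular_density
    ):
        model = am.make_partition([0, 4, 10])
        output = am.make_partition([0, 2, 6, 10])
        deaths = am.OutcomeVector(model, [30.0, 70.0])
        summary = am.distill_summary(
            deaths, identity_parameter, triangular_density, model, output
        )
        totals = summary.groupby("approach")["value"].sum()
        np.testing.assert_allclose(totals, 100.0, rtol=1e-12)

    def test_distill_summary_degenerate_approaches_coincide(
        self, constant_parameter, uniform_density
    ):
        model = am.make_partition([0, 5, 10])
        output = am.make_partition([0, 2.5, 5, 7.5, 10])
        deaths = am.OutcomeVector(model, [40.0, 60.0])
        summary = am.distill_summary(
            deaths, constant_parameter, uniform_density, model, output
        )
        pivot = summary.pivot(index="group_lo", columns="approach", values="value")
        np.testing.assert_allclose(pivot["uniform"], pivot["density"], atol=1e-7)
        np.testing.assert_allclose(pivot["uniform"], pivot["distill"], atol=1e-7)

    def test_distill_shifts_mass_older_for_increasing_parameter(
        self, identity_parameter, uniform_density
    ):
        model = am.make_partition([0, 10])
        output = am.make_partition([0, 2, 4, 6, 8, 10])
        deaths = am.OutcomeVector(model, [100.0])
        summary = am.distill_summary(
            deaths, identity_parameter, uniform_density, model, output
        )
        pivot = summary.pivot(index="group_lo", columns="approach", values="value")
        cum_distill = pivot["distill"].cumsum()
        cum_density = pivot["density"].cumsum()
        # distill's mass distribution is stochastically older
        assert (cum_distill <= cum_density + 1e-9).all()
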