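import math

import numpy as np
import pytest

from memstress import (
    COMPONENT_NAMES,
    ElasticConstants,
    InterfaceGeometry,
    analytic_component_moment_table,
    central_stress,
    component_moment_table,
    component_sB0,
    component_sB1,
    component_sB2,
    component_sG,
    component_sT,
    sample_profile,
    total_stress,
    zero_bump_ratio,
)

SQRT2 = math.sqrt(2.0)


def _table_close(params, geom, rtol=1e-8):
    num = component_moment_table(params, geom)
    ana = analytic_component_moment_table(params, geom)
    scale = max(np.abs(ana.to_numpy()).max(), 1e-3)
    np.testing.assert_allclose(
        num.to_numpy(), ana.to_numpy(), rtol=rtol, atol=rtol * scale
    )


class TestCentralValues:
    def test_sB2_at_origin(self, default_geom):
        eps = default_geom.epsilon
        expected = -3.0 * 20.0 / (2.0 * SQRT2 * eps**3)
        assert component_sB2(0.0, 20.0, default_geom) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(-36.656, abs=1e-3)

    def test_sG_at_origin(self, default_geom):
        eps = default_geom.epsilon
        expected = -35.0 * (-14.0) / (16.0 * SQRT2 * eps**3)
        assert component_sG(0.0, -14.0, default_geom) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(37.41, abs=0.02)

    def test_central_stress_closed_form(self, default_geom):
        params = ElasticConstants(k=20.0, kG0=-0.7 * 20.0)
        assert central_stress(params, default_geom) == pytest.approx(0.764, abs=1e-3)

    def test_central_stress_matches_total(self, default_geom, full_params):
        assert central_stress(full_params, default_geom) == pytest.approx(
            float(total_stress(full_params, default_geom, 0.0)), rel=1e-12
        )

    @pytest.mark.parametrize("m", [-0.1, 0.0, 0.1])
    @pytest.mark.parametrize("gamma", [0.0, 0.05])
    def test_central_stress_independent_of_m_and_gamma(self, default_geom, m, gamma):
        ref = central_stress(ElasticConstants(k=20.0, kG0=-14.0), default_geom)
        val = central_stress(
            ElasticConstants(k=20.0, kG0=-14.0, m=m, gamma=gamma), default_geom
        )
        assert val == ref


class TestZeroBumpRatio:
    def test_value(self):
        assert zero_bump_ratio() == pytest.approx(-24.0 / 35.0, abs=1e-10)

    def test_is_root(self, default_geom):
        ratio = zero_bump_ratio()
        params = ElasticConstants(k=20.0, kG0=ratio * 20.0)
        assert abs(central_stress(params, default_geom)) < 1e-10

    def test_against_algebraic_rearrangement(self):
        # s(0) = 0  <=>  3k/2 = -35 kG0/16  <=>  kG0/k = -(3/2)(16/35)
        assert zero_bump_ratio() == pytest.approx(-(3.0 / 2.0) * (16.0 / 35.0), abs=1e-12)


class TestParity:
    def test_even_components(self, default_geom):
        z = np.linspace(0.1, 6.0, 50)
        for f in (
            lambda x: component_sB2(x, 20.0, default_geom),
            lambda x: component_sB0(x, 20.0, 0.1, default_geom),
            lambda x: component_sG(x, -14.0, default_geom),
            lambda x: component_sT(x, 0.1, default_geom),
        ):
            np.testing.assert_allclose(f(z), f(-z), atol=1e-14)

    def test_odd_component(self, default_geom):
        z = np.linspace(0.1, 6.0, 50)
        np.testing.assert_allclose(
            component_sB1(z, 20.0, 0.1, default_geom),
            -component_sB1(-z, 20.0, 0.1, default_geom),
            atol=1e-14,
        )


class TestMomentConstraints:
    def test_full_parameter_table(self, full_params, default_geom):
        _table_close(full_params, default_geom)

    def test_symmetric_table(self, symmetric_params, default_geom):
        _table_close(symmetric_params, default_geom)

    def test_randomized_tables(self, default_geom):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = ElasticConstants(
                k=rng.uniform(5, 50),
                kG0=-rng.uniform(0.5, 1.2) * 20,
                m=rng.uniform(-0.3, 0.3),
                gamma=rng.uniform(0, 0.5),
            )
            _table_close(params, default_geom)

    def test_sB1_first_moment_example(self, default_geom):
        params = ElasticConstants(k=20.0, m=0.1)
        tab = component_moment_table(params, default_geom)
        assert tab.loc["sB1", "P1"] == pytest.approx(-4.0, rel=1e-10)

    def test_sB0_zeroth_moment_example(self, default_geom):
        params = ElasticConstants(k=20.0, m=0.1)
        tab = component_moment_table(params, default_geom)
        assert tab.loc["sB0", "P0"] == pytest.approx(0.4, rel=1e-10)

    def test_sG_second_moment_example(self, default_geom):
        tab = component_moment_table(ElasticConstants(k=1.0, kG0=-14.0), default_geom)
        assert tab.loc["sG", "P2"] == pytest.approx(-14.0, rel=1e-10)

    def test_sT_zeroth_moment_example(self, default_geom):
        tab = component_moment_table(ElasticConstants(k=1.0, gamma=0.005), default_geom)
        assert tab.loc["sT", "P0"] == pytest.approx(0.005, rel=1e-10)

    def test_sB2_second_moment_example(self, default_geom):
        tab = component_moment_table(ElasticConstants(k=20.0), default_geom)
        assert tab.loc["sB2", "P2"] == pytest.approx(40.0, rel=1e-10)


class TestComponentStructure:
    def test_sT_sB0_shared_shape(self, default_geom):
        z = np.linspace(-5, 5, 201)
        k, m, gamma = 20.0, 0.1, 0.005
        lhs = component_sT(z, gamma, default_geom) / gamma
        rhs = component_sB0(z, k, m, default_geom) / (2 * k * m * m)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_vanishing_components(self, default_geom):
        z = np.linspace(-5, 5, 101)
        assert np.all(component_sB1(z, 20.0, 0.0, default_geom) == 0)
        assert np.all(component_sB0(z, 20.0, 0.0, default_geom) == 0)
        assert np.all(component_sT(z, 0.0, default_geom) == 0)

    def test_sB0_zero_at_origin(self, default_geom):
        assert component_sB0(0.0, 35.0, 0.2, default_geom) == 0.0

    @pytest.mark.parametrize(
        "func,const",
        [
            (lambda z, c, g: component_sB2(z, c, g), 20.0),
            (lambda z, c, g: component_sG(z, c, g), -14.0),
            (lambda z, c, g: component_sT(z, c, g), 0.01),
        ],
    )
    def test_linearity_in_constant(self, default_geom, func, const):
        z = np.linspace(-4, 4, 81)
        np.testing.assert_allclose(
            func(z, 3.0 * const, default_geom),
            3.0 * func(z, const, default_geom),
            rtol=1e-14,
        )

    def test_sB1_negative_on_outer_side_for_positive_m(self, default_geom):
        # positive m: outer monolayer more repulsive -> stress more negative
        assert component_sB1(1.0, 20.0, 0.1, default_geom) < 0


class TestSampleProfile:
    def test_total_is_sum(self, full_params, default_geom):
        prof = sample_profile(full_params, default_geom, -5, 5, 201)
        summed = sum(prof.components[name] for name in COMPONENT_NAMES)
        np.testing.assert_array_equal(prof.total, summed)

    def test_metadata(self, full_params, default_geom):
        prof = sample_profile(full_params, default_geom, -5, 5, 11)
        assert prof.metadata["k"] == full_params.k
        assert prof.metadata["epsilon"] == default_geom.epsilon

    def test_two_point_grid(self, full_params, default_geom):
        prof = sample_profile(full_params, default_geom, -1.0, 1.0, 2)
        expect = total_stress(full_params, default_geom, np.array([-1.0, 1.0]))
        np.testing.assert_allclose(prof.total, expect, rtol=1e-15)

    def test_degenerate_grid_rejected(self, full_params, default_geom):
        with pytest.raises(ValueError):
            sample_profile(full_params, default_geom, 1.0, 1.0, 10)
        with pytest.raises(ValueError):
            sample_profile(full_params, default_geom, -1.0, 1.0, 1)

    def test_decay_beyond_thickness(self, full_params, default_geom):
        lme = default_geom.lme
        prof = sample_profile(full_params, default_geom, -2 * lme, 2 * lme, 1001)
        peak = np.max(np.abs(prof.total))
        tails = np.abs(prof.total[np.abs(prof.z) >= lme])
        assert np.all(tails < 1e-3 * peak)

    def test_far_field_negligible(self, full_params, default_geom):
        far = 10 * default_geom.lme
        peak = abs(central_stress(ElasticConstants(k=20.0), default_geom))
        val = total_stress(full_params, default_geom, np.array([-far, far]))
        assert np.all(np.abs(val) < 1e-10 * peak)

    def test_headgroup_attraction_tail_repulsion(self, symmetric_params, default_geom):
        # positive peaks near the headgroups, negative stress in the tails
        prof = sample_profile(symmetric_params, default_geom, -4, 4, 801)
        outer = prof.total[prof.z > 0]
        z_out = prof.z[prof.z > 0]
        peak_idx = np.argmax(outer)
        assert outer[peak_idx] > 0
        assert 1.0 < z_out[peak_idx] < 3.0  # headgroup region
        assert np.min(outer) < 0  # repulsive tail region
        np.testing.assert_allclose(prof.total, prof.total[::-1], atol=1e-13)

    def test_positive_m_tilts_profile_negative_outward(self, default_geom):
        params = ElasticConstants(k=20.0, kG0=-14.0, m=0.1)
        prof = sample_profile(params, default_geom, -4, 4, 801)
        mirrored = prof.total[::-1]  # s(-z) on the symmetric grid
        diff = prof.total - mirrored
        sel = (prof.z > 0.2) & (prof.z < 3.0)
        assert np.all(diff[sel] < 0)

    def test_thinning_under_fixed_constants(self, symmetric_params):
        # thinner membrane: larger peaks, smaller peak-to-peak distance
        stats = []
        for lme in (4.5, 4.75, 5.0):
            geom = InterfaceGeometry.from_thickness(lme)
            prof = sample_profile(symmetric_params, geom, -6, 6, 2401)
            peak = np.max(np.abs(prof.total))
            pos = prof.z[prof.z > 0]
            vals = prof.total[prof.z > 0]
            d_peak = 2 * pos[np.argmax(vals)]
            stats.append((peak, d_peak))
        peaks, dists = zip(*stats)
        assert peaks[0] > peaks[1] > peaks[2]
        assert dists[0] < dists[1] < dists[2]


class TestValidation:
    def test_negative_k_rejected(self):
        with pytest.raises(ValueError, match="rigidity"):
            ElasticConstants(k=-1.0)

    def test_sigma_recomputed(self):
        p = ElasticConstants(k=10.0, m=0.2, gamma=0.1)
        assert p.Sigma == pytest.approx(0.1 + 2 * 10 * 0.04, rel=1e-15)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            InterfaceGeometry(epsilon=-1.0)
        with pytest.raises(ValueError, match="thickness_ratio"):
            InterfaceGeometry(epsilon=1.0, thickness_ratio=4.0)
        geom = InterfaceGeometry.from_thickness(5.0)
        assert geom.epsilon == pytest.approx(5.0 / 6.0)
        assert geom.lme == pytest.approx(5.0)
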