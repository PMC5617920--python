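"""Gradient formation, threshold domains and the positional P factor."""

import math

import numpy as np
import pytest

from hoxspring import (
    ConfigurationError,
    ExpressionWindow,
    GridSpec,
    InputError,
    MorphogenField,
    MorphogenParams,
    ParameterError,
    ThresholdSet,
    expression_domains,
    implant_bead,
    p_factor,
    steady_state_concentration,
    steady_state_profile,
    transient_profile,
    transient_snapshots,
    window_domain,
)


class TestSteadyState:
    def test_source_value_and_zero_source(self, unit_gradient_params):
        field = steady_state_profile(unit_gradient_params, n_nodes=501)
        assert field.concentrations[0] == pytest.approx(1.0)
        dead = MorphogenParams(
            diffusion_coeff=1.0, decay_rate=1.0, source_amplitude=0.0,
            axis_length=5.0, source_position=0.0)
        assert np.all(steady_state_profile(dead).concentrations == 0.0)

    def test_half_decay_at_ln2(self, unit_gradient_params):
        # lambda = sqrt(D/k) = 1: C(ln 2) = 0.5
        c = steady_state_concentration(unit_gradient_params, math.log(2.0))
        assert c == pytest.approx(0.5, rel=1e-12)

    def test_monotone_from_posterior_source(self):
        field = steady_state_profile(MorphogenParams())
        assert np.all(np.diff(field.concentrations) >= 0)  # source at x = L

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"diffusion_coeff": 0.0},
            {"decay_rate": -1.0},
            {"source_amplitude": -0.5},
            {"axis_length": 0.0},
            {"source_position": 2.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MorphogenParams(**kwargs)


class TestTransient:
    def test_initial_condition_is_zero(self):
        field = transient_profile(MorphogenParams(), 0.0, GridSpec(n_nodes=51))
        assert np.all(field.concentrations == 0.0)

    def test_monotone_approach_in_time(self):
        params = MorphogenParams()
        times = [0.0, 1.0, 5.0, 20.0, 80.0]
        _, snaps = transient_snapshots(params, times, GridSpec(n_nodes=101))
        diffs = np.diff(snaps, axis=0)
        assert np.all(diffs >= -1e-12)

    def test_long_time_matches_closed_form(self):
        # decay length 0.25 on a unit axis; equilibrated at t = 10 / k_deg
        params = MorphogenParams(
            diffusion_coeff=0.25**2 * 0.5, decay_rate=0.5,
            axis_length=1.0, source_position=1.0)
        field = transient_profile(
            params, 10.0 / params.decay_rate, GridSpec(n_nodes=101))
        exact = steady_state_concentration(params, field.grid)
        assert np.max(np.abs(field.concentrations - exact) / exact) < 1e-3

    def test_unstable_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            GridSpec(n_nodes=2)
        with pytest.raises(ConfigurationError):
            GridSpec(dt=-0.1)
        with pytest.raises(ConfigurationError):
            # dt so coarse that dt * k_deg > 2
            transient_profile(MorphogenParams(), 1.0, GridSpec(dt=100.0))


class TestBeadImplants:
    def test_null_implant_leaves_profile_unchanged(self, unit_gradient_params):
        bead = implant_bead(unit_gradient_params, 2.0, 0.0)
        x = np.linspace(0, 5, 101)
        assert np.array_equal(
            steady_state_concentration(unit_gradient_params, x),
            steady_state_concentration(bead, x))

    def test_rescue_symmetry(self, unit_gradient_params):
        """Removing the source and implanting an equal bead there rescues C."""
        from dataclasses import replace

        removed = replace(unit_gradient_params, source_amplitude=0.0)
        rescued = implant_bead(removed, unit_gradient_params.source_position,
                               unit_gradient_params.source_amplitude)
        x = np.linspace(0, 5, 101)
        np.testing.assert_allclose(
            steady_state_concentration(rescued, x),
            steady_state_concentration(unit_gradient_params, x), rtol=1e-12)

    def test_tip_bead_raises_tip_concentration(self):
        intact = MorphogenParams()
        tip = intact.axis_length  # the posterior tip (source side)
        with_bead = implant_bead(intact, tip, 0.5)
        assert steady_state_concentration(with_bead, tip) > \
            steady_state_concentration(intact, tip)

    def test_superposition_of_sources(self, unit_gradient_params):
        bead = implant_bead(unit_gradient_params, 3.0, 0.7)
        only_bead = MorphogenParams(
            diffusion_coeff=1.0, decay_rate=1.0, source_amplitude=0.7,
            axis_length=5.0, source_position=3.0)
        x = np.linspace(0, 5, 101)
        np.testing.assert_allclose(
            steady_state_concentration(bead, x),
            steady_state_concentration(unit_gradient_params, x)
            + steady_state_concentration(only_bead, x),
            rtol=1e-12)

    def test_invalid_bead_rejected(self, unit_gradient_params):
        with pytest.raises(ParameterError):
            implant_bead(unit_gradient_params, 2.0, -1.0)
        with pytest.raises(ParameterError):
            implant_bead(unit_gradient_params, 99.0, 1.0)


class TestThresholdReadout:
    def test_domains_nested_and_analytic_boundaries(self, unit_gradient_params):
        field = steady_state_profile(unit_gradient_params, n_nodes=2001)
        domains = expression_domains(field, ThresholdSet((0.25, 0.5)))
        assert domains.is_nested()
        # S(T=0.25) extends ln 4 from the source, S(T=0.5) extends ln 2
        wide, narrow = domains.domain(1), domains.domain(2)
        dx = field.grid[1] - field.grid[0]
        assert wide.positions()[-1] == pytest.approx(math.log(4.0), abs=dx)
        assert narrow.positions()[-1] == pytest.approx(math.log(2.0), abs=dx)
        assert set(narrow.positions()) <= set(wide.positions())

    def test_thresholds_above_profile_empty_domains(self, unit_gradient_params):
        field = steady_state_profile(unit_gradient_params)
        domains = expression_domains(field, ThresholdSet((2.0, 3.0)))
        assert domains.domain(1).empty and domains.domain(2).empty

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            ThresholdSet((0.5, 0.25))
        with pytest.raises(ParameterError):
            ThresholdSet((-1.0, 1.0))

    def test_window_domain_annulus(self, unit_gradient_params):
        field = steady_state_profile(unit_gradient_params, n_nodes=2001)
        dom = window_domain(field, ExpressionWindow(0.25, 0.5))
        pos = dom.positions()
        dx = field.grid[1] - field.grid[0]
        assert pos[0] == pytest.approx(math.log(2.0), abs=dx)
        assert pos[-1] == pytest.approx(math.log(4.0), abs=dx)

    def test_window_reduces_to_threshold_when_upper_exceeds_max(
            self, unit_gradient_params):
        field = steady_state_profile(unit_gradient_params)
        dom = window_domain(field, ExpressionWindow(0.25, 10.0))
        thr = expression_domains(field, ThresholdSet((0.25,))).domain(1)
        assert np.array_equal(dom.mask, thr.mask)

    def test_window_empty_when_all_above_upper(self):
        field = MorphogenField(np.array([0.0, 1.0]), np.array([5.0, 5.0]), 0.0)
        assert window_domain(field, ExpressionWindow(1.0, 2.0)).empty

    def test_tip_inhibition_with_bead_at_tip(self):
        """A strong tip bead pushes C above the upper threshold near the tip."""
        intact = MorphogenParams()
        window = ExpressionWindow(0.3, 1.2)
        tip_field = steady_state_profile(
            implant_bead(intact, intact.axis_length, 1.0))
        dom = window_domain(tip_field, window)
        tip_mask = tip_field.grid > 0.98 * intact.axis_length
        assert not dom.empty
        assert not np.any(dom.mask[tip_mask])  # excluded around the tip
        # without the bead the tip is inside the window
        plain = window_domain(steady_state_profile(intact), window)
        assert np.all(plain.mask[tip_mask])


class TestPFactor:
    def test_threshold_counting(self):
        field = MorphogenField(np.array([0.0, 1.0, 2.0]),
                               np.array([0.5, 2.5, 3.5]), 0.0)
        thr = ThresholdSet((1.0, 2.0, 3.0))
        assert p_factor(field, thr, 0.0) == 0
        assert p_factor(field, thr, 1.0) == 2
        assert p_factor(field, thr, 2.0) == 3  # saturates at m

    def test_p_profile_monotone_in_time(self):
        from hoxspring import p_factor_profile

        params = MorphogenParams()
        thr = ThresholdSet.default_for(params)
        grid, snaps = transient_snapshots(
            params, [2.0, 10.0, 50.0], GridSpec(n_nodes=101))
        profiles = [
            p_factor_profile(MorphogenField(grid, np.clip(c, 0, None), t), thr)
            for t, c in zip([2.0, 10.0, 50.0], snaps)
        ]
        assert np.all(profiles[1] >= profiles[0])
        assert np.all(profiles[2] >= profiles[1])

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            MorphogenField(np.array([]), np.array([]), 0.0)
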