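"""Force law, Hooke-spring responses, sequential extrusion and geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hoxspring import (
    EditSpec,
    ParameterError,
    SpringParams,
    anchored_elongation,
    apply_edit,
    calibrate_spring,
    end_to_end_length,
    extrusion_state,
    force,
    geometry_readout,
    geometry_table,
    unanchored_response,
    wild_type_cluster,
)


class TestForceLaw:
    def test_products(self):
        assert force(0, 9).F == 0.0
        assert force(3, 9).F == 27.0
        assert force(3, 18).F == 2 * force(3, 9).F

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            force(-1, 9)
        with pytest.raises(ParameterError):
            force(1, -9)

    @given(
        st.floats(0, 50, allow_nan=False),
        st.floats(0, 50, allow_nan=False),
        st.floats(0, 8, allow_nan=False),
    )
    def test_bilinearity(self, p, n, a):
        assert force(a * p, n).F == pytest.approx(a * force(p, n).F)
        assert force(p, a * n).F == pytest.approx(a * force(p, n).F)


class TestAnchoredSpring:
    def test_zero_force_keeps_rest_length(self, wt_cluster, spring):
        resp = anchored_elongation(force(0, 9), spring, wt_cluster)
        assert resp.elongation == 0.0
        assert resp.total_length == 100.0
        assert np.array_equal(resp.bead_coordinates, wt_cluster.rest_offsets)

    def test_calibrated_maximal_stretch(self, wt_cluster, spring):
        resp = anchored_elongation(force(9, 9), spring, wt_cluster)
        assert resp.total_length == pytest.approx(560.0)

    def test_uniform_strain_across_segments(self, wt_cluster, spring):
        resp = anchored_elongation(force(5, 9), spring, wt_cluster)
        rest = wt_cluster.rest_offsets
        strains = np.diff(resp.bead_coordinates) / np.diff(rest) - 1.0
        assert np.ptp(strains) < 1e-12
        assert strains[0] == pytest.approx(resp.per_segment_strain)

    def test_contract_violation_on_unanchored(self, spring, wt_cluster):
        loose = apply_edit(
            wt_cluster, EditSpec(remove_centromeric_anchor=True))
        with pytest.raises(ParameterError):
            anchored_elongation(force(1, 9), spring, loose)
        with pytest.raises(ParameterError):
            unanchored_response(force(1, 9), spring, wt_cluster)


class TestUnanchoredSpring:
    @pytest.fixture
    def loose(self, wt_cluster):
        return apply_edit(wt_cluster, EditSpec(remove_centromeric_anchor=True))

    def test_hand_checked_slide_and_partial_stretch(self, loose):
        spring = SpringParams(spring_constant=0.18, friction_fraction=0.5,
                              slide_stiffness=0.25)
        resp = unanchored_response(force(3, 9), spring, loose)
        assert resp.elongation == pytest.approx(75.0)
        assert resp.slide == pytest.approx(54.0)

    def test_frictionless_limit_recovers_anchored_elongation(
            self, wt_cluster, loose):
        spring = SpringParams(friction_fraction=0.0)
        f = force(4, 9)
        assert unanchored_response(f, spring, loose).elongation == \
            pytest.approx(anchored_elongation(f, spring, wt_cluster).elongation)
        assert unanchored_response(f, spring, loose).slide == 0.0

    def test_zero_force_is_inert(self, loose, spring):
        resp = unanchored_response(force(0, 9), spring, loose)
        assert resp.elongation == 0.0 and resp.slide == 0.0

    @given(
        st.floats(0.5, 100, allow_nan=False),
        st.floats(0.01, 0.99, allow_nan=False),
    )
    def test_dissipated_elongation_smaller(self, f_val, phi):
        wt = wild_type_cluster()
        loose = apply_edit(wt, EditSpec(remove_centromeric_anchor=True))
        spring = SpringParams(friction_fraction=phi)
        f = force(f_val, 1.0)
        en = anchored_elongation(f, spring, wt).elongation
        ed = unanchored_response(f, spring, loose).elongation
        assert ed < en
        assert unanchored_response(f, spring, loose).slide > 0


class TestExtrusion:
    def test_no_force_no_extrusion(self, wt_cluster, spring):
        f = force(0, 9)
        resp = anchored_elongation(f, spring, wt_cluster)
        assert extrusion_state(wt_cluster, f, resp, spring).extruded == ()

    @pytest.mark.parametrize(
        "p, expected",
        [
            (1, ("Hoxd1",)),
            (2, ("Hoxd1", "Hoxd3")),
            (9, tuple(wild_type_cluster().names)),
        ],
    )
    def test_sequential_order_on_wild_type(self, wt_cluster, spring, p, expected):
        f = force(p, 9)
        resp = anchored_elongation(f, spring, wt_cluster)
        state = extrusion_state(wt_cluster, f, resp, spring)
        assert state.extruded == expected
        assert all(state.transcribing[n] for n in expected)

    def test_tie_counts_as_extruded(self, wt_cluster, spring):
        # drive exactly tau * i at i = 3
        f = force(3, 9)
        resp = anchored_elongation(f, spring, wt_cluster)
        assert len(extrusion_state(wt_cluster, f, resp, spring).extruded) == 3

    @given(st.integers(0, 9), st.integers(0, 9))
    def test_prefix_and_monotone_in_p(self, p1, p2):
        wt = wild_type_cluster()
        spring = SpringParams()
        sets = []
        for p in (p1, p2):
            f = force(p, 9)
            resp = anchored_elongation(f, spring, wt)
            names = extrusion_state(wt, f, resp, spring).extruded
            assert names == wt.names[: len(names)]  # always a rank prefix
            sets.append(set(names))
        if p1 <= p2:
            assert sets[0] <= sets[1]


class TestGeometryReadout:
    def test_noiseless_is_exact_and_seeded_noise_reproducible(
            self, wt_cluster, spring):
        resp = anchored_elongation(force(9, 9), spring, wt_cluster)
        assert np.array_equal(geometry_readout(resp, 0.0), resp.bead_coordinates)
        a = geometry_readout(resp, noise_sd=5.0, seed=7)
        b = geometry_readout(resp, noise_sd=5.0, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, geometry_readout(resp, 5.0, seed=8))

    def test_noise_is_unbiased(self, wt_cluster, spring):
        resp = anchored_elongation(force(9, 9), spring, wt_cluster)
        truth = end_to_end_length(resp.bead_coordinates)
        n_rep, sd = 1000, 5.0
        lengths = [
            end_to_end_length(geometry_readout(resp, sd, seed=s))
            for s in range(n_rep)
        ]
        se = np.sqrt(2 * sd**2 / n_rep)  # SE of the end-to-end mean
        assert abs(np.mean(lengths) - truth) < 3 * se

    def test_geometry_table_schema(self, wt_cluster, spring):
        f = force(2, 9)
        resp = anchored_elongation(f, spring, wt_cluster)
        state = extrusion_state(wt_cluster, f, resp, spring)
        table = geometry_table(wt_cluster, resp, state)
        assert list(table.columns) == ["locus", "rank", "coordinate_nm",
                                       "transcribing"]
        assert table["transcribing"].sum() == 2


class TestCalibration:
    def test_closed_form_value(self):
        assert calibrate_spring(100.0, 81.0, 5.6) == pytest.approx(
            0.1760869565, rel=1e-9)

    def test_round_trip(self, wt_cluster):
        k = calibrate_spring(100.0, 81.0, 5.6)
        resp = anchored_elongation(
            force(9, 9), SpringParams(spring_constant=k), wt_cluster)
        assert resp.total_length / 100.0 == pytest.approx(5.6)

    def test_rigid_limit_and_invalid_ratio(self):
        assert calibrate_spring(100.0, 81.0, 1.0 + 1e-9) > 1e8
        with pytest.raises(ParameterError):
            calibrate_spring(100.0, 81.0, 1.0)
        with pytest.raises(ParameterError):
            calibrate_spring(100.0, 0.0, 5.6)
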