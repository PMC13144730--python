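"""Analytic loop-size distributions and the polymer contact model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stripefit.model import (
    ExtrusionParams,
    NO_BLOCKS,
    Roadblock,
    RoadblockSet,
    blocked_loop_density,
    composite_loop_density,
    contact_p0,
    contact_with_loop,
    free_loop_density,
    predict_contact_profile,
    predict_ratio_profile,
)


class TestTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(processivity_p=0.0, density_d=0.1),
            dict(processivity_p=-5.0, density_d=0.1),
            dict(processivity_p=100.0, density_d=1.2),
            dict(processivity_p=100.0, density_d=0.1, gamma=0.0),
            dict(processivity_p=100.0, density_d=0.1, amplitude_A=-1.0),
        ],
    )
    def test_params_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ExtrusionParams(**kwargs)

    def test_roadblock_invariants(self):
        with pytest.raises(ValueError):
            Roadblock(position_l=0.0, pause_alpha=0.5)
        with pytest.raises(ValueError):
            Roadblock(position_l=50.0, pause_alpha=1.5)
        with pytest.raises(ValueError):
            Roadblock(position_l=10.0, pause_alpha=0.5, domain_width=25.0)

    def test_roadblockset_ordering_and_overlap(self):
        with pytest.raises(ValueError):
            RoadblockSet([Roadblock(100.0, 0.5), Roadblock(50.0, 0.5)])
        with pytest.raises(ValueError):
            RoadblockSet(
                [Roadblock(100.0, 0.5, 30.0), Roadblock(110.0, 0.5, 30.0)]
            )
        with pytest.raises(ValueError):
            RoadblockSet([Roadblock(100.0, 0.5)], terminal_position=80.0)


class TestLoopDensities:
    def test_free_density_closed_form(self):
        dist = free_loop_density(ExtrusionParams(100.0, 0.1), max_l=1000.0)
        # exponential density (1/p) e^(-l/p) at l = p
        assert dist.density_at(100.0) == pytest.approx(math.exp(-1.0) / 100.0, rel=1e-4)

    def test_free_density_normalizes(self):
        dist = free_loop_density(ExtrusionParams(150.0, 0.1), max_l=1500.0, bin_width=1.0)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_free_terminal_atom_is_truncated_tail(self):
        dist = free_loop_density(ExtrusionParams(150.0, 0.1), max_l=600.0)
        assert dist.atoms[600.0] == pytest.approx(math.exp(-4.0), rel=1e-12)

    def test_blocked_atom_mass(self):
        dist = blocked_loop_density(ExtrusionParams(100.0, 0.1), block_position=50.0)
        assert dist.atoms[50.0] == pytest.approx(math.exp(-0.5), rel=1e-12)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_blocked_density_zero_beyond_block(self):
        dist = blocked_loop_density(ExtrusionParams(100.0, 0.1), 50.0, max_l=500.0)
        beyond = dist.grid > 50.0
        assert not beyond.any() or np.all(dist.continuous_density[beyond] == 0)
        assert dist.grid[-1] == 50.0

    def test_blocked_requires_positive_position(self):
        with pytest.raises(ValueError):
            blocked_loop_density(ExtrusionParams(100.0, 0.1), block_position=-3.0)

    def test_composite_two_blocks_atom_masses(self):
        # survive the first (alpha 0.5) with prob 0.5, then hit the
        # impermeable second: atoms 0.5 e^-0.5 at 50 kb, 0.5 e^-1 at 100 kb
        params = ExtrusionParams(100.0, 0.1)
        blocks = RoadblockSet([Roadblock(50.0, 0.5), Roadblock(100.0, 1.0)])
        dist = composite_loop_density(params, blocks)
        assert dist.atoms[50.0] == pytest.approx(0.5 * math.exp(-0.5), rel=1e-12)
        assert dist.atoms[100.0] == pytest.approx(0.5 * math.exp(-1.0), rel=1e-12)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_composite_no_blocks_reduces_to_free(self):
        params = ExtrusionParams(120.0, 0.1)
        free = free_loop_density(params)
        comp = composite_loop_density(params, NO_BLOCKS)
        np.testing.assert_allclose(comp.continuous_density, free.continuous_density)
        assert comp.atoms == free.atoms

    def test_composite_single_impermeable_equals_blocked(self):
        params = ExtrusionParams(140.0, 0.1)
        comp = composite_loop_density(params, RoadblockSet([Roadblock(90.0, 1.0)]))
        blocked = blocked_loop_density(params, 90.0)
        np.testing.assert_allclose(comp.continuous_density, blocked.continuous_density)
        assert comp.atoms == pytest.approx(blocked.atoms)

    def test_domain_block_averages_over_placements(self):
        # impermeable barrier uniform over 11 grid points in [115, 125]
        params = ExtrusionParams(150.0, 0.1)
        blocks = RoadblockSet([Roadblock(120.0, 1.0, domain_width=10.0)])
        dist = composite_loop_density(params, blocks)
        positions = sorted(dist.atoms)
        assert positions == [115.0 + k for k in range(11)]
        expected_total = np.mean([math.exp(-l / 150.0) for l in positions])
        assert sum(dist.atoms.values()) == pytest.approx(expected_total, rel=1e-9)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(
        p=st.floats(20.0, 400.0),
        alphas=st.lists(st.floats(0.0, 1.0), min_size=0, max_size=3),
        data=st.data(),
    )
    def test_normalization_property(self, p, alphas, data):
        """Any valid roadblock configuration keeps total mass at 1."""
        positions = sorted(
            data.draw(
                st.lists(
                    st.integers(10, 900), min_size=len(alphas), max_size=len(alphas),
                    unique=True,
                )
            )
        )
        blocks = RoadblockSet(
            [Roadblock(float(l), a) for l, a in zip(positions, alphas)]
        )
        dist = composite_loop_density(ExtrusionParams(p, 0.1), blocks)
        assert dist.total_mass == pytest.approx(1.0, abs=1e-6)


class TestContactModel:
    @pytest.mark.parametrize(
        "s,gamma,A,expected",
        [(1.0, 1.5, 1.0, 1.0), (4.0, 1.5, 1.0, 0.125), (9.0, 1.0, 2.0, 2.0 / 9.0)],
    )
    def test_background_power_law(self, s, gamma, A, expected):
        params = ExtrusionParams(100.0, 0.1, gamma=gamma, amplitude_A=A)
        assert contact_p0(s, params) == pytest.approx(expected, rel=1e-12)

    def test_background_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            contact_p0(0.0, ExtrusionParams(100.0, 0.1))

    def test_loop_closure_contact_is_one(self):
        params = ExtrusionParams(100.0, 0.1)
        for l in (5.0, 80.0, 333.0):
            assert contact_with_loop(l, l, params) == 1.0

    def test_within_loop_value(self):
        params = ExtrusionParams(100.0, 0.1)
        expected = (2.0 * 6.0 / 8.0) ** -1.5
        assert contact_with_loop(2.0, 8.0, params) == pytest.approx(expected, rel=1e-12)

    def test_within_loop_symmetry(self):
        params = ExtrusionParams(100.0, 0.1)
        s = np.arange(1.0, 50.0)
        np.testing.assert_allclose(
            contact_with_loop(s, 50.0, params), contact_with_loop(50.0 - s, 50.0, params)
        )

    def test_rejects_nonpositive_inputs(self):
        params = ExtrusionParams(100.0, 0.1)
        with pytest.raises(ValueError):
            contact_with_loop(-1.0, 10.0, params)
        with pytest.raises(ValueError):
            contact_with_loop(5.0, 0.0, params)


class TestPredictedProfiles:
    def test_d_zero_profile_is_background(self):
        s = np.arange(1.0, 301.0)
        params = ExtrusionParams(150.0, 0.0)
        prof = predict_contact_profile(params, NO_BLOCKS, s)
        np.testing.assert_array_equal(prof.values, contact_p0(s, params))

    def test_matches_naive_double_sum(self):
        """Vectorized profile equals an independent scalar double loop."""
        s_grid = np.arange(1.0, 201.0)
        params = ExtrusionParams(150.0, 0.1)
        prof = predict_contact_profile(params, NO_BLOCKS, s_grid)

        dist = composite_loop_density(params, NO_BLOCKS)
        masses = dist.continuous_density * dist.bin_width
        atom_masses = dict(dist.atoms)
        expected = []
        for s in s_grid:
            acc = (1.0 - params.density_d) * s ** -params.gamma
            for l, m_l in list(zip(dist.grid, masses)) + list(atom_masses.items()):
                if m_l == 0.0:
                    continue
                if s == l:
                    k = 1.0
                elif s < l:
                    k = max(1.0, (s * (l - s) / l)) ** -params.gamma
                else:
                    k = max(1.0, s - l) ** -params.gamma
                acc += params.density_d * m_l * k
            expected.append(acc)
        np.testing.assert_allclose(prof.values, expected, rtol=1e-10)

    def test_impermeable_block_peaks_at_block(self):
        s = np.arange(1.0, 501.0)
        blocks = RoadblockSet([Roadblock(165.0, 1.0)])
        r = predict_ratio_profile(ExtrusionParams(150.0, 0.1), blocks, s).values
        apex = s[np.argmax(r)]
        assert abs(apex - 165.0) <= 1.0  # 1-bin plateau around the atom
        assert r.max() > 50.0
        # beyond the block the loop-free leg decays toward the mixture of
        # (1 - d) and the shortened-chain term
        assert r[250] < r[165] / 10

    def test_d_zero_ratio_is_exactly_one(self):
        s = np.arange(1.0, 201.0)
        r = predict_ratio_profile(ExtrusionParams(150.0, 0.0), NO_BLOCKS, s)
        np.testing.assert_array_equal(r.values, np.ones_like(s))

    def test_ratio_lower_bound(self):
        s = np.arange(1.0, 801.0)
        for p, d in [(60.0, 0.3), (170.0, 0.08), (400.0, 0.15)]:
            r = predict_ratio_profile(ExtrusionParams(p, d), NO_BLOCKS, s)
            assert np.all(r.values >= (1.0 - d) - 1e-12)

    def test_ratio_rises_to_peak_then_decays(self):
        """Enrichment peaks near the processivity scale and relaxes toward 1
        far beyond the loop-size support."""
        s = np.arange(1.0, 2001.0)
        r = predict_ratio_profile(ExtrusionParams(170.0, 0.08), NO_BLOCKS, s).values
        apex = s[np.argmax(r)]
        assert 100.0 <= apex <= 500.0
        assert r[np.argmax(r)] > r[9] > 1.0
        assert abs(r[-1] - 1.0) < 0.05  # support ends at 10 p = 1700

    def test_small_p_limit_leaves_background(self):
        """Vanishing processivity: bound extruders hold negligible loops and
        the profile returns to the background away from the viewpoint."""
        s = np.arange(1.0, 501.0)
        r = predict_ratio_profile(ExtrusionParams(2.0, 0.3), NO_BLOCKS, s).values
        assert np.allclose(r[49:], 1.0, atol=0.03)

    def test_amplitude_enters_only_via_closure_bins(self):
        """A rescales background and loop legs alike; only the unit closure
        contact at s = l escapes, so the ratio difference between A = 1 and
        A = 7 must equal the closure-bin term exactly."""
        s = np.arange(1.0, 501.0)
        p1 = ExtrusionParams(150.0, 0.1, amplitude_A=1.0)
        p7 = ExtrusionParams(150.0, 0.1, amplitude_A=7.0)
        r1 = predict_ratio_profile(p1, NO_BLOCKS, s).values
        r7 = predict_ratio_profile(p7, NO_BLOCKS, s).values
        dist = composite_loop_density(p1, NO_BLOCKS)
        m = dist.masses()[: s.size]
        closure_1 = 0.1 * m * 1.0 / contact_p0(s, p1)
        closure_7 = 0.1 * m * 1.0 / contact_p0(s, p7)
        np.testing.assert_allclose(r1 - r7, closure_1 - closure_7, rtol=1e-9)

    def test_empty_s_grid_rejected(self):
        with pytest.raises(ValueError):
            predict_contact_profile(ExtrusionParams(100.0, 0.1), NO_BLOCKS, np.array([]))
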