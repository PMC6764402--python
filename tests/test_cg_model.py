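"""Topology, potentials and system construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synagg.cg_model import (
    PHILIC,
    PHOBIC,
    SEED,
    ForceFieldParams,
    build_monomer_topology,
    build_system,
    default_box_length,
    doped_count,
    pair_potential,
    total_energy_forces,
)

WCA_MIN = 2.0 ** (1.0 / 6.0)


class TestMonomerTopology:
    def test_undoped_pattern_is_amphiphilic_triblock(self):
        topo = build_monomer_topology(doped=False)
        assert topo.bead_types == tuple([PHILIC] * 5 + [PHOBIC] * 5 + [PHILIC] * 5)
        assert len(topo.bonds) == 14
        assert len(topo.angles) == 13
        assert topo.bonds == tuple((i, i + 1) for i in range(14))

    def test_doped_variant_changes_only_terminal_bead(self):
        undoped = build_monomer_topology(doped=False)
        doped = build_monomer_topology(doped=True)
        diff = [
            i
            for i, (a, b) in enumerate(zip(undoped.bead_types, doped.bead_types))
            if a != b
        ]
        assert diff == [14]
        assert doped.bead_types[14] == SEED


class TestPairPotential:
    def test_lj_minimum_is_minus_epsilon_plus_shift(self, ff):
        unshifted = ForceFieldParams(energy_shift=False)
        assert pair_potential(PHOBIC, PHOBIC, WCA_MIN, unshifted) == pytest.approx(-1.0)
        shifted = pair_potential(PHOBIC, PHOBIC, WCA_MIN, ff)
        assert shifted == pytest.approx(-1.0 - ff.lj_shift)

    def test_philic_pairs_are_wca(self, ff):
        # zero exactly beyond the WCA minimum, repulsive below
        assert pair_potential(PHILIC, PHOBIC, 1.5, ff) == 0.0
        assert pair_potential(PHILIC, PHILIC, WCA_MIN * 1.001, ff) == 0.0
        assert pair_potential(PHILIC, SEED, 0.95, ff) > 0.0

    def test_all_pairs_vanish_beyond_lj_cutoff(self, ff):
        for a in (PHILIC, PHOBIC, SEED):
            for b in (PHILIC, PHOBIC, SEED):
                assert pair_potential(a, b, ff.lj_cutoff, ff) == 0.0
                assert pair_potential(a, b, 3.0, ff) == 0.0

    def test_symmetry_and_seed_equivalence_on_r_grid(self, ff):
        r_grid = np.linspace(0.8, 2.6, 50)
        for r in r_grid:
            for a in (PHILIC, PHOBIC, SEED):
                for b in (PHILIC, PHOBIC, SEED):
                    assert pair_potential(a, b, r, ff) == pair_potential(b, a, r, ff)
            # SEED is interaction-equivalent to PHOBIC
            u_hh = pair_potential(PHOBIC, PHOBIC, r, ff)
            assert pair_potential(SEED, PHOBIC, r, ff) == u_hh
            assert pair_potential(SEED, SEED, r, ff) == u_hh

    def test_nonpositive_separation_rejected(self, ff):
        with pytest.raises(ValueError):
            pair_potential(PHOBIC, PHOBIC, 0.0, ff)


class TestEnergyForces:
    def test_forces_match_finite_differences(self, small_system, ff):
        state = small_system
        _, forces, _ = total_energy_forces(state, ff)
        h = 1e-5
        rng = np.random.default_rng(5)
        picks = rng.integers(0, state.n_beads, size=12)
        for i in picks:
            for d in range(3):
                sp = state.copy()
                sp.coordinates[i, d] += h
                sm = state.copy()
                sm.coordinates[i, d] -= h
                ep, _, _ = total_energy_forces(sp, ff)
                em, _, _ = total_energy_forces(sm, ff)
                fd = -(ep - em) / (2 * h)
                assert forces[i, d] == pytest.approx(fd, abs=1e-4)

    def test_energy_invariant_under_lattice_translation(self, small_system, ff):
        e0, _, _ = total_energy_forces(small_system, ff)
        shifted = small_system.copy()
        shifted.coordinates += small_system.box_length * np.array([1.0, -2.0, 3.0])
        e1, _, _ = total_energy_forces(shifted, ff)
        assert abs(e1 - e0) < 1e-10

    def test_energy_invariant_under_rewrapping(self, small_system, ff):
        e0, _, _ = total_energy_forces(small_system, ff)
        rewrapped = small_system.copy()
        rewrapped.coordinates = np.mod(
            rewrapped.coordinates + 0.37 * rewrapped.box_length,
            rewrapped.box_length,
        )
        e1, _, _ = total_energy_forces(rewrapped, ff)
        assert abs(e1 - e0) < 1e-10

    def test_overlapping_beads_flagged_but_finite(self, ff):
        state = build_system(2, 0.0, 40.0, seed=1)
        # move one whole chain on top of the other, bead-for-bead offset 0.1
        state.coordinates[15:] = state.coordinates[:15] + 0.1
        energy, _, overlap = total_energy_forces(state, ff)
        assert overlap
        assert np.isfinite(energy)


class TestBuildSystem:
    def test_doped_counts_follow_rounding_rule(self):
        assert build_system(512, 0.0, 60.0, seed=3).n_doped == 0
        state = build_system(512, 0.3, 60.0, seed=3)
        assert state.n_doped == 154  # round(153.6)
        assert doped_count(0.3, 512) == 154
        assert doped_count(1.0, 512) == 512

    def test_same_seed_reproduces_state_exactly(self):
        a = build_system(20, 0.5, 20.0, seed=11)
        b = build_system(20, 0.5, 20.0, seed=11)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.array_equal(a.velocities, b.velocities)
        assert np.array_equal(a.bead_types, b.bead_types)

    def test_minimum_separation_respected(self):
        from scipy.spatial import cKDTree

        state = build_system(30, 0.2, 18.0, seed=2)
        tree = cKDTree(
            np.mod(state.coordinates, state.box_length), boxsize=state.box_length
        )
        pairs = tree.query_pairs(0.9 - 1e-9)
        assert not pairs

    def test_packing_failure_reports_density(self):
        with pytest.raises(RuntimeError, match="density"):
            build_system(400, 0.0, 15.5, seed=1, max_attempts=2000)

    def test_default_box_keeps_reference_density(self):
        assert default_box_length(512) == pytest.approx(60.0)
        ratio = (default_box_length(128) / 60.0) ** 3
        assert ratio == pytest.approx(128 / 512)

    @given(
        phi=st.floats(0.0, 1.0),
        n=st.integers(1, 600),
    )
    @settings(max_examples=60, deadline=None)
    def test_doped_count_rounds_half_away_from_zero(self, phi, n):
        c = doped_count(phi, n)
        assert 0 <= c <= n
        assert c == int(math.floor(phi * n + 0.5))
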