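"""Hexagonal-lattice individual-based model: geometry, fields, updates."""

import numpy as np
import pytest

from psdcoex import SpatialParams, parse_community, run_simulation
from psdcoex.spatial import (
    EMPTY,
    NEIGHBOR_OFFSETS,
    _death_probabilities,
    compute_fields,
    diffusion_kernel,
    hex_min_image_distance,
    init_lattice,
    step_generation,
)


@pytest.fixture
def psd():
    return parse_community("[P,S,D]")


def small_params(**kw) -> SpatialParams:
    defaults = dict(grid_size=30, p_init=0.5, generations=50, replicates=1)
    defaults.update(kw)
    return SpatialParams(**defaults)


class TestGeometry:
    def test_six_distinct_neighbours_under_wrap(self):
        L = 5
        for q in range(L):
            for r in range(L):
                nbrs = {((q + dq) % L, (r + dr) % L) for dq, dr in NEIGHBOR_OFFSETS}
                assert len(nbrs) == 6
                assert (q, r) not in nbrs

    def test_neighbour_offsets_at_unit_distance(self):
        dist = hex_min_image_distance(7)
        for dq, dr in NEIGHBOR_OFFSETS:
            assert dist[dq % 7, dr % 7] == pytest.approx(1.0)

    def test_kernel_point_mass_at_zero_diffusivity(self):
        kern = diffusion_kernel(8, 0.0)
        assert kern[0, 0] == 1.0 and kern.sum() == 1.0

    def test_kernel_truncation(self):
        K = 1.0
        kern = diffusion_kernel(20, K)
        dist = hex_min_image_distance(20)
        assert np.all(kern[dist > 3.0] == 0.0)
        assert kern[0, 0] == 1.0


class TestInitLattice:
    def test_zero_occupancy(self, psd):
        state = init_lattice(small_params(p_init=0.0), psd, np.random.default_rng(0))
        assert np.all(state.occupancy == EMPTY)

    def test_occupied_fraction_concentrates(self, psd):
        sp = SpatialParams(grid_size=200, p_init=0.5)
        state = init_lattice(sp, psd, np.random.default_rng(1))
        frac = state.occupied_fraction()
        sigma = np.sqrt(0.25 / 200**2)
        assert abs(frac - 0.5) < 3 * sigma

    def test_strain_labels_roughly_uniform(self, psd):
        sp = SpatialParams(grid_size=100, p_init=0.6)
        state = init_lattice(sp, psd, np.random.default_rng(2))
        counts = state.strain_counts(3)
        assert counts.min() > 0.8 * counts.mean()


class TestFields:
    def test_no_producers_zero_field(self):
        c = parse_community("[S,D,R]")
        state = init_lattice(small_params(), c, np.random.default_rng(0))
        compute_fields(state, c, small_params())
        assert np.all(state.antibiotic_fields == 0.0)

    def test_single_source_mass_and_symmetry(self, psd):
        sp = small_params(KP=2.0)
        state = init_lattice(small_params(p_init=0.0), psd, np.random.default_rng(0))
        state.occupancy[7, 11] = 0  # lone producer
        compute_fields(state, psd, sp)
        field = state.antibiotic_fields[0]
        kern = diffusion_kernel(30, 2.0)
        assert field.sum() == pytest.approx(sp.up * kern.sum(), rel=1e-10)
        # the field is the kernel translated to the source
        assert field[7, 11] == pytest.approx(sp.up * kern[0, 0], rel=1e-10)
        rolled = np.roll(np.roll(field, -7, axis=0), -11, axis=1)
        assert np.allclose(rolled, sp.up * kern, atol=1e-10)

    def test_linearity_in_sources(self, psd):
        sp = small_params(KP=1.5)
        empty = small_params(p_init=0.0)
        one = init_lattice(empty, psd, np.random.default_rng(0))
        one.occupancy[3, 3] = 0
        compute_fields(one, psd, sp)
        two = init_lattice(empty, psd, np.random.default_rng(0))
        two.occupancy[3, 3] = 0
        two.occupancy[20, 8] = 0
        compute_fields(two, psd, sp)
        lone = init_lattice(empty, psd, np.random.default_rng(0))
        lone.occupancy[20, 8] = 0
        compute_fields(lone, psd, sp)
        assert np.allclose(
            two.antibiotic_fields, one.antibiotic_fields + lone.antibiotic_fields,
            atol=1e-9,
        )

    def test_death_probability_baseline_without_antibiotic(self, psd):
        sp = small_params()
        state = init_lattice(sp, psd, np.random.default_rng(0))
        state.occupancy[state.occupancy == 0] = 1  # remove all producers
        compute_fields(state, psd, sp)
        dp = _death_probabilities(state, psd, sp)
        assert np.allclose(dp, sp.d, atol=1e-15)


class TestStepGeneration:
    def test_certain_death_empties_lattice(self, psd):
        sp = small_params(d=1.0)
        state = init_lattice(sp, psd, np.random.default_rng(3))
        step_generation(state, psd, sp, np.random.default_rng(4))
        assert np.all(state.occupancy == EMPTY)

    def test_occupancy_changes_only_by_birth_or_death(self, psd):
        """Site-level audit: deaths empty a site; births fill an empty site
        from an identical-strain neighbour; nothing else changes."""
        sp = small_params(KP=2.0, KD=2.0)
        state = init_lattice(sp, psd, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        L = sp.grid_size
        for _ in range(30):
            before = state.occupancy.copy()
            step_generation(state, psd, sp, rng)
            after = state.occupancy
            changed = np.argwhere(before != after)
            for q, r in changed:
                if after[q, r] == EMPTY:
                    assert before[q, r] != EMPTY  # death
                else:
                    # a birth: into an empty site, or into a site whose
                    # occupant died earlier in the same generation; either
                    # way the newborn's strain must be present among the
                    # neighbours (the parent lived next door)
                    s = after[q, r]
                    neighbours = [
                        before[(q + dq) % L, (r + dr) % L]
                        for dq, dr in NEIGHBOR_OFFSETS
                    ] + [
                        after[(q + dq) % L, (r + dr) % L]
                        for dq, dr in NEIGHBOR_OFFSETS
                    ]
                    assert s in neighbours

    def test_bit_reproducible(self, psd):
        sp = small_params(KP=3.0, KD=1.0)
        a = run_simulation(psd, sp, np.random.default_rng(7), generations=20)
        b = run_simulation(psd, sp, np.random.default_rng(7), generations=20)
        assert np.array_equal(a.abundances, b.abundances)
        assert np.array_equal(a.final_state.occupancy, b.final_state.occupancy)

    def test_neutral_labels_stay_balanced(self):
        # no producers, zero costs: strain labels are exchangeable
        c = parse_community("[S,R]")
        sp = SpatialParams(
            grid_size=40, p_init=0.5, cr=0.0, cd=0.0, cp=0.0, KP=1.0, KD=1.0
        )
        totals = np.zeros(2)
        for rep in range(8):
            res = run_simulation(c, sp, np.random.default_rng(100 + rep), generations=60)
            totals += res.abundances[-1]
        assert abs(totals[0] - totals[1]) / totals.sum() < 0.2

    def test_invalid_birth_probability_rejected(self, psd):
        sp = small_params(g=0.1, cp=0.15)  # producer cost exceeds g
        with pytest.raises(ValueError, match="birth probabilities"):
            sp.birth_probabilities(psd)


class TestLongRunBehaviour:
    def test_no_antibiotic_reach_reduces_to_cost_competition(self, psd):
        """With KP = 0 the antibiotic never leaves the producer's own site,
        and the cheapest strain (sensitive) outcompetes the others, matching
        the well-mixed outcome."""
        sp = SpatialParams(grid_size=40, p_init=0.5, KP=0.0, KD=0.0)
        res = run_simulation(psd, sp, np.random.default_rng(11), generations=800)
        final = res.abundances[-50:].mean(axis=0)
        assert final[1] > final[0] and final[1] > final[2]
        assert final[1] > 0.5 * res.occupied[-1]
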