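"""Microscopic dynamics: initialisation, energies, move rules, Metropolis
updates and the stationary distribution of the equilibrium variant."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import activenematic as an
from activenematic.core import DIRECTIONS, PI

from conftest import make_state, random_state


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

class TestInitLattice:
    def test_zero_density_gives_empty_lattice(self, rng):
        state = an.init_lattice(an.SimParams(L=4, C=0.0, beta_eps=1.0,
                                             burn_in_iterations=0,
                                             measure_iterations=0), rng)
        assert state.N == 0
        assert state.occupancy.sum() == 0

    def test_particle_count_and_exclusion(self, rng):
        p = an.SimParams(L=10, C=0.5, beta_eps=1.0, burn_in_iterations=0,
                         measure_iterations=0)
        state = an.init_lattice(p, rng)
        assert state.N == 50
        assert state.occupancy.sum() == 50
        assert state.occupancy.max() == 1
        state.validate()

    def test_same_seed_bit_identical(self):
        p = an.SimParams(L=12, C=0.4, beta_eps=1.0, burn_in_iterations=0,
                         measure_iterations=0)
        a = an.init_lattice(p, np.random.default_rng(7))
        b = an.init_lattice(p, np.random.default_rng(7))
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.orientation, b.orientation, equal_nan=True)

    def test_orientations_in_fundamental_domain(self, rng):
        p = an.SimParams(L=20, C=0.7, beta_eps=1.0, burn_in_iterations=0,
                         measure_iterations=0)
        state = an.init_lattice(p, rng)
        th = state.orientation[state.occupancy == 1]
        assert np.all((th >= 0) & (th < PI))

    @pytest.mark.parametrize("L,C", [(1, 0.5), (4, -0.1), (4, 1.5)])
    def test_invalid_parameters_rejected(self, L, C):
        with pytest.raises(an.ParameterError):
            an.SimParams(L=L, C=C, beta_eps=1.0)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

class TestEnergies:
    @pytest.mark.parametrize("a,b,expected", [
        (0.3, 0.3, -1.0),        # aligned neighbours minimise the energy
        (0.0, PI / 2, 1.0),      # perpendicular maximise it
        (0.0, PI / 4, 0.0),      # cos(pi/2) = 0
    ])
    def test_pair_energy_values(self, a, b, expected):
        assert an.pair_energy(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, PI - 1e-9), st.floats(0, PI - 1e-9))
    @settings(derandomize=True, max_examples=50)
    def test_pair_energy_symmetric_and_apolar(self, a, b):
        e = an.pair_energy(a, b)
        assert an.pair_energy(b, a) == pytest.approx(e, abs=1e-12)
        assert an.pair_energy(a + PI, b) == pytest.approx(e, abs=1e-12)
        assert an.pair_energy(a, b + PI) == pytest.approx(e, abs=1e-12)

    def test_local_energy_isolated_particle(self):
        state = make_state(6, [(3, 3)], [0.4])
        assert an.local_energy(state, (3, 3), 0.4) == 0.0

    def test_local_energy_two_aligned_neighbours(self):
        state = make_state(6, [(3, 3), (2, 3), (4, 3)], [1.0, 1.0, 1.0])
        assert an.local_energy(state, (3, 3), 1.0) == pytest.approx(-2.0)

    @given(st.integers(0, 10 ** 6))
    @settings(derandomize=True, max_examples=25)
    def test_local_energy_matches_total_energy_difference(self, seed):
        """Independent oracle: the bond energy touching a site equals the
        total-Hamiltonian change of removing that particle."""
        r = np.random.default_rng(seed)
        state = random_state(5, 0.6, seed)
        k = int(r.integers(state.N))
        x, y = map(int, state.particles[k])
        th = float(state.orientation[x, y])
        removed = state.copy()
        removed.occupancy[x, y] = 0
        removed.orientation[x, y] = np.nan
        removed = an.LatticeState.from_fields(removed.occupancy, removed.orientation)
        oracle = an.total_energy(state) - an.total_energy(removed)
        assert an.local_energy(state, (x, y), th) == pytest.approx(oracle, abs=1e-10)

    @given(st.integers(0, 10 ** 6), st.floats(0, PI - 1e-9))
    @settings(derandomize=True, max_examples=25)
    def test_total_energy_global_rotation_invariant(self, seed, phi):
        state = random_state(6, 0.7, seed)
        e0 = an.total_energy(state)
        rotated = state.copy()
        rotated.orientation = np.where(rotated.occupancy == 1,
                                       an.wrap_angle(rotated.orientation + phi),
                                       np.nan)
        assert an.total_energy(rotated) == pytest.approx(e0, abs=1e-9)


# ---------------------------------------------------------------------------
# movement rules
# ---------------------------------------------------------------------------

class TestMoveTargets:
    def test_equilibrium_targets_uniform(self, rng):
        n = 100_000
        counts = {}
        for _ in range(n):
            t = an.choose_move_target_equilibrium((2, 2), 5, rng)
            counts[t] = counts.get(t, 0) + 1
        assert set(counts) == {(3, 2), (1, 2), (2, 3), (2, 1)}
        sigma = math.sqrt(0.25 * 0.75 / n)
        for c in counts.values():
            assert abs(c / n - 0.25) < 3 * sigma

    def test_periodic_wrapping_at_origin(self, rng):
        for _ in range(100):
            x, y = an.choose_move_target_equilibrium((0, 0), 4, rng)
            assert 0 <= x < 4 and 0 <= y < 4

    def test_active_vertical_for_theta_near_pi_half(self, rng):
        n = 50_000
        counts = {}
        for _ in range(n):
            t = an.choose_move_target_active((2, 2), PI / 2, 5, rng)
            counts[t] = counts.get(t, 0) + 1
        assert set(counts) == {(2, 3), (2, 1)}
        sigma = math.sqrt(0.25 / n)
        for c in counts.values():
            assert abs(c / n - 0.5) < 3 * sigma

    def test_active_horizontal_for_theta_zero(self, rng):
        targets = {an.choose_move_target_active((2, 2), 0.0, 5, rng)
                   for _ in range(200)}
        assert targets == {(3, 2), (1, 2)}

    def test_active_boundary_quarter_pi_is_horizontal(self, rng):
        # the axis rule uses the strict inequality pi/4 < theta
        targets = {an.choose_move_target_active((2, 2), PI / 4, 5, rng)
                   for _ in range(200)}
        assert targets == {(3, 2), (1, 2)}
        targets = {an.choose_move_target_active((2, 2), PI / 4 + 1e-9, 5, rng)
                   for _ in range(200)}
        assert targets == {(2, 3), (2, 1)}


class TestAttemptMove:
    def test_move_to_empty_site_transfers_particle(self):
        state = make_state(4, [(1, 1)], [0.5])
        assert an.attempt_move(state, (1, 1), (2, 1)) is True
        assert state.occupancy[1, 1] == 0 and state.occupancy[2, 1] == 1
        assert state.orientation[2, 1] == 0.5
        assert state.N == 1
        state.validate()

    def test_move_to_occupied_site_rejected(self):
        state = make_state(4, [(1, 1), (2, 1)], [0.5, 1.5])
        before = state.copy()
        assert an.attempt_move(state, (1, 1), (2, 1)) is False
        assert np.array_equal(state.occupancy, before.occupancy)
        assert np.array_equal(state.orientation, before.orientation, equal_nan=True)

    def test_move_from_empty_site_is_error(self):
        state = make_state(4, [(1, 1)], [0.5])
        with pytest.raises(an.ParameterError):
            an.attempt_move(state, (0, 0), (0, 1))


# ---------------------------------------------------------------------------
# Metropolis orientation update
# ---------------------------------------------------------------------------

class TestMetropolis:
    def test_energy_lowering_always_accepted(self, rng):
        # candidate aligns with the neighbour: dH < 0
        for _ in range(200):
            state = make_state(4, [(1, 1), (2, 1)], [PI / 2, 0.0])
            assert an.metropolis_orientation_update(
                state, (1, 1), 5.0, rng, proposal=[0.0]) is True

    def test_acceptance_rate_at_ln2_barrier(self, rng):
        """With beta_eps * dH = ln 2 the Metropolis acceptance is exactly 1/2."""
        theta1 = 0.5 * math.acos(1.0 - math.log(2.0))
        state = make_state(4, [(1, 1), (2, 1)], [0.0, 0.0])
        n = 100_000
        accepted = 0
        for _ in range(n):
            if an.metropolis_orientation_update(state, (1, 1), 1.0, rng,
                                                proposal=[theta1]):
                accepted += 1
                state.orientation[1, 1] = 0.0
        sigma = math.sqrt(0.25 / n)
        assert abs(accepted / n - 0.5) < 3 * sigma

    def test_isolated_particle_always_accepts_uniform_resample(self, rng):
        state = make_state(6, [(3, 3)], [0.2])
        samples = []
        for _ in range(2000):
            assert an.metropolis_orientation_update(state, (3, 3), 2.0, rng)
            samples.append(state.orientation[3, 3])
        samples = np.asarray(samples)
        assert np.all((samples >= 0) & (samples < PI))
        # uniformity: quartile counts of a flat distribution
        counts, _ = np.histogram(samples, bins=4, range=(0, PI))
        assert np.all(np.abs(counts / 2000 - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 2000))


# ---------------------------------------------------------------------------
# iteration-level behaviour
# ---------------------------------------------------------------------------

class TestMcIteration:
    def test_particle_number_conserved(self, rng):
        p = an.SimParams(L=8, C=0.5, beta_eps=1.5, burn_in_iterations=0,
                         measure_iterations=0)
        state = an.init_lattice(p, rng)
        for _ in range(20):
            an.mc_iteration(state, p, rng)
            assert state.occupancy.sum() == p.N
        state.validate()

    def test_full_filling_blocks_all_moves(self, rng):
        p = an.SimParams(L=6, C=1.0, beta_eps=1.0, variant="active",
                         burn_in_iterations=0, measure_iterations=0)
        state = an.init_lattice(p, rng)
        counters = an.mc_iteration(state, p, rng)
        assert counters["moves_accepted"] == 0

    @given(st.integers(0, 10 ** 6))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_invariants_after_random_dynamics(self, seed):
        p = an.SimParams(L=6, C=0.6, beta_eps=1.2, variant="active",
                         burn_in_iterations=0, measure_iterations=0, seed=seed)
        r = np.random.default_rng(seed)
        state = an.init_lattice(p, r)
        for _ in range(10):
            an.mc_iteration(state, p, r)
        state.validate()


# ---------------------------------------------------------------------------
# stationary-distribution oracles
# ---------------------------------------------------------------------------

ANGLES = np.array([0.3, 1.1, 2.0])
SITES = [(x, y) for x in range(2) for y in range(2)]


def _slot_multiplicity(pos_a, pos_b):
    """Number of nearest-neighbour slots of pos_a occupied by pos_b on the
    2x2 torus (wrapped neighbours coincide pairwise)."""
    x, y = pos_a
    return sum(((x + dx) % 2, (y + dy) % 2) == pos_b for dx, dy in DIRECTIONS)


def _two_particle_chain():
    """Exact transition matrix of one elementary step for 2 particles on a
    2x2 lattice with the discrete angle set, equilibrium variant."""
    beta_eps = 1.5
    K = len(ANGLES)
    states = [(p0, p1, a0, a1) for p0 in range(4) for p1 in range(4)
              if p0 != p1 for a0 in range(K) for a1 in range(K)]
    index = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        p0, p1, a0, a1 = s
        for i in (0, 1):                 # particle pick, 1/2
            for d in range(4):           # direction pick, 1/4
                pos = [SITES[p0], SITES[p1]]
                x, y = pos[i]
                dx, dy = DIRECTIONS[d]
                target = ((x + dx) % 2, (y + dy) % 2)
                if target != pos[1 - i]:
                    pos[i] = target
                for ap in range(K):      # proposal pick, 1/K
                    aa = [a0, a1]
                    m = _slot_multiplicity(pos[i], pos[1 - i])
                    d_h = m * (an.pair_energy(ANGLES[ap], ANGLES[aa[1 - i]])
                               - an.pair_energy(ANGLES[aa[i]], ANGLES[aa[1 - i]]))
                    p_acc = min(1.0, math.exp(-beta_eps * d_h))
                    w = 0.5 * 0.25 / K
                    new_pos = (SITES.index(pos[0]), SITES.index(pos[1]))
                    acc = list(aa)
                    acc[i] = ap
                    T[index[s], index[(new_pos[0], new_pos[1], acc[0], acc[1])]] += w * p_acc
                    T[index[s], index[(new_pos[0], new_pos[1], aa[0], aa[1])]] += w * (1 - p_acc)
    return states, index, T, beta_eps


def _stationary(T):
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def _boltzmann_two_particle(states, beta_eps):
    w = []
    for p0, p1, a0, a1 in states:
        m = _slot_multiplicity(SITES[p0], SITES[p1])
        w.append(math.exp(-beta_eps * m * an.pair_energy(ANGLES[a0], ANGLES[a1])))
    w = np.array(w)
    return w / w.sum()


def test_two_particle_chain_matches_exact_enumeration_oracle():
    """Long-run state frequencies of the mobile 2-particle equilibrium
    system match the stationary vector of the exactly enumerated
    transition matrix.  The energy-blind moves make this chain
    non-reversible, so its stationary law is measurably NOT the Boltzmann
    distribution of the Hamiltonian — the oracle discriminates."""
    states, index, T, beta_eps = _two_particle_chain()
    pi = _stationary(T)
    pi_boltzmann = _boltzmann_two_particle(states, beta_eps)

    p = an.SimParams(L=2, C=0.5, beta_eps=beta_eps, variant="equilibrium",
                     burn_in_iterations=0, measure_iterations=0)
    r = np.random.default_rng(2024)
    state = make_state(2, [(0, 0), (1, 1)], [ANGLES[0], ANGLES[0]])
    counts = np.zeros(len(states))
    n_iter = 40_000
    for _ in range(n_iter):
        an.mc_iteration(state, p, r, proposal=ANGLES)
        pos = [SITES.index(tuple(xy)) for xy in state.particles]
        ai = [int(np.argmin(np.abs(ANGLES - state.orientation[tuple(xy)])))
              for xy in state.particles]
        counts[index[(pos[0], pos[1], ai[0], ai[1])]] += 1
    emp = counts / counts.sum()
    tv_oracle = 0.5 * np.abs(emp - pi).sum()
    tv_boltzmann = 0.5 * np.abs(emp - pi_boltzmann).sum()
    assert tv_oracle < 0.08
    assert tv_boltzmann > 0.25  # moves break detailed balance measurably


def test_full_filling_metropolis_is_exactly_boltzmann():
    """At C = 1 no move ever succeeds, the dynamics is pure Metropolis and
    exactly reversible: empirical angle-configuration frequencies on the
    full 2x2 lattice match the enumerated Boltzmann weights (bond
    multiplicities of the small torus included)."""
    beta_eps = 1.0
    K = len(ANGLES)
    sites = SITES
    configs = list(itertools.product(range(K), repeat=4))

    def total_h(cfg):
        h = 0.0
        for i, si in enumerate(sites):
            for j in range(i + 1, 4):
                m = _slot_multiplicity(si, sites[j])
                h += m * an.pair_energy(ANGLES[cfg[i]], ANGLES[cfg[j]])
        return h

    w = np.array([math.exp(-beta_eps * total_h(c)) for c in configs])
    boltzmann = w / w.sum()

    p = an.SimParams(L=2, C=1.0, beta_eps=beta_eps, variant="equilibrium",
                     burn_in_iterations=0, measure_iterations=0)
    r = np.random.default_rng(99)
    state = make_state(2, sites, [ANGLES[0]] * 4)
    counts = {c: 0 for c in configs}
    for _ in range(40_000):
        an.mc_iteration(state, p, r, proposal=ANGLES)
        cfg = tuple(int(np.argmin(np.abs(ANGLES - state.orientation[s])))
                    for s in sites)
        counts[cfg] += 1
    emp = np.array([counts[c] for c in configs], dtype=float)
    emp /= emp.sum()
    assert 0.5 * np.abs(emp - boltzmann).sum() < 0.06


def test_kernel_equilibrium_matches_transfer_matrix_oracle():
    """The compiled kernel with continuous angles at C = 1 reproduces the
    adjacent-bond doubled-angle correlation of the 2x2 torus computed
    independently by the Bessel-function transfer matrix (XY ring of 4
    spins at coupling K = 2 beta eps)."""
    from scipy.special import iv

    beta_eps = 1.0
    K = 2.0 * beta_eps  # doubled bonds of the small torus
    ks = np.arange(-60, 61)
    Ik = iv(ks, K)
    oracle = float((Ik ** 3 * (iv(ks + 1, K) + iv(ks - 1, K)) / 2).sum()
                   / (Ik ** 4).sum())

    p = an.SimParams(L=2, C=1.0, beta_eps=beta_eps, variant="equilibrium",
                     burn_in_iterations=2000, measure_iterations=40_000,
                     measure_stride=40_000, snapshot_stride=10, seed=5)
    series = an.run_simulation(p)
    vals = []
    for st_ in series.snapshots:
        th = st_.orientation
        vals.append(np.mean([
            math.cos(2 * (th[0, 0] - th[1, 0])),
            math.cos(2 * (th[1, 0] - th[1, 1])),
            math.cos(2 * (th[1, 1] - th[0, 1])),
            math.cos(2 * (th[0, 1] - th[0, 0]))]))
    assert abs(float(np.mean(vals)) - oracle) < 0.04


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

class TestRunSimulation:
    def test_bit_identical_reproducibility(self):
        p = an.SimParams(L=16, C=0.5, beta_eps=1.5, variant="active",
                         burn_in_iterations=50, measure_iterations=100,
                         measure_stride=5, snapshot_stride=50, seed=11)
        a = an.run_simulation(p)
        b = an.run_simulation(p)
        assert np.array_equal(a.S_series, b.S_series)
        assert np.array_equal(a.theta_bar_series, b.theta_bar_series)
        assert np.array_equal(a.times, b.times)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.occupancy, sb.occupancy)
            assert np.array_equal(sa.orientation, sb.orientation, equal_nan=True)

    def test_zero_measurement_gives_empty_series(self):
        p = an.SimParams(L=8, C=0.5, beta_eps=1.0, burn_in_iterations=10,
                         measure_iterations=0, seed=1)
        series = an.run_simulation(p)
        assert len(series) == 0
        assert series.snapshots == []

    def test_equilibrium_dense_cold_is_nematic(self):
        p = an.SimParams(L=32, C=0.9, beta_eps=2.0, variant="equilibrium",
                         burn_in_iterations=3000, measure_iterations=1000,
                         measure_stride=10, seed=3)
        series = an.run_simulation(p)
        assert float(np.mean(series.S_series)) > 0.5

    def test_active_dilute_hot_is_isotropic(self):
        p = an.SimParams(L=32, C=0.1, beta_eps=1.0, variant="active",
                         burn_in_iterations=3000, measure_iterations=1000,
                         measure_stride=10, seed=3)
        series = an.run_simulation(p)
        assert float(np.mean(series.S_series)) < 0.2

    def test_full_filling_variants_bit_identical(self):
        kw = dict(L=8, C=1.0, beta_eps=2.0, burn_in_iterations=0,
                  measure_iterations=200, measure_stride=1, seed=7)
        em = an.run_simulation(an.SimParams(variant="equilibrium", **kw))
        am = an.run_simulation(an.SimParams(variant="active", **kw))
        assert np.array_equal(em.S_series, am.S_series)
        assert em.counters["moves_accepted"] == 0
        assert am.counters["moves_accepted"] == 0

    def test_invariants_hold_after_a_million_elementary_steps(self):
        p = an.SimParams(L=32, C=0.6, beta_eps=1.5, variant="active",
                         burn_in_iterations=0, measure_iterations=1650,
                         measure_stride=1650, snapshot_stride=550, seed=13)
        series = an.run_simulation(p)
        assert series.counters["elementary_steps"] >= 1_000_000
        for snap in series.snapshots:
            assert snap.occupancy.sum() == p.N
            assert snap.occupancy.max() == 1
            snap.validate()
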