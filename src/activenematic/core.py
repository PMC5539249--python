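"""Lattice Monte Carlo model of a two-dimensional active nematic.

A collection of apolar self-propelled particles lives on an L x L square
lattice with periodic boundaries and at most one particle per site.  Each
particle carries an orientation theta in [0, pi) (theta and theta + pi are
the same physical state) and interacts with occupied nearest neighbours
through a modified Lebwohl-Lasher coupling

    H = -eps * sum_<ij> n_i n_j cos 2(theta_i - theta_j),

which favours mutual nematic alignment.  Dynamics alternates a movement
trial with a Metropolis orientation update.  Two movement rules are
implemented:

* ``equilibrium`` -- the particle hops to any of its four neighbours with
  probability 1/4 (an apolar analogue of a diluted XY lattice gas);
* ``active`` -- the particle first picks the lattice axis it is more
  inclined to (vertical if pi/4 < theta <= 3*pi/4, horizontal otherwise)
  and then hops to one of the two neighbours on that axis with probability
  1/2.  The anisotropic hop is the microscopic source of the active
  curvature-coupling current in the coarse-grained description.

Both rules reject hops onto occupied sites (volume exclusion), so particle
number is conserved exactly.  At complete filling (C = 1) every hop is
rejected and the two variants generate identical dynamics.

The module is organised in the order the method runs:

1.  parameters and lattice state;
2.  elementary dynamics operations (pure python, unit-testable);
3.  a numba-compiled kernel for production runs;
4.  the run loop (`run_simulation`) producing an `ObservableSeries`;
5.  observables: order parameter, correlation functions, number
    fluctuations, distributions, autocorrelation, coarse-graining and
    state classification;
6.  the continuum theory: linear stability of the isotropic state and the
    renormalised-mean-field effective free energy;
7.  fixtures, snapshot/run persistence and parameter sweeps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, optimize, signal

logger = logging.getLogger("activenematic")

PI = math.pi

#: Iteration count used for the published protocol (burn-in and measurement
#: each) at the reference lattice size below.  Defaults for other sizes are
#: scaled proportionally to L^2 so that sweeps stay desk-scale; the full
#: protocol remains reachable by passing explicit counts.
REFERENCE_ITERATIONS = 1_500_000
REFERENCE_L = 400

#: Progress is logged every this many iterations during a run.
LOG_STRIDE = 10_000

#: Neighbour displacements; the first two span the horizontal axis, the
#: last two the vertical axis.  The active rule picks within one pair.
DIRECTIONS = ((1, 0), (-1, 0), (0, 1), (0, -1))

SNAPSHOT_FORMAT_VERSION = 1
RUN_FORMAT_VERSION = 1


class ParameterError(ValueError):
    """Invalid simulation or observable parameters."""


class FormatError(RuntimeError):
    """Corrupt, truncated or version-mismatched persisted data."""


def wrap_angle(theta):
    """Map angles to the apolar fundamental domain [0, pi)."""
    return np.mod(theta, PI)


# ---------------------------------------------------------------------------
# Parameters and lattice state
# ---------------------------------------------------------------------------

def scaled_iterations(L: int) -> int:
    """Default iteration count for lattice size L.

    The reference protocol uses ``REFERENCE_ITERATIONS`` at
    ``REFERENCE_L``; the default scales that proportionally to L^2 (the
    work per iteration already scales with N, so total cost scales with
    L^4 at fixed C).
    """
    return max(1, round(REFERENCE_ITERATIONS * (L / REFERENCE_L) ** 2))


@dataclass(frozen=True)
class SimParams:
    """Control parameters of a single run.

    Parameters
    ----------
    L : linear lattice size (sites).
    C : packing density, C = N / L^2 with N the particle number.
    beta_eps : dimensionless inverse temperature times coupling, beta*eps.
        Only this product enters the dynamics (energies are in units of
        eps).
    variant : ``"equilibrium"`` or ``"active"`` movement rule.
    burn_in_iterations, measure_iterations : iteration counts; ``None``
        selects the L^2-scaled default.
    measure_stride : iterations between recorded (S, theta_bar) samples.
    snapshot_stride : iterations between stored configuration snapshots
        during measurement; 0 disables snapshots.
    seed : master seed of the run; fully determines the output.
    """

    L: int
    C: float
    beta_eps: float
    variant: Literal["equilibrium", "active"] = "active"
    burn_in_iterations: int | None = None
    measure_iterations: int | None = None
    measure_stride: int = 10
    snapshot_stride: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.L < 2:
            raise ParameterError(f"L must be >= 2, got {self.L}")
        if not 0.0 <= self.C <= 1.0:
            raise ParameterError(f"C must lie in [0, 1], got {self.C}")
        if self.beta_eps <= 0:
            raise ParameterError(f"beta_eps must be > 0, got {self.beta_eps}")
        if self.variant not in ("equilibrium", "active"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.measure_stride < 1:
            raise ParameterError("measure_stride must be >= 1")
        for name in ("burn_in_iterations", "measure_iterations"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, scaled_iterations(self.L))
        if self.burn_in_iterations < 0 or self.measure_iterations < 0:
            raise ParameterError("iteration counts must be >= 0")

    @property
    def N(self) -> int:
        """Realized particle number round(C * L^2)."""
        return int(round(self.C * self.L * self.L))


@dataclass
class LatticeState:
    """Microscopic configuration {n_i, theta_i} on an L x L torus.

    ``occupancy`` holds 0/1 per site; ``orientation`` holds the angle in
    [0, pi) where occupied and NaN elsewhere.  ``particles`` is an (N, 2)
    array of occupied (x, y) coordinates and ``site_index`` maps each site
    to its particle row (-1 if empty); both are kept consistent with
    ``occupancy`` by every operation so random particle selection is O(1).
    """

    L: int
    occupancy: np.ndarray
    orientation: np.ndarray
    particles: np.ndarray
    site_index: np.ndarray

    @classmethod
    def from_fields(cls, occupancy: np.ndarray, orientation: np.ndarray) -> "LatticeState":
        occupancy = np.ascontiguousarray(occupancy, dtype=np.int8)
        L = occupancy.shape[0]
        if occupancy.shape != (L, L):
            raise ParameterError("occupancy must be square")
        orientation = np.ascontiguousarray(orientation, dtype=np.float64)
        orientation = np.where(occupancy == 1, wrap_angle(orientation), np.nan)
        xs, ys = np.nonzero(occupancy)
        particles = np.column_stack([xs, ys]).astype(np.int64)
        site_index = np.full((L, L), -1, dtype=np.int64)
        site_index[xs, ys] = np.arange(len(xs))
        return cls(L, occupancy, orientation, particles, site_index)

    @property
    def N(self) -> int:
        return len(self.particles)

    def copy(self) -> "LatticeState":
        return LatticeState(self.L, self.occupancy.copy(), self.orientation.copy(),
                            self.particles.copy(), self.site_index.copy())

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError on breakage."""
        occ = self.occupancy
        assert set(np.unique(occ)).issubset({0, 1}), "occupancy must be 0/1"
        assert occ.sum() == self.N, "particle count inconsistent"
        th = self.orientation[occ == 1]
        assert np.all((th >= 0) & (th < PI)), "orientations must lie in [0, pi)"
        assert np.all(np.isnan(self.orientation[occ == 0])), "empty sites carry NaN"
        for k, (x, y) in enumerate(self.particles):
            assert occ[x, y] == 1 and self.site_index[x, y] == k
        assert (self.site_index >= 0).sum() == self.N


def init_lattice(params: SimParams, rng: np.random.Generator) -> LatticeState:
    """Place N = round(C*L^2) particles uniformly without replacement,
    each with an independent orientation uniform on [0, pi)."""
    L, N = params.L, params.N
    occupancy = np.zeros((L, L), dtype=np.int8)
    flat = rng.choice(L * L, size=N, replace=False)
    occupancy.flat[flat] = 1
    orientation = np.full((L, L), np.nan)
    orientation.flat[flat] = rng.uniform(0.0, PI, size=N)
    return LatticeState.from_fields(occupancy, orientation)


# ---------------------------------------------------------------------------
# Elementary dynamics (reference python implementation)
# ---------------------------------------------------------------------------

def pair_energy(theta_a: float, theta_b: float) -> float:
    """Lebwohl-Lasher bond energy -cos 2(theta_a - theta_b), in units of eps."""
    return -math.cos(2.0 * (theta_a - theta_b))


def local_energy(state: LatticeState, site: tuple[int, int], theta: float) -> float:
    """Energy of the bonds between ``site`` (carrying angle ``theta``) and
    its occupied nearest neighbours; empty neighbours contribute 0."""
    L = state.L
    x, y = site
    e = 0.0
    for dx, dy in DIRECTIONS:
        nx, ny = (x + dx) % L, (y + dy) % L
        if state.occupancy[nx, ny]:
            e += pair_energy(theta, state.orientation[nx, ny])
    return e


def total_energy(state: LatticeState) -> float:
    """Total Hamiltonian (each nearest-neighbour bond counted once)."""
    occ = state.occupancy.astype(float)
    e = 0.0
    for axis in (0, 1):
        pair = occ * np.roll(occ, -1, axis=axis)
        dth = state.orientation - np.roll(state.orientation, -1, axis=axis)
        mask = pair == 1
        e -= np.cos(2.0 * dth[mask]).sum()
    return e


def choose_move_target_equilibrium(site: tuple[int, int], L: int,
                                   rng: np.random.Generator) -> tuple[int, int]:
    """One of the four neighbours with probability 1/4 each."""
    d = min(int(rng.random() * 4), 3)
    dx, dy = DIRECTIONS[d]
    return (site[0] + dx) % L, (site[1] + dy) % L

def choose_move_target_active(site: tuple[int, int], theta: float, L: int,
                              rng: np.random.Generator) -> tuple[int, int]:
    """Active rule: vertical axis if pi/4 < theta <= 3*pi/4 (the particle
    is more inclined to the vertical), horizontal otherwise (strict '<' at
    theta = pi/4); then one of the two neighbours on that axis with
    probability 1/2."""
    vertical = (PI / 4.0 < theta) and (theta <= 3.0 * PI / 4.0)
    pick = rng.random() < 0.5
    if vertical:
        dx, dy = DIRECTIONS[2] if pick else DIRECTIONS[3]
    else:
        dx, dy = DIRECTIONS[0] if pick else DIRECTIONS[1]
    return (site[0] + dx) % L, (site[1] + dy) % L


def attempt_move(state: LatticeState, site: tuple[int, int],
                 target: tuple[int, int]) -> bool:
    """Transfer the particle at ``site`` to ``target`` if the target site is
    empty (volume exclusion); no energy criterion applies to moves."""
    x, y = site
    if state.occupancy[x, y] == 0:
        raise ParameterError(f"no particle at site {site}")
    tx, ty = target
    if state.occupancy[tx, ty]:
        return False
    k = state.site_index[x, y]
    state.occupancy[tx, ty] = 1
    state.occupancy[x, y] = 0
    state.orientation[tx, ty] = state.orientation[x, y]
    state.orientation[x, y] = np.nan
    state.site_index[tx, ty] = k
    state.site_index[x, y] = -1
    state.particles[k] = (tx, ty)
    return True


def metropolis_orientation_update(state: LatticeState, site: tuple[int, int],
                                  beta_eps: float, rng: np.random.Generator,
                                  proposal: str | Sequence[float] = "uniform") -> bool:
    """Metropolis trial for the orientation at ``site``.

    A candidate angle is drawn uniformly on [0, pi) (or uniformly from a
    discrete ``proposal`` set, used by exact-enumeration tests) and accepted
    with probability min(1, exp(-beta_eps * dH)) where dH is the local
    bond-energy change.
    """
    x, y = site
    if state.occupancy[x, y] == 0:
        raise ParameterError(f"no particle at site {site}")
    if isinstance(proposal, str):
        if proposal != "uniform":
            raise ParameterError(f"unknown proposal kernel {proposal!r}")
        theta_new = rng.random() * PI
    else:
        angles = np.asarray(proposal, dtype=float)
        theta_new = float(angles[min(int(rng.random() * len(angles)), len(angles) - 1)])
    d_h = local_energy(state, site, theta_new) - local_energy(state, site, state.orientation[x, y])
    if rng.random() < math.exp(-beta_eps * d_h):
        state.orientation[x, y] = wrap_angle(theta_new)
        return True
    return False


def mc_iteration(state: LatticeState, params: SimParams, rng: np.random.Generator,
                 proposal: str | Sequence[float] = "uniform") -> dict[str, int]:
    """One Monte Carlo iteration: N elementary steps, each picking a
    particle uniformly with replacement, attempting a move under the
    chosen variant, then a Metropolis orientation trial on the same
    particle (whether or not the move succeeded).  Returns accepted-move
    and accepted-rotation counters."""
    N = state.N
    moves = rotations = 0
    for _ in range(N):
        k = min(int(rng.random() * N), N - 1)
        x, y = state.particles[k]
        if params.variant == "equilibrium":
            target = choose_move_target_equilibrium((x, y), state.L, rng)
        else:
            target = choose_move_target_active((x, y), state.orientation[x, y], state.L, rng)
        if attempt_move(state, (x, y), target):
            x, y = target
            moves += 1
        if metropolis_orientation_update(state, (x, y), params.beta_eps, rng, proposal):
            rotations += 1
    return {"moves_accepted": int(moves), "rotations_accepted": rotations}


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------
# The kernel replicates the elementary step above for production runs.  It
# consumes exactly four uniforms per elementary step in both variants
# (particle pick, target pick, proposal angle, acceptance), so at C = 1.0
# the equilibrium and active variants follow identical random streams and
# produce bit-identical trajectories.

@njit(cache=True)
def _kernel_seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _neighbour_doubled_sums(occ, c2, s2, x, y, plus, minus):
    """Sums of cos 2*theta and sin 2*theta over occupied neighbours."""
    C = 0.0
    S = 0.0
    nx = plus[x]
    if occ[nx, y]:
        C += c2[nx, y]
        S += s2[nx, y]
    nx = minus[x]
    if occ[nx, y]:
        C += c2[nx, y]
        S += s2[nx, y]
    ny = plus[y]
    if occ[x, ny]:
        C += c2[x, ny]
        S += s2[x, ny]
    ny = minus[y]
    if occ[x, ny]:
        C += c2[x, ny]
        S += s2[x, ny]
    return C, S


@njit(cache=True)
def _order_parameter_k(theta, px, py):
    c = 0.0
    s = 0.0
    for k in range(len(px)):
        th = theta[px[k], py[k]]
        c += np.cos(2.0 * th)
        s += np.sin(2.0 * th)
    n = max(len(px), 1)
    S = np.sqrt(c * c + s * s) / n
    thbar = 0.5 * np.arctan2(s, c)
    if thbar < 0.0:
        thbar += np.pi
    if thbar >= np.pi:
        thbar -= np.pi
    return S, thbar


@njit(cache=True)
def _run_chunk_k(occ, theta, c2, s2, px, py, sidx, active, beta_eps, n_iters,
                 record_stride, S_out, thbar_out, rec_iters, iter_offset):
    """Advance n_iters iterations in place; record (S, theta_bar) every
    record_stride iterations (0 disables).  ``c2``/``s2`` cache
    cos 2*theta and sin 2*theta per occupied site so the Metropolis energy
    change costs two trig evaluations per trial.  Returns (accepted moves,
    accepted rotations, records written)."""
    L = occ.shape[0]
    N = len(px)
    plus = np.empty(L, np.int64)
    minus = np.empty(L, np.int64)
    for i in range(L):
        plus[i] = (i + 1) % L
        minus[i] = (i - 1) % L
    moves = 0
    rots = 0
    rec = 0
    for it in range(n_iters):
        for _ in range(N):
            u1 = np.random.random()
            k = int(u1 * N)
            if k == N:
                k = N - 1
            x = px[k]
            y = py[k]
            th = theta[x, y]
            u2 = np.random.random()
            if active:
                if (th > 0.25 * np.pi) and (th <= 0.75 * np.pi):
                    tx = x
                    ty = plus[y] if u2 < 0.5 else minus[y]
                else:
                    ty = y
                    tx = plus[x] if u2 < 0.5 else minus[x]
            else:
                d = int(u2 * 4)
                if d == 0:
                    tx, ty = plus[x], y
                elif d == 1:
                    tx, ty = minus[x], y
                elif d == 2:
                    tx, ty = x, plus[y]
                else:
                    tx, ty = x, minus[y]
            if occ[tx, ty] == 0:
                occ[tx, ty] = 1
                occ[x, y] = 0
                theta[tx, ty] = th
                theta[x, y] = np.nan
                c2[tx, ty] = c2[x, y]
                s2[tx, ty] = s2[x, y]
                sidx[tx, ty] = k
                sidx[x, y] = -1
                px[k] = tx
                py[k] = ty
                x, y = tx, ty
                moves += 1
            u3 = np.random.random()
            th_new = u3 * np.pi
            Cn, Sn = _neighbour_doubled_sums(occ, c2, s2, x, y, plus, minus)
            c_new = np.cos(2.0 * th_new)
            s_new = np.sin(2.0 * th_new)
            # dH = -(c'*Cn + s'*Sn) + (c*Cn + s*Sn)
            d_h = (c2[x, y] - c_new) * Cn + (s2[x, y] - s_new) * Sn
            u4 = np.random.random()
            if d_h <= 0.0 or u4 < np.exp(-beta_eps * d_h):
                theta[x, y] = th_new
                c2[x, y] = c_new
                s2[x, y] = s_new
                rots += 1
        if record_stride > 0 and (iter_offset + it + 1) % record_stride == 0:
            S, thbar = _order_parameter_k(theta, px, py)
            S_out[rec] = S
            thbar_out[rec] = thbar
            rec_iters[rec] = iter_offset + it + 1
            rec += 1
    return moves, rots, rec


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------

@dataclass
class ObservableSeries:
    """Steady-state record of a run: per-sample iteration index, scalar
    order parameter S and mean orientation theta_bar, plus optional stored
    configuration snapshots and acceptance counters."""

    params: SimParams
    times: np.ndarray
    S_series: np.ndarray
    theta_bar_series: np.ndarray
    snapshots: list[LatticeState] = field(default_factory=list)
    snapshot_times: list[int] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)


def _derived_kernel_seed(seed: int) -> int:
    # keep within numpy's legacy-seed range and decorrelated from the
    # init_lattice generator, which uses the raw seed
    return int((seed * 2654435761 + 0x9E3779B9) % (2 ** 31))


def run_simulation(params: SimParams) -> ObservableSeries:
    """Run burn-in plus measurement and return the recorded series.

    The lattice is initialised from ``params.seed``, burn-in iterations are
    discarded, and during measurement (S, theta_bar) is recorded every
    ``measure_stride`` iterations with full snapshots every
    ``snapshot_stride``.  The same params (including seed) reproduce the
    series bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    state = init_lattice(params, rng)
    _kernel_seed(_derived_kernel_seed(params.seed))
    occ, theta = state.occupancy, state.orientation
    with np.errstate(invalid="ignore"):
        c2 = np.where(occ == 1, np.cos(2.0 * theta), 0.0)
        s2 = np.where(occ == 1, np.sin(2.0 * theta), 0.0)
    px = np.ascontiguousarray(state.particles[:, 0]) if state.N else np.empty(0, np.int64)
    py = np.ascontiguousarray(state.particles[:, 1]) if state.N else np.empty(0, np.int64)
    sidx = state.site_index

    total_moves = total_rots = 0
    steps_done = 0

    def _advance(n_iters, record_stride, S_out, th_out, t_out, offset):
        nonlocal total_moves, total_rots, steps_done
        done = 0
        written = 0
        while done < n_iters:
            chunk = min(LOG_STRIDE, n_iters - done)
            m, r, rec = _run_chunk_k(occ, theta, c2, s2, px, py, sidx,
                                     params.variant == "active",
                                     params.beta_eps, chunk, record_stride,
                                     S_out[written:], th_out[written:], t_out[written:],
                                     offset + done)
            total_moves += m
            total_rots += r
            written += rec
            done += chunk
            steps_done += chunk * max(state.N, 1)
            if logger.isEnabledFor(logging.INFO) and state.N:
                S, _ = _order_parameter_k(theta, px, py)
                logger.info("iteration %d: S=%.4f move_acc=%.3f rot_acc=%.3f",
                            offset + done, S,
                            total_moves / steps_done, total_rots / steps_done)
        return written

    burn = params.burn_in_iterations
    meas = params.measure_iterations
    stride = params.measure_stride
    n_rec = meas // stride + 1
    S_out = np.empty(n_rec)
    th_out = np.empty(n_rec)
    t_out = np.empty(n_rec, dtype=np.int64)

    _dummy = np.empty(0)
    _advance(burn, 0, _dummy, _dummy, np.empty(0, np.int64), 0)

    snapshots: list[LatticeState] = []
    snapshot_times: list[int] = []
    written = 0
    done = 0
    snap_stride = params.snapshot_stride if params.snapshot_stride > 0 else meas
    while done < meas:
        seg = min(snap_stride, meas - done)
        # recording stride is phase-locked to the measurement window
        rec = _advance(seg, stride, S_out[written:], th_out[written:],
                       t_out[written:], burn + done)
        written += rec
        done += seg
        if params.snapshot_stride > 0:
            # rebuild the particle table from the mutated arrays
            snap = LatticeState.from_fields(occ.copy(), theta.copy())
            snapshots.append(snap)
            snapshot_times.append(burn + done)

    state.particles = np.column_stack([px, py]) if state.N else state.particles
    counters = {"moves_accepted": int(total_moves), "rotations_accepted": int(total_rots),
                "elementary_steps": int(steps_done if state.N else 0)}
    return ObservableSeries(params, t_out[:written], S_out[:written], th_out[:written],
                            snapshots, snapshot_times, counters)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def scalar_order_parameter(state: LatticeState) -> float:
    """Nematic scalar order parameter

        S = sqrt((1/N sum n_i cos 2theta_i)^2 + (1/N sum n_i sin 2theta_i)^2),

    0 in the disordered state, 1 at perfect alignment; invariant under a
    global rotation of all orientations."""
    if state.N == 0:
        raise ParameterError("S is undefined for an empty lattice")
    th = state.orientation[state.occupancy == 1]
    c = np.cos(2.0 * th).sum()
    s = np.sin(2.0 * th).sum()
    return float(np.hypot(c, s) / state.N)


def mean_orientation(state: LatticeState) -> float:
    """Director estimate: half the argument of the doubled-angle mean
    vector, mapped into [0, pi).  Undefined (signalled) when the doubled
    vector vanishes (S = 0)."""
    if state.N == 0:
        raise ParameterError("mean orientation undefined for an empty lattice")
    th = state.orientation[state.occupancy == 1]
    c = np.cos(2.0 * th).sum()
    s = np.sin(2.0 * th).sum()
    if np.hypot(c, s) < 1e-12 * state.N:
        raise ParameterError("mean orientation undefined: doubled-angle resultant is zero")
    return float(wrap_angle(0.5 * math.atan2(s, c)))


@dataclass
class CorrelationCurve:
    """Two-point orientation correlation g2(r) over axis-aligned separations.

    ``g2`` is NaN where no occupied pair exists at that separation.
    ``decay_type`` and ``fit_range`` are filled in by `classify_decay`.
    """

    r: np.ndarray
    g2: np.ndarray
    n_pairs: np.ndarray
    decay_type: str | None = None
    fit_range: tuple[int, int] | None = None


def g2_correlation(states: LatticeState | Iterable[LatticeState], r_max: int,
                   normalization: str = "pairs") -> CorrelationCurve:
    """Two-point orientation correlation

        g2(r) = < sum_i n_i n_{i+r} cos 2(theta_i - theta_{i+r}) > / norm,

    accumulated over both lattice axes and over all supplied snapshots.
    With ``normalization="pairs"`` (default) the sum is divided by the
    number of occupied pairs at separation r, so g2 = 1 for any perfectly
    aligned configuration and separations with no pairs are flagged NaN;
    ``"total"`` divides by sum n_i^2 = N instead (then dilute occupancy
    also suppresses g2)."""
    if isinstance(states, LatticeState):
        states = [states]
    states = list(states)
    if not states:
        raise ParameterError("at least one state required")
    L = states[0].L
    if r_max >= L // 2 + 1:
        raise ParameterError(f"r_max must be < L/2 = {L // 2}")
    num = np.zeros(r_max + 1)
    pairs = np.zeros(r_max + 1, dtype=np.int64)
    n_total = 0
    for st in states:
        occ = st.occupancy.astype(bool)
        n_total += st.N
        num[0] += st.N
        pairs[0] += st.N
        for r in range(1, r_max + 1):
            for axis in (0, 1):
                both = occ & np.roll(occ, -r, axis=axis)
                dth = st.orientation - np.roll(st.orientation, -r, axis=axis)
                num[r] += np.cos(2.0 * dth[both]).sum()
                pairs[r] += int(both.sum())
    if normalization == "pairs":
        with np.errstate(invalid="ignore"):
            g2 = np.where(pairs > 0, num / np.maximum(pairs, 1), np.nan)
    elif normalization == "total":
        # the pair sum runs over both axes, so the per-axis average halves it
        g2 = np.where(pairs > 0, num / (2.0 * max(n_total, 1)), np.nan)
        g2[0] = 1.0
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")
    return CorrelationCurve(np.arange(r_max + 1), g2, pairs)


def classify_decay(curve: CorrelationCurve, rss_ratio: float = 1.5,
                   abrupt_factor: float = 5.0, min_points: int = 5) -> str:
    """Classify the decay of g2(r) as exponential, power_law, abrupt or
    inconclusive.

    The fit range is the widest contiguous run of positive finite values
    starting at r = 1 (ideally spanning at least one decade).  A
    single-step collapse by more than ``abrupt_factor``, preceded by a
    plateau (at least two steps each dropping by less than
    sqrt(abrupt_factor)), is the locally-ordered-cluster signature and
    returns ``"abrupt"``; a plain steep exponential decays uniformly and
    does not trigger it.  Otherwise log g2 is fitted linearly against r
    (exponential) and against log r (power law); the model with the
    smaller residual sum of squares wins if it wins by at least
    ``rss_ratio``, else ``"inconclusive"``."""
    r = curve.r
    g2 = curve.g2
    # fit only where g2 stands clear of the pair-count noise floor
    # (sigma ~ 1/sqrt(n_pairs)); a flat noise tail would otherwise bias
    # the log-log fit toward a spurious power law
    floor = 3.0 / np.sqrt(np.maximum(curve.n_pairs, 1))
    usable = 1
    while usable < len(r) and np.isfinite(g2[usable]) and g2[usable] > floor[usable]:
        usable += 1
    rs = r[1:usable].astype(float)
    ys = g2[1:usable]
    if len(rs) >= 3:
        drops = ys[:-1] / ys[1:]
        slow = drops < math.sqrt(abrupt_factor)
        for i in np.nonzero(drops > abrupt_factor)[0]:
            if i >= 2 and slow[:i].all():
                curve.decay_type = "abrupt"
                curve.fit_range = (1, usable - 1)
                return "abrupt"
    if len(rs) < min_points:
        curve.decay_type = "inconclusive"
        curve.fit_range = None
        return "inconclusive"
    logy = np.log(ys)
    res_exp = _linear_rss(rs, logy)
    res_pow = _linear_rss(np.log(rs), logy)
    curve.fit_range = (1, usable - 1)
    if res_pow > rss_ratio * res_exp:
        curve.decay_type = "exponential"
    elif res_exp > rss_ratio * res_pow:
        curve.decay_type = "power_law"
    else:
        curve.decay_type = "inconclusive"
    return curve.decay_type


def _linear_rss(x: np.ndarray, y: np.ndarray) -> float:
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(resid @ resid)


@dataclass
class FluctuationScaling:
    """Subsystem number-fluctuation scaling DeltaN ~ <N>^zeta."""

    box_sizes: np.ndarray
    mean_counts: np.ndarray
    std_counts: np.ndarray
    zeta: float
    zeta_stderr: float


def number_fluctuations(snapshots: Sequence[LatticeState],
                        box_sizes: Sequence[int] | None = None) -> FluctuationScaling:
    """Count particles in non-overlapping l x l tiles across snapshots and
    fit DeltaN = sqrt(<N^2> - <N>^2) against <N> in log-log by ordinary
    least squares.  zeta = 1/2 is the uncorrelated (normal) value; zeta >
    1/2 signals giant number fluctuations."""
    snapshots = list(snapshots)
    if len(snapshots) < 2:
        raise ParameterError("need at least 2 snapshots")
    L = snapshots[0].L
    if box_sizes is None:
        box_sizes = [b for b in (2 ** k for k in range(1, 30)) if b <= L // 4]
    box_sizes = sorted(set(int(b) for b in box_sizes))
    if any(b < 1 or b > L // 2 for b in box_sizes):
        raise ParameterError("box sizes must lie in [1, L/2]")
    means, stds, kept = [], [], []
    for b in box_sizes:
        m = L // b
        counts = []
        for st in snapshots:
            occ = st.occupancy[: m * b, : m * b]
            tiles = occ.reshape(m, b, m, b).sum(axis=(1, 3))
            counts.append(tiles.ravel())
        counts = np.concatenate(counts).astype(float)
        mu, sd = counts.mean(), counts.std()
        if mu > 0:
            means.append(mu)
            stds.append(sd)
            kept.append(b)
    means = np.array(means)
    stds = np.array(stds)
    if len(means) < 2 or np.any(stds <= 0):
        raise ParameterError("zeta undefined: constant or empty subsystem counts")
    if len(means) >= 3:
        coef, cov = np.polyfit(np.log(means), np.log(stds), 1, cov=True)
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        coef = np.polyfit(np.log(means), np.log(stds), 1)
        stderr = float("nan")
    return FluctuationScaling(np.array(kept), means, stds, float(coef[0]), stderr)


@dataclass
class OrientationHistogram:
    """Normalized P(theta) on [0, pi) with a wrapped Gaussian peak fit."""

    bin_edges: np.ndarray
    density: np.ndarray
    fit_mu: float
    fit_sigma: float
    fit_mu_stderr: float
    fit_sigma_stderr: float
    fit_r2: float
    fit_ok: bool


def orientation_histogram(state: LatticeState, n_bins: int = 60,
                          r2_threshold: float = 0.8) -> OrientationHistogram:
    """Histogram the orientations and fit a Gaussian about the mode of the
    wrapped histogram.  Broad/flat distributions are flagged (fit_ok
    False); both the ordered active and equilibrium states produce clean
    Gaussian peaks."""
    if state.N == 0:
        raise ParameterError("empty lattice")
    th = state.orientation[state.occupancy == 1]
    density, edges = np.histogram(th, bins=n_bins, range=(0.0, PI), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(density))
    # roll so the mode sits at the center; x-coordinates follow the roll
    shift = n_bins // 2 - mode
    rolled = np.roll(density, shift)
    x = centers[mode] + (np.arange(n_bins) - n_bins // 2) * (PI / n_bins)
    # moment-based seed about the mode
    w = rolled / max(rolled.sum(), 1e-300)
    mu0 = float((w * x).sum())
    sig0 = float(np.sqrt(max((w * (x - mu0) ** 2).sum(), 1e-8)))
    amp0 = float(rolled.max())

    def gauss(xx, a, mu, sig):
        return a * np.exp(-0.5 * ((xx - mu) / sig) ** 2)

    mu, sig, mu_se, sig_se, r2 = mu0, sig0, np.inf, np.inf, 0.0
    try:
        popt, pcov = optimize.curve_fit(gauss, x, rolled, p0=(amp0, mu0, sig0), maxfev=5000)
        pred = gauss(x, *popt)
        ss_res = float(((rolled - pred) ** 2).sum())
        ss_tot = float(((rolled - rolled.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        mu, sig = float(wrap_angle(popt[1])), float(abs(popt[2]))
        mu_se, sig_se = float(np.sqrt(pcov[1, 1])), float(np.sqrt(pcov[2, 2]))
    except (RuntimeError, ValueError):
        pass
    ok = bool(np.isfinite(r2) and r2 >= r2_threshold and sig < PI)
    return OrientationHistogram(edges, density, mu, sig, mu_se, sig_se, r2, ok)


def mean_orientation_autocorrelation(theta_bar_series: np.ndarray, t_max: int) -> np.ndarray:
    """Autocorrelation of the mean orientation,

        C(t) = < (1/t) sum_{tau=1..t} cos 2(theta_bar(t0) - theta_bar(t0+tau)) >,

    averaged over all admissible start times t0.  Returns C(1..t_max)."""
    th = np.asarray(theta_bar_series, dtype=float)
    n = len(th)
    if n <= t_max:
        raise ParameterError("series must be longer than t_max")
    out = np.empty(t_max)
    running = np.zeros(n)
    for t in range(1, t_max + 1):
        c = np.cos(2.0 * (th[: n - t] - th[t:]))
        running[: n - t] += c
        out[t - 1] = running[: n - t].mean() / t
    return out


def coarse_grained_density(state: LatticeState, block: int) -> np.ndarray:
    """Occupied fraction per block x block tile; the tile mean equals the
    realized packing density exactly."""
    L = state.L
    if block < 1 or L % block != 0:
        raise ParameterError(f"block must divide L={L}, got {block}")
    m = L // block
    return state.occupancy.reshape(m, block, m, block).mean(axis=(1, 3))


def _coarse_grained_order(state: LatticeState, block: int) -> np.ndarray:
    """Local S per tile (NaN for empty tiles)."""
    L = state.L
    m = L // block
    occ = state.occupancy.reshape(m, block, m, block)
    th = state.orientation.reshape(m, block, m, block)
    c = np.where(occ == 1, np.cos(2 * th), 0.0).sum(axis=(1, 3))
    s = np.where(occ == 1, np.sin(2 * th), 0.0).sum(axis=(1, 3))
    n = occ.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, np.hypot(c, s) / np.maximum(n, 1), np.nan)


@dataclass
class SDistribution:
    """Histogram of the scalar order parameter with smoothed peak count."""

    bin_edges: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    peak_positions: np.ndarray
    n_peaks: int
    bimodal: bool


def order_parameter_distribution(S_series: np.ndarray, bin_width: float = 0.02,
                                 smooth_bins: float = 2.0, min_separation: int = 5,
                                 min_height_frac: float = 0.05) -> SDistribution:
    """Normalized P(S) on [0, 1] with deterministic peak counting: fixed
    bin width, Gaussian kernel smoothing, peaks = local maxima above
    ``min_height_frac`` of the global maximum separated by at least
    ``min_separation`` bins.  Two peaks flag a bimodal (first-order
    coexistence) distribution."""
    S = np.asarray(S_series, dtype=float)
    if len(S) < 100:
        raise ParameterError("need at least 100 samples for P(S)")
    n_bins = int(round(1.0 / bin_width))
    density, edges = np.histogram(S, bins=n_bins, range=(0.0, 1.0), density=True)
    smoothed = ndimage.gaussian_filter1d(density, sigma=smooth_bins, mode="constant")
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = signal.find_peaks(padded, height=min_height_frac * padded.max(),
                                 distance=min_separation)
    peaks = peaks - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SDistribution(edges, density, smoothed, centers[peaks], len(peaks),
                         len(peaks) >= 2)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Deterministic thresholds for the four-state classifier.

    A band is a contiguous set of coarse rows/columns whose every tile
    density exceeds C + ``band_excess``, spanning the full transverse
    extent, with interior local order above ``band_interior_S`` and
    exterior below ``band_exterior_S``."""

    s_iso: float = 0.2
    s_order: float = 0.5
    band_excess: float = 0.15
    band_interior_S: float = 0.5
    band_exterior_S: float = 0.25
    density_contrast: float = 0.15
    block_divisor: int = 16
    bistable_margin: float = 0.05
    bistable_min_transitions: int = 2


@dataclass
class StateClassification:
    label: str
    bistable: bool
    confidence: str
    metrics: dict


def _band_block(L: int, divisor: int) -> int:
    """Largest divisor of L not exceeding L // divisor (>= 1)."""
    target = max(1, L // divisor)
    for b in range(target, 0, -1):
        if L % b == 0:
            return b
    return 1


def _pooled_order(occ: np.ndarray, th: np.ndarray) -> float:
    """Doubled-angle resultant length over all particles in a region (NaN
    if empty).  Pooling avoids the single-particle-tile artefact where a
    tile-averaged local S is 1 regardless of order."""
    angles = th[occ == 1]
    if len(angles) == 0:
        return float("nan")
    return float(np.hypot(np.cos(2 * angles).sum(), np.sin(2 * angles).sum()) / len(angles))


def _detect_band(state: LatticeState, C: float, th: ClassifierThresholds) -> bool:
    block = _band_block(state.L, th.block_divisor)
    dens = coarse_grained_density(state, block)
    for axis in (0, 1):
        d = dens if axis == 0 else dens.T
        occ = state.occupancy if axis == 0 else state.occupancy.T
        ori = state.orientation if axis == 0 else state.orientation.T
        dense_rows = np.all(d > C + th.band_excess, axis=1)
        if not dense_rows.any() or dense_rows.all():
            continue
        site_rows = np.repeat(dense_rows, block)
        # the exterior pool excludes the coarse rows bordering the dense
        # strip: the band interface is partially ordered by construction
        border = (np.roll(dense_rows, 1) | np.roll(dense_rows, -1)) & ~dense_rows
        site_ext = np.repeat(~(dense_rows | border), block)
        inside = _pooled_order(occ[site_rows], ori[site_rows])
        outside = _pooled_order(occ[site_ext], ori[site_ext])
        if (np.isfinite(inside) and np.isfinite(outside)
                and inside > th.band_interior_S and outside < th.band_exterior_S):
            # require the dense rows to be contiguous on the torus
            idx = np.nonzero(dense_rows)[0]
            gaps = np.diff(np.concatenate([idx, [idx[0] + len(dense_rows)]]))
            if (gaps > 1).sum() <= 1:
                return True
    return False


def classify_state(series: ObservableSeries, thresholds: ClassifierThresholds | None = None
                   ) -> StateClassification:
    """Label the steady state as I (disordered isotropic), BS (banded), HO
    (homogeneous ordered) or IM (inhomogeneous mixed), and flag
    bistability when the S series alternates between the IM and HO bands.

    Rules, in order: mean S below ``s_iso`` -> I; a spanning dense ordered
    strip in a majority of snapshots -> BS; mean S >= ``s_order`` with low
    coarse-density contrast -> HO; otherwise IM."""
    th = thresholds or ClassifierThresholds()
    if len(series.S_series) == 0:
        raise ParameterError("empty series")
    mean_S = float(np.mean(series.S_series))
    C = series.params.C
    metrics: dict = {"mean_S": mean_S}

    bistable = False
    if len(series.S_series) >= 3:
        lo, hi = th.s_order - th.bistable_margin, th.s_order + th.bistable_margin
        level = None
        transitions = 0
        for s in series.S_series:
            new = "HO" if s > hi else ("IM" if s < lo else None)
            if new is not None:
                if level is not None and new != level:
                    transitions += 1
                level = new
        metrics["transitions"] = transitions
        bistable = transitions >= th.bistable_min_transitions

    if not series.snapshots:
        label = "I" if mean_S < th.s_iso else ("HO" if mean_S >= th.s_order else "IM")
        return StateClassification(label, bistable,
                                   "low: no snapshots, label from S only", metrics)

    band_votes = sum(_detect_band(st, C, th) for st in series.snapshots)
    contrast = float(np.mean([
        coarse_grained_density(st, _band_block(st.L, th.block_divisor)).std()
        for st in series.snapshots]))
    metrics.update(band_votes=band_votes, n_snapshots=len(series.snapshots),
                   density_contrast=contrast)

    if mean_S < th.s_iso:
        return StateClassification("I", bistable, "high", metrics)
    if band_votes * 2 >= len(series.snapshots):
        return StateClassification("BS", bistable, "high", metrics)
    if mean_S >= th.s_order and contrast < th.density_contrast:
        return StateClassification("HO", bistable, "high", metrics)
    conf = "high" if contrast >= th.density_contrast else \
        "low: moderate order with low density contrast"
    return StateClassification("IM", bistable, conf, metrics)


# ---------------------------------------------------------------------------
# Continuum theory: linear stability of the isotropic state
# ---------------------------------------------------------------------------
# Hydrodynamics of the density rho and the nematic order parameter field
# Pi_ij: d_t rho = a0 grad_i grad_j Pi_ij + D_rho lap rho, and a relaxational
# Pi equation with mean-field alignment alpha1(rho) - alpha2 (Pi:Pi), density
# coupling beta_c and diffusion D_Pi.  Linearising about the isotropic state
# (Pi = 0) along the symmetric direction q_x = q_y = q/sqrt(2) gives the
# cubic dispersion relation
#
#   (lam - alpha1 + D_Pi q^2) * {(lam + D_rho q^2)(lam - alpha1 + D_Pi q^2)
#                                 - (1/2) a0 beta_c q^4} = 0.

@dataclass(frozen=True)
class HydroParams:
    """Coefficients of the continuum equations.

    ``beta_c`` is the density-coupling coefficient of the order-parameter
    equation (distinct from the inverse temperature); only the product
    a0 * beta_c enters any result.  ``alpha1(rho) = rho / rho_IN - 1``
    changes sign at the mean-field transition density ``rho_IN``."""

    a0: float
    D_rho: float
    D_Pi: float
    beta_c: float
    rho0: float
    rho_IN: float
    alpha2: float = 1.0

    def __post_init__(self):
        if self.D_rho < 0 or self.D_Pi < 0:
            raise ParameterError("diffusivities must be >= 0")
        if self.rho_IN <= 0:
            raise ParameterError("rho_IN must be > 0")
        if self.alpha2 <= 0:
            raise ParameterError("alpha2 must be > 0")

    def alpha1(self, rho: float) -> float:
        return rho / self.rho_IN - 1.0

    @property
    def alpha1_0(self) -> float:
        return self.alpha1(self.rho0)

    @property
    def delta_D(self) -> float:
        return self.D_Pi - self.D_rho

    @property
    def a0_beta(self) -> float:
        return self.a0 * self.beta_c

    @property
    def Pi0(self) -> float:
        """Homogeneous ordered steady-state amplitude sqrt(alpha1/alpha2)
        (0 in the disordered regime alpha1 <= 0)."""
        a1 = self.alpha1_0
        return math.sqrt(a1 / self.alpha2) if a1 > 0 else 0.0


def _dispersion_coefficients(q: float, p: HydroParams) -> np.ndarray:
    """Monic cubic coefficients of the dispersion relation in lambda."""
    a1 = p.alpha1_0
    g = p.D_Pi * q * q - a1          # lam + g from the Pi_12 factor
    B = p.D_rho * q * q + g          # quadratic: lam^2 + B lam + Cq
    Cq = p.D_rho * q * q * g - 0.5 * p.a0_beta * q ** 4
    return np.array([1.0, g + B, Cq + g * B, g * Cq])


def dispersion_roots(q: float, params: HydroParams) -> np.ndarray:
    """The three complex growth rates lambda(q) of the linearised
    equations, sorted by descending real part (then imaginary part).  One
    factor is the decoupled shear mode lambda = alpha1 - D_Pi q^2; the
    other two mix density and Pi_11 through the a0*beta_c q^4 term."""
    if q < 0:
        raise ParameterError("q must be >= 0")
    a1 = params.alpha1_0
    g = params.D_Pi * q * q - a1
    root1 = -g
    B = params.D_rho * q * q + g
    Cq = params.D_rho * q * q * g - 0.5 * params.a0_beta * q ** 4
    disc = complex(B * B - 4.0 * Cq)
    sq = np.sqrt(disc)
    roots = np.array([complex(root1), (-B + sq) / 2.0, (-B - sq) / 2.0])
    order = np.lexsort((-roots.imag, -roots.real))
    return roots[order]


def dispersion_residual(q: float, params: HydroParams, lam: complex) -> float:
    """Relative residual of the dispersion cubic at lambda = lam."""
    c = _dispersion_coefficients(q, params)
    val = ((lam + c[1]) * lam + c[2]) * lam + c[3]
    scale = max(np.max(np.abs(c)), 1.0)
    return float(abs(val) / scale)


def lambda_plus_expansion(q: float, params: HydroParams) -> float:
    """Small-q expansion of the destabilised mode about the isotropic
    state (alpha1 < 0):

        lam+ = -2 D_rho q^2 + a0 b q^4 / (2|alpha1|)
               - a0 b q^6 (D_Pi - D_rho) / alpha1^2,

    evaluated verbatim.  Note this expansion and the exact cubic roots
    differ even at a0 = 0 (the expansion gives -2 D_rho q^2, the exact
    branch -D_rho q^2); both are exposed deliberately."""
    a1 = params.alpha1_0
    if a1 >= 0:
        raise ParameterError("expansion defined about the disordered state (alpha1 < 0)")
    ab = params.a0_beta
    return (-2.0 * params.D_rho * q ** 2
            + ab * q ** 4 / (2.0 * abs(a1))
            - ab * q ** 6 * (params.D_Pi - params.D_rho) / a1 ** 2)


def critical_wavevector(params: HydroParams) -> float | None:
    """Upper wavevector q_c of the long-wavelength instability,

        q_c^2 = |alpha1| / (2 dD)
                + (1/2) sqrt((|alpha1|/dD)^2 - 8 D_rho alpha1^2 / (dD a0 b)),

    valid for dD = D_Pi - D_rho > 0; returns None when the radicand is
    negative (activity below threshold, no instability)."""
    dD = params.delta_D
    if dD <= 0:
        raise ParameterError(
            "q_c requires DeltaD = D_Pi - D_rho > 0 (the instability proviso)")
    a1 = abs(params.alpha1_0)
    ab = params.a0_beta
    if ab <= 0:
        return None
    radicand = (a1 / dD) ** 2 - 8.0 * params.D_rho * a1 ** 2 / (dD * ab)
    if radicand < 0:
        return None
    qc2 = a1 / (2.0 * dD) + 0.5 * math.sqrt(radicand)
    return math.sqrt(qc2)


def instability_threshold(params: HydroParams) -> tuple[float, bool]:
    """Minimal activity a0*beta_c for a real q_c, and whether the supplied
    parameters exceed it.  Setting the q_c radicand to zero gives
    a0*beta_c >= 8 D_rho dD."""
    dD = params.delta_D
    if dD <= 0:
        raise ParameterError(
            "threshold requires DeltaD = D_Pi - D_rho > 0 (the instability proviso)")
    thr = 8.0 * params.D_rho * dD
    return thr, params.a0_beta > thr


# ---------------------------------------------------------------------------
# Continuum theory: renormalised-mean-field free energy
# ---------------------------------------------------------------------------
# Integrating density fluctuations into the mean-field theory of S yields
#
#   F_eff(S) = -(b2/2) S^2 - (b3/3) S^3 + (b4/4) S^4,
#
# whose activity-generated cubic term (b3 proportional to a0) makes the
# order-disorder transition first order: a jump S_c = 2 b3 / (3 b4) at a
# shifted density rho_c = rho_IN (1 - 2 b3^2 / (9 b4)) < rho_IN.

@dataclass(frozen=True)
class RMFCoefficients:
    """Effective-free-energy coefficients; b3 and b4 are non-negative by
    construction (b3 = 0 exactly in the passive limit a0 = 0)."""

    b2: float
    b3: float
    b4: float
    alpha1_prime: float = 1.0
    c_const: float = 0.0

    def __post_init__(self):
        if self.b4 <= 0:
            raise ParameterError("b4 must be > 0 (confining quartic)")
        if self.b3 < 0:
            raise ParameterError("b3 must be >= 0")


def rmf_coefficients(a0: float, rho0: float, D_rho: float, alpha1_prime: float,
                     alpha2: float, c_const: float = 0.0,
                     alpha1_at_rho: float = 0.0) -> RMFCoefficients:
    """Coefficients of F_eff:

        b2 = alpha1(rho) + alpha1' * c,
        b3 = a0 rho0 alpha1' / (2 D_rho),
        b4 = (1/2) rho0^2 alpha2.
    """
    if D_rho <= 0:
        raise ParameterError("D_rho must be > 0 (b3 diverges otherwise)")
    if alpha2 <= 0:
        raise ParameterError("alpha2 must be > 0")
    b2 = alpha1_at_rho + alpha1_prime * c_const
    b3 = a0 * rho0 * alpha1_prime / (2.0 * D_rho)
    b4 = 0.5 * rho0 ** 2 * alpha2
    return RMFCoefficients(b2, b3, b4, alpha1_prime, c_const)


def effective_free_energy(S, coeffs: RMFCoefficients):
    """F_eff(S) = -(b2/2) S^2 - (b3/3) S^3 + (b4/4) S^4."""
    S = np.asarray(S, dtype=float)
    out = (-0.5 * coeffs.b2 * S ** 2 - coeffs.b3 / 3.0 * S ** 3
           + 0.25 * coeffs.b4 * S ** 4)
    return out if out.ndim else float(out)


def coexistence_jump(coeffs: RMFCoefficients, rho_IN: float = 1.0) -> tuple[float, float]:
    """Closed-form first-order jump and shifted transition density:

        S_c = 2 b3 / (3 b4),   rho_c = rho_IN (1 - 2 b3^2 / (9 b4)).

    Both vanish with the activity (b3 -> 0 recovers the continuous
    equilibrium transition at rho_IN)."""
    S_c = 2.0 * coeffs.b3 / (3.0 * coeffs.b4)
    rho_c = rho_IN * (1.0 - 2.0 * coeffs.b3 ** 2 / (9.0 * coeffs.b4))
    return S_c, rho_c


def minimize_free_energy(coeffs: RMFCoefficients, s_max: float | None = None) -> float:
    """Global minimizer of F_eff on [0, s_max] by dense grid plus local
    polish (accuracy ~1e-8 in S).  Deliberately independent of the
    closed-form stationarity analysis so it can serve as its numeric
    oracle."""
    b2, b3, b4 = coeffs.b2, coeffs.b3, coeffs.b4
    if s_max is None:
        s_max = (abs(b3) + math.sqrt(b3 ** 2 + 4.0 * b4 * (abs(b2) + 1.0))) / b4 + 1.0
    grid = np.linspace(0.0, s_max, 4001)
    vals = effective_free_energy(grid, coeffs)
    # polish every grid-local minimum: near-degenerate wells must each be
    # resolved to full precision before comparing
    interior = np.nonzero((vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:]))[0] + 1
    best_s, best_f = 0.0, float(effective_free_energy(0.0, coeffs))
    for i in interior:
        res = optimize.minimize_scalar(lambda s: effective_free_energy(s, coeffs),
                                       bounds=(grid[i - 1], grid[i + 1]),
                                       method="bounded", options={"xatol": 1e-12})
        if res.fun < best_f:
            best_s, best_f = float(res.x), float(res.fun)
    return best_s


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, L: int, C: float, rng: np.random.Generator,
                 orientation: float = 0.0, band_width: int | None = None,
                 band_fraction: float = 0.9) -> LatticeState:
    """Synthetic configurations for testing and demonstration.

    ``aligned``: uniformly scattered particles sharing one orientation.
    ``random``: the standard disordered initial condition.
    ``banded``: a horizontal strip of ``band_width`` rows holding
    ``band_fraction`` of the particles at a shared orientation over a
    dilute disordered background (the banded-state geometry).
    ``half_plane``: deterministic, rows y < L/2 completely filled at the
    shared orientation (C is ignored).
    """
    if L < 2 or not 0.0 <= C <= 1.0:
        raise ParameterError("invalid L or C")
    N = int(round(C * L * L))
    if kind == "random":
        return init_lattice(SimParams(L=L, C=C, beta_eps=1.0, burn_in_iterations=0,
                                      measure_iterations=0), rng)
    if kind == "aligned":
        occupancy = np.zeros((L, L), dtype=np.int8)
        occupancy.flat[rng.choice(L * L, size=N, replace=False)] = 1
        orient = np.where(occupancy == 1, wrap_angle(orientation), np.nan)
        return LatticeState.from_fields(occupancy, orient)
    if kind == "half_plane":
        occupancy = np.zeros((L, L), dtype=np.int8)
        occupancy[:, : L // 2] = 1
        orient = np.where(occupancy == 1, wrap_angle(orientation), np.nan)
        return LatticeState.from_fields(occupancy, orient)
    if kind == "banded":
        n_in = int(round(band_fraction * N))
        n_out = N - n_in
        # default width targets a strip density of ~0.85
        w = band_width if band_width is not None else \
            min(L - 1, max(2, math.ceil(n_in / (0.85 * L))))
        if n_in > w * L or n_out > (L - w) * L or w >= L:
            raise ParameterError("band fixture infeasible for requested C/width/fraction")
        occupancy = np.zeros((L, L), dtype=np.int8)
        orient = np.full((L, L), np.nan)
        strip_sites = rng.choice(w * L, size=n_in, replace=False)
        xs, ys = strip_sites % L, strip_sites // L
        occupancy[xs, ys] = 1
        orient[xs, ys] = wrap_angle(orientation)
        out_sites = rng.choice((L - w) * L, size=n_out, replace=False)
        xo, yo = out_sites % L, w + out_sites // L
        occupancy[xo, yo] = 1
        orient[xo, yo] = rng.uniform(0.0, PI, size=n_out)
        return LatticeState.from_fields(occupancy, orient)
    raise ParameterError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_snapshot(path: str | Path, state: LatticeState,
                   params: SimParams | None = None, iteration: int = 0) -> None:
    """Plain-text snapshot: header lines, then one 'x y theta' row per
    particle (0-based row-major coordinates, theta to 6 decimals)."""
    path = Path(path)
    meta = {"L": state.L, "iteration": iteration}
    if params is not None:
        meta.update(C=params.C, beta_eps=params.beta_eps,
                    variant=params.variant, seed=params.seed)
    with path.open("w") as fh:
        fh.write(f"# activenematic-snapshot v{SNAPSHOT_FORMAT_VERSION}\n")
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# x y theta\n")
        for x, y in state.particles:
            fh.write(f"{x} {y} {state.orientation[x, y]:.6f}\n")


def read_snapshot(path: str | Path) -> tuple[LatticeState, dict]:
    """Inverse of `write_snapshot`; raises FormatError on version mismatch
    or malformed content."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# activenematic-snapshot v"):
        raise FormatError(f"{path}: not an activenematic snapshot")
    version = lines[0].rsplit("v", 1)[-1]
    if version != str(SNAPSHOT_FORMAT_VERSION):
        raise FormatError(f"{path}: unsupported snapshot version {version}")
    meta: dict = {}
    rows = []
    for line in lines[1:]:
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed particle row {line!r}")
        rows.append((int(parts[0]), int(parts[1]), float(parts[2])))
    if "L" not in meta:
        raise FormatError(f"{path}: missing L header")
    L = int(meta["L"])
    occupancy = np.zeros((L, L), dtype=np.int8)
    orient = np.full((L, L), np.nan)
    for x, y, th in rows:
        if not (0 <= x < L and 0 <= y < L):
            raise FormatError(f"{path}: site ({x},{y}) outside lattice")
        if occupancy[x, y]:
            raise FormatError(f"{path}: duplicate site ({x},{y})")
        occupancy[x, y] = 1
        orient[x, y] = th
    for key, cast in (("C", float), ("beta_eps", float), ("seed", int),
                      ("iteration", int)):
        if key in meta:
            meta[key] = cast(meta[key])
    return LatticeState.from_fields(occupancy, orient), meta


def save_run(path: str | Path, series: ObservableSeries) -> None:
    """Container holding the S/theta_bar series and all snapshots of a run
    (compressed npz with versioned header)."""
    p = series.params
    snaps_occ = np.array([s.occupancy for s in series.snapshots], dtype=np.int8) \
        if series.snapshots else np.zeros((0, p.L, p.L), dtype=np.int8)
    snaps_th = np.array([s.orientation for s in series.snapshots]) \
        if series.snapshots else np.zeros((0, p.L, p.L))
    np.savez_compressed(
        Path(path), format_version=RUN_FORMAT_VERSION,
        L=p.L, C=p.C, beta_eps=p.beta_eps, variant=p.variant,
        burn_in_iterations=p.burn_in_iterations,
        measure_iterations=p.measure_iterations,
        measure_stride=p.measure_stride, snapshot_stride=p.snapshot_stride,
        seed=p.seed, times=series.times, S=series.S_series,
        theta_bar=series.theta_bar_series,
        snapshot_times=np.asarray(series.snapshot_times, dtype=np.int64),
        snapshots_occ=snaps_occ, snapshots_theta=snaps_th,
        counters=json.dumps(series.counters))


def load_run(path: str | Path) -> ObservableSeries:
    """Inverse of `save_run`; raises FormatError on truncation or version
    mismatch."""
    try:
        with np.load(Path(path), allow_pickle=False) as data:
            if "format_version" not in data:
                raise FormatError(f"{path}: not an activenematic run container")
            if int(data["format_version"]) != RUN_FORMAT_VERSION:
                raise FormatError(f"{path}: unsupported run format "
                                  f"{int(data['format_version'])}")
            params = SimParams(
                L=int(data["L"]), C=float(data["C"]), beta_eps=float(data["beta_eps"]),
                variant=str(data["variant"]),
                burn_in_iterations=int(data["burn_in_iterations"]),
                measure_iterations=int(data["measure_iterations"]),
                measure_stride=int(data["measure_stride"]),
                snapshot_stride=int(data["snapshot_stride"]), seed=int(data["seed"]))
            snapshots = [LatticeState.from_fields(o, t) for o, t in
                         zip(data["snapshots_occ"], data["snapshots_theta"])]
            return ObservableSeries(
                params, data["times"], data["S"], data["theta_bar"], snapshots,
                [int(t) for t in data["snapshot_times"]],
                json.loads(str(data["counters"])))
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: corrupt or truncated run container ({exc})") from exc


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepPlan:
    """Grid scan over (C, beta_eps) with per-point realisations.

    Every point runs an independent simulation whose seed derives
    deterministically from (master_seed, C index, beta index, realisation)
    through a numpy SeedSequence, so each point is reproducible in
    isolation and the whole sweep is reproducible from master_seed."""

    C_values: Sequence[float]
    beta_eps_values: Sequence[float]
    template: SimParams
    realisations: int = 1
    out_root: str | Path = "sweep"
    master_seed: int = 0

    def __post_init__(self):
        if self.realisations < 1:
            raise ParameterError("realisations must be >= 1")
        for C in self.C_values:
            for b in self.beta_eps_values:
                dataclasses.replace(self.template, C=C, beta_eps=b)  # validates


def derive_seed(master_seed: int, ci: int, bi: int, realisation: int) -> int:
    """Deterministic per-point seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(ci), int(bi), int(realisation)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Execute (or resume) the sweep; completed points are skipped based on
    their per-point result files.  Returns and writes the summary table
    (one row per grid point: mean S, modal state label, bistable flag)."""
    root = Path(plan.out_root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, C in enumerate(plan.C_values):
        for bi, b in enumerate(plan.beta_eps_values):
            for r in range(plan.realisations):
                pf = root / f"point_c{ci}_b{bi}_r{r}.json"
                if pf.exists():
                    rows.append(json.loads(pf.read_text()))
                    continue
                seed = derive_seed(plan.master_seed, ci, bi, r)
                params = dataclasses.replace(plan.template, C=C, beta_eps=b, seed=seed)
                try:
                    series = run_simulation(params)
                    cls = classify_state(series)
                    rec = {"C": C, "beta_eps": b, "realisation": r, "seed": seed,
                           "mean_S": float(np.mean(series.S_series)) if len(series) else float("nan"),
                           "label": cls.label, "bistable": bool(cls.bistable)}
                except Exception as exc:  # keep sweeping on point failure
                    logger.error("sweep point C=%.4f beta_eps=%.4f r=%d failed: %s",
                                 C, b, r, exc)
                    rec = {"C": C, "beta_eps": b, "realisation": r, "seed": seed,
                           "mean_S": float("nan"), "label": "failed", "bistable": False}
                pf.write_text(json.dumps(rec))
                rows.append(rec)
    df = pd.DataFrame(rows)
    summary = (df.groupby(["C", "beta_eps"], as_index=False)
               .agg(mean_S=("mean_S", "mean"),
                    label=("label", lambda s: s.mode().iloc[0]),
                    bistable=("bistable", "any")))
    summary.to_csv(root / "summary.csv", index=False)
    return summary
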