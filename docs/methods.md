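# Methods

## The model

`activenematic` simulates apolar self-propelled particles on an L × L
square lattice with periodic boundaries. A site i carries an occupation
number nᵢ ∈ {0, 1} (volume exclusion: at most one particle per site) and,
where occupied, an orientation θᵢ ∈ [0, π). Orientations are apolar: θ and
θ + π are the same physical state, and every operation stores angles in the
fundamental domain [0, π). Neighbouring particles interact through the
modified Lebwohl–Lasher Hamiltonian

    H = −ε Σ_<ij> nᵢ nⱼ cos 2(θᵢ − θⱼ),

which is minimised by mutual nematic alignment. All energies are expressed
in units of ε, so the single control parameter of the thermal dynamics is
the product βε.

One **elementary step** is: pick a particle uniformly at random (with
replacement), attempt a move, then attempt a Metropolis orientation update
of the same particle (whether or not the move succeeded — the two
sub-steps are sequential, not conditional). One **iteration** repeats this
N times, N = round(C·L²) with C the packing density. Two movement rules
define the two model variants:

* **equilibrium** — the particle hops to one of its four nearest
  neighbours with probability 1/4 each;
* **active** — the particle first picks the axis it is more inclined to —
  vertical if π/4 < θ ≤ 3π/4 (the inequality is strict at π/4, so θ = π/4
  moves horizontally), horizontal otherwise — and hops to one of the two
  neighbours on that axis with probability 1/2.

In both variants the hop is rejected if the target site is occupied; no
energy criterion applies to moves. The orientation update proposes a new
angle θ′ uniform on [0, π) and accepts with probability
min(1, exp(−βε·ΔH)), where ΔH is the change of the bond energy between the
particle and its occupied nearest neighbours. The uniform global proposal
is a deliberate choice: it is symmetric (valid Metropolis), ergodic in one
step, and requires no tuning of a perturbation width; the pure-python
update additionally accepts a discrete proposal set, which the
exact-enumeration tests use. At complete filling (C = 1) every hop is
rejected and the two variants generate identical dynamics; because the
compiled kernel consumes exactly four uniforms per elementary step in both
variants (particle pick, target pick, proposal angle, acceptance), their
C = 1 trajectories are bit-identical for equal seeds.

A subtlety worth recording: the movement rules accept hops blind to ΔH,
so the joint position–orientation Markov chain of the *equilibrium*
variant is not reversible with respect to H whenever moving changes the
bond structure — its stationary position marginal is uniform rather than
Boltzmann-clustered. The test suite therefore checks the mobile dynamics
against the exactly enumerated stationary distribution of the full
transition matrix (2 particles on a 2×2 torus, discrete angles), and
checks Boltzmann statistics only where the chain is exactly reversible
(full filling), there against a Bessel-function transfer-matrix oracle.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `L` | lattice linear size (sites) | — |
| `C` | packing density N/L², dimensionless, ∈ [0, 1] | — |
| `beta_eps` | βε, inverse temperature × coupling, dimensionless | — |
| `variant` | `equilibrium` or `active` | `active` |
| `burn_in_iterations` | iterations discarded before measurement | 1.5·10⁶·(L/400)² |
| `measure_iterations` | iterations measured | 1.5·10⁶·(L/400)² |
| `measure_stride` | iterations per recorded (S, θ̄) sample | 10 |
| `snapshot_stride` | iterations per stored configuration (0 = none) | 0 |
| `seed` | master seed; fully determines the run | 0 |

The reference protocol (1.5·10⁶ burn-in plus 1.5·10⁶ measurement
iterations at L = 400–512, ≥ 20 realisations) is far beyond desk scale;
the default iteration counts scale it by (L/400)² so that the number of
sweeps per unit of diffusive system-crossing time is preserved. The full
protocol remains reachable by passing explicit counts.

## Observables

* **Scalar order parameter** S = |Σ nᵢ e^{2iθᵢ}| / N ∈ [0, 1]; the
  **director estimate** θ̄ is half the argument of the doubled-angle mean
  vector (the standard nematic estimator; it reduces to the arithmetic
  mean for concentrated distributions away from the wrap).
* **Two-point orientation correlation** g₂(r) accumulates
  nᵢ nᵢ₊ᵣ cos 2(θᵢ − θᵢ₊ᵣ) over axis-aligned separations on both lattice
  axes and over all supplied snapshots. The default normalisation divides
  by the number of occupied pairs at each r, so g₂ ≡ 1 for any perfectly
  aligned configuration and separations without pairs are flagged missing
  (NaN) rather than zero; the literal Σnᵢ² normalisation, under which a
  dilute aligned state saturates at ≈ C, is available as
  `normalization="total"`. An option for Euclidean shells is deliberately
  not provided: on the lattice, axis-aligned separations are the natural
  geometry and the decay classification only needs relative shape.
* **Decay classification** fits log g₂ against r (exponential) and
  against log r (power law) over the widest contiguous range starting at
  r = 1 in which g₂ stands above 3/√(pair count) — the pair-count noise
  floor; without this truncation a flat noise tail biases the log-log fit
  toward a spurious power law. The better model must win by a residual
  ratio of 1.5, else the curve is inconclusive; fewer than 5 usable points
  is inconclusive. A single-step collapse by more than a factor 5 preceded
  by a plateau (two or more steps each dropping by less than √5) is
  classified "abrupt", the signature of finite ordered clusters in the
  inhomogeneous mixed state; a plain steep exponential decays uniformly
  and does not trigger it.
* **Number fluctuations** ΔN = √(⟨N²⟩ − ⟨N⟩²) versus ⟨N⟩ over
  non-overlapping ℓ×ℓ tiles (ℓ = 2, 4, 8, …, L/4) across snapshots; ζ is
  the ordinary-least-squares slope in log-log. ζ = 1/2 is the uncorrelated
  benchmark; ζ > 1/2 signals giant number fluctuations.
* **P(θ)** is a normalised histogram on [0, π); a Gaussian is fitted to
  the histogram rolled so its mode is centred (wrapped fit), with
  moment-based seeding; fit quality below R² = 0.8 flags the fit poor
  (broad/flat distributions).
* **Mean-orientation autocorrelation** C(t) averages the running mean
  (1/t) Σ_{τ≤t} cos 2(θ̄(t₀) − θ̄(t₀+τ)) over all admissible start times.
* **P(S)** uses fixed 0.02-wide bins on [0, 1], Gaussian kernel smoothing
  with a 2-bin bandwidth, and counts peaks as local maxima above 5% of the
  global maximum separated by ≥ 5 bins. These constants are fixed so that
  bimodality (the first-order coexistence signature) is a deterministic
  function of the samples.
* **State classifier** (I / BS / IM / HO): coarse-grain at the largest
  block dividing L that is ≤ L/16. In order: mean S < 0.2 → I; a
  contiguous set of coarse rows or columns, every tile denser than
  C + 0.15, spanning the full transverse extent, whose pooled interior
  doubled-angle order exceeds 0.5 while the pooled exterior (excluding the
  one coarse row bordering the strip — the interface is partially ordered
  by construction) stays below 0.25, detected in a majority of snapshots →
  BS; mean S ≥ 0.5 with tile-density standard deviation < 0.15 → HO;
  otherwise IM. Pooling the region order (resultant over all particles in
  the region) rather than averaging per-tile S avoids the artefact that a
  one-particle tile has S = 1. The bistable flag counts switches of the S
  series between the bands below 0.45 and above 0.55 (hysteresis margin
  0.05); ≥ 2 switches flag bistability. All thresholds are configurable
  (`ClassifierThresholds`); the defaults above are the tested ones.

## Continuum theory

The coarse-grained description couples the density ρ and the nematic
order-parameter field Π_ij: the density obeys a continuity equation whose
current contains, besides ordinary diffusion D_ρ∇ρ, an active
curvature-coupling term a₀∇ⱼΠ_ij; Π relaxes under a mean-field alignment
term α₁(ρ) − α₂(Π:Π) with α₁(ρ) = ρ/ρ_IN − 1 changing sign at the
mean-field transition density ρ_IN, a density-coupling term with
coefficient β (named `beta_c` in code — it is distinct from the inverse
temperature, and only the product a₀·β_c enters any result), and diffusion
D_Π.

Linearising about the isotropic state (Π = 0, α₁ < 0) along the symmetric
direction q_x = q_y = q/√2 gives a cubic dispersion relation that
factorises into the decoupled shear branch λ = α₁ − D_Π q² and a quadratic
mixing density with Π₁₁ through the a₀β_c q⁴ coupling. `dispersion_roots`
returns all three roots in closed form (deterministic order: descending
real part, then imaginary part) and `dispersion_residual` verifies them
against the expanded cubic; the test suite holds every root of 10³ random
draws to a relative residual below 10⁻¹⁰.

The small-q expansion of the destabilised branch,

    λ₊ = −2D_ρq² + a₀βq⁴/(2|α₁|) − a₀βq⁶(D_Π − D_ρ)/α₁²,

is evaluated verbatim (`lambda_plus_expansion`). Note that this printed
expansion does not reduce to the exact density branch −D_ρq² at a₀ = 0 —
the constant differs by a factor 2. Both forms are exposed side by side
and neither is silently corrected; the exact cubic is authoritative where
they disagree.

The instability exists for q below

    q_c² = |α₁|/(2ΔD) + ½√((|α₁|/ΔD)² − 8D_ρα₁²/(ΔD·a₀β)),

valid for ΔD = D_Π − D_ρ > 0; requiring the radicand to be non-negative
gives the activity threshold a₀β ≥ 8·D_ρ·ΔD (`instability_threshold`,
cross-checked symbolically in the tests). Note q_c ∝ |α₁(ρ₀)|: the
unstable band of wavevectors *narrows* on approach to ρ_IN, which is why
small systems stop supporting the long-wavelength instability (see
"Reduced scale" below).

The renormalised-mean-field free energy for the scalar order parameter,
with density fluctuations integrated in, is

    F_eff(S) = −(b₂/2)S² − (b₃/3)S³ + (b₄/4)S⁴,
    b₂ = α₁(ρ) + α₁′c,  b₃ = a₀ρ₀α₁′/(2D_ρ),  b₄ = ½ρ₀²α₂,

with α₁′ = ∂α₁/∂ρ at ρ₀. The constant c in b₂ is an explicit parameter
defaulting to 0; results are stated in terms of b₂ wherever possible. The
activity-generated cubic term makes the transition first order, with jump
S_c = 2b₃/(3b₄) at the shifted density ρ_c = ρ_IN(1 − 2b₃²/(9b₄)) < ρ_IN;
both vanish with a₀ (the equilibrium limit is continuous).
`minimize_free_energy` is a dense-grid-plus-polish global minimiser that
polishes *every* grid-local minimum (near-degenerate wells at coexistence
must each be resolved before comparison) to ~10⁻⁸ in S; it is kept
independent of the closed forms precisely so it can serve as their numeric
oracle, and the tests confirm coexistence at b₂ = −2b₃²/(9b₄) with
minimiser jump 0 → S_c to 10⁻⁶ over random coefficient draws.

## Synthetic fixtures

`make_fixture` produces the reference configurations used in tests and
demonstrations: `aligned` (uniformly scattered particles, one shared
orientation — S = 1), `random` (the disordered initial condition),
`banded` (a strip holding a fraction of the particles at one orientation
at ~0.85 strip density over a dilute disordered background — the banded
geometry), and `half_plane` (deterministic coarse-graining fixture). These
emulate the *geometry* of the dynamical states, not their thermal
roughness: planted bands have sharp interfaces and exactly aligned
interiors, so classifier tests on fixtures demonstrate that the rules fire
on the intended geometry, not that simulation states are always classified
correctly near state boundaries.

## Determinism and the RNG

A run is a pure function of `SimParams`. Initialisation uses a
`numpy` Generator seeded with `seed`; the compiled kernel seeds its own
stream from a fixed affine hash of `seed`. Draw order per elementary step
is fixed (particle, target, proposal, acceptance — the acceptance uniform
is drawn even when ΔH ≤ 0 keeps it unused) so trajectories are
reproducible bit-for-bit across runs and across model variants at C = 1.
Sweep points derive per-point seeds < 2³¹ from
`SeedSequence([master, C-index, β-index, realisation])`, so any point can
be reproduced in isolation and a finished sweep resumes without
recomputation.

## Reduced scale: what the desk-scale runs do and do not show

The acceptance computations run at L = 64 with iteration counts scaled by
(L/400)², one to two realisations per parameter point (sizes chosen to
keep a full scan within minutes on one core). At this scale the model
reproduces the *structure* of the reference phenomenology: a disordered
isotropic state with ζ = 0.50 number-fluctuation scaling; a first-order
onset of order in the active model with bimodal P(S), banded
configurations and giant number fluctuations (ζ ≈ 0.9 at C = 0.78); an
equilibrium variant that orders only at distinctly higher density than the
active one is disordered at; bands at βε = 2.0 that are absent at
βε = 1.7; and bistable switching of S near onset.

The *locations* of the transitions, however, shift substantially upward at
this scale. Two mechanisms compound:

* the banded-state instability is long-wavelength — q_c ∝ |α₁(ρ₀)| shrinks
  on approach to the transition, so near onset the unstable mode no longer
  fits in a small box (2π/L exceeds q_c) and ordering is deferred to
  higher density where local mechanisms take over;
* below the site-percolation threshold the equilibrium dilution has no
  static spanning cluster, and quasi-long-range order must be mediated by
  particle transport, which the scaled-down sweep budgets only partially
  equilibrate (ten-fold longer runs at L = 48 moved the measured
  crossover by little).

Concretely, at L = 64 the active model's P(S) first turns bimodal near
C ≈ 0.5 (reference value 0.37 at L = 400) and the equilibrium
short-range/quasi-long-range crossover sits above the top of the 0.40–0.56
scan grid (reference value ≈ 0.48). The acceptance script reports the
measured desk-scale numbers as computed; they should be read with this
documented shift in mind. The scan protocols are: for the bimodality
onset, a coarse one-realisation ascent (step 0.04) locates the first
density whose S series leaves the isotropic band (max S > 0.3), then
P(S) pooled over two realisations is walked downward in 0.01 steps while
bimodal; for the correlation crossover, the 0.40–0.56 grid (step 0.02) is
descended from the top until a curve classifies exponential. Pooling two
realisations matters: at this scale a single run near onset tends to
commit to one branch for its whole measured window, and the coexistence
shows up across realisations rather than within one.

## Known limitations

* No numerical integration of the nonlinear continuum equations; the
  analytic layer covers the linearised dispersion and the printed
  renormalised-mean-field results only.
* No defect detection or structure factors; no continuous-space variant;
  no multiple-occupancy variant (which would suppress the bistability).
* The state classifier is threshold-based and tuned at L = 64 blocks; very
  small lattices (L < 32) leave it little coarse-graining room.
* Desk-scale transition densities are shifted, as documented above; the
  full reference protocol is reachable through explicit iteration counts
  but takes CPU-days.
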