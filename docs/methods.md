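# Methods

This note documents the model, the numerical choices and the validation
strategy of `felas`, and what the desk-scale tests do and do not
demonstrate.

## Model

Chains of N_p beads (diameter σ, mass m) are connected by FENE springs
U(r) = −½ k R0² ln(1 − r²/R0²) with k = 20 ε/σ² and R0 = 1.5 σ; bonded
neighbours additionally interact through a unit-ε WCA core (the standard
bead-spring construction, which keeps bonds near 0.97 σ and prevents chain
crossing).  Bending is harmonic, U = K_θ(θ − θ0)² with θ0 = 150°.
Non-bonded pairs interact via 12-6 LJ with pair-specific well depth
ε_ij = √(ε_ii ε_jj); the geometric-mean combining rule makes cross-motif
attraction weaker than the stronger partner's self-affinity and reduces to
ε_ii on the diagonal.  Attractive pairs use a force-shifted LJ (energy and
force both continuously zero at r_c = 2.5 σ) — the force shift is the
linear-in-r correction that takes the potential smoothly to zero at the
cutoff.  Pairs involving a spacer (ε_ij = 0 after thresholding) are WCA
repulsive, truncated and shifted at 2^{1/6} σ.

Per-residue well depths follow ε_ii = sin²(2π i / k) with 0-based residue
index, so residue 0 is an exact spacer.  Note the profile repeats every
k/2 residues; the family label P_k follows the formula parameter k.  Well
depths ≤ 0.1 are zeroed (spacer classification threshold).  Because
Σ sin² = N_p/2 over complete half-periods, all P_k at fixed N_p carry the
same total interaction energy, and the disorder variants (P_kA shuffle of
sticker values over sticker sites, P_kB high/low alternation within
domains, R_k full permutation) conserve it exactly — patterning is the only
axis being varied.

### Parameters not fixed by the model definition

* **K_θ = 2.0 ε/rad²** (config default).  Semi-flexible: random-sequence
  melts then show single-exponential tangent decorrelation with ℓ_p of a
  few σ, the worm-like-chain regime the analysis targets.
* **r_c = 2.5 σ** for attractive pairs, the conventional LJ cutoff.
* **Bulk temperature default T = 1.0 ε/k_B** (below the critical points of
  all patterns at production scale).

## Integrator

BAOAB splitting of underdamped Langevin dynamics: half force kick, half
drift, exact Ornstein–Uhlenbeck friction/noise update
(c1 = e^{−γΔt/m}, c2 = √(k_BT(1−c1²)/m)), half drift, half kick with
re-evaluated forces.  With γ = 0 the scheme is velocity Verlet, which the
NVE drift and momentum-conservation tests exploit.  Defaults Δt = 0.001 τ,
γ = 0.1 m/τ.  Initialization places chains as biased random walks with an
overlap-avoiding insertion pass, followed by a two-stage force-capped,
strongly damped push-off (caps 30 then 200 ε/σ at reduced Δt); velocities
are then redrawn from Maxwell–Boltzmann.  Bond overextension (r ≥ R0)
aborts a production run with a diagnostic; during capped relaxation the
FENE argument is clamped instead so the push-off can recover.

Neighbor lists are all-pairs rebuilds (O(N²), adequate at desk scales)
with a 0.4 σ skin, refreshed when any displacement exceeds half the skin.
Virial stress uses the kinetic term plus pairwise r⊗F accumulation; the
three-body angle term is decomposed relative to the central bead, which
keeps the tensor translation invariant under PBC.

## Phase equilibrium

Slab runs use a box elongated 5× along x with chains initialized in the
central fifth.  Profiles are circular-mean recentred before time
averaging.  Interfaces are fitted with the symmetric form
ρ(x) = (ρ_l+ρ_v)/2 − (ρ_l−ρ_v)/2 · tanh((|x−x0|−w)/d); a profile without
distinguishable plateaus raises and the temperature is excluded.  The
critical point comes from a joint nonlinear least-squares of the
rectilinear-diameter line and the order-parameter scaling with β frozen at
0.325 (the scaling law is implemented multiplicatively,
Δρ = Δρ0(1−T/T_c)^β, the only form that vanishes at T_c).  Forcing a wrong
exponent (e.g. β = 0.5) biases T_c upward, which the tests assert as a
direction.

Two practical constraints matter at small scale.  First, ρ_l(T) carries
T_c information only near criticality — deep below T_c the liquid branch
is flat and the extrapolation is pure noise — so temperature ladders must
bracket each pattern's own critical region (the desk-scale suite uses
per-pattern ladders calibrated by pilot runs).  Second, the fitted T_c is
capped at 1.5× the highest ladder temperature: the data cannot resolve a
critical point far beyond the ladder, and the cap regularizes
noise-driven runaway extrapolations.  ``workflow_phase_diagram`` can also
average recentred profiles over independent replicas per temperature for
additional stability.

## Structure and shape

S(q) is evaluated on the reciprocal lattice 2π n/L and spherically binned;
the default condensate selection is stickers-only, which isolates the
sticky-domain length scale.  Clustering is single-linkage under the
minimum-image metric (default sticker–sticker cutoff 1.5 σ, first-neighbor
shell; contact maps use 2 σ separately).  Cluster coordinates are unwrapped
by BFS before computing the gyration tensor Q; a member reachable through
two inconsistent periodic images marks the cluster percolated (its shape
metrics are reported but not meaningful).  Shape metrics use the traceless
tensor Q̂ = Q − (TrQ/3)I:

    Δ = (3/2) TrQ̂² / (TrQ)²,    Ξ = 4 DetQ̂ / ((2/3) TrQ̂²)^{3/2}

so 2Δ ∈ [0, 2] (sphere → rod) and Ξ ∈ [−1, 1] (oblate → prolate); the
normalization of Ξ by the traceless invariant is what bounds it in [−1, 1]
with rod → +1, disk → −1.  The density-sweep census flags the
sphere-to-elongated micelle transition when the mean largest principal
component exceeds 6× the smallest — well above the ~2–3 ratio that finite
isotropic clusters show purely through eigenvalue ordering.

## Dynamics

MSD is particle- and origin-averaged (FFT algorithm) on a log-spaced lag
grid (factor 1.2); exponents are log-log least squares over a stated
window.  The self-van Hove is stored as the probability density of the
displacement magnitude (the 4πr² factor absorbed, so each lag integrates
to 1).  Gaussian widths follow the convention G_s ∝ exp(−r²/W(t)), under
which free diffusion gives W = 4Dt (per-axis variance W/2).  Gaussianity
is a declared tail-mass criterion: the observed mass beyond 2× the rms
displacement must not exceed 3× the chi(3 dof) expectation.  Contact
autocorrelation C(t) = ⟨h(0)h(t)⟩/⟨h(0)⟩ uses every frame as origin and
tracks only pairs ever in contact (others contribute to neither numerator
nor denominator).

## Rheology

G(t) = V/(5k_BT)[ΣC_offdiag + (1/6)ΣC_N] with N_ij = Σ_ii − Σ_jj, all six
channels correlated with a multi-tau correlator (16 points per level,
factor-2 block averaging; level-0 lags are exact brute-force values, and
deeper levels carry the usual O((block/τ)²) bias, asserted against OU
fixtures).  Maxwell spectra are fitted by NNLS on a log-spaced τ grid from
2× the first lag to a fifth of the window (τ positions optimized
nonlinearly when ≤ 3 modes are requested); zero-weight modes are pruned.
η is Σ G_i τ_i from the spectrum or the trapezoidal ∫G dt with a
single-exponential tail extrapolation from the final decade; the fitted
tail time constant is capped at the observation window (the data cannot
support slower relaxation, and uncapped tail fits on noisy correlators
can inflate η by an order of magnitude), and a finite-horizon variant
(∫G dt to a fixed lag, no tail) is provided for noise-robust
comparisons.  A G(t) that
retains > 50% of its peak over the final decade is reported as a
Kelvin–Voigt plateau (plateau modulus + divergent-η flag) rather than
forced through the integral; the fluid/solid classifier uses a 20% decay
ratio plus a slow-mode weight fraction (25%) with all thresholds in
config.

## Sequence descriptors

Real sequences get per-residue amplitudes λ_i from the Kyte–Doolittle
hydropathy index min-max rescaled to [0, 1].  The correlation length ⟨κ⟩
is the half-decay lag of the mean-removed autocorrelation of λ (linear
interpolation between integer lags; a pure sinusoid of period p gives
p/6).  A constant profile is degenerate and defines ⟨κ⟩ = 1.  The combined
descriptor is ⟨κ⟩·(Σλ_i/λ_max)/N_p.  Pattern complexity W1 is the 1-D
optimal-transport distance between the normalized *positional* energy
profile (mass δE_i at coordinate i/N_p) and the same construction averaged
over uniform permutations — the positional construction is used because
the marginal distribution of δE values is permutation invariant and would
give W1 ≡ 0 identically.  W1 decreases monotonically with modulation
frequency at fixed N_p.

## Synthetic-data generators

Every analysis module is validated against generators with closed-form
ground truth: Brownian walkers (⟨Δr²⟩ = 6D0t, Gaussian G_s with W = 4D0t),
discrete worm-like chains (the tilted-exponential angle distribution is
inverted through the Langevin function so the sampled decay length equals
the requested ℓ_p exactly), exact-discretization Ornstein–Uhlenbeck stress
(known variance and correlation time; per-mode channel variances chosen so
the five-channel estimator returns a prescribed Maxwell G(t)), tanh
two-phase slabs, rectilinear-diameter binodals, and separated Gaussian
cluster fields.  These isolate single observables; they do not emulate
condensate physics, so passing them validates the estimators, not the
model.

## Problem sizes

The default test and benchmark runs use desk-scale systems — chains of
20–50 residues, 8–16 chains, boxes of 8–12 σ (slabs 45 σ), 10⁵-scale step
counts at Δt = 0.005 τ — chosen so the full pipeline (pattern → simulate →
analyze) runs in minutes on one CPU while preserving the qualitative
ordering effects (critical-temperature ordering with periodicity, low-q
structure-factor peaks, subdiffusion, periodic-vs-random viscosity
contrast).  Two desk-scale caveats: 50-residue chains are unentangled, so
the random-pattern MSD exponent in the cage window sits near 0.75 rather
than the deeply subdiffusive values long entangled chains show; and at
N_p = 50 the single-block P100 pattern forms micelles whose whole-droplet
diffusion masks arrest, so the arrest comparison pairs P25 (four sticker
domains per chain, the domain-count analog of a long blocky chain) with
its randomized counterpart.  Quantitative values at this scale are
finite-size- and finite-time-limited and are not comparable to
production-scale results;
the `production` preset (N_p = 200, L = 50 σ, slab 250 σ, Δt = 0.001 τ,
10⁸ steps) encodes the publication-scale study conditions.

## Known limitations

* No electrostatics, hydrodynamics, or amino-acid-specific chemistry —
  stickiness is the single axis, by design.
* The all-pairs neighbor build is O(N²) per rebuild; fine to ~10⁴ beads,
  not intended for production-scale boxes.
* Desk-scale Green–Kubo estimates are noisy at long lags; classifications
  near the fluid/solid boundary can flip with seed at small N.
* Percolating clusters receive no meaningful shape metrics (flagged
  instead).
* The Gaussianity verdict and the fluid/solid classifier are declared
  thresholds, not inferred statistics.
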