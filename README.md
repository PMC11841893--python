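# felas

**F**ree **E**nergy **La**ndscape of **S**tickers: a coarse-grained
sticker–spacer polymer simulator and analysis suite for biomolecular
condensates.

Low-complexity protein domains (LCDs) drive liquid–liquid phase separation
through weakly associating "sticker" residues separated by inert "spacers".
`felas` replaces the amino-acid alphabet with a single continuous axis: each
residue i carries a well depth δE_i ∈ [0, 1] (units of the LJ energy ε)
drawn from a sequence energy landscape, by default the periodic modulation

    ε_ii = sin²(2π i / k),          ε_ij = √(ε_ii ε_jj)

with well depths ≤ 0.1 set to zero (WCA-repulsive spacers).  Ordered
patterns P_k and their controlled-disorder variants (P_kA: stickers shuffled
among sticker sites; P_kB: alternating strong/weak stickers; R_k: fully
random) let you ask how sequence *patterning* — at fixed total interaction
energy — controls condensate thermodynamics, structure, dynamics and
viscoelasticity.

The package is aimed at polymer-physics and biophysics researchers who want
a self-contained, laptop-scale pipeline from sequence pattern to material
properties:

* **Langevin engine** — FENE bonds (k = 20 ε/σ², R0 = 1.5 σ), harmonic
  angles (θ0 = 150°), pair-specific force-shifted LJ/WCA, BAOAB integrator
  (dt = 0.001 τ, friction 0.1 m/τ by default), virial stress sampling,
  numba-compiled kernels.
* **Phase equilibrium** — slab density profiles, tanh interface fits, and
  critical-point extrapolation via rectilinear diameters with the Ising
  order-parameter scaling Δρ = Δρ0 (1 − T/T_c)^β, β = 0.325.
* **Structure** — S(q), g(r), contact maps, tangent correlations and
  persistence length, periodic-aware sticker clustering, gyration-tensor
  shape metrics (asphericity Δ, prolate/oblate parameter Ξ), percolation.
* **Dynamics** — multi-origin MSD ⟨Δr²⟩ = D t^α, self-van Hove G_s(r, t)
  with Gaussianity assessment, contact-time autocorrelation C(t).
* **Rheology** — Green–Kubo relaxation modulus from five stress channels
  (three off-diagonal + normal-stress differences at weight 1/6), multi-tau
  correlator, generalized Maxwell fits, G′(ω)/G″(ω), viscosity
  η = ∫G dt = Σ G_i τ_i, inverse loss tangent, Maxwell-fluid vs
  Kelvin–Voigt classification.
* **Sequence descriptors** — hydropathy-based λ profiles for real FASTA
  sequences, the correlation length ⟨κ⟩, the combined descriptor
  ⟨κ⟩·Σλ_i/λ_max/N_p, and Wasserstein-distance complexity W1.

## Worked example

Build a periodic pattern and its random counterpart, run short bulk
simulations, and compare their viscoelastic response:

```python
from felas.workflows import ExperimentConfig, workflow_rheology

cfg = ExperimentConfig.from_preset(
    "desk", n_residues=50, n_chains=16, box_edge=12.0,
    n_steps=120_000, relax_steps=4000, dt=0.005, stress_stride=4,
    traj_stride=200, temperature=0.7, seed=7)
cfg.variant, cfg.period_k = "P", 25      # periodic pattern P25
res_p = workflow_rheology(cfg, n_modes=8)
cfg.variant = "R"                        # random counterpart R25
res_r = workflow_rheology(cfg, n_modes=8)

for name, res in [("P25", res_p), ("R25", res_r)]:
    print(name, res["classification"], "eta=%.2f" % res["eta"].eta)
```

Output of this desk-scale run (800 beads, 600 τ at T = 0.7 ε/k_B):

```
P25 maxwell eta=14.84
R25 maxwell eta=0.71
```

i.e. at equal total interaction energy the periodically patterned chains,
whose stickers condense into long-lived sticky domains, are over an order
of magnitude more viscous than their randomized counterpart — the central
patterning effect the model isolates.  (Both systems still flow at this
small scale; arrest strengthens with chain length and sticker block size.)
Numbers vary with seed and scale; the publication-scale preset
(`ExperimentConfig.from_preset("production")`: 200-residue chains, 50 σ
boxes, 10⁸ steps) is provided for cluster hardware.

The same pipelines are scriptable from the shell:

```bash
felas landscape --variant P --period 25 --length 50 --out p25.json
felas simulate --config run.yaml --seed 1 --out run
felas rheology --stress run.stress.tsv --modes 12
```

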