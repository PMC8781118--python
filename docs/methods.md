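# Methods

## The model

`fcdg` determines the relative configuration of small organic molecules from
NMR data by *floating-chirality restrained distance geometry with
distance-bounds-driven dynamics* (fc-rDG/DDD), followed by Bayesian inference
over the resulting structure ensemble.

The molecule is described only by its constitution (bonding graph) plus one
reference 3D geometry of arbitrary configuration.  From these, holonomic
distance bounds are derived: bond lengths at the reference value ±1%, geminal
(1,3) distances ±2%, open-chain 1,4 distances spanning the syn–anti torsion
window computed in closed form from the reference internal coordinates,
ring-locked 1,4 distances ±5%, and all remaining pairs bounded below by
0.8 × the van-der-Waals radius sum and above by the bonded-path length.
Nonbonded lower bounds are additionally capped at 98% of the reference
distance so the input geometry is always feasible.  The bounds matrix is
triangle-smoothed: uppers contracted to all-pairs shortest paths, lowers
raised by the inverse triangle inequality, iterated to a fixpoint.

A candidate structure is scored by the dimensionless pseudo-energy

    E_total = E_dist + E_chir + E_NOE + E_RDC

with

* `E_dist` — flat-bottomed quadratic on bound violations,
  ½·K_dist·(d − nearest bound)², K_dist = 2.0 Å⁻²;
* `E_chir` — ½·K_chir·(V − V_target)² on signed chiral volumes
  (vector triple products), K_chir = 2.0 Å⁻⁶.  Chiral restraints are applied
  **only** to sp²-planarity elements (V_target = 0) and to the
  enantiomer-breaking reference element(s); every other stereogenic element
  floats, so all diastereomers and diastereotopic assignments are reachable;
* `E_NOE` — log-normal potential ½·K_NOE·ln²(d_exp/d_calc), with r⁻⁶
  averaging over proton groups.  Its curvature at d₀ is K_NOE/d₀², softer at
  long distances than a harmonic of equal K — matching how NOE uncertainty
  grows with distance.  Typical K_NOE = 25–250 (dimensionless);
* `E_RDC` — ½·K_RDC·Σ(D_exp − D_calc)² per alignment medium,
  K_RDC ≈ 0.1–2 Hz⁻².  Before every evaluation the Saupe alignment tensor of
  each medium is refit by linear least squares (5 parameters, ≥5 couplings
  required), so structures always satisfy the fit stationarity condition
  ∂E_RDC/∂S = 0.  Couplings are computed as D = D_max(r)·uᵀS u with
  D_max(r) = −(μ0/4π)·γiγj·ħ/(2π r³) and the instantaneous internuclear
  distance; methylene couplings may enter as unassigned sums of the two C–H
  couplings, methyl couplings as −1/3 of the C3-axis coupling (fast-rotation
  average) scaled by the mean C–H distance.

Coordinate gradients of all terms are analytic; the RDC gradient holds S at
its per-step optimum (the implicit dS/dr term vanishes by the envelope
condition).  In the 4D phase, bounds and NOE distances use the full
4-dimensional metric while chiral volumes and RDCs see the 3D projection —
this is what lets configurations invert without barriers.

## The sampling protocol

Each replicate: (1) *metrization* — pairwise distances fixed one by one in
random order, drawn uniformly within the current bounds, with exact-edge
triangle re-tightening after every choice; (2) embedding of the resulting
distance matrix into 4D by classical metric-matrix (Gram) decomposition,
negative eigenvalues clamped; (3) simulated annealing in 4D; (4) quasi-Newton
minimization; (5) compression of the 4th axis under a geometrically ramped
quadratic penalty, then truncation to 3D; (6) 3D annealing; (7) final
minimization, optionally followed by a small number of low-temperature
quench/minimize cycles that keep the best structure found (deeper relaxation
into the configurational family's energy floor).

The integrator is velocity Verlet with unit masses and a per-step
velocity-rescaling thermostat.  Temperatures are dimensionless kinetic scales
(β = 1 convention; the conventional "300 K" label of the hot phase maps to a
unit pseudo-temperature per degree of freedom).  The schedule label τ = 5 fs
maps to an internal dimensionless step dt = τ/100 = 0.05, which keeps the
integration stable for force constants of order 2.  Per-atom forces are
capped at 50 (dimensionless) — restraint gradients can be enormous for
freshly embedded structures, and capping preserves direction while preventing
integration blow-up.  Cooling ramps the target temperature linearly to zero.
All randomness derives from a master seed through `numpy` seed sequences;
ensembles are bit-reproducible.

Minimization uses limited-memory BFGS with a line search that enforces
monotone energy decrease across accepted steps, stopping at a gradient-norm
tolerance (default 10⁻⁶).

## Inference

With the uniform sampling prior P(θ) = 1/N_DG and the Boltzmann likelihood
P(D|θ) ∝ exp(−E_total(θ)), the posterior probability of configuration Θ
(its *diastereomeric differentiability*) is

    dd(Θ) = Σ_{θ∈Θ} exp(−E_total(θ)) / Z,   Z = Σ_all exp(−E_total),

computed with the ensemble minimum subtracted before exponentiation (exact in
the ratio; overflow guard).  Prior odds for M free binary elements are
1 : (2^M − 1); the Bayes factor is the posterior/prior odds ratio.  Two
further views of the same posterior are provided and agree by construction:
Metropolis Monte-Carlo resampling of the ensemble (uniform proposals,
acceptance min(1, e^{−ΔE}); chain-to-chain scatter gives the uncertainty) and
the stationary row-eigenvector of the Metropolis transition matrix, either
over structures or contracted onto configurational families (member rows
combined with their Boltzmann weights, which provably preserves the
family-level stationary distribution).  The AIC path (AIC = 2k + Σ ΔX²/σ²,
weight ratio e^{−ΔAIC/2}) is provided for comparison with static
model-selection workflows; its σ values are user inputs.

## Synthetic study systems

No experimental data ships with the package; two seeded templates emulate the
two analyte classes the method targets:

* **rigid** — 2,6,6-trimethylbicyclo[3.1.1]heptan-3-ol (C10H18O, 29 atoms):
  two free ring stereocenters, the correlated bridgehead pair fixed as the
  enantiomer-breaking reference, three tracked diastereotopic groups (two
  ring CH2, one gem-dimethyl) → 32 assignment keys.  11 one-bond CH RDCs per
  medium (4 methines, 4 individually assigned methylene protons, 3 methyls)
  in 1–4 media.
* **flexible** — an open-chain C13H28O2 diol with 4 stereocenters (one fixed
  → 8 diastereomers) and 13 RDCs in the 4 methine / 5 methylene-sum /
  4 methyl pattern, plus sparse NOE contacts (proton groups ≥3 bonds apart
  within 4.5 Å).

Reference geometries come from RDKit's ETKDG with a fixed seed.  Alignment
tensors are drawn randomly (symmetric traceless, principal order parameter
scaled so CH couplings fall within ±30 Hz).  Restraints are back-calculated
exactly from the ground-truth geometry plus optional Gaussian noise, so at
zero noise the truth configuration is a zero-energy witness.  What the
synthetic fixtures do **not** emulate: conformational averaging of real
flexible analytes, experimental error structure, incomplete or misassigned
data, and medium-dependent alignment correlations.  Passing tests therefore
demonstrate the correctness and internal consistency of the machinery at
desk scale, not field performance on real compounds.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script (the package
itself accepts arbitrary sizes): restraint-free prior ensembles use 1000
structures with 120+180 annealing steps per phase and 150 compression steps
(the prior distribution is set by the randomized embedding, so short
schedules suffice); data-restrained runs use 800–1500 steps per phase, two
quench cycles, and ensembles of 48–100 structures (pooled over seeds where a
mean posterior is wanted); dd uncertainties use 10³–10⁴ Metropolis chains.  Tie-breaks and degenerate inputs: rank-deficient tensor fits return
the minimum-norm solution with a warning; a tiny Tikhonov floor
(10⁻¹² × trace) keeps the per-step normal-equation solve finite for
degenerate geometries; near-planar stereo elements (|V| ≤ 10⁻⁶ Å³) raise an
ambiguous-classification error rather than guessing; internuclear distances
are floored at 0.5 Å inside the dipolar prefactor to survive transient
overlaps during hot dynamics.

## Known limitations

Quadrupolar couplings and chemical-shift-anisotropy restraints are not
implemented.  Absolute configurations are out of reach by construction (the
pseudo-energy is inversion-invariant; one reference element is pinned merely
to avoid double-counting enantiomeric mirror images).  The Q-factor is
reported as the plain normalized residual ratio by default with the
conventional square-root form behind a flag.  dd estimates from small
ensembles (≲100 structures) carry sampling noise of several percentage
points; the Metropolis chain scatter quantifies only the resampling part of
that uncertainty, not the structure-generation part.
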