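# fcdg — floating-chirality distance geometry with Bayesian stereo-assignment

`fcdg` assigns the relative configuration of small organic molecules from NMR
data — NOE-derived interproton distances and residual dipolar couplings
(RDCs, optionally from several alignment media).  Instead of scoring
pre-computed models of every diastereomer, molecular structures *evolve
directly from the data*: distance-geometry embedding plus
distance-bounds-driven dynamics (DDD) in four and three dimensions, with
chirality left floating so that all diastereomers and diastereotopic
assignments emerge within one simulation.  The only required input beyond the
restraint tables is the constitution with one 3D geometry of arbitrary
configuration.

The dimensionless restraint-violation pseudo-energy

    E_total = E_dist + E_chir + E_NOE + E_RDC

carries statistical meaning: with a uniform sampling prior, the Boltzmann
weight exp(−E_total) is the likelihood of the data given the structure, so
the posterior probability that the compound's configuration is Θ — its
*diastereomeric differentiability* — is

    dd(Θ) = Σ_{θ∈Θ} exp(−E_total(θ)) / Σ_all exp(−E_total).

The package computes dd three equivalent ways (direct Boltzmann summation,
Metropolis resampling with chain-scatter uncertainties, stationary vector of
the contracted Markov transition matrix), plus prior/posterior odds, Bayes
factors, and AIC weight ratios.  See `docs/methods.md` for the full model.

Intended users: NMR spectroscopists and computational chemists doing
configurational analysis of natural products and other small molecules with
two or more stereogenic elements.

## Worked example

Generate a self-contained synthetic analyte — a rigid bicyclic alcohol with
two free stereocenters and three tracked diastereotopic groups (32 possible
assignments) and zero-noise RDCs in three alignment media — then run the
pipeline:

```bash
fcdg simulate --template rigid --media 3 --seed 4 --out fixture/
fcdg run --mol fixture/molecule.mol --rdc fixture/rdc.tsv \
         --noe fixture/noe.tsv --out results/ \
         --n-structures 100 --k-rdc 2.0 --k-noe 150 \
         --hot-steps 1000 --cool-steps 1500 --seed 7 \
         --track 5,7,9 --fix 6,8
```

which prints:

```
wrote 100 structures, 8 configurational families to results
best family +++++: dd = 0.998
```

Reading: the data-driven annealing concentrated the 100 structures into 8 of
the 32 possible stereochemical assignments; the lowest-energy family is the
key `+++++` (one sign per free stereo element, in atom-index order) — the
configuration the restraints were generated from — and the Bayesian
posterior puts 99.8% of the probability on it.  Against the uniform prior of
1/32, that is posterior odds of ≈500 : 1 versus 1 : 31 prior odds, a Bayes
factor of ≈1.5·10⁴.  `results/`
contains the ensemble (`ensemble.sdf`, `energies.csv`), the family table
(`families.csv`), the energy-rank table with its step structure
(`energy_rank.csv`), the dd report (`dd.csv`, `dd.json`) and a `manifest.json`
from which the run can be reproduced exactly.

The same objects are available as a library:

```python
from fcdg import synthetic, moltop, dynamics, inference

fx = synthetic.make_fixture(synthetic.SyntheticSpec(template="rigid", seed=3))
bounds = moltop.build_bounds(fx.graph)
restraints, _ = synthetic.make_restraints(fx, np.random.default_rng(7))
records = dynamics.run_ensemble(fx.graph, bounds, restraints, 100,
                                dynamics.AnnealSchedule(5.0, 1000, 1500, 1.0),
                                seed=7, elements=fx.elements)
print(inference.boltzmann_dd(records).dd)
```

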