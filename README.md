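# cgmelt

Conformational Gaussian restraints for coarse-grained (CG) peptide models,
and melting-curve analysis of peptide–membrane binding.

`cgmelt` addresses a question from the biophysics of α-synuclein (αS): how
does the backbone conformation of the N-terminal membrane anchor
(αS residues 1–30) control its binding to lipid bilayers? The package
implements the two ingredients needed to study this with CG molecular
dynamics, for users who run such simulations or analyse their output:

1. **Conformational restraints.** An inverted-Gaussian well on each
   backbone bend angle θ and dihedral φ,

   V(x) = −K·exp(−(x − x_min)² / σ),  F = −dV/dx · dx/dr,

   with x in degrees, σ = 14 (width parameter as conventionally printed,
   dividing the squared-degree deviation) and well depth K in kJ/mol.
   Centering the wells at θ_min = 96°, φ_min = 60° pins a chain into the
   α-helical basin; θ_min = 124°, φ_min = 100° pins the extended-disordered
   ("tethered") state. Dihedral wells carry periodic images at
   φ_min ± 360° so the energy is continuous across the ±180° branch cut.
   Analytic Cartesian forces are provided for 3-bead bends and 4-bead
   dihedrals, and every restraint can be exported as a tabulated
   bonded-potential table (angle, V, −dV/dx) for use in a standard MD
   engine.

2. **Membrane-binding metrics.** Per-residue membrane *contact index*
   (fraction of frames in which a residue's backbone bead lies within
   1 nm, minimum-image, of any lipid phosphate bead), the *global contact
   index* (GCI, its mean over a sequence window), *melting curves* (GCI vs
   temperature over the 310–450 K ladder, with three-segment convergence
   errors), logistic *melting temperature* (Tm) fits, and the
   temperature-averaged GCI (*TAGCI*) for comparing deletion/mutation
   constructs with a fixed 15-residue window.

A toy internal-coordinate Metropolis sampler and a Brownian-dynamics
integrator validate the restraints statistically, and a synthetic-data
generator produces multi-temperature trajectories with known ground truth
(two-state Markov binding whose bound probability decays sigmoidally with
temperature) so the whole analysis stack can be verified end to end.

## Worked example

```python
import numpy as np
from cgmelt import (
    BindingModelParams, generate_campaign, contact_matrix,
    melting_curve, fit_melting_temperature, tagci,
)
from cgmelt.synthetic import DEFAULT_TEMPERATURE_LADDER

params = BindingModelParams(tm_true=380.0, steepness=10.0, seed=1)
campaign = generate_campaign(params, DEFAULT_TEMPERATURE_LADDER, n_frames=5000, seed=1)
mats = {t: contact_matrix(f, 1.0, t) for t, f in campaign.frames_by_temperature.items()}
curve = melting_curve(mats)
fit = fit_melting_temperature(curve)
print(f"GCI at 310 K: {curve.global_contact_index[0]:.3f}")
print(f"fitted Tm: {fit.tm:.1f} K (true {params.tm_true})")
print(f"TAGCI(WT): {tagci(mats, 'WT').value:.3f}")
```

prints

```
GCI at 310 K: 0.686
fitted Tm: 379.8 K (true 380.0)
TAGCI(WT): 0.458
```

The GCI plateau near 0.69 reflects the default extended-disordered
affinity profile, in which only the first ~7 residues bind at full
weight; the fitted Tm recovers the generator's true melting temperature
to a fraction of a kelvin at this sampling depth; and the TAGCI condenses
the 15-residue-window melting curve into one affinity score.

The same metrics run on real CG trajectories:

```sh
cgmelt --out-dir out melt \
    --structure sys.gro --trajectory sys310.xtc ... --temps 310,...,450 \
    --backbone-sel "name BB" --phosphate-sel "name PO4"
```

See `cgmelt --help` for the full set of subcommands
(`gen-restraints`, `simulate-toy`, `synth`, `analyze`, `melt`, `tagci`,
`run-all`).

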