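# liekit

Linear interaction energy (LIE) binding free-energy analysis for molecular
dynamics ensembles of enzyme–inhibitor complexes — from per-frame
interaction-energy series to calibrated binding free energies, correlation
reports, per-residue energy decompositions and trajectory geometry metrics.

It is written for computational chemists who run end-point binding
free-energy calculations: the reference use case is a set of triazole-linked
kojic-acid analogs inhibiting tyrosinase, a binuclear-copper metalloenzyme
of melanin biosynthesis, but every component works on any per-ligand table
of MD interaction energies.

## The model

For each ligand, two MD ensembles are sampled — the ligand **bound** in the
protein site and **free** in water — as several independent replicas. The
ligand-surrounding interaction energy of each frame is split into a van der
Waals and an electrostatic component, and the binding free energy is the
linear combination

```
ΔG_LIE = α (⟨U_vdW⟩_bound − ⟨U_vdW⟩_free) + β (⟨U_ele⟩_bound − ⟨U_ele⟩_free) + γ
```

with α = 0.181 (non-polar scaling), β assigned from the ligand chemistry
(0.50 if charged; 0.43 / 0.37 / 0.33 for 0 / 1 / ≥2 hydroxyls) or fixed
globally, and γ an offset calibrated by least squares against experimental
affinities:

```
ΔG_EXP = R T ln IC50 + c          (IC50 in mol/L; T = 300 K, c = 0 by default)
```

With the slope fixed at one, the least-squares γ is simply the mean of the
per-ligand residuals before offset. Uncertainties are replica-based: the
standard error of each ensemble average is the standard deviation of the
per-replica means over √n_replicas, propagated in quadrature.

The package also ships an exhaustive leave-k-out outlier search (refit γ on
every subset with up to k ligands removed, keep the subset with the best
Pearson r), per-residue decomposition tables with frame-wise closure checks,
Kabsch superposition / RMSD summaries for multi-MODEL PDB trajectories, and
a synthetic-data module that generates every input with known ground truth
(AR(1) energy series, datasets drawn from known LIE coefficients, closed
per-residue splits, toy trajectories).

## Worked example

The packaged reference tables (16 analogs with docking scores and IC50
values; 13 of them with the four ensemble averages from 5 × 2 ns replicas)
run end to end with:

```
liekit reproduce
```

which prints:

```
reproduction profile: alpha=0.181  beta=0.37  gamma=17.33  T=300K  c=0
ligand     dG_EXP  dG_EXP(ref)   dG_LIE  dG_LIE(ref)
6a          -8.07        -8.07    -8.06        -8.03
6b          -8.31        -8.31    -8.15        -8.13
6c          -8.46        -8.46    -8.44        -8.41
...
6o          -9.91        -9.91   -10.60       -10.56
6p          -8.95        -8.95    -9.90        -9.80
dG_LIE vs dG_EXP (printed columns): r=0.97
dG_LIE vs dG_EXP (recomputed):      r=0.77  r^2=0.59
docking score vs IC50 (16 analogs): r=-0.23
```

Reading the output: the `dG_EXP` column is recomputed from each IC50 at
T = 300 K and matches the reference values to ±0.01 kcal/mol; `dG_LIE`
applies the LIE equation with a global β = 0.37 to the tabulated averages
and reproduces 10 of the 13 reference predictions within 0.05 kcal/mol (the
weakest binder 6h and the charged-profile 6j belong to other polar classes,
so a single global β over-binds them — the recomputed r of 0.77 vs the
reference columns' 0.97 is entirely due to those rows). The docking score,
by contrast, does not rank potency at all (r = −0.23).

The same pipeline is available as a library:

```python
from liekit import LIEModel
from liekit.io import load_reference_dataset

model = LIEModel(load_reference_dataset(), beta=0.37)
result = model.fit(gamma=17.33)       # or model.fit() to refit gamma
print(result.summary())
print(result.correlation())
```

Other subcommands: `average`, `dg`, `fit-gamma`, `predict`, `correlate`,
`exclude`, `decompose`, `rmsd`, `distances` and `simulate` (synthetic
inputs); see `liekit --help`.

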