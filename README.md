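# fretmd

Tools for turning time-resolved FRET measurements on the cardiac troponin
complex into structural information: recovering inter-residue distance
distributions from TCSPC donor decays, converting measured distance tables
into MD-ready Cα–Cα distance restraints, and validating structural models
against the measurements.

## Who this is for

Cardiac troponin (cTnC·cTnI·cTnT) is the Ca²⁺ switch of the heart muscle thin
filament. Key regions of the complex — the cTnI N-terminal extension, the
inhibitory region, the mobile domain — are missing or unresolved in the
Ca²⁺-saturated crystal structure, and no high-resolution Ca²⁺-free structure
exists. Ensemble FRET between engineered labelling sites fills that gap: each
donor–acceptor pair yields a distance *distribution*, and those distributions
can restrain molecular-dynamics refinement toward the solution conformation in
each Ca²⁺ state. This package implements that computational chain for anyone
doing FRET-restrained modelling of large complexes.

## The model

A donor quenched by an acceptor at distance *r* decays with every rate
multiplied by the Förster factor:

    I_DA(t; r) = Σᵢ α_Di · exp[ −(t/τ_Di) · (1 + (R₀/r)⁶) ]

where (α_Di, τ_Di) describe the multi-exponential donor-only decay and R₀ is
the Förster critical distance (transfer efficiency E = 1/(1+(r/R₀)⁶) = 0.5 at
r = R₀). For an ensemble of pairs with Gaussian distance distribution P(r)
(mean r̄, half-width HW = 2.35 σ) the observed decay is

    I_DA(t) = ∫ P(r) · I_DA(t; r) dr .

`fretmd` fits (r̄, HW) to a measured donor–acceptor decay by weighted least
squares with the donor parameters frozen at their donor-only values, judging
fits by the reduced χ². Each recovered distance then becomes a flat-bottom
Cα–Cα restraint with lower bound r̄ and upper bound r̄ + 7 Å (the probe linker
folds randomly, contributing up to ~7 Å), and stiffness k = k_BT/σ² from the
measured half-width. Validation metrics include the TnC N-domain pocket
openness (the residue 13–51 Cα distance), ±10 % FRET/model agreement reports,
geometric hydrogen bonds, helix assignment from the i→i+4 backbone H-bond
pattern, helix-axis angles, Kabsch RMSD, and per-residue RMSF.

## Worked example

Simulate a matched decay pair with known ground truth (r̄ = 48.1 Å,
HW = 10.2 Å, R₀ = 40 Å — the measured cTnI-131/cTnT-240 pair in the
Ca²⁺-saturated state), refit it, and build restraints:

```sh
$ fretmd simulate --counts 1e6 --seed 11 --out donor.txt
wrote donor-only decay, 998042 counts -> donor.txt

$ fretmd simulate --rbar 48.1 --hw 10.2 --r0 40 --counts 1e6 --seed 12 --out da.txt
wrote DA decay (rbar=48.1, hw=10.2, R0=40.0), 999765 counts -> da.txt

$ fretmd fit-decay --donor donor.txt --da da.txt --r0 40 --components 1 --out fit.tsv
rbar = 48.19 Å, hw = 10.78 Å, chi2_red = 1.078

$ fretmd build-restraints --state ca_saturated --out disre.itp
45 restraints (ca_saturated, paper-default) -> disre.itp
```

The fit recovers the generating parameters within their statistical
uncertainty (r̄ to 0.1 Å, HW to 0.6 Å here) with a reduced χ² near 1,
indicating the Gaussian-distribution model fully describes the decay. The
restraint file is GROMACS `[ distance_restraints ]` dialect, distances in nm:

```
[ distance_restraints ]
;  ai   aj type index type' low up1 up2 kfac ; label site_i site_j
   13    19 1    0 1 4.81 5.51 5.71 13.24008562 ; cTnI131-cTnT240/ca_saturated ...
```

i.e. the measured 48.1 Å becomes a flat bottom of 4.81–5.51 nm, and the
10.2 Å half-width a stiffness of 13.2 kJ mol⁻¹ nm⁻², so broad (dynamic)
distance distributions restrain weakly and narrow ones strongly. The packaged
table holds the 45 measured pairs per Ca²⁺ state; `fretmd run --config
config.toml` drives the whole chain (fits → table → restraints → structure
validation) deterministically with a config hash stamped into the outputs.

Other subcommands: `fretmd pocket --pdb model.pdb` (open/closed call on the
TnC N-domain from the 13–51 distance), `fretmd analyze-structure` (per-pair
FRET agreement report), `fretmd rmsf` (per-residue fluctuations over a
multi-model PDB trajectory), `fretmd fixtures` (write packaged tables and toy
structures).

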