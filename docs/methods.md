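# Methods

## Scope

`fretmd` covers the desk-scale computational chain around FRET-restrained
modelling of the cardiac troponin complex: the decay forward model and its
inversion, restraint generation, and structure/trajectory validation metrics.
It deliberately stops at emitting restraint files and scoring supplied
structures — docking, energy minimisation, simulated annealing and the MD
simulations themselves belong to external engines (GROMACS et al.) and are
out of scope, as are anisotropy/κ² distribution modelling, acceptor-emission
kinetics and maximum-entropy P(r) recovery.

## Decay model and its assumptions

The donor-only decay is multi-exponential (1–3 components) with an additive
baseline for dark counts. A donor–acceptor pair at distance r decays with all
rates multiplied by 1 + (R₀/r)⁶; the ensemble decay integrates this over a
Gaussian P(r) with mean r̄ and half-width HW = 2.35 σ. Assumptions worth
stating explicitly:

- **Static distances on the fluorescence timescale.** Each molecule keeps its
  distance during the donor's excited-state lifetime; the distribution
  reflects ensemble heterogeneity, not intra-lifetime diffusion.
- **Isotropic orientational averaging**: κ² = 2/3 in the Förster radius. This
  is the dominant systematic in any FRET distance and the reason measured
  distances carry a ±10 % uncertainty.
- **HW/σ conversion uses 2.35**, the value conventional in the distance-
  distribution literature, not the exact 2√(2 ln 2) ≈ 2.3548 (0.2 % apart,
  far below measurement uncertainty). The constant is `HW_PER_SIGMA`.
- **Instrument response**: optional discrete convolution with a supplied IRF
  curve, off by default; the fit window (below) excludes the rise region
  instead.

## Quadrature

The P(r) integral runs on a 201-point Simpson grid over r̄ ± 5 σ, truncated
at r > 0, with P renormalised on the grid. The Gaussian mass outside ±5 σ is
< 6 × 10⁻⁷, and truncation plus renormalisation is the physically sensible
treatment of the unphysical r ≤ 0 region for broad distributions. The
delta-distribution limit (HW → 0) reproduces the fixed-distance decay to
< 10⁻⁶ relative, and the quadrature agrees with Monte-Carlo averaging over
10⁶ Gaussian draws within Monte-Carlo error (tested).

## Fitting

- **Window**: channels after the counts maximum through the last channel with
  ≥ 10 counts (falls back to all positive channels for noise-free curves).
  This avoids the rise/IRF region the tail model does not describe.
- **Donor fits** minimise Poisson-weighted residuals with Neyman weights
  1/max(counts, 1), the standard TCSPC choice; lifetimes are reported sorted
  ascending, and near-coincident lifetimes or negligible amplitudes set an
  over-parameterisation warning.
- **Distance-distribution fits** freeze the donor parameters (measured
  donor-only under identical conditions — refitting them against the DA decay
  is degenerate with the distribution parameters), and minimise over (r̄, HW)
  with the overall scale and baseline profiled out linearly at each step
  (variable projection). Weights here are **model-based** (Pearson,
  1/max(model, 1)): calibration showed observation-based weights over-weight
  downward-fluctuating low-count tail channels and bias the recovered HW low
  by ≈ 1 Å at 10⁶ counts — and the tail is exactly where the half-width
  information lives. With model-based weights the residual bias is ≈ +0.5 Å,
  inside the statistical scatter.
- **Initialisation**: r̄₀ from a mean-arrival-time efficiency estimate
  (donor reference moment computed over the same truncated window, so window
  truncation cancels), HW₀ = 10 Å; multi-start over r̄₀·{0.8, 1.0, 1.2} when
  the first fit converges poorly (reduced χ² > 1.5).
- **No-transfer guard**: an apparent efficiency below 2 % means the DA decay
  is indistinguishable from donor-only and no distance is determinable; the
  fit refuses rather than returning an arbitrary large distance. At 10⁶
  counts this genuinely bites for r̄ ≈ 75 Å with R₀ = 40 Å (true efficiency
  ≈ 2.3 %), the stated edge of that probe pair's usable range.
- **Goodness of fit**: reduced χ² = Σ (obs − model)²/max(model, 1) / (N − p),
  expectation 1 for a correct model; calibrated to 1.00 within 0.05 across
  seeds and regimes in the acceptance study.
- **Uncertainties** for (r̄, HW) come from the Gauss–Newton covariance of the
  profiled two-parameter problem scaled by the reduced χ²; they ignore the
  (small) derivative of the profiled scale/baseline and are meant as error
  indicators, not rigorous confidence intervals.

## Restraint generation

Each table row (r̄, HW) becomes one flat-bottom Cα–Cα restraint:

- **Bounds**: default scheme `[r̄, r̄ + 7 Å]`. The probe linker is ~10 Å long
  but folds randomly, contributing an effective ~7 Å; placing the measured
  distance at the lower bound and +7 Å at the upper bound was the variant
  that reproduced the experimentally known pocket behaviour during modelling
  trials, so it is the default. `symmetric` ([r̄−7, r̄+7]) and `point`
  ([r̄, r̄]) schemes remain selectable.
- **Second upper bound**: the GROMACS dialect needs an up2 where the penalty
  turns linear; up2 = up1 + 2 Å. No physical content beyond "do not let the
  quadratic region grow unbounded".
- **Stiffness**: the measured half-width maps to a Boltzmann-consistent
  harmonic width, k = k_B T/σ² with σ = HW/2.35 in nm (T = 300 K default).
  The original bond-energy mapping was never published as a formula; this is
  the most defensible reading (a harmonic restraint whose thermal width
  equals the measured width) and the mapping is a single pluggable function
  (`force_constant_from_hw`).
- The two literature distances per state (TnC 13–51, TnI 5–192) ship in a
  separate table with a nominal HW of 10 Å since their half-widths were not
  printed; they are not part of the 45-pair count.

## Structure metrics

- **Site maps** translate (subunit, residue) labels into (chain, author
  residue number, Cα) per crystallographic copy; deposited entries with
  several copies are scanned copy by copy since publications rarely state
  which copy a distance was measured on.
- **Pocket openness**: the TnC N-domain open/closed call uses the 13–51 Cα
  distance with a 24 Å default threshold — the midpoint of the closed
  (19.21 Å) and open (29.06 Å) skeletal-troponin crystal anchors; the
  boundary counts as open. Configurable.
- **Hydrogen bonds**: geometric criteria, heavy-atom D···A ≤ 3.5 Å and
  D–H···A ≥ 120° with the amide H inferred from backbone geometry when no
  explicit hydrogen is present (Ligplot-like defaults); a donor-angle proxy
  (antecedent–D···A ≥ 90°) covers donors whose H cannot be placed. Same-
  residue and sequence-adjacent pairs are excluded.
- **Helix assignment**: a backbone H-bond O(i)→N(i+4) marks residues
  i+1…i+4 helical; runs ≥ 4 residues become segments; chain breaks (Cα gap
  > 4.5 Å or numbering gap) split segments. This is the helix-only core of
  pattern-based secondary-structure assignment; the full 8-state DSSP
  alphabet is out of scope.
- **Helix axes** are first principal components of the segment's Cα
  coordinates, oriented along the chain direction so antiparallel helices
  read near 180°; segments need ≥ 5 Cα atoms.
- **RMSD** uses the closed-form Kabsch rotation (SVD with determinant
  correction); an independent quaternion-method oracle cross-checks it in the
  tests. **RMSF** is √⟨|x−⟨x⟩|²⟩ per atom over post-equilibration frames,
  reported per residue on Cα, with optional Kabsch pre-alignment.
- **FRET agreement**: a model distance agrees with a measured r̄ when
  |d − r̄| ≤ 0.10·r̄ + 7 Å (the ±10 % FRET uncertainty plus the linker
  allowance).

## Synthetic data: what it emulates and what it does not

The generators produce every input with known ground truth: Poisson-noise
TCSPC decay pairs on 1024 channels of 0.055 ns (≥ 5 lifetimes of an
AEDANS-like 11 ns donor), toy structures with exact backbone geometry (ideal
α-helix at φ = −57°, ψ = −47°: 1.5 Å rise, 100° twist, 3.8 Å Cα spacing;
extended chains; two-domain dumbbells with exactly prescribed inter-site
distances), and trajectories with prescribed per-residue isotropic Gaussian
jitter. Photon noise is pure Poisson per channel — no afterpulsing, pile-up
or IRF broadening — which matches the fitting model's assumptions. Passing
the closed-loop tests therefore demonstrates the estimator is consistent and
calibrated under its own model; it does not certify robustness against
instrument artefacts, dye photophysics beyond Förster quenching, or real
conformational dynamics, and the jitter trajectories probe the metric
implementations, not protein mechanics.

## Problem sizes in the validation suite

The closed-loop recovery study runs 18 regimes (r̄ 20–30 Å at R₀ = 29 Å and
30–75 Å at R₀ = 40 Å, matching each probe pair's usable range, × HW ∈ {3, 10,
20} Å) × 50 seeds at 10⁶ counts; Monte-Carlo quadrature checks use 10⁶ draws
(headline) and 2 × 10⁵ (randomised triples); RMSF recovery uses 2000 frames.
These sizes put Monte-Carlo error comfortably below the tested tolerances
while keeping the default suite quick to run.

## Known limitations

- Gaussian P(r) only; multimodal or heavy-tailed distance distributions fold
  into an inflated HW.
- The no-transfer guard and the upper end of recovery accuracy are set by
  photon statistics; distances beyond ~1.8 R₀ are effectively one-sided.
- Inferred amide hydrogens assume standard backbone geometry; side-chain
  donors rely on the weaker angle proxy.
- The restraint stiffness mapping is one defensible convention among several;
  anyone comparing against differently generated restraint sets should check
  k conventions first.
- Multi-copy handling reports per-copy values; it does not attempt to decide
  which copy a published number came from.
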