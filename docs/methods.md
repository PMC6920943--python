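# Methods

This note documents the models, conventions and numerical choices behind
`surfdyn`, and what the synthetic-data tests do and do not demonstrate.

## Data model and units

Coordinates and radii are in Ångström, times in nanoseconds, masses in
Dalton; atom indices are 0-based internally and PDB serials are treated as
labels only. A `MolecularSystem` partitions atoms into residues keyed by
`chain:resid` (insertion codes are rejected to keep keys unambiguous;
alternate locations collapse to the first). Van der Waals radii are
assigned per element from a Bondi-style table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, P 1.80 Å), overridable from a two-column text file; the
radius set changes absolute SASA, which is why the pipeline reports
*relative* SASA wherever a threshold is applied. Hydrogens are used when
the input contains them and can be ignored with a flag.

## SASA engine

Shrake–Rupley with a golden-section spiral quadrature: `n_points`
(default 960) near-uniform points of weight `1/n` on each atom's
probe-expanded sphere (`probe_radius` default 1.4 Å, the conventional water
probe). A point is buried if it lies inside any *masked* neighbour's
expanded sphere; atoms outside the mask neither receive SASA nor occlude.
That masking rule is what defines the two detection protocols on identical
coordinates (partner present vs. partner removed). Neighbour candidates
come from a KD-tree on the first frame, inflated by each atom's maximum
displacement over the trajectory, and are re-filtered per frame by the
exact distance test; an optional numba kernel accelerates the per-frame
loop and the pure-numpy fallback is bit-identical in results. Quadrature
accuracy at 960 points: exact for an isolated sphere, and within ~0.5 % of
the spherical-cap closed form for two-sphere systems (the analytic oracle
in the test suite).

Relative SASA divides residue SASA by the maximum a fully exposed residue
of that type would have. For proteins the default maxima are the
theoretical Gly-X-Gly values of Tien et al. (2013); for the synthetic bead
residues the generator computes each type's maximum from one isolated
residue cluster with the same engine, keeping numerator and denominator on
one scale. Values above 100 % (distorted conformers) are reported, not
clipped, with a warning.

## Detection protocols

Both protocols operate per replicate on the equilibrated window, then
combine replicates with a delete-one jack-knife; for the plain mean the
jack-knife SEM reduces exactly to `s/√n`, which the tests assert to 1e-10.

* **Interfacial**: Δ = relative SASA (partner occluding) − relative SASA
  (partner excluded) on identical coordinates. Reference condition for the
  20 % burial filter: the partner-excluded complex.
* **Allosteric**: Δ = partner-excluded relative SASA in the complex −
  relative SASA in the unbound ensemble; the SEM of Δ is propagated in
  quadrature from the two independent ensembles. Burial filter on the
  unbound condition. Because the partner is excluded from both SASA
  computations, contact occlusion cannot leak into this report.

Reporting rule: |Δ| > `delta_min` (default 5 percentage points, strictly)
and SEM(Δ) < |Δ|. The burial boundary keeps residues at exactly 20 %.
Differences are formed after averaging within a replicate (replicate-level
comparison), which is identical in expectation to per-frame differencing
and matches how replicate means are compared; the SEM then reflects
replicate-to-replicate scatter only.

## Equilibration

RMSD uses a Kabsch superposition (SVD with the determinant sign
correction, so reflections are never returned) computed on the same atom
selection that is measured — the least surprising choice when the fitting
group is not otherwise specified. COM separation defaults to mass
weighting, with a geometric option. The window rule declares the longest
trailing window stationary when every monitored series has |linear-fit
slope| ≤ `slope_tol` (0.02 Å/ns) and max–min spread within every sliding
sub-window (length `max(10, n/20)` frames) ≤ `spread_tol` (1.5 Å), and the
window spans at least `min_tail_fraction` (0.2) of the trajectory;
otherwise the result is flagged, not raised. The rule is deterministic and
monotone: loosening either tolerance can only grow the window. Windows may
always be set explicitly per replicate to reproduce by-inspection choices.

## Correlation and PCA

Frames from all replicates' windows are pooled after superposition onto a
single reference. The analysis mask (e.g. one Cα per residue, or a
selection excluding a flexible tail) controls which atoms enter the
matrices; a separate `fit_mask` controls which atoms the rigid-body fit is
computed on. Fitting on a quasi-static core is recommended whenever large
collective motions are present: a fit over the moving atoms themselves
absorbs part of the collective displacement into the rigid-body parameters
and systematically biases the planted correlations (with ~20 % of atoms
mobile the recovered value can drop from 0.9 to ≈0.75). With a static-core
fit the planted ±0.9 block correlations are recovered within ±0.04 at
8 000 pooled frames.

The covariance uses 3-vector dot products of mean-free displacements; the
DCCM is its Pearson normalisation with the diagonal pinned to exactly 1
and entries clipped to [−1, 1] against rounding. Eigendecomposition uses
the symmetric solver after a symmetry check at 1e-8 relative tolerance;
eigenvalues are reported in non-increasing order. PCA properties asserted
by the tests: variance fractions sum to 1, projection variances equal the
eigenvalues, per-residue contributions sum to 1 per component, and the
eigenvalue sum equals the total centered variance (trace conservation).
PC1 extreme-structure interpolation reconstructs `mean + α·v₁` for α
linearly spaced between the minimum and maximum observed projections.

## Synthetic generator

The generator reproduces the statistical structure the analyses assume and
nothing else — no force field, no solvent, no thermostat.

* **Geometry.** Each residue is a rigid cluster of four carbon-like beads
  (radius 1.70 Å): a central "CA" bead and three satellites at 2.2 Å,
  tilted 45° outward. Residues occupy three layers: a surface shell on a
  spherical Fibonacci spiral with ~7.5 Å neighbour spacing, an inner layer
  at half the shell radius with satellites pointing inward, and a tightly
  packed core whose relative SASA is driven below the 20 % burial line by
  the surrounding inner layer. The backbone (CA trace) is checked for
  self-avoidance; satellite beads of neighbouring buried residues may pack
  at bonded-like distances, which is precisely what buries the core.
* **Interfacial planting.** A rigid seven-bead cap hovers over each
  planted residue along its outward normal; the hover height is lowered
  stepwise until the planted residues each lose ≥10 percentage points of
  relative SASA (twice the detection threshold) while the cap's locality
  keeps the occlusion of every other residue at zero to well below
  threshold. Failure to reach the target is an error, not a silent
  degradation. With no planted residues the cap is placed three shell
  radii away — the null/far-partner configuration.
* **Allosteric planting.** Bound-state-only: the planted residue's
  satellites are scaled about its CA (collapse buries, expansion exposes)
  and the scale is calibrated by bisection against the SASA engine until
  the partner-excluded relative-SASA change matches the signed target
  within 0.5 pp. Calibration is geometric and nonlinear, hence iterative
  rather than closed-form.
* **Dynamics.** Only domain blocks named in the plan (or `moving_blocks`)
  move: rigid translations along a fixed unit direction, driven per frame
  by jointly Gaussian latent scalars with the planted correlation matrix
  (validated positive semidefinite), amplitude 1.0 Å, plus isotropic
  Gaussian noise (default σ = 0.1 Å) on every atom. Blocks linked by a
  plan entry share one direction so the latent correlation is exactly what
  the DCCM should recover; expected attenuation is `A²/(A² + 3σ²)` ≈ 0.97
  at the defaults. Frames are temporally uncorrelated — adequate for
  covariance and SASA averages, unrealistic for autocorrelation analyses.
* **Determinism.** Replicate streams derive from
  `numpy.random.SeedSequence([seed, stream, replicate])` (stream 0
  unbound, 1 bound); identical specs give bit-identical ensembles on any
  platform.

**What passing tests show — and don't.** Recovery of planted effects shows
the protocols are implemented correctly and are well-calibrated at effect
sizes twice their thresholds under isotropic noise. Real trajectories add
slow autocorrelated motions, anisotropic flexibility, rotamer dynamics and
force-field idiosyncrasies; a perfect score here does not guarantee
sensitivity or specificity at marginal effect sizes in real data.

## Problem sizes used in verification

The default synthetic study is a 30-residue receptor (18 shell, 9 inner, 3
core; 120–134 atoms), 4 replicates × 2000 frames. Detector
precision/recall is measured at that full scale; the 20-repeat null
control uses 3 replicates × 300 frames per repeat, which is ample for a
rule whose false positives require a 5-point mean excursion against a
sub-0.3-point SEM. DCCM recovery uses 4 × 2000 frames; PCA capture
2 × 2000. These sizes were chosen so the complete verification suite runs
in minutes on a single CPU while keeping every statistical margin wide.

## Known limitations

* The SASA engine is quadrature-based; it is not an analytic
  (power-diagram) surface. Errors are sub-percent at 960 points and
  strictly controlled by the two-sphere oracle, but absolute SASA depends
  on the radius table — use relative quantities across conditions, as the
  pipeline does.
* Window detection assumes series that become stationary; slowly drifting
  series yield a flagged (not raised) result and downstream code requires
  explicit windows in that case.
* The selection language covers names, chains, residue ranges and boolean
  algebra only — no distance-based or element selections.
* Compressed/binary trajectory formats (XTC, DCD) are out of scope; the
  interchange formats are multi-model PDB and the tabular XYZ dialect.
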