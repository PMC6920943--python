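# surfdyn

Ensemble analysis of molecular-dynamics trajectories of a receptor and its
binding partners: equilibration assessment, solvent-accessible-surface-area
(SASA) mapping of interfacial and allosterically modulated residues,
dynamical cross-correlation matrices (DCCM), and Cartesian principal
component analysis — plus a synthetic-trajectory generator with planted
ground truth so that every stage of the pipeline is verifiable without any
MD data.

## Who this is for

Simulation studies of antibody-receptor complexes (the motivating case is
the multi-domain extracellular region of a receptor bound by antibody
fragments) routinely ask three questions of a set of replicate
trajectories:

1. **Where is the binding interface?** A residue is *interfacial* when the
   physical presence of the partner occludes it: its SASA computed **with**
   the partner atoms present differs from its SASA computed on the *same
   coordinates* with the partner removed from the calculation.
2. **What does binding change at a distance?** A residue is
   *allosterically modulated* when its partner-**excluded** SASA differs
   between the bound and the unbound ensembles — a conformational effect,
   not a contact effect.
3. **How do the domains move together?** Correlated inter-domain motions
   are summarised by the DCCM and by the leading principal components of
   the Cartesian coordinate covariance.

`surfdyn` implements this workflow as a library with a thin command-line
interface, on plain-text formats only (multi-model PDB and a tabular XYZ
dialect), and ships a generator that fabricates replicate ensembles in
which the answers to all three questions are planted and known.

## The statistics, briefly

**SASA.** Shrake-Rupley: each atom's probe-expanded sphere of radius
`r_i + r_probe` (probe 1.4 Å) is sampled with a deterministic golden-section
spiral of `n = 960` points; the accessible fraction times `4π(r_i + r_probe)²`
is the atom's SASA. Residue SASA is converted to *relative* SASA — percent
of the maximum a fully exposed residue of that type would have — and
residues below 20 % relative exposure in the reference condition are
discarded as internalised.

**Detection rule.** For each residue the relative-SASA difference Δ between
condition and reference is averaged per replicate and combined across
replicates with a delete-one jack-knife
(`SEM = sqrt((n−1)/n · Σ(θ₍ᵢ₎ − θ̄)²)`, which equals `s/√n` for the mean).
A residue is reported when |Δ| > 5 percentage points **and** SEM(Δ) < |Δ|.
For the bound-vs-unbound comparison the SEMs of the two independent
ensembles propagate in quadrature.

**DCCM.** After superposing every equilibrated frame of every replicate on
one reference (Kabsch) and removing per-atom means,

    C_ij = ⟨Δr_i · Δr_j⟩ ,   DCCM_ij = C_ij / √(C_ii C_jj) ∈ [−1, 1],

computed on one Cα per residue. **PCA** eigendecomposes the full 3N × 3N
coordinate covariance `C = T Λ Tᵀ`: eigenvectors are collective motions,
eigenvalues their mean-square amplitudes, and a residue's contribution to a
component is the summed squared eigenvector weight on its coordinates. A
trajectory interpolating between the two most dissimilar structures along
PC1 can be exported for inspection.

**Equilibration.** Per-replicate RMSD (Cα, Kabsch-fitted on the same
selection) and centre-of-mass separation series feed a reproducible window
rule: the longest trailing window in which every series has |linear slope|
≤ 0.02 Å/ns and sliding-window spread ≤ 1.5 Å. Windows can always be set
explicitly instead.

## Worked example

Generate a bound/unbound synthetic study (30-residue toy receptor, two
planted interfacial residues, two planted allosteric residues at ±10
percentage points, two domains moving with correlation +0.9, 4 replicates
× 500 frames) and run both detectors and the correlation analyses:

```python
from surfdyn import *
from surfdyn.synthetic import max_sasa_table

spec = SyntheticSpec(n_frames=500, n_replicates=4, seed=11)
bound = simulate_bound_ensemble(spec)
unbound = simulate_unbound_ensemble(spec)
table = max_sasa_table(spec)
part = partition_complex(bound.system, ["B"])

interface = detect_interfacial(bound, part, max_table=table)
print(interface[["residue_key", "delta", "sem", "direction"]].round(2))

allostery = detect_allosteric(bound, unbound, part, max_table=table)
print(allostery[["residue_key", "delta", "sem", "direction"]].round(2))

cam = ca_mask(unbound.system)
m = dccm(center_ensemble(unbound, mask=cam,
         fit_mask=select(unbound.system, "resid 19-30").intersection(cam)))
print("mean D1-D2 correlation:", round(m.matrix[:6, 12:18].mean(), 2))
```

Output:

```
  residue_key  delta   sem direction
0         A:9 -27.33  0.01  occluded
1        A:10 -27.31  0.02  occluded
  residue_key  delta   sem direction
0         A:7 -10.35  0.05  occluded
1        A:12   9.75  0.10   exposed
mean D1-D2 correlation: 0.86
```

The interfacial report contains exactly the two planted residues (keys
`A:9`, `A:10`; the partner cap hides ~27 points of their relative SASA,
with jack-knife SEM far below the difference). The allosteric report
recovers the planted ±10-point conformational changes with the correct
signs, and the planted inter-domain correlation of +0.9 appears as a mean
DCCM block value of 0.86 (attenuated slightly by positional noise).

The same analysis runs from the shell:

```sh
surfdyn simulate --spec demo.toml --out sim/
surfdyn sasa-interface --bound sim/bound_rep0.pdb --bound sim/bound_rep1.pdb \
        --max-table sim/max_sasa.tsv --out interface.tsv
surfdyn run --config run.toml --out results/
```

`surfdyn run` executes the whole pipeline (windows → interface → allostery
→ DCCM → PCA) from one TOML config and writes a manifest recording the
software version, every defaulted parameter and the hash of every output.

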