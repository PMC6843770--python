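# heatdyn

Correlation, essential-dynamics and hydrogen-bond analysis of
conformational ensembles of large multi-domain protein/RNA assemblies —
the kind of comparative trajectory analysis used to contrast wild-type
and mutant spliceosome models, where the interesting signal is not a
single structure but how named components (HEAT repeats of an
SF3B1/Hsh155-like solenoid, Prp8-like domains, RNA filaments) move
relative to one another.

## What it computes

Given an ensemble of frames over a fixed atom table (multi-model PDB,
GRO, or topology + DCD), the package selects one analysis bead per
residue (Cα for amino acids, P for nucleotides), removes global
rotation/translation by a least-squares (Kabsch) fit to a reference
frame, and estimates a Gaussian fluctuation model over an analysis
window:

- **Fluctuation profiles** — per-bead RMSF about the window mean, per-
  frame RMSD to the reference, radius of gyration, with per-component
  aggregation.
- **Dynamical cross-correlation matrix (DCCM)** — from the
  mass-weighted positional covariance C (3N × 3N, entries
  √(mᵢmⱼ)⟨Δrᵢα Δrⱼβ⟩), the per-bead Pearson coefficient

      CC_ij = ⟨Δr_i · Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)  ∈ [−1, 1],

  +1 for lockstep motion, −1 for anti-correlated motion (masses cancel).
- **Correlation scores (CS)** — the DCCM coarsened to component pairs,
  CS(A,B) = Σ_{i∈A, j∈B} CC_ij / (|A|·|B|), a correlation density with
  no cutoff applied on the CC values entering the sum.
- **Essential dynamics** — eigenmodes of the covariance, cumulative
  variance against the full spectrum, per-frame projections, and
  NMWiz-compatible NMD export for drawing mode arrows.
- **Switch regions** — the pivots of accordion-like inter-domain
  motions: contiguous residues where the correlation against a probe
  component flips sign while the first principal mode carries almost
  no displacement.
- **Hydrogen-bond occupancies** — fraction of window frames in which a
  donor–acceptor pair satisfies d(D,A) ≤ 3.3 Å and D–H···A ≥ 145°
  (both configurable; distance-only mode available), plus cross-model
  occupancy delta tables.

Because production trajectories of such assemblies are rarely
deposited, the package ships first-class synthetic generators with
planted ground truth — block-correlated Gaussian ensembles,
two-rigid-segment hinge motions with an immobile pivot, and
donor–H–acceptor geometry series with prescribed occupancy — so every
stage of the pipeline can be validated end to end.

## Worked example

A 60-bead hinge ensemble (two rigid 30-bead arms opening and closing
about residue 31 by ±20°) analysed with the model interface:

```python
from heatdyn import synthetic as syn
from heatdyn.io import ComponentMap
from heatdyn.model import EnsembleDynamics

spec = syn.HingeSpec(segment_lengths=(30, 30), opening_amplitude=20.0,
                     n_frames=5000, seed=7)
ensemble, pivot = syn.make_hinge_ensemble(spec)
cmap = ComponentMap.from_entries([("N-arm", "A", 1, 30),
                                  ("C-arm", "A", 31, 60)])
results = EnsembleDynamics(ensemble, component_map=cmap).fit(n_modes=5)
print(results.summary())
for region in results.switch_regions("N-arm"):
    print(f"switch region: chain {region.chain_id} residues "
          f"{region.residue_start}-{region.residue_end} "
          f"(flip {region.flip_magnitude:.2f})")
```

prints

```
Ensemble dynamics fit
====================================================
frames (window):        5000 [0, 5000)
beads:                  60
superposition:          kabsch (uniform weights)
covariance weighting:   mass
mean RMSD to reference: 9.164 A
mean RMSF:              7.016 A
covariance trace:       4.551e+04

Principal modes
----------------------------------------------------
  PC1   eigenvalue    4.549e+04   cumulative variance  0.999
  PC2   eigenvalue        25.79   cumulative variance  1.000
  PC3   eigenvalue     0.001112   cumulative variance  1.000
  PC4   eigenvalue    2.728e-12   cumulative variance  1.000
  PC5   eigenvalue    2.112e-12   cumulative variance  1.000

Correlation scores (component pairs)
----------------------------------------------------
       N-arm  C-arm
N-arm  0.901 -0.802
C-arm -0.802  0.790

switch region: chain A residues 26-37 (flip 1.05)
```

Reading it: the two arms are strongly anti-correlated
(CS(N-arm, C-arm) = −0.80), a single principal mode carries
essentially all the variance (the opening motion), and the detected
switch region (residues 26–37) contains the planted pivot at
residue 31.

The same pipeline runs from the shell; `heatdyn synth` writes
synthetic ensembles with a ground-truth JSON sidecar, and `heatdyn
run --manifest manifest.yaml` executes a full multi-model comparison
(per-model CS matrices, CS differences against a reference model,
switch regions, RMSF per component, H-bond deltas, provenance):

```bash
heatdyn synth --config hinge.yaml --out hinge.pdb
heatdyn corr --topology hinge.pdb --component-map arms.tsv \
             --probe-block N-arm --out-dir out/
heatdyn run --manifest manifest.yaml
```

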