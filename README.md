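# statescan

Conformational-ensemble analysis for small GTPases (and anything
structurally similar): given a multi-model PDB trajectory, `statescan`
quantifies how the nucleotide-binding site and the two mobile "switch"
loops behave — which conformational states exist, how populated they are,
how exposed the bound nucleotide is, and whether the catalytic machinery
is arranged for hydrolysis.

## What it computes

For a trajectory of topology-identical conformers the package provides:

- **Superposition metrics** — Kabsch least-squares superposition
  (proper rotations only), per-frame RMSD with independent fit/measure
  selections, and per-residue RMSF about the iteratively re-aligned
  ensemble mean.
- **Dynamic cross-correlation (DCCM)** — for Cα atoms *i*, *j* with
  displacements Δr = r(t) − ⟨r⟩,
  `C(i,j) = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) ∈ [−1, 1]`.
- **Coordinate PCA** — covariance of aligned Cα coordinates,
  eigenvalues λᵢ / eigenvectors Vᵢ, and projections
  `Proj(M, PCᵢ) = (M − ⟨x⟩)·Vᵢ` of snapshots onto the leading modes.
- **Conformational clustering** — average-linkage (UPGMA) agglomeration of
  the pairwise superposed Cα-RMSD matrix, cut at a height threshold
  (1.5 Å default), with representative-structure extraction per cluster.
- **Two-distance state classifier** — d1 = |Cα(G60) − Pβ| and
  d2 = |Cα(T35) − Pβ|; frames with d1 ∈ [5.8, 8.0) Å are *active* (both
  switch loops coupled to the γ-phosphate), d1 ∈ [8.0, 10.0) Å is
  *inactive substate 3* (G60–γ-phosphate coupling lost), everything else
  is reported as unassigned.  All atoms and bounds are configurable.
- **Nucleotide exposure** — deterministic Shrake–Rupley SASA (golden-spiral
  quadrature, 960 points, 1.4 Å probe) of the bound nucleotide with
  protein-only occlusion.
- **Catalytic-site geometry** — Q61 carbonyl–Pγ distance, arginine-finger
  NH1/NH2 salt bridges to the α/γ-phosphate oxygens, the NE2–OE1–Pγ
  angle, and water-mediated bridge occupancy.
- **Synthetic two-state generator** — a seeded pseudo-GTPase with a buried
  pseudo-nucleotide, Markov switching between a closed (active-like) and
  open (inactive-like) basin, and iid Gaussian positional noise, providing
  exact ground truth for every analysis above.

## Worked example

```bash
statescan simulate --out run --seed 3 --n-frames 400
statescan states   --in run/ensemble.pdb --out run
statescan cluster  --in run/ensemble.pdb --out run --sel "name CA and chain A"
statescan report   --run run
```

prints (seed 3):

```
simulate: wrote run/ensemble.pdb (400 frames of truth)
states: active=0.780, inactive_substate3=0.220, unassigned=0.000
cluster: 2 clusters at 1.5 A (sizes [39, 11])
report: aggregated 20 artifacts into report.json
```

The simulated chain had a realized closed-state occupancy of 0.78 at this
seed; the d1 classifier recovers exactly that fraction as *active*, and
average-linkage clustering of the written snapshots finds the same two
conformational families (39 closed + 11 open frames of the 50 stored).
Every artifact (CSV/JSON/PDB) carries the hash of the configuration that
produced it, and identical seeds give byte-identical outputs.

The same pipeline is available as a library; the numbered scripts under
`analysis/` run the full synthetic study (simulation → classification →
clustering/PCA/DCCM → exposure and catalytic geometry) and write their
tables under `results/`.

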