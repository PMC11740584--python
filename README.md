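# swsx — small-wedge synchrotron crystallography toolkit

Small-wedge synchrotron crystallography (SWSX) determines protein structures
from many microcrystals: each randomly oriented crystal contributes only a
1–10° rotation wedge of diffraction data, and hundreds to thousands of wedges
are classified, scaled and merged into one complete data set.  The questions
this package addresses are the practical ones of that workflow: which wedges
are isomorphous enough to merge, how far structural information keeps growing
as multiplicity accumulates, whether anomalous signal is governed by photons
or by multiplicity, and how low the dose per sweep may go before
per-data-set processing starts losing signal.

`swsx` implements the full analysis chain as a tested, reusable library,
driven by a synthetic-data generator so every finding can be exercised
without downloading raw diffraction data:

- **Simulation** (`swsx.sim_core`) — ground-truth intensities (Wilson
  statistics or a toy atomic model with anomalous scatterers and
  polymorph mixtures of prescribed intensity correlation), rotation-geometry
  Ewald-crossing prediction, and a dose-proportional Poisson noise model with
  per-crystal scale/B variation and a frame-shared multiplicative systematic
  error.
- **Clustering** (`swsx.cluster`) — pairwise intensity correlations between
  wedges, Ward hierarchical clustering on the distance d = √(1 − CC²), the
  isomorphic threshold (0.7 × maximum Ward distance) above which cluster
  nodes may mix polymorphs, cluster selection by completeness/multiplicity,
  and indexing-ambiguity resolution by iterative consensus reindexing.
- **Scaling and merging** (`swsx.scale_merge`) — per-wedge relative scales
  ln g and relative B against a lowest-B reference, the three-run protocol
  (scale/merge, outlier-frame rejection, outlier-wedge rejection),
  inverse-variance merging with per-reflection rejection, and
  R_merge/R_meas/R_pim statistics.
- **Metrics** (`swsx.metrics`) — CC₁/₂ by random half-data-sets, the
  resolution cutoff d_min at the CC₁/₂ = 50% crossing, ⟨I/σ⟩ by shell,
  Wilson-B estimation with an over-sharpening check, a Kullback–Leibler
  information-gain metric (bits per reflection against the Wilson prior),
  and anomalous difference Fourier peak heights from Bijvoet differences
  with model phases.
- **Dose slicing** (`swsx.dose_slice`) — repeated low-dose sweeps as 2D
  photon-count frames, exact pixelwise frame summation into virtual
  high-dose data, profile-window spot integration, and signal-recovery /
  integration-degradation diagnostics versus dose per sweep.
- **Experiments** (`swsx.experiments`) — seeded end-to-end campaigns
  (`multiplicity`, `wedge_size`, `polymorph`, `dose_slice`) that print every
  measured trend next to the bound it is checked against.

## Core quantities

For wedge j with observation I_jh of unique reflection h at s = sinθ/λ:

- relative scaling fits ln(I_jh / ⟨I_h⟩) ≈ ln g_j − 2 B_j s², re-referenced
  so the lowest-B wedge carries (ln g, B) = (0, 0);
- clustering distance d_ij = √(1 − CC_ij²) on the correlation of internally
  merged intensities over common uniques, agglomerated by Ward's
  minimum-variance criterion (Lance–Williams update, deterministic
  tie-breaks);
- CC₁/₂ is the Pearson correlation of random half-data-set means per
  resolution shell, and d_min is the 50% crossing interpolated linearly in
  1/d²;
- information gain per reflection is ∫ q(J) log₂[q(J)/p(J)] dJ with Wilson
  prior p(J) = e^(−J) and a Gaussian intensity likelihood posterior q;
- anomalous maps use coefficients ΔF = |F₊| − |F₋| with model phases
  φ_c − 90°, synthesized by Hermitian summation; peaks are reported in map
  σ units.

## Worked example

Cluster a simulated two-polymorph mixture (intensity correlation 0.7,
40 + 40 wedges of 5°) and test whether the isomorphic threshold separates
the polymorphs:

```sh
$ swsx experiment polymorph --seed 7 --out-dir results/
{
 "target_cc": 0.7,
 "threshold": 2.934879396835559,
 "max_height": 4.192684852622228,
 "ari": 1.0,
 "bound_ari": 1.0,
 "splitting_node_above_threshold": true,
 "n_clusters_at_threshold": 2
}
```

The dendrogram's maximum Ward height (4.19) is the node that merges the two
polymorphs; it lies above the isomorphic threshold 0.7 × 4.19 = 2.93, and
cutting there recovers the planted partition exactly (adjusted Rand index
1.0, two clusters).

A small dose-slicing run (20 sweeps summed in groups of 1, 4 and 20):

```sh
$ swsx doseslice --sweeps 20 --group-sizes 1,4,20 --seed 7 --out ds.csv
 group_size  dose_fraction  cc_truth  rmse_intensity  rmsd_centroid  profile_fit_rate
          1           0.05  0.960857        0.345344       0.426579          0.770833
          4           0.20  0.988022        0.093596       0.210388          0.980556
         20           1.00  0.995249        0.043994       0.111409          1.000000
```

All sliced stacks contain the same total photons; what changes is how well
each virtual sweep can be processed on its own.  At 1/20 of the dose the
per-sweep profile models start failing (fit rate 0.77), spot centroids
wander (rmsd 0.43 px) and the merged intensities lose agreement with the
ground truth (cc 0.961 vs 0.995 at full dose).

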