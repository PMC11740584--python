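# Methods

This note records the models behind `swsx`, the defaults and why they were
chosen, what the synthetic data do and do not emulate, and the numerical
conventions a maintainer would need to modify the code safely.  No number
here is asserted that the test suite or `scripts/acceptance.py` does not
itself compute.

## Wedge simulation

**Ground truth.** Unique reflections are enumerated to d_min over the full
index sphere and reduced to canonical representatives, defined as the
lexicographically greatest index over all point-group images (plus the
Friedel mate when folding); this avoids hand-coded asymmetric-unit
boundaries.  Bijvoet pairs are tracked as (folded key, branch sign).  Two
truth modes exist:

- *wilson*: acentric intensities i.i.d. exponential with mean
  C·exp(−2 B_true s²); optional Bijvoet differences with s.d.
  bijvoet_ratio × I on acentrics.
- *model*: I = |F|² from a toy atomic model,
  F(h) = Σ occ (f0 + f′ + i f″) e^(2πi h·x) e^(−(B_iso+B_overall)s²), with
  F(−h) summed independently so anomalous differences are exact.  Scattering
  strengths are constant per atom (no s-dependent form factors) — a
  documented simplification; at the toy scale every property tested depends
  only on relative intensities.  `random_symmetric_model` places atoms at
  random general positions and expands them over the point-group rotations
  so intensities respect the symmetry exactly.  With ~120 unique light atoms
  (f0 = 7) and one S per asymmetric unit (f″ = 0.243 e⁻, the value for S at
  1 Å wavelength), the Bijvoet ratio is of order a few tenths of a percent.

**Polymorphs.** A second intensity set with target correlation ρ is built in
complex-amplitude space, F₂ = √ρ·F₁ + √(1−ρ)·F_ind, using the property of
circular complex Gaussians that the intensity correlation equals the squared
amplitude correlation.  Monte-Carlo checks in the tests confirm the sample
CC lands on the target.

**Geometry.** The spindle is +z, the beam +x, and a reflection is recorded
when its rotated reciprocal vector satisfies the Ewald condition
|Rz(φ)·R·A·h + s₀| = 1/λ, solved in closed form per reflection; a fine-scan
(0.001°) sign-change oracle in the tests agrees on ≥ 99.9% of reflections.
Partiality is ignored: a crossing inside the wedge is recorded fully.  The
blind region and the d < λ/2 limit fall out of the solvability condition.

**Noise model.** Expected counts for an observation are
λ = n0·(dose_total/wedge_deg)·g_j·exp(−2(B_j + β·D_f)s²)·I_true: a crystal's
photon budget is fixed by its dose, and counts scale with dose per degree,
so halving the wedge at fixed dose doubles the photons per degree.  Raw
counts are Poisson(λ + bg); i_obs = (counts − bg)·e^η with a frame-shared
η ~ N(0, σ_sys²) (default s.d. 0.03).  The frame-shared multiplicative error
is what makes multiplicity, not only photon count, improve anomalous signal:
averaging m observations beats one m-times-brighter observation only for
error terms that do not shrink with intensity.  σ uses the standard
one-count floor √max(counts + bg, 1)·e^η, since the pure counting formula is
zero for empty observations.  Per-crystal variation defaults:
ln g ~ N(0, 0.3²), B ~ |N(0, 3²)| Å².  Radiation damage (β) defaults to off;
the beam-misalignment illumination loss is not modelled.

**Calibration.** The dose→photon constant n0 is a free beamline parameter.
Experiment presets set it by anchoring the median low-resolution reflection
at a target count (`calibrate_n0`), then let the Wilson falloff fix the
high-resolution counts.  The multiplicity preset uses atomic B = 30 Å²,
bg = 10 and an 80-count low-resolution anchor: these place the campaign in
the photon-limited regime in which the CC₁/₂ = 50% cutoff moves with
accumulated photons, which is the regime the experiment studies — with much
brighter settings every shell saturates and the resolution trend is
undefined by construction.

## Scaling and merging

Scaling iterates (1) inverse-variance merge with current scales, (2)
per-wedge weighted least squares of ln(I_jh/⟨I_h⟩) on s² over strong
(I > 3σ) common reflections, (3) re-referencing to the lowest fitted B (ties
broken by observation count), until the largest parameter change is below
1e−6.  Wedges with fewer than 10 usable reflections are flagged unscalable
and excluded with a warning.  The lowest-B reference convention reproduces
the over-sharpening failure mode that the Wilson-B check is there to catch.

The three-run protocol: run01 scale/merge; run02 rejects frames whose median
|I_scaled − ⟨I⟩|/σ exceeds median + k·MAD over all frames (normalized MAD,
1.4826×, so k = 3.5 is on a σ-like scale; the raw-MAD cutoff rejected ~2% of
clean frames); run03 rejects wedges whose correlation with the leave-one-out
consensus is below 0.8.  The final merge scales observations by
exp(−ln g + 2 B s²), rejects observations more than 4σ from the per-unique
weighted median, and reports the inverse-variance mean with
σ = (Σ1/σ²)^(−1/2).  R statistics use the unweighted per-unique mean,
exclude multiplicity-1 uniques, and are reported absent (not zero) when no
unique has multiplicity ≥ 2.

Calibration caveat: merged σ is counting-statistics only.  With *known*
scales the z-scores of merged intensities against truth have unit spread
(the test asserts s.d. in [0.9, 1.1]); *fitted* scales leave a sub-percent
multiplicative residual that inflates z for the brightest reflections.
Production programs absorb this with a refined error model, which is out of
scope here.

## Clustering

Pairwise CC uses Friedel-folded, internally merged intensities on common
uniques (anomalous differences are far too weak to inform isomorphism);
pairs with fewer than 10 common uniques are flagged missing and imputed at
the matrix's maximum distance, which keeps sparse-overlap wedge sets
clusterable without dropping leaves.  Ward clustering runs on
d = √(1 − CC²) through the Lance–Williams update on squared distances — the
convention of intensity-correlation merging pipelines, applied without a
squared-Euclidean embedding check.  Ties are broken by the smallest leaf id
in the candidate pair, so permuting the input order cannot change
memberships; a from-scratch naive Ward agglomerator and scipy's linkage both
serve as oracles in the tests.  The isomorphic threshold is 0.7 × the
maximum Ward distance; nodes above it are flagged potentially polymorphic.
Cluster selection merges every node with the full three-run protocol and
keeps those meeting completeness/multiplicity bounds (defaults 95%/5.0;
anomalous preset 90%/3).

Indexing ambiguity is broken by consensus reindexing: a greedy seeding pass
(first wedge keeps its indexing; each next wedge takes the operator
maximizing correlation with the growing consensus) followed by leave-one-out
reassignment until stable.  The seeding pass is essential: from a symmetric
all-identity start on a 50/50 mixture the leave-one-out step has no
gradient.  Solutions are defined up to a global operator.

## Metrics

Shells partition the resolution range into 10 equal volumes in 1/d³.  CC₁/₂
splits each unique's observations into random halves (seeded; optionally
averaged over several splits) and correlates half-means across the uniques
of each shell; shells with fewer than 3 usable uniques are reported absent.
The d_min cutoff interpolates the 50% crossing linearly in 1/d² between
shell centres; if CC₁/₂ never drops below the level the finest shell
boundary is returned, and if it is below the level already in the first
shell the coarsest boundary is returned with a no-signal flag.

Wilson B comes from a shell-count-weighted fit of ln⟨I⟩ vs s² over the upper
half of the s² range; B = −slope/2, with an over-sharpening flag below
8 Å² (emulating a sanity check against typical temperature factors at
comparable resolution).

Information gain is a simplified acentric analog of the likelihood-based
metric: prior p(J) = e^(−J) on J = I/⟨I⟩_shell, Gaussian likelihood
N(i_obs; J⟨I⟩, σ), posterior by normalized product on a per-reflection
trapezoid grid over [0, max(10, (i_obs+6σ)/⟨I⟩)] with 2000 nodes (the
2000-node result matches a 10⁵-node oracle to well below 1e−3 bits).  The
prior is renormalized on the same interval so the gain is an exact KL
divergence and never negative.  Centric corrections are omitted.  Both the
total and the per-reflection mean are reported.

Anomalous difference Fourier maps use coefficients ΔF = |F₊| − |F₋| (with
|F| = √max(I,0)) and phases φ_calc − 90° from the non-anomalous model
structure factors; centric reflections are excluded.  The Hermitian
summation is evaluated exactly on a grid of spacing ≤ d_min/3 via FFT (grid
size also ≥ 2·h_max + 2 so indices cannot alias), the site density by direct
summation at the exact coordinates, and the peak is
(ρ(site) − mean ρ)/rms ρ over the full grid — the tiny bias from including
the peak in the rms is negligible at toy scale.

## Dose slicing

Frames are abstract photon-count images: pixel-integrated Gaussian spots
with a pseudo-resolution label on a flat background, Poisson counts
proportional to dose.  No crystal geometry enters — the study isolates
counting statistics and processing stability.  Frame summation is exact
integer pixel arithmetic, so a g-fold sum is distributionally identical to a
g-fold-dose simulation (asserted by moment and KS tests) and photon totals
are conserved exactly.

Integration fits a background plane on a square annulus and sums the
plane-subtracted counts over a circular window of radius 3× the profile
width (capturing 1 − e^{−4.5} ≈ 98.9% of a Gaussian spot), with σ from the
window counts plus the plane-estimate covariance.  Two window modes exist:
*fixed* (true centre and width — an idealized oracle) and *adaptive* (a 2D
Gaussian profile model fitted per spot per virtual sweep, emulating
independent processing of each sliced data set).  The adaptive model is only
trusted for significantly detected spots (window sum > 2σ) with a plausible
fit (positive amplitude, width within [0.3, 2×nominal] px, centre within
2 px); otherwise the observation is flagged unconverged and excluded from
merging — real pipelines have no oracle to fall back on, and unmodellable
reflections are lost.  At low dose the fitted widths collapse toward the few
recorded pixels (the mosaicity-underestimate analog, visible as a negative
width bias), centroids wander, fit rates drop, and the surviving
observations are selected on upward fluctuations.  This processing-model
failure is the mechanism of low-dose signal loss here: summation in
truth-derived windows shows no dose dependence at all after merging, since
total photons are identical across slicing levels.

The default layout places a jittered spot grid on a 128×128 detector with
the beam corner at (0,0), three radius-tertile shells labelled 3.0/2.0/1.5 Å
with shell-banded intensities 120–500 / 25–120 / 5–25 photons per low-dose
sweep (Wilson falloff; the high-resolution shell is barely per-sweep
visible), widths 1.1–1.6 px, background 0.05 photons/pixel/sweep, 100
sweeps.  The agreement metric cc_truth is the mean over pseudo-resolution
shells of the within-shell Pearson correlation of merged vs true
amplitudes — the resolution-resolved form in which shell statistics are
reported in practice; a single correlation over the full dynamic range is
dominated by the brightest spots and insensitive to weak-shell damage.

## Experiment presets and sizes

All presets are bit-reproducible for a fixed seed, and every reported trend
carries its bound in the output.  Default sizes — 64 wedges (multiplicity),
160 crystals per wedge size (wedge size), 40+40 wedges (polymorph), 100
sweeps (dose slicing), cells of 25 Å in point group 23 — keep each preset
between seconds and ~15 s on one CPU so that 20-seed repetitions remain
cheap.  The wedge-size preset uses uniform crystals (no scale/B spread):
with per-crystal variability, scale-fit noise acts as an extra coherent
error that is larger for 1° wedges and would contaminate the σ_sys = 0
control, which is meant to isolate counting statistics.  Its crystal count
(160) is chosen so the 1° arm reaches Bijvoet-pair completeness; otherwise
missing mates, not photons, would differentiate the arms.

## Known limitations

- No partiality, absorption, anisotropic B, detector geometry or
  s-dependent form factors; real-data effects such as ice rings or spatial
  overlaps are absent, so passing tests demonstrate the statistical
  machinery, not robustness to real-image artefacts.
- Merged σ carries no refined error model (see the scaling caveat above).
- The information-gain metric is acentric-only and Gaussian-likelihood; it
  tracks, but does not numerically reproduce, full likelihood-based
  implementations.
- The dose-slicing study abstracts away geometry refinement; unit-cell and
  mosaicity degradation are represented only through the per-spot profile
  model.
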