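# Methods

## Descriptor model

The descriptor summarizes the orientation structure of the uptake gradient
field. Conventions, fixed across all modules: voxel indices are 0-based
with half-open extents; axes are ordered (x, y, z); gradients are in
intensity units per voxel (voxel spacing is not folded in, and anisotropic
volumes are rejected rather than resampled, since mixing unequal axis
scales would silently distort orientations).

**Gradient.** Central differences in the interior, one-sided differences at
the boundary faces. The discrete stencil is a free choice; central
differences are the standard second-order scheme matching the continuous
∂v/∂x notation.

**Integral volume.** Triple cumulative sum of each gradient component,
accumulated in float64 (single precision visibly degrades cumulative sums
over ~10⁶ voxels). The mean gradient of a w×h×d cuboid is the standard
eight-corner inclusion–exclusion evaluation divided by w·h·d. Printed
renderings of this formula sometimes omit the 1/(w·h·d) factor or permute
corner signs; the implementation uses the mathematically consistent mean
with the standard 3D sign pattern and is verified against brute-force
looped means rather than transcription.

**Orientation quantization.** Face-center directions use the golden-ratio
constructions: icosahedron faces are the normalized dodecahedron vertices
{(±1,±1,±1), (0,±1/φ,±φ) cyclic}, dodecahedron faces the normalized
icosahedron vertices {(0,±1,±φ) cyclic}. The projection threshold t is the
maximum pairwise dot product over distinct, non-antipodal faces of the full
set — the adjacent-face cosine (0.7454 for the icosahedron, 0.4472 for the
dodecahedron). This is the only choice under which a face-aligned gradient
votes in exactly one bin. Numerically, thresholded projections below 1e-12
are zeroed so a projection that ties t exactly does not leak an O(ε) vote
into a neighbouring bin. In half-orientation mode one face per antipodal
pair is retained, projections are taken in absolute value, and t is
inherited from the full set (a `recompute_half_threshold` switch provides
the folded-set alternative; for these two solids the values coincide).
A zero gradient contributes a zero vote — constant regions are common in
masked PET volumes and are not an error. If thresholding ever annihilated
every projection of a nonzero gradient, the full magnitude would fall back
to the best-aligned bin (lowest index on ties); this is counted and logged,
and property tests over 10⁵ random directions confirm it does not occur
for either solid.

**Cells.** The volume is partitioned into ⌊dim/k⌋ cells per axis, anchored
at a centered offset so partial cells are discarded symmetrically from both
ends — every histogram then has identical k³ support. Cell order is
x-fastest with bins contiguous per cell, fixed so feature CSVs are
comparable across implementations. Sub-block votes are summed within a cell
by default; a `concat_subblocks` flag instead concatenates them, covering
the alternative reading in which sub-blocks contribute separate histogram
blocks. No normalization is applied beyond the magnitude weighting of the
quantizer; per-cell L2 normalization exists behind a flag, off by default.

Default parameters (k=16 voxels, S=1, icosahedron, half-orientation) are
the configuration found optimal on florbetapir training data; at the
standard 80×96×80 (2 mm) matrix they give 5×6×5 cells × 10 bins = 1500
features. The optimisation grid spans k ∈ {4,…,32} in steps of 4,
S ∈ {1,2,4}, both solids and both orientation modes: 96 combinations.

## Classification

Soft-margin RBF-SVM (scikit-learn SVC). HOG features enter unscaled — their
magnitudes are commensurate by construction; intensity-baseline features
are z-normalized per image instead. Hyperparameters are selected over
C = 10⁻²…10³ and γ = 10⁻⁵…10² by stratified ten-fold cross-validation:
within each class, subjects are shuffled with the seed and dealt
round-robin across folds. The selection maximizes pooled CV accuracy with
ties broken by higher sensitivity, then higher specificity, then **fewer
support vectors in a full-set fit**, then smaller C, then smaller γ.

The support-vector tie-break deserves explanation. On strongly separable
data every (C, γ) pair can tie at CV accuracy 1.0, including degenerate
pairs whose kernel is effectively flat at the data's scale; such a model's
decision function follows the training class balance, and under
leave-one-out (where the held-out subject's class is always the training
minority) it scores *exactly* zero accuracy while balanced CV folds hide
the defect entirely. The number of support vectors is the classical
leave-one-out generalization bound (LOO error ≤ #SV/n) and cleanly
separates fitted models (few SVs) from degenerate ones (all points are
SVs), keeping the selection deterministic.

Hyperparameters are fixed once before leave-one-out testing, not re-tuned
per fold, matching the use of a single selected configuration on held-out
data. Signed decision values are taken from the SVM decision function;
because reported distances are normalized to the cohort's maximum absolute
value, the unknown global margin scale cancels and the normalized values
are the Euclidean-distance ratios. ROC curves and AUC use the standard
threshold sweep (trapezoidal AUC equals the Mann–Whitney rank statistic
with ties counted half), cross-checked in tests against an O(n²) pairwise
oracle.

## SUVR and threshold conversion

Regional SUVR is the target-mean over reference-mean intensity ratio; the
composite is the unweighted mean of regional values (volume weighting is
available behind a flag). Positivity is strict: composite > threshold, so
equality is negative — a literal reading of the published cut points, and a
measure-zero event in practice. The PiB threshold on the sPAP scale is
obtained by composing t_Joshi = 0.67·t_Jagust + 0.15 with
t_sPAP = 0.9782·t_Joshi + 0.04264 at full precision (the rounded combined
coefficients 0.6554 and 0.1894 are reproduced only for reporting);
1.465 maps to 1.1495…, i.e. 1.15 at two decimals.

## Phantom generator

The generator emulates the one image property the classifier relies on:
grey/white contrast and its loss under amyloid deposition. Geometry is an
ellipsoidal white-matter core (60% of the brain semi-axes) inside a
grey-matter shell inside an ellipsoidal brain mask on an 80×96×80 grid at
2 mm; six equal azimuthal sectors of the superior shell act as cortical
target regions (mirroring the six-region composite layout) and an
inferior-posterior blob at grey-matter intensity serves as the
cerebellum-like reference. Defaults: white matter 1.8, grey matter 1.0
(arbitrary units), cortical uptake factor 1.5 for positives (1.0 for
negatives), Gaussian PSF of 8 mm FWHM (clinical amyloid-PET resolution),
multiplicative low-frequency bias field of ±10% (three random-direction
cosine waves, normalized), additive Gaussian noise with σ = 0.05 — about
5% of grey matter, realistic for smoothed clinical reconstructions. The
clean (pre-bias, pre-noise) composite SUVR is recorded as ground truth:
1.0 for negatives and ≈1.5 for positives by construction. Cohorts add
per-subject jitter (±10% tissue intensities, ±1 voxel ellipsoid axes) from
a single seeded PCG64 stream; the stream is consumed in an order
independent of the uptake factor, so same-seed positive/negative phantoms
differ only through the uptake change.

What the phantom does *not* model: anatomy (no gyri, no off-target binding,
no asymmetric atrophy), attenuation or scatter, tracer kinetics, motion, or
registration error. Passing tests therefore demonstrate that the pipeline
recovers the designed contrast mechanism under bias and noise — not
clinical-grade accuracy. On real scans the separating signal is weaker and
the reported accuracies of this pipeline on phantoms (typically 1.0) should
not be read as clinical performance.

## Problem sizes

Unit tests run on reduced grids (mostly ≤48³) where brute-force oracles are
exact and fast; the end-to-end recovery experiment uses the full 80×96×80
resolution with a 30+30 cohort, chosen as the smallest cohort at which
stratified ten-fold CV retains 3 subjects per class per fold. The
bias-robustness comparison uses a 40×48×40 grid with 10+10 subjects, large
enough for both feature types to be informative.

## Known limitations

- The descriptor assumes isotropic voxels and refuses anisotropic input;
  resampling is deliberately out of scope.
- Tetrahedron/hexahedron/octahedron quantizers are not provided; the
  optimisation grid only ever uses the two finest solids.
- Model persistence uses joblib; files are environment-portable only to
  the extent scikit-learn's estimators are.
- The SUVR module expects user-supplied region masks (integer-label NIfTI +
  name map); no atlas or template registration is shipped.
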