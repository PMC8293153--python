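# Methods

## Problem setting

A density map is a 3D scalar grid with voxel spacing, physical origin
and a contour level; voxels above the contour form the molecular
foreground.  A segmentation is a labeling of exactly those voxels with
positive integers, ideally one label per protein subunit.  Watershed
segmentation seeded at the local density maxima floods one basin per
maximum, so every noise bump becomes a segment; scale-space grouping
repairs some of this by merging basins whose maxima coalesce under
Gaussian smoothing, but the right smoothing level is map-dependent.
The package searches the space of segmentations directly, guided by a
learned quality score.

## Watershed and scale-space grouping

`watershed_segment` negates the density (peaks become basins), seeds at
plateau-aware local maxima under 6-connectivity and floods within the
foreground mask.  `scale_space_group(labels, map, params)` performs
`steps` rounds; each round smooths the previously smoothed density by
`sigma` (so round *r* carries an effective width of `sigma * sqrt(r)`),
recomputes basins of the smoothed field, and merges regions whose
original-density maxima fall into the same smoothed basin.  Identical-
width rounds would be idempotent under this merging rule, which is why
the ladder is cumulative: `steps` then genuinely indexes a
coarse-to-fine hierarchy.  The segment count never increases, background
is never touched, and regions of disconnected foreground components that
hold no maximum of the smoothed field keep their own labels rather than
being merged into a neighbour.

Random segmentation states draw `sigma ~ U[1, 4]` continuously (it is a
smoothing width) and `steps ~ U{1..4}` (it is a count of rounds).

`random_watershed` — used by the split operation — smooths the density
by a random `sigma ~ U[1, 4]` and floods without any grouping rounds.
Splitting needs a partition *finer* than the segment being split;
grouped segmentations on desk-scale maps are frequently coarser than
the target segment, which would make splits infeasible, while the plain
watershed of the smoothed density always remains fine-grained.

## Feature encoding

A segmentation is summarised by 121 numbers: the segment count
(capped at 60), then for each of the up-to-60 largest segments a pair
(volume proportion of the total foreground, Euler–Poincaré
characteristic).  Ordering by descending volume (ties broken by label)
makes the encoding invariant to label permutation, which the classifier
requires to be meaningful; unused slots are zero.  When more than 60
segments exist, the 60 largest are encoded and the count component
reports the capped value.

The Euler characteristic is computed on the closed cubical complex of
the voxel set, χ = V − E + F − C, by vectorised counting of vertices,
edges, faces and cubes; the convention is consistent with the
6-connectivity used everywhere else.  A solid blob scores 1, each
tunnel subtracts 1, each enclosed cavity adds 1.  The test suite checks
the implementation against an independent brute-force cell-enumeration
oracle on random voxel sets, plus the hand-derivable shapes (single
voxel 1, planar ring 0, hollow cube 2) and translation invariance.

## Fitness classifier

Training data are manufactured from any map with ground truth
("augmentation", 20 samples per map):

* 10 "bad" samples: feature vectors of independent random watershed +
  grouping segmentations (random σ, s) of the noisy map;
* 10 "good" samples: the ground truth with one uniformly chosen subunit
  split exactly in two along a random-watershed boundary — near-ideal
  segmentations that are not literally the truth.

The split picks the subunit uniformly among those the fresh watershed
actually subdivides; if no draw subdivides anything after 20 retries,
the unsmoothed watershed (the finest partition available) is used as a
last resort.

Four model families sit behind one interface — logistic regression,
RBF-SVM, MLP, random forest — each fitted by stratified cross-validated
grid search maximising ROC AUC (5 folds by default; the fold count is a
free choice).  The random-forest grid includes 1200 trees with sqrt(d)
features per split, and the forest is the default family.  The fitted
model's probability of the "good" class, in [0, 1], is the GA fitness.
Models persist via joblib plus a JSON sidecar (family, grid, AUC, seed).

## Evolutionary optimizer

Defaults (all configurable through `GAConfig`): population 30, 30
parents per generation drawn with replacement with probability
proportional to fitness (uniform fallback when all fitnesses are equal
or zero), paired round-robin (1st with 2nd, …) into 15 offspring;
crossover probability 0.9, mutation probability 0.1; stop at 200
generations or after 20 consecutive generations without a new best
fitness.

* **Crossover** pools both parents' segment sets, draws segments
  uniformly without repetition, and stamps each onto the offspring where
  voxels are still unlabeled, stopping once the foreground is covered.
  Every offspring segment is a (possibly truncated) parental segment.
* **Merge mutation** unites one uniformly chosen segment with one
  uniformly chosen face-adjacent neighbour (identity if none exists).
* **Split mutation** replaces one uniformly chosen segment by its
  intersections with a fresh `random_watershed`; if the segment falls in
  a single region the draw is repeated (5 retries, then identity).
* **Replacement**: generational mode replaces the whole population with
  the 15 offspring plus 15 fresh random segmentations (the heavy
  turnover explains generation-to-generation fluctuation); elitist mode
  keeps the 15 best of the previous generation.  The refill rule is a
  package choice — only the 30/15 counts are fixed by the protocol.
* Mutation applies to copied (non-crossover) offspring as well, and the
  merge/split choice is 50/50 when mutation fires; both are free choices
  where the protocol is silent.
* The best individual ever seen is archived and returned even when
  generational turnover removes it from the population; per-generation
  best/mean fitness (and matched IoU when truth is supplied) go to the
  run log.

One "iteration" is one generation.

## Evaluation metrics

Given prediction P (p segments) and ground truth Γ (t segments), the
pairwise IoU matrix is matched by optimal linear assignment
(`scipy.optimize.linear_sum_assignment`), which is equivalent to
searching all label permutations — verified against an exhaustive
permutation oracle for up to 6 labels per side.  Two aggregations:

* mode `all`: sum of matched IoUs divided by max(p, t), so every
  unmatched segment contributes zero — penalises over- and
  under-segmentation symmetrically (the denominator is a package choice);
* mode `matched_only`: mean over matched pairs (pairs with positive
  IoU).

Homogeneity H = TP/(TP+FP) over voxels, where TP are voxels of matched
predicted segments lying in their matched subunit and every other
predicted-foreground voxel (including all voxels of unmatched predicted
segments) counts as FP.  Proportion P is the mean over subunits of the
number of distinct predicted segments overlapping each.  Consistency C
is that overlap count for one designated subunit — by default the
largest-volume subunit; the alternative `max_si` variant (maximum over
subunits) is exposed as an option.  The two variants genuinely disagree
(max_si ≥ P always; largest-volume can be below P), and both are
implemented because the protocol's two descriptions of C conflict; the
largest-volume reading is the default since it is the only one
consistent with reported C < P cases.

A perfect segmentation scores matched IoU = 1, H = 1, P = 1, C = 1.

## Synthetic phantoms

`generate_phantom` emulates an intermediate-resolution map of a
multi-subunit assembly:

* each subunit is a chain of 3–5 isotropic Gaussian blobs (kernel sd =
  radius/2, radius ~ U[3.5, 5.5] voxels) with amplitudes U[0.6, 1.0] and
  centre offsets of 1.6 radii — the amplitude variation and spacing
  carve domain-scale saddles inside a subunit, giving the scale-space
  ladder genuine structure at intermediate smoothing widths;
* subunit centres are placed chained at ~1.05 × the sum of radii
  (touching, fuzzy shared boundaries), with bounded retries and a
  placement error if the grid cannot hold them;
* each subunit's blurred field (resolution blur sigma = 1 voxel) is
  normalised to unit peak so subunits contribute comparable density,
  then summed; additive Gaussian noise with sd = 0.05 of the subunit
  peak is spatially correlated over 1 voxel, emulating the
  mid-frequency artefacts of real reconstructions;
* the contour sits at 0.3 of the subunit peak — above the noise floor,
  as a practitioner would contour a real map; ground truth assigns every
  pre-noise foreground voxel to the subunit with the largest blurred
  field (ties to the lowest subunit index), so the truth is exact by
  construction.

Under these conditions the raw watershed over-segments by roughly an
order of magnitude (13–22 segments for 2–5 subunits) and random grouped
segmentations span the coarse-to-fine range, which is the regime the
optimizer is designed for.  What the phantoms do **not** model: real
electron-scattering densities, solvent/membrane context, resolution
anisotropy, masking artefacts, or subunits of wildly different sizes.
Passing tests therefore demonstrate the mechanics and the expected
qualitative behaviour (over-segmentation repair, baseline improvement),
not performance on experimental maps.

`generate_dataset(73, seed)` reproduces the training-corpus size used
throughout (73 maps × 20 augmented samples = 1460).

## Ground truth from atomic models

When a real map has an associated atomic structure, chains define the
subunits: every foreground voxel takes the label of the chain with the
nearest atom in physical coordinates (gemmi for PDB/mmCIF, KD-trees per
chain; ties go to the lower chain index), and voxels farther than a
5 Å cutoff (configurable) from every atom stay background.  Dataset
screening accepts entries with ≥ 2 subunits, reported resolution within
4.5–10 Å, and a map/model volume ratio within [0.8, 1.2] (inclusive
bounds); the model volume is the count of voxels within the cutoff of
any atom.

## Numerical choices and limitations

* Volumes are MRC/CCP4 2014 via gemmi; densities mode 2 float32, label
  maps float32 with integral values (validated on read); grids are
  indexed (z, y, x); labels are int32.  The contour level is
  user-supplied or estimated by Otsu's method on the nonzero densities.
  Maps are used as stored (no resampling to isotropic voxels).
* All randomness flows through `numpy.random.Generator`; a fixed seed
  makes a whole GA run bit-reproducible.
* Degenerate inputs: an empty foreground raises; a single-segment
  individual cannot merge; an unsplittable segment leaves the split
  mutation as the identity.
* Test-scale runs use 24³–40³ grids, 2–5 subunits, and GA runs of up to
  30 generations with patience 10 — large enough for the coarse-to-fine
  behaviour to appear, small enough for a laptop; the protocol defaults
  (200/20) remain the package defaults.
* The fitness classifier is only as good as the augmented phantom
  corpus; on phantoms the good/bad classes are close to separable
  (held-out AUC ≈ 1), which overstates what the same recipe achieves on
  experimental data.
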