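# evoseg

Evolutionary refinement of watershed segmentations of 3D density maps.

Cryo-electron microscopy maps describe the density envelope of a
macromolecular assembly; segmenting that envelope into its protein
subunits is a first step toward understanding how the machine works.
The classic immersive watershed (optionally followed by scale-space
grouping) over-segments noisy maps badly, and tuning it by hand is
map-specific drudgery.  `evoseg` instead treats segmentation as an
optimization problem: a population of candidate segmentations is
evolved — selection, crossover, merge/split mutation, replacement —
under a fitness function learned by a classifier that tells "ideal-like"
segmentations from over-segmented ones using only basic structural
information (segment count, per-segment volume fractions and
Euler–Poincaré characteristics).

## The method in brief

* A candidate segmentation is a full labeling of the foreground voxels
  (voxels above the map's contour level).  The initial population of 30
  candidates comes from watershed + *s* rounds of scale-space grouping
  with σ, *s* ~ U[1, 4].
* Each candidate is encoded as a 121-component feature vector
  x = (x₁, x₂, …): x₁ is the segment count, then up to 60 pairs
  (volume proportion, Euler characteristic χ = V − E + F − C of the
  segment's cubical complex), largest segment first.
* A random-forest classifier (grid-searched, ROC-AUC selected) trained
  on augmented good/bad examples maps the feature vector to the
  probability of being a good segmentation — the GA fitness.
* Per generation, 30 parents are drawn with probability proportional to
  fitness and paired round-robin into 15 offspring; crossover fires with
  probability 0.9 (uniform superposition of parental segments), one
  merge-or-split mutation with probability 0.1.  The run stops after 200
  generations or 20 without a new best fitness.
* Results are scored against ground truth with permutation-matched IoU
  (optimal label assignment), homogeneity H (voxel precision),
  proportion P (mean predicted segments per true subunit) and
  consistency C (predicted segments in the largest subunit).

A synthetic phantom generator manufactures multi-subunit maps with
exact per-voxel ground truth, so the whole pipeline is testable without
downloading any data; a ground-truth builder does the same from a real
map plus an atomic model (chains = subunits, nearest-atom labeling).

## Worked example

```bash
evoseg phantom --subunits 3 --shape 32,32,32 --seed 7 \
    --out-map scratch/m.mrc --out-truth scratch/t.mrc
# phantom: 3 subunits, threshold 0.3

evoseg segment --map scratch/m.mrc --threshold 0.3 --sigma 2 --steps 2 \
    --out scratch/baseline.mrc
# segments: 3

evoseg train --maps 73 --family rf --seed 1 --out scratch/model.bin
# rf: cross-validated AUC 0.995 on 1460 samples

evoseg evolve --map scratch/m.mrc --model scratch/model.bin \
    --threshold 0.3 --seed 1 --truth scratch/t.mrc \
    --out scratch/best.mrc --log scratch/run.json
# best fitness 0.966 (4 segments, stop: patience)

evoseg eval --pred scratch/best.mrc --truth scratch/t.mrc
# {
#   "matched_iou_all": 0.637,
#   "matched_iou_matched_only": 0.850,
#   "homogeneity": 0.914,
#   "proportion": 2.0,
#   "consistency": 1,
#   ...
# }
```

The evolved best has 4 segments against 3 true subunits: three match
their subunits well (matched IoU 0.85 over matched pairs, 91% of
predicted voxels in the right subunit) and one small spurious fragment
drags the all-slots IoU down to 0.64.  On seeded 5-subunit phantoms the
evolved best
segmentation typically reaches matched IoU 0.16–0.48 with 4–5 segments
where the raw watershed produces 13–22 segments at matched IoU ≤ 0.14 —
the same qualitative behaviour as on real maps: an order-of-magnitude
reduction in over-segmentation with equal-or-better voxel agreement.

The same pipeline is available from Python:

```python
from evoseg import PhantomSpec, generate_phantom, GAConfig, run_evolution, evaluate

pair = generate_phantom(PhantomSpec(n_subunits=5, grid_shape=(40, 40, 40), seed=1000))
# train or load a FitnessModel, then:
best, log = run_evolution(pair.map, model, GAConfig(seed=0), truth=pair.truth)
print(evaluate(best.labels, pair.truth))
```

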