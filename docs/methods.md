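# Methods

## The pseudolabeling model

All five mixed-sample operators share one premise: if a generated image
`I_aug` is built so that the lesion named by the annotated mask `T_L` is
still the lesion in `I_aug`, then `(I_aug, T_L)` is a valid supervised
training pair even though `I_aug` contains content from an unlabeled
image. The operators therefore only ever blend intensities; they never
move, warp or re-segment the lesion, and the returned mask is the source
mask bit for bit. This "label invariance" is the load-bearing property of
the whole package and is tested both per operator and end to end.

The operators interpolate between two extremes. PixMix perturbs the whole
labeled image globally with an `α/β` convex blend (the `α + β = 1`
constraint is enforced in `MixParams`; the ablation interface varies `α`
with `β = 1 − α`). The two LesionBlend variants act regionally through a
soft mask: LesionBlend keeps the labeled lesion and swaps in unlabeled
background, LesionBlend2 does the opposite. SegMix2 transplants the
(γ-blended) lesion onto the unlabeled image, and PixMix2 is the direct sum
of both images. Algebraically, LesionBlend + LesionBlend2 = `I_L + I_U`
pixelwise — a useful machine-checkable identity — and SegMix2 with γ = 1
and vanishing smoothing degenerates to hard copy-paste.

## Soft masks

`smooth_mask` convolves the {0,1} mask with a normalized Gaussian,
truncated at 4σ, with reflective boundary handling, and uses the result
directly as per-pixel blend weights (no re-binarization): the point of the
smoothing is a feathered, natural-looking transition at the lesion
boundary, which hard weights would destroy. Defaults: σ = 5 px at the
224×224 working resolution, giving a ~10–20 px transition band. Constant
masks are exact fixed points of the smoothing, and mask mass is conserved
away from borders; both properties are tested.

## Arithmetic domain

All mixing happens on per-file min-max-normalized float64 fields in
[0, 1]. Float arithmetic avoids the uint8 overflow ambiguity that the
PixMix2 sum would otherwise create; its [0, 2] output is mapped back by
min-max rescaling by default (a degenerate constant sum maps to all
zeros), with clipping available as `pixmix2_overflow="clip"`. A constant
input file (zero dynamic range) normalizes to all zeros. Mask PNGs are
binarized at half their dynamic range, which tolerates anti-aliased mask
files.

## Expansion protocol

`sample_subset` draws a seeded simple random sample without replacement
after sorting by source id (so the draw is independent of directory
order); subset sizes use half-up rounding, e.g. 5% of 414 → 21.
`expand_dataset` then generates `target_size − subset_size` samples with
one strategy per plan: labeled sources are cycled round-robin so each
contributes nearly equally, unlabeled partners are drawn uniformly with
replacement, and an image is never paired with itself (relevant when the
pool is the remaining labeled images with masks hidden, which is the
default when no separate pool is supplied). The α-sweep generates all its
datasets from one frozen pairing list, so two settings differ per pixel by
exactly `(α₁ − α₂)(I_L − I_U)`.

Every generated sample carries provenance (strategy, source ids, JSON
parameters, per-sample seed derived from the plan seed via a seed
sequence), written to `manifest.csv`; `replay_sample` regenerates any
sample bit-exactly from its manifest row.

## Baselines

Rotation draws an angle uniformly from [15°, 345°] (near-identity angles
deliberately excluded), rotating the image bilinearly and the mask with
nearest-neighbor, zero-filling out-of-frame pixels. Translation draws
independent per-axis shifts of up to ±20% of the axis length, rounded half
away from zero to integer pixels so the mask is never resampled. Gaussian
noise draws a variance uniformly from 10–50 on the 8-bit scale — the only
scale on which those numbers are meaningful — converts it to the [0, 1]
domain as `var/255²`, perturbs the image only, and clips. Horizontal flip
mirrors both image and mask with probability 0.5. Interpolation orders and
the zero fill are this package's choices; they avoid inventing mask values.

## Metrics

Jaccard and Dice come from pixelwise confusion counts; `TN` is counted for
completeness but enters no formula. Two empty masks score 1.0 by
convention (with a warning); this keeps batch evaluation total. The
boundary metric is computed on boundary pixels (mask minus its 4-connected
erosion, with out-of-frame treated as background) using Euclidean
distances between pixel centers: per direction the 95th percentile
(linear-interpolation definition) of minimum point-to-set distances, the
two directions combined by max. `percentile=100` gives the classical
Hausdorff distance; the 95th-percentile variant is the default because it
is the field's standard robust choice for the quantity reported under the
name HD95, even where the printed max-min formula is the 100th-percentile
form. One empty mask yields the image diagonal as a defined penalty,
flagged in the report. Per-image metrics are aggregated by arithmetic mean
(and stdev) in the CSV report.

## Synthetic phantoms

`make_phantom` builds a background as a base intensity (0.35) modulated by
unit-mean gamma-distributed multiplicative noise (shape `1/s²` for speckle
scale `s = 0.3`, the standard fully-developed-speckle model), smoothed
with a σ = 1.2 px Gaussian to mimic the spatial correlation of real
speckle; one elliptical lesion is added as a signed contrast offset
(±0.1–0.3) through a Gaussian-feathered indicator (edge σ = 2 px), and the
*hard* ellipse indicator is the ground-truth mask. Defaults (224×224
frames, semi-axes 8–40 px) match the working resolution of the intended
ultrasound pipelines. The phantoms reproduce the speckle texture, low
contrast and blurred lesion boundaries that motivate the operators, but
not beamforming artifacts (shadowing, reverberation, attenuation) — so
green tests demonstrate the correctness and determinism of the machinery,
not segmentation performance on clinical data, which requires training
real models on real images and is out of scope here.

## Determinism and numerics

Operators contain no randomness; all randomness (phantom synthesis, subset
draws, pairings, baseline draws) flows from explicit integer seeds through
`numpy` generators, with per-sample seeds derived via `SeedSequence` and
kept below 2³¹. The end-to-end pipeline is byte-deterministic: two runs
with the same config produce identical PNGs and manifests (the run log,
which records the output path, is the only file allowed to differ between
differently-named runs). Images are written as 8-bit PNG with
`round(p·255)`, so a write/read round trip moves no pixel by more than
1/255.

Problem sizes in the tests and the acceptance script (16×16 oracle
images, 48–64 px phantoms for property sweeps, a 20 + 100 phantom corpus
at 224×224 for the end-to-end run, 414 lightweight samples for the
expansion-count check) are chosen as the smallest sizes at which each
property is non-trivial; every checked identity is size-independent.

## Known limitations

* One lesion and one mask per image; multi-lesion instance labels are not
  modeled.
* No physical pixel spacing: HD95 is reported in pixels at the evaluated
  resolution.
* The phantom generator is a texture model, not an acoustic simulation.
* Combining several strategies in one expanded dataset is intentionally
  unsupported (one plan = one strategy); strategy mixing is future work.
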