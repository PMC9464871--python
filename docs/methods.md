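# Methods

This note documents the models and procedures implemented in
`noisyensemble`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical conventions used
throughout.

## 1. The training procedure

### Single-class selection and label flipping

Training tiles first pass the per-patient single-class constraint: for every
training patient, one class is chosen and only that class's tiles are
retained. Patients with tiles of a single class are forced to that class;
for the rest, the default *balanced* assignment processes patients in a
seeded random order and gives each to whichever class currently holds fewer
retained tiles (seeded coin on ties), keeping the retained class totals
within one patient's tile count of each other. A plain fair coin is
available (`balance=False`).

Noise is then injected as an exact count, not per-tile Bernoulli draws:
exactly ⌊ρ·N⌉ of the N retained tiles (round half up) are selected uniformly
without replacement and their training labels flipped. ρ is interpreted
globally over the retained set — a per-patient fraction would distort
patients with few tiles — and must lie in [0, 0.5); at 0.5 the labels carry
no information. The draw is recorded as a `NoisePlan` (retained set, class
choices, flipped ids, seed), serializable to JSON, so any training run can
be audited or replayed. Flipping is an involution: applying a plan twice
restores the truth, and ground-truth labels in the cohort are never mutated.

Validation tiles come from the same single-class selection but keep their
true labels. Members are checkpointed on validation accuracy; flipping
validation labels would corrupt the checkpoint criterion, so noise is
confined to the training side.

### Splits

All sampling units are patients; tiles never straddle a split boundary.

* **Repeat splits** hold out ⌊test_fraction·n⌉ patients per repeat.
  Assignment is balanced greedily — each repeat takes the patients with the
  fewest test appearances so far, with seeded random tie-breaks — so test
  appearances across patients never differ by more than one regardless of
  whether n_repeats·test_fraction is integral.
* **Member splits** give each of the n members (odd, default 15) a
  validation set of ⌊val_fraction·pool⌉ patients and the remaining pool as
  training set. Validation sets must be pairwise distinct as patient sets;
  when n·val_size fits in the pool they are dealt as disjoint blocks of a
  shuffled pool (which reproduces leave-one-patient-out exactly when the
  pool size equals the member count), otherwise they are resampled until
  distinct, with an explicit error when C(pool, val_size) < n. The member
  validation fraction is not pinned by the study design this emulates;
  0.2 is the package default and is configurable.
* **Site-restricted splits** hold out n_test_per_site patients from *every*
  site to form one common test pool, and draw the training pool only from
  the chosen training site (or the union for `"all"`). The held-out pools
  are derived from (seed, repeat, site) only, so they are identical across
  training-site choices — cross-site comparisons always see the same test
  tiles.

Every random stream is derived from the experiment seed with SHA-256-keyed
`numpy` `SeedSequence`s over composite keys such as (seed, "noise", repeat,
site, ρ). This gives piecewise reproducibility (any stage can be re-derived
in isolation) and no collisions between adjacent seeds or stages.

### Members and voting

The default member is a compact convolutional network implemented in numpy:
a parameter-free stem (centre pixels at 0, average-pool by 2), three 3×3
convolution blocks of 8/16/32 filters with ReLU (2×2 max-pool after the
first two), global average pooling, and a sigmoid head; trained with Adamax
(lr 5·10⁻³, β₁ 0.9, β₂ 0.999) on binary cross-entropy. Training is
single-threaded, seeded, and bit-reproducible. After each epoch the member's
validation accuracy is recorded; the returned model is the checkpoint with
the maximum validation accuracy, resolving ties toward the earliest epoch so
reruns are stable. Backends are pluggable behind a four-method contract
(`setup` / `train_epoch` / `predict_proba` / `get_state`+`set_state`); a
logistic-regression backend on flattened pixels is included for fast tests
and baselines.

Members vote 1 when their probability is ≥ 0.5 (the boundary value votes 1
by convention). Ensembles aggregate *votes*, not probabilities: the ensemble
label is the majority (tie-free because n is odd) and the agreement — the
number of members matching the ensemble label, in {⌈n/2⌉..n} — is the
confidence score. "Group" performance (mean of member accuracies) is kept
distinct from "ensemble" performance (accuracy of the majority label).

### Selective prediction and reports

`accuracy_by_agreement` sweeps the agreement threshold t from bare majority
to unanimity, reporting retained counts, accuracy over retained tiles, false
positives and negatives (class 1 = cancer is the positive class), and how
many discarded tiles would have been correct or wrong. When a threshold
retains zero tiles its accuracy is NaN — a flagged missing value, never 0 or
1. `stratified_performance` groups accuracy by site, quality grade or
patient; AUC, when present, uses the fraction of member votes for class 1 as
the score, the only score a vote-based design provides. `flag_suspect_labels`
lists tiles whose recorded label the ensemble contradicts at or above a
review threshold, most confidently contradicted first, for human re-review —
labels are never changed automatically. `apply_exclusion_list` evaluates any
third-party tile-rejection mask (e.g. from an external quality-control tool)
by set difference plus a before/after accuracy delta.

## 2. The synthetic cohort

Each tile is a blob texture on a pale eosin-like background: "cancer"
(class 1) renders many small dark nuclei-like ellipses (9 blobs per 1000 px²,
radius 3.5 ± 0.7 px), "non-cancer" (class 0) fewer, larger structures
(2 per 1000 px², radius 6 ± 1.2 px, more eccentric). Blob counts are Poisson
in the tile area; positions, radii, eccentricities and orientations are
drawn per tile. The classes therefore differ in *granularity* (a
high-frequency cue that blur and compression erode) and more mildly in total
stained area (~22% vs ~29%, a cue that survives blur). Every patient draws
one stain-colour offset (sd 0.07 per channel) shared by all its tiles,
emulating staining batch effects; the offset exceeds the between-class mean
colour gap, so colour alone cannot classify.

Quality grades 1–3 are assigned per patient (mirroring per-slide quality
scores) from each site's grade mixture and realised as a fixed operator
chain — stain gain → brightness → contrast toward the image mean →
reflect-padded Gaussian blur → JPEG round-trip — ordered as the physical
acquisition chain (stain and illumination act on tissue, optics blur the
field, compression comes last). Defaults:

| grade | blur σ (px) | contrast | brightness | stain gain (R,G,B) | JPEG |
|------:|------------:|---------:|-----------:|--------------------|-----:|
| 1     | 0.3         | 0.97     | 0          | 1, 1, 1            | —    |
| 2     | 0.8         | 0.88     | +0.02      | 1.05, 0.96, 1.02   | 75   |
| 3     | 1.4         | 0.75     | +0.05      | 1.12, 0.88, 1.05   | 50   |

The three default sites are A (80% grade 1, 20% grade 2; tiles stored as
JPEG quality 30), B (15/35/50% grades 1/2/3; JPEG 70) and C (50/40/10%;
PNG) — a high-quality source site, a mixed/low-quality site, and an
intermediate external site. The grade magnitudes were calibrated during
simulator design against two anchors: models trained on the mixed-quality
site must still classify that site well (poor-quality clinical slides remain
diagnostically usable), while clean-trained models must lose measurable
accuracy on it. Identity profiles return the input bit-exactly, and the
whole cohort — metadata and pixels, including the stored-file bytes — is a
pure function of (site/texture config, sizes, seed).

Desk-scale defaults shrink the emulated study: 64×64 px tiles (not 512×512),
8 tiles per patient (not 40), 30 patients per site, 7 members (not 15) and
30 epochs in the packaged benchmark. A from-scratch compact CNN needs more
passes over ~90 tiles than a fine-tuned pretrained network needs over
thousands, hence the higher epoch default in the benchmark configuration;
every study-scale value (15 members, 10 epochs, 40 tiles/patient) remains
reachable through configuration.

What the simulator does **not** emulate: real H&E morphology (nuclear
pleomorphism, stroma, necrosis), annotation error, scanner-specific
artifacts (dust, air bubbles, focal plane tilt), intra-patient heterogeneity
across slides, or class-imbalanced extraction. Passing benchmarks here show
the *mechanics* (splitting, noise, voting, rejection, statistics) behave as
specified and that the qualitative quality/transfer structure can be
reproduced; they are not evidence about performance on clinical images.

## 3. Statistics

`one_way_anova` is the classical fixed-effects ANOVA (scipy's
implementation; F = MS_between/MS_within on (k−1, N−k) degrees of freedom),
with an explicit error when every group has zero variance.
`pairwise_t_holm` runs all k(k−1)/2 two-sided two-sample t-tests —
pooled-variance by default, the classical post-hoc choice after ANOVA, with
Welch available by flag since the equal-variance assumption is often
doubtful for per-slide accuracies — and adjusts p-values by Holm's step-down
procedure (sort ascending, multiply p₍ᵢ₎ by m−i+1, running maximum, clip at
1), marking pairs significant below α = 0.05. The Holm implementation is
statsmodels'; the test suite pins it against a long-hand step-down oracle
and checks family-wise error control on null simulations.

## 4. The packaged benchmark

`run_benchmark` executes generate → split → select → flip → train → vote →
evaluate for every (train_site, ρ) cell across repeats, regenerating the
cohort per repeat from a derived seed. Within a repeat, all noise levels
share the same member partitions and single-class selection, so cells differ
only in flipped labels; all plans are serialized beside the result tables.
Outputs are tidy CSV tables (per-site and per-grade accuracy, per-patient
accuracy, agreement curves, agreement-by-correctness) plus the
quality-grade ANOVA/post-hoc on per-patient accuracies of clean-trained
runs. `scripts/acceptance.py` runs the 10-repeat mechanism study (clean-site
training at ρ = 0 and 0.15, degraded-site training at ρ = 0) and writes the
aggregate quantities as JSON.

## 5. Numerical conventions and edge cases

* Rounding of all split/flip sizes: half up, ⌊x+0.5⌋.
* Images are float64 in [0,1] in memory; files are 8-bit PNG/JPEG, and the
  in-memory store always equals the decoded stored bytes, so file-based and
  in-memory pipelines see identical pixels.
* Member probabilities of exactly 0.5 vote for class 1.
* Checkpoint ties go to the earliest epoch.
* Max-pool gradients split equally over tied maxima so gradient mass is
  conserved.
* Zero-retained agreement thresholds yield NaN accuracy; groups with a
  single class yield NaN AUC.
* Degradation profiles accept a seed for future stochastic operators; the
  five built-in operators are deterministic given the profile.

## 6. Known limitations

* The packaged mechanism benchmark reproduces the quality→accuracy gradient,
  the asymmetric cross-site transfer, the correct-vs-incorrect agreement
  gap, and the accuracy-vs-agreement trade. The remaining direction — a
  *consistent* accuracy gain on degraded data from training with 15% label
  noise — behaves neutrally at this scale: across seeds the median effect of
  noise on degraded-site accuracy is within a few percentage points of zero
  in either direction. With ~90 single-class training tiles and from-scratch
  compact members, label flips mostly reduce the effective sample size; the
  regularisation benefit that large pretrained members can harvest from
  noise has little capacity to act on. Study-scale backends can be plugged
  in unchanged where that regime is affordable.
* Small common test pools (7 patients per site) make single-repeat site
  accuracies noisy; conclusions should always be drawn from the repeat
  aggregates.
* Best-effort determinism: all shipped backends are bit-reproducible, but
  the contract only requires it of plans (cohorts, splits, noise), so
  third-party backends may introduce run-to-run variation in weights.
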