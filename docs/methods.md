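# Methods

This note records what `fdtaudit` computes, the assumptions behind it,
the tunable parameters, and the design decisions taken where the design
was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The verification model

A classification decision over the four-class label space {glioma,
meningioma, pituitary, no_tumor} is audited against guarded threshold
rules on three symbolic features computed from the raw slice, never from
the classifier's internals. The decision is recorded as a formal
decision trace — an alternating state/action sequence
⟨raw slice, feature extraction, featured state, prediction, decided
state⟩ — and the trace plus rule set is encoded into quantifier-free
linear real arithmetic:

* one real constant per feature, rendered as the *exact* decimal
  expansion of its IEEE-754 double (so the logical value and the float
  value are identical objects, and no channel can disagree through
  rounding);
* one Boolean selector per class, with the predicted selector asserted
  and an exactly-one side condition tracked as its own named assertion;
* one tracked implication per rule, `is_<class> ⇒ feature <cmp> τ`.

The default rule set (version `default-1`):

| id   | guard       | predicate                         | default τ |
|------|-------------|-----------------------------------|-----------|
| C1   | glioma      | enhancement_variance >            | 0.1       |
| C2   | pituitary   | sellar_band_overlap >             | 0.5       |
| C3   | meningioma  | border_edge_density >             | 0.05      |
| C4   | glioma      | enhancement_variance >            | 0.1       |
| PRED | —           | exactly one class predicted       | —         |

C4 is the consistency invariant "no glioma call without heterogeneous
enhancement"; it deliberately duplicates C1's predicate as a separately
tracked assertion so unsat cores distinguish the two rules. Comparisons
are strict at the boundary: variance exactly 0.1 violates C1. C3's
threshold has no canonical value anywhere; it is a required
configuration parameter whose default, 0.05, was calibrated on phantoms
(a bar-free border band measures ≈ 0, a single dural-tail bar ≈ 0.02 at
64×64). An explicitly supplied configuration that omits it is rejected.

### The solver

No SMT solver package is assumed; the package ships an exact decision
procedure for the fragment its encoder emits (Boolean guards, real
constants, univariate linear atoms). It enumerates Boolean assignments
(at most 2⁴ here) and decides each induced conjunction of atoms by
per-variable interval intersection in rational (`fractions.Fraction`)
arithmetic — sound and complete for this fragment, with named-assumption
tracking for unsat cores. Certificates are a satisfying assignment for
SAT and the core listing for UNSAT. Cores contain every *individually*
violated named assertion (identification, not minimality; duplicated
rules are each named), falling back to a deletion-based core for
mutually conflicting assumptions. A wall-clock timeout (default 1 s,
never observed in practice — the fragment is decided in microseconds)
yields UNKNOWN, which downstream code treats as an environment fault
flagged for manual review.

### Dual-channel agreement

The second channel evaluates every rule directly as a material
implication in plain Python, sharing no code with the solver path.
Agreement is defined as (solver says SAT) ⇔ (all direct evaluations
true). Because both channels compare the same exact rationals, agreement
is a mathematical identity *if the encoder is faithful* — which is
precisely what the check certifies; the fault-injection test shows a
deliberately corrupted encoder is caught.

### Artifacts

The artifact payload (trace, per-assertion SMT-LIB text, conjunction,
verdict, certificate, metadata) is canonically serialized — sorted keys,
exact-decimal floats, UTF-8, no insignificant whitespace — and hashed
with SHA-256. Re-serialization is byte-stable, so the digest is
reproducible; any mutation is detected by recomputing it. The solver's
wall-clock time is reported but excluded from the hashed payload
(operational, not evidential). Timestamps are hashed; tests pass a
frozen timestamp so digests serve as regression fixtures.

## Symbolic features

All three extractors are pure functions of the pixel grid, computed on
intensities normalized to [0, 1].

* **Enhancement variance** — Otsu's threshold on a 256-bin histogram;
  mask = pixels strictly above it; feature = *population* variance of
  in-mask intensities. On a bounded [0, 1] scale the ceiling is 0.25,
  which is what makes the 0.1 threshold meaningful. A constant image has
  a degenerate histogram: empty mask, features 0, flag recorded in the
  trace.
* **Sellar band overlap** — fraction of mask pixels with row index in
  [0.4·H, 0.6·H) (top = row 0). A point centroid has no well-defined
  overlap fraction with a box, so the comparison against the 0.5
  threshold uses this mask fraction; the intensity-weighted centroid is
  computed and reported as auxiliary output.
* **Border edge density** — Canny edges (σ = 1.0, hysteresis 0.1/0.2 on
  the [0, 1] scale) counted inside the outer 10% margin on all four
  sides, divided by the band's pixel count.

No connected-component filtering is applied to the Otsu mask (a
largest-component option exists for sensitivity analysis but is off by
default).

## Phantoms

Phantoms emulate axial post-contrast T1-like slices: dark background
(0.1) with optional Gaussian noise (background pixels only, so structure
intensities stay exact), a bright skull rim (0.95, radius 0.47·S), and a
class-specific structure:

* glioma — off-center disk (radius 0.17·S) whose pixels alternate
  between two levels chosen so the in-blob population variance equals
  the target exactly (the parity imbalance of the checkerboard is folded
  into the level gap);
* pituitary — compact disk (radius 0.08·S, intensity 0.9) whose center
  row is chosen so the achieved in-band area fraction is as close as
  possible to the target; the achieved fraction is the ground truth;
* meningioma — peripheral disk (0.85) plus bright 3-px "dural tail"
  bars in the border band; modeled Canny output is two edge lines per
  bar plus six end-cap pixels, and the modeled density is the ground
  truth;
* no_tumor — background and rim only.

Ground-truth variance and overlap are computed from the constructed
bright-structure pixel multiset itself, so they are exact; edge density
is model-based and approximate by nature of Canny.

Keeping structure intensities at or above 0.5 over a 0.1 background
guarantees a bimodal histogram, so Otsu's cut falls in the
background/structure gap and the segmented mask equals the structure
exactly (rim suppressed, noise-free). This bounds constructible in-blob
variance at 0.05 — an equal mix of {0.553, 1.0}; requesting more raises
a parameter error, because widening the level gap further makes Otsu's
between-class criterion prefer a cut *inside* the blob, destroying
mask recovery. Glioma phantoms therefore cannot exercise C1's 0.1
threshold from pixels; threshold-boundary verification uses directly
synthesized traces, where feature values are set numerically.

The rim is on by default, mirroring full field-of-view preprocessing
(no skull stripping). With the rim on, the Otsu mask is structure ∪ rim,
and the extracted features are rim-contaminated; for band overlap this
contamination is unbounded in principle (the rim ring spans all rows),
so the feature-recovery guarantees — variance ±0.02, overlap ±0.05,
density ±0.05 — are stated and tested for the rim-suppressed, noise-free
configuration. Rim-on cohorts remain the default for training and audit
demonstrations, where only class separability matters.

Cohort generation derives per-slice seeds from (master seed, slice
index) via `numpy.random.SeedSequence`, draws per-slice feature targets
from per-class ranges (defaults: glioma variance U[0.02, 0.05],
pituitary overlap U[0.7, 1.0], meningioma density U[0.06, 0.12]) with a
cohort-level generator, and is byte-reproducible. Default image size for
cohorts is 64 px (phantom geometry is resolution-independent down to
32 px), default noise_sd 0.01.

What phantoms do **not** emulate: anatomy, 3-D context, multi-sequence
appearance, intensity physics, scanner effects, or the ambiguity of real
glioma/meningioma borderline cases. Passing tests on phantoms certify
the *machinery* — extraction, encoding, solving, attestation, training
plumbing — not clinical performance on real MRI.

## Preprocessing and augmentation

Evaluation preprocessing is deterministic: bilinear resize
(half-pixel-center convention) to the model input size, grayscale
replicated to three channels, normalization with mean 0.5 / sd 0.5.
Training augmentation applies flip (p = 0.5) → rotation (uniform ±15°,
bilinear, zero fill — dark background) → multiplicative brightness
jitter (±20%) → contrast jitter (±20%) pivoting on the image mean, then
clips to [0, 1]. The order, the multiplicative form of the jitter, and
the mean pivot are conventions fixed here for reproducibility; vertical
flips are never applied (they invert the superior–inferior axis).

## Class weighting

f_c = n_c / Σ n_k, w_c = 1/f_c, w_c^norm = w_c / ((1/C) Σ w_k), so
Σ w_c^norm = C identically and the mean weight is 1. The loss uses the
*normalized* weights and the natural logarithm, with probabilities
clamped at 1e-12. Weights are recomputed per training partition.

## Reference classifier and training

Two conv blocks (each two 3×3 convs + batch norm + ReLU; block 2 adds an
identity skip after its final batch norm, then ReLU), 2×2 max pool,
global average pooling, dropout 0.5, FC-512-ReLU, linear 4-way softmax.
At width 64 / hidden 512 the analytic parameter count is 148,420
(reported as computed; the architecture as described does not yield a
seven-figure count). Implemented in NumPy with explicit backprop
(im2col convolution) and AdamW (β₁ = 0.9, β₂ = 0.999, weight decay
1e-4), batch 32, early stopping on validation macro-F1 (patience 5,
best checkpoint retained), plateau LR halving (factor 0.5, patience 2).
A mixed-precision flag (float16 activations) exists and is off by
default — correctness first at desk scale.

### Desk-scale weighting experiment

The directional claim — inverse-frequency weighting does not hurt, and
tends to help, macro-F1 on an imbalanced cohort — is evaluated on the
internal class proportions at 1/40 scale (40/44/56/60 slices, cohort
seed 20), 80/10/10 stratified split (seed 42), width 16 / hidden 64 at
64×64. Two departures from the full-scale protocol, both forced by the
scale: the learning rate is 5e-3 (at ~100 optimizer updates total,
3e-4 leaves the network at chance), and the comparison is the **mean**
test macro-F1 over three fixed training seeds (0, 1, 2), because
single-run outcomes at this scale are dominated by optimization noise.
BLAS threading is pinned to one thread during this experiment so the
result is bit-reproducible on a single-CPU machine. The magnitude of
the gap is data- and scale-specific and is not asserted — only the
direction; at this scale part of the observed gap reflects convergence
reliability rather than minority-class recall alone.

## Evaluation

Stratified 80/10/10 hold-out and 5-fold stratified cross-validation
(shuffled, seed 42) preserve class proportions to ±1 sample per fold.
Metrics: accuracy, per-class precision/recall/F1, macro-F1 (primary),
support-weighted F1, macro one-vs-rest ROC AUC (trapezoidal, midrank
ties; a class absent from the truth vector is excluded from the macro
with a warning), row-normalized confusion matrices. Bootstrap CIs are
percentile (2.5/97.5) over seeded i.i.d. slice resamples — there is no
patient grouping to respect at slice level.

## Numerical conventions and degenerate inputs

* Population (not sample) variance throughout.
* Exact decimal rendering of doubles in formulas and artifacts; exact
  rational comparison in both verification channels.
* Softmax ties resolve to the lowest class index; a softmax vector is
  rejected unless it sums to 1 within 1e-6 and its argmax matches the
  stated label.
* Empty/degenerate masks: all masked features 0.0 plus a trace flag.
* Constant images: degenerate-histogram flag, empty mask.
* Problem sizes in the test suite (64-px phantoms, 200-slice cohorts,
  1,000-trace verification batches, width-16 classifier) were chosen so
  the whole suite runs in minutes on one CPU; all are configurable
  upward.

## Known limitations

* The constraint set is a small, fixed rule family; thresholds are
  conventions, not fitted quantities, and C3's default is
  phantom-calibrated.
* The solver handles exactly the fragment the encoder emits; it is not
  a general SMT solver.
* Phantom realism is deliberately minimal (see above); headline
  accuracies on real clinical data are out of scope and no claim about
  them is made or tested.
* The reference CNN is a low-capacity baseline for exercising the audit
  loop, not a competitive classifier.
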