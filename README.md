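# fdtaudit

Post hoc symbolic auditing for slice-level brain-tumor classifiers.

Deep classifiers for axial post-contrast T1-weighted MRI slices (four
classes: glioma, meningioma, pituitary tumor, no tumor) output a softmax
vector and nothing else. For clinical accountability one wants more: a
check that each prediction is *consistent with observable radiologic
features*, and an audit trail proving what was checked. `fdtaudit`
implements that verification layer, together with the class-weighted
training, partitioning, and metric machinery needed to exercise the full
predict → verify loop on synthetic phantoms, with no external data.

## What it does

**Symbolic features.** Three model-independent surrogates are computed
per slice from the raw pixels: in-mask intensity variance after Otsu
segmentation (heterogeneous enhancement), the fraction of the mask in the
central 20% y-band (sellar proximity), and Canny edge density in the
outer 10% border band (dural-contact proxy).

**Constraint verification.** Neuroradiologic rules are guarded threshold
tests, e.g.

> C1: IF predicted glioma THEN enhancement_variance > 0.1

Each decision is recorded as a formal decision trace
T = ⟨s₀, a₀, s₁, a₁, …, sₙ⟩ and encoded into quantifier-free linear real
arithmetic (QF_LRA): feature values become exact decimal real constants,
classes become Boolean selectors, rules become tracked implications. The
conjunction Φ = ⋀ᵢ φᵢ is decided exactly (rational arithmetic); UNSAT
verdicts come with an unsat core naming the violated rules. A second,
fully independent Boolean evaluator re-checks every rule directly; any
disagreement between the two channels is flagged for manual review.

**Tamper-evident artifacts.** Trace, formulas, verdict, certificate and
metadata are canonically serialized and attested with a SHA-256 digest;
any single-byte mutation of the record is detectable.

**Class-weighted learning.** Inverse-frequency weights w_c = 1/f_c,
normalized so Σ w_c^norm equals the number of classes, feed a weighted
cross-entropy L = −Σ_c w_c 𝟙[y=c] log p_c. A small NumPy reference CNN
(two residually connected conv blocks → GAP → dropout → FC) trains on
phantom cohorts in minutes on a CPU; any external model plugs into the
audit loop through the same `PreprocessedSlice -> Prediction` contract.

**Phantoms.** A generator renders four-class slice phantoms whose three
symbolic features are *analytically known at generation time*, with
configurable class imbalance — every stage above is testable end to end
without downloading anything.

## Worked example

A correctly predicted glioma slice whose segmented-region variance is
0.098 — just under the 0.1 heterogeneous-enhancement threshold:

```python
from fdtaudit import (SymbolicFeatures, Prediction, build_trace,
                      default_constraints, dual_channel_verify)

cs = default_constraints()
features = SymbolicFeatures(
    enhancement_variance=0.098, sellar_band_overlap=0.7,
    border_edge_density=0.2, mask_area=412,
)
pred = Prediction("glioma", (0.91, 0.03, 0.03, 0.03))
trace = build_trace("slice_0042", features, pred, model_id="swin-external")
result, agreement = dual_channel_verify(trace, cs)
print("verdict:   ", result.status)
print("unsat core:", result.violated_ids)
print("agreement: ", agreement)
```

prints

```
verdict:    UNSAT
unsat core: ['C1', 'C4']
agreement:  True
```

The verdict is UNSAT because the glioma guard demands variance
strictly above 0.1; the core names both rules sharing that predicate
(C1 and the C4 consistency invariant). Raising the variance to 0.101
flips the verdict to SAT. `agreement: True` certifies that the solver
channel and the direct Boolean evaluator reached the same verdict.

The command line exposes the same stages:

```
$ fdtaudit weights compute --counts 1608,1768,2251,2413
glioma      n= 1608 f=0.2000 w=5.0000 w_norm=1.2157
meningioma  n= 1768 f=0.2199 w=4.5475 w_norm=1.1057
pituitary   n= 2251 f=0.2800 w=3.5717 w_norm=0.8684
no_tumor    n= 2413 f=0.3001 w=3.3320 w_norm=0.8101
sum of normalized weights: 4.000000
```

The minority classes (glioma, meningioma) receive weights above 1, the
majority classes below 1, and the normalized weights sum exactly to the
number of classes, preserving the loss scale.

```
$ fdtaudit phantom generate --counts 2,2,2,2 --seed 42 --out cohort --image-size 64 --no-rim
$ fdtaudit audit run --manifest cohort/manifest.csv --out audit_out
{"n_slices": 8, "sat_pct": 75.0, "unsat_pct": 25.0, "unsat_correct_label_pct": 0.0,
 "unsat_incorrect_label_pct": 25.0, "dual_channel_agreement_pct": 100.0}
```

Per-slice `*.fdt.json` artifacts land in `audit_out/artifacts/`, each
carrying its SMT-LIB rendering, verdict, certificate, and digest.

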