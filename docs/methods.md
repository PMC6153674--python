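# Methods

## Problem and labels

Fetoscopic TTTS laser therapy is segmented frame-by-frame into three
phases. *Ablation* is visually salient: a high-intensity blue laser spot
and tissue whitening into a coagulated blob. *Targeting* shows the
low-power green aiming spot. *Other* covers everything incompatible with
imminent ablation: laser off, umbilical-cord occlusion, the scope too far
from the placenta. The targeting/other boundary is ambiguous for human
annotators, so ground truth uses only the binary projection *ablation* vs
*not-ablation*; the three-way label is recovered at inference time
(below). Frames are classified independently — no temporal model.

## Binary classifier

A strided convolutional network with a pooling head and a two-way softmax.
Scores are softmax probabilities, so the two scores of a prediction sum to
one and scores from different inference passes are directly comparable.
Three head variants adapt a stride-32 classification backbone to the input
resolution:

| variant | input | final map | head |
| --- | --- | --- | --- |
| `downsample224` | 224 px | 7×7 | global average pool |
| `avg448` | 448 px | 14×14 | enlarged (full-map) average pool |
| `maxavg448` | 448 px | 14×14 | 7×7-kernel average pool, stride 7, then spatial max ("maximum over averages") |
| `small_cnn` | 64 px | 8×8 | global average pool |

The engine is plain numpy (im2col convolutions, manual backprop, SGD with
momentum 0.9); inference is bitwise deterministic, which the channel-swap
symmetry guarantee below relies on. No pretrained weights ship with the
package; requesting them raises rather than silently using a random
initialisation. The published full-scale fine-tuning recipe (30000
iterations, learning rate 1e-5, batch 4) is kept as the `PAPER_TRAIN`
profile for the 224/448 variants; the desk-scale default (`DESK_TRAIN`) is
`small_cnn`, 1000 iterations, batch 8, learning rate 0.01.

**Input normalisation.** Each input image is standardised to zero mean and
unit variance over all pixels and channels. Fetoscope light sources range
from very bright to very dim between procedures, and ablation frames are
systematically the brightest, so absolute intensity is a confound that
does not transfer across procedures; standardisation forces chromatic and
structural cues. The statistic pools channels, so it is invariant under a
green/blue swap and preserves score symmetry bitwise. The learning rate
was chosen for stable convergence of the training loss across folds
(0.003–0.01 converge cleanly; ≥0.03 collapses to the constant classifier).

**Training data.** Complete procedures are heavily imbalanced towards
*not-ablation*, so training sets subsample the majority class to exact 1:1
parity (minority kept whole, uniform random majority subset, seeded). The
laser tool keeps a fixed image orientation within one procedure but an
arbitrary one between procedures, so every training image is randomly
rotated (uniform 0–360°, redrawn each visit, bilinear, black fill;
quarter-turns are exact array rotations). Validation sequences are never
balanced or rotated.

## Channel-swap complete classification

A *targeting* frame is defined as an image that would be classified
*ablation* if its green and blue channels were exchanged. The same trained
binary detector therefore runs twice per frame — on the original image
(ablation score) and on its green/blue-swapped copy (targeting score).
Arbitration at threshold τ (default 0.5, ties positive):

- both below τ → *other*;
- only ablation pass ≥ τ → *ablation*;
- only targeting pass ≥ τ → *targeting*;
- both ≥ τ → the larger score; exact score ties go to *ablation* (the
  clinically costlier miss; configurable).

Whether "score" means probabilities or logits is immaterial for a shared
model (softmax is monotone); probabilities are used so the comparison is
well-posed. The pipeline's *filtering action* follows structurally: a
frame can only remain *ablation* if the original pass fired, so filtered
positives ⊆ raw positives, recall can only drop, and precision rises
whenever the relabelled frames are mostly false positives. Timelines are
maximal constant-label runs over half-open index ranges.

## Evaluation

Precision `p = tp/(tp+fp)`, recall `r = tp/(tp+fn)`, F-measure
`f1 = 2/(1/r + 1/p)`. A zero denominator yields NaN ("undefined"), which
propagates to f1 and is excluded from cross-fold means — never coerced to
0 or 1, since any such coercion would fabricate a convention. Metrics are
printed at two decimals; serialised reports keep full precision.
Cross-validation is leave-one-procedure-out (one fold per procedure;
procedure-level k-fold is available as an option). Cumulative confusion
tables are cell-wise sums over folds. PR curves sweep an even grid of 101
thresholds on [0, 1]; for the filtered method the prediction at τ is
"arbitration kept *ablation* AND score ≥ τ"; sweeping the raw score
instead is available behind a flag. Points with undefined precision are
omitted.

## SVM + histogram baseline

Joint HSV histogram, 16 equal bins per channel (4096 bins, H-major
flattening), counted inside the scope disc only — the black border would
otherwise dominate every histogram (a documented choice). Variance-ranked
PCA to at most 1000 components, capped by the rank bound
min(n_samples−1, 4096) with a warning; "most discriminant" is read as
variance-ranked. RBF-kernel SVM with C=1 and gamma=1/n_features (no
published setting; grid search is external). The variant that drops the V
channel is documented as tried-and-worse and deliberately not implemented:
the flag exists and raises. PCA and SVM are scikit-learn; features and
masks are computed in-package.

## Synthetic data generator

The simulator emulates the appearance factors reported for clinical
sequences, not their photometric detail (no quantitative spot photometry
is published; all intensity ratios are simulator choices):

- **Scene** (per procedure): centred circular scope mask
  (radius 0.82–0.95 of the half-width); reddish placenta base with a
  smooth texture field and radial vignette; light intensity 0.55–1.0
  (bright) with dedicated dim (0.25) conditions; turbidity blends towards
  a gray haze (0–0.3, turbid procedure 0.7); Gaussian defocus blur;
  per-pixel Gaussian sensor noise (σ = 0.02, applied after compositing); a
  dark fibre tool entering at a per-procedure fixed angle.
- **Spot photometry**: Gaussian radial profile (σ = 0.045 of the image
  width) near the tool tip with per-frame jitter. Targeting tint is
  green-dominant; ablation tint blue-dominant at 2.2× the targeting peak
  (the "increases in intensity and turns blue" cue) plus a flat white
  coagulation blob whose amplitude (0.30) deliberately leaves the green
  and red channels below saturation, so blue remains strictly dominant
  after clipping.
- ***Other* frames** arise three ways, drawn per frame: laser off, cord
  occluder over the spot, or defocus with a faint wide spot (scope
  drifted).
- **Matched pairs**: with a channel-balanced (R=G=B) background, the
  ablation member is constructed as the exact green/blue swap of the
  targeting member — same geometry, background, and noise realisation —
  making swap symmetry testable to zero pixel error. Chromatic
  backgrounds are refused.
- **Studies**: with ≥5 procedures the generator fixes one turbid, one
  dim, and one weak-spot (0.12 peak) procedure among bright ones,
  mirroring the clinical study's five-sequence variability. Output is
  PNG frames + a labels CSV per procedure + a JSON manifest of every
  parameter and seed. All rendering is deterministic per seed.

What passing tests on this data do **not** show: robustness to real
placental texture, vessels, specular highlights, foetus motion, scope
optics, or annotation noise. The simulator makes the binary task
separable by construction; cross-procedure transfer under the appearance
shift is the only generalisation it probes.

## Problem sizes

The test suite and the acceptance script use a 5-procedure study, 110
frames per procedure, rendered at 160 px (the generator's default is
448 px, the published input size), with the `small_cnn` desk profile.
These sizes were fixed as the package's desk-scale study conditions; the
full leave-one-out run takes about a minute on one CPU. The end-to-end
recovery check holds out the first (bright) procedure; the weak-spot
procedure mirrors the clinical worst case and is reported, not bounded.

## Known limitations

- The 224/448 variants share the small numpy backbone geometry; they
  realise the published head adaptations but not a 101-layer residual
  network, and no ImageNet initialisation is available.
- The SVM baseline's hyperparameters are library defaults; its reported
  weakness is partly by construction (colour histograms cannot transfer
  across the simulated lighting shift, which is the point of the
  comparison).
- Undefined (NaN) fold metrics are excluded from means, so a mean over
  folds can rest on fewer than five values; serialised reports always
  carry the per-fold table.
- Two-fold cross-validation is mentioned in one published summary while
  the detailed protocol is leave-one-out over five sequences; this
  package implements leave-one-out and exposes k-fold as an option.
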