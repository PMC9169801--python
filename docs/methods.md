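# Methods

`xleaf` implements an explanation-guided model-improvement loop for image
classifiers: train, explain, encode expertise as per-pixel annotations,
retrain with a right-for-the-right-reasons penalty, and quantify whether the
retrained model both performs and *attends* better. This note records the
model, the defaults, and the design decisions, in enough detail to reproduce
or criticize them.

## The four-step loop

Given a labeled image dataset, `pipeline.run_framework`:

1. trains a baseline CNN with cross-entropy;
2. computes Grad-CAM explanations of the baseline;
3. attaches a binary **annotation matrix** `A` to each sample
   (1 = useless pixel). For the synthetic tasks these are generated
   automatically (see below); for real data they come from the manifest. A
   zero matrix opts a sample out of guidance entirely;
4. retrains from a fresh, identically seeded initialization with the
   combined loss, then assesses both models on the identical test split.

Both trainings use the same data, architecture, epoch count, optimizer and
batch schedule, so the comparison isolates the loss change.

## Grad-CAM

For network `M`, image `X` (U×V×B) and class `c`, with feature maps
`A^1..A^K` (P×Q) taken at the last convolutional stage (post-ReLU), the
channel weights are globally averaged gradients of the **pre-softmax** class
score `y^c`:

    w_k^c = (1/(P·Q)) Σ_ij ∂y^c/∂A^k_ij

and the explanation is

    G(M, X, c) = Trans(ReLU(Σ_k w_k^c A^k)),

where `Trans` is corner-aligned bilinear interpolation to U×V
(`scipy.ndimage.map_coordinates`, order 1: exact on constants, never
overshoots the input range). Heatmaps are stored unnormalized; the
assessment metrics max-normalize internally. Assessment explanations use the
sample's true class by default (`class_choice="predicted"` switches to the
argmax class); which of the two a given study used is rarely reported, so it
is explicit here.

## The balanced right-reasons loss

The guided training minimizes

    NLoss = CLoss + λ · Balance(RLoss, CLoss)
    Balance(l1, l2) = 10^⌈log10(l2/l1)⌉ · l1

where `CLoss` is batch-mean cross-entropy and `RLoss` the input-gradient
penalty. The input gradient is taken on the log-transformed class
probabilities,

    Grad_X = ∂ Σ_c ln(ŷ_c + 1) / ∂X ,   ŷ = softmax(f(X)),

and the default penalty squares the annotation-masked gradient and averages
per-sample sums over the batch:

    RLoss = mean_i Σ (A_i ⊙ Grad_{X_i})².

Probabilities (not raw logits) are used inside the logarithm because
`ln(y+1)` is undefined for logits ≤ −1; with probabilities the target is
finite everywhere. The square guarantees `RLoss ≥ 0`, which `Balance`
requires; a `literal_sum` variant (no square) is selectable for comparison.
The annotation matrix is U×V and is broadcast across the image channels.

`Balance` brings the penalty into the decade of the classification loss
(`l2 ≤ Balance(l1,l2) < 10·l2`, positively homogeneous), so one λ transfers
across tasks whose raw gradient magnitudes differ by orders of magnitude.
Task defaults: λ = 1.5 for the fake-vs-real task, λ = 2 for the disease and
species tasks.

### When to evaluate Balance (`balance_mode`)

Where in training the rescaling is evaluated turns out to be decisive, and
is configurable:

* **`per_batch`** recomputes `Balance` from each batch's loss values. This
  is the literal reading of the formula, but it creates a positive feedback
  loop: the rescaling factor grows like `CLoss/RLoss` while the squared
  penalty's own gradient shrinks only like `√RLoss`, so the balanced term's
  gradient diverges as the penalty succeeds. On small models this reliably
  drives training into a constant predictor (for the `ln(ŷ+1)` target the
  uniform output is additionally a stationary point of the penalty, which
  reinforces the attractor). At large scale, where raw `RLoss` starts in the
  same decade as `CLoss`, the amplification is mild and the mode behaves.
* **`calibrated`** (default) treats `Balance` as a one-time decade
  calibration: the first `warmup_frac` (default 1/3) of the epochs run plain
  cross-entropy, then the rescaling factor is computed once from the first
  penalized batch and held fixed. The penalty enters at the same order of
  magnitude as the classification loss — the stated purpose of `Balance` —
  but cannot chase `RLoss` downward, so training remains stable at any
  scale.

Both modes satisfy the exact reduction contracts: λ = 0, or all-zero
annotation matrices, give a trajectory bit-identical to plain cross-entropy
(the guard that skips the penalty when `RLoss ≤ 1e−12` makes the reduction
exact, not approximate).

## Explanation assessment

With the normalized explanation `a ∈ [0,1]^N` (flattened, max-normalized;
all-zero heatmaps pass through) and the **assessment mask** `b ∈ {0,1}^N`
(1 = useful-region pixel, the complement of the annotation matrix):

    RMSE    = √(Σ (a_i − b_i)²/N)                    lower is better
    CosineS = Σ a_i b_i / (‖a‖‖b‖)                    higher is better
    PIP@p%  = |IP ∩ RM| / |IP|,                       higher is better

where `IP` is the set of the `⌈N·p/100⌉` highest-valued explanation pixels
(ties broken toward the lowest flat index — PIP is discontinuous in ties, so
the rule is fixed and documented) and `RM = {i : b_i = 1}`. PIP is reported
in percent, at 1, 5 and 10% by default; a warning fires when `p/100` is not
below `|RM|/N`, where the score saturates.

`assess_model` averages the three metrics over a split, computing one
explanation per sample (true class). Exclusions, counted and reported rather
than imputed: samples whose assessment mask is trivial (all-zero or all-one
— such a mask cannot rank explanations; PIP is identically 1 against an
all-ones mask) are skipped for the three metrics; all-zero heatmaps are
additionally skipped for the cosine (undefined). Accuracy is always computed
over the full split.

## The synthetic scene generator

`leafsim` renders procedural leaf scenes — an ellipse-union silhouette with
low-amplitude color texture, green-dominant, on a contrasting background —
with the foreground mask known exactly. Three tasks:

* **fake_vs_real** — class 1 images receive 1–5 transparent circles (radius
  5–15% of the image side, opacity 0.3–0.7, centers uniform over the frame,
  so circles may fall in the background), alpha-blended toward the
  background color to imitate the thinning of diseased tissue. The
  annotation marks everything outside the circles as useless; the assessment
  mask is the circle region. Circle-free class-0 images carry the zero
  (opt-out) annotation: a circle-free image has no lesion reference, and the
  literal complement (an all-ones annotation) measurably destroys training
  by suppressing input sensitivity on half the dataset.
* **diseased_vs_healthy** — class 1 leaves receive opaque brown blotches
  inside the foreground; the annotation is the exact scene background (for
  real photographs an external foreground extractor can fill the same
  manifest columns).
* **species** — two or three procedurally distinct silhouettes (round /
  elongated / trilobed); the annotation is everything strictly outside the
  leaf's minimum axis-aligned bounding rectangle (bounds inclusive, 0-based
  row-major coordinates).

Everything is deterministic given (config, seed): per-sample seeds derive
from the dataset seed, and splits are stratified per class with
largest-remainder allocation (per-class split counts differ by at most 1).

A fourth generator, `build_watermark_dataset`, builds the
spurious-correlation benchmark: fake-vs-real scenes whose class-1 training
images additionally carry a bright 6×6 top-left watermark, absent from the
test split; every training annotation marks exactly that corner. Its default
circle opacity is reduced to 0.2–0.45 so that the watermark is decisively
the easier cue — the benchmark needs an unguided learner to actually take
the shortcut. These values were fixed once, from pilot runs of the
generator, before the comparison experiments were frozen.

What the simulator does **not** emulate: photographic texture, lighting,
occlusion, camera noise, background clutter, or label noise. Results on it
bound what the pipeline can do when masks are exact and the signal is known;
they say nothing about mask quality on real images, where foreground
extraction itself is an estimate.

## Networks, training, numerics

Two architectures, both ending in a convolutional stage as Grad-CAM
requires. `tiny` (default): a fixed input normalization ([0,1] → [−1,1]),
three stride-2 3×3 convolutions (8/16/32 channels, ReLU), global average
pooling, one linear head — trains in seconds on a CPU. `alexnet_like`: the
classic five-conv/three-FC layout with max-pooling, global average pooling
in place of the fixed-size adaptive pool so any input ≥ 64×64 works; kept
for full-scale runs, untested at full scale here.

Defaults: He-normal initialization (seed-deterministic), Adam, learning rate
3e−3, batch 16. These were chosen because at the desk-scale study size (a
few hundred 64×64 samples, ~15 epochs) smaller rates leave the tiny model at
chance; the fixed input normalization is what makes the task conditioning
sane. All values are configurable; full-scale defaults from the source
experiments (90/60/90 epochs, λ 1.5/2/2) are preserved in
`pipeline.DEFAULT_EPOCHS` / `DEFAULT_LAMBDA`.

All tensor math runs in float32 on a small reverse-mode autodiff engine
(`xleaf.autodiff`) written for this package: convolution and pooling are
expressed through gather/scatter-add and matmul primitives whose backward
rules are themselves graph operations, so the double backpropagation the
penalty needs (∂/∂θ of ∂/∂X) is exact rather than approximated. Training is
deterministic on fixed hardware; NaN losses abort with the offending
component named.

## Known limitations

* **Broad-region guidance at miniature scale.** When the annotation covers
  most of the image (the fake-vs-real task marks ~90% of pixels useless),
  the balanced penalty — at its task default λ = 1.5, in either balance
  mode — typically costs the tiny model several points of accuracy and
  moves the heatmaps *away* from the reference masks. The package's own
  desk-scale comparison (`tests/test_acceptance.py`, direction test;
  `scripts/acceptance.py`) computes and reports exactly this. The mechanism
  is the one described under `balance_mode`: keeping the penalty pinned to
  the decade of the classification loss is a heavy constraint for a model
  with three conv layers and a few hundred training images. Guidance on
  *narrow* spurious regions (the watermark benchmark, <1% of pixels) is
  where the desk-scale effect is reliably positive.
* Grad-CAM resolution is bounded by the last conv stage (8×8 for 64×64
  inputs on `tiny`); sub-cell localization comes only from bilinear
  upsampling.
* The cosine and PIP metrics compare against binary masks; graded notions of
  pixel importance are out of scope, as are other attribution methods.
* `load_dataset` trusts the manifest's masks; no consistency check between
  annotation and assessment columns is enforced beyond shape.
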