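# Methods

## The model

`depfuse` implements a two-stream deep belief network (DBN) recognizer for
facial-expression-based depression-risk screening, with all numerical
machinery written from first principles on top of `numpy`.

**2D static appearance stream (2D-SADN).** Each 100×100 RGB face crop is
split into its R, G and B channels, flattened, and fed to one four-layer
DBN per channel (hidden sizes 8192–4096–2048–502 at full scale). Each
channel DBN carries a logistic output unit; the stream's probability is
the arithmetic mean of the three channel outputs and its fused feature is
the element-wise sum of the three 502-d top activations.

**3D dynamic geometry stream (3D-DGDN).** Each Kinect frame contributes
the 3-D coordinates of 1,347 facial landmarks, z-scored per frame and per
coordinate set (all x of frame t together, likewise y, z; Eq. below), plus
17 z-scored AU intensities:

    x̄_i(t) = (x_i(t) − μ_t) / σ_t      (population σ, divisor N)

The 4041-d landmark vector passes a three-hidden-layer DBN
(3000–2048–1024); the 1024-d penultimate activation is concatenated with
the 17 AUs and fed to a top-level Gaussian–Bernoulli RBM (1041→150). The
per-frame 150-d feature sequence runs through a two-layer (200, 64) LSTM
and the session is scored from a logistic unit on the final hidden state.
The intermediate named variants (`4dbn`, `4dbn-au`, `au-4dbn`) score
frames individually and average over the session.

**Fusion.** The reported decision rule is the log-odds sum
ŷ = σ(logit(p_2D) + logit(p_3D)). A separate fully connected sigmoid head
over the concatenated (502+64)-d top features produces ŷ_2D-3D, whose
cross-entropy is the third term of the joint fine-tuning loss

    L = λ1·L_2D + λ2·L_3D + λ3·L_2D-3D,   λ = (1, 1, 0.1).

Gradients of L flow into both streams and the head; class 1 is predicted
iff the fused output ≥ 0.5 (ties go to class 1).

## Energy model conventions

The printed literature form of the Gaussian–Bernoulli energy carries a
doubled "/2" and scales the hidden-bias term by 1/σ²; we use the standard
self-consistent form

    E(v,h) = Σ_i (v_i−a_i)²/(2σ²) − (1/σ²) Σ_ij w_ij v_i h_j − Σ_j b_j h_j

whose derived conditionals are P(h_j=1|v) = σ((Wᵀv)_j/σ² + b_j) and
P(v|h) = N(a + Wh, σ²I). With σ = 1 (the default — all inputs are
standardized) every printed variant coincides. Exhaustive-normalization
oracles in the test suite verify the conditionals against exp(−E) to
1e−10. In the LSTM cell update the previous cell state C^(t−1) enters the
forget product (one printed source shows C^(t+1), a typographical slip).

## Training procedure

1. **Greedy CD pretraining.** Each RBM trains with CD-k (k = 1 default)
   on the hidden-probability representation of its predecessor;
   minibatch updates with momentum 0.9, learning rate 0.02, weights
   initialized N(0, 0.01), biases zero. A Lee-style sparsity penalty
   (weight 3, target 0.1) on the hidden-bias gradient is applied to the
   first 2D-SADN layer only.
2. **Per-stream supervised fine-tuning.** Channel DBNs are fine-tuned by
   backpropagation on binary cross-entropy; the 3D head stack (top RBM
   weights as a feedforward layer, LSTM, logistic head) is trained by
   BPTT with the base DBN frozen.
3. **Joint fine-tuning.** Full backpropagation of the weighted
   three-term loss through both streams, the LSTM, the top RBM and the
   fusion head.

### Numerical conditioning at reduced scale

Two conditioning devices keep short training schedules healthy; both are
configuration switches (`rescale`) that leave the mathematical model
unchanged:

* **Inter-layer standardization.** During greedy pretraining each layer's
  input representation is standardized per dimension and the affine map
  is absorbed into that layer's weights and biases
  (`rbm.absorb_input_affine`), so the returned model needs no external
  scaling. Without it, activation variance collapses exponentially
  through a freshly initialized sigmoid stack and the published 100-epoch
  schedules are the only escape.
* **Unit tempering.** After CD, any hidden unit whose pre-activation
  spread exceeds the sigmoid's quasi-linear range (SD > 1.5) is rescaled
  to it. Saturated units quantize their inputs to near-binary values,
  burying graded appearance information and blocking fine-tuning
  gradients.

The absorbed layers are recognition-exact: the hidden conditional equals
the one trained in standardized coordinates. The generative direction is
only approximately mapped back, which the discriminative pipeline never
uses.

The model-level `InputStandardizer` similarly centers all three input
streams against the training cohort (deviation from the mean face), with
statistics estimated on training subjects only.

At desk scale the 2D stream scores the session's temporal-mean frame per
channel rather than averaging per-frame probabilities: static appearance
is a subject-level trait, and averaging pixels before the network removes
frame noise ahead of the nonlinearity. The per-frame scoring operation
(`sadn2d_predict`) remains available and tested. A frame-level
discriminative pass over the 3D base DBN is likewise available
(`ft3d_base`) but disabled in the workstation schedule, where it
memorized training subjects without improving held-out sessions.

### Validation-based selection and calibration

The evaluation protocol reserves one fold of subjects per round for
validation; the pipeline uses it in two ways:

* **Restart selection.** Channel fine-tuning and the LSTM stage are run
  from a few random restarts and the restart with the best validation
  session accuracy is kept (`restarts2d`/`restarts3d`).

**Fusion calibration.** The raw log-odds sum is dominated by whichever
stream is most overconfident — after supervised fine-tuning the 2D
stream's training probabilities saturate, so its logits can be an order
of magnitude larger than the 3D stream's. The shipped fused decision
therefore normalizes every vote by the standard deviation of its
*training-set* log-odds (floored at 1, so a vote is never amplified) and
adds the trained fusion head as a third vote:

    ŷ = σ( l_2D/s_2D + l_3D/s_3D + l_head/s_head )

This is label-free — no validation labels enter the rule — and shrinks
exactly the votes whose confidence outruns their information. Labeled
slope-only (Platt temperature) calibration on the validation subjects is
also implemented (`TwoStreamResults.calibrate`) but is not the default:
with four validation subjects per round its slope estimates proved
noisier than the label-free scales.

## Synthetic cohort generator

The generator emulates the study design: gender × group balanced cells,
5 stimulus tasks × 3 valences per subject (15 sessions), aligned image
and landmark/AU streams subsampled one-in-100 from the raw frame rate,
and SAM valence/arousal ratings before and after every stimulus.

A single scalar expression state s(t) drives all modalities per session:
an onset–apex–offset envelope scaled by the stimulus valence plus AR(1)
jitter (ρ = 0.95). The class signal, controlled by `effect_size` e:

* depressed amplitude under ±valence is blunted by 1/(1+0.6e), short-time
  variability by 1/(1+0.3e), with a small negative drift; neutral
  sessions are generated identically for both groups;
* the depressed group's baseline mouth curvature (a subject trait
  rendered into the images) is shifted by −0.2e against a between-subject
  SD of 0.2;
* SAM deltas interpolate between the healthy pattern (shift follows the
  stimulus sign, larger arousal response) and a blunted, non-positive
  pattern.

All class differences vanish at e = 0, which the null-calibration checks
rely on. Faces are parametric (oval, eyes, mouth arc whose mean row
position is strictly monotone in the state); landmarks are a fixed
Fibonacci-lattice half-ellipsoid template deformed by mouth/brow modes
plus sensor jitter. The generator does **not** emulate photorealistic
texture, identity variation beyond the two trait axes, head pose, or
real Kinect noise spectra — passing tests demonstrate that the pipeline
recovers a planted signal of this structure, not performance on clinical
data.

Presets: `tiny` (8 subjects, 16×16 images, unit tests), `desk`
(40 subjects, 32×32 images, 300 raw → 10 stored frames per session,
layer widths 1/16 — the cross-validation experiments), `paper-shape`
(52 subjects per cell, full sizes). At workstation scale sessions store
only the frames that survive subsampling; the state trajectory is still
simulated at the raw rate. The desk preset keeps ten stored frames per
session (interval 30) so the sequence model sees an actual trajectory;
a three-frame session leaves a recurrent model nothing to integrate.

## Evaluation harness

Folds are subject-wise, stratified by label and gender, with rotating
roles (test = fold r, validation = fold r+1, train = rest), reproducing
the 42/5/5 split for a 52-subject stratum. Accuracy is (TP+TN)/total at
the session level; subject-level leakage is asserted programmatically in
every round. The SAM analysis reports per task × valence group means of
the post−pre deltas with Welch two-sample p-values flagged at p < 0.1
(the study's threshold); no multiplicity correction by default, with an
optional Benjamini–Hochberg switch.

For the null-calibration check the binomial band around 0.5 is computed
with n = 40 (the number of subjects), not the number of sessions: the 15
sessions of one subject share that subject's traits, so the subject is
the independent unit under subject-wise cross-validation.

## Problem sizes and schedules

The cross-validation experiments use the desk preset and the `fast()`
training schedule (5 CD epochs on ≤600 frames per layer; 60/200 epochs
of stream fine-tuning; 4 joint epochs; 2 validation-scored restarts per
stream) — chosen as a workstation-scale working point; the `paper()`
profile reproduces the published 100/50-epoch schedules for full-scale
runs. The null-calibration CV drops restarts and shortens the LSTM and
joint stages since there is no signal to select for.

## Known limitations

* The generative direction of rescaled/tempered layers is approximate;
  sampling from the DBN as a generative model is not supported there.
* The LSTM variant scores a session from the final hidden state only;
  very long sessions would benefit from pooling over time.
* Slope-only fusion calibration is fit on as few as four validation
  subjects per round and is accordingly noisy; per-valence calibration is
  implemented but off by default for that reason.
* Desk-scale accuracies are not estimates of the published full-scale
  clinical results; the private dataset cannot be reproduced.
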