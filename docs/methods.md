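# Methods

## The model

`sctrnnpb` implements a stochastic continuous-time recurrent neural
network with parametric bias (S-CTRNNPB), a hierarchical predictive-
processing model of how emotion categories can self-organize from the
dynamics of facial expressions, and how that process degrades when the
intrinsic excitability of the network is made homogeneous (an ASD-like
manipulation).

The network has three levels. A small set of **parametric-bias (PB)**
units forms the top of the hierarchy: their internal state is constant
across the time steps of a sequence, so whatever they encode is by
construction sequence-level (abstract) rather than moment-to-moment. A
recurrent **lower level** of leaky-integrator neurons carries the
short-term dynamics. Two non-recurrent **output heads** read the lower
level out into a predicted mean `y` and an estimated variance `v` of the
next sensory input.

Internal states update as

    u_t[PB]    = u_{t-1}[PB]
    u_t[lower] = (1/tau) (W_x x_t + W_l l_{t-1} + W_p p_t + a)
                 + (1 - 1/tau) u_{t-1}[lower]
    u_t[head]  = W_y l_t + a

with `p = tanh(u)` (PB activity), `l = tanh(u)` (lower activity),
`y = tanh(u)` (predicted mean) and `v = exp(u)` (estimated variance).
Learning minimizes the precision-weighted Gaussian negative
log-likelihood per feature and step,

    L = ln(2 pi v)/2 + (y_hat - y)^2 / (2 v),

summed over features, steps and sequences. Because the squared error is
divided by the estimated variance, the network weighs each prediction
error by the precision it attributes to that input — the core
predictive-processing quantity. The loss is accrued from the second
target step onward: the first step has no preceding input to predict
from.

**Intrinsic-excitability heterogeneity.** Lower-level activity
thresholds are drawn once from `a_i ~ N(0, K)` and never updated. `K` is
the variance of that draw. At `K = 1000` (heterogeneous,
typical-development condition) many thresholds are so large that their
neurons saturate near ±1 and effectively drop out, leaving a smaller
*functional* network; at `K = 0.001` (homogeneous, ASD-like condition)
every neuron sits at the sensitive center of tanh and the full anatomical
network is recruited.

**Training (developmental learning).** Full-batch gradient descent
(Adam) jointly optimizes all weights, the output-head thresholds, and one
PB internal state per training sequence. Emotion labels never enter the
computation; the geometry of the PB space is shaped only by the demand of
predicting each sequence with shared weights. Gradients are exact
backpropagation through time, hand-derived and verified against central
finite differences to < 1e-5 relative error in the test suite.

**Recognition (error regression).** For an unseen sequence the weights
are frozen and gradient descent runs on the PB state alone, minimizing
the same precision-weighted NLL with teacher-forced inputs. The best
iterate (lowest NLL seen) is returned, so inference never ends worse than
its zero initialization. Emotion is read out by the nearest training-
emotion centroid in PB-activity space; no classifier is trained.

## Synthetic facial-expression data

The generator emulates onset-to-peak facial expression movies: 9 landmark
displacement channels per sequence, six basic emotions with fixed,
pairwise-distinct peak displacement patterns, and a logistic ramp in
normalized time carrying each channel from a neutral start toward its
peak. Per-sequence variation comes from a mean-one lognormal amplitude
jitter (sigma 0.2), per-channel phase jitter on the ramp midpoint (sd
0.05 in normalized time), a uniform baseline offset per sequence and
channel on [-1, 1], additive Gaussian observation noise (sd 0.02 in raw
landmark units), and lengths uniform on [10, 40] steps.

The ramp midpoint sits at 25% of the movie with steepness 5, so motion
begins essentially at the first frame and the expression holds near its
peak toward the end. This mirrors how onset-to-peak clips are trimmed in
practice. It also matters for the science: if the face instead stayed
frozen for the first half of every movie, the early frames would carry no
emotion information at all and the sequence-level code would be dominated
by *onset timing* rather than emotion — the PB space then organizes
around speed, not category. The baseline offsets exist so that
first-frame normalization has an observable effect, which is what makes
the normalization ablation meaningful on synthetic data.

What the generator does **not** emulate: real landmark trajectories are
not rank-one in space-time (different facial regions move with different
time courses), subjects differ in facial geometry beyond an additive
offset, and CK+-style data has tracking artifacts and non-monotone
dynamics. Passing tests on this generator show that the model family
behaves as described on idealized expression dynamics; they are not
evidence about any specific real dataset.

## Preprocessing

Two steps produce the target sequences. *Mapping to normal face*
subtracts each sequence's first frame, so every feature starts at exactly
zero; this unifies the neutral configuration across sequences and is the
target of the ablation experiment. *Min-max scaling* then maps each
feature's global minimum/maximum — computed over all sequences and steps
of the fitting set — onto [-0.9, 0.9], inside the linear range of tanh.
Scaling statistics are fit on the training folds only and reused for test
folds (the test phase must not peek); test values that consequently
escape the band are left unclipped so the prediction-error signal is not
distorted. Feature reduction (dropping channels whose range is below 5%
of the median channel range, then greedily dropping channels with
absolute Pearson correlation above 0.95 against an already-kept channel)
is available but off in the synthetic pipeline, which already emits nine
informative channels.

## Parameters that matter

| parameter | default | meaning / why |
| --- | --- | --- |
| `n_lower` | 50 (desk scale); 500/1000 full scale | lower-level neurons |
| `n_pb` | 2 | PB dimensionality; 2 permits direct scatter plots |
| `K` | 1000 / 1 / 0.001 | threshold variance; the experimental manipulation |
| `tau` | 2 | shared lower-level time constant; leaky integration with tau > 1 |
| `variance_floor` | 1e-6 | added to `exp(u)`; keeps the NLL bounded below |
| `learning_rate` | 1e-3 | Adam step on weights |
| `pb_learning_rate` | 0.1 | Adam step on PB states during training |
| `input_noise_sd` | 0.15 | sd of Gaussian noise on fed-in values during training |
| `n_iterations` | 15000 | full-batch training iterations |
| recognition lr / iters | 1e-2 / 300 | PB-only error regression settings |

Two of these deserve explanation because the self-organization the model
is known for depends on them:

* **PB learning rate (0.1, ten times the weight rate).** The PB states
  are two numbers per sequence competing against the full weight matrices
  for explanatory power. With equal step sizes the weights absorb all
  structure and the PB states collapse into an undifferentiated blob; a
  larger PB step lets sequences spread out early, and the shared weights
  then organize a smooth PB-to-dynamics map around them, which is what
  groups similar sequences.
* **Input noise during training (sd 0.15 in normalized units).** Fresh
  Gaussian noise corrupts the fed-in values each iteration while the loss
  targets stay clean. Two effects: (i) the learned dynamics become
  contracting around the training trajectories, so the network can
  regenerate them in closed loop (feeding back its own predictions)
  rather than only track them under teacher forcing; (ii) degrading the
  bottom-up input shifts explanatory weight to the top-down PB channel,
  which strengthens emotional clustering. Recognition and evaluation
  always run on clean inputs.

## Numerical choices

* Weight initialization: uniform on ±1/sqrt(fan_in) per connection group;
  head thresholds start at zero; PB states start at zero (the center of
  tanh, unbiased across sequences).
* Gradient clipping at global norm 1.0 over all parameter groups and PB
  states jointly; the variance head can spike gradients early in
  training when `v` is far from the residual scale.
* Averaging order for MSE and mean variance is fixed as steps within a
  sequence, then features, then sequences (then seeds where applicable),
  making reported numbers bit-stable.
* Tolerance maps evaluate a 41 x 41 grid of PB activities on
  [-0.98, 0.98]^2 — strictly inside ±1 because grid activities are mapped
  through the model, and closed-loop generation is seeded with each
  sequence's first target frame.
* Silhouette widths use Euclidean distance in PB-activity space;
  singleton clusters contribute 0, as do exactly coincident
  configurations (0/0 treated as 0). The implementation is cross-checked
  against scikit-learn's in the test suite.
* Checkpoints serialize parameters as JSON; Python's float repr
  round-trips IEEE-754 doubles exactly, so reload is lossless.
* Degenerate inputs fail loudly: sequences shorter than 2 steps,
  features with MAX = MIN, non-finite activations, and non-finite losses
  (reported with the iteration index) all raise.

## The desk-scale study

The standard study trains 24 sequences (6 emotions x 4) with 6 held out
(one per emotion), 50 lower-level neurons, and the training settings
above; comparisons between conditions average 5 seeds. These sizes keep a
full three-condition, five-seed study within minutes on one core while
preserving every qualitative contrast of the full-scale design: the
homogeneous network trains to a lower error but generalizes worse,
estimates higher precision (lower variance), clusters emotions more
weakly in PB space, and recruits its whole anatomical network, whereas
the heterogeneous network leaves a large fraction of neurons near-silent
and tolerates within-emotion variation. The cross-validated
`experiment_runner` supports the full-scale four-condition design
(500/1000 neurons, eightfold CV) for longer runs.

## Known limitations

* The PB space is 2-D by design; with six emotions the clusters can
  overlap, and silhouette values fluctuate noticeably across seeds at
  desk scale. Orderings between conditions are asserted as seed-mean or
  seed-majority properties, not per-seed guarantees.
* Closed-loop regeneration quality depends on the input-noise setting;
  with noise-free training the network tracks well under teacher forcing
  but drifts in closed loop.
* Training-time input noise makes the estimated variance reflect both
  observation noise and the injected noise; absolute variance values are
  therefore not comparable across different `input_noise_sd` settings,
  only across conditions trained with the same setting.
* The model is a rate-coded system-level abstraction; neuron counts and
  `K` values do not map onto biological quantities.
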