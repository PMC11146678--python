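# Methods

## The task and the data model

The package analyses populations of spiking units recorded (or, here,
simulated) during a 9-target instructed-delay reaching task. Each correct
trial traverses four behavioural epochs: **FREE** (home button pressed,
target not yet shown; 1,000 ms), **DELAY** (target fixated, movement
withheld; 1,800–2,300 ms, plus a 200–400 ms reaction time after the go
signal), **MOVE** (the reach itself; drawn 240–480 ms, mean 360 ms) and
**HOLD** (hand on target; 800–1,200 ms). The nine targets form a 3 × 3
direction × depth grid at eye level: version angles −15°/0°/+15°, radial
distances 10/15/25 cm.

All analyses run on *emission sequences*: spike trains are binned at 2 ms
and every bin is replaced by one symbol — 0 when no unit fired, otherwise
the id of the unit that fired. When several units fire in one bin, one is
drawn uniformly at random; the draw is repeated to give 100 sequences per
trial, so the ensemble of sequences retains the information a single
sequence would lose to collisions. Bins holding two or more spikes of the
*same* unit emit that unit's symbol once: symbols carry identity, not
count. Sequence sets keep, per concatenated segment, the alignment event
and window, so sliding windows can be mapped back to trial time and are
never laid across the seam between segments (which is a genuine temporal
discontinuity, not recorded activity).

## Hidden Markov machinery

States form a feedforward (Bakis) chain: from state *i* the process may
stay or advance to *i* + 1; all other transitions are structural zeros.
The initial distribution pins the chain to its first state.

*Unsupervised estimation* is multi-sequence Baum–Welch with expected counts
accumulated over all training sequences per iteration. The structural zeros
are enforced exactly in every M-step. Emission rows receive a smoothing
floor of 1e-6 (added, then renormalized): a symbol that never occurred in
training — in particular the symbol of a unit later removed in the
neuron-loss experiments — must reduce, not annihilate, the likelihood.
Stopping uses the protocol defaults: 500 iterations or a
log-likelihood improvement below 1e-6, whichever comes first. The
forward–backward pass is scaled per bin (no log-space needed) and
implemented as a numba kernel; posterior rows are checked to sum to 1
within 1e-9. EM on these chains has local optima in which one behavioural
state is split and two are merged; estimation therefore restarts from
several pseudo-random initializations (3 for decoding models, 5 for the
consistency analysis) and keeps the highest-likelihood fit. The
initialization draws self-transitions near 0.98 with ±0.01 jitter and
uniform-random emission rows.

*Supervised estimation* bypasses EM: the forward probability of state *i*
is 1 / (mean number of bins spent in epoch *i* in the training sequences),
the last state is absorbing, and emissions are the per-epoch symbol
frequencies (same smoothing floor).

### Consistency analysis (how many states?)

Candidate chains with 2–7 states are fitted per target on movement-centred
(−1,000..+1,000 ms) training sequences and applied to held-out sequences. A
sequence is *consistent* with a K-state model when every state's posterior
exceeds 0.7 at least once. The codified selection rule — the largest K
whose pooled consistent fraction reaches 0.9 (falling back to the
highest-fraction K when none does) — is deterministic and exploits the
typical shape of the consistency curve: saturated below the true state
count, collapsing above it. Consistency is always scored on held-out
sequences, never on the training fold. On synthetic sessions
the three post-FREE epochs are recovered as the modal selection across
seeds; single seeds occasionally select 2 (one target's 3-state fit
underperforms) or 4 (a split state stays above threshold), which is why the
headline quantity is the mode over five populations.

### State-transition timing

A state's *rise* in a sequence is the start time of the first bin whose
posterior exceeds 0.7. Rise statistics are taken in aligned time; the mean
is reported relative to a reference behavioural event's mean time, and the
corrected SD removes that event's own timing variability:
`sqrt(max(0, var_rise − var_event))`. States that never rise are excluded
and counted.

## The 28-state boosted decoder

Nine two-state models (FREE→DELAY, trained on −500..+500 ms around cue
onset) and nine three-state models (DELAY→MOVE→HOLD, trained on
−1,000..+1,000 ms around movement onset) are merged into one 28-state chain
(1 + 9 × 3): the FREE emission row and self-transition are averaged over
the nine two-state models' first states; the remaining FREE mass is split
equally over the nine target-specific DELAY states (a uniform prior over targets, the
neutral choice); each target's
3 × 3 block is copied as-is; rows are renormalized. The two-state models'
DELAY states are discarded — DELAY/MOVE/HOLD come exclusively from the
three-state models. Cross-target transitions and backward steps are
structural zeros, so once the chain leaves FREE it is committed to one
target.

Decoding classifies sliding windows (widths 50–300 ms, step 10 ms) of the
concatenated sequences (last 500 ms of FREE + the movement-centred
2,000 ms): each window restarts the chain at FREE, is decoded by
forward–backward, posteriors are averaged over the window's bins, and the
argmax state is predicted (ties break to the earliest state in chain
order). True labels follow the window midpoint: the epoch containing it
(boundaries belong to the later epoch, so movement onset is MOVE) and the
trial's target (FREE windows carry no target). The FREE restart is what
produces the characteristic error anatomy: misclassifications skew toward
epochs *preceding* the true one, and when FREE and HOLD population activity
are similar (the PE-like regime) HOLD fragments are captured by the FREE
"attractor" rather than traversing the whole chain.

## Baselines

The SVM decodes per-unit mean firing rates in the same 200-ms windows
(scikit-learn SVC, native one-vs-one multiclass). The model-selection grid scans
C ∈ {0.001…1000} against an RBF kernel (automatic width) and polynomial
kernels of degree 2–8. The LSTM consumes the raw 2-ms binned counts
(window × bins × units) through one LSTM layer, dropout on the final hidden
state, a fully connected softmax layer and winner-takes-all; it is written
directly in numpy (Adam, full backpropagation through time, gradient-norm
clipping at 5) and verified against finite differences. Defaults — 200 hidden units, learning rate 1e-2,
minibatch 1,024 (reduced automatically for smaller training sets), dropout
0.1 — are fixed; training retains the weights with the lowest validation
loss, and no hyperparameter search is built in beyond an optional grid. For perturbation experiments, removed
units are zeroed in the inputs (SVM rates, LSTM count rows); for the HMM,
sequences are regenerated without the removed units while the symbol
alphabet is kept, so the trained model simply stops seeing their symbols.

## Evaluation battery

Accuracy is correct / total over all decoded windows (each of the
independent sequence repeats of a validation trial counts as a sample).
Chance is the distribution of accuracies under 1,000 shuffles of the true
labels; the chance level is operationalized as the 95th percentile of that
distribution, and the full distribution is kept. Confusion matrices are row-normalized (true × predicted); absent
classes give flagged zero rows. The error pattern splits misclassified
windows by whether the predicted epoch precedes or follows the true one
(FREE < DELAY < MOVE < HOLD) and tracks the named confusions DELAY→MOVE,
FREE→MOVE, HOLD→FREE. Target confusions are symmetrized and correlated
(Pearson by default, Spearman optional) with the planar inter-target
distances computed from version angle and radial distance; vergence is
redundant given the radial distances and unused, and distances are planar
(the targets sit in one horizontal plane at eye level).

Cluster structure uses the Davies–Bouldin 1979 definition on per-(trial,
epoch) mean-rate vectors: R_ij = (S_i + S_j)/M_ij with S the mean distance
to the centroid and M the centroid separation; DBI is the mean over
clusters of the worst R. Feature columns are z-scored for both the
embedding and the DBI, keeping the feature space consistent. Unit-resampling bootstraps (90% of units, or a
fixed 40) give DBI distributions; infinite R values (coincident centroids)
are excluded from summaries with a logged count. The t-SNE embedding
(perplexity 30, library implementation) is visualization-only.

Perturbations: *neuron loss* removes k ∈ {2,4,8,16,32,64} random units
(bootstrapped) without retraining; *noise injection* keeps each perturbed
unit's first and last spike per trial and redraws the interior spike times
uniformly between them, preserving spike counts exactly (an inter-spike-interval
permutation variant is the natural alternative noise model and would be a
drop-in replacement). Units with
fewer than 3 spikes in a trial are left unchanged. The subsampling curve
retrains on random subsets in 5-unit steps (10 repeats) and reports the
smallest population whose mean accuracy exceeds 50%. Group comparisons use
Wilcoxon / Mann–Whitney rank tests.

## The synthetic generator

Every stage is exercised on simulated sessions, since the recorded
datasets are external. Units are epoch-wise homogeneous Poisson processes:
rate = baseline × epoch_gain × target_tuning, with lognormal baselines
(median ≈ 7.4 sp/s, capped at 100 sp/s to keep 2-ms bins from saturating)
and all randomness split into one substream per (trial, unit) from a single
seed. Epoch gains are lognormal around per-epoch centres; the spread
(σ ≈ 0.3–0.65 in log space) creates a mixture of fixation-, reach- and
hold-preferring cells, which is what actually carries epoch information
into the one-symbol-per-bin alphabet (a global rate scale would mostly
modulate the silence probability). Target tuning is a Gaussian bump
(σ = 3.5 cm) over the physical target layout with a random per-unit
centre, normalized to mean 1, so nearby targets drive correlated rates —
this is what makes the distance–confusion correlation reproducible. Tuning
is inactive during FREE: the target is unknown before the cue.

The three presets are calibrated to the qualitative contrasts between
areas, not to absolute values (no quantitative per-area tuning parameters
are available): **V6A-like** — strong tuning (amplitude 2.5–5);
**PEc-like** — strongest epoch separation, intermediate tuning (1.2–2.5);
**PE-like** — weak tuning (0.2–0.6), reduced epoch heterogeneity, and the
HOLD gain tied to the FREE gain (±5%), which reproduces the FREE/HOLD
population similarity and its decoding consequences. On these defaults the
target-cluster DBI orders V6A-like < PEc-like < PE-like and the FREE/HOLD
R value is larger in PE-like than in V6A-like sessions.

What the generator does *not* emulate — and what passing tests therefore do
not show about real recordings: within-epoch firing-rate dynamics
(ramping), refractoriness and spike-history dependence, correlated noise
across units, eye-position signals, non-stationarity across sessions, and
real inter-area differences beyond the three qualitative contrasts above.

## Problem sizes and numerical choices

Defaults follow the analysis protocol (2-ms bins, 100 repeats/trial,
widths 50–300 ms at 10-ms step, threshold 0.7, EM stop at 500 iterations
or ΔLL < 1e-6, 1,000 label shuffles, leave-one-out over 10 trials/target).
The packaged experiments are sized for a single CPU: sessions of 40–100
units; training on 2–10 sequence repeats per trial and decoding 2–3 repeats
(accuracy estimates change negligibly beyond that because every window of
every repeat is a sample); one cross-validation fold for the heavyweight
experiments; EM capped at 150–300 iterations for the consistency and
decoding fits (the log-likelihood plateau is reached much earlier); LSTM
runs with 24–48 hidden units and a few hundred Adam steps on 50-ms-step
windows. The consistency analysis uses 4 training repeats, 20 test repeats
and 5 EM restarts per model. Row-sum assertions use 1e-9; posterior/oracle
agreement is required to 1e-10 on enumerable instances.

## Known limitations

- The chain topology hard-codes the task's epoch order; it cannot describe
  error trials or backward dynamics.
- With 40 units the fixed-40 DBI bootstrap is degenerate (the only subset
  is the full population); it becomes informative for larger sessions.
- The FREE→DELAY uniform split and the pseudo-random initialization are
  genuinely open choices; restarts make the results insensitive to the
  initialization.
- Consistency selection on a single synthetic session is noisy (see above);
  only the modal choice across sessions is a stable quantity.
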