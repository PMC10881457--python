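# Methods

## Model

Two reservoirs of `N` leaky rate neurons stand for the D1- and
D2-receptor-dominated medium spiny neuron (MSN) populations of the
striatum.  Both receive the same cortical character stream; each has a
single plastic linear readout.  The membrane dynamics of population
*i* ∈ {1, 2} are

    tau_i dx/dt = -x + g_i J_rec r + h_i J_fb z_i + J_in I(t) + sigma xi(t),
    r = tanh(x),      z_i = w_i^T r,

integrated with Euler–Maruyama at `dt = 1 ms`:

    x <- x + (dt/tau) (-x + drive) + (sigma/tau) sqrt(dt) N(0, 1).

`J_rec` (dense or Bernoulli(p)-sparse, entries N(0, 1/(pN))), `J_fb`
(uniform [0, 1]) and `J_in` (uniform [-1, 1]) are frozen at
construction; only the readout `w` learns.  The readout feeds back into
its own population through `J_fb` with gain `h` — a population-level
re-excitation loop summarizing cholinergic feedback.  The feedback
weights are non-negative by construction: with sign-symmetric feedback
the loop injects a random-direction perturbation proportional to `z`,
and the gain `h` acts as signal-dependent noise instead of recency, so
its modeled meaning (stronger feedback holds the population's response
longer, shifting peaks later) is lost.

### Mutual FORCE training

Each readout is trained online (recursive least squares, `P(0) = I/alpha`)
toward the *other* population's output, squashed and optionally
rectified:

    f_i = [tanh(zhat_j / beta)]_+          (i != j, beta = 3)
    e_i = z_i - kappa_i f_i

`zhat` is the readout standardized by bias-corrected exponential
running statistics (window 10 s, variance floor 1e-6).  Two details of
this normalizer matter and were fixed on training diagnostics:

* **Window length.** The window must be long relative to the
  inter-chunk interval (~1 s at the default stream statistics); a
  shorter window absorbs each chunk response into the running mean and
  the teaching signal loses selectivity.
* **Bias correction.** The accumulated exponential weight is divided
  out (as in Adam-style moment estimates).  Without it a 10 s window
  never converges within a 10 s training stream, `zhat` stays
  under-scaled, and the consensus amplitude contracts toward zero.

Readout weights start at small random values `N(0, 1/n)` rather than
zero: each population's training target is a function of the other's
readout, so exactly silent readouts are a fixed point of mutual
training, and a small random start is required to break it.

With `kappa = 1` on both sides the populations are driven toward
consensus; the only signal they can agree on is the input-locked
response component, and the recurring chunk is the only reproducible
multi-character structure in the stream, so chunk-locked responses
emerge.  Negative `kappa` makes the partner's output a repulsive
target (competition); rectification is lifted in the kappa-sweep
experiment so the teaching signal can go negative.

## Task

The synthetic stream emits, per epoch-serial draw, either the full
chunk word (probability `chunk_rate`) or one uniformly drawn distractor
character.  Defaults: alphabet 10, chunk length 4 (6 in experiment 6),
50 ms per character, `chunk_rate = 0.2`, 10 s training stream, 10 s
held-out test stream.  At rate 0.2 the stream is roughly half
background by time and ~80% of chunk presentations are preceded by a
distractor; at substantially higher rates a length-4 chunk dominates
the stream and most presentations sit inside back-to-back chunk runs
with no onset event, which removes the very structure the model is
meant to segment.  Distractors never use chunk characters, chunks never
overlap, and every full presentation window `[start, start + L*50 ms)`
is recorded for scoring.

What the generator does **not** emulate: competing chunk words,
probabilistic grammars, hierarchical chunks, or any cortico-thalamic
feedback on the input side.  Passing tests therefore show that the
mutual-teaching mechanism segments a single recurring word from an
i.i.d. background — not that it parses structured language-like input.

## Metrics

* **TOPA** (time offset of peak activity): per chunk window, the argmax
  latency of the readout within the window, from chunk onset; ties
  break to the earliest sample.  Offsets near 0 resemble "Start-cell"
  signaling, offsets near the window end "Stop-cell" signaling.
* **Per-simulation peak**: the single tallest in-window peak of a test
  trace; its latency and z-score.  The z-score standardizes the peak
  against the whole post-training readout trace (mean/SD); per-window
  peaks are standardized the same way.  The readout trace (not the rate
  matrix) is the baseline, since peaks are measured on the readout.
  Degenerate (constant) traces yield a flagged null, never NaN-division.
* **Histograms and clusters**: pooled TOPA offsets are histogrammed
  over the window.  For cluster counting the package bins at character
  resolution (one bin per presented character) and counts bins above a
  noise floor of 5% of the tallest bin (`count_clusters`): histogram
  "clusters" correspond to chunk characters attracting peak activity.
  A plateau-aware local-maximum counter over arbitrary binnings
  (`count_modes`) is provided for general histogram summaries; on
  pooled argmax data it picks up bin-level jaggedness, which is why the
  character-resolution count is the reported cluster statistic.

## Experiments and numerics

Eight presets encode the simulation experiments (time constants,
self-feedback gain, connection probability, recurrent gain at N = 600,
teaching coefficients, 6-character chunks, combined early-recognition
parameters, learning rate x training time).  Baseline parameters:
N = 300, n = 300, sigma = 0.3, beta = 3, tau = 10 ms, h = 1, g = 1.5,
p = p3 = 1, kappa = 1, alpha = 100, 10 s training.  Grid step sizes
within the published ranges are package choices (e.g. tau in
{2, 6, ..., 30} ms; g in {0.25, ..., 2.25} step 0.25; alpha in
{20, ..., 160} step 20) and are configurable.

Sweeps run a Cartesian grid x seeds.  The trial seed fixes weights,
initial states, the training stream and all process noise through
independent sub-streams; within a sweep the trial seed depends only on
the replicate index, and test streams come from held-out seeds shared
across grid points, so surfaces are compared on matched realizations.
Results aggregate over 10 seeds per regime by default (reduced to 4-5
per grid point in the largest sweeps; the acceptance script states its
sizes in its output).

Numerical choices: Euler–Maruyama with the noise increment inside the
1/tau factor (matching the membrane equation as written; a plain
`sigma sqrt(dt)` variant is available); `x(0) ~ N(0, 0.5^2)`;
self-connections in `J_rec` are sampled like any entry; the readout
connects to the first `n` neurons when `n < N`; the RLS matrix `P` is
re-symmetrized every 1000 steps against float drift and checked for
positive-definiteness; readouts beyond 1e6 abort the run with a
diagnostic naming the timestep.

## Known limitations

* The qualitative parameter surfaces (TOPA vs. tau, h, g) are noisy at
  10 seeds; single grid points move by tens of ms between seed sets.
  Conclusions should be drawn from whole-grid trends, not single cells.
* The model omits cortico-striato-thalamo-cortical feedback, dopamine
  concentration dynamics, explicit cholinergic interneurons (only the
  gain `h` represents them) and any overlap between the D1 and D2
  pools.
* The normalization scheme of the teaching signal and all weight
  initialization distributions are package choices (documented above),
  since only their roles, not their forms, are fixed by the model
  description.
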