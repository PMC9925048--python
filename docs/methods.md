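# Methods

## The map neuron

Each ORN is a discrete-time map iterated at h = 0.5 ms. The fast variable
x makes a one-iteration excursion to x = 1 (the spike) whenever it is
carried above −1/2; the branch `a(1−x) + u` below −1/2 relaxes toward a
stable fixed point `x* = (a+u)/(1+a)`, so the neuron is a noisy threshold
unit whose instantaneous excitability is `u = y + beta_n`. The slow
variable

    y[n+1] = y[n] − mu (1 + x[n] − sigma − sigma_n[n])

has zero drift when the running mean of x equals `sigma − 1 + sigma_n`, so
it steers time-averaged activity toward an input-shifted set point with
relaxation time `(1+a)/mu` iterations. Spikes drain y (each spike cycle
costs about 2·mu), which gives a relative refractory period and
spike-frequency adaptation.

### Input coupling and why the fast path carries the unit gain

The input current I drives the map through a fast path
(`beta_n = beta_xi·xi + beta_r·I`, into x) and a slow path
(`sigma_n = sigma_xi·xi + sigma_r·I`, into y). Fixed-point analysis pins
down the only viable gain placement. Write F = beta_r·I/(1+a) for the fast
shift of the resting point and S = sigma_r·I for the slow set-point shift;
during a sustained stimulus y relaxes until the set point is met, and at
stimulus offset the excitability overshoots baseline by `(F − S)` before
relaxing. Reproducing the four motifs therefore requires `F` to dominate
`S`:

* excitatory (`a_s > 0`): fast depolarization produces the onset burst;
  the smaller slow gain lets y drain during the burst, so the response
  decelerates back toward a slightly elevated steady rate and decrements
  over pulse trains;
* inhibitory / offset (`a_s < 0`): the fast path holds the cell below
  threshold for the whole pulse while y charges toward the bounded level
  `(F − S)(1+a)`; releasing the stimulus exposes the charge as a rebound.
  The offset motif's larger slow gain (0.2 vs 0.1) and deeper drive
  (−0.04 vs −0.02) make its rebound large and its pulse-train response
  grow, while the inhibitory rebound stays near the noise floor;
* delayed (slow-gain 0.01): the response is carried almost entirely by the
  fast path tracking the cascade current below, with negligible
  adaptation.

With the placement reversed (slow path dominant), sustained excitatory
input would produce a rising plateau instead of a decaying onset peak,
suppressed cells could never rebound above baseline, and pulse trains
would facilitate instead of adapting — none of which is how these motifs
behave. The package therefore ships the unit gain on the fast path
(`beta_r = 1` for every motif, `beta_xi = 1`) and the per-motif small gain
on the slow path (`sigma_r` = 0.1 excitatory/inhibitory, 0.2 offset, 0.01
delayed; `sigma_xi = 0.1`).

### Input shaping

The excitatory/inhibitory/offset motifs shape the odor concentration s
with a first-order low-pass `I' = g_s I + (1−g_s) a_s s` (gain `a_s`,
relaxation `g_s`; time constant `h/(1−g_s)`, i.e. 100 ms for the
excitatory motif, 250 ms for the suppressive ones). The delayed motif uses
a cascade: a fast high-pass of the stimulus increment
(`I_d`, gain 0.8, 50 ms) forms a short negative pulse at odor onset; a
slow high-pass envelope (`h_p`, ~3.3 s) gated by the stimulus feeds a slow
low-pass (`I_p`, gain 0.08, 500 ms) that carries the delayed excitation.
The mixed current `I_M = I_p − H(I_d) I_d` is passed when above the depth
limit L = −0.04 and zeroed otherwise (`H(0) = 0`): the onset inhibition is
limited to depth |L|, and the literal alternative — gating on `I_M + L`,
which would erase the designed negative pulse altogether — is not used.
Because `I_p` multiplies the stimulus by its slow envelope, the delayed
motif responds strongly to long odor bursts and barely to brief flickers.

### Noise

Channel noise is a discrete Ornstein–Uhlenbeck process
`xi[n+1] = q·xi[n] − p·w[n]` with `q = exp(−h/tau_c)` and
`p = d·sqrt(1−q²)`, so the stationary standard deviation equals d = 0.01
and the correlation time equals tau_c = 3 ms exactly (verified against the
AR(1) closed form in the tests). Trials differ only in their noise draws;
each (neuron, trial) pair owns an independent, seed-derived stream, so
results are independent of how a population is split into simulation
batches.

### Intrinsic calibration

The intrinsic parameters (a, sigma, mu) are not derivable from the input
tables; they were calibrated once (`scripts/calibrate_map.py`) against
three criteria: low tonic baseline (~2–5 spikes/s under the stated noise),
the four motif shapes with peak rates in the tens of spikes/s at gain 1,
and the motif-specific adaptation directions under ten 200 ms pulses at
0.5 s inter-pulse interval (excitatory decreasing, offset increasing,
inhibitory flat). Frozen values: a = 0.01 for all motifs;
sigma = 0.473 (0.472 inhibitory), placing the rest point ~2.7 noise
standard deviations below threshold; mu = 2e−3 (excitatory), 3e−3
(delayed), 3e−4 (offset), 1e−5 (inhibitory). Small a keeps the map in a
single-spike (non-bursting) regime: the self-sustaining spike-run
hysteresis band, of width `0.5a/(1+a)` in x, stays below the per-spike
slow-variable drain. Per-neuron baseline heterogeneity is a fixed,
population-seeded jitter of sigma (width 0.002 by default).

## Odor selectivity and motif switching

Odors and ORN selectivities are unit vectors in the positive octant of a
3-D space; the efficacy `R = sigmoid(|V_odor| cos^p(theta))` (steepness 15,
midpoint 0.3, receptive-field exponent p = 1 by default) multiplies the
stimulus before input shaping, scaling response magnitude while preserving
motif shape. ORN vectors are sampled uniformly over octant directions
(folded Gaussian). Companion odors at a prescribed angular separation are
constructed by seeded rotation inside the octant; note the geometry: from
the octant center nothing is farther than ~55°, so classification sweeps
up to 80° use a reference odor near an axis. `cos^p` is clamped at zero
beyond 90° to avoid complex values at fractional p. Motif identity per
(neuron, odor) is independent of efficacy; switching between odors is a
seeded Markov draw — keep with probability 1−p, otherwise uniform over the
other three motifs (any 4×4 row-stochastic transition matrix can be
supplied instead, since the true conditional structure is configurable,
not fixed).

## Plume stimuli

Plumes are binary valve traces alternating gamma-distributed odor bursts
and clean-air gaps, truncated at the requested duration and fully seeded.
The shape parameter is recovered from arithmetic and geometric means by
solving `log k − psi(k) = log mu − log geo` (digamma; bracketed root find
to 1e−12 on log k), with the scale then `theta = mu/k`. The per-distance
preset table follows open-field tracer-plume phenomenology: near the
source the plume flickers rapidly; with distance both burst durations and
return times lengthen as fine structure mixes out, so burst frequency
falls monotonically (means: bursts 0.25/0.40/0.70/1.20 s and gaps
0.5/1.2/2.8/6.0 s at 2.5/5/10/20 m; shapes slightly below 1). The numbers
are package defaults standing in for field measurements and are shipped as
an editable table; concentration fluctuations within bursts and true fluid
dynamics are not modeled (an optional first-order low-pass can mimic
delivery-line smoothing). For distance-decoding experiments each distance
is represented by one seeded, repeatable plume delivered on every trial
(trials differ only in neural noise); with a fresh realization per trial
the published feature construction (concatenated 50 ms bins, a handful of
training trials) is uninformative because bins are burst-misaligned
across trials — a linear SVM then sits at chance, which we verified
directly.

## Analysis pipelines

**Binning and rates.** Spikes are counted in half-open [t, t+Δ) bins
(50 ms default) with the trailing partial bin dropped; rates are
trial-averaged counts on a 10 ms grid smoothed with a unit-area Gaussian
(σ = 50 ms).

**Clustering and validation.** Responses (trial-averaged binned PSTHs of
units passing a two-sided 2-SD responsiveness rule against the
pre-stimulus epoch) are z-scored per response and clustered by
Ward/Euclidean agglomeration. Test 1 draws 10,000 random same-size subsets
of all responses (without replacement by default) and requires each
cluster's mean intra-cluster pairwise distance to fall below the 5th
percentile of that null; an all-identical cluster (zero distances) passes
by definition. Test 2 compares each cluster's intra-distances against its
inter-distances to every other cluster with Welch t-tests, Bonferroni
corrected over the k(k−1) ordered pairs; the matrix is deliberately
non-symmetric. The motif count is the largest k (2..k_max) for which every
cluster passes Test 1 and every pair passes Test 2, with 1 returned when
nothing passes. Caveat discovered during validation: because Ward
*selects* compact groups, partitions of pure i.i.d. noise also pass both
tests — the procedure's real rejection mode is loose or outlier clusters,
so a validated k should be read as "k compact, mutually distinct groups",
not as evidence against fewer.

**Adaptation.** Per pulse, the maximum |rate − baseline| inside a
detection window ([onset, offset + 0.2 s]; for the offset motif
[offset, offset + min(IPI, 0.5 s)]), normalized within each trial by that
trial's maximum rate, with the sign of the extreme deviation restored;
baseline is the 2 s before the first pulse. Repeated-measures one-way
ANOVA across pulse index (no sphericity correction by default).

**LN estimation.** Stimulus and smoothed rate are aligned on a 10 ms grid
(finer grids add nothing under 50 ms smoothing); the filter spans 2 s of
delay. The filter solves the regularized least-squares problem on the
causal convolution matrix: the cross-correlation `X'y` is multiplied by an
SVD-regularized inverse of the stimulus covariance `X'X` in which the
leading eigenspace covering 70% of the stimulus variance is inverted
exactly and the remaining eigenvalues are clipped at the boundary value
(clipping, rather than zeroing, leaves a flat white-noise spectrum — and
hence the filter — essentially untouched while refusing to amplify the
noise directions of a correlated plume). The result is low-passed with a
zero-phase FIR (passband 8 Hz, stopband 10 Hz) and L2-normalized. The
nonlinearity is a 100-bin histogram lookup (per-bin mean filtered value vs
mean rate) with linear interpolation and edge clamping; empty bins are
interpolated and flagged. Confidence bands come from an ensemble of models
trained on shifted 50%-of-record stretches (95% pointwise band). For a
40 s plume record the default split trains on the first 16 s.

**Population PCA.** Observations are per-trial 50 ms bins of the stimulus
epoch (e.g. 10 trials × 80 bins for a 4 s pulse), variables are neurons;
explained-variance fractions, the component count needed for a cumulative
target, and trial-averaged 2-D trajectories are reported. Trial-averaged
observations are available as an option.

**Decoding.** All classifiers are linear SVMs with unit cost (one-vs-one
for multiclass) — with feature dimension far above the sample count a
linear kernel is the conventional choice, exposed as a knob. Odor
classification trains per 50 ms bin with a rotating held-out trial and
averages accuracy over bins and rotations. Distance classification
concatenates binned counts into NCells × NBins vectors, samples the
requested number of cells from a motif subset, splits trials into equal
train/test halves, and repeats 25 times (ensemble distribution reported);
an optional window truncation supports sample-duration analyses. Subset
comparisons use one-way ANOVA with a pooled-SEM gap grouping as the
post-hoc. Motif correlations are Pearson coefficients between
motif-averaged rate traces truncated to the requested sample duration.

## What the generator does and does not emulate

The simulator reproduces the qualitative phenomenology the analyses need:
four motif shapes at single-pulse and pulse-train timescales,
motif-specific adaptation directions, graded efficacy with odor angle,
switching statistics, and plume responses whose burst-length sensitivity
differs across motifs. A template-plus-noise surrogate generator
(inhomogeneous Poisson trains around canonical motif rate templates with
per-pair lognormal gain jitter) provides ground-truth-labeled data for
validating the clustering pipeline independently of the map model.

Known limitations, found and quantified while validating:

* **Trial reliability is higher than in vivo.** The only stochastic
  element is the OU input noise (d = 0.01), and during strong drive the
  map fires sub-Poisson-regularly. Population PCA therefore shows a
  thinner noise floor than real recordings: the excitatory-only first
  component lands near 30% with a ~1% second component, but the all-motif
  first component stays near 23% with very few components needed to reach
  30% cumulative variance, whereas noisier data would push the first
  component toward ~15% and spread the remainder across a
  Marchenko–Pastur-like tail of dozens of components.
* **The excitatory response is fast-onset.** Noise-gated threshold
  crossing plus the 100 ms input low-pass yields a PSTH latency near
  0.1 s, and plume-driven LN filters for excitatory cells peak within the
  first ~0.1 s of delay. Response kinetics peaking several hundred
  milliseconds after filament arrival would require the slow, integrating
  path to carry the response — the gain placement that breaks the rest of
  the motif phenomenology (see above).
* **Delayed responses track odor presence.** Although delayed cells
  integrate long bursts, their window-averaged plume activity remains
  positively correlated with the excitatory motif's; opponent
  excitatory/delayed coding strong enough to decorrelate the two would
  need a stronger burst-length opponency than the delayed input cascade
  produces here.
* The inhibitory motif shows a small, slow post-stimulus rebound after
  long pulses (its charge mechanism is the offset motif's at lower gain);
  it is near the noise floor for 1 s pulses but visible after 4 s.

Passing tests therefore demonstrate internal consistency of the pipelines
and qualitative fidelity of the motif phenomenology — not that real ORN
data would yield the same variance spectra or filter latencies.
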