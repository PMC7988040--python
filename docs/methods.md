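# Methods

`microgt` analyses spontaneous activity of cortical microcircuits recorded by
two-photon calcium imaging: it infers discrete calcium transients from
fluorescence, characterises their temporal statistics (burstiness), builds a
correlation-based functional graph per imaging session, summarises each graph
by six topology indexes, and compares the indexes across experimental groups
with rank-based statistics.  A first-class synthetic-data generator produces
cohorts with known ground truth, so every stage of the pipeline can be scored
against what was actually simulated.

## Forward model and synthetic cohorts

Each neuron fires as a point process binned at the frame rate (default
30 Hz, a typical resonance-scanner rate; the underlying studies of this kind
rarely report it).  Two regimes are modelled:

- **poisson** — an inhomogeneous Poisson process at `base_rate` (events/s).
- **burst** — a `bursty_fraction` of neurons additionally follow a two-state
  Markov chain: burst entry with probability `burst_entry_prob` per frame,
  geometric burst lengths with mean `burst_mean_length` frames, and rate
  `burst_rate` inside a burst.  This is the simplest process that produces
  the disease phenotype of interest — an excess of short inter-event
  intervals carried by a small subpopulation — while leaving the session
  mean event count controllable in closed form
  (`SpikeTrainModel.expected_rate()`).

Correlation structure comes from latent non-overlapping modules.  Every
neuron belongs to exactly one module; each module carries a shared lognormal
rate drive `g_m(t) = exp(sigma * z_m(t) - sigma^2/2)` with unit mean, where
`z_m` is a stationary AR(1) Gaussian with a 0.5 s correlation time (matched
to the default analysis bin) and `sigma = 1.5 * shared_drive_strength`.
Multiplying rates by `g_m` raises within-module correlations of binned spike
counts without changing mean rates; at strength 0 neurons are independent.
The linear mapping from the strength parameter to the lognormal log-sd was
chosen so that realistic strengths (0.2–0.9) span per-pair binned-count
correlations from barely detectable to ~0.1, the range where group
differences in mean node strength emerge over the sampling noise floor.

Fluorescence follows a linear indicator model (appropriate for synthetic
dyes such as OGB-1, whose responses to successive action potentials add
nearly linearly): `F(t) = baseline + unit_amplitude * sum_events
gamma^(t - t_event) + N(0, noise_sd)`, with per-frame decay `gamma` in
(0, 1).  Saturation, indicator nonlinearity, neuropil contamination and
motion artifacts are deliberately out of scope; conclusions from passing
tests therefore apply to the linear-indicator regime only.

### Default ("paper-like") cohort

`paper_like_config()` freezes the study conditions: three groups of five
sessions, 120 s at 30 Hz, with per-session neuron counts 316 / 384 / 503 so
the group totals (1580 / 1920 / 2515) match the published assembly sizes.

| group       | firing                                  | drive | modules | amplitude |
|-------------|------------------------------------------|-------|---------|-----------|
| WT-like     | poisson, 10.6 events/session            | 0.9   | 4       | 0.25      |
| FAD-like    | burst, 4.8 events/session total; 10% bursty neurons, 4 Hz bursts of ~1 s | 0.2 | 8 | 0.175 |
| treated     | poisson, 7.7 events/session             | 0.3   | 4       | 0.21      |

Noise sd is 0.035 everywhere, giving per-event SNRs of 7.1 / 5.0 / 6.0.  The
published work quantifies neither the bursty fraction nor the treated
group's parameters; 10% bursty neurons operationalises "a small fraction",
and the treated group sits between the other two (its recovery "approached"
but did not reach control values).  The FAD-like base rate is solved from
the burst parameters so the stationary mean count is exactly the configured
4.8 events per session.  Amplitude for the disease group is 0.7x the control
amplitude, the scaling also used in the amplitude-contrast tests.

Reproducibility: one global integer seed; per-session generators derive from
`SeedSequence([seed, group_index, session_index])`, so single sessions can be
regenerated in isolation and identical configs give byte-identical outputs.

## Deconvolution

The observation model is AR(1): calcium `c(t) = gamma * c(t-1) + s(t)` with
non-negative activity `s`, observed as `y = c + noise`.  `oasis_ar1` solves

    min_c 1/2 ||c - y||^2 + lambda * sum_t s(t),   s(t) >= 0  (c(-1) = 0)

exactly by the online-active-set pool-merging scheme: one pool per frame,
adjacent pools violating the decay constraint are merged with their value
recomputed in closed form, then back-substitution.  Tests verify the
solution equals penalized non-negative least squares (the problem rewritten
in `s` with the lower-triangular kernel matrix) to 1e-6 on random instances,
and that noiseless forward-model traces are recovered exactly at zero
penalty.

Nuisance parameters are estimated from the data:

- **noise sd** — median of the Welch power spectral density over the upper
  frequency quartile, where the slow kernel contributes negligibly, scaled
  back to a standard deviation.
- **gamma** — ratio of summed autocovariances at lags 2..6 over lags 1..5
  (lag 0 is noise-inflated, all later lags decay by gamma).  A lag-1
  autocovariance within two standard errors of zero means no detectable
  decay and returns a near-zero value.  Because near-silent traces carry no
  usable signal, session-level deconvolution pools gamma as the median of
  the per-trace estimates, clipped into [0.6, 0.99] (decay time constants of
  roughly 60 ms to several seconds at typical frame rates).
- **baseline** — running 8th percentile over a 30 s window (block-evaluated
  with linear interpolation), subtracted before deconvolution.
- **penalty** — noise-constrained: bisection (20 iterations) on lambda until
  the residual sd of the fit matches the estimated noise sd.  A fixed
  penalty can be supplied instead.

Event calling thresholds the deconvolved activity at `3 * noise_sd`
(configurable) and merges candidates closer than 100 ms into one event at
the first frame with summed amplitude.  Before thresholding, amplitudes are
debiased by a zero-penalty refit on the penalized solution's active set,
with activity below `0.5 * noise_sd` treated as decay-phase fragments of the
preceding pool rather than separate onsets.  Without this step the L1
shrinkage plus noise-driven fragmenting of single transients across adjacent
frames pushes detection recall at SNR 5 below 0.9; with it, recall ~0.93 and
precision ~0.97 at SNR 5.  The exact penalized solution is still what
`oasis_ar1` returns; the debiased vector is used only for event calling.

Parameter-recovery comparisons use `ground_truth_event_times()`, which maps
the true spike trains through the same 100 ms merge rule: events closer than
the merge window are indistinguishable to the extractor by construction, so
the honest reference is the merged truth.

## Event statistics

Inter-event intervals (IEIs) are successive differences of one neuron's
event times; histograms use left-closed right-open bins, and group-level
IEI distributions pool intervals over all neurons of a group.  The joint-IEI
histogram pairs each interval with its successor; the boundary (per-neuron
mean interval by default, or a fixed value) classifies each pair into
within-burst (both below), burst-initial (preceding at/above, following
below), burst-final (reverse), or sporadic (both at/above); ties classify to
the at/above side.  No binary per-neuron "bursting" label is assigned — the
within-burst fraction is reported instead.  Event rates are reported both as
raw per-session counts and per minute.

## Functional graphs

Nodes are neurons; edge weights are pairwise Pearson correlations of binned
activity (500 ms bins by default).  The default correlated signal is the
binned *detected events*: binning the raw deconvolved activity (including
its sub-threshold residue) adds a spurious positive-correlation floor whose
size depends on transient amplitude, which inverted group contrasts at
realistic SNR in calibration runs; binned event trains track the
ground-truth spike correlations closely.  Raw-dF/F and full-deconvolved
modes remain available for comparison.  Negative correlations are zeroed by
default (absolute-value mode available), silent neurons are excluded with a
warning, and a binary display view keeps edges above 50% of the session's
maximum off-diagonal weight — a display convention; all indexes are computed
on the full positive-weighted graph unless binary mode is requested.

## Topology indexes

Computed from first principles over a CSR adjacency (Dijkstra distances and
Brandes-style betweenness accumulation, numba-accelerated), with naive
enumeration oracles in `microgt.reference` used by the tests:

- **mean degree** — mean of the per-node degree (binary) or strength
  (weighted) distribution; the full distribution is also exported.
- **characteristic path length** — mean shortest-path distance over
  connected ordered pairs; weighted edge length is `1/weight` (stronger
  correlation = shorter link; `1-weight` is available).  Disconnected pairs
  are excluded and their (unordered) count reported, keeping the statistic
  finite on sparse sessions.
- **global efficiency** — mean inverse shortest-path distance, `1/inf = 0`.
- **modularity** — Newman's Q of the partition found by seeded greedy
  agglomerative modularity maximization (merge the community pair with the
  largest gain until no merge improves Q; ties broken by a seeded draw).
- **betweenness** — shortest-path betweenness with each unordered pair
  counted once, unnormalized.
- **assortativity** — Pearson correlation of endpoint degrees over both
  orientations of every edge; undefined (flagged) when endpoint degrees have
  zero variance, as in regular graphs.

Undefined values propagate as flags and are dropped from group tests with a
recorded count.  Whether published analyses of this kind use weighted or
binarized graphs is typically unstated; both modes are first-class and the
weighted mode is the default.

## Group statistics

A Lilliefors normality test per group (table-based small-sample critical
values, alpha 0.05) combined with a maximum/minimum variance-ratio check
(threshold 4) gates parametric vs nonparametric branches.  Three or more
groups are compared by the tie-corrected midrank Kruskal-Wallis H with
per-group mean ranks reported; two groups by a pooled-variance unpaired t
(parametric branch) or the two-sample Kolmogorov-Smirnov D with asymptotic
p-value (nonparametric branch).  `t_from_summary` reconstructs the pooled t
from printed (mean, SEM, n) triples via `var_i = n_i * sem_i^2`,
`df = n1 + n2 - 2`; the pooled rather than Welch form matches the
`n1 + n2 - 2` degrees of freedom convention of the summaries it is meant to
check.  No multiple-testing correction is applied across the six indexes by
default (a Holm option exists), mirroring the reporting style of the
source analyses.  P-values that underflow are printed as "< 1e-300".

Monte-Carlo calibration (recomputed by the test suite and acceptance
script): Kruskal-Wallis type-I error at alpha 0.05 on three null groups of
30, and the Lilliefors rejection rate on normal samples of 200, both within
0.05 +/- 0.02 over 1000 replicates.

## Problem sizes and numerical choices

The default cohort analysis deconvolves ~6000 traces of 3600 frames per
cohort; the directional-effect suites evaluate 20 such cohorts using the
degree-only metrics level (the path-based indexes are not needed for those
contrasts), and the full six-index report is computed on the single
recovery cohort.  Feasibility of the active-set solution holds to 1e-9;
correlation matrices are symmetrized and clipped to [-1, 1]; shortest-path
tie comparisons use exact floating-point equality, which is safe for the
binary and generic-weight graphs exercised here.

## Known limitations

- Single AR(1) kernel: no rise time (AR(2)) and no indicator nonlinearity;
  adequate for synthetic-dye data, not for GCaMP-family indicators.
- Modules are non-overlapping by construction; overlap in real assemblies is
  treated as a display property.  As a proxy, `community_overlap_scores`
  reports per node the exact modularity change of moving it to its best
  alternative community (near zero = boundary node, strongly negative =
  core member); no overlapping-community algorithm is implemented.
- The display threshold ("50% of connection strength") is interpreted
  relative to the session's maximum off-diagonal correlation.
- The correlation noise floor of the event-binned graph grows with both
  session size and firing rate, so mean node strength is comparable across
  groups of different sizes only through the group tests actually run, not
  as an absolute quantity.
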