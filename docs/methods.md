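# Methods

## The kinetic scheme

A single U2AF heterodimer on a candidate 3' splice site moves through
three bound states,

```
U  --k_on[U2AF]-->  E  --k_fwd1-->  Intermediate  --k_fwd2-->  A
U  <--k_off_E--     E
U  <--k_off_int--   Intermediate
U  <--k_off_A--     A
```

Forward steps are irreversible (ATP-consuming); dissociation returns the
molecule to the unbound pool. There is no Intermediate-to-E backtracking,
no downstream catalytic state beyond A (the A complex recycles to unbound
at `k_off_A`, since a terminal splicing step is not observable in the
tracking data this model is fitted to), and one U2AF molecule per
transcript. Both dissociation checkpoints read the same sequence: the two
off-rates of a site carry a common Boltzmann factor `r = e^{-ddG/RT}`
relative to a competing site, while association is sequence-independent.

Slow-tracking experiments observe molecules that have already passed the
E-complex checkpoint, so the observable dwell starts in the Intermediate.
Its survival is the two-phase mixture given in the README; the removable
singularity at `lam = k_off_A` is evaluated by the limit
`S(t) = (1 + k_fwd2 t) e^{-lam t}` whenever
`|lam - k_off_A| < 1e-9 max(lam, k_off_A)`.

Deriving the PSI equation from the scheme: a binding attempt at site i
succeeds with probability `q_i = [Kf/(Kf+r_i)] [Ks/(Ks+r_i)]` (two
independent exponential races), attempts alternate between the two sites
with probability 1/2 each, and PSI is the splitting probability
`q_S3/(q_S3+q_S2)`. The closed form in the README follows with `r_S2 = 1`
and `r_S3 = r`. One consequence worth noting (it constrains what "higher
accuracy" can mean): at `Kf >> 1` the partial-proofreading curve is
pointwise *below* the equilibrium logistic for `ddG > 0` — its advantage
over equilibrium selection lies in rejecting weak sites (`ddG < 0`) and in
permitting forward progression at all, and its PSI is capped by the
asymptote `(Kf+1)(Ks+1)/[(Kf+1)(Ks+1)+Kf Ks]` (about 0.894 at
`Kf = 10, Ks = 0.15`).

All free energies are in units of RT internally (`EnergyContext(RT=1)`);
callers converting kcal/mol at 310 K pass `RT = 0.616`.

## Fitting dwell-time data

The joint survival fit maximises a censoring-aware likelihood: complete
events contribute the dwell density, events ended by the video limit or by
photobleaching contribute the survival at their censoring time. Because
dwells arrive frame-discretised (an event spanning m frames had a true
duration in `[m dt, (m+1) dt)`, and events shorter than one frame go
undetected), the default likelihood is interval-censored and conditioned
on detection; censored events are evaluated at the midpoint of their final
frame. A continuous-time mode exists for undiscretised data and reduces
exactly to the closed-form exponential MLE when the forward rate is fixed
at zero.

Each of the three identifiable rates (`k_off_int`, `k_fwd2`, `k_off_A`)
can be declared shared across conditions, free per condition, or fixed —
the device used to encode biological hypotheses (an inhibitor of forward
progression: off-rates shared, `k_fwd2` free; a helicase knockdown that
slows dissociation: `k_fwd2` shared, off-rates free). Sharing
specifications are compared by AIC (BIC reported); the likelihood surface
is multimodal when the two lifetimes approach each other, so optimisation
is multi-start (8 log-space starts around moment-based anchors) bounded
L-BFGS on log-rates. Uncertainty comes from event-resampling bootstrap
(default 1000 replicates in the CLI; tests and the acceptance script use
100-200 for speed), and any scalar derived from the fitted schemes can be
given a percentile CI.

Photobleaching is handled two ways, matching practice: when bleach events
are flagged (the generator knows them), they are ordinary right-censoring;
when only an uncorrected survival curve is available, it is divided by the
bleach-reference survival (a chromatin-bound control that disappears only
by bleaching), clipped to [0, 1], with points where the reference has
fallen below 0.05 flagged unreliable.

## Trace analysis

The two-state HMM (Gaussian emissions, pooled EM across traces via
hmmlearn, quantile-anchored initialisation) yields per-frame transition
probabilities. These convert to rates by the exact inversion of the
sampled telegraph — `lambda = -ln(1 - p01 - p10)/dt` split by branching
fractions — rather than the first-order `-ln(1-p)/dt`, which
underestimates each rate once the opposite transition becomes likely
within a frame (a 4% effect at the dissociation rates studied here).
Dwell lists from the decoded path use a 2-frame minimum (single-frame
states are mostly noise misassignment) and optionally the complete-event
rule (bound runs flanked by unbound runs on both sides), the criterion
appropriate at fast frame rates where photobleaching ends many tracks.

Association kinetics: the low-to-high rate is pseudo-first-order, so a
weighted regression of that rate on protein concentration (through the
origin by default) estimates `kon`.

Equilibrium titrations are fitted to the non-cooperative isotherm
`F(c) = 1 + (fmax-1) c/(c+KD)` with residual-bootstrap CIs.

## Correlation estimators

For a two-state telegraph the autocorrelation decays at the sum of the
switching rates; with the on-state occupancy `p` the mean on-dwell is
`1/(lambda (1-p))`. Two numerical choices matter in practice:

* the exponential fit includes a free baseline, absorbing the negative
  offset that per-trace mean subtraction imprints on correlation functions
  of finite traces (without it the decay rate is biased high once the
  correlation time is within ~an order of magnitude of the trace length);
* occupancy comes from a two-component Gaussian mixture on the pooled
  intensity histogram with robust initialisation (median / upper 0.1%
  quantile, MAD scale), validated against a single-Gaussian fit by BIC.
  A histogram threshold (Otsu) was tried first and collapses when the
  on state is rare (a few percent duty cycle, as in binding-pulse
  channels); the mixture weight also avoids the noise-spillover inflation
  a hard threshold suffers at moderate SNR.

Cross-correlation between the binding channel and the transcription
channel is computed per trace (mean-subtracted, normalised), averaged, and
fitted with a Gaussian plus baseline over an adaptive window (iterated to
+/-5 sigma of the peak). The fitted center is the delay of the first
channel relative to the second and is exact for shifted-copy signals. The
reported width is the fitted sigma times a calibration constant fixed by
construction: the cross-correlation of a short pulse against rectangular
on-states of duration T is a rectangle of width T in lag, and the
calibration makes the reported width equal T under the same fit protocol.
On *exponentially* distributed event durations this width estimator is
biased low (we measure roughly 35% at the default conditions): the
one-sided exponential kernel concentrates the Gaussian fit near its sharp
edge. The unbiased route to the mean event duration in this package is the
occupancy-corrected autocorrelation estimator, which recovers exponential
on-times within ~5% at 100 overnight traces; the cross-correlation width
is kept for its qualitative use (a broader curve means slower splicing)
and is exact on the rectangular calibration construction.

The dynamic-metagene half-life is the censoring-aware Kaplan-Meier median
of per-intron splicing times.

## Sequence-level binding

Enrichment per k-mer is `R = freq_IP/freq_input` with a 0.5 pseudocount
(desk-scale pools are orders of magnitude smaller than a real selection
experiment, so unobserved k-mers must stay defined). "Significantly
enriched" means a two-sided binomial test of the IP count at the input
frequency, Benjamini-Hochberg adjusted at 0.05. The energy model is a
mononucleotide-additive position matrix (no dinucleotide terms, no
secondary-structure correction): per-position, per-base penalties in RT
anchored so the consensus window scores relative affinity 1; sequences are
scored by the best window (overlapping windows, as for peak-affinity
assignment). Affinities below 1/370 of consensus are outside the model's
validated range and gate all site-pair analyses; a second configurable
floor (default 1e-3) and a 50-fold-of-consensus filter for the
two-condition PSI analysis mirror the filters used when comparing
predictions with transcriptome data. Coordinates are BED-style 0-based
half-open and strand-aware; DNA input (T) is mapped to RNA (U).

## Synthetic data: what it emulates and what it does not

Every generator is deterministic given its seed and records the generating
parameters. Defaults encode the study conditions: slow tracking at 1
frame / 3 s for 20 min, fast tracking at 100 Hz, smPIFE at 1 Hz over 500
frames with a 1.5-fold bound-state emission contrast, orbital-style
dual-channel traces at 4 frames/min; dwell generators implement the
exponential races of the scheme, frame flooring, detection loss of
sub-frame events, and photobleaching as an independent exponential.
PSI tables draw binomial reads (depth 200 by default) around the model
PSI, with an optional beta-binomial overdispersion emulating
transcript-level variation (0.05 is used where that variation matters —
it is what makes large `Kf` one-sided identifiable, as in real data;
clean binomial tables at desk scale can otherwise bound `Kf` from above
too). Selection in the RBNS-style generator uses Boltzmann occupancy
`conc*A/(conc*A + K0)` with `K0 = 20 nM` so the consensus sits at half
occupancy at 20 nM. Orbital trace noise (SD 0.1 of the low level) and the
off-period mean (30 min) are not anchored to published values and are
exposed as parameters.

Not emulated: photophysics beyond a single-exponential bleach, localisation
and tracking errors, labeling efficiency, RNA secondary structure,
read-mapping artefacts, and transcriptome-scale read depths. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own statistical assumptions, not robustness to every
real-data pathology.

## Problem sizes

Tests run the recovery protocols at the study-scale sizes (3000 dwells per
condition, 100-200 traces, 50 sites per ddG bin at depth 200) and check
coverage of bootstrap intervals; the acceptance script reports point
estimates and uses 50,000 dwells per condition for the survival fits so
that the recovered values are dominated by the protocol, not by sampling
noise. Monte-Carlo equivalence checks use 1e5 trials per grid point with
multiplicity-aware 3-4 SE bands.

## Known limitations

* `Kf` is reported as a profile with a flat-region lower bound; its point
  estimate in the flat regime is not meaningful.
* The cross-correlation width estimator carries the duration-distribution
  bias described above.
* The interval likelihood evaluates censored events at the frame midpoint,
  an approximation that is negligible at the frame rates used but untested
  for frames comparable to the shortest lifetime.
* The PSI chain assumes exactly two competing sites and equal association;
  multi-site competition and concentration effects are out of scope.
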