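# Methods

`mtsig` analyzes three simultaneously recorded readouts of mitral/tufted-cell
(M/T) activity in the mouse olfactory bulb — a fiber-photometry population
calcium trace (GCaMP6s, 500 Hz), a local field potential (1 kHz), and sorted
single-unit spike trains — around 2-s odor presentations delivered as 8 odors
× 20 trials per session. Because the in-vivo recordings behind this design
are not publicly available, the package ships a synthetic cohort generator
that reproduces the design and the qualitative response structure with known
ground truth; every analysis stage is validated against that ground truth or
against an independent analytic oracle.

## Preprocessing

All signals are reduced to a common grid of trials × half-open 50-ms bins
spanning −2 to +6 s around odor onset, with the first 2 s forming the
baseline window.

**ΔF/F.** Each calcium segment is converted to (F − F₀)/F₀, where F₀ is the
mean fluorescence over the 2-s pre-onset baseline of that trial. The
transform is exactly invariant to multiplicative rescaling of the raw trace,
and its baseline mean is 0 by construction.

**LFP band power.** Bands are theta 2–12, beta 15–35, low gamma 36–65, and
high gamma 66–95 Hz; the analysis focuses on beta and high gamma, the bands
that odors reliably modulate in awake animals. Time-resolved power is the
squared modulus of a continuous wavelet transform with an analytic Morlet
mother wavelet (ω₀ = 6), averaged across ≥10 log-spaced center frequencies
per band (averaging vs summing is config-switchable; the two differ by a
constant that cancels under baseline normalization). Two numeric
calibrations — a per-scale probe sinusoid at each scale's own center
frequency, then one band-level probe at the geometric band center — make the
operator return the signal's in-band mean-square amplitude. The calibration
is deterministic and cached; it was validated against a
bandpass-filter + Hilbert-envelope oracle (≈0.3% agreement on a mid-band
sinusoid) and against the PSD × bandwidth closed form for white noise (≈5%
for beta). LFP segments are cut with 4 s of pre-onset padding so wavelet
edge effects never reach the analysis window, then cropped to the common
−2 … +6 s grid. Each trial's power trace is divided by its own 2-s baseline
mean ("baseline normalized to 1"), making trials of different absolute power
comparable.

**Spikes.** Units with ≥0.75% of inter-spike intervals below 1 ms fail the
single-unit criterion and are excluded from all downstream statistics.
Firing rates are spike counts per half-open 50-ms bin divided by the bin
width (Hz). Binning conserves spike counts exactly within each trial window;
a 1e-9-bin tolerance keeps spikes lying exactly on a bin edge in the bin
that starts there despite floating-point edge representation.

## Response detection

For each source–odor pair, discriminability of each post-onset bin against
baseline is the area under the ROC curve (auROC), computed from the
Mann–Whitney rank statistic — exactly the fraction of cross pairs in which
the evoked value exceeds the baseline value, ties credited ½. 0.5 means
complete overlap, 1 perfect separation.

**Baseline sample.** The baseline distribution pools the individual
baseline-bin values across trials (n_trials × 40 values), so baseline and
evoked samples are measured on the same footing: one bin of one trial. This
choice matters for sparse spike counts. At a 5-Hz baseline, ~78% of 50-ms
bins hold zero spikes; against a *continuous* baseline summary (e.g.
per-trial baseline means) a zero bin always loses, pinning the null per-bin
auROC at P(count ≥ 1) ≈ 0.22 — below the inhibitory threshold — and
generating chronic false inhibitory calls. Pooled baseline bins share the
same atoms as the evoked bins, and tie-halving restores the null to exactly
0.5 at any rate (verified by simulation at 5 and 10 Hz).

**Classification.** Bins with auROC > 0.75 mark excitation, < 0.25
inhibition. A call requires ≥3 consecutive bins (150 ms) beyond a threshold;
the persistence rule suppresses isolated crossings, holding the false-call
rate on 1000 simulated no-response pairs below 10% (measured ≈2–3%). When
both polarities occur, the earlier-onset run decides. Onset latency is the
left edge of the first qualifying run; the response ends when the trace
re-enters (0.25, 0.75) for ≥3 bins (or at the trace end); peak latency is
the bin of maximal (excitatory) or minimal (inhibitory) auROC within the
response, earliest bin winning ties; duration is end − onset. The auROC
trace is not smoothed by default (a 3-bin moving average is available in
config). A scalar baseline-vs-evoked auROC — per-trial 2-s window means, the
quantity used for the reference excitatory/inhibitory examples — is always
reported alongside the time-resolved call.

## Correlation and reliability

All correlations are |Pearson r| between single-trial vectors on the
−2 … +6 s grid (window includes the baseline; config-exposed). Zero-variance
trials produce missing values that are excluded pairwise, never imputed.
Cross-signal correlation pairs calcium trial i with ephys trial j; the
headline summary is the matched-trial (diagonal) mean, with full matrices
retained. For spikes, correlations are computed per unit and averaged within
a mouse. Within-odor reliability is the mean pairwise |r| among one odor's
20 trials; between-odors reliability is the mean over the 20 × 140 block
against the other 7 odors' trials; the specificity index is (W − B)/W.

## Odor-pair decoding

Two readouts per unordered odor pair (28 pairs with 8 odors):

* **Pair auROC** between the two odors' per-trial scalars
  (baseline-subtracted 0–2 s evoked means), folded to max(a, 1−a) ∈ [0.5, 1]
  so it reads as a magnitude of difference; raw values are also reported.
* **Logistic regression** (scikit-learn, L2, C = 1.0, tolerance 1e-6) on
  concatenated baseline-subtracted 50-ms-binned features over cumulative
  windows (0, t] up to 5 s (100 bins at the full grid). Features are
  standardized with the training folds' moments only; accuracy is stratified
  10-fold cross-validation (20 trials/class → 2 test trials per class per
  fold), averaged over folds and pairs. Calcium and each band contribute one
  feature channel; spikes contribute one channel per single unit
  (population decoding).

Shuffled labels decode at 0.50 ± 0.10 and linearly separable pairs at ≥0.95
by construction of the validation suite.

## Statistical battery

Group comparisons route purely on (number of groups, paired): Wilcoxon
signed-rank (2 paired; all-zero differences reported as p = 1), Friedman
(>2 paired), Kruskal–Wallis (>2 independent), Mann–Whitney (2 independent),
two-sample Kolmogorov–Smirnov for distribution comparisons, and
Anderson–Darling normality per group, all via scipy. Significance is
p < 0.05. The Tukey-style post hoc after Friedman/Kruskal–Wallis is a
Nemenyi-type comparison of mean ranks against studentized-range critical
values (q_{α,k,∞}); scipy's `studentized_range` supplies the distribution.
Summaries are mean ± SE (SD/√n).

## Synthetic cohort generator

The generator's defaults are the study conditions: 8 odors × 20 trials of
2-s presentations per mouse. Desk-scale defaults shrink the inter-trial
interval (30 → 8 s) and mouse count (11 → 3, 6 cells each) but never the
trial/odor design, which downstream statistics key on; `SimConfig.full_scale()`
restores the in-vivo schedule.

Each mouse draws a ground-truth manifest: every cell–odor pair is assigned
(not sampled, so requested mixtures are realized exactly) a response class —
35% excitatory, 25% inhibitory, 40% none at desk scale — with modulation
depth U(2, 4) for excitatory and U(0.70, 0.95) for inhibitory pairs, onset
latency on the 50-ms grid spanning 0.10–0.60 s (the range typical of
odor-evoked M/T responses), and duration ∈ {1.5, 2.0, 2.5} s. The source
recordings report no quantitative amplitude distributions; these are free
parameters of the generator.

* **Spikes** are inhomogeneous-Poisson trains: a homogeneous baseline
  (U(5, 20) Hz per cell) plus, during responses, a superposed thinned extra
  process (excitatory) or thinning of the baseline train (inhibitory),
  following a trapezoidal profile (linear rise to the peak latency, plateau,
  0.25-s fall). Spikes closer than 1.5 ms are deleted, so every generated
  unit passes the <1-ms ISI criterion by construction. Rates floored at 0;
  ISIs follow the exponential law exactly when refractoriness is disabled.
* **LFP** is 1/f Gaussian background (50 µV RMS; log-log spectral slope −1)
  plus band-limited beta and high-gamma carriers (30/20 µV RMS) whose
  envelopes scale by per-odor gain factors during responses — beta gain
  U(1.8, 2.4) (power gain = amplitude gain², i.e. ~4× at gain 2), high-gamma
  gain U(0.4, 0.6) — reproducing the beta-up / high-gamma-down phenomenology.
* **Calcium** is the summed spike train convolved with a peak-normalized
  double-exponential kernel (rise τ = 0.2 s, decay τ = 1.5 s, GCaMP6s-like;
  the source reports no kernel), scaled so a fractional population-rate
  change δ moves ΔF/F by ≈ coupling·δ/(1+coupling) with coupling 0.5, plus
  Gaussian noise (SD 0.5% of baseline F₀).

One lognormal per-trial amplitude scalar (σ = 0.15) multiplies the spike
modulation and both LFP envelopes, so trial-to-trial amplitude covaries
across signals and the cross-signal correlation structure the analysis
measures exists by construction, with the beta band sharing the calcium
amplitude directly while spikes add Poisson noise. Seeding uses
`numpy.random.SeedSequence` spawning (one child per mouse); identical seeds
yield bit-identical cohorts with no time-based entropy.

`SimConfig.high_snr()` (baseline 15–25 Hz, depths 3–4 / 0.90–0.98, 0.05-s
rise, reduced jitter and noise) is the preset for parameter-recovery
validation: on it, response classes are recovered for ≥97% of cell–odor
pairs, the median onset-latency error is 0 bins, and true vs estimated
onsets rank-correlate at ρ ≈ 0.93.

**What the generator does not emulate.** Sniff-cycle coupling, behavioral
state, photobleaching, movement artifacts, electrode drift, correlated
(non-Poisson) spiking, and any biophysical olfactory-bulb network dynamics.
Responses are piecewise-linear rate envelopes, not mechanistic models.
Passing tests therefore demonstrate that the analysis recovers the
statistical structure it assumes — not that real recordings satisfy those
assumptions. In particular, the LFP's odor specificity is amplitude-only
(per-odor gain scalars), so within- and between-odor correlations are
near-equal for band power by construction; odor-specific *temporal*
templates exist only for spikes (per cell–odor) and calcium (pooled cells),
which is why reliability-direction validation keys on those two signals, and
why the spike specificity index (W−B)/W exceeds the calcium one (pooling
across cells blurs odor identity).

## Numerical choices and problem sizes

Bins are half-open [t, t+Δ) aligned to odor onset; segment windows are
−2/+6 s (−4 s pre for LFP). Degenerate inputs: constant trial matrices give
flat 0.5 auROC traces (not errors); F₀ ≤ 0 or zero baseline power raise
domain errors; zero-variance correlation inputs become missing values.
Validation scales are chosen for a single CPU: desk cohorts of 1–3 mice for
end-to-end checks, 1000 replicates for null calibrations, the full 100-point
cumulative decoding grid for one mouse and 1-s steps in the cohort driver.

## Known limitations

* Absolute wavelet-power calibration degrades near band edges (Gaussian
  scale response roll-off, worst for the narrow theta band); baseline
  normalization cancels it for all within-pipeline uses.
* Onset latencies are estimated at 50-ms resolution; responses rising more
  slowly than the bin width are detected at the first bin whose
  discriminability clears the threshold, which can lag the true onset by a
  bin at moderate SNR.
* Detection power for inhibitory responses is intrinsically low at baseline
  rates of a few Hz (a suppressed 50-ms bin is indistinguishable from an
  ordinary empty one), so low-rate inhibitory cell–odor pairs are often
  called "none" at desk scale; this is a property of the method, not a bug.
* The statistical battery reports the named tests faithfully but does not
  correct across the many source–odor pairs of a cohort; cohort-level
  screening should treat per-pair p-values descriptively.
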