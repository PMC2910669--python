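# Methods

This note documents the model assumptions, the numerical choices and the
defaults of `betasift`, and what the synthetic validation does and does
not demonstrate.

## Signal model and conventions

An epoch is an `M × N` matrix **B** of channel signals in microvolts at a
fixed sampling rate, with sample `k` at `t = t0_offset + k/fs` seconds
relative to the movement event.  The default geometry is a 32-channel
10-20 montage (including bipolar VEOG/HEOG leads) sampled at 1000 Hz over
`[-4, 3)` s, i.e. `N = 7000`.  All analysis windows are half-open
`[start, end)`, so a 1-s window at 1000 Hz is exactly 1000 samples and
adjacent windows never double-count a sample.  The scoring windows are
the reference period `[-3.5, -2.5)` s and the post-movement period
`[0.5, 1.5)` s.  Trials whose EOG channels reach 100 µV peak absolute
amplitude are rejected before any processing.

## Empirical mode decomposition

Sifting subtracts the mean of the natural-cubic-spline envelopes through
the local maxima and minima.  Extrema are strict; plateaus contribute one
extremum at their midpoint (ties to the lower index).  Before spline
fitting, the two outermost extrema at each end are mirror-reflected past
the signal boundary — this suppresses spline end-swings that would
otherwise corrupt the epoch edges.

Sifting of one IMF stops when **both**

* the stoppage statistic `SD_k = ‖h_{k-1} − h_k‖² / ‖h_{k-1}‖²` of the
  last subtraction is below `eps` (default 0.2, the classic sifting
  value), and
* the current pre-IMF satisfies the IMF definition: extrema and
  zero-crossing counts within one of each other, and envelope-mean
  magnitude ≤ 5 % of its peak-to-peak amplitude.

The second condition is part of what makes a component an IMF; with an
`SD`-only stop a substantial fraction of broadband IMFs violate the
definition they are supposed to satisfy.  Safety caps (`max_sift_iters`
= 100 per IMF, `max_imfs` = 16) guarantee termination; the termination
reason is recorded on the result.  Decomposition ends when the remainder
is monotonic (fewer than two interior extrema, or one-signed successive
differences within `1e-12 × peak-to-peak`).  A component that loses its
extrema *during* sifting is not oscillatory and is left in the residue
rather than emitted.  Completeness (`Σ IMFs + residue = input`) is an
algebraic identity of the recursion and is verified to relative L2 error
≤ 1e-8 on every construction.  The whole decomposition is deterministic.

## Spatial maps, template matching, selection

The spatial map of IMF `j` is the vector of Pearson correlations between
the IMF and each channel row; matching against the spatial template is a
further Pearson correlation, hence invariant to channel gain and offset.
The `J` correlations are partitioned into highly/middle/lowly correlated
groups by an **exact** 1-D 3-means: because optimal 1-D clusters are
contiguous in sorted order, all `O(J²)` contiguous partitions are scored
by within-cluster sum of squares and the global optimum taken.  This is
deterministic and removes any dependence on random centroid seeding.
Only the high group is reconstructed.  With fewer than three IMFs the
partition is undefined; the fallback takes the single best IMF provided
its correlation is at least 0.5, otherwise the trial is flagged
unusable.  The monotonic residue never enters the selection.

Reconstruction modes:

* `ci` (default): plain sum of the chosen IMFs — the CI-channel signal.
* `multichannel`: each channel is projected onto each chosen IMF by least
  squares (`β(i,k) = cov(b_i, c_k)/var(c_k)`), giving an `M × N`
  reconstruction whose BR can be searched across channels.

`ci` is the default because the projection coefficients are systematically
shrunk whenever the IMF carries CI-local noise or the source splits
across IMFs (the numerator misses part of the IMF's variance), which
biases the single-trial BR low by ~20–25 % on the default simulation;
the plain IMF sum at the CI is unbiased.  The multichannel BR search is
retained where the conventional-ERS procedure uses it (template
building), where no projection is involved.

## Trial-specific band and filtering

One-second segments are demeaned, Hann-tapered and Fourier-transformed;
amplitudes are normalized so a unit sinusoid at a bin frequency reads
1.0 (worst-case off-bin scalloping ≈ 0.85).  The differential spectrum
(post − reference) is thresholded inside a 13–30 Hz search range:
`two_sd` (threshold `2·SD` of the differential spectrum over the search
range; default) or `zscore` (`Z > 3.09`, the stricter per-bin P < 0.01
rule).  The detected band runs from the lowest to the highest
supra-threshold bin; detections narrower than 2 Hz are widened
symmetrically and kept inside the search range.  The per-trial
false-positive rate of `two_sd` on stationary null data is substantial
(tens of percent — it is a liberal rule); `zscore` reduces it to ~1 %,
and the suite verifies the ordering.  Filtering is a 4th-order
Butterworth band-pass applied forward–backward (zero phase, effective
8th order), so envelope latencies are not delayed.

## Envelope and beta rebound

The AM envelope is the analytic-signal magnitude, computed over the full
epoch so the scoring windows are free of Hilbert edge transients (the
outer 0.25 s of the envelope is edge-unreliable).  BR = envelope maximum
over the post window minus envelope mean over the reference window; it
may be negative (no rectification to zero, preserving the statistic's
distribution for the paired test).  Latency is the time of the post-window
maximum, ties to the earliest sample.

## Template building and the session comparison

Per subject: a task-specific band from trial-averaged reference/post
spectra at the CI (same supra-threshold rule), then per channel band-pass
→ envelope → cross-trial average → `BR_channel = max(post) − mean(ref)`
("for each sensor site").  Per-subject BR vectors are averaged across
subjects into the template, stored unnormalized in µV (Pearson matching
makes scale irrelevant).  Fewer than 20 trials per subject triggers a
warning-level note but is accepted.

`run_session` compares single-trial BRs against the conventional
baseline computed on the *same* trials (internally valid pairing), using
a one-sample Wilcoxon signed-rank of the per-trial BRs against the
conventional BR constant — exact null distribution for n ≤ 25, normal
approximation above.  The averaging-attenuation experiment reports, for
each group size `k`, the mean BR over disjoint consecutive groups of `k`
averaged envelopes (`k = 1` is exactly the mean single-trial BR); with
latency jitter this curve decreases in `k`.

## The synthetic generator

The generator emulates the statistical structure the method assumes:

* **Source**: a narrowband carrier (single tone by default; optionally a
  multi-tone band carrier whose components are spaced 2 Hz — two analysis
  bins — apart so each is resolvable under the Hann kernel) multiplied by
  an amplitude profile: 2 µV baseline, suppression to 50 % between −2 s
  and movement, recovery by +0.5 s, plus a Gaussian rebound bump
  (SD 0.3 s, default amplitude 2 µV) at the trial's latency.  A sustained
  "plateau" rebound shape is available for experiments that require a
  stationary post-window amplitude contrast.
* **Trial jitter**: latency ~ N(1.2 s, 0.45 s) clipped to [0.1, 2.4] s;
  carrier frequency ~ N(20, 1) Hz; amplitude ~ 20 % relative SD.
* **Forward model**: fixed non-negative weights, Gaussian fall-off with
  schematic 10-20 scalp distance from C3 (1.0 at C3, ≈ 0.7 at FC3/CP3,
  ≈ 0.02 at C4, 0 on EOG leads).
* **Noise**: independent per-channel 1/f background at 1 µV RMS; common
  60 Hz line at 3 µV (± 30 % per channel); low-pass (< 0.3 Hz) drifts at
  15 µV RMS; ocular artifacts (150 µV bump coupled into EOG/frontal
  channels) with probability 0.05.

Everything is deterministic given `(seed, trial_index)`.

Two defaults deserve justification.  The background RMS (1 µV) puts the
beta-band noise envelope (~0.2 µV) well below the smallest rebound of
interest (1 µV) — the regime in which single-trial beta work operates;
with much stronger in-band noise no envelope method can read a 1 µV
rebound off a single trial.  The line amplitude (3 µV) keeps the mains
component in its own high-frequency IMFs: when the line is several times
the beta source, vanilla EMD mode-mixes the strong rebound segments into
the line IMF and the spatial-template selection loses part of the source
— a known limitation of single-channel EMD with strong narrowband
interference (see Limitations), not of the selection logic.

What the generator does **not** emulate: volume-conduction head models,
mu rhythm and multi-source interactions, non-stationary background
spectra, realistic blink/saccade morphology, electrode drift/popping.
Passing tests therefore demonstrate correctness of the algorithmic chain
under the assumed signal model, not performance on arbitrary real
recordings.

## Validation scenarios and problem sizes

The end-to-end suite runs on 7 s / 1000 Hz epochs: 50 random signals for
the EMD contract; 100 trials per condition for band detection and BR
recovery; 20 sessions of 100 trials for the single-trial-vs-conventional
ordering; 4 × 100 trials for template building plus 100 validation
trials.  The amplitude-recovery scenario bounds the rebound latency to
[0.6, 1.4] s so the injected peak lies inside the post window — an
amplitude-recovery experiment can only score peaks it observes; latency
truncation under full jitter is studied separately by the attenuation
experiment.  The band-detection scenario uses the plateau rebound (a
stationary 3× post/reference contrast per bin, which is what a
contrast-scale-free 2·SD rule can meaningfully detect).

## Known limitations

* **Mode mixing**: with strong narrowband interference (mains ≫ beta) or
  highly intermittent sources, EMD splits the target across IMFs or
  merges it with the interferer; the high-correlation cluster then
  captures only part of the source.  Ensemble/masked EMD variants would
  mitigate this but are out of scope.
* The `two_sd` band rule is liberal on single trials; sessions where no
  band should exist will still yield bands in a sizable fraction of
  trials.  Use `zscore` when false positives are costlier than misses.
* The multichannel reconstruction's least-squares coefficients are noisy
  for channels dominated by large out-of-band activity (drifts), which
  can occasionally misrank the most-reactive channel.
* Templates are montage-locked: channel labels must match exactly; no
  interpolation across montages or reference schemes is attempted.
* EDF ingestion carries no event anchor; the caller must supply the
  epoch's `t0_offset`.
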