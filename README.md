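# betasift

Single-trial extraction of post-movement beta oscillations from
multichannel EEG, using empirical mode decomposition (EMD) with
spatial-template selection of intrinsic mode functions.

## The problem

After a voluntary movement, the sensorimotor cortex produces a transient
increase of ~20 Hz (beta) amplitude — the *post-movement beta rebound*
(BR).  The rebound is non-phase-locked and jitters from trial to trial in
latency, frequency and amplitude, so the conventional approach (band-pass
with a fixed band, rectify, average over dozens of trials) smears the
response and underestimates it.  `betasift` extracts the rebound from
**one trial at a time**:

1. **EMD** — the channel of interest (CI, typically C3 for right-hand
   movement) is sifted into intrinsic mode functions
   `x(t) = Σ_k c_k(t) + r(t)`, each `c_k` an oscillation whose extrema and
   zero-crossing counts differ by at most one and whose upper/lower
   spline-envelope mean is ~zero; `r(t)` is a monotonic residue.
2. **Spatial maps** — each IMF gets a length-M vector of Pearson
   correlations with every channel: its scalp weight distribution `V_j`.
3. **Template matching** — maps are correlated against a spatial template
   `T` (per-channel conventional-ERS beta rebounds); the resulting
   `ρ_1..ρ_J` are split into highly-/middle-/lowly-correlated groups by an
   exact 1-D 3-means, and only the high group `s_1` is kept.
4. **Reconstruction** — the chosen IMFs are summed into noise-suppressed
   sensorimotor activity (optionally projected onto every channel).
5. **Trial-specific band** — the amplitude spectra of a post-movement
   window (0.5–1.5 s) and a reference window (−3.5 to −2.5 s) are
   subtracted; bins of the differential spectrum above `2·SD` (or
   `Z > 3.09`) inside a 13–30 Hz search range define this trial's beta
   band.
6. **Envelope and BR** — the reconstruction is band-passed (zero-phase
   Butterworth), rectified into its AM envelope
   `m(t) = |M_BP(t) + i·H(M_BP(t))|` (Hilbert transform), and
   `BR = max m(t) over the post window − mean m(t) over the reference
   window`, with the peak time as the single-trial latency.

A synthetic-EEG generator with exact ground truth (focal beta source under
C3, 1/f background, mains line, drifts, ocular artifacts, per-trial
jitter) makes every stage testable without any recordings.

## Worked example

```python
from betasift import (SimConfig, SpatialTemplate, forward_weights,
                      simulate_session, run_session)
from betasift.synthetic import MONTAGE_32

cfg = SimConfig(seed=42, n_trials=100)          # 32 ch, 1 kHz, [-4, 3) s
epochs, truth = simulate_session(cfg)
template = SpatialTemplate(weights=forward_weights(),
                           channel_labels=MONTAGE_32, ci_label="C3")
summary = run_session(epochs, template)
print(f"single-trial BR {summary.br_mean_uv:.2f} ± {summary.br_sd_uv:.2f} uV, "
      f"conventional {summary.conventional_br_uv:.2f} uV, "
      f"Wilcoxon p = {summary.wilcoxon_p:.2g}")
```

prints

```
single-trial BR 1.51 ± 0.68 uV, conventional 0.69 uV, Wilcoxon p = 9.9e-13
```

With the default 0.45 s latency jitter, cross-trial averaging smears the
rebound: the conventional averaged-ERS estimate (0.69 µV) is less than
half the mean single-trial value (1.51 µV), and the paired Wilcoxon test
confirms the ordering.  Per-trial results (selected IMFs, template
correlations, detected band, BR, latency, QC flags) are in
`summary.table()`.

The same workflow is available from the shell:

```bash
betasift simulate --out-dir session/ --n-trials 100 --seed 42
betasift template --session session/ --out template.tsv
betasift compare  --session session/ --template template.tsv --out-dir results/
betasift attenuation --session session/ --template template.tsv --out att.tsv
```

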