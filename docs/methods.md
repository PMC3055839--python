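# Methods

This note records the model implemented by `tilewave`, the conventions and
defaults chosen where the design was genuinely open, the study conditions
used by the test and acceptance suites, and the known limitations.

## Signal model

A two-color tiling array measures red (Cy5, immunoprecipitated) and green
(Cy3, genomic control) fluorescence for 50-mer probes laid along the
genome. Each chromosome is rendered as two per-base step signals: a base
inside exactly one probe takes that probe's intensity; a base inside the
overlap of two neighboring probes is assigned to the nearer probe, i.e.
the overlap is split at its midpoint (an odd overlap gives the extra base
to the upstream probe — a deterministic tie-break); untiled bases are
exactly zero. Coordinates are 0-based, half-open throughout, matching BED
conventions. Probes may overlap only with their immediate neighbors;
triple overlaps and duplicated coordinates are rejected rather than
silently resolved. Chromosomes are independent analysis units processed as
single arrays at 1-base resolution (a 30 Mb chromosome is one `2^25`
array; ~0.8 GB of coefficients per channel, inside desk memory).

## Wavelet pyramid

Both signals are zero-padded on the right to the next power of two and
decomposed with the orthonormal Mallat pyramid on the Coiflet-1 filters.
The taps are constructed in closed form (`rec_lo = √2/32·[1−s, 5+s,
14+2s, 14−2s, 1−s, −3+s]` with `s = √7`; `dec_lo` its reversal;
high-pass by the quadrature-mirror rule) and kept at full double
precision: 4-decimal truncations would break perfect reconstruction at
the ~1e-4 level. The low-pass taps sum to √2 and the high-pass to zero.

Conventions, fixed once and used everywhere:

* **Analysis** is the stride-2 periodic correlation
  `A(m+1)[n] = Σ_k dec_lo[k]·A(m)[(2n+k) mod N]`, `k = 0..5`; likewise
  the detail with `dec_hi`. No extra prefactor: with the orthonormal taps
  this gives exact energy conservation and perfect reconstruction, and
  the red/green ratio statistic is invariant to any common rescaling
  anyway (only the fixed validity floor sees absolute scale).
* **Synthesis** is the adjoint, the exact inverse for an orthonormal
  periodized bank; it coincides with the usual reconstruction-filter
  formula up to the fixed index alignment.
* **Boundary**: periodic extension on the padded dyadic array. The pad
  and any untiled tail are zero, so wrap-around touches only zeros in
  practice, and invertibility is exact for any even length (verified down
  to length 2).
* **Dominant children**: coefficient `n` at level `m+1` draws most of its
  value from the three largest-|tap| offsets (0.8526, 0.3849, 0.3379 at
  offsets 3, 2, 4), i.e. coefficients `2n+2, 2n+3, 2n+4` at level `m`.
  Two descents give 7 distinct grandchildren `4n+6..4n+12`: the three
  3-sets overlap, so the deduplicated support set has 3 + 7 = 10 members.
* Equivalence with PyWavelets' periodization mode holds up to a circular
  shift of one coefficient when PyWavelets is run with the filter bank in
  this orientation (PyWavelets convolves, i.e. correlates with reversed
  filters, and offsets by one); the test suite uses this as an
  independent-engine oracle.

## Scoring

With levels `M1 ≤ m ≤ M2` chosen so that targeted peak widths satisfy
`2^M1 ≤ L ≤ 2^M2`, levels `M1−2..M2` are thresholded (the two extra
levels only ever support the consistency check):

1. Coefficient pairs with either channel at or below the validity floor
   (default 1.0, raw fluorescence units) are masked: such coefficients
   sit on untiled gaps or padding where the log transform is meaningless.
2. Per level, `ln(A_red/A_green)` over unmasked positions is fit by a
   Gaussian — sample mean and SD (n−1 denominator), enrichment outliers
   deliberately *not* trimmed; a robust median/1.4826·MAD alternative is
   available but off by default.
3. Candidates satisfy `(logratio − μ_m·[center]) > α·σ_m`. Mean-centering
   is the default because the aggregated null log-ratio carries a small
   positive offset (see "noise model" below) and because it is robust to
   global dye imbalance; `center=False` thresholds the raw log-ratio.
   Natural log is used throughout; the α·σ rule is base-invariant.
4. A candidate at a callable level is confirmed if at least
   `min_consistent` (default 3) of its 10 dominant supporters pass the
   threshold at their own levels. No per-level quota is imposed on how
   the supporters distribute over `m−1` vs `m−2`.
5. Confirmed coefficients trace back through dominant children to level
   0. The dominant index set stays contiguous under descent, so the
   traceback reduces to its endpoints: level-0 span
   `[2^m·n + 2(2^m−1), 2^m·n + 4(2^m−1) + 1)`, clipped to the unpadded
   extent and shifted by the chromosome origin. Spans from overlapping or
   book-ended confirmed coefficients merge (levels union, scores max)
   into final hit regions.

σ_m is fit pooling all chromosomes of the array, matching the fact that a
single hybridization produces one noise regime. Scores are
`(logratio − μ_m)/σ_m`, max over contributing coefficients.

### Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `m1, m2` | 8, 11 | peak widths 256–2048 bp (Pol II-style); `m2=12` for broad histone domains |
| `alpha` | 3.0 | threshold multiplier; in practice chosen via the FPR operating point |
| `floor` | 1.0 | coefficient validity floor, raw intensity units |
| `min_consistent` | 3 | supporters required among the 10 dominant children+grandchildren |
| `center` | on | subtract fitted `μ_m` before thresholding |

## FPR estimation

Red intensities are permuted uniformly across all probes genome-wide
(no stratification), green and coordinates untouched, and the identical
pipeline — including refitting σ_m on the shuffled coefficients — is
re-run. `FPR = mean(N_shuff)/N`. A single permutation gives a
high-variance estimate, so the default is 10 replicates with the mean
reported; `n_replicates=1` reproduces the single-shuffle procedure, and a
flag can freeze the original σ_m for sensitivity analysis. The α for a
requested FPR (e.g. 5%) is found by bisection, reusing the same shuffle
replicates at every α so the estimated FPR is deterministic and
essentially monotone in α; tolerance ±0.01 in FPR.

## Synthetic arrays

The generator emulates the tiling design the method was built for:
50-mer probes every 38 bases (12-base overlaps), untiled gaps from an
alternating exponential tiled/gap process (defaults: gap fraction 0.5,
mean gap 2 kb — on a 30 Mb genome this yields ~384k probes, the scale of
an ENCODE-style array). Green intensities are log-normal
(`meanlog 7.0`, `sdlog 0.5`: median ~1100 arbitrary fluorescence units,
well above the floor); red equals green times a triangular enrichment
profile (evaluated at the probe midpoint) times `exp(ε)`,
`ε ~ N(0, 0.3²)` per probe. Spike peaks (default 100 per array, widths
uniform 200–2000 bp, apex folds uniform 3–6 — real spike-in
concentrations are not published, so folds are drawn from a configurable
range) are placed disjointly inside tiled territory by rejection
sampling. Everything is deterministic per seed.

Calls are scored truth-side: TP = truth intervals overlapped (≥1 base by
default; a minimum-overlap fraction is configurable) by any hit, FP =
hits overlapping no truth, sensitivity = TP/n_truth, FP ratio =
FP/n_truth. The ROC sweep shares the decomposition and σ fits across the
descending α grid, which is exactly equivalent to independent full runs.

### What the generator does and does not emulate

It reproduces the features the caller's assumptions rest on: probe
geometry with gaps, multiplicative log-normal intensity noise shared
between channels, triangular peaks across the targeted width range. It
does **not** model probe-sequence affinity or GC bias, dye-specific
nonlinearity, replicate structure, or spatially correlated
cross-hybridization. Passing benchmarks therefore demonstrate the
machinery and its calibration under the stated noise model, not
performance on any particular laboratory dataset.

## Noise model fine print

Two measured properties of the statistic are worth stating plainly:

* **Jensen offset.** A level-`m` coefficient averages `e^ε` over the
  probes in its support, so the null log-ratio has mean ≈ `σ_ε²/2`
  (≈0.045 at `σ_ε = 0.3`) at aggregated levels, not 0. Mean-centering
  (the default) removes it; with `center=False` the offset is simply
  absorbed into a slightly more permissive effective threshold.
* **Scale mixture on gapped arrays.** Coefficients at gap edges average
  few probes and have inflated variance. The per-level log-ratio on a
  realistically gapped array is therefore a scale mixture of normals with
  visibly heavy tails (normal-quantile correlation ~0.86–0.94), and its
  α·σ tail exceedance overshoots the Gaussian prediction. On fully tiled
  territory with homogeneous background the statistic is very close to
  Gaussian (quantile correlation ≥ 0.998; tail exceedance within ~2
  binomial SE at α up to 3). The calibration studies in the test suite
  run on such homoskedastic nulls, which isolate the distributional
  claim; on gapped data the shuffle FPR, not the Gaussian tail, is the
  operative error control.

## Study conditions used by the suites

Chosen once for the test and acceptance suites (sized to run on one CPU
in minutes) and fixed:

* Calibration null: 30 Mb, fully tiled, `background_sdlog 0`,
  `noise_sd 0.3`, seed 20 (~790k probes; ≥10⁴ coefficients at every level
  8–11).
* Spike-in benchmark: generator defaults (30 Mb, ~384k probes, 100
  spikes), `m1=8, m2=9`, seeds 1–5; α sweep 6.0 → 2.5.
* FPR mechanics: 3 Mb gapped spike array (30 peaks) for the 5%-target
  bisection; 2 Mb gapped nulls, 20 shuffle replicates, for the
  exchangeability checks (with 10 replicates the replicate range covers
  an exchangeable count only ~82% of the time; 20 replicates bring the
  theoretical coverage to ~90%).
* Full-scale run: generator defaults with `m1=8, m2=11` plus a
  10-replicate FPR estimate.

## Known limitations

* Single-chromosome arrays larger than ~100 Mb at 1-base resolution would
  need chunking or coarser rendering; no binning is implemented.
* No per-peak p-values or FDR: error control is the global shuffle FPR.
* Detail coefficients are computed but never scored (the signal of
  interest lives in the approximations); no detail-thresholding denoiser
  is provided.
* Dye-bias/GC normalization is out of scope; inputs are raw two-channel
  intensities.
* The traceback clips at array ends rather than wrapping with the
  periodic boundary; hits abutting the (zero) padded tail are truncated
  to the tiled extent.
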