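# Methods

## Burst definition and detection

A single-electrode burst is a maximal run of consecutive spikes whose
successive inter-spike intervals (ISIs) are all ≤ `max_isi_s`, retained
iff the run has ≥ `min_spikes` spikes. Defaults (`min_spikes = 5`,
`max_isi_s = 0.1 s`) reproduce the AxIS Navigator single-electrode burst
detector settings used for CytoView hippocampal cultures. Two
conventions are deliberate and documented rather than inferred:

- **Boundary inclusivity.** An ISI exactly equal to `max_isi_s` joins
  the burst (≤, not <): "maximum ISI" reads as inclusive. Whether the
  vendor detector agrees at exact equality is unknowable from its
  output alone; sampling at 12.5 kHz makes exact ties measure-zero in
  practice.
- **Duration.** `last − first` spike time. Vendor advanced-metrics
  durations exceed this by one sample period (1/12500 s) on
  single-burst electrodes (e.g. 0.09224 vs 0.09216 s), i.e. the vendor
  appears to add one sampling interval; this package reproduces the
  `last − first` convention, and the two stay within any tolerance down
  to ~1e-4 s.

Detection is a vectorized run-split on `diff(times) > max_isi_s`.
Correctness is tested against a brute-force oracle that enumerates all
contiguous index ranges, keeps those satisfying the definition, and
selects the maximal ones; the two agree exactly on thousands of random
trains, and detection is local (trains separated by more than
`max_isi_s` detect independently).

## The four burst parameters and windowing

Per electrode and labeled half-open window `[t0, t1)` (membership by
burst **start** time, so any partition of the recording conserves
counts exactly):

| parameter | definition |
|---|---|
| `n_bursts` | count of in-window bursts |
| `mean_duration_s` | arithmetic mean of burst durations |
| `mean_spikes_per_burst` | arithmetic mean of burst sizes |
| `mean_burst_isi_s` | mean over bursts of `duration/(size − 1)` |

The last is the mean of per-burst mean ISIs, **not**
`mean_duration/(mean_size − 1)`; the two differ on any heterogeneous
electrode (the bundled reference well's B6_12 row — 0.1212651/10.2 ≠
0.012609743 — fixes the convention, and a regression test keeps the
distinction). All three means are reported as missing (NaN), never 0,
for electrodes with no in-window bursts.

Well-level summaries are across-electrode mean ± SEM, with SEM the
sample (n−1) standard deviation over √n. Burst counts include inactive
electrodes as zeros (all 16 electrodes are physically present and
observed nothing); the other three parameters average over active
electrodes only, where they are defined. Both choices are switchable
(`count_policy`), because vendor documentation does not state its rule.

## Cross-software validation

`compare_with_reference` compares per-electrode parameters against a
flat reference CSV cell by cell at an absolute tolerance (default 1e-3,
i.e. agreement to 3 decimals); electrodes present on one side only are
flagged but not fatal. The bundled reference table (well B6, 597-s
baseline recording, two independent pipelines) passes at 1e-3 on 63 of
64 cells; the one failing cell (B6_23 spikes-per-burst, |Δ| ≈ 0.0166)
is a known discrepancy between the two upstream pipelines whose cause
(detector edge case vs rounding) cannot be resolved from the published
numbers, and the comparison semantics treat it as the expected
exception.

## ICC(2,k)

Consistency between single-electrode means uses the Shrout–Fleiss
two-way random-effects, absolute-agreement, average-of-k-raters
intraclass correlation,

    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n),

computed from the explicit two-way ANOVA decomposition (SS_subject +
SS_rater + SS_residual = SS_total, df = n−1, k−1, (n−1)(k−1)). The
decomposition conserves total SS to ~1e-16 relative error; identical
rater columns give exactly 1; an all-equal matrix raises an
undefined-result error rather than returning 0 or 1. The
implementation is cross-checked in the test suite against pingouin's
independent implementation (agreement ~1e-15).

Which dimension plays "subjects" is genuinely open when ICC is reported
per parameter per time period, so both orientations are first-class:
subjects = wells with raters = in-well electrode positions (one window
at a time), or subjects = time windows with raters = the electrodes of
one well. No imputation is ever performed on incomplete matrices; the
caller may opt in to dropping incomplete rater columns.

**Finite-sample bias under the null.** For i.i.d. noise the ICC(2,k)
*estimator* is not mean-zero: at n = 20 subjects × k = 8 raters its
mean over 500 matrices is ≈ −0.12 (median ≈ 0.01), because the
Spearman–Brown step amplifies the slightly negative null single-rater
ICC; the bias shrinks with n (≈ −0.01 at n = 100). This is a property
of the standard estimator (pingouin reproduces it to machine
precision), worth knowing when reading small-n ICC values near zero.

## Synthetic generator

The generator emulates the structure of a bursty multi-well recording,
not its biophysics: per electrode, inter-burst gaps are exponential
with a hard floor, burst sizes are shifted Poisson
(`min_spikes + Poisson(mean − min_spikes)`), and within-burst ISIs are
log-normal. Defaults — 597 s recording, 10 bursts/min, mean size 20
(min 5), ISI median 6 ms with σ = 0.5, gap floor 0.25 s, 24 wells × 16
electrodes — were chosen once to produce the parameter ranges seen on
real baseline electrodes (1–211 bursts per 597 s, sizes 7–42, mean ISIs
4–29 ms) and are configuration, not code.

Numerical choices that make ground truth *exact*:

- Timestamps are integer ticks of the 12.5 kHz sampling grid (80 µs),
  converted to seconds only at the boundary, mirroring real data's
  granularity.
- Within-burst ISIs are clipped to at most `floor(max_isi/Δt) − 1`
  ticks and gaps to at least `floor(max_isi/Δt) + 2` ticks — one tick
  of slack on each side — so converting tick counts to floats can never
  move an ISI across the detector threshold. Hence generated burst
  boundaries equal detected boundaries on every seed (asserted, not
  assumed), and the ground-truth means are recomputed from the emitted
  quantized spike times with the same float arithmetic the pipeline
  sees, making end-to-end recovery exact rather than approximate.
- One global seed expands to per-electrode substreams keyed by a stable
  hash (CRC-32) of the electrode token, so enlarging the plate never
  perturbs existing electrodes' trains.

What the generator does **not** emulate: spike-level structure outside
bursts (no tonic firing, so every spike belongs to a burst),
within-well spatial correlation, electrode noise/artifacts, or
biophysical dynamics. Passing the recovery tests therefore shows the
*bookkeeping* (windowing, per-electrode aggregation, I/O round-trips)
is correct under realistic magnitudes; it says nothing about detector
behaviour on tonic or borderline firing, which the brute-force oracle
tests cover instead.

## Scale of the shipped checks

The test suite and the acceptance script run entirely on synthetic or
bundled plain-text inputs: random-train oracle comparisons use 1000
trains of ≤ 50 spikes; conservation and recovery checks use 1–2 wells
and 90–300 s recordings across up to 20 seeds; ICC noise studies use
500 matrices of 20 × 8. These sizes give exact (count) or
machine-precision (mean) assertions; nothing in the method scales worse
than linearly in spikes, so larger plates change runtime, not
conclusions.

## Known limitations

- Only the AxIS burst-list CSV dialect (plus a configurable alias map
  and preamble skip) is parsed; binary vendor formats and hierarchical
  "advanced metrics" reports are out of scope (a flat CSV comparator
  covers validation).
- Network-level (multi-electrode) bursts, synchrony metrics, firing
  rate metrics, and ICC confidence intervals are not implemented.
- A burst straddling a window edge is attributed entirely to the window
  containing its start; windows that cut bursts mid-flight therefore
  attribute all of that burst's spikes to the earlier window.
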