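# meaburst

Single-electrode burst analysis for multi-electrode array (MEA)
recordings, downstream of AxIS Navigator (Axion BioSystems) processing.

MEA plates embed a grid of microelectrodes in each culture well and
record extracellular action potentials ("spikes") from excitable cells.
A *burst* is a run of at least `min_spikes` consecutive spikes on one
electrode whose every inter-spike interval (ISI) is at most `max_isi`
(defaults: 5 spikes, 100 ms — the AxIS single-electrode burst
definition). Most analysis software summarizes bursting per well;
`meaburst` computes and plots the four standard burst parameters **per
electrode** over user-defined time windows, which exposes the spatial
variability of a network (uneven cell distribution, electrodes near
grounding pins, local responses to a stimulus such as KCl) that a
whole-well average hides.

For each electrode *e* and half-open window *[t0, t1)* it computes:

- **number of bursts** `n_e`,
- **average burst duration** `mean(d_i)` (s),
- **average spikes per burst** `mean(s_i)`,
- **average mean within-burst ISI** `mean(d_i / (s_i − 1))` (s) — the
  arithmetic mean over bursts of each burst's own mean ISI, *not*
  `mean(d) / (mean(s) − 1)`.

Well-level summaries report the across-electrode mean ± SEM
(sample SD / √n); electrodes with zero bursts count as 0 in the burst-count
mean and are excluded from the other three (undefined) means.
Across-electrode consistency is quantified with the Shrout–Fleiss
intraclass correlation ICC(2,k) — two-way random effects, absolute
agreement, average of k raters:

```
ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)
```

with MSR/MSC/MSE the subject/rater/residual mean squares of the two-way
ANOVA of the n×k matrix (subjects = wells or windows, raters =
electrodes).

The package also contains an ISI-threshold burst detector that
reproduces the AxIS definition from raw spike timestamps, and a seeded
synthetic spike-train generator whose bursts survive detection exactly
(by construction, and asserted in tests), so the entire pipeline is
testable without recordings.

## Worked example

```python
import meaburst as mb
from meaburst.datasets import load_b6_baseline_reference

# bundled reference: well B6 of a 597-s baseline hippocampal recording,
# analysed independently by two software pipelines
ref = load_b6_baseline_reference("r_pipeline").set_index("electrode")
row = ref.loc["B6_13"]          # an electrode with exactly one burst
mb.mean_burst_isi(row.mean_duration_s, int(row.mean_spikes_per_burst))
# 0.00576  -> a 0.09216 s burst of 17 spikes has a 5.76 ms mean ISI

report = mb.compare_with_reference(
    load_b6_baseline_reference("r_pipeline"),
    load_b6_baseline_reference("axion"),
    tol=1e-3,
)
[(m.electrode, m.parameter) for m in report.mismatches]
# [('B6_23', 'mean_spikes_per_burst')]
# 63 of the 64 cells agree to 3 decimals; the one exception is a known
# spikes-per-burst discrepancy (26.524862 vs 26.541436) on B6_23.
```

The same pipeline from the shell, on a synthetic plate:

```sh
# synthetic 24-well plate, KCl-like rate doubling in the second window
meaburst simulate --config synth.yaml --seed 1 --out fixture/
meaburst summarize --input fixture/bursts.csv \
    --windows windows.yaml --level electrode --out summary.csv
meaburst icc --input summary.csv --parameter n_bursts \
    --orientation windows-by-electrodes --well B6
# ICC(2,k) = 0.988227  (n=2 subjects x k=16 raters; MSR=1815.03, MSC=18.9146, MSE=23.7646)
# -> the 16 electrodes of B6 agree almost perfectly on the rate change
meaburst plot electrode --input fixture/bursts.csv --windows windows.yaml \
    --well B6 --parameter mean_duration_s --out b6.png
meaburst validate --input fixture/bursts.csv --reference metrics.csv --tol 1e-3
```

where `windows.yaml` is a list of labeled windows, e.g.
`- {label: baseline, t0_s: 0, t1_s: 120}`, and `synth.yaml` holds the
generator parameters (here `modulation: {kcl: 2.0}` over those same
windows). Every figure writes a sidecar
CSV of exactly the values it drew; electrode panels sit at their
physical 4×4 grid position, and electrodes with no bursts are drawn as
empty panels labeled "inactive", never as zero bars.

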