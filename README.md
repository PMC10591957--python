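# diaqc

Data-driven optimization and quality control for data-independent
acquisition (DIA) mass spectrometry, including multiplexed (plexDIA,
mTRAQ-labeled) single-cell proteomics.

Optimizing a DIA method means balancing coupled trade-offs: more MS2
isolation windows reduce spectral complexity but lengthen the duty
cycle, so each elution peak is sampled fewer times and its apex may be
missed; equal-width windows waste ion-trap capacity because precursor
density is far from uniform in m/z; extra MS1 survey scans improve
precursor-level sampling at a small cycle-time cost. `diaqc` makes
these trade-offs measurable from the two artifacts every DIA experiment
already produces — the per-scan metadata in an mzML file and the search
engine's report TSV — and provides channel-aware QC metrics for
routine multiplexed acquisition, plus a fully synthetic 3-plex LC-MS
run generator so everything is testable without instrument data.

## The models at the core

**Duty-cycle timing.** Per-scan time on an Orbitrap is
`max(transient(R), τ_max) + overhead`, where `transient(R)` follows the
doubling law (256 ms at R = 70,000) and `τ_max` is the maximum ion
injection time; accumulation parallelizes with the previous transient.
Cycle time is the scan count times this; the MS1 sampling interval Δ is
the largest survey-to-survey gap (with cycle wrap-around). A Gaussian
elution peak of width σ sampled with spacing Δ captures at best
`exp(−d²/2σ²)` of its apex (d = apex-to-nearest-sample distance), with
median `exp(−Δ²/32σ²)` over a uniform phase.

**Window placement.** Given an MS1 ion-current histogram h(m/z), the
equal-TIC scheme puts boundaries at the k/n quantiles of the cumulative
histogram (linear interpolation within bins); the equal-precursor
scheme uses empirical quantiles of identified precursor m/z with
midpoint cuts, so per-window counts differ by ≤ 1.

**plexDIA QC.** Data completeness between identification sets A and B
is the Jaccard index `J = |A∩B| / |A∪B|`; quantification variability
per cell is the median over proteins of CV = sd/mean of peptide
relative levels (per-cell median-normalised, then divided by each
peptide's across-cell mean); translated identifications — those that
exist only by propagation from another channel — are counted separately
from direct ones.

## Worked example

`python examples/duty_cycle_tradeoffs.py` prints the window-count
trade-off for a Q-Exactive-style method (70k resolving power, 300 ms
max injection, 2.5 s-sigma elution peaks):

```
 MS2 windows  cycle (s)  points/peak  median apex fraction
           2        0.9        11.11                 0.996
           4        1.5         6.67                 0.989
           6        2.1         4.76                 0.978
           8        2.7         3.70                 0.964
          10        3.3         3.03                 0.947
          12        3.9         2.56                 0.927
          16        5.1         1.96                 0.878

8 MS2 windows, 251 ms max injection:
  1 survey scan : MS1 interval 2.30 s
  2 survey scans: MS1 interval 1.28 s (cycle only 1.11x longer)
```

Read: a 2-window method cycles in 0.9 s and essentially never misses an
elution apex (99.6% of apex intensity at the median phase), but
co-isolates half the precursor range per spectrum; a 16-window method
samples each precursor only every 5.1 s, collects fewer than 2 points
per peak, and loses 12% of apex intensity at the median — the
quantitative penalty behind "more windows, worse ratios". Adding a
second survey scan to an 8-window method nearly doubles MS1 sampling
frequency for an 11% cycle-time cost.

`python examples/window_placement.py` simulates a complex 3-plex run
and shows the accumulation-time signature of bad window placement:
with equal-m/z windows the low-m/z windows fill the trap in 6–23 ms
while the top window idles at 243 ms of its 251 ms ceiling; re-tiling
the same run by equal ion current flattens per-window accumulation
(variance 8818 → 49 ms²). `python examples/plexdia_qc.py` shows
channel-level QC flagging a degraded channel: its completeness drops to
0.84 (vs 0.99 between clean channels) and its median within-protein CV
rises to 0.42 (vs 0.17).

## Command line

```
diaqc simulate --config cfg.yaml --out bundle/        # synthetic run bundle
diaqc windows  --strategy equal_tic --mzml run.mzML --out scheme/
diaqc qc --mzml run.mzML --report report.tsv --out qc/   # TSVs + HTML report
```

`diaqc qc` writes one tidy TSV per metric and a self-contained HTML
report (tables and embedded plots) covering: per-channel intensity
distributions, intersected-precursor ratio distributions, precursor and
protein counts (direct vs translated), identifications vs FDR
threshold, identifications across the gradient, MS1/MS2 accumulation
times per window and retention time, the TIC ion map with mean-m/z
trace, peptide-like feature counts and elution lengths, MS1-quantified
fraction, pairwise data completeness, within-protein CV, and precursor
signal-to-noise.

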