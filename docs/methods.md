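# Methods

`diaqc` models and measures the acquisition behaviour of
data-independent acquisition (DIA) proteomics experiments, with
particular support for multiplexed (plexDIA, mTRAQ-labeled) single-cell
runs. This note documents the models, the defaults and why they were
chosen, what the bundled simulator does and does not emulate, and the
numerical conventions.

## Duty-cycle timing model

An Orbitrap DIA duty cycle is a repeating sequence of `n_ms1` survey
scans and one MS2 scan per isolation window. Per-scan time is

    scan_time = max(transient, max_injection_time) + overhead

because ion accumulation for the next scan proceeds in parallel with
the previous transient: whichever is longer dominates. The transient
table follows the standard doubling law (17.5k → 64 ms, 35k → 128 ms,
70k → 256 ms, 140k → 512 ms at m/z 200) and is overridable per
instrument. Overhead defaults to 0 ms; with these defaults the model
reproduces the familiar desk numbers for a Q-Exactive at 70k resolving
power and 300 ms maximum injection: a 1 MS1 + 2 MS2 method cycles in
0.9 s and a 1 MS1 + 16 MS2 method samples precursors every 5.1 s.

The MS1 sampling interval is the largest gap between consecutive survey
scans, computed with wrap-around across cycle boundaries, so one survey
scan gives interval = cycle time and unevenly placed surveys are scored
by their worst gap.

**Apex sampling.** A Gaussian elution peak of width sigma sampled on a
grid of spacing Δ attains at best `exp(-d²/(2σ²))` of its apex
intensity, where d is the apex-to-nearest-sample distance. For a
uniformly random grid phase, d is uniform on [0, Δ/2], so the median
captured fraction is `exp(-Δ²/(32σ²))`; a Monte-Carlo sampler
cross-checks this closed form in the tests. Points-per-peak uses a 4σ
base width.

## Isolation-window placement

Window schemes are contiguous tilings of the precursor m/z range;
boundaries are half-open `[lower, upper)` so a precursor exactly on a
boundary belongs deterministically to the upper window.

* **equal m/z** — n windows of width (range / n).
* **equal TIC** — boundaries at the k/n quantiles of the cumulative MS1
  intensity-vs-m/z histogram, linearly interpolated within bins so the
  result converges as the bin width shrinks. Runs of zero-mass bins
  that would collapse several boundaries are spread evenly across the
  empty span. Pro-rating clips partial edge bins when the histogram
  overhangs the range.
* **equal precursor count** — boundaries at midpoints between the order
  statistics flanking each empirical k/n quantile; per-window counts
  then differ by at most one. Cuts landing inside a run of duplicate
  m/z values shift to the nearest end of the run.

Optional rounding snaps interior boundaries to 0.5 Th for instrument
method editors and re-validates the tiling (off by default).

## Search-report semantics

Reports are read in the DIA-NN TSV dialect with a small alias map
(`Ms1.Area`/`Ms1.Translated`, `Precursor.Quantity`/`Precursor.Translated`).
The plexDIA channel is parsed from mTRAQ tags in the modified sequence
(dialects `mTRAQ-K-0`, `mTRAQ-d4`, `mTRAQ-n-8`, bracket or parenthesis,
anywhere in the sequence); conflicting deltas raise. A record is
**translated** iff its translated q-value passes the threshold while
its direct channel q-value (or the run q-value when no channel q-value
exists) does not — i.e. the identification exists only by cross-channel
propagation. Which q-value column gates identifications is a caller
option (`gating_column`, default the run-wide `Q.Value`), since engines
differ here. Duplicate (run, precursor, charge) rows keep the lowest
q-value and log the collision.

## QC metrics: definitions and conventions

* **Data completeness** is the Jaccard index `|A∩B| / |A∪B|` between
  two identification sets, reported for all pairwise channel (or run)
  combinations. Two empty sets score 1 (logged). Cross-channel
  comparisons identify a precursor by (stripped sequence, charge) so
  the label tag itself does not separate channels; cross-run
  comparisons keep the modified sequence.
* **Quantification variability** per cell (run × channel): peptide =
  stripped sequence, charge states collapsed by summed MS1 intensity;
  each cell is first normalised by its median peptide intensity; each
  peptide is then divided by its mean across cells (relative level);
  per protein with ≥ 3 quantified peptides the CV = sample SD (ddof 1)
  / mean of relative levels; the cell's score is the median CV over
  proteins. The per-cell median normalisation is what makes the metric
  exactly invariant to a global per-cell intensity scale — without it,
  rescaling one cell perturbs every cell's relative levels through the
  across-cell means. With relative levels (2, 4) the protein CV is
  √2/3 ≈ 0.4714.
* **Ratio distributions** use only precursors quantified in every
  compared group (the intersected set) and report per-group log2 ratios
  against a reference group; the `by` axis selects runs or channels.
* **Intensity distributions** are log10 histograms with shared
  0.1-decade bins across groups.
* **ids_vs_fdr** counts records with q ≤ t on an unfiltered table and
  is non-decreasing by construction.
* **MS2 accumulation per window** groups MS2 scans by (isolation
  center, width) and averages injection times per RT bin, skipping
  missing values. Defaults: RT bin 60 s, m/z bin 10 Th, all bins
  half-open.
* **TIC ion map / mean-m/z trace** sum MS1 centroid intensity per
  (RT, m/z) bin; the trace is the intensity-weighted mean m/z per RT
  bin; the map's total mass equals the summed peak intensities exactly
  (up to float addition order).
* **Precursor S/N** takes the MS1 scan nearest in RT, matches the
  centroid within ±10 ppm of the precursor m/z and divides intensity by
  the per-peak noise value; missing (never zero) when no noise array,
  no match, or no precursor m/z.

## Feature detection

The feature finder is a deliberately simple greedy trace builder, not a
reimplementation of an isotope-pattern-scoring tool: centroids in
consecutive MS1 scans within 10 ppm of a trace's running median m/z are
chained (closest first, one centroid per trace per scan); a trace
survives one missed scan (gap tolerance 1, chosen for robustness to
sampling dropouts); traces spanning ≥ 3 scans become features. A
coeluting trace at +1.00335/z (z in 1..4) assigns the charge and is
absorbed into the envelope, so one envelope yields one monoisotopic
feature. "Elution length at the base" is defined as rt_end − rt_start
of the trace. Feature-to-precursor matching accepts the first three
isotope positions of an identified precursor, since those peaks are
explained by it. A Dinosaur-style TSV can be read in place of the
built-in finder.

## The simulator: what it emulates, and what it does not

`simulate.simulate_run` generates a full 3-plex acquisition under an
explicit generative model so every metric has ground truth:

* **Precursor m/z** — two-component log-normal mixture over
  380–1400 Th, calibrated so the low-m/z half of the range holds the
  large majority (~70%) of precursors and the top equal-m/z window is
  nearly empty, the way tryptic-digest precursor densities behave. (A
  looser calibration with more mass above the midpoint would leave
  measurable flux in the top window and blur the accumulation-ceiling
  contrast the window-placement analysis is about.)
* **Abundance** — log-normal, median 2e7 arbitrary units, σ_log 1.8
  (~3 decades of dynamic range, single-cell-like).
* **Elution** — Gaussian peaks, σ log-normal with median 2.5 s; apex RT
  mapped from a per-precursor hydrophobicity surrogate (a uniform %B
  threshold) through the piecewise-linear LC gradient. The default
  gradient is a 30-min 8–32 %B ramp at 200 nL/min.
* **Channels** — mTRAQ d0/d4/d8 copies offset by 4.0071·k/z (one label
  site), scaled by per-channel abundance factors, with optional
  per-channel log-normal peptide noise to model degraded samples.
* **Scans** — scheduled by the duty-cycle model; per scan the
  instantaneous ion flux into the scan's m/z window (3 isotopes per
  trace, ratios 1 / 0.5 / 0.18, plus a constant noise-floor flux) sets
  the injection time by the AGC law
  `min(max_injection, AGC_target / flux)`; centroids above the limit of
  detection are emitted with 2 ppm mass jitter and a constant per-peak
  noise value.
* **Report emulation** — phenomenological by design: direct
  identification probability grows with the precursor's flux share
  within its isolation window at apex (a spectral-complexity proxy,
  threshold 2%); MS1 quantification requires ≥ 1 survey-scan sample
  above the LOD (applied per sampled scan, not at apex);
  non-identified channel copies of an identified peptide become
  translated with probability 0.75; q-values are drawn so that direct
  IDs pass a 1% threshold, translated IDs fail their direct channel
  q-value, and a 15% tail of marginal rows above the threshold
  exercises FDR curves. It exists to exercise the metrics, not to
  model a search engine.
* **Contaminants** — 20% of all ion traces are singly charged,
  low-m/z-biased, broader "decoy" features absent from the report,
  giving feature-matching a known answer.

It does **not** emulate: fragment spectra or chimeric-spectrum
interference, retention-time structure from real sequences, isotope
envelopes beyond three peaks, mass-calibration drift, charge states
beyond 2–3 (peptides) and 1 (contaminants), or engine-specific scoring.
Passing tests therefore validate the metric implementations and the
qualitative acquisition physics (AGC fill behaviour, sampling-frequency
effects), not search-engine behaviour on real data.

Determinism: all randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns (population / identification /
report noise / scan jitter), so equal seeds give bit-identical bundles.

## mzML subset

No installed Python package parses mzML in this environment, so scan
reading is a small streaming reader over `lxml.iterparse` covering the
subset the package consumes: spectrum-level cvParams (ms level, TIC),
scan start time with unit accession (seconds/minutes/hours; minutes
assumed, with a warning, when undeclared — the common Thermo
convention), ion injection time, isolation-window target and offsets,
and 32/64-bit float binary arrays with zlib or no compression,
including named non-standard arrays (per-peak noise). The writer emits
exactly this subset (64-bit, uncompressed, RT in minutes) plus run-level
userParams carrying instrument settings; a Bioconductor mzR cross-read
verifies the writer in the test suite. Isolation width is lower + upper
offset; absent offsets leave the width missing rather than defaulted.

## Problem sizes and test conditions

The test suite and examples run the simulator at 500 precursors × 3
channels on a compressed 10-minute active gradient (1000 precursors for
the window-placement experiments, mirroring the more complex sample
used for that analysis), which keeps a full simulated run around two
thousand scans — large enough for stable medians and fractions, small
enough for quick iteration. Ratio-recovery checks use 500 precursors;
at that size configured channel log2 factors are recovered within
±0.1.

## Known limitations

* The identification model has no notion of spectral libraries or
  fragment evidence; absolute identification rates are not meaningful,
  only their responses to acquisition parameters.
* `equal_tic_windows` reflects the histogram it is given; computed from
  a run acquired with strongly unequal windows, MS1 survey data (full
  range) should be used, as the CLI does.
* The CV metric needs ≥ `min_peptides` peptides per protein per cell;
  sparse single-cell data can leave cells without a score (reported as
  missing, never zero).
* The greedy feature finder merges coeluting traces that happen to sit
  one isotope spacing apart even when unrelated; at realistic densities
  this inflates charge assignments slightly, and is documented as a
  divergence from full isotope-pattern scoring.
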