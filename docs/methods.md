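# Methods

This note documents the model and the numerical and design choices behind
`eegsmallworld`, in the order the data flow through the pipeline.

## Recording conventions and preprocessing

The analysis montage is the 19 scalp channels of the 10–20 system (frontal
pole through occiput, temporal chain named T3/T4/T5/T6 with modern
T7/T8/P7/P8 aliases accepted at ingestion).  Recordings are resampled to
256 Hz (polyphase) if the source differs.  `preprocess` applies an average
reference (instantaneous mean of the 19 channels subtracted) and a
zero-phase 4th-order Butterworth band-pass of 1–100 Hz, applied
forward–backward; only the pass band is a recording convention, the filter
family and order are package choices.

Synthetic recordings are emitted **already referenced**: re-referencing a
signal whose generators live on arbitrary channel subsets injects a scaled
common-mode copy (−k/19 of each oscillator, for a k-channel set) into every
channel, which purely relative peak criteria then detect, destroying the
planted connectivity.  The simulate→analyze configuration therefore defaults
to `reference="none"`, `bandpass=False`; the clinical preset
(`clinical_config()`) enables both.

Epoch schedule: one 300-s interval per hour of registration through 48 h
after the arrest, then one per 2 h, placed at the earliest covered time of
each slot (placement within the hour is not dictated by the data, so the
earliest artifact-free placement is used).  Artifact handling consumes an
epoch-level include/exclude table; automated artifact detection is out of
scope.

## Spectral peak detection

2-s Hann windows stepped by 1 s give 299 windows per 300-s epoch and a
0.5 Hz bin grid.  Amplitudes are moduli of the Fourier coefficients,
normalised to equivalent-sinusoid microvolts (a bin-centred tone of
amplitude A reads A).  Spectra carry a 0.5 Hz margin beyond the analysed
1–25 Hz band so the edge bins have four neighbours for criterion (c);
without the margin, 1 and 25 Hz would be systematically excluded.

The three significance criteria are implemented exactly as stated, with
choices where the statement is under-determined:

- (a) the "surrounding 4 s" neighbourhood is the set of windows whose start
  times lie within ±2 s of the current window (≤ 5 windows), truncated at
  epoch edges.
- (b) the reference maximum is taken over the 1–25 Hz band of the same
  window and channel.
- (c) "larger than" is strict; equal neighbours (in particular all-zero
  channels) fail.
- thresholds (5%, 50%) are configuration values defaulting to the printed
  ones.

**Amplitude floor.**  All three criteria are ratios, hence scale-invariant:
a channel containing only noise always yields a handful of "significant"
bins (its local maxima above half its own spectral maximum), so a
low-voltage or iso-electric record would paradoxically produce large
noise-driven networks.  Clinically, a detectability floor exists — EEG waves
below a few microvolts are not readable oscillations.  `CriteriaConfig`
therefore offers an optional absolute floor in equivalent-sinusoid
microvolts, off by default at the module level (the criteria as published
are purely relative) but set to 4 µV in the default pipeline configuration.
Calibration: white noise of standard deviation σ has a per-bin equivalent
amplitude of ≈ 0.077 σ (Rayleigh scale) and an expected per-window maximum
of ≈ 0.21 σ, so at the simulator's background levels (σ ≤ 5 µV) noise bins
stay below ≈ 1.1 µV, well under the floor, while planted oscillators
(≥ 6 µV) pass it.

## Networks and small-world metrics

Per second, channels sharing ≥ 1 significant frequency are connected; the
diagonal flags any oscillation.  Conventions:

- *network size*: electrodes with at least one inter-electrode connection —
  a lone oscillating electrode is "no network".
- *number of connections*: nonzero cells of the full 19×19 matrix (max
  361, matching the complete-network arithmetic); the undirected edge count
  m = (count − trace)/2 feeds all graph algorithms.  Reports can switch to
  the undirected convention (`connection_count: edges`).
- *C*: Watts–Strogatz clustering averaged over present electrodes (degree-1
  nodes contribute 0).
- *L*: mean shortest-path distance over reachable ordered pairs of present
  electrodes; unreachable pairs are excluded, keeping L finite for
  fragmented networks without selecting a component.
- degenerate networks (size < 2): C = 0, L = 1, SWI = 0.

Normalisation uses uniform G(n, m) random graphs (not degree-preserving
rewiring — the matching is by size and edge count only), n_rand = 50 draws
per (n, m), seeded per (n, m) so values are independent of evaluation
order, and cached.  C_rel = C/⟨C_rand⟩ is undefined (NaN) when the
reference mean clustering is 0; NaNs propagate to epoch averages, which are
computed metric-wise over the valid seconds.  Both SWI = C_rel/L_rel (the
magnitude that cohort tables show, near 1) and SWI_raw = C_raw/L_raw (the
magnitude the worked examples print, near 0.3–0.5) are emitted.

Per-second matrices within an epoch are deduplicated before metric
computation; steady oscillatory activity makes long runs identical, which
keeps a 300-s epoch's cost at a few dozen metric evaluations.

## Cohort statistics

Subject summaries average each metric over the epochs starting inside
0–24/0–48/0–72 h; subjects whose registration stopped early contribute what
they have.  Contrasts:

- pooled-variance two-sample t-tests per metric (the test family for the
  published group comparisons; Welch was the alternative and pooled was
  chosen as the classical default),
- Spearman rank correlation with the CPC score, mid-ranks for ties; the
  two-sided p uses exhaustive permutation for n ≤ 8 (40,320 permutations)
  and the tie-corrected large-sample approximation above that — exact
  enumeration beyond n = 8 grows factorially for negligible practical gain,
- the composite **sum of centered ranks**: each of network size, number of
  connections, L_rel and C_rel is ranked across the cohort, C_rel with
  inverted orientation so all four components point toward survival
  (survivors show larger size, more connections, longer relative paths and
  lower relative clustering), each rank column is centred at zero, and the
  per-subject score is the sum of the four centred ranks.  Centring makes
  scores sum to zero and allows negative group means (raw ranks cannot go
  negative); the orientation is configurable.  Groups are compared with the
  Wilcoxon rank-sum test on the scores, using the exact null distribution
  when the scores are tie-free.
- ROC analysis of the (negated) composite score against poor outcome,
  reporting the maximum sensitivity among thresholds with zero false
  positives.

Subgroup contrasts follow the clinical groupings: bilateral-absent vs
present SSEP, and iso-electric + low-voltage pooled vs diffuse slowing
(burst suppression and "other" excluded from the visual-EEG contrast).

## The synthetic cohort

`generate_epoch` renders planted sinusoids (frequencies on the 0.5 Hz grid,
separated by ≥ 1.5 Hz so no two peaks interact within a Hann main lobe) on
chosen channel subsets over independent Gaussian noise, with archetypes
gating the envelope: continuous (normal/slowed), low-voltage (≤ 10 µV
oscillators), iso-electric (≤ 2 µV noise only), burst suppression (fixed
10-s cycle, duty-cycle fraction "on") and generalized periodic discharges
(difference-of-Gaussians biphasic transients, identical on all channels, at
the discharge rate).  The implied adjacency (channels sharing an oscillator
frequency) is returned as ground truth; noise-free epochs reproduce it
essentially exactly through the full detection path.

`generate_cohort` draws labelled subjects.  Survivors (CPC 1–4, skewed
toward 1–2) carry rich continuous backgrounds; non-survivors (CPC 5) a
clinical mixture: 60% continuous slowed background, 20% burst suppression,
16% low-voltage, 4% iso-electric.  The mixture follows the observed
composition of monitored post-anoxic cohorts, where a substantial fraction
of non-survivors retain continuous slowed EEG and truly iso-electric
records are rare; it is deliberately *not* dominated by near-silent
records, which would make the groups trivially separable.

Continuous backgrounds are parameterised on subject-level axes with
independent within-group variation: the number of local oscillator "cores"
(spatially clustered channel sets; drives network size), core width
(connection count), the number of spatially distributed "bridge"
oscillators (joins the cores into one component; drives relative path
length) and the clustered fraction of core placement (relative clustering).
A minority of epochs undergo two-sided transient state excursions —
suppression, arousal, fragmentation, integration — giving every metric a
heavy within-group tail, as ICU EEG state changes do.  Group parameter
ranges were chosen so the per-subject metric distributions overlap between
groups (as the published per-group means and standard deviations do) while
all five effect directions remain stable.

**What the simulator does not emulate**: 1/f background spectra, spindles,
reactivity, inter-channel noise correlation, volume conduction and common
drivers (which the shared-frequency method cannot distinguish from true
coupling), and electrode artifacts.  Passing tests therefore validate the
pipeline's arithmetic and its behaviour under the stated statistical
structure, not clinical performance on real recordings.

## Problem sizes and runtime choices

Defaults keep a full study desk-sized: 10 + 10 subjects, three 300-s epochs
each (hours 1, 30, 60, populating all three aggregation windows), n_rand =
50 random graphs per (n, m) with caching, ~15 s per simulated cohort
analysis.  The replication study in the acceptance suite runs 20 seeded
cohorts.

## Known limitations

- The composite-score replication at 10 + 10 subjects is at the edge of
  what the exact Wilcoxon rank-sum distribution allows: its two-sided
  p-value cannot go below 2/C(20,10) ≈ 1.1·10⁻⁵, so whenever a single
  metric's t-test lands below that, the composite cannot be the most
  significant contrast, whereas at the published cohort size (27 vs 29) the
  corresponding floor (~10⁻⁸) never binds.  The effect *directions* are
  recovered robustly; the composite is usually, but not always, the
  strongest contrast at this reduced scale.
- Criterion (a)'s 5% threshold is so permissive that it almost never
  excludes a bin; it is implemented as printed and left configurable.
- EDF export writes plain 16-bit EDF (1-s records); EDF+ annotations are
  not written.
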