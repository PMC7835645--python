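# Methods

## ECoG processing and the burst-suppression ratio

The quantitative-EEG chain is: common-average reference (subtract the
instantaneous cross-channel mean; requires ≥ 2 channels, idempotent) →
4th-order Butterworth band-pass 1–50 Hz applied forward–backward
(zero phase; order and band configurable) → polyphase anti-aliased
resampling to exactly 254 Hz (the 1,526 → 254 Hz ratio is the non-integer
127/763; the output rate is set exactly in metadata) → suppression
segmentation → windowed BSR.

Suppression is a maximal run of samples with |x| ≤ `amp_threshold` lasting
*strictly* longer than `min_duration`. Conventions fixed here:

* threshold boundary inclusive (|x| equal to the threshold counts toward
  suppression); duration boundary strict (a run of exactly 0.5 s is not
  suppression);
* default threshold 25 µV, minimum duration 0.5 s, 60 s windows with 30 s
  step; epochs are anchored at the recording start and trailing partial
  epochs are dropped;
* per-channel BSR = suppressed time overlapping the epoch / 60 s; the
  cross-channel mean gives one value per epoch (BSR is averaged across
  channels, not the signals);
* `bsr_pipeline` flags the first and last 2 s as invalid for segmentation
  (zero-phase filter transients). The low-level `detect_suppression`
  defaults to no trimming so its contract ("an all-zero 10 s channel is
  one [0, 10) interval") holds on raw input; pass `edge_exclude` to
  change either.

The 25 µV default deserves a note: burst-suppression thresholds in the
rodent ECoG literature are tens of microvolts, while source instruments
sometimes print the same number in millivolts — three orders of magnitude
above cortical amplitudes. The threshold is therefore an explicit
parameter everywhere and the default is the physiologically plausible
microvolt reading. The epoch anchor (recording start vs asphyxia onset)
is likewise configurable via the recording's `t0_offset` metadata.

## Synthetic ECoG

The generator is a two-state semi-Markov process. The instantaneous
suppression probability decays exponentially,
p(t) = p_end + (p_start − p_end)·2^(−t/half-life), defaults
p_start = 0.9, p_end = 0.2, half-life 1,800 s — the qualitative shape of
early post-resuscitation recovery over a 4 h recording. State durations
are exponential (gamma optional) with means scaled so the local
stationary suppressed fraction equals p(t):
mean_supp = (b̄ + s̄)·p(t), mean_burst = (b̄ + s̄)·(1 − p(t)), with
b̄ = 3 s, s̄ = 6 s by default. This makes the long-run suppressed fraction
analytically controllable (s̄/(s̄ + b̄) for constant p) and the degenerate
p = 0 or 1 configs exact single-state tracks.

Bursts are 1–30 Hz band-limited Gaussian noise at 100 µV RMS; suppression
is white Gaussian at 5 µV RMS — amplitudes chosen to straddle the 25 µV
threshold by a factor of four in either direction ("separable"). One state
track is shared by all channels (burst suppression is a global brain
state), with independent channel noise. An optional EKG artifact adds
periodic 10 ms biphasic spikes to all channels; it exists to exercise
contamination-flag plumbing, not to support artifact detection.

What a green recovery test establishes: that the segmentation and
windowing arithmetic recover a known suppressed fraction when amplitude
separates the states. It does not establish performance on real data,
where suppression amplitude varies continuously, artifacts are broadband,
and states are not piecewise stationary.

Small known bias: suppression runs shorter than 0.5 s are (correctly, per
the definition) not counted, so the estimate sits ≈ 0.3 % below the track
fraction at the default duration means — far inside the 0.05 recovery
tolerance.

## Neurological Deficit Scale

The rubric ships as TOML and is self-checked at load (block maxima
19/21/6/6/6/12, total 70, zero level present everywhere). Two printed
ambiguities in the source instrument are encoded explicitly and are
editable in the file: respiration scores 6/3/0 (consistent with the /19
arousal maximum 10 + 3 + 6), and the turning-alley item scores abnormal
performance 0 (unlike the 3/1/0 pattern of its neighbours). Limb strength
and pain response are each two entries (left/right forelimb, max 3 each),
giving the printed /6 block totals.

Not every integer in [0, 70] is a legal total (e.g. 69 is unreachable:
no combination of legal drops sums to 1). The cohort generator therefore
decomposes a noisy target total into exact legal subscores with a
suffix-reachability dynamic program, rounding unreachable targets to the
nearest reachable total (ties toward the lower). Cohort summaries use
mean ± SD when the normality gate passes in both groups, else median +
IQR with linear-interpolation (type-7) quartiles — stated here because
quartile conventions differ across software.

Generator defaults: control mean totals 15.4 / 48.5 / 52.0 / 55 at
4 / 24 / 48 / 72 h (the 72 h value is a plausible continuation of the
published trajectory, which switches to medians there), group shift
+7 points, noise SD 6. An animal dying at time t has sheets only for
timepoints strictly before t, which reproduces the published control
group sizes 12 / 11 / 10 / 10.

## Stereology

Sections are indexed anterior → posterior; default 30 µm thickness over
bregma +3.24 to −14.64 mm (span 17,880 µm), sampling every 12th section
from a seeded uniformly random start offset. Note the internal tension in
the source protocol: one-of-twelve 30 µm sections is a 360 µm period, not
the 330 µm it also states; the interval *in sections* is the primitive
here and both readings are expressible. Flanking sections sit
±round(90 µm / thickness) indices from a marked section, clipped with a
warning at the series ends. Field halving keeps ⌈n/2⌉ fields, uniformly
without replacement, seeded.

Counting frame: x rightward, y upward, µm; top/right are inclusion
borders, bottom/left exclusion borders, and exclusion dominates at
corners (top-left and bottom-right excluded, top-right included). An
object counts iff its disk footprint intersects the closed frame and does
not touch the bottom or left border segment; for radius-0 points this is
membership in (x₀, x₀+w] × (y₀, y₀+h]. That half-open convention is the
r → 0 limit of the footprint rule and is exactly what makes a
border-sharing tiling count every point once — the property the unbiased
frame exists for, verified by Monte-Carlo (mean count = density × area)
and by an explicit tiling test. Region totals sum per animal × region and
flag (never impute) missing sections.

## Statistics

* **Kaplan–Meier / log-rank** are first-principles implementations.
  The log-rank accumulates O, E and the hypergeometric variance over
  distinct event times; censored subjects remain in the risk set of their
  own time point (censoring after events at ties). Deaths during failed
  resuscitation are events at t = 0 h; a death exactly at the 72 h
  horizon is an event, not a censoring. Null calibration (empirical size
  0.052 at nominal 0.05 over 1,000 simulated null cohorts) is part of the
  test suite. lifelines is used in tests as an independent cross-check,
  never as the implementation.
* **Normality gate**: the named test is Kolmogorov–Smirnov, but mean and
  SD are estimated from the sample, so the default is the Lilliefors
  variant (plain KS available for parity with naive usage). Constant or
  n < 4 samples are degenerate: the gate fails with an explicit flag.
* **Mann–Whitney U** uses the exact null distribution when n₁+n₂ ≤ 20
  without ties (verified against full permutation enumeration), else the
  tie-corrected normal approximation; the method used and both U₁/U₂ are
  reported. The headline statistic is U for the first group.
* **Mixed RM-ANOVA** (between group × within timepoint) is delegated to
  pingouin behind the module surface, with listwise exclusion of subjects
  missing any within level (recorded in the result metadata) and no
  sphericity correction by default (irrelevant for 2-level within
  factors). A hand-rolled balanced sums-of-squares decomposition serves
  as the test oracle. Published F statistics with denominator df larger
  than the animal count are not reproducible from any standard
  repeated-measures accounting; this module states its own df convention
  in the output rather than chasing them.
* **Šidák**: α′ = 1 − (1 − α)^(1/m), adjusted p = 1 − (1 − p)^m clipped
  to [0, 1].

## Analyte simulation

Gaussian draws around group (× pre/post-arrest, for glucose) means,
truncated at zero; defaults are the published group summaries (control
glucose 219.5 ± 16.4 → 277.6 ± 30.6 mg/dL, restricted 147.1 ± 15.7 →
143.4 ± 42.4; ketone 0.6 ± 0.2 vs 1.4 ± 0.5 mmol/L; corticosterone,
glucagon, insulin likewise). Pre and post values are drawn independently
per animal — no within-animal correlation — which makes the
repeated-measures error conservative relative to real paired data; the
configured interaction is still detected at α = 0.01 in ≈ 84 % of
simulated cohorts of 14 per group. Glucagon and insulin follow the prose
direction (lower under restriction); the source's bracket ordering for
those two panels is internally inconsistent, so this reading is flagged
as an interpretation.

## Pipeline

One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`, so stages are independently reproducible;
the manifest records config, per-stage seeds and SHA-256 checksums of
every output, and a failing stage leaves a FAILED marker plus partial
outputs. Configs are read from TOML or JSON and written as JSON (the
runtime has no TOML writer). Signal I/O is delimited-table (CSV) only:
EDF support would require pyedflib/mne, which are not part of the
supported runtime. The pipeline's default ECoG block simulates 120 s —
a deliberately scaled-down stand-in for a 4 h recording so demo runs and
tests stay fast; the 1 h, 4-channel recovery property runs in the
acceptance tests.

## Known limitations

* The synthetic ECoG has no physiological forward model (no ischemia
  dynamics, no spectral evolution within bursts) and no artifact
  *detection* is provided; contaminated channels are excluded by flag.
* The deficit-scale generator targets totals, not per-component
  psychometrics; component correlations are whatever the decomposition
  induces.
* Counting-frame unbiasedness is exact for point objects; for extended
  objects the footprint rule is the standard field practice but tiling
  exactness is only guaranteed for points.
* Group-level published curves (per-epoch BSR, NDS trajectories) are not
  reproduced numerically: the underlying per-animal data are unpublished,
  so simulation-recovery properties stand in for them.
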