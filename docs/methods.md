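# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `micacardio`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

All imaging computation happens on a common voxel grid: masks and tissue
priors must match the functional grid exactly and no resampling is performed
anywhere (registration is treated as preprocessing and is out of scope).
Physiological traces carry explicit validity flags; dropouts are marked, not
encoded as sentinel values, so cleaning knows exactly where they were.
Every stage draws its randomness from a SHA-256-derived sub-seed of one
master seed, so a pipeline run is a pure function of (config, seed) and
reruns are byte-identical.

## Masked spatial ICA

Runs are demeaned per voxel inside the mask and scaled by one global factor
per run (the overall in-mask standard deviation), then temporally
concatenated, reduced to k dimensions and unmixed by fixed-point negentropy
maximisation with the tanh contrast (FastICA; tolerance 1e-4, max 500
iterations, seeded). Spatial maps are z-scored over voxels and oriented so
the heavier z tail is positive (ICA signs are arbitrary, but winner-take-all
segmentation needs positively signed peaks). Per-run mixing time courses are
recovered by least-squares projection of the normalized run data onto the
maps.

A design note on normalization: per-voxel unit-variance scaling (as used by
MELODIC-lineage tools) is available via `voxel_norm=True`, but it is not the
default because it provably flattens a noiseless source's spatial amplitude
profile into its support indicator — every in-support voxel is rescaled to
unit variance — which destroys exact map recovery on clean data. The global
per-run scaling preserves amplitude profiles; on the noiseless two-source
phantom the recovered maps correlate with the generating blobs at r > 0.999.

## Model-order selection

Split-half reproducibility: subjects (runs grouped by subject; a subject's
runs never straddle halves) are randomly split in half `n_splits` times
(default 30; 10 in the desk-scale experiments). For each candidate K, ICA is
run on both halves, components are matched one-to-one by Hungarian
assignment maximising the summed |spatial correlation| (matching uses |r|
because ICA signs are arbitrary; the sign is retained separately), and the
mean matched |r| is recorded. Splits where either half failed to converge
are excluded from the mean and counted; by default only K values that
converged on **every** split are eligible (`min_converged_frac=1.0`), and
ties break toward the smaller K. On the default 8-source phantom the curve
peaks at K=8 with mean r ≈ 0.96, falling off in both directions, and
dimensionalities ≥ 10 start failing to converge — the convergence penalty
does real work.

## Specificity filtering and segmentation

Stage-1 dual regression of each run on the component maps gives per-run time
courses; stage-2 regression onto a cuboid volume around the mask (bounding
box + 2 voxels) gives per-component activation maps. The specificity score
is Σ A·(gm+wm) / Σ A·csf with A the group-mean |beta| and the tissue priors
as weights ("weighted quotient"); a component with zero CSF-weighted
activation gets a +inf sentinel, which participates in the exclusion rule as
the largest finite score (so one empty-CSF component cannot mask genuinely
low quotients). Components with score < mean − 1 SD (sample SD) are
excluded. Winner-take-all segmentation labels each mask voxel with the
surviving component of highest z (label = component index + 1); exact ties
go to the lowest index, and voxels where every kept z ≤ 0 stay background —
the rule is silent on excluded-component territory, and background is the
conservative choice.

Component maps can be reduced to display probability maps with a 1/2/3-class
Gaussian mixture fitted to the z histogram by EM, model-selected by BIC
(null = class with mean nearest 0), posterior of the non-null classes
thresholded at 0.5. On pure N(0,1) maps BIC selects one class and nothing
survives; EM failure or a degenerate map falls back to |z| > 2.3 with a
warning.

## Physiological processing

* Pulse: zero-phase 4th-order Butterworth band-pass 0.64–2.5 Hz; beat
  detection by local maxima exceeding 0.4 x the rolling signal amplitude
  (2 s window) with a 0.4 s refractory interval. The returned beat series
  exposes insert/delete hooks — the "semi-automated" review step.
* Blood pressure: dropouts plus valid samples outside the 1st–99th
  percentile of the valid samples are replaced by linear interpolation
  (nearest-value extension at the ends); more than 50 % excluded is a
  quality error. The output keeps replaced samples flagged invalid and
  records the cleaning in trace metadata, making re-application an exact
  no-op; recomputing percentile thresholds from an already-trimmed signal
  would otherwise creep inward by ~2 % of the mass on every pass, so exact
  idempotence under re-estimated thresholds is impossible by construction.
* Beat-to-beat series: IBI_i = t_{i+1} − t_i timestamped at beat i; systolic
  value = max of cleaned pressure within the beat interval.
* Spectra: beat series are linearly interpolated to 4 Hz (standard HRV
  practice), detrended, and analysed with a Welch periodogram (Hann taper,
  segment = min(span, 120 s), 50 % overlap). Band fractions use half-open
  bin membership lo ≤ f < hi and normalise by all power above the 0.005 Hz
  high-pass floor, so fractions over a disjoint partition sum to exactly 1.
* Band definition: per subject, the highest interior spectral peak within
  the physiologic window (LF 0.04–0.15 Hz from systolic-pressure spectra;
  HF 0.15–0.5 Hz from respiration) is located; the band is mean ± sample SD
  of the peaks. The pipeline enforces a minimum half-width (0.02 Hz) because
  a synthetic cohort can produce a degenerate zero-width band.
* Paired statistics: classical paired t on differences; Cohen's d is the
  mean condition difference over the pooled condition SD — the convention
  that reproduces the worked systolic-pressure example (d = −0.95 from
  132.6/113.4 mmHg, both SD 20.2). All-zero differences return the null
  record (t=0, p=1, d=0); constant non-zero differences are degenerate and
  raise.
* Motion QC: per consecutive volume pair, RMS over the 8 corners of an 80 mm
  cube centred at the origin of the rigid-transform displacement; block
  means are compared LBNP vs Rest with the paired t.

## Permutation inference

The paired non-parametric test is a sign-flip of subject-level differences.
For scalars (band fractions) the t statistic is flipped exhaustively when
2^n fits the permutation budget (always for n ≤ 12), else with random
flips; exhaustive p-values are #{|t_perm| ≥ |t_obs|}/2^n and are
seed-independent. For maps, the voxelwise paired t image (both tails,
via enhancing the map and its negation) is TFCE-enhanced (E=0.5, H=2,
26-connectivity, dh = max/100 — the canonical defaults) and each voxel is
referred to the permutation distribution of the image-wide maximum enhanced
statistic. TFCE is evaluated inside the target-mask bounding box only; this
is exact, since connected components cannot leave the mask support.
Zero-variance voxels get t = 0 when the mean difference is also zero,
otherwise a large sentinel (±100). Empirical FWER measured over 200 null
datasets (6×6×6 target, n=8, exhaustive 256 flips) is ≈ 0.04–0.06 at
nominal 0.05.

The spectral criterion is applied per component and band at p ≤ 0.05 without
multiplicity correction, mirroring the uncorrected spectral arm of the
two-criterion design; the connectivity criterion is FWE-corrected within
each target map. The dual criterion (spectral AND connectivity, either
target) is monotone in both alphas.

## The phantom generator

The generator produces the statistical structure the analysis assumes, at
desk scale: a 24×24×12 grid with a 600-voxel ellipsoidal mask, k=8 Gaussian
blob sources (σ=1, truncated at 2σ) on two staggered rings, adjacent blobs
overlapping ~15 % by volume (neighbouring nuclei abut; masked ICA must cope
with partial overlap), 4–20 runs of 240 volumes at tr = 1.25 s with
alternating LBNP/Rest labels (consecutive pairs form one synthetic subject)
— a miniature of a 2 mm / 1.23 s / 4×233-volume protocol. Source time
courses are drift + condition-gated sinusoids at 0.1 and 0.28 Hz + white
noise; imaging noise sd 0.5 (map-peak units).

Three generator choices deserve emphasis:

* **Variance-neutral spectral injections.** A band-gain change alone also
  changes total time-course variance, which dual regression correctly
  reports as a connectivity change across the source's whole territory (the
  real-data analogue is "within-nucleus" connectivity change). To provide
  sources that are *spectral-only* ground truth, the stochastic noise power
  compensates the sinusoid power difference, so injected band changes alter
  spectral composition at constant amplitude.
* **Coupling as off-profile shared signal.** A shared latent added to two
  sources' time courses is mathematically invisible to a joint stage-2 dual
  regression: every target voxel remains in the span of its own time-course
  regressor and partial betas never move. Couplings are therefore directed
  injections of one source's stochastic component into the *core* of the
  partner's territory (0.6 x radius blob, orthogonalized against the span of
  all source maps plus intercept over mask voxels). Orthogonality keeps the
  injection out of every stage-1 time course — so coupling changes
  connectivity without touching any component's spectrum — and the default
  couplings all point into the dual-criterion sources' territories.
* **Per-run heterogeneity.** Gains, noise, overall amplitude and coupling
  weight are jittered per run (CV 0.15, clipped to [0.5, 1.5]). Without it a
  synthetic cohort has near-zero between-subject variance and epsilon-level
  ICA map-estimation biases become "significant" under sign-flip tests — a
  degenerate regime no real cohort occupies.

The physiological generator produces a Gaussian-upstroke pulse train whose
instantaneous rate carries respiratory sinus arrhythmia (depth 0.08, halved
under LBNP), blood pressure as a 120/80 mmHg beat-synchronous envelope with
a 0.1 Hz Mayer oscillation (4 mmHg, doubled under LBNP), fixed-SD (2 mmHg)
per-beat systolic jitter (the amplitude-independent variability floor
without which a Mayer-depth change could not move the LF power *fraction*),
respiration at 0.28 Hz, and dropouts/outlier spikes at configurable rates.
True beat times and corrupted sample indices are recorded. Beats start
0.5 s after trace onset and end 0.5 s before the end so every true beat has
a fully supported, detectable waveform.

What the phantom does **not** emulate: haemodynamic response convolution,
MR physics (distortion, multiband artefacts), structured physiological
noise fields, pulsatile partial-volume effects, or between-site variation.
Passing tests demonstrate that the pipeline recovers exactly what it claims
from data obeying its own statistical model — not that the model captures
every property of real recordings.

## Problem sizes used in tests

Unit tests run on small phantoms (2–6 sources, 40–160 volumes). The
recovery experiments use the default study conditions: dimensionality
selection with dims {4,6,8,10,12} × 10 splits over 5 phantom seeds;
specificity over 5 seeds; dual-criterion selection with 10 subjects,
500 permutations, 5 seeds; FWER calibration with 200 null datasets. The
acceptance script runs single-seed versions of the same computations.

## Known limitations

* `run_pipeline` orchestrates the phantom study end-to-end; file-based
  studies use the same stage functions (and the CLI subcommands) directly.
* The reproducibility curve's absolute level depends on the split
  granularity; with very few subjects the halves are small and mean r is
  noisy.
* The spectral arm is uncorrected for multiplicity by design; expect ~5 %
  false positives per component-band cell, which the dual criterion (but
  not the spectral arm alone) largely suppresses.
* Exact idempotence of blood-pressure cleaning relies on the recorded
  cleaning marker, as discussed above.
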