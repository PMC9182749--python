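# Methods

This note records the model, the numerical choices, and what the
synthetic test substrate does and does not establish.

## Data model and cleaning

A session holds one irregularly sampled series per channel (hr in bpm,
speed in m/s, altitude in m), timestamps in seconds from session start.
Cleaning proceeds in this order:

1. **Outlier repair on raw samples.** Heart-rate samples with |z| > 3
   (global mean/SD) are replaced by linear interpolation over the
   timestamps of the surrounding inliers. This happens *before* any
   gridding: a single spiked reading interpolated onto a 1 s grid smears
   into ~10 grid points whose shoulders fall below the z threshold and
   survive a grid-level pass — repairing at the source avoids that
   failure mode entirely. The grid-level variant
   (`remove_outliers_zscore`) is kept for uniform inputs; both are
   single-pass and idempotent on isolated spikes.
2. **Alignment.** All channels are linearly interpolated onto a shared
   1 s grid spanning the overlap of their observed ranges. Observation
   gaps longer than 30 s (configurable) split the session into segments
   rather than being bridged — we never invent half a minute of data.
3. **Speed filtering.** GPS speed is the noisiest channel; it gets a
   zero-phase (forward–backward) Butterworth low-pass, cutoff 0.01 as a
   fraction of Nyquist at the 1 Hz grid (i.e. 0.005 Hz), order 2. Zero
   phase matters because the features compare speed-derived energy with
   heart rate window by window; a causal filter would shift one against
   the other. DC gain is exactly 1, so mean speed is untouched.
4. **Altitude rebasing** subtracts the session's starting altitude so
   sessions at different elevations are comparable (idempotent).
5. **Intense-zone restriction.** The analysis domain is HR ≥ 90% of the
   Tanaka age-predicted maximum (208 − 0.7·age). Contiguous in-zone runs
   shorter than one analysis window are dropped. Zone restriction defines
   *segments*; it never deletes samples inside a window — a window must
   lie entirely within one retained segment, so no window mixes in-zone
   and out-of-zone dynamics.

The z-score is global rather than rolling (the simplest reading of a
"3 standard deviations" rule), and replacement — rather than deletion —
preserves the uniform grid that the autocorrelation and recurrence
analyses require.

## Window width from the ACF cutoff

The statistical unit is a sliding window stepped one grid point at a
time. Its width is the heart-rate correlation horizon: after polynomial
detrending (order 1, escalated once to order 2 if the augmented
Dickey–Fuller test still fails to reject a unit root at p < 0.05, then
the session is excluded with a warning), the sample ACF is compared with
the Bartlett large-lag band ±z_{0.975}·√((1 + 2Σ_{j<k} r_j²)/n). The
cutoff lag t_cut is the first downward crossing of the upper band,
located by intersecting the chord between the bracketing ACF values with
the chord between the corresponding band values (the crossing is a
curve/bound intersection, not an integer lag). If lag 1 is already
inside the band, t_cut = one grid step; crossings are only detected on
the upper band — negative excursions carry no correlation-horizon
information.

Across calibration sessions the per-session t_cut values are aggregated
as mean ± SD. The chosen width is the mean rounded to 10 s, except that
the canonical 90 s is preferred whenever it lies within one SD of the
mean: the per-session cutoff estimate has an SD of ~25 s, and the
analysis needs one fixed window across sessions, so the canonical value
should win unless the data clearly contradict it. An explicit override
is available and logged.

## Features

Energy demand: E = minmax(g·(z − z₀)) + minmax(v²/2) with g = 9.80665
m/s². The min–max normalization is computed once per session over the
union of retained intense-zone samples — windows sample a session-level
demand curve; per-window renormalization would destroy cross-window
comparability. A constant channel (e.g. a treadmill run with no altitude
variation) contributes identically zero with a warning. E ∈ [0, 2], and
both terms carry comparable weight regardless of the channels' physical
scales; mass never enters.

Per window and channel x ∈ {E, HR}: γ₀ = (mean − first value)/σ and
γ₁ = Fisher–Pearson skewness (1/n)Σ((xᵢ − x̄)/σ)³, both with the
population SD (divide by n), and ΔX = γ₀ + γ₁ exactly. The 1/n in the
skewness is deliberate: without it the statistic grows linearly with the
number of samples per window, making windows incomparable across
sampling rates. Zero-SD windows yield 0 for both terms. Windows are
half-open [start, start + width) — 90 samples at 1 Hz for the canonical
width.

ΔX is invariant under positive affine rescaling of the channel and flips
sign under negation; its sign agrees with the sign of a per-window
regression slope whenever the window is clearly sloped (|slope|·width
above twice the residual SD), while in near-flat or strongly non-linear
windows the skewness term carries the decision — that robustness is the
reason for the composite feature.

## Clustering

Features are rescaled per axis by (x − mean)/(α·s) with α = 3; if fewer
than 99% of points land in the unit square, α is raised directly to the
empirical 99% quantile of the per-point max standardized coordinate.
k-means is Lloyd's algorithm from k-means++ starts (10 restarts, best
final L2 objective wins), stopping when no point is reassigned or no
centroid moves more than 1e−5. An empty cluster is re-seeded at the
point farthest from its former centroid — Lloyd leaves the case
unspecified, and the farthest point is the most defensible single
relocation under the L2 objective. The objective is recorded after every
assignment step and asserted non-increasing.

The silhouette uses the standard per-point form s = (b − a)/max(a, b)
with a the mean distance to the point's own cluster (divisor n_A − 1), b
the smallest mean distance to another cluster, and s = 0 for singleton
clusters. k is chosen as the argmax of the mean silhouette over 2–10
(ties to the smaller k); a best score below 0.4 triggers a
"weak cluster structure" warning. Note that this threshold is
geometry-dependent — k-means partitions of a structureless *uniform*
square in 2-D score ≈ 0.41–0.44, while a single Gaussian blob scores
≈ 0.35.

With k = 4, each centroid is mapped back to raw (ΔE, ΔHR) coordinates
and named sign(ΔE)/sign(ΔHR); the four names must be distinct, otherwise
the model does not represent the four dynamic regimes and an error is
raised. A centroid exactly on an axis counts as "+" (and warns). The
default pipeline fixes k = 4 — the four regimes are the scientific
object — and reports the silhouette as a diagnostic; `--select-k`
switches to data-driven selection.

## Session and cohort statistics

Regime frequencies are computed over *all* overlapping windows (the
temporal maps need every window); hypothesis tests use the greedy
non-overlapping subset (stride = width from the first admissible start),
whose members are pairwise disjoint and hence statistically independent
points. Sections split normalized analysis time into thirds
(start/middle/end); a window belongs to the section containing its
midpoint. Cross-session association with VO2max is the Pearson r between
per-session regime frequency and the device-reported VO2max (≥ 3
sessions; constant inputs leave r undefined with a flag).

Group comparisons gate on Shapiro–Wilk normality of every group at 0.05:
all-normal → one-way ANOVA with Tukey HSD post-hoc (Tukey p-values are
already family-corrected, so no further adjustment is stacked on top);
otherwise Kruskal–Wallis with Mann–Whitney post-hoc and Bonferroni
adjustment (min(1, m·p)). Repeated designs (e.g. sections within
sessions) use the subject-blocked one-way repeated-measures F test or
Friedman, with paired t / Wilcoxon post-hocs, Bonferroni-adjusted.

## Recurrence analysis

Heart rate on the concatenated intense-zone series is delay-embedded
(m = 7, lag 1 sample); recurrences are pairs of embedded states within
Euclidean radius 5, interpreted as an absolute distance in bpm-embedded
space to match the unnormalized HR input (a percent-of-max-distance mode
exists, as both conventions circulate in the recurrence literature).
DET = Σ_{l≥4} l·N(l) / Σ_{l≥1} l·N(l) over diagonal line lengths outside
a Theiler window of 1 (only the line of identity is excluded; 0/0 is
reported as DET = 0 with a flag). The recurrence rate is the recurrent
fraction of off-Theiler pairs. Section-wise DET is computed on
index-thirds of the series. Empirically DET is non-decreasing in the
radius (more recurrences join or extend lines); this is verified as a
check, not claimed as a theorem.

## Synthetic sessions

The generator is the package's test substrate and defines its study
conditions:

* **Acquisition**: per-channel sampling intervals are clipped normals
  (floor 0.5 s) with pre-clip parameters moment-matched so the empirical
  mean/SD hit 5.1 ± 2.6 s (HR), 2.6 ± 1.4 s (speed), 2.0 ± 1.8 s
  (altitude); naive clipping would bias the altitude mean by ~10%.
  Sensor spikes of ±(5–10)·SD hit HR samples at rate 0.002; white GPS
  noise (0.3 m/s) and barometric noise (0.5 m) corrupt speed and
  altitude.
* **Heart-rate noise** is stationary AR(1) with correlation time 85 s —
  chosen so the window-estimation path, run on steady sessions with
  AR sd 2.5 bpm plus 1.5 bpm white sensor noise, lands at a cutoff of
  ≈ 90 ± 25 s — plus the white observation noise.
* **Regimes**: a session is a chain of segments, each ramping an
  abstract demand curve and the HR level with slopes whose signs realize
  one of the four regimes. The cycle +/+, −/+, −/−, +/− is
  level-neutral, so arbitrary regime time-shares can be planted with a
  bounded HR path. Demand is rendered into altitude and speed (50/50
  potential/kinetic split by default; the split does not affect regime
  signs because each term is min–max normalized). Regime plans default
  to *well-separated* noise: the planted HR ramp per 90 s window
  (12 bpm per segment ⇒ 3.3–3.6 bpm per window) is at least three times
  the AR noise SD (0.7 bpm), and the baseline (166 bpm, age 57) keeps
  the whole level path inside the intense zone.
* **Cohorts** interpolate VO2max linearly across sessions while moving
  the −/+ time-share up (0.16 → 0.32 by default) and −/− down by the
  same amount; expected window frequencies are recorded as ground truth.
* **Fatigue series** mix a deterministic oscillation (period 20 s) with
  white noise so that the oscillation's variance share rises linearly
  with normalized time at rate `fatigue_gain` — the signature DET
  detects.

What passing these tests shows: the pipeline recovers planted window
labels (≥ 95% on well-separated plans), planted cohort trends (Pearson r
of the expected sign and magnitude), the planted correlation horizon
(window ≈ 90 s), and planted regularity trends (DET rising in ≥ 90% of
seeds, flat under the null). What it does not show: performance on real
wrist-sensor data, whose HR noise is neither Gaussian nor AR(1)
(motion artifacts are bursty and signal-dependent), whose regimes do not
switch as clean piecewise ramps, and whose demand proxy ignores wind,
surface and temperature. The generator makes no biomechanical claims —
it produces exactly the statistical structure the pipeline measures,
with known answers.

## Problem sizes used in the shipped checks

Sixteen 1 h calibration sessions for the window estimate; one 1 h
four-regime session (~3 500 windows) for end-to-end recovery; a
12-session cohort for the VO2max correlations; 50 seeds × 900 s series
for the fatigue trend; oracle equivalences (features, silhouette,
k-means optimum, DET) on 100–1000 random instances each. These sizes
keep the full suite around half a minute while leaving the recovery
margins wide.

## Known limitations

* Single-subject design throughout: no between-subject normalization or
  mixed models; regime frequencies are comparable across sessions of one
  runner, not across runners.
* The energy proxy is session-normalized, so E values are not comparable
  across sessions — only their within-session dynamics are.
* The GPX importer derives speed from consecutive haversine distances
  (no smoothing of the raw positions) and reads HR only from the Garmin
  track-point extension; FIT/TCX files are not parsed.
* RQA parameters are fixed, not estimated (no false-nearest-neighbour or
  mutual-information embedding selection); DET values are therefore only
  comparable at identical parameter settings.
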