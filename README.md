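# hbregimes

Heartbeat-dynamics regime analysis of wearable running sessions.

Wrist-worn devices report VO2max — maximal oxygen uptake, the standard
index of cardiorespiratory fitness — as a single number per run. They do
not say *when*, within a session, the cardiovascular response behaved in a
way associated with fitness improvement or with emerging fatigue.
`hbregimes` answers that question from the raw watch channels alone: heart
rate (bpm), speed (m/s) and altitude (m), each sampled at irregular
intervals.

## Method

For a runner of a given age the analysis domain is the *intense zone*,
samples with HR above 90% of the age-predicted maximum
(Tanaka: HRmax = 208 − 0.7·age). After sensor-glitch repair (global
z-score, |z| > 3), zero-phase Butterworth smoothing of the GPS speed
(cutoff 0.01, order 2) and altitude rebasing, all channels are aligned on
a 1 s grid.

External energy demand is summarized by a dimensionless proxy

    E = minmax(g·(z − z₀)) + minmax(v²/2)   ∈ [0, 2],

the sum of session-normalized potential and kinetic terms. The series is
cut into overlapping sliding windows whose width is *derived from the
data*: the lag at which the detrended heart-rate autocorrelation function
first drops inside its Bartlett 95% confidence band (the cutoff lag
t_cut). Aggregated over calibration sessions this gives the canonical
90 s window. Each window yields two features per channel x ∈ {E, HR}:

    γ₀(x) = (x̄ − x₀)/σ        (standardized mean-vs-start displacement)
    γ₁(x) = ⟨((x − x̄)/σ)³⟩    (skewness)
    ΔX    = γ₀ + γ₁

ΔE and ΔHR are scale-free trend detectors robust to noisy, non-linear
windows. k-means (Lloyd iterations, k-means++ seeding, L2 objective) in
the rescaled (ΔE, ΔHR) plane — with k = 4 selected by the mean silhouette
score — separates four *dynamic regimes*, named by the sign pair
sign(ΔE)/sign(ΔHR):

* `+/+`, `-/-` — HR follows demand (the ordinary coupled response);
* `-/+` — HR rises while demand falls; its session frequency tracks
  VO2max across a cohort of runs;
* `+/-` — HR falls despite rising demand, a delayed response linked to
  fatigue.

Finally, recurrence quantification analysis (time-delay embedding m = 7,
lag 1, radius 5, Euclidean distance) measures determinism (DET), the
fraction of recurrence points on diagonal lines of length ≥ 4 — a
regularity index that rises with neuromuscular fatigue, computed per
start/middle/end third of the session.

No public recordings exist for this protocol, so the package ships a
synthetic-session generator that emulates the acquisition (irregular
sampling at 5.1 ± 2.6 s for HR, 2.6 ± 1.4 s for speed, 2.0 ± 1.8 s for
altitude, sensor outliers, GPS noise, AR(1) heart-rate variability with
85 s correlation time) with planted regimes and known ground truth.

## Worked example

```python
import hbregimes as hb

plan = hb.make_balanced_plan(seed=3)          # 1 h, four planted regimes
session, truth = hb.generate_session(plan)
result = hb.RunningSessionModel(session).fit(seed=0)
print(result.summary())
```

```
Heartbeat-dynamics regime analysis
==================================================
session            synthetic
analysis window    90 s
windows            3509
clusters (k)       4
mean silhouette    0.699
scaling alpha      3.00 (coverage 1.000)
--------------------------------------------------
regime   frequency   <dE>      <dHR>
+/+          0.239   +1.646    +1.366
+/-          0.234   +1.627    -1.437
-/+          0.266   -1.600    +1.481
-/-          0.261   -1.611    -1.404
--------------------------------------------------
section     +/+     +/-     -/+     -/-     DET
start     0.238   0.241   0.255   0.267   0.993
middle    0.229   0.247   0.252   0.273   0.991
end       0.250   0.214   0.294   0.242   0.991
```

The four regimes come back with near-equal frequencies (the plan planted
25% each), centroids sit in the four quadrants of the (ΔE, ΔHR) plane
with magnitudes ≈ ±1.4–1.6, and the window labels agree with the planted
ground truth for 98.9% of windows:

```python
merged = result.window_features.merge(
    truth.rename(columns={"regime": "truth"}), on="window_start_s")
print((merged["regime"] == merged["truth"]).mean())   # 0.989
```

A cohort with a planted VO2max trend reproduces the expected correlation
structure (`hb.generate_cohort` + `hb.CohortModel`), and
`hb.generate_fatigue_series` + `hbregimes.rqa.section_det` reproduce the
rising start→end determinism of fatiguing sessions.

The same pipeline is scriptable from the shell:

```bash
hbregimes simulate --n-sessions 4 --cohort-trend --out sessions/
hbregimes analyze sessions/synthetic-00.csv --out analysis/
hbregimes cohort sessions/ --out cohort/
hbregimes report sessions/synthetic-00.csv --out figures/
```

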