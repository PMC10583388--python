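# Methods

This note documents the models, the calibrated defaults, and the numerical
and design choices behind `nevolt`. Units are fixed package-wide: current
nA, time s, charge µC, potential V, concentration µg/mL.

## Scan protocol and cycle segmentation

The protocol is a triangular sweep −0.4 → 1.3 → −0.4 V at 400 V/s (8.5 ms)
repeated at 10 Hz with a −0.4 V hold (91.5 ms). Time is seconds from
acquisition start, cycle indices are 0-based, a cycle's "time" is its sweep
start, and all windows are half-open `[t_start, t_end)`. Segmentation
checks the observed voltage against the protocol template (default
tolerance 1 mV, worst-case over all samples), drops a trailing partial
cycle with a warning, and records per-cycle voltage residuals for QC.

**Acquisition rate.** The instrument class this emulates archives at
1 kHz, which leaves only ~8 samples per 8.5-ms sweep — far too coarse to
resolve peak geometry. `sample_rate` is therefore a free protocol
parameter: the simulator default is 50 kHz (425 samples/sweep); anything
below 32 samples/sweep triggers a low-resolution warning, and below 4
samples/sweep is rejected outright. Scenario families whose analysis needs
only per-cycle amplitudes (dose ladders, stimulation series, shams) are
generated at 10 kHz to keep Monte-Carlo studies cheap; families whose
analysis interrogates E° (in-vitro wells, the in-vivo E° replicate set)
use the full 50 kHz, where one voltage grid step is 8 mV.

## Preprocessing

Background subtraction removes the non-faradaic double-layer current:
the template is the per-sample mean sweep over cycles in a pre-event
window (default `[-15, -5)` s relative to the event; ≥5 cycles required;
averaging across ~100 cycles is standard FSCV practice and suppresses
noise by ~10×). The template is retained and reported (`background_qc.csv`).

Smoothing is a centered moving average along each sweep, window forced
odd, with shrinking windows at the edges (no invented padding). The
`smooth()` primitive defaults to the instrument convention of 5 ms — five
samples at the 1 kHz archival rate. The *pipeline* default is 0.2 ms: the
same five-sample-scale kernel carried onto the simulator's finer grid. A
literal 5-ms kernel at 50 kHz would span 59 % of the sweep, mix the anodic
and cathodic limbs, and (because shrinking edge windows renormalize by
window length) bias the smoothed argmax toward the search-band edge —
destroying E° recovery. Both the duration and the subtract/smooth order
are configurable; the default order is subtract-then-smooth.

## Signal extraction

* **i°** per cycle: within the anodic limb restricted to a 0.40–1.20 V
  band (brackets all three medium E° values; excludes the 1.3 V switching
  artifact), the peak is the maximum current (ties toward the lowest
  voltage) and the trough the minimum current at or below the peak's
  voltage; i° = peak − trough ≥ 0 by construction.
* **Window detection**: baseline mean/SD of i° over all pre-event cycles
  (≥10 required). Open at the first cycle ≥ the event onset with i° >
  mean + k_rise·SD for `min_rise_cycles` consecutive cycles (default
  k_rise = 3, 5 cycles); no qualifying rise within `max_latency_s` (60 s)
  means no signal. Close at the first subsequent run of
  `min_quiet_cycles` (20) cycles below mean + k_end·SD (k_end = 1), capped
  at `max_window_s` (600 s) and at the end of the trace. These constants
  are a committed reconstruction — the source instrument's exact
  thresholds are not public — and every output row records the full
  parameter set used.
* **Q°**: trapezoidal integral over cycle times in the closed interval
  `[t_start, t_end]` (closure at the shared node makes Q° exactly additive
  when split at an interior cycle time) of `max(i° − baseline_mean, 0)`,
  divided by 1000 (nA·s → µC). The baseline offset and clamp make sham Q°
  ≈ 0 and immunize Q° against slow drift; `--qo-raw` disables both for
  sensitivity analysis. An undetected window yields Q° = 0.
* **E°**: i°-weighted average of the subtracted sweeps of supra-threshold
  cycles inside the window (≥3 required, otherwise E° is undefined, not a
  number); E° is the voltage of the band maximum of that average sweep.

## Forward simulator

Simulated current = capacitive background + faradaic signal + drift +
white noise:

* background: `c_dl · dV/dt` with c_dl = 1.5 nF → ±600 nA on the limbs;
* faradaic: `gain · c(t) · φ(V)` on the anodic limb, where φ is a
  unit-height asymmetric Gaussian centred on E° (upper-side σ 0.12 V,
  lower-side σ 0.6×) — an empirical peak shape chosen over a Butler–Volmer
  solver because only peak location, width and amplitude matter to the
  pipeline; a reduction peak of 0.3× height at 0.0 V sits on the cathodic
  limb. Concentration is quasi-static within a sweep and sampled once per
  cycle;
* drift: 0.5 nA/min linear plus a per-cycle random walk (0.05 nA steps) —
  small enough that sham traces drift slowly and monotonically; because
  drift is constant within a cycle it cancels exactly in the i°
  trough-to-peak difference;
* noise: i.i.d. Gaussian per sample (calibrated SD below).

**Kinetics.** IV boluses follow a two-exponential model
`c(t) = c_peak·(e^{−k_clear·Δt} − e^{−k_rise·Δt})/norm` with
c_peak = dose/Vd (Vd = 2 mL, the murine blood volume), k_rise = 0.35 s⁻¹
(peak ~8 s after injection, matching a 10-s infusion) and
k_clear = 0.02 s⁻¹ (return to baseline over minutes). Stimulation-evoked
release solves `dc/dt = block·R(t) − vmax·c/(km + c) − k_diff·c` (fixed-step
RK4 at the cycle rate, 4 substeps, drive held constant per substep so the
train on/off discontinuity never straddles a step; step-halving is the
convergence check). R saturates in the per-second stimulus charge
u = intensity·pulse-width·frequency: R = release_gain·u/(u + u50) with
release_gain 0.025 (µg/mL)/s and u50 0.5 µC/s. Reuptake uses vmax
0.0015 µg/mL/s, km 0.1 µg/mL (high-affinity, low-capacity transporter)
and k_diff 0.005 s⁻¹, giving transients that decay over one to several
minutes. In-vitro wells use a saturating step with no clearance.

**Blockades** scale the release drive: reserpine 0 (vesicular depletion),
afferent-only optogenetic drive 0, distal vagotomy 0.05, lidocaine 0.08,
proximal vagotomy 1 (efferent path intact). A boolean bradycardia flag
accompanies vagal scenarios (present only when the efferent cardiac branch
is intact and driven).

**Scenario bank.** The default bank reflects the study design: a
3-subject × {0.01, 0.05, 0.1, 0.25, 0.5} µg/mL bolus ladder with 3 saline
controls; in-vitro PBS and blood wells at 3.3 µg/mL (3 each); six
0.5 µg/mL boluses for the in-vivo E° replicate set; SpNS 100–500 µA and
VNS 10–70 µA intensity series (500 µs, 10 Hz, 10 s trains); splanchnic
stimulation at 2/4/30 Hz with n = 8/8/6 (500 µA, 100 µs); reserpine vs
vehicle (5/5), paired lidocaine (5), distal/proximal vagotomy and
efferent/afferent optogenetic VNS (3 each); shams. VNS drive reaches the
splenic nerve through the ganglion relay at 0.4× efficacy, reproducing the
observation that VNS yields smaller signals than direct SpNS. Every
scenario's seed derives deterministically from the top-level seed and the
scenario id; ground-truth concentration series are emitted alongside.

## Calibrated preset

Four constants are not first-principles quantities and are calibrated once
by the shipped `nevolt calibrate-noise` command (the output is the
versioned `presets/default.yaml`; nothing is hard-coded in logic):

* `gain` = 642 nA/(µg/mL): a 0.5 µg/mL bolus produces a pipeline peak i°
  of ≈300 nA, inside the observed 21.5–688.3 nA range;
* `noise_sd` = 6.2 nA: the i° rise criterion lands at the geometric
  midpoint between the peak i° of the 0.01 and 0.05 µg/mL doses, so the
  detection threshold falls in the (0.01, 0.1] µg/mL decade;
* `subjects.gain_sigma` = 0.806 (log-normal σ of per-animal electrode
  gain, mean-one): calibrated so the pooled 3-animal dose-ladder Pearson r
  averages ≈0.79 — the dominant source of between-animal signal
  variability, standing in for electrode placement;
* `cohort.tnf_sigma` = 1.65: multiplicative TNF noise calibrated so the
  Q°→TNF power fit explains ≈40 % of TNF variance on average.

**Endotoxemia cohort.** 17 stimulated subjects draw Q° log-uniformly over
the observed 2.3–121.7 µC range and TNF = a·Q°^b·exp(ε) with a = 5,
b = 1.5, ε ~ N(0, 1.65²); 10 shams draw TNF from a zero-truncated
N(7500, 2500²) pg/mL with Q° = 0. TNF *increases* with Q° — large NE
signals predict failed TNF suppression. The log-uniform Q° choice is
deliberate: with heavy-tailed (log-normal) Q°, original-scale R² and the
rank correlation are locked to the same signal-to-noise ratio and a 40 %
R² implies only ~75 % Spearman power at n = 17; lighter tails decouple the
two, and the calibrated generator attains mean R² ≈ 40 % with a
significant Spearman correlation in ≈94 % of seeds. The "second-order
power" reading of the fitted curve is ambiguous, so both the generator's
exponent and the fitter expose the model form (`power` with free exponent,
`power2` with b fixed at 2).

## Statistics

Standard procedures delegate to scipy: OLS/Pearson (`linregress`), Student
t tests (paired on differences; unpaired with pooled variance), one-way
ANOVA with Tukey HSD all-pairs comparisons (Holm-adjusted pairwise t tests
available via config), nonlinear least squares for the power fit
(initialized from the log–log OLS line, bounded trust-region, residuals
minimized on the original TNF scale since that is where the curve is
drawn). Spearman ρ uses mid-ranks; its p-value is an exact full
permutation enumeration for n ≤ 10 and the t approximation otherwise.
The detection threshold is the smallest dose whose Q° exceeds
mean(saline) + 3·SD(saline) in a majority of replicates; a zero-variance
saline set (noiseless runs where nothing is detected) falls back to a
configured absolute floor (0.05 µC), logged.

## What the synthetic data does and does not show

The generator reproduces the *operating points* of the real preparation —
background magnitude, E° per medium, i°/Q° ranges, transient time courses,
detection decade, dose-linearity strength, cohort variance structure — so
green tests demonstrate that the extraction and statistics recover known
ground truth under realistic amplitudes, noise, drift and between-animal
spread. They do not validate the electrochemistry itself: the faradaic
peak is empirical (no electron-transfer kinetics, pH, fouling dynamics, or
co-analyte interference), drift is stationary, and the spleen's spatial
geometry (electrode placement relative to nerve terminals, red-pulp
diffusion) is collapsed into a single per-animal gain factor. Findings on
real recordings additionally depend on electrode QC and media effects the
simulator only parameterizes.

A consequence of the calibrated between-animal gain spread (~90 % CV in
Q°) is limited power for the small blockade comparisons: an n = 5/5
unpaired t on raw Q° rejects in ~80 % of seeds for a complete reserpine
knockout, the n = 5 paired lidocaine test in ~60 %, and the splanchnic
30 Hz vs 2 Hz Tukey comparison in ~75 %. The pipeline tests therefore
assert directional consistency plus rejection-rate majorities rather than
per-seed significance.

## Numerical details and degenerate inputs

Cycle phase is computed via an epsilon-guarded floor rather than `mod`, so
samples at exact cycle boundaries never misclassify limb membership.
i° ties break toward the lowest voltage. Recordings are written with 10
significant digits so the time axis stays uniform to ≪1 % of a sample
interval for minutes-long files. Degenerate cases: a zero-span sweep, a
sweep longer than the cycle period, E° outside the sweep range, negative
rates/doses, and unknown config keys are all hard errors; an empty search
band, too few background/baseline cycles, and windows outside the trace
are analysis errors; undetected events yield Q° = 0 and an undefined E°
marker rather than numbers.

Problem sizes in the shipped tests and acceptance script (100-seed ladders
at 10 kHz, 200 sham replicates, 2000 null resamples, 400 cohort seeds)
were chosen to estimate each stochastic quantity to well under its
assertion tolerance; everything runs single-threaded in a few minutes.
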