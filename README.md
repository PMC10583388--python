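# nevolt

Fast-scan cyclic voltammetry (FSCV) analysis of norepinephrine (NE) release
in the spleen, for researchers developing anti-inflammatory neurostimulation
(vagus, splanchnic, or splenic nerve stimulation) who need a real-time
marker of splenic nerve engagement.

A carbon-fiber electrode in the spleen is driven with a triangular waveform
(−0.4 → 1.3 → −0.4 V at 400 V/s, cycled at 10 Hz with a −0.4 V hold). NE
oxidizes on the rising (anodic) limb of each sweep, producing a
concentration-dependent current peak at the medium-dependent oxidation
potential E° (≈0.57 V in PBS, ≈0.72 V in blood, ≈0.88 V in spleen in vivo).
The package implements the full analysis chain:

* **i°** — per-cycle oxidation current: the trough-to-peak current
  difference on the anodic limb of the background-subtracted, smoothed
  voltammogram, searched in a 0.40–1.20 V band;
* **E°** — the voltage of the oxidation peak of the i°-weighted average
  voltammogram across supra-baseline cycles;
* **integration window** — automatic boundaries around a stimulus: the
  window opens when i° exceeds baseline mean + 3 SD for 5 consecutive
  cycles, and closes when i° stays below baseline mean + 1 SD for 20
  consecutive cycles;
* **Q°** — the NE voltammetry signal: the time integral of the
  baseline-offset i° trace over the window, in µC.

Around this core sit a forward simulator (capacitive background + faradaic
peak driven by bolus/release–reuptake kinetics + drift + noise) that
generates the full scenario bank of the study design — NE dose ladders,
stimulation intensity/frequency series, pharmacological and surgical
blockades, sham controls, and a synthetic LPS-endotoxemia cohort — and the
statistics layer: dose/intensity linear fits, paired/unpaired t tests,
one-way ANOVA with Tukey HSD, a saline-referenced detection threshold, and
the power-model regression TNF = a·Q°^b with Spearman correlation and
original-scale variance explained.

## Worked example

Run the full synthetic study (simulate → extract → report) with one seed:

```bash
nevolt reproduce --seed 7 --out run7
cat run7/stats_report.txt
```

Selected output (abridged):

```
== 1. Dose linearity (Q° vs estimated peak NE concentration) ==
   pooled n=15: Pearson r=0.701 (p=0.00361), slope=32.093 µC/(µg/mL)

== 3. Blockade tests ==
   reserpine_vs_vehicle: unpaired_t t=-2.145, p=0.0643, means 0.00 ± 0.00 vs 12.90 ± 6.02 µC
   lidocaine_pre_vs_post: paired_t t=5.323, p=0.00599, means 6.36 ± 1.19 vs 0.00 ± 0.00 µC

== 6. Detection threshold ==
   estimated detection threshold: 0.05 µg/mL

== 7. Q° vs TNF (endotoxemia cohort) ==
   power fit (power): TNF = 0.234·Q°^2.63, R²=0.760 -> 76.0% of TNF variance explained
   Spearman rho=0.770, p=0.000303 (n=17)
```

Reading this: pooling 3 synthetic animals × 5 bolus doses gives a Q° vs
estimated-concentration Pearson r of 0.70 for this seed (the 100-seed
average is ≈0.79 — single 15-point ladders are noisy by design, because
per-animal electrode gain varies strongly with placement). NE depletion
(reserpine) abolishes the signal while nerve-conduction block (lidocaine)
removes it within-animal; the paired design is the more powerful one here.
The smallest bolus concentration distinguishable from saline is 0.05 µg/mL,
inside the method's (0.01, 0.1] µg/mL detection decade. In the endotoxemia
cohort, larger NE signals during stimulation predict *higher* TNF (less
suppression); for this seed the power fit explains 76 % of TNF variance
(the 100-cohort average is ≈40 %).

Other subcommands: `nevolt simulate` writes the scenario bank as CSV
recordings with YAML sidecars plus ground-truth concentrations;
`nevolt extract` turns recordings into a `signals.csv` (one row per event,
with the full window-parameter provenance and a `background_qc.csv`);
`nevolt report` runs the statistics on any signals/cohort tables;
`nevolt calibrate-noise` regenerates the calibrated simulator preset.

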