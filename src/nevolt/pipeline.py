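"""End-to-end drivers: scenario bank -> signals table -> statistics report.

These functions are the library behind the CLI subcommands and the
reproduction script: everything is a pure function of (config, seed), so a
fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference
from .config import (
    RunConfig,
    cohort_from_presets,
    config_hash,
    electrode_for_spec,
    kinetics_from_presets,
    load_presets,
)
from .oxidation import WindowParams, extract_event
from .preprocess import BackgroundSpec, preprocess_cycles
from .simulate import (
    ScenarioSpec,
    make_endotoxemia_cohort,
    make_scenario_bank,
    simulate_cycles,
    simulate_recording,
)
from .waveform import CycleMatrix, VoltammetryRecording, segment_cycles

logger = logging.getLogger(__name__)


def window_params(cfg: RunConfig) -> WindowParams:
    w = cfg.window
    return WindowParams(
        k_rise=w.k_rise,
        k_end=w.k_end,
        min_rise_cycles=w.min_rise_cycles,
        min_quiet_cycles=w.min_quiet_cycles,
        max_latency_s=w.max_latency_s,
        max_window_s=w.max_window_s,
    )


def background_spec(cfg: RunConfig) -> BackgroundSpec:
    return BackgroundSpec(
        t_from=cfg.preprocess.background_from_s, t_to=cfg.preprocess.background_to_s
    )


def extract_cycles(
    cycles: CycleMatrix,
    event_onset: float,
    cfg: RunConfig,
    scenario_id: str = "",
    event_label: str = "",
):
    """Preprocess a cycle matrix and extract the NE signal for one event."""
    sub = preprocess_cycles(
        cycles,
        event_onset,
        background=background_spec(cfg),
        smooth_duration_s=cfg.preprocess.smooth_duration_s,
        smooth_first=cfg.preprocess.smooth_first,
    )
    return extract_event(
        sub,
        event_onset,
        scenario_id=scenario_id,
        event_label=event_label,
        params=window_params(cfg),
        band=(cfg.window.band_lo_V, cfg.window.band_hi_V),
        subtract_baseline_in_qo=not cfg.qo_raw,
    )


def extract_recording(recording: VoltammetryRecording, cfg: RunConfig,
                      scenario_id: str = "") -> tuple[list, list[dict]]:
    """Extract one NE signal summary per event of a continuous recording.

    Returns ``(summaries, qc_rows)`` where each QC row records the
    background window actually used (cycle count and template RMS)."""
    cycles = segment_cycles(recording)
    summaries, qc = [], []
    for ev in recording.events:
        sub = preprocess_cycles(
            cycles,
            ev.onset_s,
            background=background_spec(cfg),
            smooth_duration_s=cfg.preprocess.smooth_duration_s,
            smooth_first=cfg.preprocess.smooth_first,
        )
        summaries.append(
            extract_event(
                sub,
                ev.onset_s,
                scenario_id=scenario_id,
                event_label=ev.label,
                params=window_params(cfg),
                band=(cfg.window.band_lo_V, cfg.window.band_hi_V),
                subtract_baseline_in_qo=not cfg.qo_raw,
            )
        )
        qc.append(
            {
                "scenario_id": scenario_id,
                "event": ev.label,
                "n_background_cycles": sub.n_background_cycles,
                "template_rms_nA": sub.template_rms_nA,
            }
        )
    return summaries, qc


def run_scenario(spec: ScenarioSpec, cfg: RunConfig, presets: dict):
    """Simulate one scenario (fast sweep-only path) and extract its signal.

    Returns ``(summary, cycles, truth)``.
    """
    bolus, stim = kinetics_from_presets(presets)
    electrode = electrode_for_spec(spec, presets)
    proto = cfg.protocol.protocol()
    cycles, truth = simulate_cycles(
        spec, proto, electrode, stim_kinetics=stim, bolus_kinetics=bolus
    )
    summary = extract_cycles(
        cycles, spec.onset_s, cfg, scenario_id=spec.scenario_id,
        event_label=spec.modality,
    )
    return summary, cycles, truth


def bank_specs(cfg: RunConfig, presets: dict, seed: int | None = None) -> list[ScenarioSpec]:
    return make_scenario_bank(
        seed=cfg.seed if seed is None else seed,
        families=tuple(cfg.bank.families),
        dose_ladder=tuple(cfg.bank.dose_ladder_ug_ml),
        n_subjects=cfg.bank.n_subjects,
        subject_gain_sigma=presets["subjects"]["gain_sigma"],
    )


def run_bank(cfg: RunConfig, presets: dict | None = None,
             seed: int | None = None) -> pd.DataFrame:
    """Simulate and extract the whole scenario bank; one row per event."""
    presets = presets or load_presets(cfg.preset_path)
    rows = []
    chash = config_hash(cfg)
    for spec in bank_specs(cfg, presets, seed):
        summary, _, truth = run_scenario(spec, cfg, presets)
        logger.info(
            "extracted %s: detected=%s qo=%.3f uC",
            spec.scenario_id, summary.window.detected, summary.qo,
        )
        rows.append(signal_row(spec, summary, truth, chash))
    return pd.DataFrame(rows)


def signal_row(spec: ScenarioSpec, summary, truth: np.ndarray, chash: str) -> dict:
    p = summary.params
    return {
        "scenario_id": spec.scenario_id,
        "family": spec.family,
        "subject_id": spec.subject_id,
        "modality": spec.modality,
        "medium": spec.medium,
        "blockade": spec.blockade,
        "event_label": summary.event_label,
        "est_conc_ug_ml": spec.est_conc_ug_ml,
        "intensity_uA": spec.intensity_uA,
        "freq_hz": spec.freq_hz,
        "bradycardia": spec.bradycardia,
        "eo_V": np.nan if summary.e_ox_hat is None else summary.e_ox_hat,
        "peak_io_nA": summary.peak_io,
        "qo_uC": summary.qo,
        "window_start_s": summary.window.t_start,
        "window_end_s": summary.window.t_end,
        "detected": summary.window.detected,
        "truth_peak_conc_ug_ml": float(np.max(truth)) if truth.size else 0.0,
        "k_rise": p.k_rise,
        "k_end": p.k_end,
        "min_rise_cycles": p.min_rise_cycles,
        "min_quiet_cycles": p.min_quiet_cycles,
        "max_latency_s": p.max_latency_s,
        "max_window_s": p.max_window_s,
        "seed": spec.seed,
        "config_hash": chash,
    }


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def dose_linearity(signals: pd.DataFrame) -> inference.LinearFitResult:
    """Pooled Pearson fit of Q° vs estimated concentration (bolus ladder)."""
    sub = signals[signals["family"] == "ne_bolus"]
    if len(sub) < 3:
        raise inference.AnalysisError("no bolus dose-ladder rows in signals table")
    return inference.linear_fit(sub["est_conc_ug_ml"], sub["qo_uC"])


def intensity_fits(signals: pd.DataFrame, family: str) -> dict[str, inference.LinearFitResult]:
    """Per-subject least-squares fits of Q° vs stimulation intensity."""
    sub = signals[signals["family"] == family]
    out = {}
    for subject, grp in sub.groupby("subject_id"):
        if len(grp) >= 3:
            out[str(subject)] = inference.linear_fit(grp["intensity_uA"], grp["qo_uC"])
    return out


def blockade_tests(signals: pd.DataFrame) -> dict[str, inference.GroupTestResult]:
    out = {}
    res = signals[signals["family"] == "reserpine"]
    if len(res):
        out["reserpine_vs_vehicle"] = inference.two_group_test(
            res[res["blockade"] == "reserpine"]["qo_uC"],
            res[res["blockade"] == "none"]["qo_uC"],
            paired=False,
        )
    lido = signals[signals["family"] == "lidocaine"].sort_values("subject_id")
    if len(lido):
        out["lidocaine_pre_vs_post"] = inference.two_group_test(
            lido[lido["blockade"] == "none"]["qo_uC"],
            lido[lido["blockade"] == "lidocaine"]["qo_uC"],
            paired=True,
        )
    vago = signals[signals["family"] == "vagotomy"]
    if len(vago):
        out["distal_vs_proximal_vagotomy"] = inference.two_group_test(
            vago[vago["blockade"] == "distal_vagotomy"]["qo_uC"],
            vago[vago["blockade"] == "proximal_vagotomy"]["qo_uC"],
            paired=False,
        )
    opto = signals[signals["family"] == "optogenetic"]
    if len(opto):
        out["efferent_vs_afferent_opto"] = inference.two_group_test(
            opto[opto["blockade"] == "none"]["qo_uC"],
            opto[opto["blockade"] == "afferent_only"]["qo_uC"],
            paired=False,
        )
    return out


def splanchnic_anova(signals: pd.DataFrame, method: str = "tukey"):
    sub = signals[signals["family"] == "splanchnic"]
    if not len(sub):
        return None
    groups, labels = [], []
    for freq, grp in sub.groupby("freq_hz"):
        groups.append(grp["qo_uC"].to_numpy())
        labels.append(f"{freq:g}Hz")
    return inference.anova_multcomp(groups, labels, method=method)


def threshold_from_signals(signals: pd.DataFrame, cfg: RunConfig) -> float | None:
    dose_qo = {
        float(c): grp["qo_uC"].tolist()
        for c, grp in signals[signals["family"] == "ne_bolus"].groupby("est_conc_ug_ml")
    }
    saline = signals[signals["family"] == "saline"]["qo_uC"].tolist()
    return inference.detection_threshold(
        dose_qo, saline,
        k=cfg.stats.threshold_k,
        zero_variance_floor=cfg.stats.threshold_floor_uC,
    )


def cohort_analysis(cohort: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fig. 5 analogue: group TNF comparison and the Q°->TNF power model."""
    stim = cohort[cohort["group"] == "spns"]
    sham = cohort[cohort["group"] == "sham"]
    out: dict = {}
    if len(stim) >= 2 and len(sham) >= 2:
        out["tnf_group_test"] = inference.two_group_test(
            stim["tnf_pg_ml"], sham["tnf_pg_ml"], paired=False
        )
    fit = inference.power_fit(
        stim["qo_uC"], stim["tnf_pg_ml"], model=cfg.stats.power_model
    )
    out["power_fit"] = fit
    out["variance_explained_pct"] = inference.variance_explained(fit)
    return out


def modality_summary(signals: pd.DataFrame) -> pd.DataFrame:
    """Cross-condition table of E°, peak i° and Q° by stimulation modality."""
    keep = signals[signals["family"].isin(
        ["saline", "ne_bolus", "spns", "vns", "splanchnic"]
    )]
    return (
        keep.groupby("modality")
        .agg(
            n=("qo_uC", "size"),
            eo_V_mean=("eo_V", "mean"),
            peak_io_nA_mean=("peak_io_nA", "mean"),
            peak_io_nA_max=("peak_io_nA", "max"),
            qo_uC_mean=("qo_uC", "mean"),
            qo_uC_max=("qo_uC", "max"),
        )
        .reset_index()
    )


def render_report(signals: pd.DataFrame, cohort: pd.DataFrame | None,
                  cfg: RunConfig) -> str:
    """Plain-text report with the seven analysis sections."""
    chash = config_hash(cfg)
    qdef = "raw i° integral" if cfg.qo_raw else "baseline-offset, clamped i° integral"
    lines = [
        "NE voltammetry signal report",
        f"config_hash: {chash}  seed: {cfg.seed}  qo_definition: {qdef}",
        "",
    ]

    def sect(title: str) -> None:
        lines.extend([f"== {title} ==", f"   (Q° definition: {qdef})"])

    sect("1. Dose linearity (Q° vs estimated peak NE concentration)")
    try:
        fit = dose_linearity(signals)
        lines.append(
            f"   pooled n={fit.n}: Pearson r={fit.pearson_r:.3f} "
            f"(p={fit.p_value:.3g}), slope={fit.slope:.3f} µC/(µg/mL)"
        )
    except inference.AnalysisError as exc:
        lines.append(f"   skipped: {exc}")
    lines.append("")

    sect("2. Stimulation-intensity fits (per subject)")
    for fam in ("spns", "vns"):
        for subject, f in intensity_fits(signals, fam).items():
            lines.append(
                f"   {fam} {subject}: r^2={f.r_squared:.3f}, "
                f"slope={f.slope:.4f} µC/µA (n={f.n})"
            )
    lines.append("")

    sect("3. Blockade tests")
    for name, t in blockade_tests(signals).items():
        lines.append(
            f"   {name}: {t.test} t={t.statistic:.3f}, p={t.p_value:.3g}, "
            f"means {t.group_means[0]:.2f} ± {t.group_sems[0]:.2f} vs "
            f"{t.group_means[1]:.2f} ± {t.group_sems[1]:.2f} µC"
        )
    lines.append("")

    sect("4. Splanchnic pulsing-frequency ANOVA")
    an = splanchnic_anova(signals, cfg.stats.multcomp)
    if an is None:
        lines.append("   skipped: no splanchnic scenarios")
    else:
        lines.append(f"   F={an.statistic:.3f}, p={an.p_value:.3g}")
        for c in an.comparisons:
            lines.append(
                f"   {c['pair'][0]} vs {c['pair'][1]}: adj. p={c['p_adjusted']:.3g}"
            )
    lines.append("")

    sect("5. Cross-condition summary (E°, peak i°, Q° by modality)")
    lines.append(modality_summary(signals).to_string(index=False))
    lines.append("")

    sect("6. Detection threshold")
    try:
        thr = threshold_from_signals(signals, cfg)
        lines.append(f"   estimated detection threshold: {thr} µg/mL")
    except inference.AnalysisError as exc:
        lines.append(f"   skipped: {exc}")
    lines.append("")

    sect("7. Q° vs TNF (endotoxemia cohort)")
    if cohort is None or cohort[cohort["group"] == "sham"].empty or \
            cohort[cohort["group"] == "spns"].empty:
        reason = "no cohort table" if cohort is None else "a cohort group is empty"
        logger.info("cohort section skipped: %s", reason)
        lines.append(f"   skipped: {reason}")
    else:
        res = cohort_analysis(cohort, cfg)
        t = res["tnf_group_test"]
        fit = res["power_fit"]
        lines.append(
            f"   TNF stim vs sham: t={t.statistic:.3f}, p={t.p_value:.3g}, "
            f"means {t.group_means[0]:.0f} ± {t.group_sems[0]:.0f} vs "
            f"{t.group_means[1]:.0f} ± {t.group_sems[1]:.0f} pg/mL"
        )
        lines.append(
            f"   power fit ({fit.model}): TNF = {fit.a:.3g}·Q°^{fit.b:.3g}, "
            f"R²={fit.r_squared:.3f} -> {res['variance_explained_pct']:.1f}% "
            "of TNF variance explained"
        )
        lines.append(
            f"   Spearman rho={fit.spearman_rho:.3f}, p={fit.spearman_p:.3g} "
            f"(n={fit.n})"
        )
    lines.append("")
    return "\n".join(lines)


def report_table(signals: pd.DataFrame, cohort: pd.DataFrame | None,
                 cfg: RunConfig) -> pd.DataFrame:
    """Machine-readable companion of the text report: one row per test."""
    chash = config_hash(cfg)
    rows: list[dict] = []

    def add(section: str, name: str, **kw) -> None:
        rows.append({"section": section, "name": name, "config_hash": chash, **kw})

    try:
        fit = dose_linearity(signals)
        add("dose_linearity", "pooled_pearson", statistic=fit.pearson_r,
            p_value=fit.p_value, estimate=fit.slope, n=fit.n)
    except inference.AnalysisError:
        pass
    for fam in ("spns", "vns"):
        for subject, f in intensity_fits(signals, fam).items():
            add("intensity_fit", f"{fam}/{subject}", statistic=f.r_squared,
                p_value=f.p_value, estimate=f.slope, n=f.n)
    for name, t in blockade_tests(signals).items():
        add("blockade", name, statistic=t.statistic, p_value=t.p_value,
            estimate=t.group_means[0] - t.group_means[1], n=np.nan)
    an = splanchnic_anova(signals, cfg.stats.multcomp)
    if an is not None:
        add("splanchnic_anova", "f_test", statistic=an.statistic,
            p_value=an.p_value, estimate=np.nan, n=np.nan)
        for c in an.comparisons:
            add("splanchnic_anova", f"{c['pair'][0]}_vs_{c['pair'][1]}",
                statistic=np.nan, p_value=c["p_adjusted"],
                estimate=c["mean_diff"], n=np.nan)
    try:
        thr = threshold_from_signals(signals, cfg)
        add("detection_threshold", "ug_per_ml", statistic=np.nan, p_value=np.nan,
            estimate=np.nan if thr is None else thr, n=np.nan)
    except inference.AnalysisError:
        pass
    if cohort is not None and not cohort[cohort["group"] == "sham"].empty and \
            not cohort[cohort["group"] == "spns"].empty:
        res = cohort_analysis(cohort, cfg)
        t = res["tnf_group_test"]
        fit = res["power_fit"]
        add("cohort", "tnf_stim_vs_sham", statistic=t.statistic,
            p_value=t.p_value, estimate=t.group_means[0] - t.group_means[1],
            n=np.nan)
        add("cohort", "power_fit_variance_explained_pct", statistic=fit.b,
            p_value=fit.spearman_p, estimate=res["variance_explained_pct"],
            n=fit.n)
        add("cohort", "spearman_rho", statistic=fit.spearman_rho,
            p_value=fit.spearman_p, estimate=np.nan, n=fit.n)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full reproduction driver
# --------------------------------------------------------------------------

def reproduce(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full synthetic study: bank, cohort, signals table, report.

    Deterministic: identical config + seed give byte-identical files.
    """
    from .io import write_cohort  # local import to avoid cycle at module load

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    presets = load_presets(cfg.preset_path)
    signals = run_bank(cfg, presets)
    cohort = make_endotoxemia_cohort(
        cohort_from_presets(presets), seed=cfg.seed + 10_000
    )
    paths = {
        "signals": out / "signals.csv",
        "cohort": out / "cohort.csv",
        "report": out / "stats_report.txt",
        "report_table": out / "stats_report.csv",
        "manifest": out / "bank_manifest.csv",
    }
    signals.to_csv(paths["signals"], index=False, float_format="%.6g")
    report_table(signals, cohort, cfg).to_csv(
        paths["report_table"], index=False, float_format="%.6g"
    )
    write_cohort(cohort, paths["cohort"])
    manifest = signals[
        ["scenario_id", "family", "modality", "est_conc_ug_ml", "intensity_uA",
         "freq_hz", "blockade", "seed"]
    ]
    manifest.to_csv(paths["manifest"], index=False, float_format="%.6g")
    paths["report"].write_text(render_report(signals, cohort, cfg))
    return paths
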