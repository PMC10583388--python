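"""Run configuration and calibrated presets.

A :class:`RunConfig` gathers every tunable of the pipeline — protocol,
scenario bank, preprocessing, window detection, statistics — plus the top
seed and output directory.  It round-trips through YAML unchanged; unknown
keys are errors, not warnings, so typos never silently fall back to
defaults.  Key names carry units (``…_s``, ``…_nA``, ``…_uC``).

Calibrated simulator constants (electrode gain/noise, subject gain spread,
cohort noise) live in the shipped preset file, regenerated by the
``calibrate-noise`` subcommand, never hard-coded in logic.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .simulate import (
    BolusKinetics,
    CohortParams,
    DEFAULT_FAMILIES,
    ElectrodeModel,
    ScenarioSpec,
    StimReleaseKinetics,
)
from .waveform import ScanProtocol


def load_presets(path: str | Path | None = None) -> dict:
    """Load the calibrated preset file (the shipped default when no path)."""
    if path is None:
        text = (
            resources.files("nevolt").joinpath("presets/default.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def electrode_from_presets(
    presets: dict, medium: str = "spleen", gain_scale: float = 1.0
) -> ElectrodeModel:
    e = presets["electrode"]
    try:
        e_ox = e["e_ox_V"][medium]
    except KeyError:
        raise ConfigurationError(f"no E° preset for medium '{medium}'") from None
    return ElectrodeModel(
        c_dl=e["c_dl_nF"],
        e_ox=e_ox,
        e_red=e["e_red_V"],
        gain=e["gain_nA_per_ug_ml"] * gain_scale,
        peak_width=e["peak_width_V"],
        asym_ratio=e["asym_ratio"],
        red_fraction=e["red_fraction"],
        drift_rate=e["drift_rate_nA_per_min"],
        drift_rw_sd=e["drift_rw_sd_nA"],
        noise_sd=e["noise_sd_nA"],
    )


def kinetics_from_presets(presets: dict) -> tuple[BolusKinetics, StimReleaseKinetics]:
    b = presets["bolus_kinetics"]
    s = presets["stim_kinetics"]
    bolus = BolusKinetics(
        dose_ug=0.0, k_rise=b["k_rise_per_s"], k_clear=b["k_clear_per_s"]
    )
    stim = StimReleaseKinetics(
        release_gain=s["release_gain_ug_ml_s"],
        u50=s["u50_uC_per_s"],
        vmax=s["vmax_ug_ml_s"],
        km=s["km_ug_ml"],
        k_diff=s["k_diff_per_s"],
    )
    return bolus, stim


def cohort_from_presets(presets: dict) -> CohortParams:
    c = presets["cohort"]
    return CohortParams(
        n_stim=c["n_stim"],
        n_sham=c["n_sham"],
        a=c["a"],
        b=c["b"],
        qo_min_uC=c["qo_min_uC"],
        qo_max_uC=c["qo_max_uC"],
        tnf_sigma=c["tnf_sigma"],
        sham_tnf_mean=c["sham_tnf_mean_pg_ml"],
        sham_tnf_sd=c["sham_tnf_sd_pg_ml"],
    )


def electrode_for_spec(spec: ScenarioSpec, presets: dict) -> ElectrodeModel:
    return electrode_from_presets(presets, medium=spec.medium)


# --------------------------------------------------------------------------
# run configuration blocks
# --------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    v_hold_V: float = -0.4
    v_peak_V: float = 1.3
    scan_rate_V_per_s: float = 400.0
    cycle_freq_hz: float = 10.0
    sample_rate_hz: float = 50_000.0

    def protocol(self, n_cycles: int = 10) -> ScanProtocol:
        return ScanProtocol(
            v_hold=self.v_hold_V,
            v_peak=self.v_peak_V,
            scan_rate=self.scan_rate_V_per_s,
            cycle_freq=self.cycle_freq_hz,
            sample_rate=self.sample_rate_hz,
            n_cycles=n_cycles,
        )


@dataclass
class BankConfig:
    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    n_subjects: int = 3
    dose_ladder_ug_ml: list[float] = field(
        default_factory=lambda: [0.01, 0.05, 0.1, 0.25, 0.5]
    )


@dataclass
class PreprocessConfig:
    background_from_s: float = -15.0
    background_to_s: float = -5.0
    smooth_duration_s: float = 0.0002
    smooth_first: bool = False


@dataclass
class WindowConfig:
    k_rise: float = 3.0
    k_end: float = 1.0
    min_rise_cycles: int = 5
    min_quiet_cycles: int = 20
    max_latency_s: float = 60.0
    max_window_s: float = 600.0
    band_lo_V: float = 0.40
    band_hi_V: float = 1.20


@dataclass
class StatsConfig:
    alpha: float = 0.05
    power_model: str = "power"        # or "power2" (fixed exponent 2)
    multcomp: str = "tukey"           # or "holm"
    threshold_k: float = 3.0
    threshold_floor_uC: float = 0.05


@dataclass
class RunConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    bank: BankConfig = field(default_factory=BankConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 1
    qo_raw: bool = False              # integrate raw i° (no baseline offset)
    output_dir: str = "nevolt_out"
    preset_path: str | None = None


_BLOCKS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"'{context}' must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in '{context}'; "
            f"expected one of {sorted(known)}"
        )
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ConfigurationError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"expected one of {sorted(_BLOCKS)}"
        )
    kwargs: dict = {}
    block_types = {
        "protocol": ProtocolConfig,
        "bank": BankConfig,
        "preprocess": PreprocessConfig,
        "window": WindowConfig,
        "stats": StatsConfig,
    }
    for name, value in data.items():
        if name in block_types:
            kwargs[name] = _from_dict(block_types[name], value, name)
        else:
            kwargs[name] = value
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (all defaults when no path given)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration, for output provenance."""
    canon = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
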