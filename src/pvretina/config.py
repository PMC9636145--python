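"""Experiment configuration: schema, validation, and named runners.

Configurations are plain hierarchical mappings (YAML or JSON on disk).  A
minimal config names an experiment and may override any block:

.. code-block:: yaml

    experiment: fig3_grating_contrast
    seed: 1
    geometry: {pixel_width_um: 40, array_diameter_um: 1500, electrode_diameter_um: 18}
    medium: {resistivity_ohm_cm: 700}
    protocol: {irradiance_mw_mm2: 1.0, pulse_width_ms: 10, repetition_rate_hz: 40}
    output_dir: results/fig3

Every run writes a resolved-config snapshot next to its outputs so results
are reproducible from the artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import experiments
from .errors import ConfigError
from .fields import Medium
from .geometry import build_hex_array

log = logging.getLogger("pvretina")

EXPERIMENTS = (
    "safety_arithmetic",
    "fig3_grating_contrast",
    "fig4_field_stop",
    "fig5_frequency_sweep",
    "fig7_acuity_recovery",
)

DEFAULT_CONFIG = {
    "experiment": "safety_arithmetic",
    "seed": 0,
    "geometry": {
        "pixel_width_um": 40.0,
        "array_diameter_um": 1500.0,
        "electrode_diameter_um": 18.0,
    },
    "medium": {"resistivity_ohm_cm": 700.0},
    "protocol": {
        "irradiance_mw_mm2": 1.0,
        "pulse_width_ms": 10.0,
        "repetition_rate_hz": 40.0,
    },
    "stats": {"n_animals": 5, "alpha": 0.05, "ci_multiplier": 1.92},
    "output_dir": "results",
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def resolve_config(cfg: dict) -> dict:
    """Overlay a user config on the defaults (two levels deep)."""
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> list[str]:
    """Return a list of human-readable issues; empty iff the config is runnable."""
    issues: list[str] = []
    if not isinstance(cfg, dict) or not cfg:
        return ["config: empty or not a mapping"]
    full = resolve_config(cfg)
    exp = full.get("experiment")
    if exp not in EXPERIMENTS:
        issues.append(f"experiment: unknown name {exp!r} (choose from {EXPERIMENTS})")
    geo = full["geometry"]
    for key in ("pixel_width_um", "array_diameter_um", "electrode_diameter_um"):
        if not isinstance(geo.get(key), (int, float)) or geo[key] <= 0:
            issues.append(f"geometry.{key}: must be a positive number")
    if (
        isinstance(geo.get("electrode_diameter_um"), (int, float))
        and isinstance(geo.get("pixel_width_um"), (int, float))
        and geo["electrode_diameter_um"] >= geo["pixel_width_um"]
    ):
        issues.append("geometry.electrode_diameter_um: must be smaller than pixel width")
    med = full["medium"]
    if not isinstance(med.get("resistivity_ohm_cm"), (int, float)) or med["resistivity_ohm_cm"] <= 0:
        issues.append("medium.resistivity_ohm_cm: must be a positive number")
    pro = full["protocol"]
    for key in ("irradiance_mw_mm2", "pulse_width_ms", "repetition_rate_hz"):
        if not isinstance(pro.get(key), (int, float)) or pro[key] < 0:
            issues.append(f"protocol.{key}: must be a nonnegative number")
    if (
        isinstance(pro.get("pulse_width_ms"), (int, float))
        and isinstance(pro.get("repetition_rate_hz"), (int, float))
        and pro["repetition_rate_hz"] > 0
        and pro["pulse_width_ms"] >= 1000.0 / pro["repetition_rate_hz"]
    ):
        issues.append("protocol.pulse_width_ms: must be shorter than the pulse period")
    if not isinstance(full.get("seed"), int):
        issues.append("seed: must be an integer")
    return issues


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_experiment(cfg: dict) -> dict:
    """Execute the named experiment and write its report bundle.

    Returns the summary dictionary (also written as ``summary.json`` in the
    output directory together with the resolved config snapshot).
    """
    issues = validate_config(cfg)
    if issues:
        raise ConfigError("invalid config: " + "; ".join(issues))
    full = resolve_config(cfg)
    geo, med, pro = full["geometry"], full["medium"], full["protocol"]
    # per-experiment canonical protocol values, overridable only explicitly
    pro_raw = cfg.get("protocol") or {}
    outdir = Path(full["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    medium = Medium(med["resistivity_ohm_cm"])
    exp = full["experiment"]
    log.info("running experiment %s (seed %d)", exp, full["seed"])

    def make_layout():
        return build_hex_array(
            geo["pixel_width_um"], geo["array_diameter_um"], geo["electrode_diameter_um"]
        )

    if exp == "safety_arithmetic":
        summary = experiments.safety_arithmetic(
            irradiance_mw_mm2=pro_raw.get("irradiance_mw_mm2", 1.2),
            pulse_width_ms=pro_raw.get("pulse_width_ms", 10.0),
        )
    elif exp == "fig3_grating_contrast":
        layout = make_layout()
        summary = {}
        for label, bias in (("preconditioned_0.5V", 0.5), ("unpreconditioned_0.2V", 0.2)):
            res = experiments.grating_contrast_run(
                layout,
                medium,
                bias,
                irradiance_mw_mm2=pro["irradiance_mw_mm2"],
                pulse_width_ms=pro["pulse_width_ms"],
                repetition_rate_hz=pro["repetition_rate_hz"],
            )
            res.report.to_json(outdir / f"contrast_{label}.json")
            summary[label] = {
                "contrast_percent": res.report.contrast_percent,
                "bright_mean_mV": res.report.bright_mean_mv,
                "dark_mean_mV": res.report.dark_mean_mv,
                "peak_time_ms": res.peak_time_ms,
            }
    elif exp == "fig4_field_stop":
        layout = make_layout()
        res = experiments.field_stop_run(
            layout,
            medium,
            irradiance_mw_mm2=pro_raw.get("irradiance_mw_mm2", 8.0),
            pulse_width_ms=pro["pulse_width_ms"],
            repetition_rate_hz=pro["repetition_rate_hz"],
        )
        summary = {
            "probe_pixel": res.probe_pixel,
            "min_potential_mV": float(res.potential_v.min() * 1e3),
            "max_potential_mV": float(res.potential_v.max() * 1e3),
            "cathodic_dip": bool(res.potential_v.min() < 0),
        }
    elif exp == "fig5_frequency_sweep":
        layout = make_layout()
        res = experiments.frequency_sweep_run(
            layout,
            medium,
            irradiance_mw_mm2=pro_raw.get("irradiance_mw_mm2", 1.2),
            pulse_width_ms=pro_raw.get("pulse_width_ms", 4.0),
        )
        summary = {
            "rates_hz": res["rates_hz"],
            "normalized_amplitude": [float(v) for v in res["normalized_amplitude"]],
        }
    elif exp == "fig7_acuity_recovery":
        res = experiments.acuity_recovery_run(
            seed=full["seed"], n_animals=full["stats"]["n_animals"]
        )
        est = res["estimate"]
        est.to_json(outdir / "acuity_estimate.json")
        summary = {
            "acuity_um": est.acuity_um,
            "acuity_cpd": est.acuity_cpd,
            "sd_um": est.sd_um,
            "ci95_um": list(est.ci95_um),
            "true_acuity_um": res["true_acuity_um"],
            "noise_floor_uV": res["noise_floor"].mean,
        }
    else:  # pragma: no cover - guarded by validate_config
        raise ConfigError(f"unknown experiment {exp!r}")

    summary["experiment"] = exp
    summary["seed"] = full["seed"]
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(full, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    log.info("wrote %s", outdir / "summary.json")
    return summary
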