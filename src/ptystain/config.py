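"""Run configuration: YAML schema with the published defaults.

An empty file loads the full default configuration; unknown keys are
rejected so typos cannot silently fall back to defaults; negative loss
weights are refused.  Every run should write its resolved configuration
next to its outputs (the CLI does).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .optics import LEDArrayGeometry, OpticalSystem, led_wavevectors

__all__ = ["DEFAULT_CONFIG", "RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "optics": {
        "wavelength_nm": 505.0,
        "na": 0.13,
        "magnification": 4.0,
        "pixel_um": 6.5,
        "hr_size": 128,
        "upsample_factor": 4,
        "array": {"rows": 13, "cols": 13, "pitch_mm": 8.0, "distance_mm": 98.0},
    },
    "reconstruction": {
        "method": "bip-fpm",
        "preset": "desk",            # desk | full network width preset
        "iterations": 50,            # AP+EPRY
        "epochs": 200,               # self-supervised optimization
        "learning_rate": 2.0e-4,
        "freeze_epochs": 10,
        "loss": {"lambda_d": 0.1, "lambda_tv": 1.0e-4, "lambda_p": 1.0e-3,
                 "eta1": 1.0, "eta2": 1.0, "alpha_wiener": 1.0e-3},
    },
    "staining": {
        "learning_rate": 1.0e-4,
        "batch_size": 8,
        "epochs": 150,
        "objective": {"lambda1": 10.0, "lambda2": 0.2, "lambda3": 1.0},
        "cross_task": {"alpha": 1.0, "beta": 0.5, "gamma": 0.2, "tau": 0.5},
        "joint": {"lambda_s": 0.5, "warmup_start": 0.1, "warmup_epochs": 10},
        "ablation": {"use_wtconv": True, "use_fsff": True, "use_se": True,
                     "use_dp_net": True, "use_bip_features": False},
    },
    "seed": 0,
}

_PRESET_WIDTHS = {"desk": 16, "full": 32}

_NONNEGATIVE_KEYS = {"lambda_d", "lambda_tv", "lambda_p", "eta1", "eta2",
                     "alpha_wiener", "lambda1", "lambda2", "lambda3",
                     "alpha", "beta", "gamma", "lambda_s", "warmup_start"}


def _merge(defaults: dict, overrides: dict, path: str = ""):
    out = {}
    for key, default in defaults.items():
        if key in overrides:
            value = overrides[key]
            if isinstance(default, dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"{path}{key} must be a mapping")
                out[key] = _merge(default, value, f"{path}{key}.")
            else:
                out[key] = value
        else:
            out[key] = {k: v for k, v in default.items()} if isinstance(default, dict) \
                else default
            if isinstance(default, dict):
                out[key] = _merge(default, {}, f"{path}{key}.")
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration keys: "
                          f"{sorted(path + k for k in unknown)}")
    return out


def _validate(tree: dict, path: str = ""):
    for key, value in tree.items():
        if isinstance(value, dict):
            _validate(value, f"{path}{key}.")
        elif key in _NONNEGATIVE_KEYS:
            if not isinstance(value, (int, float)) or value < 0:
                raise ConfigError(f"{path}{key} must be a nonnegative number, got {value!r}")


class RunConfig(dict):
    """Validated configuration tree (plain nested dict with helpers)."""

    def optical_system(self, hr_size: int | None = None) -> OpticalSystem:
        o = self["optics"]
        size = hr_size or o["hr_size"]
        return OpticalSystem(wavelength=o["wavelength_nm"] * 1e-9,
                             objective_na=o["na"],
                             magnification=o["magnification"],
                             camera_pixel_size=o["pixel_um"] * 1e-6,
                             hr_shape=(size, size),
                             upsample_factor=o["upsample_factor"])

    def led_geometry(self) -> LEDArrayGeometry:
        a = self["optics"]["array"]
        return LEDArrayGeometry(rows=a["rows"], cols=a["cols"],
                                pitch=a["pitch_mm"] * 1e-3,
                                distance=a["distance_mm"] * 1e-3)

    def illumination(self, system: OpticalSystem | None = None):
        system = system or self.optical_system()
        return led_wavevectors(self.led_geometry(), system)

    @property
    def network_width(self) -> int:
        return _PRESET_WIDTHS[self["reconstruction"]["preset"]]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load YAML (or nothing) over the published defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
    if overrides:
        data = _merge_overrides(data, overrides)
    merged = _merge(DEFAULT_CONFIG, data)
    _validate(merged)
    preset = merged["reconstruction"]["preset"]
    if preset not in _PRESET_WIDTHS:
        raise ConfigError(f"reconstruction.preset must be one of {sorted(_PRESET_WIDTHS)}")
    return RunConfig(merged)


def _merge_overrides(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge_overrides(out[key], value)
        else:
            out[key] = value
    return out


def save_config(path, config: RunConfig):
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=False))
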