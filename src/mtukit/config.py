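"""Run configuration: strict-schema YAML config and deterministic seeding.

A run config is a nested mapping validated against the default schema —
unknown keys are rejected before any stage runs, and every effective value
(defaults included) is echoed into the run log.  One global seed is fanned
out into independent per-stage child seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seeds"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["sweep", "flow", "mechanics", "morphometry"],
    "design": {
        "n_bridges": 4,
        "bridge_width": None,
        "total_length": 15.0,
        "width": 6.0,
        "height": 3.0,
        "muscle_section_length": 9.0,
        "interdigitation_radius": 0.8,
    },
    "mesh": {"h": 0.5, "surface_layer_depth": 1},
    "materials": {
        "E_muscle": 49.7,
        "E_tendon": 158.9,
        "nu": 0.4,
        "density": 1000.0,
    },
    "actuation": {
        "strain": 0.10,
        "duration": 0.4,
        "dt": 0.010,
        "ramp": "linear",
    },
    "sweep": {
        "n_bridges": [1, 2, 4],
        "bridge_widths": {1: [6.0, 3.0], 2: [3.0, 2.0, 1.5], 4: [0.75]},
    },
    "flow": {
        "video": {
            "width_px": 192,
            "height_px": 192,
            "n_frames": 6,
            "pixel_size_um": 10.0,
            "frame_rate": 25.0,
            "texture_scale_px": 4.0,
            "noise_sd": 0.01,
            "strain_per_frame": 0.01,
        },
        "angle_deg": 135.0,
        "tolerance_deg": 22.5,
        "magnitude_floor": 0.1,
        "rho_kg_m3": 1000.0,
        "void_threshold": 0.3,
    },
    "mechanics": {
        "hertz": {
            "E_kpa": [49.7, 158.9],
            "nu": 0.4,
            "R_um": 100.0,
            "d_max_um": 10.0,
            "noise_sd_uN": 2.0,
            "n_replicates": 25,
        },
        "tensile": {
            "E_kpa": [61.5, 27.2],
            "cross_section_mm2": [18.0, 9.0],
            "gauge_length_mm": 15.0,
            "fracture_strain": [0.156, 0.261],
            "noise_sd_mN": 1.0,
        },
    },
    "morphometry": {
        "n_tubes": 8,
        "mean_width_um": 25.0,
        "angle_concentration": 8.0,
        "fusion_fraction": 0.5,
        "n_nuclei": 60,
    },
}


def _merge(default, override, path=""):
    if isinstance(default, dict):
        if not isinstance(override, dict):
            raise ValueError(f"config key '{path}' must be a mapping")
        out = {}
        for key in override:
            if key not in default:
                raise ValueError(
                    f"unknown config key '{path + str(key)}'"
                    f" (known: {sorted(map(str, default))})"
                )
        for key, dval in default.items():
            if key in override:
                # leaf dicts with free-form keys (e.g. bridge_widths) pass
                # through after type checking
                if path + str(key) in ("sweep.bridge_widths",):
                    out[key] = override[key]
                else:
                    out[key] = _merge(dval, override[key], f"{path}{key}.")
            else:
                out[key] = copy.deepcopy(dval)
        return out
    return override


def load_config(source: str | Path | dict | None = None) -> dict:
    """Resolve a config from a YAML file, a dict, or the defaults.

    Unknown keys raise ``ValueError``; unspecified keys take their default.
    """
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, source)


def stage_seeds(seed: int, stages: list[str]) -> dict[str, int]:
    """Deterministic independent child seed per stage (values < 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(stages, children)
    }
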