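"""Default analysis parameters and config merging.

Every tunable of the pipeline lives here with its default so that a YAML
config file documents the full provenance of a run. Values are grouped by
pipeline stage; units are micrometers unless stated otherwise.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Mapping


def default_config() -> dict:
    return {
        # channel order of input TIFFs; pixel_size_um has no default because
        # it depends on the objective/camera and must come from metadata or
        # be set explicitly.
        "channels": ["dapi", "er", "atf6"],
        "pixel_size_um": None,
        "segmentation": {
            "min_nucleus_area_um2": 40.0,
            "max_nucleus_area_um2": 400.0,
            "declump_min_distance_um": 6.0,
            "connectivity": 2,          # skimage connectivity: 2 = 8-connected
            "exclude_border_cells": True,
        },
        "translocation": {
            "bin_width": 0.05,          # ratio units
            "run_length": 3,            # consecutive qualifying bins required
            "count_mode": "frequency",  # or "raw"
            "min_cells_per_well": 50,
            "hit_sd_multiplier": 3.0,
        },
        "eres": {
            "d_min_um": 0.167,
            "d_max_um": 1.67,
            "threshold_method": "otsu",
            "declump_min_distance_px": 3,
            "correlation_mode": "pooled",  # or "per_object"
            "min_correlation_pixels": 3,
        },
    }


def merge_config(base: Mapping, override: Mapping) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    merged = copy.deepcopy(dict(base))
    for key, value in override.items():
        if (
            key in merged
            and isinstance(merged[key], Mapping)
            and isinstance(value, Mapping)
        ):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def config_hash(config: Mapping) -> str:
    """Stable short hash of a config for run-metadata logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
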