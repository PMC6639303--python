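"""Default parameters for every analysis stage, overridable from YAML.

All tunable thresholds used by the analysis modules live here so that a run
can be reproduced from its config alone.  ``load_config`` deep-merges a YAML
file over the defaults; analysis functions take their defaults from this
mapping via keyword arguments, so a config file is never required.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Package-wide defaults.  Units are noted per key.
DEFAULTS: dict = {
    # Synthetic camera model. The assays' source acquisitions do not document
    # bit depth or read noise, so these are explicit, overridable defaults:
    # a 12-bit detector with modest Gaussian read noise and no shot noise.
    "camera": {
        "bit_depth": 12,            # dynamic range = 2**bit_depth - 1 AU
        "read_noise_sd": 5.0,       # AU, additive Gaussian
        "photon_scale": 0.0,        # AU per photon; 0 disables shot noise
    },
    # Dye-entry (repair) classifier.
    "repair": {
        "window": 20.0,             # s; sliding plateau window
        "slope_epsilon": 0.005,     # ΔF/F per second
        "horizon": 120.0,           # s; latest allowed plateau onset
        "smoothing_sigma": 1.0,     # frames, Gaussian
        "saturation_level": None,   # AU; raw ceiling that voids a plateau call
    },
    # Fluo-4 calcium metrics.
    "calcium": {
        "window": 180.0,            # s; AUC integration window post injury
        "smoothing_sigma": 2.0,     # frames; peak/threshold detection only
        "clip_negative_auc": True,
        "baseline_return_fraction": 0.05,
    },
    # ER fragmentation texture scoring.
    "er": {
        "window_length": 16.0,      # px along the injury axis
        "band_halfwidth": 12.0,     # px either side of the axis
        "min_band_coverage": 0.5,   # fraction of band inside the cell mask
        "threshold": None,          # None -> calibrated from synthetic fields
    },
    # FRAP recovery fitting.
    "frap": {
        "model": "single",          # single | double exponential
    },
    # Bead-injury counting.
    "bead": {
        "min_area": 30,             # px^2
        "split_touching": False,
    },
    # Default synthetic signal-to-noise used by cohort generators: Gaussian
    # trace noise in AU on a baseline of 100 AU.
    "synthetic": {
        "trace_noise_sd": 2.0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Return the default configuration, optionally overridden from YAML."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULTS, override)


def dynamic_range(bit_depth: int) -> float:
    """Intensity ceiling in AU for a given camera bit depth."""
    return float(2 ** bit_depth - 1)
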