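"""Single-file YAML configuration for the whole pipeline.

Every tunable surfaced by the modules appears here with its default, under
one section per pipeline stage.  ``load_config`` merges a user file over
the defaults (shallow, per section).
"""

from __future__ import annotations

from pathlib import Path

import yaml


def default_config() -> dict:
    return {
        "synth": {
            "tile": 256,
            "cell_density": 0.0022,
            "nucleus_radius": [4.0, 7.0],
            "membrane_gap": 1.0,
            "membrane_thickness": 2.0,
            "noise_sigma": 0.02,
            "poisson_noise": False,
            "hema_od_vector": [0.650, 0.704, 0.286],
            "dab_od_vector": [0.269, 0.568, 0.778],
        },
        "register": {
            "n_keypoints": 800,
            "residual_threshold": 2.0,
            "tile_size": 1024,
            "levels": 3,
            "block_size": 192,
            "overlap": 0.5,
            "smooth_factor": 6.0,
            "search": 10,
            "max_rounds": 5,
            "tol": 0.5,
            "ncc_min": 0.5,
            "tissue_min": 0.10,
        },
        "network": {
            "down_in": [4, 64, 128, 256],
            "down_out": [64, 128, 256, 512],
            "up_in": [1024, 1024, 512, 256],
            "up_out": [1024, 512, 256, 128],
            "leaky_slope": 0.1,
            "disc_init_channels": 64,
            "disc_fc_hidden": 512,
            "alpha": 10.0,
            "lambda": 0.2,
            "gamma": 0.5,
            "beta": 1.0,
            "c1": 1.0e-4,
            "c2": 9.0e-4,
        },
        "train": {
            "crop": 256,
            "batch": 28,
            "lr_g": 1.0e-4,
            "lr_d": 1.0e-5,
            "weight_decay": 1.0e-5,
            "g_d_ratio": [2, 1],
            "max_steps": 2000,
            "checkpoint_every": 250,
            "fractions": [0.8, 0.1, 0.1],
        },
        "stain": {
            "tile_size": 512,
            "overlap": 64,
            "blend": "feather",
            "normalize_percentiles": [0.1, 99.9],
        },
        "metrics": {
            "opening_radius": 2,
            "min_area": 30,
            "s_start": 0.10,
            "s_stop": 0.50,
            "s_step": 0.02,
            "s_conn": 0.25,
            "connectivity": 2,
            "psnr_cap": 100.0,
            "histogram_bins": 64,
            "histogram_bandwidth": 0.05,
        },
        "stats": {
            "n_rois_per_wsi": 10,
            "roi_size": 8000,
            "chi_square_layout": "assigned_by_modality",
            "significance": 0.05,
        },
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if section in cfg and isinstance(values, dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def save_config(path, cfg: dict | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(cfg or default_config(), sort_keys=False))
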