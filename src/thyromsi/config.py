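"""YAML configuration loading for the CLI.

A config file may carry three sections::

    cohort:      # CohortConfig fields (counts, pixels, noise-free knobs)
      pixels_per_nodule: 500
    noise:       # NoiseModel fields
      additive_noise_sd: 3.0
    preprocess:  # PreprocessConfig fields
      peak_snr_threshold: 3.0
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import yaml

from thyromsi.errors import ParameterError
from thyromsi.preprocess import PreprocessConfig
from thyromsi.synthetic import CohortConfig, NoiseModel


def load_config(path: Optional[str]) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    return data


def cohort_config_from_yaml(path: Optional[str], rng_seed: Optional[int] = None) -> CohortConfig:
    data = load_config(path)
    noise = NoiseModel(**data.get("noise", {}))
    kwargs = dict(data.get("cohort", {}))
    if "mz_range" in kwargs:
        raise ParameterError("the acquisition m/z range is fixed")
    kwargs["noise"] = noise
    if rng_seed is not None:
        kwargs["rng_seed"] = rng_seed
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"bad cohort config: {exc}") from exc


def preprocess_config_from_yaml(path: Optional[str]) -> PreprocessConfig:
    data = load_config(path)
    kwargs = dict(data.get("preprocess", {}))
    if "mz_range" in kwargs:
        kwargs["mz_range"] = tuple(kwargs["mz_range"])
    try:
        return PreprocessConfig(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"bad preprocess config: {exc}") from exc
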