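"""YAML configuration for the pipeline.

A config file may override any stage's window geometry, filter cut-off,
architecture and feature set, plus detector and scoring options.  Example::

    detector:
      max_hold_s: 30
    smoothing_width: 3
    stages:
      transition:
        window_s: 1.135
        step_s: 0.073
        filter_fc: 4.5
        hidden_layers: [40, 40, 40, 40]
        features:
          - {name: rms, scope: acc}
          - {name: pitch, scope: acc}

Unspecified entries keep the stock defaults.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .classify import ClassifierConfig, default_configs
from .exceptions import ParameterError
from .features import FeatureSpec


def _merge_stage(base: ClassifierConfig, override: dict) -> ClassifierConfig:
    kwargs = {}
    for key in ("model_kind", "window_s", "step_s", "filter_fc",
                "n_estimators", "max_depth", "autocorr_lag"):
        if key in override:
            kwargs[key] = override[key]
    if "hidden_layers" in override:
        kwargs["hidden_layers"] = tuple(override["hidden_layers"])
    if "features" in override:
        kwargs["feature_set"] = tuple(
            FeatureSpec(f["name"], f.get("scope", "acc"))
            for f in override["features"])
    return replace(base, **kwargs)


def load_config(path=None) -> dict:
    """Load pipeline options, falling back to the stock defaults.

    Returns a dict with keys ``stages`` (stage name -> ClassifierConfig),
    ``detector`` (options dict) and ``smoothing_width``.
    """
    stages = default_configs()
    out = {"stages": stages, "detector": {"max_hold_s": 30.0},
           "smoothing_width": 3}
    if path is None:
        return out
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for stage, override in (raw.get("stages") or {}).items():
        if stage not in stages:
            raise ParameterError(f"unknown stage {stage!r} in config")
        stages[stage] = _merge_stage(stages[stage], override or {})
    out["detector"].update(raw.get("detector") or {})
    if "smoothing_width" in raw:
        out["smoothing_width"] = int(raw["smoothing_width"])
    return out
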