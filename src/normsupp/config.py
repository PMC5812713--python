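"""Named model presets and TOML/JSON config loading."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .normalization_model import ModelParams

__all__ = ["PRESETS", "get_preset", "load_model_config", "DEFAULT_CRITERIA"]

# per-contrast decision criteria used with the baseline preset (a lower
# criterion for low-contrast stimuli)
DEFAULT_CRITERIA = {0.98: 105.0, 0.03: 5.0}

# Model instantiations: baseline, the two lorazepam accounts (reduced
# input gain with a raised exponent, or reduced output gain), and the
# criterion-shift account of high-GABA+ observers.  Spatial parameters
# are marked "assumed": chosen within the regime the model requires
# (suppressive pooling broader than excitatory; excitatory width
# comparable to the smallest stimuli; sigma within ~2 orders of
# magnitude of the low contrast), not published values.
PRESETS: dict[str, ModelParams] = {
    "baseline": ModelParams(),
    "lorazepam_contrast_gain": ModelParams(contrast_gain=0.7,
                                           contrast_gain_exponent=2.6),
    "lorazepam_response_gain": ModelParams(response_gain=0.7),
    "criterion_shift": ModelParams(criterion=84.0),
}

ASSUMED_KEYS = frozenset({"sigma", "exc_space_width", "sup_space_width",
                          "exc_feature_width", "sup_feature_width"})


def get_preset(name: str) -> ModelParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None


def load_model_config(path) -> tuple[ModelParams, dict]:
    """Load a [model] table from TOML (or a JSON object) into ModelParams.

    Returns (params, criteria) where criteria maps contrast fraction ->
    criterion; a ``preset`` key selects a named preset as the base and
    remaining keys override it.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    table = dict(doc.get("model", doc))
    preset = table.pop("preset", None)
    criteria = {float(k): float(v)
                for k, v in table.pop("criteria", DEFAULT_CRITERIA).items()}
    base = get_preset(preset) if preset else ModelParams()
    params = base.with_(**table) if table else base
    return params, criteria
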