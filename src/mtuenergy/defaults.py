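"""Access to the packaged default model constants.

The curve shapes of the contraction model and the coefficients of the
heat-rate accounting are not subject-specific: they belong to the model
family itself and are shipped as one versioned YAML document
(``data/default_curves.yaml``) so they can be inspected, diffed, and
overridden as a whole.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def load_default_constants() -> dict:
    """Return the parsed packaged constants document (read once per process)."""
    ref = resources.files("mtuenergy").joinpath("data/default_curves.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)
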