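"""Packaged configuration: named primer sets and the sgRNA template scheme."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml


@lru_cache(maxsize=None)
def _load_packaged_config() -> dict:
    with resources.files("ampliguide.data").joinpath("primers.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Load the packaged config, or a user-supplied YAML with the same layout."""
    if path is None:
        return _load_packaged_config()
    with open(path) as fh:
        return yaml.safe_load(fh)


def available_primer_sets(config: dict | None = None) -> list[str]:
    cfg = config or load_config()
    return sorted(cfg["primers"])


def get_primer_pair(name: str = "universal_V4", config: dict | None = None):
    """Return the named :class:`~ampliguide.insilico_pcr.PrimerPair`."""
    from .insilico_pcr import PrimerPair

    cfg = config or load_config()
    try:
        entry = cfg["primers"][name]
    except KeyError:
        raise KeyError(
            f"unknown primer set {name!r}; available: {available_primer_sets(cfg)}"
        ) from None
    return PrimerPair(name=name, forward=entry["forward"], reverse=entry["reverse"])


def get_sgrna_scheme(config: dict | None = None):
    """Return the default :class:`~ampliguide.guide_design.SgRNAScheme`."""
    from .guide_design import SgRNAScheme

    cfg = config or load_config()
    entry = cfg["sgrna_template"]
    return SgRNAScheme(
        promoter=entry["promoter"],
        overlap=entry["overlap"],
        require_leading_g=bool(entry.get("require_leading_g", False)),
    )
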