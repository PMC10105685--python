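"""Named parameter registry.

``get_params(name)`` returns the raw dict for a registry entry;
``get_model(name)`` wraps Hill / biphasic / feedthrough entries in their
typed parameter objects from :mod:`ip3rkit.gating`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

from ..gating import BiphasicHillParams, FeedthroughMotParams, HillParams

__all__ = ["get_params", "get_model", "registry"]


@lru_cache(maxsize=1)
def registry() -> dict[str, Any]:
    text = (
        resources.files(__package__).joinpath("registry.yaml").read_text()
    )
    return yaml.safe_load(text)


def get_params(name: str) -> dict[str, Any]:
    reg = registry()
    if name not in reg:
        raise KeyError(f"unknown parameter set {name!r}; known: {sorted(reg)}")
    return dict(reg[name])


def get_model(name: str):
    entry = get_params(name)
    kind = entry.pop("kind", None)
    if kind == "hill":
        return HillParams(**entry)
    if kind == "biphasic":
        return BiphasicHillParams(**entry)
    if kind == "mot_edf":
        return FeedthroughMotParams(**entry)
    raise ValueError(f"registry entry {name!r} has no typed model (kind={kind!r})")
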