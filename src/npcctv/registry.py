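"""Canonical structure naming.

The registry (shipped as ``data/structures.yaml``) lists every structure
name any downstream rule may reference: the 27 delineated head-and-neck
structures, the nodal levels Ib-Vb and RP per side, and the gross tumor
volumes.  :func:`canonical_name` maps free-form file / ROI names onto it
with case-insensitive aliasing and "_L"/"_R" laterality resolution.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Set

import yaml

__all__ = [
    "canonical_names",
    "canonical_name",
    "UnknownStructureError",
    "NODAL_LEVEL_NAMES",
]


class UnknownStructureError(KeyError):
    """A structure name could not be mapped onto the canonical registry."""


@lru_cache(maxsize=1)
def _registry() -> dict:
    with resources.files("npcctv.data").joinpath("structures.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def canonical_names() -> Set[str]:
    """The full set of canonical structure names."""
    return set(_registry()["structures"])


NODAL_LEVEL_NAMES = [
    f"LN_{level}_{side}"
    for level in ("Ib", "II", "III", "IV", "Va", "Vb", "RP")
    for side in ("L", "R")
]


def _normalize(name: str) -> str:
    s = re.sub(r"[\s\-]+", "_", name.strip())
    s = re.sub(r"_+", "_", s).strip("_")
    return s.lower()


@lru_cache(maxsize=1)
def _lookup_table() -> Dict[str, str]:
    reg = _registry()
    table: Dict[str, str] = {}
    for canon in reg["structures"]:
        table[_normalize(canon)] = canon
    for alias, canon in reg.get("aliases", {}).items():
        table[_normalize(alias)] = canon
    return table


@lru_cache(maxsize=1)
def _laterality_tokens() -> Dict[str, str]:
    out: Dict[str, str] = {}
    for suffix, tokens in _registry()["laterality"].items():
        for tok in tokens:
            out[tok] = suffix
    return out


def canonical_name(name: str, allow_custom: bool = False) -> str:
    """Resolve ``name`` to a canonical registry name.

    Tries the whole name, then re-tries with a trailing or leading
    laterality token ("left", "Lt", "R", ...) folded into the "_L"/"_R"
    suffix convention.  Unknown names raise
    :class:`UnknownStructureError` unless ``allow_custom`` is set, in
    which case the normalized name is returned as-is.
    """
    table = _lookup_table()
    norm = _normalize(name)
    if norm in table:
        return table[norm]

    lat = _laterality_tokens()
    parts = norm.split("_")
    if len(parts) >= 2:
        # trailing laterality token: "orbit_left" -> orbit + _L
        if parts[-1] in lat:
            base, side = "_".join(parts[:-1]), lat[parts[-1]]
            cand = _normalize(f"{base}_{side}")
            if cand in table:
                return table[cand]
            resolved = table.get(base)
            if resolved is not None and f"{resolved}_{side}" in canonical_names():
                return f"{resolved}_{side}"
        # leading laterality token: "left_orbit"
        if parts[0] in lat:
            base, side = "_".join(parts[1:]), lat[parts[0]]
            cand = _normalize(f"{base}_{side}")
            if cand in table:
                return table[cand]
            resolved = table.get(base)
            if resolved is not None and f"{resolved}_{side}" in canonical_names():
                return f"{resolved}_{side}"

    if allow_custom:
        return norm
    raise UnknownStructureError(
        f"structure name {name!r} is not in the canonical registry "
        "(pass allow_custom=True to keep it)"
    )
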