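"""Load and save model configuration (memberships and capacities) as YAML.

The packaged defaults under ``msrisk/data/`` encode the canonical model:
the four piecewise-linear membership functions and the two sex-specific
reference capacities. User-supplied files with the same layout can swap in
alternative breakpoints or capacity tables.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Mapping, TextIO, Union

import yaml

from .errors import MSRiskError
from .membership import PiecewiseLinearMembership

PathOrFile = Union[str, "os.PathLike[str]", TextIO]  # noqa: F821


def subset_key(subset) -> str:
    """Canonical text form of a factor subset: sorted indices, comma-joined."""
    return ",".join(str(i) for i in sorted(subset))


def parse_subset_key(key: str) -> frozenset:
    key = (key or "").strip()
    if not key:
        return frozenset()
    try:
        return frozenset(int(tok) for tok in key.split(","))
    except ValueError as exc:
        raise MSRiskError(f"cannot parse subset key {key!r}") from exc


def _load_yaml(source: PathOrFile) -> dict:
    if hasattr(source, "read"):
        return yaml.safe_load(source.read())
    with open(source, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_memberships(source: PathOrFile) -> Dict[int, PiecewiseLinearMembership]:
    """Read a membership config; returns {factor_index: membership}."""
    doc = _load_yaml(source)
    try:
        entries = doc["memberships"]
    except (TypeError, KeyError):
        raise MSRiskError("membership config must contain a 'memberships' mapping")
    out: Dict[int, PiecewiseLinearMembership] = {}
    for idx, entry in entries.items():
        out[int(idx)] = PiecewiseLinearMembership(
            factor_name=entry["factor_name"],
            pieces=entry["pieces"],
            domain_min=entry.get("domain_min", 0.0),
            soft_max=entry.get("soft_max"),
        )
    return out


def dump_memberships(memberships: Mapping[int, PiecewiseLinearMembership], target: PathOrFile) -> None:
    doc = {
        "memberships": {
            int(idx): {
                "factor_name": f.factor_name,
                "domain_min": f.domain_min,
                "soft_max": f.soft_max,
                "pieces": [list(p) for p in f.pieces],
            }
            for idx, f in memberships.items()
        }
    }
    if hasattr(target, "write"):
        yaml.safe_dump(doc, target, sort_keys=True)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_capacity_tables(source: PathOrFile) -> Dict[str, Dict[frozenset, float]]:
    """Read a capacity config; returns {label: {subset: value}} raw tables."""
    doc = _load_yaml(source)
    try:
        entries = doc["capacities"]
    except (TypeError, KeyError):
        raise MSRiskError("capacity config must contain a 'capacities' mapping")
    return {
        str(label): {parse_subset_key(k): float(v) for k, v in table.items()}
        for label, table in entries.items()
    }


def dump_capacities(capacities, target: PathOrFile) -> None:
    """Write capacities ({label: Capacity}) in canonical sorted-subset form."""
    doc = {
        "n_factors": next(iter(capacities.values())).n_factors,
        "capacities": {
            label: {subset_key(s): float(v) for s, v in sorted(
                cap.values.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )}
            for label, cap in capacities.items()
        },
    }
    if hasattr(target, "write"):
        yaml.safe_dump(doc, target, sort_keys=False)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _default_resource(name: str):
    return resources.files("msrisk.data").joinpath(name).open("r", encoding="utf-8")


def load_default_memberships() -> Dict[int, PiecewiseLinearMembership]:
    with _default_resource("memberships.yaml") as fh:
        return load_memberships(fh)


def load_default_capacity_tables() -> Dict[str, Dict[frozenset, float]]:
    with _default_resource("capacities.yaml") as fh:
        return load_capacity_tables(fh)
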