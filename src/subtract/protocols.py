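"""Tractography protocol definitions, validation, and manifest expansion.

A protocol is a named recipe of ROI masks: one seed (where streamlines
start), one or more targets (waypoints a streamline must visit, in any
order, to be valid), an optional stop mask (truncates propagation), and
exclusion masks (touching one invalidates the streamline). Bilateral tracts
are instantiated once per hemisphere; commissural and unilateral tracts once.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .volumes import BinaryMask, read_mask

__all__ = [
    "Protocol",
    "ProtocolManifest",
    "TractInstance",
    "load_protocol",
    "load_manifest",
    "expand_manifest",
    "subcortical_manifest",
]

LATERALITIES = ("bilateral", "commissural", "unilateral")


@dataclass
class Protocol:
    name: str
    seed: BinaryMask
    targets: list[BinaryMask] = field(default_factory=list)
    stop: Optional[BinaryMask] = None
    exclusions: list[BinaryMask] = field(default_factory=list)
    symmetric: bool = False
    laterality: str = "unilateral"

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.seed.is_empty:
            raise ValueError("empty seed")
        grid = self.seed.grid
        for m in [*self.targets, *( [self.stop] if self.stop else []), *self.exclusions]:
            if m.grid != grid:
                raise ValueError("protocol masks are on different grids")
        for e in self.exclusions:
            if np.any(e.membership & self.seed.membership):
                raise ValueError("seed overlaps an exclusion mask")
        if self.symmetric and not self.targets:
            raise ValueError("symmetric protocol requires at least one target")

    def flipped(self) -> "Protocol":
        """Swap the seed with the final target (symmetric-run semantics)."""
        if not self.targets:
            raise ValueError("cannot flip a protocol without targets")
        new_targets = list(self.targets[:-1]) + [self.seed]
        return replace(self, seed=self.targets[-1], targets=new_targets)


@dataclass(frozen=True)
class TractInstance:
    name: str
    base_name: str
    laterality: str
    hemisphere: Optional[str] = None  # 'L' / 'R' for bilateral instances


@dataclass
class ProtocolManifest:
    """Roster of protocol names with lateralities, in a named template space."""

    entries: list[tuple[str, str]]
    space: str = "phantom"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("manifest names must be unique")
        for _, lat in self.entries:
            if lat not in LATERALITIES:
                raise ValueError(f"unknown laterality {lat!r}")


_PROTOCOL_KEYS = {"name", "laterality", "seed", "targets", "stop", "exclusions", "symmetric"}


def load_protocol(path) -> Protocol:
    """Load a YAML/JSON protocol file; mask paths are relative to the file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: protocol file must be a mapping")
    unknown = set(doc) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    base = path.parent

    def _mask(rel: str) -> BinaryMask:
        return read_mask(base / rel)

    return Protocol(
        name=doc.get("name", path.stem),
        laterality=doc.get("laterality", "unilateral"),
        seed=_mask(doc["seed"]),
        targets=[_mask(t) for t in doc.get("targets", [])],
        stop=_mask(doc["stop"]) if doc.get("stop") else None,
        exclusions=[_mask(e) for e in doc.get("exclusions", [])],
        symmetric=bool(doc.get("symmetric", False)),
    )


def load_manifest(path) -> ProtocolManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = [(e["name"], e["laterality"]) for e in doc["tracts"]]
    return ProtocolManifest(entries=entries, space=doc.get("space", "phantom"))


def expand_manifest(manifest: ProtocolManifest) -> list[TractInstance]:
    """Instantiate the roster: bilateral entries become one left and one right
    instance; commissural and unilateral entries one instance each."""
    out: list[TractInstance] = []
    for name, lat in manifest.entries:
        if lat == "bilateral":
            out.append(TractInstance(f"{name}_L", name, lat, "L"))
            out.append(TractInstance(f"{name}_R", name, lat, "R"))
        else:
            out.append(TractInstance(name, name, lat))
    names = [t.name for t in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tract instance names after expansion")
    return out


def subcortical_manifest() -> ProtocolManifest:
    """The shipped cortico-subcortical roster (11 bilateral + 1 commissural)."""
    ref = importlib.resources.files("subtract") / "data" / "subcortical_manifest.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_manifest(p)
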