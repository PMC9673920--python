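"""Glycoform attribute registry.

Short glycan codes (G0F, Man5, G2FS2, ...) are mapped to the structural
attributes that drive derived glycosylation traits and the simulation's
clearance multipliers: number of antennae, galactoses and sialic acids,
core fucosylation, and whether the glycan is of the oligomannose type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


class RegistryError(ValueError):
    """Raised for malformed or inconsistent registry definitions."""


class UnknownGlycoformError(KeyError):
    """Raised when a glycoform name cannot be resolved in the registry."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown glycoform {self.name!r}: not present in the registry"


@dataclass(frozen=True)
class GlycoformAttributes:
    """Structural attributes of one glycoform.

    Parameters
    ----------
    name:
        Short glycan code, e.g. ``G0F`` (agalactosylated, core-fucosylated
        diantennary), ``Man5`` (oligomannose), ``G0F-N`` (monoantennary),
        ``G2FS2`` (digalactosylated, disialylated, fucosylated).
    n_antennae:
        Number of antennae (0 for oligomannose, 1 for monoantennary,
        2 for diantennary complex glycans).
    n_galactose, n_sialic:
        Number of galactoses / sialic acids (0-2).
    core_fucose:
        Whether the chitobiose core carries a fucose.
    oligomannose:
        Whether the glycan is of the oligomannose type.
    hexoses, hexnacs:
        Optional monosaccharide composition, for glycans identified by
        composition only.
    provisional:
        Structural assignment inferred from composition rather than
        established (e.g. the minor H6N4F1S2 species).
    hybrid:
        Explicitly registered hybrid type; relaxes the oligomannose
        consistency checks.
    """

    name: str
    n_antennae: int
    n_galactose: int = 0
    n_sialic: int = 0
    core_fucose: bool = False
    oligomannose: bool = False
    hexoses: int | None = None
    hexnacs: int | None = None
    provisional: bool = False
    hybrid: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("glycoform name must be non-empty")
        if not 0 <= self.n_antennae <= 2:
            raise RegistryError(f"{self.name}: n_antennae must be in 0..2")
        for label, n in (("n_galactose", self.n_galactose), ("n_sialic", self.n_sialic)):
            if not 0 <= n <= 2:
                raise RegistryError(f"{self.name}: {label} must be in 0..2")
        if self.n_sialic > self.n_galactose:
            raise RegistryError(
                f"{self.name}: n_sialic ({self.n_sialic}) exceeds n_galactose ({self.n_galactose})"
            )
        if self.oligomannose and not self.hybrid:
            if self.n_antennae != 0 or self.core_fucose or self.n_galactose:
                raise RegistryError(
                    f"{self.name}: oligomannose glycans carry no antennae, galactose or core fucose"
                )
        if not self.oligomannose and self.n_galactose > self.n_antennae:
            raise RegistryError(
                f"{self.name}: n_galactose ({self.n_galactose}) exceeds "
                f"n_antennae ({self.n_antennae}) for a complex-type glycan"
            )


class GlycoformRegistry:
    """Ordered, name-keyed collection of :class:`GlycoformAttributes`.

    Every glycoform appearing in any profile table must resolve here;
    an unresolvable name raises :class:`UnknownGlycoformError` rather than
    being silently dropped.
    """

    def __init__(self, entries: Iterator[GlycoformAttributes] | None = None):
        self._entries: dict[str, GlycoformAttributes] = {}
        for entry in entries or ():
            self.add(entry)

    def add(self, entry: GlycoformAttributes) -> None:
        if entry.name in self._entries:
            raise RegistryError(f"duplicate glycoform name {entry.name!r}")
        self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> GlycoformAttributes:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownGlycoformError(name) from None

    def __contains__(self, name: object) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[GlycoformAttributes]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def require(self, names) -> None:
        """Raise if any of ``names`` is not registered (registry closure)."""
        missing = [n for n in names if n not in self._entries]
        if missing:
            raise UnknownGlycoformError(missing[0])


def default_registry() -> GlycoformRegistry:
    """Registry covering the glycoforms of the minipig mAb glycovariants.

    H6N4F1S2 is a minor glycan identified by composition only; it is
    registered as a provisional diantennary, digalactosylated, disialylated,
    fucosylated species.
    """
    A = GlycoformAttributes
    return GlycoformRegistry(
        [
            A("Man5", 0, oligomannose=True, hexoses=5, hexnacs=2),
            A("G0", 2, 0, 0, core_fucose=False),
            A("G0F", 2, 0, 0, core_fucose=True),
            A("G0F-N", 1, 0, 0, core_fucose=True),
            A("G1", 2, 1, 0, core_fucose=False),
            A("G1F", 2, 1, 0, core_fucose=True),
            A("G2F", 2, 2, 0, core_fucose=True),
            A("G2FS1", 2, 2, 1, core_fucose=True),
            A("G2S2", 2, 2, 2, core_fucose=False),
            A("G2FS2", 2, 2, 2, core_fucose=True),
            A("H6N4F1S2", 2, 2, 2, core_fucose=True, hexoses=6, hexnacs=4, provisional=True),
            A("G1S-N", 1, 1, 1, core_fucose=False),
            A("G1FS-N", 1, 1, 1, core_fucose=True),
        ]
    )


def _parse_bool(value, column: str, line: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise RegistryError(f"line {line}: cannot parse {column}={value!r} as a boolean")


REGISTRY_COLUMNS = ["name", "n_antennae", "n_galactose", "n_sialic", "core_fucose", "oligomannose"]


def load_registry(path: str | Path) -> GlycoformRegistry:
    """Read a registry from a delimited text file.

    Required header columns: name, n_antennae, n_galactose, n_sialic,
    core_fucose, oligomannose. Optional: hexoses, hexnacs, provisional,
    hybrid.
    """
    df = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"{path}: missing registry columns {missing}")
    registry = GlycoformRegistry()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        kwargs = {}
        for opt in ("hexoses", "hexnacs"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = int(row[opt])
        for opt in ("provisional", "hybrid"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = _parse_bool(row[opt], opt, line)
        registry.add(
            GlycoformAttributes(
                name=str(row["name"]),
                n_antennae=int(row["n_antennae"]),
                n_galactose=int(row["n_galactose"]),
                n_sialic=int(row["n_sialic"]),
                core_fucose=_parse_bool(row["core_fucose"], "core_fucose", line),
                oligomannose=_parse_bool(row["oligomannose"], "oligomannose", line),
                **kwargs,
            )
        )
    if len(registry) == 0:
        logger.warning("%s: registry file contained a header but no glycoforms", path)
    return registry


def write_registry(registry: GlycoformRegistry, path: str | Path) -> None:
    rows = [
        {
            "name": a.name,
            "n_antennae": a.n_antennae,
            "n_galactose": a.n_galactose,
            "n_sialic": a.n_sialic,
            "core_fucose": a.core_fucose,
            "oligomannose": a.oligomannose,
            "hexoses": a.hexoses,
            "hexnacs": a.hexnacs,
            "provisional": a.provisional,
            "hybrid": a.hybrid,
        }
        for a in registry
    ]
    pd.DataFrame(rows, columns=list(rows[0]) if rows else REGISTRY_COLUMNS).to_csv(path, index=False)
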