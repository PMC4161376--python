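"""Empirical thumb motor-performance tables.

Two tables drive all scoring: effective index of performance (IPe,
bits/sec) per directed thumb movement direction (8 entries) and per tap
location on the screen (12 entries, one per region of a 3x4 partition).
Each table carries an integer rank from 1 (worst IPe) to n (best IPe);
the scoring model consumes only the ranks, the IPe values document where
the ranks come from and are validated for consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: The 8 directed movement direction labels, in canonical table order.
#: Compass points refer to the screen: N is the top edge.
DIRECTIONS: tuple[str, ...] = (
    "N to S",
    "S to N",
    "W to E",
    "E to W",
    "NE to SW",
    "SW to NE",
    "NW to SE",
    "SE to NW",
)

#: The 12 tap-location region indices (3 columns x 4 rows, row-major from
#: the top-left corner of the screen).
LOCATIONS: tuple[int, ...] = tuple(range(1, 13))


class TableValidationError(ValueError):
    """A performance table violates its structural invariants."""


class RankTieWarning(UserWarning):
    """Tied scores were ranked ordinally by key order."""


def rank_values(values: Mapping) -> dict:
    """Rank scores from worst to best: smallest score gets rank 1.

    Ranks are a permutation of ``1..n``. Ties are broken ordinally by the
    (deterministic) insertion order of ``values`` and a :class:`RankTieWarning`
    is emitted, because downstream scoring requires a true permutation.

    Parameters
    ----------
    values
        Mapping from key to a finite numeric score.

    Returns
    -------
    dict
        Mapping from key to integer rank, 1 = worst, ``n`` = best.
    """
    if not values:
        raise ValueError("cannot rank an empty mapping")
    items = list(values.items())
    for key, score in items:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for key {key!r}: {score!r}")
    scores = [s for _, s in items]
    if len(set(scores)) != len(scores):
        warnings.warn(
            "tied scores ranked ordinally by key order", RankTieWarning, stacklevel=2
        )
    order = sorted(range(len(items)), key=lambda i: (items[i][1], i))
    return {items[i][0]: rank for rank, i in enumerate(order, start=1)}


@dataclass(frozen=True)
class PerformanceTable:
    """IPe values and worst-to-best ranks keyed by direction label or region index.

    Parameters
    ----------
    kind
        ``"direction"`` or ``"location"``; fixes the expected key set.
    ipe
        Mapping key -> effective index of performance (bits/sec).
    rank
        Mapping key -> integer rank, 1 = worst, n = best.
    """

    kind: str
    ipe: dict = field(default_factory=dict)
    rank: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.expected_keys(self.kind)
        missing = [k for k in expected if k not in self.rank]
        if missing:
            raise TableValidationError(
                f"{self.kind} table is missing entries for: {missing}"
            )
        unknown = [k for k in self.rank if k not in expected]
        if unknown:
            raise TableValidationError(
                f"{self.kind} table has unknown keys: {unknown}"
            )
        n = len(expected)
        if sorted(self.rank.values()) != list(range(1, n + 1)):
            raise TableValidationError(
                f"{self.kind} ranks must be a permutation of 1..{n}, "
                f"got {sorted(self.rank.values())}"
            )
        if self.ipe:
            if set(self.ipe) != set(expected):
                raise TableValidationError(
                    f"{self.kind} table IPe keys do not match the expected key set"
                )
            by_ipe = sorted(expected, key=lambda k: self.ipe[k])
            ranks_in_ipe_order = [self.rank[k] for k in by_ipe]
            if ranks_in_ipe_order != sorted(ranks_in_ipe_order):
                raise TableValidationError(
                    f"{self.kind} ranks are inconsistent with IPe ordering "
                    "(higher IPe must have higher rank)"
                )

    @staticmethod
    def expected_keys(kind: str) -> tuple:
        if kind == "direction":
            return DIRECTIONS
        if kind == "location":
            return LOCATIONS
        raise ValueError(f"unknown table kind {kind!r}")

    @classmethod
    def from_ipe(cls, kind: str, ipe: Mapping) -> "PerformanceTable":
        """Build a table by ranking IPe values (smallest IPe -> rank 1)."""
        keys = [k for k in cls.expected_keys(kind) if k in ipe]
        ordered = {k: float(ipe[k]) for k in keys}
        ordered.update({k: float(v) for k, v in ipe.items() if k not in ordered})
        return cls(kind=kind, ipe=dict(ordered), rank=rank_values(ordered))

    @property
    def n(self) -> int:
        return len(self.rank)

    def to_records(self) -> list[dict]:
        key_field = "label" if self.kind == "direction" else "index"
        return [
            {key_field: k, "ipe": self.ipe.get(k), "rank": self.rank[k]}
            for k in self.expected_keys(self.kind)
        ]


def _parse_records(kind: str, records: Iterable[Mapping]) -> PerformanceTable:
    key_field = "label" if kind == "direction" else "index"
    ipe: dict = {}
    rank: dict = {}
    for rec in records:
        if key_field not in rec:
            raise TableValidationError(
                f"{kind} entry missing {key_field!r} field: {rec!r}"
            )
        key = rec[key_field]
        if "rank" not in rec:
            raise TableValidationError(f"{kind} entry for {key!r} missing 'rank'")
        rank[key] = int(rec["rank"])
        if rec.get("ipe") is not None:
            ipe[key] = float(rec["ipe"])
    return PerformanceTable(kind=kind, ipe=ipe, rank=rank)


def load_tables(path) -> tuple[PerformanceTable, PerformanceTable]:
    """Load (direction table, location table) from a YAML/JSON config.

    Schema: ``{directions: [{label, ipe, rank} x8], locations:
    [{index, ipe, rank} x12]}``. Both tables are fully validated; unknown
    labels, missing entries, non-permutation ranks and rank/IPe order
    inconsistencies are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise TableValidationError(f"table config {path} is not a mapping")
    for section in ("directions", "locations"):
        if section not in doc:
            raise TableValidationError(f"table config missing {section!r} section")
    directions = _parse_records("direction", doc["directions"])
    locations = _parse_records("location", doc["locations"])
    return directions, locations


def dump_tables(
    directions: PerformanceTable, locations: PerformanceTable, path
) -> None:
    """Write both tables back to a YAML config (round-trips with load_tables)."""
    doc = {
        "directions": directions.to_records(),
        "locations": locations.to_records(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def default_tables() -> tuple[PerformanceTable, PerformanceTable]:
    """The bundled tables: published direction IPes; location IPes are a
    synthetic transcription consistent with the published ordering (top-right
    regions 3 and 6 best, bottom-right region 12 worst)."""
    ref = resources.files("thumbkey.data").joinpath("default_tables.yaml")
    with resources.as_file(ref) as path:
        return load_tables(path)
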