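"""Keyboard geometry: base layout, design transforms, and screen classifiers.

A keyboard design is a triple (R, O, L):

* ``R`` — radius of curvature of the home row, in mm. ``FLAT`` (infinite
  radius) means a straight keyboard. Positive R curves the keyboard down
  (ends of the home row drop below its middle), negative R curves it up.
* ``O`` — orientation in degrees about the home row's middle key (the "G"
  key); counter-clockwise is positive.
* ``L`` — vertical location of the G-key centre on the screen: bottom,
  middle or top, i.e. 1/4, 1/2 or 3/4 of the screen height.

Transforms are applied in the fixed order curvature -> rotation ->
translation; the first two fix the G centre, so L retains its exact
meaning (G height on the screen) for every (R, O).

The screen is partitioned into 12 equal regions (3 columns x 4 rows,
numbered row-major from the top-left), and displacements between
consecutive taps are binned into 8 compass directions; both
classifications feed the empirical performance tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

#: Sentinel curvature value for a straight (uncurved) keyboard: an
#: infinite radius of curvature.
FLAT = math.inf

#: Vertical location levels -> fraction of the screen height at which the
#: G-key centre sits.
L_FRACTIONS = {"bottom": 0.25, "middle": 0.5, "top": 0.75}

#: Order used for deterministic tie-breaking across designs.
_L_ORDER = {"bottom": 0, "middle": 1, "top": 2}

# Direction sector centres, counter-clockwise from East; index k covers
# angles (45k - 22.5, 45k + 22.5] so a boundary angle falls in the sector
# clockwise of it. Labels name the movement as origin -> destination.
_SECTOR_LABELS = (
    "W to E",    # E
    "SW to NE",  # NE
    "S to N",    # N
    "SE to NW",  # NW
    "E to W",    # W
    "NE to SW",  # SW
    "N to S",    # S
    "NW to SE",  # SE
)


class LayoutError(ValueError):
    """The layout configuration is malformed."""


class InfeasibleCurvatureError(ValueError):
    """|R| is too small for the home-row chord under the curvature mapping."""


@dataclass(frozen=True)
class DesignParams:
    """One keyboard design: curvature R (mm), orientation O (deg), location L."""

    r: float = FLAT
    o: float = 0.0
    l: str = "bottom"

    def __post_init__(self) -> None:
        if self.l not in L_FRACTIONS:
            raise ValueError(f"unknown location level {self.l!r}")
        if math.isnan(self.o) or math.isinf(self.o):
            raise ValueError("orientation must be finite")
        if math.isnan(self.r) or self.r == 0.0:
            raise ValueError("curvature must be nonzero or FLAT")

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.r)

    def sort_key(self) -> tuple:
        """Deterministic (L, O, R) lexicographic key for tie-breaking."""
        return (_L_ORDER[self.l], self.o, self.r)

    def label(self) -> str:
        r = "flat" if self.is_flat else f"{self.r:g}"
        return f"R={r}, O={self.o:g}, L={self.l}"


@dataclass(frozen=True)
class Key:
    """One key: centre (x, y) in mm, origin bottom-left of screen, y up."""

    id: str
    layer: str
    x: float
    y: float
    width: float
    height: float
    kind: str = "character"
    sub: int | None = None  # spacebar subkey index 0..3


@dataclass(frozen=True)
class KeyboardLayout:
    keys: tuple[Key, ...]
    screen_w: float
    screen_h: float
    home_x: float
    home_y: float

    @property
    def screen(self) -> tuple[float, float]:
        return (self.screen_w, self.screen_h)

    @property
    def layers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for k in self.keys:
            seen.setdefault(k.layer, None)
        return tuple(seen)

    def lookup(self, layer: str, key_id: str) -> Key:
        """Find the unique non-spacebar key (layer, id)."""
        for k in self.keys:
            if k.layer == layer and k.id == key_id and k.kind != "spacebar-subkey":
                return k
        raise KeyError(f"no key {key_id!r} on layer {layer!r}")

    def space_subkeys(self, layer: str) -> list[Key]:
        subs = [
            k for k in self.keys if k.layer == layer and k.kind == "spacebar-subkey"
        ]
        return sorted(subs, key=lambda k: k.sub or 0)

    @property
    def g_key(self) -> Key:
        return self.lookup("letters", "g")


def _load_layout_config(config=None) -> Mapping:
    if config is None:
        ref = resources.files("thumbkey.data").joinpath("default_layout.yaml")
        with resources.as_file(ref) as path:
            return yaml.safe_load(path.read_text(encoding="utf-8"))
    if isinstance(config, Mapping):
        return config
    with open(config, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _parse_row(row) -> tuple[bool, list[Mapping]]:
    """Normalise a row entry to (is_home, [key dicts with id/kind/span])."""
    home = False
    if isinstance(row, Mapping):
        home = bool(row.get("home", False))
        entries = row["keys"]
    else:
        entries = row
    keys = []
    for entry in entries:
        if isinstance(entry, Mapping):
            keys.append(
                {
                    "id": str(entry["id"]),
                    "kind": entry.get("kind", "character"),
                    "span": float(entry.get("span", 1.0)),
                }
            )
        else:
            keys.append({"id": str(entry), "kind": "character", "span": 1.0})
    return home, keys


def build_base_layout(config=None) -> KeyboardLayout:
    """Build the untransformed three-layer QWERTY layout from a config.

    The home row is vertically placed at half the screen height in the base
    layout; ``apply_design`` sets the actual height via L. The G key ends up
    horizontally centred because the letters home row has an odd key count
    and rows are centred on the screen.
    """
    cfg = _load_layout_config(config)
    try:
        sw = float(cfg["screen"]["width"])
        sh = float(cfg["screen"]["height"])
        px = float(cfg["pitch"]["x"])
        py = float(cfg["pitch"]["y"])
        kw = float(cfg["key"]["width"])
        kh = float(cfg["key"]["height"])
        layers = cfg["layers"]
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"malformed layout config: missing {exc}") from exc
    if min(sw, sh, px, py, kw, kh) <= 0:
        raise LayoutError("screen, pitch and key dimensions must be positive")
    if kw > px:
        raise LayoutError("key width cannot exceed horizontal pitch")

    gap = px - kw
    home_y = sh / 2.0
    keys: list[Key] = []
    for layer_name, layer_cfg in layers.items():
        rows = [_parse_row(r) for r in layer_cfg["rows"]]
        home_idx = [i for i, (h, _) in enumerate(rows) if h]
        if len(home_idx) != 1:
            raise LayoutError(
                f"layer {layer_name!r} must mark exactly one home row"
            )
        hi = home_idx[0]
        for ri, (_, row_keys) in enumerate(rows):
            y = home_y + (hi - ri) * py
            total_span = sum(k["span"] for k in row_keys)
            x0 = (sw - total_span * px) / 2.0
            cum = 0.0
            for k in row_keys:
                span = k["span"]
                if span <= 0:
                    raise LayoutError(f"key {k['id']!r} has non-positive span")
                width = span * px - gap
                if width <= 0:
                    raise LayoutError(f"key {k['id']!r} has non-positive width")
                if k["kind"] == "spacebar":
                    # the spacebar is modelled as 4 adjacent subkeys sharing
                    # the logical id
                    subspan = span / 4.0
                    subwidth = subspan * px - gap
                    if subwidth <= 0:
                        raise LayoutError("spacebar subkeys have non-positive width")
                    for s in range(4):
                        cx = x0 + (cum + subspan * (s + 0.5)) * px
                        keys.append(
                            Key(
                                id=k["id"],
                                layer=layer_name,
                                x=cx,
                                y=y,
                                width=subwidth,
                                height=kh,
                                kind="spacebar-subkey",
                                sub=s,
                            )
                        )
                else:
                    cx = x0 + (cum + span / 2.0) * px
                    keys.append(
                        Key(
                            id=k["id"],
                            layer=layer_name,
                            x=cx,
                            y=y,
                            width=width,
                            height=kh,
                            kind=k["kind"],
                        )
                    )
                cum += span

    layout = KeyboardLayout(
        keys=tuple(keys),
        screen_w=sw,
        screen_h=sh,
        home_x=sw / 2.0,
        home_y=home_y,
    )
    for layer in layout.layers:
        if len(layout.space_subkeys(layer)) != 4:
            raise LayoutError(f"layer {layer!r} must have a 4-subkey spacebar")
    g = layout.g_key  # raises if absent
    if not math.isclose(g.x, sw / 2.0, abs_tol=1e-9):
        raise LayoutError("the G key must be horizontally centred")
    return layout


def _home_chord_half(layout: KeyboardLayout) -> float:
    """Half the home-row chord: the largest |x - G| over home-row keys."""
    home_keys = [
        k
        for k in layout.keys
        if k.layer == "letters" and abs(k.y - layout.home_y) < 1e-9
    ]
    return max(abs(k.x - layout.home_x) for k in home_keys)


def min_feasible_radius(layout: KeyboardLayout, positive: bool = True) -> float:
    """Smallest usable curvature radius rho for this layout.

    rho must be at least half the home-row chord (the arc-length mapping
    keeps key angles below ~1 rad) and large enough that rows on the inner
    side of the circle keep a positive radius.
    """
    half_chord = _home_chord_half(layout)
    dys = [k.y - layout.home_y for k in layout.keys]
    inner = -min(dys) if positive else max(dys)
    return max(half_chord, inner)


def apply_design(
    layout: KeyboardLayout, params: DesignParams, *, r_scale: float = 1.0
) -> KeyboardLayout:
    """Apply (R, O, L) to a base layout; key count and sizes are unchanged.

    Curvature places the home-row key centres on a circle of radius
    ``rho = |R| * r_scale`` at equal arc-length spacing that preserves their
    original horizontal spacing; rows above and below follow concentric
    circles offset by their vertical distance from the home row. ``r_scale``
    converts the nominal R parameter into a physical radius (default 1:1).
    Rotation is about the G centre, counter-clockwise positive. Translation
    finally places the G centre at the height prescribed by L.
    """
    hx, hy = layout.home_x, layout.home_y

    def curve(x: float, y: float) -> tuple[float, float]:
        return (x, y)

    if not params.is_flat:
        rho = abs(params.r) * r_scale
        positive = params.r > 0
        min_rho = min_feasible_radius(layout, positive=positive)
        if rho < min_rho:
            raise InfeasibleCurvatureError(
                f"|R| = {abs(params.r):g} mm gives radius {rho:g} mm, below the "
                f"minimum feasible radius {min_rho:g} mm "
                f"(|R| >= {min_rho / r_scale:g} at r_scale={r_scale:g})"
            )

        def curve(x: float, y: float) -> tuple[float, float]:
            dx, dy = x - hx, y - hy
            theta = dx / rho
            if positive:  # curved down: circle centre below the home row
                r_k = rho + dy
                return (hx + r_k * math.sin(theta), hy - rho + r_k * math.cos(theta))
            r_k = rho - dy  # curved up: circle centre above
            return (hx + r_k * math.sin(theta), hy + rho - r_k * math.cos(theta))

    phi = math.radians(params.o)
    cos_p, sin_p = math.cos(phi), math.sin(phi)

    def rotate(x: float, y: float) -> tuple[float, float]:
        dx, dy = x - hx, y - hy
        return (hx + dx * cos_p - dy * sin_p, hy + dx * sin_p + dy * cos_p)

    target_y = L_FRACTIONS[params.l] * layout.screen_h
    ty = target_y - hy

    new_keys = []
    for k in layout.keys:
        x, y = curve(k.x, k.y)
        x, y = rotate(x, y)
        new_keys.append(replace(k, x=x, y=y + ty))
    return replace(layout, keys=tuple(new_keys), home_y=target_y)


def classify_region(
    point: Sequence[float], screen: Sequence[float]
) -> int:
    """Bin a screen point into one of 12 regions (3 cols x 4 rows).

    Regions are numbered row-major from the top-left (1) to the
    bottom-right (12). Cells are half-open — a point on an interior
    boundary belongs to the cell on its upper/right side — and points
    beyond the screen edge are clamped to the nearest cell.
    """
    x, y = float(point[0]), float(point[1])
    w, h = float(screen[0]), float(screen[1])
    if w <= 0 or h <= 0:
        raise ValueError("screen dimensions must be positive")
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite point coordinates: {(x, y)!r}")
    col = min(max(int(math.floor(x / (w / 3.0))), 0), 2)
    row_from_top = 3 - min(max(int(math.floor(y / (h / 4.0))), 0), 3)
    return row_from_top * 3 + col + 1


def classify_direction(
    frm: Sequence[float], to: Sequence[float]
) -> str:
    """Bin the displacement between two taps into one of 8 directions.

    The angle is measured with East = 0 deg and North (screen top) =
    90 deg; sectors are 45 deg wide, centred on the compass points, and an
    angle exactly on a sector boundary is assigned to the sector clockwise
    of it. Labels follow the origin-to-destination convention: movement
    toward the screen top is "S to N".
    """
    dx = float(to[0]) - float(frm[0])
    dy = float(to[1]) - float(frm[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("zero displacement has no direction")
    angle = math.degrees(math.atan2(dy, dx)) % 360.0
    sector = math.ceil((angle - 22.5) / 45.0) % 8
    return _SECTOR_LABELS[sector]


def export_layout_csv(layout: KeyboardLayout, path) -> None:
    """Write the layout to a flat CSV of (layer, id, sub, x, y, width, height)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["layer", "id", "kind", "sub", "x", "y", "width", "height"])
        for k in layout.keys:
            writer.writerow(
                [k.layer, k.id, k.kind, "" if k.sub is None else k.sub,
                 f"{k.x:.6f}", f"{k.y:.6f}", f"{k.width:.6f}", f"{k.height:.6f}"]
            )
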