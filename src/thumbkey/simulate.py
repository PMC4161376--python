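"""Simulated typing: text -> keystroke sequence -> tap distributions.

Typing is modelled as a task analysis: each character becomes one or more
taps (shift before a capital, one or two layer-switch function keys before
a character that lives on the numbers or symbols layer), and every tap is
classified by screen region while every displacement between consecutive
taps is classified by movement direction. Auto-correct, auto-capitalisation
and auto-complete are assumed off.

Layer switching is lazy: a switch key is pressed only when the next
character requires a different layer, and no trailing switch is emitted.
The spacebar tap resolves to whichever of its 4 subkeys is closest to the
previous tap. Consecutive taps on the same physical key produce no
movement-direction event ("no change in tap location"); a stricter
region-based exclusion is available as ``zero_mode="region"``.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

from .geometry import Key, KeyboardLayout, classify_direction, classify_region

#: (current layer, required layer) -> function-key taps that perform the switch.
_SWITCH_TOKENS = {
    ("letters", "numbers"): (("letters", "123"),),
    ("letters", "symbols"): (("letters", "123"), ("numbers", "#+=")),
    ("numbers", "letters"): (("numbers", "ABC"),),
    ("numbers", "symbols"): (("numbers", "#+="),),
    ("symbols", "letters"): (("symbols", "ABC"),),
    ("symbols", "numbers"): (("symbols", "123"),),
}

_LAYER_ORDER = ("letters", "numbers", "symbols")


class UnproducibleCharacterError(ValueError):
    def __init__(self, char: str):
        self.char = char
        super().__init__(f"character {char!r} cannot be produced on any layer")


@dataclass(frozen=True)
class TransitionDistribution:
    """Tap-location and movement-direction counts for one (text, design) pair.

    ``total_taps`` (Tt) counts every tap including shift and layer-switch
    keys; location counts always sum to Tt, while direction counts sum to
    at most Tt - 1 because zero-displacement repeats are excluded.
    """

    location_counts: dict = field(default_factory=dict)
    direction_counts: dict = field(default_factory=dict)
    total_taps: int = 0

    def __post_init__(self) -> None:
        if sum(self.location_counts.values()) != self.total_taps:
            raise ValueError("location counts must sum to total_taps")
        if self.total_taps > 0 and (
            sum(self.direction_counts.values()) > self.total_taps - 1
        ):
            raise ValueError("direction counts cannot exceed total_taps - 1")
        if any(v < 0 for v in self.location_counts.values()) or any(
            v < 0 for v in self.direction_counts.values()
        ):
            raise ValueError("counts must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "location_counts": {str(k): v for k, v in self.location_counts.items()},
                "direction_counts": dict(self.direction_counts),
                "total_taps": self.total_taps,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionDistribution":
        doc = json.loads(text)
        return cls(
            location_counts={int(k): v for k, v in doc["location_counts"].items()},
            direction_counts=dict(doc["direction_counts"]),
            total_taps=doc["total_taps"],
        )


def _char_map(layout: KeyboardLayout) -> dict:
    """Char -> (layer, key id); first layer in canonical order wins."""
    mapping: dict[str, tuple[str, str]] = {}
    for layer in _LAYER_ORDER:
        for k in layout.keys:
            if k.layer == layer and k.kind == "character" and len(k.id) == 1:
                mapping.setdefault(k.id, (layer, k.id))
    return mapping


def encode_text(text: str, layout: KeyboardLayout) -> list[tuple[str, str]]:
    """Expand a text into (layer, key id) taps under the layer state machine.

    Capitals emit shift then the lowercase letter (switching to the letters
    layer first if needed); spaces and newlines use the current layer's
    spacebar/return and never force a switch. Raises
    :class:`UnproducibleCharacterError` for characters on no layer.
    """
    cmap = _char_map(layout)
    tokens: list[tuple[str, str]] = []
    layer = "letters"

    def switch_to(target: str) -> None:
        nonlocal layer
        if layer != target:
            tokens.extend(_SWITCH_TOKENS[(layer, target)])
            layer = target

    for ch in text:
        if ch == " ":
            tokens.append((layer, "space"))
            continue
        if ch == "\n":
            tokens.append((layer, "return"))
            continue
        if ch.isalpha() and ch.lower() != ch and ch.lower() in cmap:
            switch_to("letters")
            tokens.append(("letters", "shift"))
            tokens.append(("letters", ch.lower()))
            continue
        if ch not in cmap:
            raise UnproducibleCharacterError(ch)
        target_layer, key_id = cmap[ch]
        switch_to(target_layer)
        tokens.append((layer, key_id))
    return tokens


def decode_tokens(tokens: list[tuple[str, str]]) -> str:
    """Replay a keystroke sequence through the layer state machine.

    Inverse of :func:`encode_text`; used to verify round-trip fidelity.
    """
    out: list[str] = []
    layer = "letters"
    shift = False
    for tok_layer, key_id in tokens:
        if tok_layer != layer:
            raise ValueError(
                f"token {key_id!r} on layer {tok_layer!r} but state is {layer!r}"
            )
        if key_id == "space":
            out.append(" ")
        elif key_id == "return":
            out.append("\n")
        elif key_id == "shift":
            shift = True
        elif key_id == "123":
            layer = "numbers"
        elif key_id == "#+=":
            layer = "symbols"
        elif key_id == "ABC":
            layer = "letters"
        elif key_id == "backspace":
            if out:
                out.pop()
        else:
            out.append(key_id.upper() if shift else key_id)
            shift = False
    return "".join(out)


def resolve_space(
    previous_tap_center: tuple[float, float] | None,
    layout: KeyboardLayout,
    layer: str = "letters",
) -> Key:
    """Pick the spacebar subkey closest to the previous tap.

    Ties go to the leftmost tied subkey; with no previous tap the
    left-middle subkey (index 1 of 0..3) is used.
    """
    subs = layout.space_subkeys(layer)
    if len(subs) != 4:
        raise ValueError(f"layer {layer!r} does not have a 4-subkey spacebar")
    if previous_tap_center is None:
        return subs[1]
    px, py = previous_tap_center
    return min(subs, key=lambda k: (math.hypot(k.x - px, k.y - py), k.x))


def simulate_tokens(
    tokens: list[tuple[str, str]],
    layout: KeyboardLayout,
    *,
    zero_mode: str = "key",
) -> TransitionDistribution:
    """Accumulate region and direction counts for a keystroke sequence."""
    if zero_mode not in ("key", "region"):
        raise ValueError("zero_mode must be 'key' or 'region'")
    loc: Counter = Counter()
    dirs: Counter = Counter()
    prev_center: tuple[float, float] | None = None
    prev_region: int | None = None
    total = 0
    for layer, key_id in tokens:
        if key_id == "space":
            key = resolve_space(prev_center, layout, layer)
        else:
            key = layout.lookup(layer, key_id)
        center = (key.x, key.y)
        region = classify_region(center, layout.screen)
        loc[region] += 1
        total += 1
        if prev_center is not None and center != prev_center:
            moved = region != prev_region if zero_mode == "region" else True
            if moved:
                dirs[classify_direction(prev_center, center)] += 1
        prev_center, prev_region = center, region
    return TransitionDistribution(
        location_counts=dict(loc), direction_counts=dict(dirs), total_taps=total
    )


def simulate(
    text: str, layout: KeyboardLayout, *, zero_mode: str = "key"
) -> TransitionDistribution:
    """Simulate typing ``text`` on a (design-transformed) layout.

    Returns the tap-location distribution, the movement-direction
    distribution and the total tap count Tt. Tt depends only on the text
    (it counts shift/switch overhead), never on the design geometry.
    """
    return simulate_tokens(encode_text(text, layout), layout, zero_mode=zero_mode)
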