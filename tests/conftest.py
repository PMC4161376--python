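import pytest

import thumbkey as tk

#: Published direction IPe values (bits/sec).
TABLE1_IPE = {
    "N to S": 11.17,
    "S to N": 12.93,
    "W to E": 11.61,
    "E to W": 11.84,
    "NE to SW": 12.50,
    "SW to NE": 13.22,
    "NW to SE": 11.13,
    "SE to NW": 11.93,
}

#: Published worst-to-best ranks for the direction table.
TABLE1_RANK = {
    "N to S": 2,
    "S to N": 7,
    "W to E": 3,
    "E to W": 4,
    "NE to SW": 6,
    "SW to NE": 8,
    "NW to SE": 1,
    "SE to NW": 5,
}


@pytest.fixture(scope="session")
def tables():
    return tk.default_tables()


@pytest.fixture(scope="session")
def base_layout():
    return tk.build_base_layout()


@pytest.fixture(scope="session")
def mini_grid():
    """A small but non-degenerate grid: 3 R x 3 O x 2 L = 18 designs."""
    return tk.generate_grid(
        {
            "r_levels": ["flat", -40, 40],
            "o_levels": [-30.0, 0.0, 30.0],
            "l_levels": ["bottom", "middle"],
        }
    )


@pytest.fixture(scope="session")
def default_sweep(tables):
    """The full default sweep (663 designs) on a seeded 375-character text."""
    text = tk.generate_text(tk.TextSpec(length=375, seed=1))
    return tk.sweep(text, tk.DesignGrid(), tables)


def exact_letters_config(pitch_x=4.0, key_w=3.0):
    """A letters-only layout on exact binary dimensions, for tie tests."""
    return {
        "screen": {"width": 48.0, "height": 64.0},
        "pitch": {"x": pitch_x, "y": 8.0},
        "key": {"width": key_w, "height": 6.0},
        "layers": {
            "letters": {
                "rows": [
                    ["q", "w", "e", "r", "t", "y", "u"],
                    {"home": True, "keys": ["a", "s", "d", "g", "h", "j", "k"]},
                    [
                        {"id": "shift", "kind": "shift", "span": 1.5},
                        "z",
                        "x",
                        "c",
                        "v",
                        {"id": "backspace", "kind": "backspace", "span": 1.5},
                    ],
                    [
                        {"id": "123", "kind": "function", "span": 1.5},
                        {"id": "space", "kind": "spacebar", "span": 4.0},
                        {"id": "return", "kind": "return", "span": 1.5},
                    ],
                ]
            }
        },
    }
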