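"""Design-space enumeration, the sweep, sensitivity tests and extrema.

The default grid crosses 17 curvature levels (flat plus +/-20..90 mm in
10 mm steps), 13 orientations (-60..+60 deg in 10 deg steps) and 3
vertical locations, i.e. 663 designs; the standard keyboard
(flat, 0 deg, bottom) is one of them. Sensitivity of PI_TOT to each design
variable is measured with Kruskal-Wallis tests, and well/poorly performing
designs are located as local extrema of the PI_TOT surface over the
R x O lattice at each location level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import FLAT, DesignParams, KeyboardLayout, apply_design, build_base_layout
from .scoring import DesignEvaluation, score_designs
from .simulate import encode_text, simulate_tokens
from .tables import PerformanceTable

#: Default curvature levels (mm): flat plus +/-{20..90} in 10 mm steps.
DEFAULT_R_LEVELS: tuple[float, ...] = tuple(
    sorted(
        [FLAT] + [s * v for s in (-1, 1) for v in range(20, 100, 10)],
        key=lambda r: 0.0 if math.isinf(r) else 1.0 / r,
    )
)

#: Default orientation levels (deg): -60..+60 in 10 deg steps.
DEFAULT_O_LEVELS: tuple[float, ...] = tuple(float(o) for o in range(-60, 70, 10))

#: Default vertical location levels.
DEFAULT_L_LEVELS: tuple[str, ...] = ("bottom", "middle", "top")


def _curvature_key(r: float) -> float:
    """Order curvature levels by signed curvature 1/R; flat sits at 0."""
    return 0.0 if math.isinf(r) else 1.0 / r


@dataclass(frozen=True)
class DesignGrid:
    """Cartesian product of curvature, orientation and location levels."""

    r_levels: tuple[float, ...] = DEFAULT_R_LEVELS
    o_levels: tuple[float, ...] = DEFAULT_O_LEVELS
    l_levels: tuple[str, ...] = DEFAULT_L_LEVELS

    def __post_init__(self) -> None:
        for name, levels in (
            ("r_levels", self.r_levels),
            ("o_levels", self.o_levels),
            ("l_levels", self.l_levels),
        ):
            if not levels:
                raise ValueError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicate values")

    def __len__(self) -> int:
        return len(self.r_levels) * len(self.o_levels) * len(self.l_levels)

    def designs(self) -> list[DesignParams]:
        """All designs, in deterministic (L, O, R) iteration order."""
        return [
            DesignParams(r=r, o=o, l=l)
            for l, o, r in product(self.l_levels, self.o_levels, self.r_levels)
        ]


def generate_grid(config: Mapping | None = None) -> DesignGrid:
    """Build a grid from a config mapping with optional r/o/l level lists.

    Absent entries fall back to the defaults (17 x 13 x 3 = 663 designs).
    Curvature entries may use the string ``"flat"`` for the uncurved level.
    """
    if config is None:
        return DesignGrid()

    def parse_r(v) -> float:
        if isinstance(v, str) and v.lower() == "flat":
            return FLAT
        return float(v)

    r = config.get("r_levels")
    o = config.get("o_levels")
    l = config.get("l_levels")
    return DesignGrid(
        r_levels=tuple(sorted((parse_r(v) for v in r), key=_curvature_key))
        if r is not None
        else DEFAULT_R_LEVELS,
        o_levels=tuple(float(v) for v in o) if o is not None else DEFAULT_O_LEVELS,
        l_levels=tuple(str(v) for v in l) if l is not None else DEFAULT_L_LEVELS,
    )


def sweep(
    text: str,
    grid: DesignGrid,
    tables: tuple[PerformanceTable, PerformanceTable],
    layout: KeyboardLayout | None = None,
    *,
    r_scale: float = 1.0,
    zero_mode: str = "key",
) -> list[DesignEvaluation]:
    """Evaluate every design in the grid for one input text.

    Deterministic: identical inputs give identical outputs. The keystroke
    sequence is encoded once (it does not depend on geometry); each design
    only re-resolves tap coordinates and spacebar subkeys.
    """
    direction_table, location_table = tables
    if layout is None:
        layout = build_base_layout()
    tokens = encode_text(text, layout)
    params_list = grid.designs()
    distributions = [
        simulate_tokens(
            tokens, apply_design(layout, p, r_scale=r_scale), zero_mode=zero_mode
        )
        for p in params_list
    ]
    return score_designs(params_list, distributions, direction_table, location_table)


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis H (tie-corrected) and chi-square p for one variable."""

    variable: str
    h: float
    p: float
    df: int

    def __post_init__(self) -> None:
        if self.h < -1e-12 or not (0.0 <= self.p <= 1.0):
            raise ValueError("invalid Kruskal-Wallis result")


def kruskal_wallis(
    values: Sequence[float], group_labels: Sequence, variable: str = ""
) -> KWResult:
    """Kruskal-Wallis rank-sum test of ``values`` across label groups.

    Uses the tie-corrected H statistic with a chi-square p-value on
    (groups - 1) degrees of freedom. If every observation is identical the
    tie correction is degenerate and H = 0 (p = 1) by convention.
    """
    if len(values) != len(group_labels):
        raise ValueError("values and group_labels must align")
    groups: dict = {}
    for v, g in zip(values, group_labels):
        groups.setdefault(g, []).append(v)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("all groups must be non-empty")
    samples = list(groups.values())
    df = len(samples) - 1
    flat = [v for g in samples for v in g]
    if len(set(flat)) == 1:
        return KWResult(variable=variable, h=0.0, p=1.0, df=df)
    h, p = stats.kruskal(*samples)
    return KWResult(variable=variable, h=float(h), p=float(p), df=df)


def sensitivity(evaluations: Sequence[DesignEvaluation]) -> pd.DataFrame:
    """Kruskal-Wallis test of PI_TOT against each design variable.

    Returns a table with one row per variable (R, O, L): the H statistic,
    its degrees of freedom and the p-value. Larger H means the variable
    stratifies PI_TOT more strongly.
    """
    pi_tot = [e.pi_tot for e in evaluations]
    rows = []
    for var, labels in (
        ("R", [e.params.r for e in evaluations]),
        ("O", [e.params.o for e in evaluations]),
        ("L", [e.params.l for e in evaluations]),
    ):
        res = kruskal_wallis(pi_tot, labels, variable=var)
        rows.append({"variable": var, "H": res.h, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def pi_tot_matrix(
    evaluations: Sequence[DesignEvaluation], grid: DesignGrid, l_level: str
) -> pd.DataFrame:
    """PI_TOT over the R x O lattice at one location level.

    Rows are curvature levels ordered by signed curvature (flat between
    the negative and positive branches), columns are orientations.
    """
    r_levels = sorted(grid.r_levels, key=_curvature_key)
    o_levels = sorted(grid.o_levels)
    lookup = {
        (e.params.r, e.params.o): e.pi_tot
        for e in evaluations
        if e.params.l == l_level
    }
    mat = np.full((len(r_levels), len(o_levels)), np.nan)
    for i, r in enumerate(r_levels):
        for j, o in enumerate(o_levels):
            if (r, o) not in lookup:
                raise ValueError(
                    f"incomplete R x O lattice at L={l_level!r}: missing "
                    f"(R={r!r}, O={o!r})"
                )
            mat[i, j] = lookup[(r, o)]
    index = ["flat" if math.isinf(r) else r for r in r_levels]
    return pd.DataFrame(mat, index=index, columns=o_levels)


def find_local_extrema(
    evaluations: Sequence[DesignEvaluation],
    grid: DesignGrid,
    *,
    strict: bool = False,
    neighborhood: int = 8,
    interior_only: bool = True,
) -> dict:
    """Local maxima/minima of PI_TOT over the R x O lattice per L level.

    A design is a local maximum (minimum) if its PI_TOT is >= (<=) — or
    strictly > (<) when ``strict`` — every lattice neighbour at the same
    location level. ``neighborhood`` is 4 (edge-adjacent) or 8 (including
    diagonals). By default only cells with a complete neighbourhood
    (interior cells) are considered.
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]

    by_params = {
        (e.params.r, e.params.o, e.params.l): e for e in evaluations
    }
    out: dict = {}
    for l_level in grid.l_levels:
        mat = pi_tot_matrix(evaluations, grid, l_level)
        r_levels = sorted(grid.r_levels, key=_curvature_key)
        o_levels = sorted(grid.o_levels)
        nr, no = len(r_levels), len(o_levels)
        maxima, minima = [], []
        for i in range(nr):
            for j in range(no):
                neigh = [
                    mat.iat[i + di, j + dj]
                    for di, dj in offsets
                    if 0 <= i + di < nr and 0 <= j + dj < no
                ]
                if interior_only and len(neigh) < len(offsets):
                    continue
                v = mat.iat[i, j]
                ev = by_params[(r_levels[i], o_levels[j], l_level)]
                if strict:
                    if all(v > w for w in neigh):
                        maxima.append(ev)
                    if all(v < w for w in neigh):
                        minima.append(ev)
                else:
                    if all(v >= w for w in neigh):
                        maxima.append(ev)
                    if all(v <= w for w in neigh):
                        minima.append(ev)
        out[l_level] = {"maxima": maxima, "minima": minima}
    return out
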