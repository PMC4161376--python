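"""Performance-index computation.

For one design, the gross tap-location index is sum over regions of
(count x empirical rank of that region); likewise for movement directions.
Dividing by the total tap count Tt gives per-tap indices, which are
rank-weighted means and therefore bounded by the table's rank range.

Across a design sweep, each component index is ranked in ascending order
over the N designs and the rank is normalised by N, giving PI_TL and
PI_MD in (0, 1]; PI_TOT = PI_TL + PI_MD lies in (0, 2], 2 being the best
attainable score (best of N in both components).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geometry import DesignParams
from .simulate import TransitionDistribution
from .tables import PerformanceTable


def gross_index(counts, table: PerformanceTable) -> float:
    """Rank-weighted sum: sum_k counts[k] * rank[k]."""
    total = 0.0
    for key, count in counts.items():
        if key not in table.rank:
            raise KeyError(f"key {key!r} not present in the {table.kind} table")
        total += count * table.rank[key]
    return total


def per_tap_index(gross: float, tt: int) -> float:
    """Normalise a gross index by the total number of taps."""
    if tt <= 0:
        raise ValueError("total tap count must be positive")
    return gross / tt


def rank_normalize(
    values: Sequence[float], tie_order: Sequence | None = None
) -> tuple[list[int], list[float]]:
    """Rank designs ascending by value and normalise ranks by N.

    The design with the smallest value gets rank 1 (PI = 1/N); the largest
    gets rank N (PI = 1.0). Ties are broken deterministically by
    ``tie_order`` (design-parameter sort keys) or, failing that, input
    position, so the ranks are always a permutation.

    Returns
    -------
    (ranks, pis)
        Integer ranks 1..N and normalised ranks rank/N, aligned with the
        input order.
    """
    n = len(values)
    if n == 0:
        raise ValueError("cannot rank an empty value list")
    keys = tie_order if tie_order is not None else range(n)
    order = sorted(range(n), key=lambda i: (values[i], keys[i]))
    ranks = [0] * n
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks, [r / n for r in ranks]


def total_index(pi_tl: float, pi_md: float) -> float:
    """PI_TOT = PI_TL + PI_MD, each component a normalised rank in (0, 1]."""
    for name, v in (("pi_tl", pi_tl), ("pi_md", pi_md)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} = {v!r} outside (0, 1]")
    return pi_tl + pi_md


@dataclass(frozen=True)
class DesignEvaluation:
    """All indices for one design within a sweep population of N designs."""

    params: DesignParams
    total_taps: int
    pi_tl_gross: float
    pi_md_gross: float
    pi_tl_pertap: float
    pi_md_pertap: float
    rank_tl: int
    rank_md: int
    pi_tl: float
    pi_md: float
    pi_tot: float


def score_designs(
    params_list: Sequence[DesignParams],
    distributions: Sequence[TransitionDistribution],
    direction_table: PerformanceTable,
    location_table: PerformanceTable,
) -> list[DesignEvaluation]:
    """Score a population of designs from their tap distributions.

    Cross-design ranking operates on the per-tap indices; with a fixed text
    Tt is constant so this ordering coincides with ranking the gross
    indices. Ties rank deterministically by (L, O, R).
    """
    if len(params_list) != len(distributions):
        raise ValueError("one distribution per design required")
    if not params_list:
        raise ValueError("empty design population")
    gross_tl = [gross_index(d.location_counts, location_table) for d in distributions]
    gross_md = [gross_index(d.direction_counts, direction_table) for d in distributions]
    pertap_tl = [
        per_tap_index(g, d.total_taps) for g, d in zip(gross_tl, distributions)
    ]
    pertap_md = [
        per_tap_index(g, d.total_taps) for g, d in zip(gross_md, distributions)
    ]
    tie = [p.sort_key() for p in params_list]
    rank_tl, pi_tl = rank_normalize(pertap_tl, tie)
    rank_md, pi_md = rank_normalize(pertap_md, tie)
    return [
        DesignEvaluation(
            params=params_list[i],
            total_taps=distributions[i].total_taps,
            pi_tl_gross=gross_tl[i],
            pi_md_gross=gross_md[i],
            pi_tl_pertap=pertap_tl[i],
            pi_md_pertap=pertap_md[i],
            rank_tl=rank_tl[i],
            rank_md=rank_md[i],
            pi_tl=pi_tl[i],
            pi_md=pi_md[i],
            pi_tot=total_index(pi_tl[i], pi_md[i]),
        )
        for i in range(len(params_list))
    ]


def evaluations_frame(evaluations: Sequence[DesignEvaluation]) -> pd.DataFrame:
    """Tabulate a sweep: one row per design, full precision."""
    rows = []
    for e in evaluations:
        rows.append(
            {
                "R": e.params.r,
                "O": e.params.o,
                "L": e.params.l,
                "total_taps": e.total_taps,
                "pi_tl_gross": e.pi_tl_gross,
                "pi_md_gross": e.pi_md_gross,
                "pi_tl_pertap": e.pi_tl_pertap,
                "pi_md_pertap": e.pi_md_pertap,
                "rank_tl": e.rank_tl,
                "rank_md": e.rank_md,
                "pi_tl": e.pi_tl,
                "pi_md": e.pi_md,
                "pi_tot": e.pi_tot,
            }
        )
    return pd.DataFrame(rows)


def evaluations_from_frame(df: pd.DataFrame) -> list[DesignEvaluation]:
    """Rebuild evaluations from a results table (inverse of evaluations_frame)."""
    return [
        DesignEvaluation(
            params=DesignParams(r=float(row.R), o=float(row.O), l=str(row.L)),
            total_taps=int(row.total_taps),
            pi_tl_gross=float(row.pi_tl_gross),
            pi_md_gross=float(row.pi_md_gross),
            pi_tl_pertap=float(row.pi_tl_pertap),
            pi_md_pertap=float(row.pi_md_pertap),
            rank_tl=int(row.rank_tl),
            rank_md=int(row.rank_md),
            pi_tl=float(row.pi_tl),
            pi_md=float(row.pi_md),
            pi_tot=float(row.pi_tot),
        )
        for row in df.itertuples()
    ]
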