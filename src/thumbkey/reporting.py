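"""Result export: ranked tables, plot-ready PI surfaces, highlights, logs.

PI values are carried at full precision throughout the pipeline; rounding
(default 2 decimals) happens only here, at report time. Because PI is a
population-relative quantity (a normalised rank), a single design can only
be evaluated against a reference sweep, never in isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from pathlib import Path
from typing import Mapping, Sequence

from .geometry import DesignParams
from .scoring import DesignEvaluation, evaluations_frame
from .sweep import DesignGrid, find_local_extrema, pi_tot_matrix, sensitivity


def _design_record(e: DesignEvaluation, precision: int) -> dict:
    return {
        "R": "flat" if e.params.is_flat else e.params.r,
        "O": e.params.o,
        "L": e.params.l,
        "rank_tl": e.rank_tl,
        "rank_md": e.rank_md,
        "pi_tl": round(e.pi_tl, precision),
        "pi_md": round(e.pi_md, precision),
        "pi_tot": round(e.pi_tot, precision),
    }


def evaluate_single(
    design: DesignParams, reference: Sequence[DesignEvaluation]
) -> DesignEvaluation:
    """Look up one design's evaluation within a reference sweep.

    Raises if the reference sweep is empty or the design is not part of the
    reference grid (inserting new designs would change every rank, so it is
    not supported implicitly).
    """
    if not reference:
        raise ValueError("reference sweep is empty")
    for e in reference:
        if e.params == design:
            return e
    raise KeyError(
        f"design ({design.label()}) is not in the reference sweep; "
        "re-run the sweep with a grid containing it"
    )


def report(
    evaluations: Sequence[DesignEvaluation],
    grid: DesignGrid,
    outdir,
    *,
    precision: int = 2,
    strict_extrema: bool = False,
    config: Mapping | None = None,
    plots: bool = False,
) -> dict:
    """Write the full report for one sweep into ``outdir``.

    Produces ``results.csv`` (one row per design, ranked best to worst,
    full precision), one plot-ready ``pi_tot_L-<level>.csv`` matrix of
    PI_TOT over R x O per location level, ``highlights.json`` (best, worst
    and local extrema at the configured precision, plus the sensitivity
    table) and ``run_log.json`` (config hash and versions). With
    ``plots=True`` a heatmap PNG per location level is rendered as well.

    Returns the mapping of artifact names to paths.
    """
    if not evaluations:
        raise ValueError("cannot report on an empty sweep")
    if precision < 0:
        raise ValueError("precision must be >= 0")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = evaluations_frame(evaluations).sort_values(
        "pi_tot", ascending=False, kind="stable"
    )
    paths["results"] = outdir / "results.csv"
    df.to_csv(paths["results"], index=False)

    for l_level in grid.l_levels:
        mat = pi_tot_matrix(evaluations, grid, l_level)
        p = outdir / f"pi_tot_L-{l_level}.csv"
        mat.to_csv(p, index_label="R")
        paths[f"matrix_{l_level}"] = p

    best = max(evaluations, key=lambda e: e.pi_tot)
    worst = min(evaluations, key=lambda e: e.pi_tot)
    extrema = find_local_extrema(evaluations, grid, strict=strict_extrema)
    sens = sensitivity(evaluations)
    highlights = {
        "n_designs": len(evaluations),
        "best": _design_record(best, precision),
        "worst": _design_record(worst, precision),
        "local_extrema": {
            l: {
                kind: [_design_record(e, precision) for e in items]
                for kind, items in per_l.items()
            }
            for l, per_l in extrema.items()
        },
        "sensitivity": [
            {
                "variable": row.variable,
                "H": round(float(row.H), precision),
                "df": int(row.df),
                "p": float(row.p),
            }
            for row in sens.itertuples()
        ],
    }
    paths["highlights"] = outdir / "highlights.json"
    paths["highlights"].write_text(
        json.dumps(highlights, indent=2, sort_keys=True), encoding="utf-8"
    )

    cfg = dict(config or {})
    cfg.setdefault(
        "grid",
        {
            "r_levels": ["flat" if math.isinf(r) else r for r in grid.r_levels],
            "o_levels": list(grid.o_levels),
            "l_levels": list(grid.l_levels),
        },
    )
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    import thumbkey

    log = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "thumbkey_version": thumbkey.__version__,
        "python_version": platform.python_version(),
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(
        json.dumps(log, indent=2, sort_keys=True), encoding="utf-8"
    )

    if plots:
        _render_heatmaps(evaluations, grid, outdir, paths)
    return paths


def _render_heatmaps(evaluations, grid, outdir: Path, paths: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for l_level in grid.l_levels:
        mat = pi_tot_matrix(evaluations, grid, l_level)
        fig, ax = plt.subplots(figsize=(7, 5))
        im = ax.imshow(mat.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), [f"{c:g}" for c in mat.columns])
        ax.set_yticks(range(len(mat.index)), [str(r) for r in mat.index])
        ax.set_xlabel("orientation O (deg)")
        ax.set_ylabel("curvature R (mm)")
        ax.set_title(f"PI_TOT, L = {l_level}")
        fig.colorbar(im, ax=ax, label="PI_TOT")
        p = outdir / f"pi_tot_L-{l_level}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths[f"plot_{l_level}"] = p
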