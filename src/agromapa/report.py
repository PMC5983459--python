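"""Run summaries and human-readable reporting.

Values are rounded to one decimal for display only; all machine outputs
keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .geo_core import Grid, LandraceRecord
from .prioritize import NormalizationParams, ThresholdSet

_INDEX_COLS = ("ldi", "h_prime", "pws_pct", "aed_pct")


@dataclass(frozen=True)
class RunSummary:
    n_quadrants: int
    n_records_assigned: int
    n_records_unassigned: int
    thresholds: ThresholdSet
    normalization: NormalizationParams
    general_threshold: float
    n_rs_mapas: int
    n_as_mapas: int
    #: per-index (min, max) over RS-selected quadrants; None when no MAPA
    rs_ranges: Mapping[str, tuple[float, float] | None]
    as_ranges: Mapping[str, tuple[float, float] | None]
    rs_subset_of_as: bool


def _ranges(
    index_table: pd.DataFrame, selected_ids: set[str]
) -> dict[str, tuple[float, float] | None]:
    sub = index_table[index_table["quadrant_id"].isin(selected_ids)]
    if sub.empty:
        return {c: None for c in _INDEX_COLS}
    return {c: (float(sub[c].min()), float(sub[c].max())) for c in _INDEX_COLS}


def build_summary(
    index_table: pd.DataFrame,
    mapa_result: pd.DataFrame,
    *,
    n_unassigned: int = 0,
    n_assigned: int = 0,
) -> RunSummary:
    """Condense a run into counts, thresholds and per-index value ranges
    computed separately over the RS- and AS-selected quadrants.

    With an empty MAPA set the ranges are reported as undefined (None),
    never as zeros.
    """
    rs_ids = set(mapa_result.loc[mapa_result["rs_pass"], "quadrant_id"])
    as_ids = set(mapa_result.loc[mapa_result["as_pass"], "quadrant_id"])
    return RunSummary(
        n_quadrants=len(index_table),
        n_records_assigned=n_assigned,
        n_records_unassigned=n_unassigned,
        thresholds=mapa_result.attrs["thresholds"],
        normalization=mapa_result.attrs["normalization"],
        general_threshold=mapa_result.attrs["general_threshold"],
        n_rs_mapas=len(rs_ids),
        n_as_mapas=len(as_ids),
        rs_ranges=_ranges(index_table, rs_ids),
        as_ranges=_ranges(index_table, as_ids),
        rs_subset_of_as=rs_ids <= as_ids,
    )


def format_summary(summary: RunSummary) -> str:
    """One-decimal plain-text report mirroring the threshold and value-
    range tables of the method."""
    t, n = summary.thresholds, summary.normalization
    lines = [
        "Run summary",
        "===========",
        f"quadrants: {summary.n_quadrants}",
        f"records assigned/unassigned: "
        f"{summary.n_records_assigned}/{summary.n_records_unassigned}",
        "",
        "Thresholds (Restrictive Strategy)  |  normalized (Additive)",
        f"  LDI  >= {t.ldi_min:g}",
        f"  H'   >= {t.h_min:.4f}",
        f"  PWS  >= {t.pws_min_pct:g}%",
        f"  AED  >= {t.aed_min_pct:g}%",
        f"scaling maxima: LDI {n.ldi_max:g}, H' {n.h_max:.4f}",
        f"general threshold (AS): {summary.general_threshold:.1f} degrees",
        "",
        f"MAPAs: RS {summary.n_rs_mapas}, AS {summary.n_as_mapas} "
        f"(RS subset of AS: {summary.rs_subset_of_as})",
        "",
        "Index ranges over selected MAPAs (min - max)",
        f"{'index':<10}{'RS':>20}{'AS':>20}",
    ]
    for col in _INDEX_COLS:
        cells = []
        for ranges in (summary.rs_ranges, summary.as_ranges):
            r = ranges[col]
            cells.append("undefined" if r is None else f"{r[0]:.1f} - {r[1]:.1f}")
        lines.append(f"{col:<10}{cells[0]:>20}{cells[1]:>20}")
    return "\n".join(lines)


def plot_map(
    grid: Grid,
    mapa_result: pd.DataFrame,
    path: str,
) -> None:
    """Static map of quadrants coloured by strategy outcome (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    status = {
        row.quadrant_id: (row.rs_pass, row.as_pass)
        for row in mapa_result.itertuples(index=False)
    }
    fig, ax = plt.subplots(figsize=(7, 7))
    for q in grid:
        rs, as_ = status.get(q.id, (False, False))
        colour = "#c0392b" if rs else "#e67e22" if as_ else "#ecf0f1"
        minx, miny, maxx, maxy = q.geometry.bounds
        ax.add_patch(
            Rectangle(
                (minx, miny),
                maxx - minx,
                maxy - miny,
                facecolor=colour,
                edgecolor="black",
                linewidth=0.4,
            )
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title("MAPAs: red = RS (and AS), orange = AS only")
    fig.savefig(path, dpi=120)
    plt.close(fig)
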