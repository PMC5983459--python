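"""MAPA selection: arcsine-square-root normalization and the Restrictive
and Additive prioritization strategies.

Restrictive Strategy (RS): a sequential sieve — a quadrant is a MAPA iff it
meets every per-criterion threshold (all comparisons ≥). Because each stage
is a pure filter, the outcome is invariant to stage order and is computed
here as an intersection of per-criterion pass sets.

Additive Strategy (AS): every index value is normalized with
``asin(sqrt(p))`` expressed in degrees (counts and H' are first scaled by
their across-grid maxima; percentages are treated as proportions), the four
normalized values are summed per quadrant, and the sum is compared against
a general threshold — the sum of the four normalized per-criterion
thresholds. No per-criterion sieve applies, so a quadrant can qualify on
protected-area and land-cover strength alone.

Since arcsine normalization is strictly increasing, a quadrant passing all
RS thresholds always reaches the AS general threshold: RS MAPAs are a
subset of AS MAPAs by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo_core import LandraceRecord
from .indices import h_threshold_from_median

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-criterion thresholds for the Restrictive Strategy.

    ``h_min=None`` means "use the median H' over quadrants with LDI ≥ 1",
    resolved against the index table at selection time.
    """

    ldi_min: float = 1.0
    h_min: float | None = None
    pws_min_pct: float = 20.0
    aed_min_pct: float = 90.0

    def __post_init__(self) -> None:
        if self.ldi_min < 0 or (self.h_min is not None and self.h_min < 0):
            raise ValueError("thresholds must be non-negative")
        for pct in (self.pws_min_pct, self.aed_min_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("percentage thresholds must lie in [0, 100]")

    def resolve(self, index_table: pd.DataFrame) -> "ThresholdSet":
        """Return a copy with ``h_min`` computed from the data if unset."""
        if self.h_min is not None:
            return self
        return replace(self, h_min=h_threshold_from_median(index_table))


@dataclass(frozen=True)
class NormalizationParams:
    """Scaling maxima turning LDI and H' into proportions for the arcsine
    transform. By default they are the observed across-grid maxima;
    ``from_table`` recomputes them, or they can be pinned to published
    values (e.g. 315 and 2.525)."""

    ldi_max: float
    h_max: float

    def __post_init__(self) -> None:
        if self.ldi_max <= 0 or self.h_max <= 0:
            raise ValueError("normalization maxima must be positive")

    @classmethod
    def from_table(cls, index_table: pd.DataFrame) -> "NormalizationParams":
        ldi_max = float(index_table["ldi"].max())
        h_max = float(index_table["h_prime"].max())
        return cls(ldi_max=max(ldi_max, 1.0), h_max=h_max if h_max > 0 else 1.0)


def arcsine_normalize(value: float, max_value: float = 1.0) -> float:
    """Arcsine-square-root transform to degrees in [0, 90].

    ``value`` is first scaled to a proportion by ``max_value`` (percentages
    must be divided by 100 by the caller, with ``max_value=1``). Values
    above the maximum are clamped to 90 degrees with a warning; negative
    values are an error.
    """
    value = float(value)
    if value < 0:
        raise ValueError(f"cannot normalize negative value {value}")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    p = value / max_value
    if p > 1.0:
        logger.warning(
            "value %g exceeds scaling maximum %g; clamping to 90 degrees",
            value,
            max_value,
        )
        p = 1.0
    return math.degrees(math.asin(math.sqrt(p)))


def _normalized_columns(
    index_table: pd.DataFrame, norm: NormalizationParams
) -> pd.DataFrame:
    """Vectorised arcsine normalization of the four index columns."""
    def asin_deg(p: np.ndarray) -> np.ndarray:
        return np.degrees(np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0))))

    out = pd.DataFrame(index=index_table.index)
    out["ldi_norm"] = asin_deg(index_table["ldi"].to_numpy(float) / norm.ldi_max)
    out["h_norm"] = asin_deg(index_table["h_prime"].to_numpy(float) / norm.h_max)
    out["pws_norm"] = asin_deg(index_table["pws_pct"].to_numpy(float) / 100.0)
    out["aed_norm"] = asin_deg(index_table["aed_pct"].to_numpy(float) / 100.0)
    return out


def restrictive_select(
    index_table: pd.DataFrame, thresholds: ThresholdSet
) -> set[str]:
    """Quadrant ids passing every criterion (the sieve's fixed point).

    Implemented as the intersection of the four per-criterion pass sets, so
    the result cannot depend on the order the sieve stages are applied in.
    """
    t = thresholds.resolve(index_table)
    passing = (
        (index_table["ldi"] >= t.ldi_min)
        & (index_table["h_prime"] >= t.h_min)
        & (index_table["pws_pct"] >= t.pws_min_pct)
        & (index_table["aed_pct"] >= t.aed_min_pct)
    )
    return set(index_table.loc[passing, "quadrant_id"])


def general_threshold(
    thresholds: ThresholdSet, norm: NormalizationParams
) -> float:
    """Additive-Strategy general threshold: the sum of the four arcsine-
    normalized per-criterion thresholds, in degrees (unrounded; round to
    one decimal only for display)."""
    if thresholds.h_min is None:
        raise ValueError("h_min must be resolved before computing the threshold")
    return (
        arcsine_normalize(thresholds.ldi_min, norm.ldi_max)
        + arcsine_normalize(thresholds.h_min, norm.h_max)
        + arcsine_normalize(thresholds.pws_min_pct / 100.0)
        + arcsine_normalize(thresholds.aed_min_pct / 100.0)
    )


def additive_select(
    index_table: pd.DataFrame,
    thresholds: ThresholdSet,
    norm: NormalizationParams | None = None,
) -> pd.DataFrame:
    """Score every quadrant under both strategies.

    Returns a ``MapaResult`` table with one row per quadrant and columns
    ``quadrant_id, rs_pass, as_score, as_pass``; the general threshold used
    is attached as ``result.attrs["general_threshold"]``. Decisions are
    made on unrounded values. Quadrants with no landrace data still get an
    AS score (their LDI/H' terms contribute 0 degrees), so areas strong on
    protected cover and agro-ecosystem diversity alone can be selected.
    """
    t = thresholds.resolve(index_table)
    if norm is None:
        norm = NormalizationParams.from_table(index_table)
    gt = general_threshold(t, norm)
    normed = _normalized_columns(index_table, norm)
    as_score = normed.sum(axis=1)
    rs_ids = restrictive_select(index_table, t)

    result = pd.DataFrame(
        {
            "quadrant_id": index_table["quadrant_id"],
            "rs_pass": index_table["quadrant_id"].isin(rs_ids),
            "as_score": as_score,
            "as_pass": as_score >= gt,
        }
    )
    result.attrs["general_threshold"] = gt
    result.attrs["thresholds"] = t
    result.attrs["normalization"] = norm
    return result


def species_composition(
    mapa_ids: Iterable[str],
    records: Sequence[LandraceRecord],
    assignment: Mapping[str, Sequence[LandraceRecord]],
) -> pd.DataFrame:
    """Species make-up of the selected MAPAs.

    For the records falling inside selected quadrants, the percentage of
    distinct landraces belonging to each species, sorted descending.
    Returns columns ``species, n_landraces, pct``.
    """
    mapa_ids = set(mapa_ids)
    label: dict[str, str] = {}  # normalized key -> first-seen original label
    pairs = set()
    for qid in mapa_ids:
        for r in assignment.get(qid, ()):
            key = r.species.strip().casefold()
            label.setdefault(key, r.species.strip())
            pairs.add((key, r.landrace_name.strip().casefold()))
    if not pairs:
        return pd.DataFrame(columns=["species", "n_landraces", "pct"])
    counts = (
        pd.Series([label[sp] for sp, _ in pairs], name="species")
        .value_counts()
        .rename_axis("species")
        .reset_index(name="n_landraces")
    )
    counts["pct"] = 100.0 * counts["n_landraces"] / counts["n_landraces"].sum()
    return counts.sort_values(
        ["n_landraces", "species"], ascending=[False, True]
    ).reset_index(drop=True)
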