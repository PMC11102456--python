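"""Region definition by top-fraction thresholding, and overlap metrics.

A region is the top fraction ``f`` (default 10%) of search-space vertices
ranked by a contrast map; the size rule is ``k = max(1, round_half_up(f * S))``
with ties broken toward the smaller vertex id so definitions are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FROI",
    "OverlapResult",
    "top_fraction_size",
    "define_froi",
    "dice",
    "overlap_metrics",
]


def top_fraction_size(n: int, fraction: float) -> int:
    """Number of vertices selected at fraction ``fraction`` of ``n``
    (round half up, at least 1)."""
    if n < 1:
        raise ValueError("empty search space")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    return max(1, min(n, math.floor(fraction * n + 0.5)))


@dataclass(frozen=True)
class FROI:
    """A defined region: vertex subset with provenance."""

    froi_id: str
    method: str                 # connectivity | localizer-run1 | atlas-* | ground-truth
    vertices: tuple[int, ...]   # sorted global vertex ids
    fraction: float
    source: str = ""

    def __post_init__(self) -> None:
        if list(self.vertices) != sorted(set(self.vertices)):
            raise ValueError("vertices must be sorted and unique")

    @property
    def vertex_set(self) -> frozenset[int]:
        return frozenset(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class OverlapResult:
    dice_pred_actual: float
    dice_actual_actual: float
    explainable_ratio: float | None   # None when the actual/actual Dice is 0
    chance_adjusted: float
    fraction: float


def define_froi(
    values: np.ndarray,
    vertices: np.ndarray,
    *,
    froi_id: str,
    method: str,
    fraction: float = 0.10,
    source: str = "",
) -> FROI:
    """Select the top-``fraction`` vertices of a map over a search space.

    ``values[i]`` is the map value at ``vertices[i]``. Ties are broken by
    the smaller vertex id; the selection is invariant under any strictly
    increasing transform of the map.
    """
    values = np.asarray(values, dtype=float)
    vertices = np.asarray(vertices)
    if values.shape != vertices.shape:
        raise ValueError("values and vertices must align")
    if vertices.size == 0:
        raise ValueError("empty search space")
    if not np.all(np.isfinite(values)):
        raise ValueError("map values must be finite")
    k = top_fraction_size(vertices.size, fraction)
    order = np.lexsort((vertices, -values))
    chosen = np.sort(vertices[order[:k]])
    return FROI(
        froi_id=froi_id,
        method=method,
        vertices=tuple(int(v) for v in chosen),
        fraction=fraction,
        source=source,
    )


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|). Errors if both sets are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def overlap_metrics(pred: FROI, actual_run1: FROI, actual_run2: FROI) -> OverlapResult:
    """Overlap of a predicted region with localizer-defined regions.

    The explainable-overlap ratio divides Dice(pred, actual-run1) by the
    run1/run2 test-retest Dice; the chance-adjusted overlap rescales Dice
    by its expectation ``f`` for two independent top-f selections drawn
    from the same search space.
    """
    if not (pred.froi_id == actual_run1.froi_id == actual_run2.froi_id):
        raise ValueError("regions must share a froi id")
    if not (pred.fraction == actual_run1.fraction == actual_run2.fraction):
        raise ValueError("regions must share the threshold fraction")
    f = pred.fraction
    d_pa = dice(pred.vertices, actual_run1.vertices)
    d_aa = dice(actual_run1.vertices, actual_run2.vertices)
    ratio = d_pa / d_aa if d_aa > 0 else None
    chance_adj = (d_pa - f) / (1.0 - f) if f < 1 else 0.0
    return OverlapResult(
        dice_pred_actual=d_pa,
        dice_actual_actual=d_aa,
        explainable_ratio=ratio,
        chance_adjusted=chance_adj,
        fraction=f,
    )
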