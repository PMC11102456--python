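"""Synthetic group atlases built from the cohort's true regions.

Three flavours emulate common atlas failure modes relative to
individual-specific regions:

* ``union-threshold`` — vertices belonging to at least a fraction ``q`` of
  subjects' true regions (a probabilistic group parcel);
* ``dilated`` — the union-threshold set morphologically grown on the
  sheet (a coarse parcel);
* ``shifted`` — the union-threshold set displaced by a fixed planar
  offset (a systematically mismatched parcel).
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort

__all__ = ["make_group_atlas", "ATLAS_MODES"]

ATLAS_MODES = ("union-threshold", "dilated", "shifted")


def make_group_atlas(
    cohort: Cohort,
    mode: str,
    *,
    q: float = 0.1,
    dilate_radius: float = 2.0,
    shift: tuple[float, float] = (4.0, 0.0),
) -> dict[str, np.ndarray]:
    """One shared vertex set per region, keyed by froi id."""
    if mode not in ATLAS_MODES:
        raise ValueError(f"unknown atlas mode {mode!r}; expected one of {ATLAS_MODES}")
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")

    surface = cohort.surface
    tab = surface.table.set_index("vertex")
    n_total = surface.n_vertices
    out: dict[str, np.ndarray] = {}
    for entry in cohort.registry:
        counts = np.zeros(n_total)
        for subj in cohort.subjects:
            counts[subj.ground_truth.froi_vertices[entry.froi_id]] += 1
        base = np.flatnonzero(counts >= q * cohort.n_subjects - 1e-9)
        if base.size == 0:
            raise ValueError(f"empty atlas set for {entry.froi_id} at q={q}")

        if mode == "union-threshold":
            chosen = base
        else:
            hemi_verts = surface.hemi_vertices(entry.hemisphere)
            hemi_xy = tab.loc[hemi_verts, ["x", "y"]].to_numpy(dtype=float)
            base_xy = tab.loc[base, ["x", "y"]].to_numpy(dtype=float)
            if mode == "dilated":
                d = np.sqrt(
                    ((hemi_xy[:, None, :] - base_xy[None, :, :]) ** 2).sum(axis=2)
                ).min(axis=1)
                chosen = hemi_verts[d <= dilate_radius + 1e-9]
            else:  # shifted: nearest vertex to each displaced base vertex
                target = base_xy + np.asarray(shift)[None, :]
                d2 = ((hemi_xy[:, None, :] - target[None, :, :]) ** 2).sum(axis=2)
                chosen = np.unique(hemi_verts[np.argmin(d2, axis=0)])
        if chosen.size == 0:
            raise ValueError(f"empty atlas set for {entry.froi_id} in mode {mode}")
        out[entry.froi_id] = np.sort(chosen)
    return out
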