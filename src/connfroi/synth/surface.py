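"""Synthetic cortical sheet: a flat 2-D vertex grid per hemisphere embedded
in 3-D, with smooth anatomy fields, a contiguous parcellation (179 parcels
per hemisphere) and 9 disjoint search spaces per hemisphere.

Vertex ids are global and 0-based: the left hemisphere occupies
``0 .. n-1`` and the right hemisphere ``n .. 2n-1``. Hemispheres never mix:
parcels and search spaces are ipsilateral by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import FROIRegistry, default_registry

__all__ = ["SurfaceModel", "generate_surface"]

HEMISPHERES = ("lh", "rh")
NO_SEARCH_SPACE = ""


@dataclass
class SurfaceModel:
    """Vertex table for both hemispheres plus label lookups.

    ``table`` columns: vertex (global id), hemi, x, y, z, curvature,
    thickness, parcel (0..P-1 within hemisphere), search_space (label or
    empty string).
    """

    table: pd.DataFrame
    n_parcels: int
    registry: FROIRegistry

    def __post_init__(self) -> None:
        counts = self.table.groupby("hemi", observed=True).size()
        if len(counts) == 2 and counts.iloc[0] != counts.iloc[1]:
            raise ValueError("hemispheres must have identical vertex counts")
        if self.table["parcel"].isna().any():
            raise ValueError("every vertex needs a parcel label")

    @property
    def n_vertices(self) -> int:
        """Total vertex count over both hemispheres."""
        return len(self.table)

    def hemi_mask(self, hemi: str) -> np.ndarray:
        return (self.table["hemi"] == hemi).to_numpy()

    def hemi_vertices(self, hemi: str) -> np.ndarray:
        return self.table.loc[self.hemi_mask(hemi), "vertex"].to_numpy()

    def parcel_labels(self, hemi: str) -> np.ndarray:
        """Per-vertex parcel label for one hemisphere, in vertex order."""
        return self.table.loc[self.hemi_mask(hemi), "parcel"].to_numpy()

    def search_space_vertices(self, label: str) -> np.ndarray:
        """Global vertex ids of one search space, sorted."""
        out = self.table.loc[self.table["search_space"] == label, "vertex"].to_numpy()
        if out.size == 0:
            raise KeyError(f"unknown or empty search space: {label!r}")
        return np.sort(out)

    def hemisphere_of(self, label: str) -> str:
        rows = self.table.loc[self.table["search_space"] == label, "hemi"]
        if rows.empty:
            raise KeyError(label)
        return str(rows.iloc[0])

    def coordinates(self, vertices: np.ndarray) -> np.ndarray:
        sub = self.table.set_index("vertex").loc[np.asarray(vertices)]
        return sub[["x", "y", "z"]].to_numpy(dtype=float)

    def anatomy(self, vertices: np.ndarray) -> pd.DataFrame:
        """curvature, thickness, x, y, z for the requested vertices."""
        sub = self.table.set_index("vertex").loc[np.asarray(vertices)]
        return sub[["curvature", "thickness", "x", "y", "z"]]


def _smooth_field(xy: np.ndarray, rng: np.random.Generator, n_waves: int = 6) -> np.ndarray:
    """Smooth random field on the sheet as a small sum of plane waves."""
    freqs = rng.uniform(0.05, 0.25, size=(n_waves, 2))
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.normal(0, 1.0, size=n_waves)
    field = np.zeros(len(xy))
    for f, ph, a in zip(freqs, phases, amps):
        field += a * np.sin(xy @ f + ph)
    return field / max(n_waves, 1) ** 0.5


def generate_surface(
    n_vertices: int,
    n_parcels: int = 179,
    *,
    searchspace_size: int = 30,
    registry: FROIRegistry | None = None,
    seed: int | np.random.Generator | None = 0,
) -> SurfaceModel:
    """Build the two-hemisphere synthetic sheet.

    Parameters
    ----------
    n_vertices:
        Vertices per hemisphere.
    n_parcels:
        Ipsilateral parcel count (Voronoi cells of well-spread seeds, so
        parcels are contiguous on the sheet).
    searchspace_size:
        Target number of vertices per search space (9 per hemisphere,
        disjoint by construction).
    """
    registry = registry or default_registry()
    if n_vertices < n_parcels:
        raise ValueError("need at least as many vertices as parcels")
    if 9 * searchspace_size > n_vertices:
        raise ValueError("search spaces would not fit on the hemisphere")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nx = int(np.ceil(np.sqrt(n_vertices)))
    ny = int(np.ceil(n_vertices / nx))
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    grid = np.column_stack([gx.ravel(), gy.ravel()])[:n_vertices]

    frames = []
    for hi, hemi in enumerate(HEMISPHERES):
        xy = grid.copy()
        # mirror hemispheres left/right of the midline with a gap
        x = xy[:, 0] + 5.0 if hemi == "rh" else -(xy[:, 0] + 5.0)
        y = xy[:, 1]
        z = 3.0 * np.sin(0.15 * xy[:, 0]) * np.cos(0.12 * xy[:, 1])
        curvature = _smooth_field(xy, rng)
        thickness = 2.5 + 0.5 * _smooth_field(xy, rng)

        # search spaces first: 9 disjoint disks around well-separated centers
        search_space = np.full(n_vertices, NO_SEARCH_SPACE, dtype=object)
        centers = _searchspace_centers(nx, ny)
        taken = np.zeros(n_vertices, dtype=bool)
        space_members: list[np.ndarray] = []
        for entry, c in zip(registry.by_hemisphere(hemi), centers):
            dist = np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1])
            dist[taken] = np.inf
            chosen = np.argsort(dist, kind="stable")[:searchspace_size]
            search_space[chosen] = entry.search_space
            taken[chosen] = True
            space_members.append(chosen)

        # contiguous parcels: each search space is one dedicated parcel
        # (0..8); the remainder are Voronoi cells of random seed vertices
        outside = np.flatnonzero(~taken)
        if outside.size < n_parcels - 9:
            raise ValueError(
                "not enough vertices outside the search spaces to seed "
                f"{n_parcels - 9} parcels (have {outside.size})"
            )
        seeds = outside[rng.choice(outside.size, size=n_parcels - 9, replace=False)]
        d2 = ((xy[:, None, :] - xy[seeds][None, :, :]) ** 2).sum(axis=2)
        parcel = 9 + np.argmin(d2, axis=1)
        for label, members in enumerate(space_members):
            parcel[members] = label

        frames.append(
            pd.DataFrame(
                {
                    "vertex": np.arange(n_vertices) + hi * n_vertices,
                    "hemi": hemi,
                    "x": x,
                    "y": y,
                    "z": z,
                    "curvature": curvature,
                    "thickness": thickness,
                    "parcel": parcel,
                    "search_space": search_space,
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)
    for hemi in HEMISPHERES:
        labels = table.loc[table["hemi"] == hemi, "parcel"]
        if labels.nunique() != n_parcels:
            raise RuntimeError("parcellation produced empty parcels")
    return SurfaceModel(table=table, n_parcels=n_parcels, registry=registry)


def _searchspace_centers(nx: int, ny: int) -> list[tuple[float, float]]:
    """Nine well-separated centers on a 3x3 arrangement with margins."""
    xs = [nx * f for f in (0.17, 0.5, 0.83)]
    ys = [ny * f for f in (0.17, 0.5, 0.83)]
    return [(x, y) for y in ys for x in xs]
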