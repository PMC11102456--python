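"""Vertex-to-parcel functional connectomes from resting runs.

For a region's search space, the connectome is the Fisher-transformed
Pearson correlation between each search-space vertex's timeseries and the
mean timeseries of each of the 179 ipsilateral parcels, computed over the
motion-censored frames only. The model feature matrix appends the five
anatomical columns (curvature, thickness, x, y, z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth.cohort import RestingRun
from .synth.surface import SurfaceModel

__all__ = [
    "FrameMask",
    "Connectome",
    "FeatureMatrix",
    "censor_frames",
    "fisher_z",
    "compute_connectome",
    "build_feature_matrix",
    "ANATOMY_COLUMNS",
]

logger = logging.getLogger(__name__)

ANATOMY_COLUMNS = ("curvature", "thickness", "x", "y", "z")
_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FrameMask:
    keep: np.ndarray        # boolean, length = run volumes
    threshold_mm: float

    def __post_init__(self) -> None:
        if int(self.keep.sum()) < 2:
            raise ValueError("fewer than 2 frames survive censoring")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class Connectome:
    """S x P matrix of Fisher-z vertex-to-parcel correlations."""

    z: np.ndarray             # (S, P)
    vertex_ids: np.ndarray    # (S,) global vertex ids (row order)
    froi_id: str
    threshold_mm: float = np.nan

    def __post_init__(self) -> None:
        if self.z.shape[0] != self.vertex_ids.shape[0]:
            raise ValueError("row count must match vertex ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectome entries must be finite")


@dataclass
class FeatureMatrix:
    """S x (P + 5) model design block: connectivity then anatomy columns."""

    values: np.ndarray
    columns: tuple[str, ...]
    vertex_ids: np.ndarray
    froi_id: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.vertex_ids), len(self.columns)):
            raise ValueError("shape mismatch between values, columns and vertices")


def censor_frames(run: "RestingRun | np.ndarray", threshold_mm: float = 0.5) -> FrameMask:
    """Keep frames with framewise displacement <= threshold (strict ``>``
    drops)."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    fd = run.fd if isinstance(run, RestingRun) else np.asarray(run, dtype=float)
    keep = ~(fd > threshold_mm)
    return FrameMask(keep=keep, threshold_mm=threshold_mm)


def fisher_z(r):
    """arctanh with clipping at |r| = 1 - 1e-7 to avoid divergence."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("correlations must be finite")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return float(out) if out.ndim == 0 else out


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows; returns (standardized, zero-variance row mask)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    return (x - mu) / sd, zero


def compute_connectome(
    run: RestingRun,
    mask: FrameMask,
    surface: SurfaceModel,
    froi_id: str,
) -> Connectome:
    """Fisher-z correlations of each search-space vertex against every
    ipsilateral parcel-mean timeseries, over kept frames only.

    A vertex's own parcel is included among the targets (all P columns are
    always present). Zero-variance series produce r = 0 with a logged
    warning.
    """
    entry = surface.registry[froi_id]
    vertices = surface.search_space_vertices(entry.search_space)
    hemi_verts = surface.hemi_vertices(entry.hemisphere)
    parcels = surface.parcel_labels(entry.hemisphere)
    P = surface.n_parcels

    if mask.keep.shape[0] != run.n_volumes:
        raise ValueError("mask length must equal run volumes")
    kept = run.signal[:, mask.keep]

    hemi_sig = kept[hemi_verts]
    parcel_mean = np.zeros((P, hemi_sig.shape[1]))
    counts = np.bincount(parcels, minlength=P).astype(float)
    if np.any(counts == 0):
        raise ValueError("hemisphere has empty parcels")
    np.add.at(parcel_mean, parcels, hemi_sig)
    parcel_mean /= counts[:, None]

    v_std, v_zero = _standardize_rows(kept[vertices].astype(float))
    p_std, p_zero = _standardize_rows(parcel_mean)
    if v_zero.any() or p_zero.any():
        logger.warning(
            "zero-variance series in connectome %s: %d vertices, %d parcels "
            "(their correlations set to 0)",
            froi_id, int(v_zero.sum()), int(p_zero.sum()),
        )
    r = (v_std @ p_std.T) / v_std.shape[1]
    r[v_zero, :] = 0.0
    r[:, p_zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return Connectome(
        z=fisher_z(r), vertex_ids=vertices, froi_id=froi_id, threshold_mm=mask.threshold_mm
    )


def build_feature_matrix(connectome: Connectome, surface: SurfaceModel) -> FeatureMatrix:
    """Connectivity columns followed by curvature, thickness, x, y, z.

    No standardization is applied here; model fitting owns that step.
    """
    anat = surface.anatomy(connectome.vertex_ids)
    if anat.isna().any().any():
        raise ValueError("missing anatomy for some vertices")
    P = connectome.z.shape[1]
    columns = tuple(f"parcel_{p:03d}" for p in range(P)) + ANATOMY_COLUMNS
    values = np.hstack([connectome.z, anat.to_numpy(dtype=float)])
    return FeatureMatrix(
        values=values,
        columns=columns,
        vertex_ids=connectome.vertex_ids,
        froi_id=connectome.froi_id,
    )
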