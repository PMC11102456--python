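"""Cohort generator: coupled resting-state and localizer task runs with
known ground truth.

The generative model realizes the working assumption of the analysis —
that a vertex's resting connectivity fingerprint carries its category
selectivity — as an explicit linear coupling:

* each subject has a latent selectivity field ``s_v`` (a Gaussian bump per
  region, displaced per subject by a rigid jitter of the group template);
* resting signal at vertex ``v`` is ``eta_parcel(v) + gamma * s_v *
  (c . eta) + noise`` where the ``eta_p`` are P autocorrelated latent
  parcel series and ``c`` is a cohort-level unit coupling vector per
  region — so the vertex->parcel correlation fingerprint is (to first
  order) linear in ``s_v``;
* task signal embeds ``s_v`` as the amplitude of the preferred condition
  on top of a common response to every condition, so the localizer
  contrast recovers the same field.

Seeds: one master seed; every stream is derived as
``SeedSequence(master, spawn_key=(stream, index))`` so per-subject data do
not depend on cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..froi import top_fraction_size
from .design import BlockDesign, make_block_design
from .registry import CONDITIONS, FROIRegistry, default_registry
from .surface import HEMISPHERES, SurfaceModel, generate_surface

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "RestingRun",
    "TaskRun",
    "Subject",
    "Cohort",
    "generate_resting_run",
    "generate_task_run",
    "generate_cohort",
    "subseed",
]

# stream ids of the seed-derivation scheme
_STREAM_SURFACE = 0
_STREAM_COUPLING = 1
_STREAM_GROUND_TRUTH = 2
_STREAM_REST = 3
_STREAM_TASK = 4  # index = 10 * subject + run


def subseed(master: int, stream: int, index: int = 0) -> np.random.Generator:
    """Derived RNG stream: ``SeedSequence(master, spawn_key=(stream, index))``."""
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=(stream, index)))


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the acquisition being emulated: 40 subjects, one
    ~9.67-min resting run (580 volumes at TR = 1 s) and two 234-volume
    localizer runs of five conditions in 18-s blocks.
    """

    n_subjects: int = 40
    n_vertices: int = 600          # per hemisphere
    n_parcels: int = 179
    searchspace_size: int = 30
    tr: float = 1.0
    rest_duration_min: float = 9.67
    rest_noise_sd: float = 0.5
    task_noise_sd: float = 1.0
    latent_smooth_tr: float = 2.0
    coupling_strength: float = 0.8
    jitter_scale: float = 1.5
    size_jitter_per_unit: float = 0.05
    bump_sigma: float = 2.5
    froi_fraction: float = 0.10
    baseline: float = 100.0
    base_amplitude: float = 0.5
    task_amplitude: float = 2.0
    drift_amplitude: float = 0.5
    fd_spike_prob: float = 0.05
    movement_spike_prob: float = 0.02
    block_duration_s: float = 18.0
    rest_block_s: float = 18.0
    blocks_per_condition: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_vertices", "n_parcels", "searchspace_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rest_noise_sd", "task_noise_sd", "jitter_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.froi_fraction <= 1):
            raise ValueError("froi_fraction must be in (0, 1]")
        if self.tr <= 0 or self.rest_duration_min <= 0:
            raise ValueError("tr and rest duration must be positive")

    @property
    def rest_volumes(self) -> int:
        """Volumes in the resting run (duration floored to whole volumes)."""
        return int(np.floor(self.rest_duration_min * 60.0 / self.tr))

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Known per-subject generative state.

    ``amplitude`` is the latent selectivity field ``s_v`` over all global
    vertices (non-zero only inside search spaces). ``coupling`` is the
    cohort-level map from regions to unit parcel-loading vectors.
    """

    amplitude: np.ndarray                      # (2 * n_vertices,)
    froi_vertices: dict[str, np.ndarray]       # froi_id -> global vertex ids
    coupling: dict[str, np.ndarray]            # froi_id -> (P,) unit vector
    centers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("ground-truth amplitudes must be finite")


@dataclass
class RestingRun:
    signal: np.ndarray   # (vertices, time)
    fd: np.ndarray       # framewise displacement, mm, length = time
    tr: float

    def __post_init__(self) -> None:
        if self.fd.shape[0] != self.signal.shape[1]:
            raise ValueError("FD trace length must equal the number of volumes")
        if np.any(self.fd < 0):
            raise ValueError("FD must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]


@dataclass
class TaskRun:
    signal: np.ndarray       # (vertices, time)
    design: BlockDesign
    motion: np.ndarray       # (6, time) motion-parameter traces
    movement: np.ndarray     # between-TR total vector movement, mm, (time,)

    def __post_init__(self) -> None:
        if self.design.n_volumes != self.signal.shape[1]:
            raise ValueError("design volumes must equal the signal time dimension")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]


@dataclass
class Subject:
    subject_id: str
    ground_truth: GroundTruth
    rest: RestingRun
    task_runs: tuple[TaskRun, ...]


@dataclass
class Cohort:
    config: CohortConfig
    surface: SurfaceModel
    registry: FROIRegistry
    subjects: list[Subject]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _coupling_vectors(registry: FROIRegistry, n_parcels: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for entry in registry:
        # constant-magnitude random-sign loadings: every parcel carries equal
        # coupling energy, so column standardization in downstream models
        # rescales all coupling features identically
        c = np.sign(rng.normal(size=n_parcels))
        c[c == 0] = 1.0
        out[entry.froi_id] = c / np.linalg.norm(c)
    return out


def _make_ground_truth(
    surface: SurfaceModel,
    cfg: CohortConfig,
    coupling: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> GroundTruth:
    amplitude = np.zeros(surface.n_vertices)
    froi_vertices: dict[str, np.ndarray] = {}
    centers: dict[str, np.ndarray] = {}
    tab = surface.table.set_index("vertex")
    for entry in surface.registry:
        verts = surface.search_space_vertices(entry.search_space)
        xy = tab.loc[verts, ["x", "y"]].to_numpy(dtype=float)
        # fixed off-grid template offset: breaks grid-symmetry ties so the
        # ranked amplitude values are generically distinct
        center = xy.mean(axis=0) + np.array([0.17, 0.17]) + cfg.jitter_scale * rng.normal(size=2)
        sigma = cfg.bump_sigma * float(
            np.exp(cfg.jitter_scale * cfg.size_jitter_per_unit * rng.normal())
        )
        d2 = ((xy - center) ** 2).sum(axis=1)
        s = np.exp(-d2 / (2.0 * sigma**2))
        amplitude[verts] = s
        k = top_fraction_size(len(verts), cfg.froi_fraction)
        order = np.lexsort((verts, -s))
        froi_vertices[entry.froi_id] = np.sort(verts[order[:k]])
        centers[entry.froi_id] = center
    return GroundTruth(amplitude=amplitude, froi_vertices=froi_vertices, coupling=coupling, centers=centers)


def _vertex_froi_map(surface: SurfaceModel) -> dict[str, np.ndarray]:
    """froi_id -> search-space vertex ids (global)."""
    return {
        e.froi_id: surface.search_space_vertices(e.search_space)
        for e in surface.registry
    }


def generate_resting_run(
    ground_truth: GroundTruth,
    surface: SurfaceModel,
    cfg: CohortConfig,
    seed: int | np.random.Generator,
) -> RestingRun:
    """Simulate one resting run from the subject's ground truth.

    Per hemisphere: P latent low-pass-filtered Gaussian series ``eta_p``;
    vertex signal = eta of its own parcel + coupling_strength * s_v *
    (c . eta) for vertices inside a search space, plus white noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = cfg.rest_volumes
    if T < 2:
        raise ValueError("resting run must have at least 2 volumes")
    P = surface.n_parcels
    n_total = surface.n_vertices
    signal = np.empty((n_total, T))
    froi_map = _vertex_froi_map(surface)

    for hemi in HEMISPHERES:
        verts = surface.hemi_vertices(hemi)
        parcels = surface.parcel_labels(hemi)
        eta = rng.normal(size=(P, T))
        if cfg.latent_smooth_tr > 0:
            eta = gaussian_filter1d(eta, sigma=cfg.latent_smooth_tr, axis=1)
        eta -= eta.mean(axis=1, keepdims=True)
        eta /= eta.std(axis=1, keepdims=True)

        hemi_sig = eta[parcels].copy()
        if cfg.coupling_strength != 0:
            for entry in surface.registry.by_hemisphere(hemi):
                ss = froi_map[entry.froi_id]
                c = ground_truth.coupling[entry.froi_id]
                shared = c @ eta                      # (T,), unit-variance mixture
                s = ground_truth.amplitude[ss]
                local = np.searchsorted(verts, ss)
                # variance-preserving mixing: coupling loading a = gamma*s is
                # linear in s and the own-parcel loading sqrt(1-a^2) keeps
                # vertex variance at 1, so the correlation fingerprint itself
                # is linear in s (no saturation)
                a = np.clip(cfg.coupling_strength * s, 0.0, 0.95)
                hemi_sig[local] = (
                    np.sqrt(1.0 - a**2)[:, None] * hemi_sig[local]
                    + a[:, None] * shared[None, :]
                )
        if cfg.rest_noise_sd > 0:
            hemi_sig += cfg.rest_noise_sd * rng.normal(size=hemi_sig.shape)
        signal[verts] = hemi_sig

    fd = np.abs(rng.normal(0.0, 0.12, size=T)).clip(max=0.45)
    spikes = rng.random(T) < cfg.fd_spike_prob
    fd[spikes] = 0.55 + rng.exponential(0.3, size=int(spikes.sum()))
    return RestingRun(signal=signal, fd=fd, tr=cfg.tr)


def generate_task_run(
    ground_truth: GroundTruth,
    surface: SurfaceModel,
    design: BlockDesign,
    cfg: CohortConfig,
    seed: int | np.random.Generator,
) -> TaskRun:
    """Simulate one localizer run for the given block design.

    Vertex signal = baseline + sum over conditions of amplitude x
    (boxcar convolved with the HRF, peak-normalized) + linear drift +
    white noise. Every vertex responds ``base_amplitude`` to every
    condition; vertices inside a search space additionally respond
    ``task_amplitude * s_v`` to that region's preferred condition.
    """
    from ..glm import HRFParams, condition_regressors  # late import: avoid cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = design.n_volumes
    n_total = surface.n_vertices
    regs = condition_regressors(design, HRFParams())   # condition -> (T,), peak 1

    amp = np.full((n_total, len(CONDITIONS)), cfg.base_amplitude)
    for entry, ss in _vertex_froi_map(surface).items():
        cond_idx = CONDITIONS.index(surface.registry[entry].preferred_condition)
        amp[ss, cond_idx] += cfg.task_amplitude * ground_truth.amplitude[ss]

    signal = np.full((n_total, T), cfg.baseline)
    for j, cond in enumerate(CONDITIONS):
        signal += amp[:, [j]] * regs[cond][None, :]
    if cfg.drift_amplitude > 0:
        drift = rng.normal(0, cfg.drift_amplitude, size=(n_total, 1))
        signal += drift * np.linspace(-0.5, 0.5, T)[None, :]
    if cfg.task_noise_sd > 0:
        signal += cfg.task_noise_sd * rng.normal(size=signal.shape)

    motion = np.cumsum(rng.normal(0, 0.02, size=(6, T)), axis=1)
    movement = np.abs(rng.normal(0.0, 0.15, size=T)).clip(max=0.9)
    spikes = rng.random(T) < cfg.movement_spike_prob
    movement[spikes] = 1.05 + rng.exponential(0.3, size=int(spikes.sum()))
    return TaskRun(signal=signal, design=design, motion=motion, movement=movement)


def generate_cohort(cfg: CohortConfig, registry: FROIRegistry | None = None) -> Cohort:
    """Generate the full cohort: surface, ground truth and all runs."""
    registry = registry or default_registry()
    surface = generate_surface(
        cfg.n_vertices,
        cfg.n_parcels,
        searchspace_size=cfg.searchspace_size,
        registry=registry,
        seed=subseed(cfg.seed, _STREAM_SURFACE),
    )
    coupling = _coupling_vectors(registry, cfg.n_parcels, subseed(cfg.seed, _STREAM_COUPLING))

    subjects = []
    for i in range(cfg.n_subjects):
        gt = _make_ground_truth(surface, cfg, coupling, subseed(cfg.seed, _STREAM_GROUND_TRUTH, i))
        rest = generate_resting_run(gt, surface, cfg, subseed(cfg.seed, _STREAM_REST, i))
        runs = []
        for run in (1, 2):
            rng = subseed(cfg.seed, _STREAM_TASK, 10 * i + run)
            design = make_block_design(
                block_duration_s=cfg.block_duration_s,
                rest_duration_s=cfg.rest_block_s,
                blocks_per_condition=cfg.blocks_per_condition,
                tr=cfg.tr,
                seed=rng,
            )
            runs.append(generate_task_run(gt, surface, design, cfg, rng))
        subjects.append(Subject(f"sub-{i:03d}", gt, rest, tuple(runs)))
    return Cohort(config=cfg, surface=surface, registry=registry, subjects=subjects)
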