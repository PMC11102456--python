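"""First-level GLM for the localizer task.

Condition regressors are boxcars convolved with a gamma hemodynamic
response function (delay 2.25 s, dispersion 1.25 s, exponent 2 — the
FS-FAST-style parameterization) and peak-normalized so that betas are in
signal units. Nuisance columns: 6 motion traces, one indicator per
high-movement frame, an intercept and a linear drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .synth.design import BlockDesign
from .synth.registry import CONDITIONS

__all__ = [
    "HRFParams",
    "GLMDesign",
    "BetaMap",
    "ContrastSpec",
    "ContrastMap",
    "hrf_kernel",
    "condition_regressor",
    "condition_regressors",
    "flag_motion_frames",
    "build_glm_design",
    "fit_glm",
    "compute_contrast",
    "compute_psc",
    "contrast_for_category",
    "DEFAULT_CONTRASTS",
]

INTERCEPT = "intercept"
DRIFT = "drift"


@dataclass(frozen=True)
class HRFParams:
    """Gamma HRF: h(tau) = ((tau-d)/t)^a * exp(-(tau-d)/t) for tau >= d."""

    delay: float = 2.25       # d, seconds
    dispersion: float = 1.25  # t, seconds
    exponent: float = 2.0     # a

    def __post_init__(self) -> None:
        if self.delay < 0 or self.dispersion <= 0:
            raise ValueError("delay must be >= 0 and dispersion > 0")


def hrf_kernel(params: HRFParams, dt: float, duration: float = 32.0) -> np.ndarray:
    """Sample the gamma HRF on a dt grid, normalized to peak 1.

    The analytic peak sits at ``tau = delay + exponent * dispersion``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < params.delay:
        raise ValueError("duration must cover the kernel delay")
    tau = np.arange(0.0, duration + dt / 2, dt)
    x = (tau - params.delay) / params.dispersion
    h = np.where(x > 0, np.power(np.clip(x, 0, None), params.exponent) * np.exp(-x), 0.0)
    peak = h.max()
    return h / peak if peak > 0 else h


def _fine_boxcar(design: BlockDesign, condition: str, dt: float) -> np.ndarray:
    n_fine = int(round(design.n_volumes * design.tr / dt))
    t = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for b in design.blocks_for(condition):
        box[(t >= b.onset - 1e-9) & (t < b.onset + b.duration - 1e-9)] = 1.0
    return box


def condition_regressor(
    design: BlockDesign,
    condition: str,
    hrf: "HRFParams | np.ndarray",
    *,
    oversample: int = 10,
    normalize: bool = True,
) -> np.ndarray:
    """Boxcar for one condition convolved with the HRF, sampled at the TR.

    ``hrf`` may be an :class:`HRFParams` or an explicit kernel sampled at
    ``dt = tr / oversample`` (e.g. ``[1.0]`` for an identity kernel).
    When ``normalize`` the regressor is scaled to peak 1 so betas read in
    signal units.
    """
    dt = design.tr / oversample
    kernel = hrf_kernel(hrf, dt) if isinstance(hrf, HRFParams) else np.asarray(hrf, float)
    fine = np.convolve(_fine_boxcar(design, condition, dt), kernel)[
        : int(round(design.n_volumes * design.tr / dt))
    ]
    reg = fine[::oversample][: design.n_volumes]
    if normalize and reg.max() > 0:
        reg = reg / reg.max()
    return reg


def condition_regressors(design: BlockDesign, hrf: HRFParams) -> dict[str, np.ndarray]:
    """Peak-normalized regressors for every stimulus condition."""
    return {c: condition_regressor(design, c, hrf) for c in design.conditions}


def flag_motion_frames(movement, threshold_mm: float = 1.0) -> np.ndarray:
    """Frames whose between-TR total vector movement exceeds the threshold
    (strict ``>``)."""
    trace = getattr(movement, "movement", movement)
    return np.flatnonzero(np.asarray(trace, dtype=float) > threshold_mm)


@dataclass
class GLMDesign:
    matrix: np.ndarray             # (volumes, regressors)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("design column count must match names")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def column(self, name: str) -> int:
        return self.names.index(name)


def build_glm_design(
    design: BlockDesign,
    hrf: HRFParams,
    motion: np.ndarray | None = None,
    spike_frames=(),
    *,
    add_drift: bool = True,
) -> GLMDesign:
    """Assemble the GLM design matrix and verify it has full column rank."""
    T = design.n_volumes
    cols = [condition_regressor(design, c, hrf) for c in design.conditions]
    names = list(design.conditions)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[1] != T:
            raise ValueError("motion traces must span the run")
        for i, m in enumerate(motion):
            cols.append(m)
            names.append(f"motion_{i}")
    for f in sorted(int(f) for f in np.asarray(spike_frames, dtype=int).ravel()):
        spike = np.zeros(T)
        spike[f] = 1.0
        cols.append(spike)
        names.append(f"spike_{f:03d}")
    cols.append(np.ones(T))
    names.append(INTERCEPT)
    if add_drift:
        cols.append(np.linspace(-0.5, 0.5, T))
        names.append(DRIFT)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * max(diag.max(), 1)]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad or names}")
    return GLMDesign(matrix=X, names=tuple(names))


@dataclass
class BetaMap:
    """Per-vertex OLS estimates for one run."""

    beta: np.ndarray           # (vertices, regressors)
    names: tuple[str, ...]
    resid_var: np.ndarray      # (vertices,)
    df: int
    xtx_inv: np.ndarray        # (regressors, regressors)
    vertex_ids: np.ndarray     # (vertices,) row labels

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("non-positive residual degrees of freedom")

    def column(self, name: str) -> np.ndarray:
        return self.beta[:, self.names.index(name)]

    def rows_for(self, vertices) -> np.ndarray:
        idx = np.searchsorted(self.vertex_ids, np.asarray(vertices))
        if np.any(self.vertex_ids[idx] != np.asarray(vertices)):
            raise KeyError("vertices not covered by this beta map")
        return idx


def fit_glm(signal, design: GLMDesign, vertex_ids: np.ndarray | None = None) -> BetaMap:
    """Ordinary least squares per vertex.

    ``signal`` is a (vertices, volumes) array or a TaskRun.
    """
    Y = getattr(signal, "signal", signal)
    Y = np.asarray(Y, dtype=float)
    X = design.matrix
    if Y.shape[1] != X.shape[0]:
        raise ValueError("design rows must equal run volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design is rank deficient")
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    resid_var = (resid**2).sum(axis=0) / df
    if vertex_ids is None:
        vertex_ids = np.arange(Y.shape[0])
    return BetaMap(
        beta=beta.T,
        names=design.names,
        resid_var=resid_var,
        df=df,
        xtx_inv=np.linalg.pinv(X.T @ X),
        vertex_ids=np.asarray(vertex_ids),
    )


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    positive: str
    negative: str

    def weights(self, names: tuple[str, ...]) -> np.ndarray:
        c = np.zeros(len(names))
        try:
            c[names.index(self.positive)] = 1.0
            c[names.index(self.negative)] = -1.0
        except ValueError as exc:
            raise ValueError(f"contrast condition missing from design: {exc}") from exc
        return c


DEFAULT_CONTRASTS = {
    "face": ContrastSpec("faces>objects", "faces", "objects"),
    "body": ContrastSpec("bodies>objects", "bodies", "objects"),
    "scene": ContrastSpec("scenes>objects", "scenes", "objects"),
    "object": ContrastSpec("objects>scrambled", "objects", "scrambled"),
}


def contrast_for_category(category: str) -> ContrastSpec:
    return DEFAULT_CONTRASTS[category]


@dataclass
class ContrastMap:
    """Per-vertex contrast effect (beta difference) and t statistic."""

    effect: np.ndarray
    t: np.ndarray
    name: str
    vertex_ids: np.ndarray
    df: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.effect)):
            raise ValueError("contrast effects must be finite")

    def effect_for(self, vertices) -> np.ndarray:
        idx = np.searchsorted(self.vertex_ids, np.asarray(vertices))
        if np.any(self.vertex_ids[idx] != np.asarray(vertices)):
            raise KeyError("vertices not covered by this contrast map")
        return self.effect[idx]


def compute_contrast(betamap: BetaMap, spec: ContrastSpec) -> ContrastMap:
    """Effect = c'beta; t = effect / sqrt(resid_var * c'(X'X)^-1 c)."""
    c = spec.weights(betamap.names)
    effect = betamap.beta @ c
    var_scale = float(c @ betamap.xtx_inv @ c)
    se = np.sqrt(betamap.resid_var * var_scale)
    # se at float-noise level means an exact fit: report t = 0, not 0/0 noise
    t = np.divide(effect, se, out=np.zeros_like(effect), where=se > 1e-12)
    return ContrastMap(
        effect=effect, t=t, name=spec.name, vertex_ids=betamap.vertex_ids, df=betamap.df
    )


def compute_psc(betamap: BetaMap, vertices, condition: str) -> float:
    """Percent signal change: 100 * mean(beta_condition / beta_intercept)
    over the vertex set. The intercept beta is the baseline."""
    idx = betamap.rows_for(vertices)
    if idx.size == 0:
        raise ValueError("empty vertex set")
    baseline = betamap.column(INTERCEPT)[idx]
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline beta in PSC computation")
    return float(np.mean(100.0 * betamap.column(condition)[idx] / baseline))
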