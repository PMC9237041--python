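"""Running (neighborhood) standard deviation over a component space.

The estimator behind the variance maps: for every respondent, take the k
nearest neighbors (Euclidean distance) in a low-dimensional object-score
subspace — a "socioeconomic neighborhood" of people with similar covariate
profiles — and compute the sample SD of fasting glycemia within it.  Regions
of the socioeconomic space where this local SD is elevated are candidate
decanalized groups, even when the local mean is unremarkable.

k-nearest-neighbor windows (rather than fixed-radius balls) keep the
neighborhood sample size, and hence the precision of each local SD, constant
across dense and sparse regions of the score cloud.  Distance ties are broken
by ascending row index; the exact brute-force search implements that rule
directly and is used automatically for small inputs, while a k-d tree serves
large continuous-score inputs where exact ties have probability zero.

Inference on a variance gradient uses a permutation null that re-assigns the
glycemia values to positions and recomputes the whole running-SD field on the
fixed neighborhoods: running SDs of overlapping windows are strongly
autocorrelated, so naive independence-based p-values for the rank correlation
would be wildly anticonservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import ConfigError, InputError

__all__ = [
    "RunningSDConfig",
    "RunningSDResult",
    "default_k",
    "running_sd",
    "variance_gradient_test",
    "GradientTestResult",
    "smooth_surface",
    "SmoothSurface",
]

_BRUTE_MAX_N = 2048


def default_k(n: int) -> int:
    """Default neighborhood size: max(50, ceil(0.05 n))."""
    return max(50, int(np.ceil(0.05 * n)))


@dataclass(frozen=True)
class RunningSDConfig:
    k: int | None = None               # None -> default_k(n)
    include_self: bool = True
    center_correct: bool = False       # two-pass running-mean correction
    method: str = "auto"               # auto | brute | tree

    def validate(self) -> None:
        if self.method not in ("auto", "brute", "tree"):
            raise ConfigError("method: must be auto, brute or tree")
        if self.k is not None:
            kmin = 2 if self.include_self else 1
            if self.k < kmin:
                raise ConfigError(f"k: must be >= {kmin}")


@dataclass
class RunningSDResult:
    sd: np.ndarray                 # per-observation running SD (mg/dL)
    mean: np.ndarray               # per-observation running mean (mg/dL)
    neighbors: np.ndarray          # n x k neighbor row indices
    values: np.ndarray             # the response values used
    k: int
    include_self: bool
    center_correct: bool
    sd_first_pass: np.ndarray | None = None  # uncentered SD when center_correct


def _neighbor_indices(scores: np.ndarray, k: int, include_self: bool, method: str) -> np.ndarray:
    n = scores.shape[0]
    if method == "auto":
        method = "brute" if n <= _BRUTE_MAX_N else "tree"
    if method == "brute":
        from scipy.spatial.distance import cdist

        out = np.empty((n, k), dtype=np.intp)
        chunk = max(1, int(2**22 // max(n, 1)))
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            d = cdist(scores[start:stop], scores)
            if not include_self:
                d[np.arange(stop - start), np.arange(start, stop)] = np.inf
            # stable sort => ties broken by ascending row index
            out[start:stop] = np.argsort(d, axis=1, kind="stable")[:, :k]
        return out
    tree = cKDTree(scores)
    kk = k + (0 if include_self else 1)
    _, idx = tree.query(scores, k=kk)
    idx = np.atleast_2d(idx)
    if not include_self:
        self_col = idx == np.arange(n)[:, None]
        # drop self; if self not returned (duplicate points), drop the last
        keep = np.empty((n, k), dtype=np.intp)
        for i in range(n):
            row = idx[i][~self_col[i]]
            keep[i] = row[:k]
        return keep
    return idx.astype(np.intp)


def _sd_from_neighbors(values: np.ndarray, nbrs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = values[nbrs]
    return v.std(axis=1, ddof=1), v.mean(axis=1)


def running_sd(scores, values, config: RunningSDConfig | None = None) -> RunningSDResult:
    """Per-observation neighborhood SD (n-1 denominator) of ``values`` over
    the Euclidean score subspace."""
    if config is None:
        config = RunningSDConfig()
    config.validate()
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]  # 1-D coordinate vector
    values = np.asarray(values, dtype=float)
    n = scores.shape[0]
    if values.shape[0] != n:
        raise InputError("running_sd: scores and values length mismatch")
    if not (np.isfinite(scores).all() and np.isfinite(values).all()):
        raise InputError("running_sd: missing/non-finite values present")
    k = config.k if config.k is not None else default_k(n)
    if n < k:
        raise InputError(f"running_sd: n = {n} < k = {k}")
    if np.allclose(scores.std(axis=0), 0):
        warnings.warn("running_sd: zero-variance subspace; all neighborhoods identical",
                      stacklevel=2)
    nbrs = _neighbor_indices(scores, k, config.include_self, config.method)
    sd, mean = _sd_from_neighbors(values, nbrs)
    first = None
    if config.center_correct:
        first = sd
        centered = values - mean
        sd, _ = _sd_from_neighbors(centered, nbrs)
    return RunningSDResult(
        sd=sd, mean=mean, neighbors=nbrs, values=values, k=k,
        include_self=config.include_self, center_correct=config.center_correct,
        sd_first_pass=first,
    )


@dataclass(frozen=True)
class GradientTestResult:
    rho: float          # Spearman correlation of running SD with the axis
    p_value: float      # two-sided permutation p, (1 + exceedances)/(B + 1)
    n_permutations: int


def variance_gradient_test(result: RunningSDResult, axis, *, B: int = 199,
                           seed: int | None = None) -> GradientTestResult:
    """Spearman correlation between the running SD and a covariate axis, with
    a permutation p-value that re-assigns values to positions and recomputes
    the running-SD field over the fixed neighborhoods."""
    axis = np.asarray(axis, dtype=float)
    n = result.sd.shape[0]
    if axis.shape[0] != n:
        raise InputError("variance_gradient_test: axis length mismatch")
    if np.ptp(axis) == 0:
        raise InputError("variance_gradient_test: axis is constant")
    if B < 1:
        raise InputError("variance_gradient_test: B must be >= 1")
    k = result.neighbors.shape[1]
    axis_rank = rankdata(axis)
    ar = axis_rank - axis_rank.mean()
    ar_den = np.sqrt((ar * ar).sum())

    def rho_of(sd: np.ndarray) -> float:
        r = rankdata(sd)
        r = r - r.mean()
        den = np.sqrt((r * r).sum()) * ar_den
        return float((r * ar).sum() / den) if den > 0 else 0.0

    obs = rho_of(result.sd)
    # neighborhood membership matrix for fast SD recomputation under permutation
    rows = np.repeat(np.arange(n), k)
    M = sparse.csr_matrix((np.ones(n * k), (rows, result.neighbors.ravel())), shape=(n, n))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        vp = rng.permutation(result.values)
        s1 = M @ vp
        s2 = M @ (vp * vp)
        var = (s2 - s1 * s1 / k) / (k - 1)
        sd_perm = np.sqrt(np.maximum(var, 0.0))
        if abs(rho_of(sd_perm)) >= abs(obs) - 1e-12:
            exceed += 1
    return GradientTestResult(rho=obs, p_value=(1 + exceed) / (B + 1), n_permutations=B)


@dataclass
class SmoothSurface:
    grid_x: np.ndarray      # len rx
    grid_y: np.ndarray      # len ry
    z: np.ndarray           # ry x rx smoothed values
    bandwidth: tuple[float, float]


def smooth_surface(scores, values, resolution: tuple[int, int] = (40, 40),
                   bandwidth: tuple[float, float] | None = None) -> SmoothSurface:
    """Local-linear (LOESS-like, Gaussian-weighted) smooth of a scalar field
    over a 2-D score plane, evaluated on a rectangular grid.  Display aid
    only — no inference attached.  Local-linear fitting reproduces planar
    fields exactly, whatever the bandwidth."""
    scores = np.asarray(scores, dtype=float)
    values = np.asarray(values, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise InputError("smooth_surface: scores must be n x 2")
    if scores.shape[0] != values.shape[0]:
        raise InputError("smooth_surface: scores and values length mismatch")
    x, y = scores[:, 0], scores[:, 1]
    rx, ry = int(resolution[0]), int(resolution[1])
    gx = np.linspace(x.min(), x.max(), rx)
    gy = np.linspace(y.min(), y.max(), ry)
    degenerate = np.linalg.matrix_rank(np.cov(scores.T)) < 2 if scores.shape[0] > 2 else True
    if bandwidth is None:
        bandwidth = (max((x.max() - x.min()) / 8, 1e-9), max((y.max() - y.min()) / 8, 1e-9))
    hx, hy = bandwidth
    if degenerate:
        warnings.warn("smooth_surface: collinear scores; returning a 1-D smooth along x",
                      stacklevel=2)
    z = np.empty((ry, rx))
    design = np.column_stack([np.ones_like(x), x, y])
    for iy, cy in enumerate(gy):
        for ix, cx in enumerate(gx):
            w = np.exp(-0.5 * (((x - cx) / hx) ** 2 + ((y - cy) / hy) ** 2))
            w_sum = w.sum()
            if w_sum < 1e-12:
                z[iy, ix] = np.nan
                continue
            if degenerate:
                wx = np.column_stack([np.ones_like(x), x])
                coef, *_ = np.linalg.lstsq(wx * w[:, None] ** 0.5,
                                           values * w ** 0.5, rcond=None)
                z[iy, ix] = coef[0] + coef[1] * cx
                continue
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(design * sw[:, None], values * sw, rcond=None)
            z[iy, ix] = coef[0] + coef[1] * cx + coef[2] * cy
    return SmoothSurface(grid_x=gx, grid_y=gy, z=z, bandwidth=(float(hx), float(hy)))
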