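"""Optimal-scaling (PRINCALS-style) principal component analysis.

Classical PCA assumes interval-scaled variables; survey covariates are mostly
ordered categories (education levels, income bands, salt-adding frequency...).
Optimal scaling replaces each category with a numeric *quantification*,
chosen — simultaneously with the component solution — to maximize the
variance the components account for, subject to a monotonicity constraint for
ordinal variables.  The result is a joint embedding: per-respondent *object
scores* ``X`` (n x p, columns centered with variance 1), per-variable
*loadings* (correlations between the quantified variable and each component)
and per-variable category quantifications.

The fit is alternating least squares on the single-rank Gifi loss

    L(X, q, a) = (1/(n*m)) * sum_j || X - t_j a_j' ||_F^2,
    t_j = q_j[codes_j],  q_j' D_j q_j = n,

where ``D_j`` holds category counts.  Each sweep updates, per variable, the
category centroids of the object scores, projects them onto the variable's
scaling cone (weighted isotonic regression via pooled adjacent violators for
ordinal variables, unrestricted for nominal, fixed standardized raw values
for numeric) and re-estimates the loading; the object scores are then the
orthogonal-Procrustes optimum, so the loss is non-increasing by construction.
With every variable declared numeric the procedure converges to classical PCA
of the standardized data.

Component signs follow a fixed convention (largest-magnitude loading entry of
each component is positive) so fits are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigError, InputError

__all__ = [
    "OrdinalPCAConfig",
    "OrdinalPCAResult",
    "fit",
    "scores_subspace",
    "variance_accounted",
]

_EPS = 1e-12


@dataclass(frozen=True)
class OrdinalPCAConfig:
    """Fit settings.

    ``scaling`` maps variable name -> "ordinal" | "nominal" | "numeric";
    unlisted variables use ``default_scaling``.
    """

    n_components: int = 8
    scaling: dict = field(default_factory=dict)
    default_scaling: str = "ordinal"
    max_iterations: int = 200
    tol: float = 1e-6
    seed: int | None = None  # reserved for randomized initialization variants

    def validate(self, n_vars: int) -> None:
        if self.n_components < 1 or self.n_components > n_vars:
            raise ConfigError("n_components: must lie in 1..number of variables")
        if self.tol <= 0:
            raise ConfigError("tol: must be > 0")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations: must be >= 1")
        for lvl in (self.default_scaling, *self.scaling.values()):
            if lvl not in ("ordinal", "nominal", "numeric"):
                raise ConfigError(f"scaling: unknown scaling level {lvl!r}")


@dataclass
class OrdinalPCAResult:
    object_scores: pd.DataFrame        # n x p, columns PC1..PCp
    loadings: pd.DataFrame             # m x p, rows = variables
    quantifications: dict              # name -> (categories array, quantification array)
    vaf: np.ndarray                    # per-component fraction of total variance
    loss_path: np.ndarray
    converged: bool
    n_iterations: int
    scaling: dict                      # name -> level actually used


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s < _EPS:
        raise InputError("constant column")
    return (x - x.mean()) / s


def _weighted_isotonic(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(np.arange(y.size), y, sample_weight=w)


def fit(table: pd.DataFrame, config: OrdinalPCAConfig | None = None) -> OrdinalPCAResult:
    """Fit the optimal-scaling PCA to a complete-case table of explanatory
    variables (ordinal columns as category codes, numeric columns as floats)."""
    if config is None:
        config = OrdinalPCAConfig()
    if table.isna().any().any():
        raise InputError("ordinal_pca.fit: missing values present; filter first")
    names = list(table.columns)
    m = len(names)
    config.validate(m)
    n = len(table)
    p = config.n_components
    if n <= p:
        raise InputError("ordinal_pca.fit: need more rows than components")

    scaling = {name: config.scaling.get(name, config.default_scaling) for name in names}

    codes: list[np.ndarray | None] = []
    cats: list[np.ndarray | None] = []
    counts: list[np.ndarray | None] = []
    T = np.empty((n, m))
    quant: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, name in enumerate(names):
        col = table[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise InputError(f"ordinal_pca.fit: variable {name!r} is constant")
        if scaling[name] == "numeric":
            codes.append(None)
            cats.append(None)
            counts.append(None)
            T[:, j] = _standardize(col)
        else:
            c, inv = np.unique(col, return_inverse=True)
            if c.size < 2:
                raise InputError(f"ordinal_pca.fit: variable {name!r} has < 2 categories")
            codes.append(inv)
            cats.append(c)
            counts.append(np.bincount(inv, minlength=c.size).astype(float))
            T[:, j] = _standardize(col)  # integer-coded start
    # initial quantifications: standardized category values (linear start)
    qlist: list[np.ndarray | None] = []
    for j, name in enumerate(names):
        if cats[j] is None:
            qlist.append(None)
        else:
            col = table[name].to_numpy(dtype=float)
            qlist.append((cats[j] - col.mean()) / col.std())

    # init object scores from classical PCA of the integer-coded standardized data
    U, s, Vt = np.linalg.svd(T / np.sqrt(n), full_matrices=False)
    # deterministic signs at init (largest |entry| of each right-singular vector positive)
    for d in range(min(p, Vt.shape[0])):
        k = np.argmax(np.abs(Vt[d]))
        if Vt[d, k] < 0:
            U[:, d] = -U[:, d]
    X = np.sqrt(n) * U[:, :p]
    A = T.T @ X / n

    def loss_value() -> float:
        # (1/(n m)) sum_j ||X - t_j a_j'||^2 with ||t_j||^2 = n, ||X||^2 = n p
        cross = np.einsum("jd,jd->", A, T.T @ X / n)
        return p - (2.0 * cross - float((A * A).sum())) / m

    loss_path = [loss_value()]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # --- quantification + loading sweep
        for j, name in enumerate(names):
            if scaling[name] == "numeric":
                A[j] = T[:, j] @ X / n
                continue
            inv, D = codes[j], counts[j]
            K = D.size
            # category centroids of the object scores (K x p)
            Yhat = np.zeros((K, p))
            np.add.at(Yhat, inv, X)
            Yhat /= D[:, None]
            a = A[j]
            na2 = float(a @ a)
            if na2 < _EPS:
                continue  # direction lost; skip to keep the loss monotone
            qt = Yhat @ a / na2
            if scaling[name] == "ordinal":
                q = _weighted_isotonic(qt, D)
            else:
                q = qt
            nq = float(q @ (D * q))
            if nq < _EPS:
                continue  # degenerate projection; keep previous quantification
            q = q * np.sqrt(n / nq)
            qlist[j] = q
            t = q[inv]
            T[:, j] = t
            A[j] = t @ X / n
        # --- object-score step: orthogonal Procrustes on Z = T A / m
        Z = T @ A
        Z -= Z.mean(axis=0)
        Uz, sz, Vtz = np.linalg.svd(Z, full_matrices=False)
        X = np.sqrt(n) * Uz @ Vtz
        A = T.T @ X / n
        loss_path.append(loss_value())
        prev, cur = loss_path[-2], loss_path[-1]
        if prev - cur < config.tol * max(abs(prev), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn("ordinal_pca.fit: maximum iterations reached without convergence",
                      stacklevel=2)

    # fixed sign convention on the final solution
    for d in range(p):
        k = int(np.argmax(np.abs(A[:, d])))
        if A[k, d] < 0:
            A[:, d] = -A[:, d]
            X[:, d] = -X[:, d]

    for j, name in enumerate(names):
        if scaling[name] == "numeric":
            col = table[name].to_numpy(dtype=float)
            c = np.unique(col)
            quant[name] = (c, (c - col.mean()) / col.std())
        else:
            quant[name] = (cats[j], qlist[j])

    vaf = (A * A).sum(axis=0) / m
    comp_names = [f"PC{d + 1}" for d in range(p)]
    return OrdinalPCAResult(
        object_scores=pd.DataFrame(X, columns=comp_names, index=table.index),
        loadings=pd.DataFrame(A, index=names, columns=comp_names),
        quantifications=quant,
        vaf=vaf,
        loss_path=np.asarray(loss_path),
        converged=converged,
        n_iterations=it,
        scaling=scaling,
    )


def scores_subspace(result: OrdinalPCAResult, components) -> np.ndarray:
    """Select object-score columns by 1-based component index (order kept)."""
    comps = list(components)
    p = result.object_scores.shape[1]
    if len(set(comps)) != len(comps):
        raise InputError("scores_subspace: duplicate component index")
    for c in comps:
        if not 1 <= int(c) <= p:
            raise InputError(f"scores_subspace: component {c} outside 1..{p}")
    return result.object_scores.to_numpy()[:, [int(c) - 1 for c in comps]]


def variance_accounted(result: OrdinalPCAResult) -> pd.DataFrame:
    """Per-component and cumulative fractions of total variance accounted."""
    vaf = np.asarray(result.vaf, dtype=float)
    return pd.DataFrame({
        "component": np.arange(1, vaf.size + 1),
        "vaf": vaf,
        "cumulative": np.cumsum(vaf),
    })
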