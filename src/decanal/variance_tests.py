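"""Group-level permutation inference in the component space.

* :func:`permanova` — permutational multivariate ANOVA: partitions the sum of
  squared interpoint Euclidean distances into between- and within-group parts
  and refers the pseudo-F to a label-permutation null.
* :func:`dispersion_test` — multivariate homogeneity of dispersion (the
  equal-spread assumption behind PERMANOVA): ANOVA F on distances to group
  centroids, permutation p.
* :func:`pairwise_permanova` — all group pairs, Bonferroni-adjusted.
* :func:`g_test` — log-likelihood-ratio test of independence for contingency
  tables, with signed per-cell contributions for decomposition plots.
* :func:`build_contingency` — income x education rows vs residual-category
  columns from a derived table.

Permutation p-values use the (1 + exceedances) / (1 + B) estimator, so they
are strictly positive and valid at any B.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import InputError

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "GTestResult",
    "permanova",
    "pairwise_permanova",
    "dispersion_test",
    "g_test",
    "build_contingency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class DispersionResult:
    f_stat: float
    group_mean_distance: dict
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    contributions: pd.DataFrame        # per-cell 2*O*ln(O/E); sums to G
    pearson_residuals: pd.DataFrame    # (O - E) / sqrt(E), alternative display


def _as_groups(groups, n: int) -> tuple[np.ndarray, list]:
    g = pd.Categorical(np.asarray(groups))
    if len(g) != n:
        raise InputError("groups length does not match the data")
    labels = list(g.categories)
    codes = np.asarray(g.codes)
    if (codes < 0).any():
        raise InputError("groups contain missing labels")
    counts = np.bincount(codes, minlength=len(labels))
    if len(labels) < 2:
        raise InputError("need >= 2 groups")
    if (counts < 2).any():
        small = [labels[i] for i in np.where(counts < 2)[0]]
        raise InputError(f"singleton group(s): {small}")
    return codes, labels


def _is_distance_matrix(x: np.ndarray) -> bool:
    return (x.ndim == 2 and x.shape[0] == x.shape[1]
            and np.allclose(np.diag(x), 0) and np.allclose(x, x.T))


def _ss_from_scores(x: np.ndarray, codes: np.ndarray, g: int) -> tuple[float, float]:
    """Euclidean SS_total / SS_within via the centroid identity."""
    n = x.shape[0]
    total_sq = float((x * x).sum())
    grand = x.sum(axis=0)
    ss_total = total_sq - float(grand @ grand) / n
    counts = np.bincount(codes, minlength=g).astype(float)
    sums = np.zeros((g, x.shape[1]))
    np.add.at(sums, codes, x)
    ss_within = total_sq - float(((sums * sums).sum(axis=1) / counts).sum())
    return ss_total, ss_within


def _ss_from_distances(d2: np.ndarray, codes: np.ndarray, g: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    counts = np.bincount(codes, minlength=g).astype(float)
    u = np.zeros((n, g))
    u[np.arange(n), codes] = 1.0
    within = np.einsum("ig,ij,jg->g", u, d2, u) / 2.0
    ss_within = float((within / counts).sum())
    return float(ss_total), ss_within


def permanova(data, groups, B: int = 999, seed: int | None = None) -> PermanovaResult:
    """PERMANOVA on an n x p score matrix or an n x n Euclidean distance matrix.

    SS_total = (1/n) * sum_{i<j} d_ij^2; SS_within sums (1/n_g) * within-group
    squared distances; pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g));
    p = (1 + #{F_perm >= F_obs}) / (B + 1) over unrestricted label permutations.
    """
    if B < 1:
        raise InputError("permanova: B must be >= 1")
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    codes, labels = _as_groups(groups, n)
    g = len(labels)
    use_dist = _is_distance_matrix(x)
    d2 = x * x if use_dist else None

    def ss(codes_: np.ndarray) -> tuple[float, float]:
        if use_dist:
            return _ss_from_distances(d2, codes_, g)
        return _ss_from_scores(x, codes_, g)

    ss_total, ss_within = ss(codes)
    ss_between = ss_total - ss_within
    dfb, dfw = g - 1, n - g

    def f_of(ssw: float) -> float:
        if ssw <= 0:
            return np.inf if ss_total > ssw else 0.0
        return ((ss_total - ssw) / dfb) / (ssw / dfw)

    f_obs = f_of(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(codes)
        _, ssw_p = ss(perm)
        if f_of(ssw_p) >= f_obs - 1e-12:
            exceed += 1
    return PermanovaResult(
        pseudo_f=float(f_obs), df_between=dfb, df_within=dfw,
        ss_between=float(ss_between), ss_within=float(ss_within),
        ss_total=float(ss_total), p_value=(1 + exceed) / (B + 1),
        n_permutations=B, seed=seed,
    )


def pairwise_permanova(data, groups, B: int = 999, seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every group pair; Bonferroni adjustment over all pairs."""
    x = np.asarray(data, dtype=float)
    codes, labels = _as_groups(groups, x.shape[0])
    use_dist = _is_distance_matrix(x)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    m = len(pairs)
    seeds = np.random.SeedSequence(seed).spawn(m)
    rows = []
    for (i, j), child in zip(pairs, seeds):
        mask = (codes == i) | (codes == j)
        sub = x[np.ix_(mask, mask)] if use_dist else x[mask]
        res = permanova(sub, codes[mask], B=B,
                        seed=int(child.generate_state(1)[0] % (2**31)))
        rows.append({
            "group_a": labels[i], "group_b": labels[j],
            "pseudo_f": res.pseudo_f, "p_value": res.p_value,
            "p_bonferroni": min(1.0, m * res.p_value),
        })
    return pd.DataFrame(rows)


def dispersion_test(data, groups, B: int = 999, seed: int | None = None) -> DispersionResult:
    """Multivariate homogeneity-of-dispersion check (betadisper-style).

    Distances of observations to their group centroid are compared across
    groups by a one-way ANOVA F; the permutation p relabels observations and
    recomputes centroids, distances and F.  Distance-matrix input is embedded
    first by classical scaling (Gower double-centering).
    """
    if B < 1:
        raise InputError("dispersion_test: B must be >= 1")
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    codes, labels = _as_groups(groups, n)
    g = len(labels)
    if _is_distance_matrix(x):
        d2 = x * x
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        keep = w > 1e-10 * max(w.max(), 1.0)
        x = v[:, keep] * np.sqrt(w[keep])

    def f_of(codes_: np.ndarray) -> tuple[float, np.ndarray]:
        counts = np.bincount(codes_, minlength=g).astype(float)
        sums = np.zeros((g, x.shape[1]))
        np.add.at(sums, codes_, x)
        cent = sums / counts[:, None]
        z = np.linalg.norm(x - cent[codes_], axis=1)
        means = np.zeros(g)
        np.add.at(means, codes_, z)
        means /= counts
        ssb = float((counts * (means - z.mean()) ** 2).sum())
        ssw = float(((z - means[codes_]) ** 2).sum())
        if ssw <= 0:
            return (np.inf if ssb > 0 else 0.0), means
        return (ssb / (g - 1)) / (ssw / (n - g)), means

    f_obs, means = f_of(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        if f_of(rng.permutation(codes))[0] >= f_obs - 1e-12:
            exceed += 1
    return DispersionResult(
        f_stat=float(f_obs),
        group_mean_distance={lab: float(m) for lab, m in zip(labels, means)},
        p_value=(1 + exceed) / (B + 1), n_permutations=B, seed=seed,
    )


def g_test(observed) -> GTestResult:
    """Log-likelihood-ratio (G) test of independence.

    G = 2 * sum_{O_ij > 0} O_ij * ln(O_ij / E_ij), chi-square reference with
    (r-1)(c-1) df; zero observed cells contribute 0 (x ln x -> 0 limit).  No
    continuity or Williams correction.
    """
    if isinstance(observed, pd.DataFrame):
        obs_df = observed.astype(float)
    else:
        obs_df = pd.DataFrame(np.asarray(observed, dtype=float))
    o = obs_df.to_numpy()
    if o.ndim != 2 or o.shape[0] < 2 or o.shape[1] < 2:
        raise InputError("g_test: need a table with >= 2 rows and >= 2 columns")
    if (o < 0).any() or not np.allclose(o, np.round(o)):
        raise InputError("g_test: counts must be non-negative integers")
    if (o.sum(axis=1) == 0).any() or (o.sum(axis=0) == 0).any():
        raise InputError("g_test: all-zero row or column margin")
    ntot = o.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / ntot
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(o > 0, 2.0 * o * np.log(np.where(o > 0, o, 1.0) / e), 0.0)
    gstat = float(contrib.sum())
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    p = float(chi2.sf(gstat, df))
    pearson = (o - e) / np.sqrt(e)
    wrap = lambda a: pd.DataFrame(a, index=obs_df.index, columns=obs_df.columns)
    return GTestResult(g=gstat, df=df, p_value=p, observed=obs_df,
                       expected=wrap(e), contributions=wrap(contrib),
                       pearson_residuals=wrap(pearson))


def build_contingency(table: pd.DataFrame,
                      row_cols: tuple[str, ...] = ("income_category", "edu_interviewee"),
                      col: str = "residual_category") -> pd.DataFrame:
    """Counts of the column categories per combined row grouping.

    Row labels join the grouping values with '-'; empty (all-zero) rows or
    columns are dropped with a log entry, mirroring sparse survey cells.
    """
    for c in (*row_cols, col):
        if c not in table.columns:
            raise InputError(f"build_contingency: column {c!r} not in table")
    key = table[list(row_cols)].astype(str).agg("-".join, axis=1)
    ct = pd.crosstab(key, table[col], dropna=True)
    empty_rows = ct.index[ct.sum(axis=1) == 0]
    empty_cols = ct.columns[ct.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        logger.info("build_contingency: dropping empty rows %s / columns %s",
                    list(empty_rows), list(empty_cols))
    ct = ct.drop(index=empty_rows, columns=empty_cols)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise InputError("build_contingency: fewer than 2 non-empty rows or columns")
    return ct
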