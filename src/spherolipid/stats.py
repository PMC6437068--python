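"""Statistical layer: preprocessing, univariate tests, PCA, PLS-DA, GSEA.

Conventions
-----------
Matrices are samples x features (rows are biological samples).  The
standard preprocessing chain for multivariate analysis is quantile
normalization across samples, log2 transform with a half-minimum
pseudocount, and pareto scaling (mean-center, divide by the square root
of the feature standard deviation).

PLS-DA is PLS1 via NIPALS on a centered 0/1 class code; VIP scores are
reported for the fitted components and cross-validated Q2 uses stratified
leave-one-out by default.  The gene-set enrichment score is the signed
extremum of the weighted Kolmogorov-Smirnov running sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DesignedMatrix",
    "PlsdaModel",
    "TestResult",
    "InsufficientData",
    "quantile_normalize",
    "log_transform",
    "pareto_scale",
    "preprocess",
    "bh_qvalues",
    "ttest_bh",
    "pca",
    "plsda_fit",
    "plsda_predict",
    "vip",
    "q2_cv",
    "optimal_components",
    "gsea_es",
]


class InsufficientData(ValueError):
    """Too few samples (or a single-class fold) for the requested fit."""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(x: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Force every sample (row) onto the mean quantile vector.

    After normalization all per-sample value distributions are identical:
    each sample's sorted values equal the across-sample mean of sorted
    values; ties within a sample receive the average of the reference
    values they span.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientData("quantile normalization needs >=2 samples")
    order = np.sort(arr, axis=1)
    reference = order.mean(axis=0)
    p = arr.shape[1]
    out = np.empty_like(arr)
    positions = np.arange(1, p + 1, dtype=float)
    for i in range(arr.shape[0]):
        ranks = sps.rankdata(arr[i], method="average")
        out[i] = np.interp(ranks, positions, reference)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def log_transform(
    x: np.ndarray | pd.DataFrame,
    base: float = 2.0,
    pseudocount: float | None = None,
) -> np.ndarray | pd.DataFrame:
    """log(x + c).  The default pseudocount c is half the smallest nonzero
    value of the matrix, so zeros map below every observed value without
    distorting the bulk."""
    arr = np.asarray(x, dtype=float)
    if pseudocount is None:
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero matrix cannot be log-transformed")
        pseudocount = float(nonzero.min()) / 2.0
    out = np.log(arr + pseudocount) / np.log(base)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def pareto_scale(x: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Pareto scaling per feature (column): (x - mean) / sqrt(sd).

    Constant features are centered only (all zeros), avoiding the 0/0.
    """
    arr = np.asarray(x, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    scale = np.sqrt(sd, out=np.ones_like(sd), where=sd > 0)
    scale[sd == 0] = 1.0
    out = (arr - mean) / scale
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


@dataclass
class DesignedMatrix:
    """Preprocessed samples x features matrix with its two-group design."""

    matrix: pd.DataFrame
    groups: pd.Series
    transforms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.groups.index):
            raise ValueError("matrix rows and group labels must share an index")
        counts = self.groups.value_counts()
        if len(counts) != 2 or (counts < 2).any():
            raise InsufficientData("need exactly two groups with >=2 samples each")
        if np.isnan(self.matrix.to_numpy()).any():
            raise ValueError("matrix contains missing values")


def preprocess(
    matrix: pd.DataFrame,
    groups: pd.Series,
    steps: Sequence[str] = ("quantile", "log", "pareto"),
    log_base: float = 2.0,
    pseudocount: float | None = None,
) -> DesignedMatrix:
    """Apply the named transforms in order and record the provenance."""
    out = matrix
    applied = []
    for step in steps:
        if step == "quantile":
            out = quantile_normalize(out)
        elif step == "log":
            out = log_transform(out, base=log_base, pseudocount=pseudocount)
        elif step == "pareto":
            out = pareto_scale(out)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
        applied.append(step)
    return DesignedMatrix(matrix=out, groups=groups, transforms=tuple(applied))


# ---------------------------------------------------------------------------
# univariate testing
# ---------------------------------------------------------------------------

def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (exact, no estimation
    of the null proportion)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class TestResult:
    """Per-feature two-group test statistics with BH adjustment."""

    table: pd.DataFrame  # columns: t, p, q, significant, zero_variance
    alpha: float
    fdr: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def ttest_bh(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    fdr: float = 0.10,
    equal_var: bool = True,
) -> TestResult:
    """Per-feature Student's two-tailed t-test with BH q-values.

    Pooled-variance Student's t by default (``equal_var=False`` switches
    to Welch).  Features with zero pooled variance get t = 0, p = 1 and a
    ``zero_variance`` flag.  Significance is gated on p < ``alpha`` and
    q < ``fdr`` jointly.
    """
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise InsufficientData("t-test needs exactly two groups")
    a = matrix.loc[groups[groups == levels[0]].index].to_numpy(dtype=float)
    b = matrix.loc[groups[groups == levels[1]].index].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientData("each group needs >=2 samples")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    zero_var = ~np.isfinite(t)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "significant": (p < alpha) & (q < fdr),
            "zero_variance": zero_var,
        },
        index=matrix.columns,
    )
    return TestResult(table=table, alpha=alpha, fdr=fdr)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: pd.DataFrame, n_components: int = 2):
    """PCA by SVD of the column-centered matrix.

    Returns (scores, loadings, explained_variance_ratio).  Sign convention:
    within each component the largest-magnitude loading is positive.
    """
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(f"rank {rank} < requested {n_components} components; truncating")
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    signs[signs == 0] = 1.0
    scores = u[:, :k] * s[:k] * signs
    loadings = (vt[:k].T) * signs
    evr = (s**2) / np.sum(s**2)
    scores_df = pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    loadings_df = pd.DataFrame(
        loadings, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return scores_df, loadings_df, evr[:k]


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1), VIP, Q2
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """Fitted PLS1 discriminant model.

    Components are indexed a = 1..A: unit-norm weights ``w``, scores
    ``t = X_a w_a``, X-loadings ``p``, y-loadings ``q``; the y code is the
    centered 0/1 group indicator.
    """

    weights: np.ndarray  # features x A
    scores: np.ndarray  # samples x A
    x_loadings: np.ndarray  # features x A
    y_loadings: np.ndarray  # A
    x_mean: np.ndarray
    y_mean: float
    r2y: float
    feature_names: tuple[str, ...] = ()
    group_levels: tuple = ()

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def _encode_y(groups: pd.Series | np.ndarray) -> tuple[np.ndarray, tuple]:
    g = pd.Series(groups)
    levels = tuple(sorted(pd.unique(g), key=str))
    if len(levels) != 2:
        raise InsufficientData("PLS-DA needs exactly two classes")
    counts = g.value_counts()
    if (counts < 2).any():
        raise InsufficientData("each class needs >=2 samples")
    return (g == levels[1]).to_numpy(dtype=float), levels


def plsda_fit(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int = 2,
) -> PlsdaModel:
    """NIPALS PLS1 against a centered two-level class code.

    Per component: w = X'y normalized, t = Xw, p = X't/t't, q = y't/t't,
    then X and y are deflated.  R2Y is 1 - RSS/TSS of the fitted y.
    """
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yraw, levels = _encode_y(y)
    n, pfeat = Xarr.shape
    x_mean = Xarr.mean(axis=0)
    Xc = Xarr - x_mean
    y_mean = yraw.mean()
    yc = yraw - y_mean
    tss = float(np.sum(yc**2))

    A = min(n_components, n - 1, pfeat)
    W = np.zeros((pfeat, A))
    T = np.zeros((n, A))
    P = np.zeros((pfeat, A))
    Q = np.zeros(A)
    Xa, ya = Xc.copy(), yc.copy()
    kept = 0
    for a in range(A):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm <= 1e-12 * max(1.0, np.abs(Xa).max(initial=0.0)):
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = Xa.T @ t / tt
        q_load = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q_load * t
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, p_load, q_load
        kept = a + 1
    if kept == 0:
        raise InsufficientData("PLS-DA found no informative component")
    W, T, P, Q = W[:, :kept], T[:, :kept], P[:, :kept], Q[:kept]
    rss = float(np.sum((yc - T @ Q) ** 2))
    r2y = 1.0 - rss / tss if tss > 0 else 0.0
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else ()
    return PlsdaModel(
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=Q,
        x_mean=x_mean,
        y_mean=y_mean,
        r2y=r2y,
        feature_names=names,
        group_levels=levels,
    )


def plsda_predict(model: PlsdaModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Continuous class-code prediction for new samples."""
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xc = Xarr - model.x_mean
    yhat = np.full(Xarr.shape[0], model.y_mean)
    Xa = Xc.copy()
    for a in range(model.n_components):
        t = Xa @ model.weights[:, a]
        yhat = yhat + model.y_loadings[a] * t
        Xa = Xa - np.outer(t, model.x_loadings[:, a])
    return yhat


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection over the fitted components.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a't_a; the mean of squared VIPs is exactly 1.
    """
    ss = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("degenerate model: no explained y-variance")
    wnorm2 = model.weights**2  # columns already unit norm
    p = model.weights.shape[0]
    return np.sqrt(p * (wnorm2 @ ss) / total)


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    idx0 = rng.permutation(np.flatnonzero(y == 0))
    idx1 = rng.permutation(np.flatnonzero(y == 1))
    assignments = np.empty(y.size, dtype=int)
    for pool in (idx0, idx1):
        assignments[pool] = np.arange(pool.size) % folds
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def q2_cv(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int = 2,
    folds: int | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Cross-validated Q2 = 1 - PRESS/TSS with out-of-fold predictions.

    ``folds=None`` means leave-one-out; k-fold splits are stratified by
    class and every training fold must retain both classes.
    """
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ycode, _ = _encode_y(y)
    n = Xarr.shape[0]
    if folds is None:
        fold_indices = [np.array([i]) for i in range(n)]
    else:
        if folds < 2:
            raise ValueError("folds must be >=2")
        fold_indices = _stratified_folds(ycode, folds, seed)
    press_per_fold = np.zeros(len(fold_indices))
    residuals = np.zeros(n)
    for f, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_train = ycode[train_idx]
        if len(np.unique(y_train)) < 2:
            raise InsufficientData(f"training fold {f} lost a class")
        model = plsda_fit(Xarr[train_idx], y_train, n_components)
        yhat = plsda_predict(model, Xarr[test_idx])
        residuals[test_idx] = ycode[test_idx] - yhat
        press_per_fold[f] = float(np.sum((ycode[test_idx] - yhat) ** 2))
    tss = float(np.sum((ycode - ycode.mean()) ** 2))
    q2 = 1.0 - float(np.sum(residuals**2)) / tss
    return q2, press_per_fold


def optimal_components(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    max_components: int = 5,
    folds: int | None = None,
    seed: int = 0,
) -> tuple[int, float]:
    """Number of PLS components maximizing cross-validated Q2."""
    best = (1, -np.inf)
    n = len(np.asarray(y))
    for a in range(1, max(2, min(max_components, n - 1)) + 1):
        try:
            q2, _ = q2_cv(X, y, n_components=a, folds=folds, seed=seed)
        except InsufficientData:
            break
        if q2 > best[1]:
            best = (a, q2)
    return best


# ---------------------------------------------------------------------------
# GSEA enrichment score
# ---------------------------------------------------------------------------

def gsea_es(
    ranked_genes: Sequence[str],
    ranking_weights: Sequence[float],
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed extremum of the GSEA running sum P_hit - P_miss.

    ``ranked_genes`` is the universe ordered from most up- to most
    down-regulated, ``ranking_weights`` the aligned ranking metric.  Hits
    step by |weight|^exponent normalized over the set; misses step by
    1/(N - set size).  Exponent 0 recovers the classic Kolmogorov-Smirnov
    statistic.
    """
    genes = list(ranked_genes)
    weights = np.asarray(ranking_weights, dtype=float)
    if len(genes) != weights.size:
        raise ValueError("ranked_genes and ranking_weights must align")
    members = set(gene_set)
    in_set = np.array([g in members for g in genes])
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == len(genes):
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    w = np.abs(weights) ** weight_exponent
    hit_total = w[in_set].sum()
    if hit_total <= 0:
        raise ValueError("all in-set ranking weights are zero")
    steps = np.where(in_set, w / hit_total, -1.0 / (len(genes) - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])
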