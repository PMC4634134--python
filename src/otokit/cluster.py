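"""Gene filtering, PCA, PC-correlated gene selection and gap-statistic
k-means clustering.

The clustering chain mirrors the standard single-cell recipe for this kind
of dataset: drop genes detected in too few cells or with low cell-to-cell
coefficient of variation, run PCA over the remainder (cells as
observations), keep the genes most correlated with the leading components,
then cluster cells (and, for heatmap grouping, genes) by k-means with the
number of clusters chosen by the gap statistic of Tibshirani, Walther &
Hastie: Gap(k) compares the log within-cluster dispersion of the data with
that of B uniform reference draws over each feature's observed range, and
the selected k is the smallest k at (or left of) the first local maximum
whose gap is within one reference standard error of that maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix, require_units


def filter_variable_genes(
    matrix: ExpressionMatrix,
    min_cells: int = 2,
    cv_min: float = 0.5,
    lod: float = 1.0,
) -> list[str]:
    """Keep genes detected (above ``lod`` nTPM) in more than ``min_cells``
    cells and with coefficient of variation (population sd / mean, linear
    nTPM) of at least ``cv_min``. Zero-mean genes are removed."""
    require_units(matrix, "nTPM")
    values = matrix.to_numpy()
    n_detected = (values > lod).sum(axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    keep = (n_detected > min_cells) & (np.nan_to_num(cv, nan=-1.0) >= cv_min)
    genes = np.asarray(matrix.gene_ids)
    return genes[keep].tolist()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame             # cell x component
    loadings: pd.DataFrame           # gene x component
    explained_variance: np.ndarray   # per-component eigenvalues
    scaled: bool


def run_pca(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    scale: bool = True,
    n_components: int | None = None,
) -> PcaResult:
    """PCA with cells as observations and genes as variables.

    Variables are centered and (by default) scaled to unit population
    variance, so eigenvalues sum to the number of retained variables.
    Zero-variance genes are dropped with a warning when scaling. Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    require_units(matrix, "log2nTPM", "nTPM")
    sub = matrix.subset(genes=genes) if genes is not None else matrix
    X = sub.to_numpy().T  # cells x genes
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 cells and 2 genes")
    gene_ids = np.asarray(sub.gene_ids)
    sd = X.std(axis=0, ddof=0)
    if scale:
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before scaled PCA")
            X, sd, gene_ids = X[:, keep], sd[keep], gene_ids[keep]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / n  # population covariance eigenvalues
    k = min(len(S), n_components or len(S))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):  # deterministic sign: top |loading| positive
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_ids = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=sub.cell_ids, columns=comp_ids),
        loadings=pd.DataFrame(loadings, index=gene_ids, columns=comp_ids),
        explained_variance=eigvals[:k],
        scaled=scale,
    )


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value from the exact t transform."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), df=n - 2))


def select_pc_correlated_genes(
    matrix: ExpressionMatrix,
    pca: PcaResult,
    n_components: int = 2,
    n_genes: int = 50,
    alpha: float = 0.05,
    mode: str = "correlation",
) -> list[str]:
    """Select the genes most associated with the leading components.

    ``mode="correlation"`` keeps, per component, the ``n_genes`` genes with
    the largest |Pearson r| against the component scores among those with a
    significant two-sided correlation test (p < alpha); both tails are kept.
    ``mode="loading"`` ranks by |loading| instead. Selections across
    components are deduplicated, preserving first-seen order.
    """
    if n_components > pca.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    selected: list[str] = []
    if mode == "loading":
        for comp in pca.loadings.columns[:n_components]:
            ranked = pca.loadings[comp].abs().sort_values(ascending=False)
            selected.extend(ranked.index[:n_genes])
    elif mode == "correlation":
        values = matrix.values
        X = values.to_numpy().T  # cells x genes
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        xsd = X.std(axis=0, ddof=0)
        for comp in pca.scores.columns[:n_components]:
            y = pca.scores[comp].to_numpy()
            yc = y - y.mean()
            denom = n * xsd * y.std(ddof=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
            r = np.clip(r, -1.0, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = r * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-300))
            p = 2 * stats.t.sf(np.abs(t), df=n - 2)
            sig = np.nonzero(p < alpha)[0]
            if len(sig) < n_genes:
                warnings.warn(
                    f"{comp}: only {len(sig)} genes significant at alpha={alpha}"
                )
            order = sig[np.argsort(-np.abs(r[sig]), kind="stable")][:n_genes]
            selected.extend(values.index[order])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(dict.fromkeys(selected))


# ---------------------------------------------------------------------------
# k-means and the gap statistic
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignment: pd.Series   # item -> cluster label (0..k-1)
    k: int
    inertia: float
    seed: int


def kmeans_cluster(
    data,
    k: int,
    n_restarts: int = 25,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-restarts k-means (k-means++ initialization, seeded).

    ``data`` is an observations-by-features array or DataFrame; to cluster
    genes rather than cells, pass the transposed matrix.
    """
    index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(len(data))
    X = np.asarray(data, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} observations")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31)).fit(X)
    return ClusterResult(
        assignment=pd.Series(km.labels_, index=index, name="cluster"),
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


@dataclass
class GapResult:
    k_values: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    selected_k: int
    B: int
    log_w: np.ndarray


def _log_inertia(X: np.ndarray, k: int, n_init: int, rs: int) -> float:
    if k == 1:
        w = float(((X - X.mean(axis=0)) ** 2).sum())
    else:
        w = float(KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(X).inertia_)
    return float(np.log(max(w, 1e-300)))


def gap_statistic(
    data,
    k_range=range(1, 16),
    B: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
) -> GapResult:
    """Gap statistic over ``k_range`` with a uniform-box reference.

    Gap(k) = mean_b log(W*_kb) - log(W_k), with W the k-means within-cluster
    dispersion and the B reference datasets drawn uniformly over each
    feature's observed range. s_k = sd_b(log W*_kb) * sqrt(1 + 1/B).
    Selection: find the first local maximum k* of Gap (ties toward smaller
    k, boundary k judged one-sided), then pick the smallest k <= k* with
    Gap(k) >= Gap(k*) - s_{k*}.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    ks = []
    for k in k_range:
        if k > n:
            warnings.warn(f"skipping k={k} > {n} observations")
            continue
        ks.append(int(k))
    if not ks or ks[0] != 1:
        raise ValueError("k_range must start at 1")
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array([
        _log_inertia(X, k, n_restarts, int(rng.integers(2**31))) for k in ks
    ])
    log_w_star = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            # same optimization effort as the data fit: an asymmetric number
            # of restarts biases Gap upward at larger k
            log_w_star[b, j] = _log_inertia(ref, k, n_restarts, int(rng.integers(2**31)))
    gap = log_w_star.mean(axis=0) - log_w
    s_k = log_w_star.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    selected = _select_k(np.asarray(ks), gap, s_k)
    return GapResult(np.asarray(ks), gap, s_k, selected, B, log_w)


def _select_k(ks: np.ndarray, gap: np.ndarray, s_k: np.ndarray) -> int:
    """First-local-maximum / one-standard-error gap selection rule."""
    m = len(ks)
    star = m - 1
    for i in range(m):
        left_ok = i == 0 or gap[i] >= gap[i - 1]
        right_ok = i == m - 1 or gap[i] >= gap[i + 1]
        if left_ok and right_ok:
            star = i
            break
    threshold = gap[star] - s_k[star]
    for i in range(star + 1):
        if gap[i] >= threshold:
            return int(ks[i])
    return int(ks[star])


def cluster_cells(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    k: int | None = None,
    k_range=range(1, 16),
    B: int = 100,
    n_restarts: int = 25,
    seed: int = 0,
) -> tuple[ClusterResult, GapResult | None]:
    """Cluster cells on the selected genes; choose k by gap statistic when
    not given. Cells are observations, genes features (log2 expression)."""
    require_units(matrix, "log2nTPM")
    sub = matrix.subset(genes=genes) if genes is not None else matrix
    X = pd.DataFrame(sub.to_numpy().T, index=sub.cell_ids)
    gap = None
    if k is None:
        gap = gap_statistic(X.to_numpy(), k_range=k_range, B=B, seed=seed)
        k = gap.selected_k
    return kmeans_cluster(X, k, n_restarts=n_restarts, seed=seed + 1), gap
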