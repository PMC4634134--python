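"""Pseudotime ordering and kinetic-trend analysis.

Cells are embedded in two dimensions (ICA by default, PCA as a
deterministic alternative), connected by a Euclidean minimum spanning tree,
and ordered along the tree's diameter — the longest weighted path between
two leaves, the backbone of the differentiation trajectory. A backbone
cell's pseudotime is its cumulative path distance rescaled to [0, 1];
off-backbone cells inherit the pseudotime of the backbone cell where their
tree path attaches. Orientation follows a root hint (the cell group that
should sit at pseudotime 0) or, absent one, a lexicographic endpoint rule.

Gene dependence on pseudotime is tested by comparing a natural cubic spline
fit (default 3 degrees of freedom) against an intercept-only model with the
Gaussian likelihood-ratio statistic ``n * ln(RSS0/RSS1)`` on a chi-square
with df degrees of freedom; q-values are Benjamini-Hochberg. Significant
genes are grouped into kinetic trends (Off / Early / Transient / Late in
the default k=4) by k-means on their standardized fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import FastICA

from .cluster import kmeans_cluster, run_pca
from .diffexpr import bh_adjust
from .matrix import ExpressionMatrix, ValidationError, require_units


def reduce_dimensions(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    method: str = "ica",
    n_components: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Embed cells in ``n_components`` dimensions (cell x component table)."""
    require_units(matrix, "log2nTPM")
    sub = matrix.subset(genes=genes) if genes is not None else matrix
    X = sub.to_numpy().T  # cells x genes
    if X.shape[0] < 3:
        raise ValidationError("need at least three cells")
    if method == "pca":
        pca = run_pca(sub, scale=False, n_components=n_components)
        emb = pca.scores.to_numpy()
        if emb.shape[1] < n_components:
            raise ValidationError(f"data rank below {n_components}")
    elif method == "ica":
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < n_components:
            raise ValidationError(f"data rank {rank} below {n_components}")
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            random_state=int(seed) % (2**31),
            max_iter=1000,
        )
        emb = ica.fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(emb, index=sub.cell_ids,
                        columns=[f"C{j + 1}" for j in range(emb.shape[1])])


@dataclass
class Trajectory:
    embedding: pd.DataFrame
    mst_edges: list[tuple[str, str, float]]
    backbone: list[str]
    pseudotime: pd.Series
    root_cells: list[str] = field(default_factory=list)


def _weighted_farthest(tree: nx.Graph, source: str):
    dist = nx.single_source_dijkstra_path_length(tree, source, weight="weight")
    far = max(sorted(dist), key=lambda v: dist[v])  # sorted => deterministic ties
    return far, dist


def order_cells_mst(
    embedding: pd.DataFrame,
    root_cells: list[str] | None = None,
) -> Trajectory:
    """Order cells along the diameter path of the Euclidean MST.

    ``root_cells`` (e.g. the cells of the progenitor cluster) orient the
    axis: the orientation giving them the lower mean pseudotime is kept.
    Without a hint the backbone endpoint with the lexicographically smaller
    cell id comes first. Ties in the distance matrix are broken by cell id
    order, making the ordering invariant to input order.
    """
    cells = embedding.index.tolist()
    if len(cells) < 3:
        raise ValidationError("need at least three cells")
    order = np.argsort(np.asarray(cells, dtype=object), kind="stable")
    cells_sorted = [cells[i] for i in order]
    X = embedding.to_numpy()[order]

    dm = squareform(pdist(X))
    tree = nx.minimum_spanning_tree(
        nx.from_numpy_array(dm), algorithm="kruskal"
    )
    tree = nx.relabel_nodes(tree, dict(enumerate(cells_sorted)))

    start = cells_sorted[0]
    end_a, _ = _weighted_farthest(tree, start)
    end_b, dist_a = _weighted_farthest(tree, end_a)
    backbone = nx.shortest_path(tree, end_a, end_b, weight="weight")

    # cumulative distance along the backbone
    cum = [0.0]
    for u, v in zip(backbone[:-1], backbone[1:]):
        cum.append(cum[-1] + tree[u][v]["weight"])
    total = cum[-1] if cum[-1] > 0 else 1.0
    t = {c: cum[i] / total for i, c in enumerate(backbone)}

    # off-backbone cells attach where their tree path first meets the backbone
    backbone_set = set(backbone)
    for cell in cells_sorted:
        if cell in backbone_set:
            continue
        path = nx.shortest_path(tree, cell, backbone[0], weight="weight")
        attach = next(node for node in path if node in backbone_set)
        t[cell] = t[attach]

    pseudotime = pd.Series({c: t[c] for c in cells}, name="pseudotime").loc[cells]
    root_cells = list(root_cells or [])
    flip = False
    if root_cells:
        missing = [c for c in root_cells if c not in pseudotime.index]
        if missing:
            raise ValidationError(f"root cells not in embedding: {missing[:5]}")
        flip = pseudotime.loc[root_cells].mean() > 0.5
    else:
        flip = backbone[0] > backbone[-1]
    if flip:
        pseudotime = 1.0 - pseudotime
        backbone = backbone[::-1]

    edges = [(u, v, tree[u][v]["weight"]) for u, v in tree.edges]
    return Trajectory(embedding, edges, backbone, pseudotime, root_cells)


# ---------------------------------------------------------------------------
# natural-spline pseudotime dependence test
# ---------------------------------------------------------------------------

def natural_spline_basis(t: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (intercept excluded).

    Boundary knots sit at the extremes of ``t``; the remaining knots at
    evenly spaced quantiles, giving ``df + 1`` knots in total. ``df=1``
    degenerates to the identity (simple linear regression).
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return t[:, None]
    knots = np.quantile(t, np.linspace(0, 1, df + 1))
    if len(np.unique(knots)) != len(knots):
        raise ValidationError("degenerate pseudotime: duplicate spline knots")
    K = len(knots)

    def d(k):
        num = np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [t]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class KineticFit:
    table: pd.DataFrame        # per gene: lrt_statistic, p_value, q_value, rss0, rss1
    curves: pd.DataFrame       # gene x grid fitted curves
    grid: np.ndarray
    df: int
    n_cells: int


def spline_pseudotime_test(
    matrix: ExpressionMatrix,
    pseudotime: pd.Series,
    df: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_size: int = 100,
) -> KineticFit:
    """Test each gene for pseudotime dependence with a natural-spline fit."""
    require_units(matrix, "log2nTPM")
    t = pseudotime.loc[matrix.cell_ids].to_numpy(dtype=float)
    if len(np.unique(t)) < df + 2:
        raise ValidationError("pseudotime must take at least df + 2 distinct values")
    rng = np.random.default_rng(seed)
    Y = matrix.to_numpy().T  # cells x genes
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    n = Y.shape[0]

    basis = natural_spline_basis(t, df)
    design = np.column_stack([np.ones(n), basis])
    coef, _, _, _ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss1 = np.maximum(rss1, 1e-300)
    lrt = n * np.log(np.maximum(rss0, rss1) / rss1)
    p = stats.chi2.sf(lrt, df=df)
    q = bh_adjust(p)

    grid = np.linspace(t.min(), t.max(), grid_size)
    grid_design = np.column_stack([np.ones(grid_size), _basis_on_grid(t, grid, df)])
    curves = (grid_design @ coef).T
    table = pd.DataFrame(
        {"lrt_statistic": lrt, "p_value": p, "q_value": q, "rss0": rss0, "rss1": rss1},
        index=matrix.gene_ids,
    )
    return KineticFit(table, pd.DataFrame(curves, index=matrix.gene_ids), grid, df, n)


def _basis_on_grid(t_fit: np.ndarray, grid: np.ndarray, df: int) -> np.ndarray:
    """Evaluate the basis fitted on ``t_fit`` at new points ``grid``."""
    if df == 1:
        return grid[:, None]
    knots = np.quantile(t_fit, np.linspace(0, 1, df + 1))
    K = len(knots)

    def d(k):
        num = np.clip(grid - knots[k], 0, None) ** 3 - np.clip(grid - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [grid]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def cluster_kinetic_trends(
    fits: KineticFit,
    fdr_alpha: float = 0.05,
    k: int = 4,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group significant genes by the shape of their fitted curves.

    Each significant gene's fitted curve is standardized (zero mean, unit
    variance on the grid, so amplitude does not matter) and the curves are
    k-means clustered. Returns the per-gene cluster assignment and the
    per-cluster average standardized trend on the grid.
    """
    sig = fits.table.index[fits.table["q_value"] < fdr_alpha]
    if len(sig) < k:
        raise ValidationError(
            f"only {len(sig)} significant genes for k={k}; reduce k"
        )
    curves = fits.curves.loc[sig].to_numpy()
    mean = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    standardized = (curves - mean) / np.where(sd > 0, sd, 1.0)
    result = kmeans_cluster(pd.DataFrame(standardized, index=sig), k, seed=seed)
    trends = pd.DataFrame(
        [standardized[(result.assignment == c).to_numpy()].mean(axis=0) for c in range(k)],
        index=[f"trend{c}" for c in range(k)],
    )
    return result.assignment, trends
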