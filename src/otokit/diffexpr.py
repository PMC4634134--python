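"""Group-wise differential expression and marker specificity.

Differential expression between cell groups uses a Gaussian likelihood-ratio
test on log2 expression: the full model fits one mean per group, the reduced
model a grand mean, and the statistic is the profile-likelihood form
``n * ln(RSS0 / RSS1)`` referred to a chi-square with (groups - 1) degrees
of freedom. Because zero-inflated genes can have zero within-group variance,
a small seeded Gaussian jitter is injected once before testing. P-values are
corrected by Benjamini-Hochberg step-up.

Marker quality is scored by Jensen-Shannon specificity: per gene, the group
geometric means over detected (nonzero) cells are taken to log2, clamped at
zero, and normalized into a probability vector p over groups; the
specificity for group k is ``1 - JSdist(p, e_k)`` where e_k is the ideal
one-group indicator and JSdist the base-2 Jensen-Shannon distance (square
root of the divergence, so both live in [0, 1]). A score of 1 means the
gene is detected in exactly one group; 0 means its support excludes that
group entirely.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ValidationError, require_units


def _group_indices(groups: pd.Series, cell_ids: list[str]) -> dict[str, np.ndarray]:
    groups = pd.Series(groups).astype(str)
    missing = [c for c in cell_ids if c not in groups.index]
    if missing:
        raise ValidationError(f"cells without group assignment: {missing[:10]}")
    groups = groups.loc[cell_ids]
    return {g: np.nonzero((groups == g).to_numpy())[0] for g in groups.unique()}


def filter_testable_genes(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    min_cells: int = 2,
    lod: float = 1.0,
    require_all_groups: bool = False,
) -> list[str]:
    """Keep genes detected (above ``lod`` nTPM) in more than ``min_cells``
    cells in at least one group (or in every group when
    ``require_all_groups``)."""
    require_units(matrix, "nTPM")
    idx = _group_indices(pd.Series(groups), matrix.cell_ids)
    values = matrix.to_numpy()
    per_group = np.column_stack([
        (values[:, cols] > lod).sum(axis=1) > min_cells for cols in idx.values()
    ])
    keep = per_group.all(axis=1) if require_all_groups else per_group.any(axis=1)
    return np.asarray(matrix.gene_ids)[keep].tolist()


def lrt_group_test(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian likelihood-ratio test of group-dependent mean expression.

    Returns a per-gene table with the LRT statistic, p-value, BH q-value
    and per-group mean log2 expression (computed on the noise-injected
    values actually tested).
    """
    require_units(matrix, "log2nTPM")
    idx = _group_indices(pd.Series(groups), matrix.cell_ids)
    if len(idx) < 2:
        raise ValidationError("need at least two groups")
    for g, cols in idx.items():
        if len(cols) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 cells")
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy()
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    rss0 = ((values - grand) ** 2).sum(axis=1)
    rss1 = np.zeros_like(rss0)
    group_means = {}
    for g, cols in idx.items():
        block = values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        rss1 += ((block - mu) ** 2).sum(axis=1)
        group_means[f"mean_log2_{g}"] = mu.ravel()
    zero_var = rss1 <= 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} genes with zero residual variance; jitter applied")
        rss1 = np.where(zero_var, 1e-12, rss1)
        rss0 = np.maximum(rss0, rss1)
    lrt = n * np.log(rss0 / rss1)
    p = stats.chi2.sf(lrt, df=len(idx) - 1)
    table = pd.DataFrame(
        {"lrt_statistic": lrt, "p_value": p, **group_means}, index=matrix.gene_ids
    )
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Jensen-Shannon specificity
# ---------------------------------------------------------------------------

def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logarithms (in [0, 1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def specificity_scores(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    lod: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-group Jensen-Shannon specificity (gene x group table).

    Group summary expression is the geometric mean over cells with nonzero
    nTPM (0 when all cells are zero), taken to log2 and clamped below at 0;
    the clamp keeps the normalized vector a probability distribution. Genes
    whose vector is all zero score 0 for every group.
    """
    require_units(matrix, "nTPM")
    idx = _group_indices(pd.Series(groups), matrix.cell_ids)
    if len(idx) < 2:
        raise ValidationError("need at least two groups")
    values = matrix.to_numpy()
    log2_geomeans = np.zeros((values.shape[0], len(idx)))
    group_names = list(idx)
    for j, g in enumerate(group_names):
        block = values[:, idx[g]]
        with np.errstate(divide="ignore"):
            logs = np.where(block > 0, np.log2(np.where(block > 0, block, 1.0)), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            log2_geomeans[:, j] = np.nanmean(logs, axis=1)  # log2 of geometric mean
        log2_geomeans[np.isnan(log2_geomeans[:, j]), j] = 0.0
    log2_geomeans = np.maximum(log2_geomeans, 0.0)

    totals = log2_geomeans.sum(axis=1)
    scores = np.zeros_like(log2_geomeans)
    eye = np.eye(len(group_names))
    for i in range(values.shape[0]):
        if totals[i] <= 0:
            continue
        prob = log2_geomeans[i] / totals[i]
        for j in range(len(group_names)):
            scores[i, j] = 1.0 - np.sqrt(js_divergence(prob, eye[j]))
    return pd.DataFrame(np.clip(scores, 0.0, 1.0), index=matrix.gene_ids, columns=group_names)


def detected_fractions(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    lod: float = 1.0,
) -> pd.DataFrame:
    """Fraction of cells per group with expression above the LOD."""
    if matrix.units == "log2nTPM":
        detect = matrix.to_numpy() > 0
    else:
        detect = matrix.to_numpy() > lod
    idx = _group_indices(pd.Series(groups), matrix.cell_ids)
    return pd.DataFrame(
        {g: detect[:, cols].mean(axis=1) for g, cols in idx.items()},
        index=matrix.gene_ids,
    )


def build_de_table(
    matrix_ntpm: ExpressionMatrix,
    matrix_log2: ExpressionMatrix,
    groups: pd.Series | dict,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Full differential-expression table: LRT p/q-values, specificity
    scores (``spec_<group>``) and detected fractions (``detfrac_<group>``)."""
    lrt = lrt_group_test(matrix_log2, groups, noise_sd=noise_sd, seed=seed)
    spec = specificity_scores(matrix_ntpm, groups).add_prefix("spec_")
    frac = detected_fractions(matrix_ntpm, groups).add_prefix("detfrac_")
    return pd.concat([lrt, spec, frac], axis=1)


def refine_marker_list(
    de: pd.DataFrame,
    fdr_alpha: float = 0.05,
    specificity_threshold: float = 0.5,
    detection_fraction: float = 0.5,
) -> dict[str, list[str]]:
    """Per-group marker lists from a DE table.

    A gene is a marker of group k iff q < fdr_alpha, its specificity for k
    exceeds the threshold, k is the gene's argmax-specificity group, and
    the gene is detected in at least ``detection_fraction`` of k's cells.
    """
    spec_cols = [c for c in de.columns if c.startswith("spec_")]
    groups = [c[len("spec_"):] for c in spec_cols]
    markers: dict[str, list[str]] = {g: [] for g in groups}
    if de.empty:
        return markers
    spec = de[spec_cols].to_numpy()
    best = spec.argmax(axis=1)
    for i, gene in enumerate(de.index):
        if de["q_value"].iloc[i] >= fdr_alpha:
            continue
        k = best[i]
        g = groups[k]
        if spec[i, k] <= specificity_threshold:
            continue
        if de[f"detfrac_{g}"].iloc[i] < detection_fraction:
            continue
        markers[g].append(gene)
    return markers


def split_by_marker_expression(
    matrix: ExpressionMatrix,
    gene: str,
    high_threshold: float = 10.0,
    low_value: float = 0.0,
) -> pd.Series:
    """Split cells into marker-positive / marker-negative groups.

    Cells with log2 expression above ``high_threshold`` are "positive",
    cells exactly at ``low_value`` are "negative", and cells in between are
    left out of the comparison entirely.
    """
    require_units(matrix, "log2nTPM")
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    x = matrix.values.loc[gene]
    labels = pd.Series(index=x.index, dtype=object)
    labels[x > high_threshold] = "positive"
    labels[x == low_value] = "negative"
    labels = labels.dropna()
    if (labels == "positive").sum() == 0 or (labels == "negative").sum() == 0:
        raise ValidationError("both positive and negative groups must be non-empty")
    return labels


def organ_exclusive_genes(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    de: pd.DataFrame,
    min_cells: int = 10,
    fdr_alpha: float = 0.05,
    organ_a: str | None = None,
    organ_b: str | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Classify genes as organ-exclusive or shared between two organs.

    A gene is A-specific when detected in strictly more than ``min_cells``
    cells of A, zero cells of B, with q < fdr_alpha and a perfect
    specificity score for A; symmetrically for B. Shared genes are detected
    in every cell of both organs yet fail significance (q >= fdr_alpha).
    """
    require_units(matrix_a, "log2nTPM")
    require_units(matrix_b, "log2nTPM")
    genes_a, genes_b = set(matrix_a.gene_ids), set(matrix_b.gene_ids)
    if genes_a != genes_b:
        diff = sorted(genes_a.symmetric_difference(genes_b))
        raise ValidationError(f"gene universes differ: {diff[:10]}")
    spec_cols = [c for c in de.columns if c.startswith("spec_")]
    if len(spec_cols) != 2:
        raise ValidationError("expected a two-group (organ) DE table")
    col_a = f"spec_{organ_a}" if organ_a is not None else spec_cols[0]
    col_b = f"spec_{organ_b}" if organ_b is not None else spec_cols[1]
    if col_a not in de.columns or col_b not in de.columns:
        raise ValidationError(f"organ specificity columns not found: {col_a}, {col_b}")
    spec_a, spec_b = de[col_a], de[col_b]
    det_a = (matrix_a.values > 0).sum(axis=1)
    det_b = (matrix_b.values > 0).sum(axis=1)
    n_a, n_b = matrix_a.shape[1], matrix_b.shape[1]
    a_specific, b_specific, shared = [], [], []
    for gene in matrix_a.gene_ids:
        if gene not in de.index:
            continue
        q = de.loc[gene, "q_value"]
        if det_a[gene] > min_cells and det_b[gene] == 0 and q < fdr_alpha \
                and spec_a[gene] >= 1.0 - 1e-9:
            a_specific.append(gene)
        elif det_b[gene] > min_cells and det_a[gene] == 0 and q < fdr_alpha \
                and spec_b[gene] >= 1.0 - 1e-9:
            b_specific.append(gene)
        elif det_a[gene] == n_a and det_b[gene] == n_b and q >= fdr_alpha:
            shared.append(gene)
    return a_specific, b_specific, shared
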