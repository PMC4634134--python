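"""Normalization, limit of detection, QC cutoffs and batch correction.

The preprocessing chain for a raw TPM matrix is:

1. :func:`median_ratio_normalize` — cross-sample median-of-ratios scaling
   (the size-factor scheme of DESeq): each gene's values are divided by the
   gene's geometric mean across cells, and a cell's size factor is the
   median of its ratios over genes whose geometric mean is nonzero. The
   result is in nTPM units.
2. :func:`identify_outlier_cells` — flag low-expressing cells against the
   cohort after trimming poorly detected genes.
3. :func:`correct_batch_effects` — per-gene location/scale equalization of
   isolation batches (applied on the log2 scale).
4. :func:`apply_lod_log2` — zero values below the limit of detection
   (default 1 nTPM) and move to log2(nTPM).

:func:`estimate_lod_from_spikeins` recovers the limit of detection from a
spike-in dilution series; :func:`saturation_read_cutoff` computes the
sequencing-depth cutoff from a gene-count saturation curve analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ValidationError, require_units
from .simulate import SpikeInSeries

#: sentinel returned when a spike-in series cannot pin down a detection limit
UNDETERMINABLE = "undeterminable"


class NoReferenceGenesError(ValidationError):
    """No gene is positive in every cell, so no size factor is computable."""


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix                # nTPM
    size_factor: pd.Series                  # cell -> positive real
    n_genes_used: int


def median_ratio_normalize(matrix: ExpressionMatrix) -> NormalizationResult:
    """Median-of-ratios cross-sample normalization (TPM -> nTPM).

    Genes containing any zero have a zero geometric mean and are excluded
    from the size-factor median. Size factors are rescaled to unit geometric
    mean (normalization is then exactly idempotent). Raises
    :class:`NoReferenceGenesError` when no gene is positive in all cells.
    """
    require_units(matrix, "TPM", "nTPM")
    values = matrix.to_numpy()
    if values.shape[0] < 1 or values.shape[1] < 1:
        raise ValidationError("matrix must have at least one gene and one cell")
    positive = np.all(values > 0, axis=1)
    if not positive.any():
        raise NoReferenceGenesError("no reference genes: every gene has a zero geometric mean")
    ref = values[positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geomean[:, None]
    size_factor = np.median(ratios, axis=0)
    # rescale to unit geometric mean so normalization is exactly idempotent
    size_factor = size_factor / np.exp(np.mean(np.log(size_factor)))
    normalized = values / size_factor[None, :]
    out = ExpressionMatrix(
        pd.DataFrame(normalized, index=matrix.gene_ids, columns=matrix.cell_ids), "nTPM"
    )
    return NormalizationResult(
        out, pd.Series(size_factor, index=matrix.cell_ids, name="size_factor"),
        int(positive.sum()),
    )


def apply_lod_log2(matrix: ExpressionMatrix, lod: float = 1.0) -> ExpressionMatrix:
    """Zero entries below ``lod`` nTPM and log2-transform the rest."""
    require_units(matrix, "nTPM")
    if lod <= 0:
        raise ValueError("lod must be positive")
    values = matrix.to_numpy()
    out = np.where(values < lod, 0.0, np.log2(np.maximum(values, lod)))
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.cell_ids), "log2nTPM"
    )


def estimate_lod_from_spikeins(series: SpikeInSeries) -> float | str:
    """Estimate the limit of detection from a spike-in dilution series.

    A spike species is "detected" when its mean measured abundance is
    nonzero. Walking up the known-concentration ladder, the estimate is the
    smallest mean abundance among species above the last undetected rung —
    the level at which every species becomes detectable. Returns the
    :data:`UNDETERMINABLE` sentinel when no species (or none above the last
    undetected one) is detected.
    """
    if series.measured.shape[1] == 0:
        raise ValidationError("empty spike-in series")
    if len(np.unique(series.known_concentration)) < 2:
        raise ValidationError("need at least two distinct spike concentrations")
    means = series.measured.mean(axis=1).to_numpy()
    detected = means > 0
    if not detected.any():
        return UNDETERMINABLE
    if detected.all():
        return float(means.min())
    order = np.argsort(series.known_concentration)
    means_sorted = means[order]
    det_sorted = detected[order]
    last_undetected = np.max(np.nonzero(~det_sorted)[0])
    above = means_sorted[last_undetected + 1:]
    if above.size == 0:
        return UNDETERMINABLE
    return float(above.min())


# ---------------------------------------------------------------------------
# saturation-based depth cutoff
# ---------------------------------------------------------------------------

@dataclass
class SaturationCurve:
    depths: np.ndarray
    expected_unique_genes: np.ndarray
    cutoff_depth: int


def expected_unique_genes(gene_counts: np.ndarray, depth: int) -> float:
    """Expected number of distinct genes seen when down-sampling ``depth``
    reads without replacement from a cell with the given per-gene counts.

    For gene g with count c_g out of N total reads the chance it is missed
    entirely is hypergeometric: C(N-c_g, d) / C(N, d); summing the
    complements over genes gives the expectation exactly.
    """
    counts = np.asarray(gene_counts)
    counts = counts[counts > 0]
    N = int(counts.sum())
    d = min(int(depth), N)
    # P(miss gene) = C(N-c, d)/C(N, d), computed stably in log space
    from scipy.special import gammaln

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.where(
        counts > N - d,
        0.0,
        np.exp(log_comb(N - counts, d) - log_comb(N, d)),
    )
    return float(np.sum(1.0 - miss))


def saturation_read_cutoff(
    gene_counts,
    fraction: float = 0.9,
    depth_grid=None,
) -> SaturationCurve:
    """Find the read depth at which the expected number of unique genes
    detected reaches ``fraction`` of the genes present in the cell."""
    counts = np.asarray(gene_counts)
    if counts.sum() <= 0:
        raise ValidationError("all-zero count vector")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    N = int(counts.sum())
    n_genes = int((counts > 0).sum())
    if depth_grid is None:
        depth_grid = np.unique(np.round(np.geomspace(1, N, 50)).astype(int))
    depths = np.asarray(sorted(set(int(d) for d in depth_grid if d >= 1)))
    expected = np.array([expected_unique_genes(counts, d) for d in depths])
    target = fraction * n_genes
    reached = np.nonzero(expected >= target)[0]
    if reached.size == 0:
        warnings.warn("saturation target not reached on the depth grid; using max depth")
        cutoff = int(depths[-1])
    else:
        cutoff = int(depths[reached[0]])
    return SaturationCurve(depths, expected, cutoff)


# ---------------------------------------------------------------------------
# outlier cells
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    retained_gene_ids: list[str]
    per_cell_median: pd.Series
    percentile_cutoff: float
    outlier_cell_ids: list[str]


def identify_outlier_cells(
    matrix: ExpressionMatrix,
    gene_fraction: float = 0.95,
    cell_fraction: float = 0.5,
    percentile: float = 15.0,
    lod: float = 1.0,
    median_scale: str = "log2",
) -> OutlierReport:
    """Flag abnormally low-expressing cells.

    Low-mean genes are trimmed (ascending mean, one at a time) until at
    least ``gene_fraction`` of the remaining genes are above ``lod`` nTPM in
    at least ``cell_fraction`` of cells. A pooled distribution of expression
    (log2 by default) over the retained genes and all cells is built, and a
    cell is an outlier when its median expression over those genes falls
    strictly below the ``percentile``-th percentile of that pooled
    distribution. A healthy cell's median sits near the pooled 50th
    percentile, so only globally depressed cells are flagged.
    """
    require_units(matrix, "nTPM")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least two cells")
    values = matrix.to_numpy()
    n_cells = values.shape[1]
    detected = (values > lod).sum(axis=1) >= cell_fraction * n_cells

    order = np.argsort(values.mean(axis=1), kind="stable")
    det_in_order = detected[order]
    n_genes = len(order)
    # after trimming the j lowest-mean genes the criterion is
    # sum(detected among remaining) >= gene_fraction * (n_genes - j)
    remaining_detected = det_in_order[::-1].cumsum()[::-1]
    trim = None
    for j in range(n_genes):
        if remaining_detected[j] >= gene_fraction * (n_genes - j):
            trim = j
            break
    if trim is None:
        raise ValidationError("no genes satisfy detection criterion")
    retained_idx = np.sort(order[trim:])
    retained = values[retained_idx]
    if median_scale == "log2":
        retained = np.where(retained < lod, 0.0, np.log2(np.maximum(retained, lod)))
    medians = np.median(retained, axis=0)
    cutoff = float(np.percentile(retained, percentile))  # linear interpolation
    outliers = [matrix.cell_ids[i] for i in range(n_cells) if medians[i] < cutoff]
    gene_ids = np.asarray(matrix.gene_ids)
    return OutlierReport(
        retained_gene_ids=gene_ids[retained_idx].tolist(),
        per_cell_median=pd.Series(medians, index=matrix.cell_ids, name="median_log2"),
        percentile_cutoff=cutoff,
        outlier_cell_ids=outliers,
    )


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def correct_batch_effects(
    matrix: ExpressionMatrix,
    batches: pd.Series | dict,
) -> ExpressionMatrix:
    """Equalize per-gene batch means and scales toward the grand mean.

    Deterministic location/scale standardization: within each batch a gene's
    values are centered, rescaled to the pooled within-batch standard
    deviation, and re-anchored at the gene's grand mean. Batches with a
    single cell get a location-only adjustment (with a warning). A
    single-batch matrix is returned unchanged.
    """
    require_units(matrix, "log2nTPM", "nTPM")
    batches = pd.Series(batches).astype(str)
    missing = [c for c in matrix.cell_ids if c not in batches.index]
    if missing:
        raise ValidationError(f"cells without batch assignment: {missing[:10]}")
    batches = batches.loc[matrix.cell_ids]
    labels = batches.unique()
    if len(labels) < 2:
        return ExpressionMatrix(matrix.values.copy(), matrix.units)

    values = matrix.to_numpy()
    grand_mean = values.mean(axis=1)
    cols = {b: np.nonzero((batches == b).to_numpy())[0] for b in labels}
    # pooled within-batch sd over batches with >= 2 cells
    multi = [b for b in labels if len(cols[b]) >= 2]
    singletons = [b for b in labels if len(cols[b]) == 1]
    if singletons:
        warnings.warn(
            f"batches with a single cell get location-only adjustment: {singletons}"
        )
    if multi:
        ss = np.zeros(values.shape[0])
        dof = 0
        for b in multi:
            block = values[:, cols[b]]
            ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += len(cols[b]) - 1
        pooled_sd = np.sqrt(ss / max(dof, 1))
    else:
        pooled_sd = np.zeros(values.shape[0])

    out = values.copy()
    for b in labels:
        idx = cols[b]
        block = values[:, idx]
        mean_b = block.mean(axis=1, keepdims=True)
        if len(idx) >= 2:
            sd_b = block.std(axis=1, keepdims=True, ddof=0)
            scale = np.where(sd_b > 0, pooled_sd[:, None] / np.where(sd_b > 0, sd_b, 1.0), 1.0)
            adjusted = (block - mean_b) * scale + grand_mean[:, None]
        else:
            adjusted = block - mean_b + grand_mean[:, None]
        out[:, idx] = adjusted
    if matrix.units == "log2nTPM":
        out = np.maximum(out, 0.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.cell_ids), matrix.units
    )
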