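"""Single-cell qPCR preprocessing.

Primer efficiency is estimated from a standard curve: replicate Ct values
are averaged per dilution, a line is fit to mean Ct versus log10(relative
concentration), and the efficiency is ``E = 10 ** (-1 / slope)`` — the
fold-amplification per cycle, 2 for perfect doubling chemistry (slope
-3.32193 per decade). Assays outside a window around the ideal efficiency
are rejected. Ct values convert to log2 expression as ``LOD_Ct - Ct``
(default LOD at cycle 24), clamped at 0 for undetected reactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ValidationError


@dataclass
class StandardCurve:
    """A dilution series with replicate Ct measurements.

    ``relative_concentration`` holds the relative template amounts (e.g.
    1, 1/3, 1/9, ... for threefold dilutions); ``ct_replicates`` is a
    dilution x replicate array.
    """

    relative_concentration: np.ndarray
    ct_replicates: np.ndarray

    def __post_init__(self):
        self.relative_concentration = np.asarray(self.relative_concentration, dtype=float)
        self.ct_replicates = np.atleast_2d(np.asarray(self.ct_replicates, dtype=float))
        if np.any(self.relative_concentration <= 0):
            raise ValidationError("relative concentrations must be positive")
        if self.ct_replicates.shape[0] != len(self.relative_concentration):
            raise ValidationError("one row of Ct replicates per dilution required")


def threefold_dilution_series(n_dilutions: int = 8) -> np.ndarray:
    """Relative concentrations for the standard 8-point threefold series."""
    return (1.0 / 3.0) ** np.arange(n_dilutions)


def primer_efficiency(curve: StandardCurve) -> tuple[float, float]:
    """Estimate (slope, efficiency) from a standard curve.

    Replicates are averaged per dilution; the slope comes from least
    squares of mean Ct on log10(relative concentration); efficiency is
    ``10 ** (-1/slope)``.
    """
    if len(curve.relative_concentration) < 3:
        raise ValidationError("need at least three dilutions")
    mean_ct = curve.ct_replicates.mean(axis=1)
    order = np.argsort(-curve.relative_concentration)
    if np.any(np.diff(mean_ct[order]) < 0):
        warnings.warn("mean Ct not monotone along the dilution series")
    x = np.log10(curve.relative_concentration)
    slope, _ = np.polyfit(x, mean_ct, 1)
    if slope >= -1e-3 or not np.isfinite(slope):
        raise ValidationError(f"non-functional assay: slope {slope:.3g} is not negative")
    return float(slope), float(10.0 ** (-1.0 / slope))


def validate_primers(
    efficiencies: dict[str, float],
    ideal: float = 2.0,
    window: float = 0.2,
) -> dict[str, bool]:
    """Pass/fail per assay: pass iff |E - ideal| <= window (inclusive)."""
    return {assay: abs(e - ideal) <= window + 1e-12 for assay, e in efficiencies.items()}


def ct_to_log2_expression(ct, lod_ct: float = 24.0):
    """Convert Ct to log2 expression: ``LOD - Ct`` clamped below at 0.

    Ct at or above the LOD (or missing) counts as undetected (0). Accepts
    scalars or arrays.
    """
    ct_arr = np.asarray(ct, dtype=float)
    if np.any(ct_arr[np.isfinite(ct_arr)] <= 0):
        raise ValidationError("Ct values must be positive")
    expr = np.where(np.isfinite(ct_arr) & (ct_arr < lod_ct), lod_ct - ct_arr, 0.0)
    if np.isscalar(ct) or ct_arr.ndim == 0:
        return float(expr)
    return expr


def plate_to_expression(plate: pd.DataFrame, lod_ct: float = 24.0) -> pd.DataFrame:
    """Convert an assay x cell Ct plate (NaN = no amplification) to a log2
    expression table on the same axes."""
    return pd.DataFrame(
        ct_to_log2_expression(plate.to_numpy(), lod_ct=lod_ct),
        index=plate.index,
        columns=plate.columns,
    )
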