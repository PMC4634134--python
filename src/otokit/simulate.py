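"""Truth-known synthetic data emulating inner-ear single-cell experiments.

Every analysis stage in this package is exercised on generated data whose
ground truth is recorded, so recovery can be scored without any download:

* :func:`simulate_cell_types` — discrete populations (think hair cells,
  supporting cells and transitional epithelial cells) with planted marker
  genes, log-normal expression noise and logistic dropout;
* :func:`simulate_trajectory` — a differentiation trajectory with four
  kinetic gene classes (Off / Early / Transient / Late) over pseudotime;
* :func:`simulate_spikeins` — a 92-species RNA spike-in dilution series
  spanning six orders of magnitude, Poisson capture noise included;
* :func:`add_batch_effect` — per-batch log2 shifts emulating isolation
  batches;
* :func:`simulate_qpcr_plate` — single-cell qPCR Ct tables with an
  undetected floor at the LOD cycle threshold.

Expression noise is Gaussian on the log2 scale (log-normal in linear units),
matching the Gaussian modelling assumption the differential-expression tests
make downstream; dropout is logistic in the latent log2 mean. Identical
seeds yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

N_SPIKE_SPECIES = 92


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# discrete cell populations
# ---------------------------------------------------------------------------

@dataclass
class CellTypeSpec:
    """One synthetic population: marker count, expression levels and dropout.

    ``marker_log2_mean`` is the latent log2 abundance of this type's markers
    in its own cells, ``baseline_log2_mean`` their level everywhere else.
    Dropout zeroes an observation with probability
    ``sigmoid(dropout_slope * (dropout_midpoint - latent_mean))``.
    """

    name: str
    n_cells: int = 50
    n_marker_genes: int = 50
    marker_log2_mean: float = 8.0
    baseline_log2_mean: float = 1.0
    log2_sd: float = 1.0
    dropout_midpoint: float = 1.0
    dropout_slope: float = 1.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.log2_sd < 0:
            raise ValidationError("log2_sd must be >= 0")


def default_cell_type_specs() -> list[CellTypeSpec]:
    """Three 50-cell populations with 50 markers each (the default study
    condition: 150 cells, three major types)."""
    return [CellTypeSpec(name) for name in ("HC", "SC", "TEC")]


def simulate_cell_types(
    specs: list[CellTypeSpec],
    n_background_genes: int = 1850,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a TPM matrix and annotation for discrete cell populations.

    Marker genes of each type have latent log2 mean ``marker_log2_mean`` in
    their own type and ``baseline_log2_mean`` elsewhere; background genes get
    a per-gene latent mean drawn uniformly on [0, 8], identical across types.
    The observed value is ``2**Normal(latent, log2_sd)`` zeroed by logistic
    dropout in the latent mean. Truth labels and marker assignments are
    returned in the annotation / recorded in gene ids.
    """
    if not specs:
        raise ValidationError("need at least one cell type spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("cell type names must be unique")

    rng = np.random.default_rng(seed)
    n_cells = sum(s.n_cells for s in specs)
    cell_type = np.repeat(names, [s.n_cells for s in specs])
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]

    gene_ids: list[str] = []
    latent_rows = []
    bg_means = rng.uniform(0.0, 8.0, size=n_background_genes)
    for g in range(n_background_genes):
        gene_ids.append(f"bg{g:05d}")
        latent_rows.append(np.full(n_cells, bg_means[g]))
    for s in specs:
        for m in range(s.n_marker_genes):
            gene_ids.append(f"marker_{s.name}_{m:03d}")
            row = np.where(cell_type == s.name, s.marker_log2_mean, s.baseline_log2_mean)
            latent_rows.append(row.astype(float))
    latent = np.vstack(latent_rows) if latent_rows else np.empty((0, n_cells))

    sd = np.array([next(s.log2_sd for s in specs if s.name == t) for t in cell_type])
    mid = np.array([next(s.dropout_midpoint for s in specs if s.name == t) for t in cell_type])
    slope = np.array([next(s.dropout_slope for s in specs if s.name == t) for t in cell_type])

    log2_obs = latent + rng.normal(0.0, 1.0, size=latent.shape) * sd[None, :]
    values = np.power(2.0, log2_obs)
    p_drop = _sigmoid(slope[None, :] * (mid[None, :] - latent))
    values[rng.random(latent.shape) < p_drop] = 0.0

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=cell_ids), "TPM")
    ann = pd.DataFrame(
        {
            "organ": "synthetic",
            "batch": "b0",
            "truth_label": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return matrix, ann


# ---------------------------------------------------------------------------
# differentiation trajectory
# ---------------------------------------------------------------------------

KINETIC_CLASSES = ("Off", "Early", "Transient", "Late")


@dataclass
class KineticGeneSpec:
    """One trajectory gene: kinetic class, onset position, width, amplitude.

    The class picks the latent log2 curve over pseudotime t in [0, 1]:
    Off falls as ``a*(1 - sigmoid((t-onset)/width))``, Early and Late rise as
    ``a*sigmoid((t-onset)/width)`` (onset small vs large), Transient is a
    Gaussian bump ``a*exp(-(t-onset)^2 / (2 width^2))``.
    """

    kinetic_class: str
    onset: float = 0.5
    width: float = 0.08
    amplitude_log2: float = 8.0

    def __post_init__(self):
        if self.kinetic_class not in KINETIC_CLASSES:
            raise ValidationError(f"unknown kinetic class {self.kinetic_class!r}")
        if self.width <= 0:
            raise ValidationError("width must be > 0")

    def latent_log2(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, o, w = self.amplitude_log2, self.onset, self.width
        if self.kinetic_class == "Off":
            return a * (1.0 - _sigmoid((t - o) / w))
        if self.kinetic_class in ("Early", "Late"):
            return a * _sigmoid((t - o) / w)
        return a * np.exp(-((t - o) ** 2) / (2.0 * w**2))


def default_kinetic_gene_specs(n_per_class: int = 25) -> list[KineticGeneSpec]:
    """25 genes per kinetic class with onsets spread over the class's range."""
    specs = []
    ranges = {"Off": (0.2, 0.35), "Early": (0.2, 0.35), "Transient": (0.45, 0.55), "Late": (0.65, 0.8)}
    for cls in KINETIC_CLASSES:
        lo, hi = ranges[cls]
        onsets = np.linspace(lo, hi, n_per_class)
        width = 0.12 if cls == "Transient" else 0.08
        specs.extend(KineticGeneSpec(cls, onset=o, width=width) for o in onsets)
    return specs


def simulate_trajectory(
    n_cells: int = 200,
    gene_specs: list[KineticGeneSpec] | None = None,
    noise_log2_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a TPM matrix for cells on a differentiation trajectory.

    Truth pseudotime is uniform on [0, 1]; each gene follows its kinetic
    curve plus Gaussian log2 noise. The annotation records truth_pseudotime;
    the truth kinetic class is recorded per gene in the returned annotation's
    ``attrs["gene_class"]``.
    """
    if n_cells < 10:
        raise ValidationError("need at least 10 cells for a trajectory")
    if gene_specs is None:
        gene_specs = default_kinetic_gene_specs()
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    gene_ids = [f"{s.kinetic_class.lower()}_{i:03d}" for i, s in enumerate(gene_specs)]

    latent = np.vstack([s.latent_log2(t) for s in gene_specs])
    log2_obs = latent + rng.normal(0.0, noise_log2_sd, size=latent.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, log2_obs), index=gene_ids, columns=cell_ids), "TPM"
    )
    ann = pd.DataFrame(
        {"organ": "synthetic", "batch": "b0", "truth_pseudotime": t},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ann.attrs["gene_class"] = pd.Series(
        [s.kinetic_class for s in gene_specs], index=gene_ids, name="kinetic_class"
    )
    return matrix, ann


# ---------------------------------------------------------------------------
# spike-in dilution series
# ---------------------------------------------------------------------------

@dataclass
class SpikeInSeries:
    """A 92-species spike-in dilution series and its measured abundances."""

    spike_ids: list[str]
    known_concentration: np.ndarray   # molecules per capture site, 6 decades
    measured: pd.DataFrame            # spike x cell, TPM-like units

    def __post_init__(self):
        self.known_concentration = np.asarray(self.known_concentration, dtype=float)
        if len(self.spike_ids) != N_SPIKE_SPECIES:
            raise ValidationError(f"expected {N_SPIKE_SPECIES} spike species")
        if np.any(self.known_concentration <= 0):
            raise ValidationError("concentrations must be strictly positive")


def simulate_spikeins(
    n_cells: int = 30,
    capture_efficiency: float = 0.1,
    seed: int = 0,
    tpm_per_molecule: float = 20.0,
) -> SpikeInSeries:
    """Simulate a spike-in dilution series with Poisson capture.

    Known concentrations are geometric over six decades (1e-2 to 1e4
    molecules); each cell captures ``Poisson(concentration * efficiency)``
    molecules, reported in TPM-like units. Species near the low end drop out
    of every cell; with the defaults the detection boundary sits at a mean
    abundance of about 1, emulating the empirical limit of detection.
    """
    if not (0 < capture_efficiency <= 1):
        raise ValidationError("capture_efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(1e-2, 1e4, N_SPIKE_SPECIES)
    lam = conc * capture_efficiency
    counts = rng.poisson(lam[:, None], size=(N_SPIKE_SPECIES, n_cells))
    measured = counts.astype(float) * tpm_per_molecule
    spike_ids = [f"ERCC-{i:05d}" for i in range(N_SPIKE_SPECIES)]
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    return SpikeInSeries(spike_ids, conc, pd.DataFrame(measured, index=spike_ids, columns=cells))


# ---------------------------------------------------------------------------
# batch effects and qPCR plates
# ---------------------------------------------------------------------------

def add_batch_effect(
    matrix: ExpressionMatrix,
    batches: pd.Series | dict,
    shift_log2: dict,
    seed: int = 0,
    gene_jitter_sd: float = 0.0,
) -> ExpressionMatrix:
    """Shift each batch's log2 expression by a constant (plus optional
    per-gene jitter). Linear-unit matrices are multiplied by ``2**shift``;
    log2 matrices have the shift added to detected (nonzero) entries."""
    batches = pd.Series(batches).astype(str)
    missing = [c for c in matrix.cell_ids if c not in batches.index]
    if missing:
        raise ValidationError(f"cells without batch assignment: {missing[:10]}")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    n_genes = values.shape[0]
    for batch, shift in shift_log2.items():
        cols = [c for c in matrix.cell_ids if batches[c] == str(batch)]
        if not cols:
            continue
        per_gene = shift + (rng.normal(0.0, gene_jitter_sd, size=n_genes)
                            if gene_jitter_sd > 0 else 0.0)
        if matrix.units == "log2nTPM":
            block = values[cols].to_numpy()
            shifted = np.where(block > 0, block + np.atleast_1d(per_gene)[:, None], block)
            values[cols] = np.maximum(shifted, 0.0)
        else:
            values[cols] = values[cols].to_numpy() * np.power(2.0, np.atleast_1d(per_gene))[:, None]
    return ExpressionMatrix(values, matrix.units)


def simulate_qpcr_plate(
    n_cells: int,
    assay_specs: list[tuple[str, float, float, float]],
    lod_ct: float = 24.0,
    seed: int = 0,
    ct_floor: float = 5.0,
) -> pd.DataFrame:
    """Simulate an assay-by-cell Ct table.

    Each spec is ``(assay, on_fraction, ct_mean, ct_sd)``: a cell expresses
    the assay with probability ``on_fraction`` and then yields
    ``Normal(ct_mean, ct_sd)`` truncated below at ``ct_floor``; "off" cells
    get Ct equal to ``lod_ct`` (undetected).
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for assay, on_fraction, ct_mean, ct_sd in assay_specs:
        if ct_mean >= lod_ct:
            raise ValidationError(f"assay {assay}: ct_mean must be below lod_ct")
        on = rng.random(n_cells) < on_fraction
        ct = np.maximum(rng.normal(ct_mean, ct_sd, size=n_cells), ct_floor)
        rows[assay] = np.where(on, ct, lod_ct)
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    return pd.DataFrame(rows, index=cells).T
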