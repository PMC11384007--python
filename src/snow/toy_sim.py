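"""Synthetic rhythmic/flat-gene datasets with known ground truth.

The simulator emulates a time-course single-cell experiment in which mature
cells of several types are destroyed and profiled at fixed sampling times.
Two gene classes are generated:

* *flat* genes: integer-rounded Gaussian noise around a cell-type-specific
  basal level, ``round(b_ij + eps_f)``;
* *rhythmic* genes: a 24 h cosine lifted to a zero minimum,
  ``round(a_ij * (cos(2*pi*t/period - phi_ij) + 1) + eps_c)``,
  where the amplitude ``a`` and/or the phase ``phi`` may be cell-type
  dependent.

Amplitudes and basal levels are uniform on [0, 20], phases uniform on
[0, 2*pi) radians, noise scales eps_f ~ N(0, 2) and eps_c ~ N(0, 0.1), and
negative values are thresholded to zero, so every entry is a non-negative
integer.  Cells are assigned uniformly at random to cell types and to
sampling times (default 0, 4, ..., 48 h).  A ground-truth table accompanies
the data so recovery tests need no re-derivation.

A batch-spike injector multiplies one gene's counts at a single timepoint,
producing the fixture used to exercise the batch-effect criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import SnowDataError, TimedCountData

__all__ = [
    "ToyDesign",
    "ToyGeneSpec",
    "ToyTruth",
    "make_gene_specs",
    "simulate_toy",
    "inject_batch_spike",
]

DEPENDENCE_MODES = ("phase-only", "amplitude-only", "both", "none")


@dataclass(frozen=True)
class ToyDesign:
    """Study design of the synthetic experiment.

    Defaults follow the reference simulation setting: 1000 cells over
    13 timepoints 4 h apart, 120 rhythmic and 30 flat genes, 5 cell types
    distinguished by their rhythmic phases (and always by their flat basal
    levels).
    """

    n_cells: int = 1000
    n_types: int = 5
    n_rhythmic: int = 120
    n_flat: int = 30
    time_levels: tuple = tuple(float(t) for t in range(0, 49, 4))
    dependence_mode: str = "phase-only"
    period: float = 24.0
    noise_sd_flat: float = 2.0
    noise_sd_rhythmic: float = 0.1

    def __post_init__(self):
        if self.n_types < 1 or self.n_cells < self.n_types:
            raise SnowDataError("require n_cells >= n_types >= 1")
        if self.dependence_mode not in DEPENDENCE_MODES:
            raise SnowDataError(
                f"dependence_mode must be one of {DEPENDENCE_MODES}"
            )


@dataclass(frozen=True)
class ToyGeneSpec:
    """Per-gene parameters; arrays are indexed by cell type."""

    kind: str  # "flat" | "rhythmic"
    basal: np.ndarray | None = None  # b_ij, flat genes
    amplitude: np.ndarray | None = None  # a_ij, rhythmic genes
    phase: np.ndarray | None = None  # phi_ij in [0, 2*pi), radians
    period: float = 24.0

    def __post_init__(self):
        if self.kind not in ("flat", "rhythmic"):
            raise SnowDataError("kind must be 'flat' or 'rhythmic'")
        for arr, lo in ((self.basal, 0.0), (self.amplitude, 0.0)):
            if arr is not None and np.any(np.asarray(arr) < lo):
                raise SnowDataError("basal levels and amplitudes must be >= 0")
        if self.phase is not None:
            p = np.asarray(self.phase)
            if np.any((p < 0) | (p >= 2 * np.pi)):
                raise SnowDataError("phases must lie in [0, 2*pi)")

    def noiseless(self, type_idx: int, t_hours) -> np.ndarray:
        """Expected (pre-rounding, noise-free) expression at times ``t_hours``."""
        t = np.asarray(t_hours, dtype=float)
        if self.kind == "flat":
            return np.full_like(t, float(self.basal[type_idx]))
        a = float(self.amplitude[type_idx])
        phi = float(self.phase[type_idx])
        return a * (np.cos(2 * np.pi * t / self.period - phi) + 1.0)


@dataclass
class ToyTruth:
    """Ground truth emitted alongside the simulated counts."""

    design: ToyDesign
    specs: list[ToyGeneSpec]
    cell_types: np.ndarray  # integer type index per cell
    cell_times: np.ndarray  # hours per cell

    def curve(self, gene_idx: int, type_idx: int, t_hours) -> np.ndarray:
        return self.specs[gene_idx].noiseless(type_idx, t_hours)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, spec in enumerate(self.specs):
            for j in range(self.design.n_types):
                rows.append(
                    {
                        "gene": g,
                        "cell_type": j,
                        "kind": spec.kind,
                        "basal": None if spec.basal is None else float(spec.basal[j]),
                        "amplitude": None
                        if spec.amplitude is None
                        else float(spec.amplitude[j]),
                        "phase_rad": None if spec.phase is None else float(spec.phase[j]),
                    }
                )
        return pd.DataFrame(rows)


def make_gene_specs(design: ToyDesign, seed: int | np.random.Generator = 0) -> list[ToyGeneSpec]:
    """Draw per-gene parameters; factors excluded by ``dependence_mode`` are
    shared across cell types (drawn once and tiled)."""
    rng = np.random.default_rng(seed)
    specs: list[ToyGeneSpec] = []
    amp_dependent = design.dependence_mode in ("amplitude-only", "both")
    phase_dependent = design.dependence_mode in ("phase-only", "both")
    for _ in range(design.n_rhythmic):
        if amp_dependent:
            a = rng.uniform(0.0, 20.0, design.n_types)
        else:
            a = np.full(design.n_types, rng.uniform(0.0, 20.0))
        if phase_dependent:
            phi = rng.uniform(0.0, 2 * np.pi, design.n_types)
        else:
            phi = np.full(design.n_types, rng.uniform(0.0, 2 * np.pi))
        specs.append(
            ToyGeneSpec(kind="rhythmic", amplitude=a, phase=phi, period=design.period)
        )
    for _ in range(design.n_flat):
        b = rng.uniform(0.0, 20.0, design.n_types)  # flat basal is always type-specific
        specs.append(ToyGeneSpec(kind="flat", basal=b, period=design.period))
    return specs


def simulate_toy(
    design: ToyDesign,
    specs: list[ToyGeneSpec] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[TimedCountData, ToyTruth]:
    """Simulate counts under ``design``; returns data and ground truth."""
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = make_gene_specs(design, rng)
    cell_types = rng.integers(0, design.n_types, size=design.n_cells)
    cell_times = rng.choice(np.asarray(design.time_levels, float), size=design.n_cells)

    n_genes = len(specs)
    values = np.empty((design.n_cells, n_genes))
    for g, spec in enumerate(specs):
        base = np.empty(design.n_cells)
        for j in range(design.n_types):
            mask = cell_types == j
            base[mask] = spec.noiseless(j, cell_times[mask])
        sd = design.noise_sd_flat if spec.kind == "flat" else design.noise_sd_rhythmic
        values[:, g] = base + rng.normal(0.0, sd, design.n_cells)
    counts = np.maximum(np.round(values), 0.0).astype(np.int64)

    data = TimedCountData(
        counts=counts,
        times=cell_times,
        gene_names=np.array(
            [f"{spec.kind[0]}gene{g}" for g, spec in enumerate(specs)]
        ),
        cell_labels=np.array([f"type{j}" for j in cell_types]),
    )
    truth = ToyTruth(design=design, specs=list(specs), cell_types=cell_types, cell_times=cell_times)
    return data, truth


def inject_batch_spike(
    data: TimedCountData, gene: int, timepoint: float, fold: float
) -> TimedCountData:
    """Multiply one gene's counts at one timepoint by ``fold`` (rounded).

    The spike mimics a batch artifact confined to a single collection: the
    gene's per-timepoint mean expression and capture rate jump at that
    timepoint only.  Library sizes are recomputed by the container.
    """
    if not 0 <= gene < data.n_genes:
        raise IndexError(f"gene index {gene} out of range")
    if timepoint not in data.time_levels:
        raise IndexError(f"timepoint {timepoint} not among observed time levels")
    if fold <= 0:
        raise SnowDataError("fold must be positive")
    counts = data.counts.copy()
    mask = data.times == timepoint
    counts[mask, gene] = np.round(counts[mask, gene] * fold).astype(np.int64)
    return TimedCountData(
        counts=counts,
        times=data.times.copy(),
        gene_names=data.gene_names.copy(),
        cell_ids=data.cell_ids.copy(),
        cell_labels=None if data.cell_labels is None else data.cell_labels.copy(),
    )
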