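"""Containers and I/O for timed single-cell count matrices.

The central object is :class:`TimedCountData`: a dense cells x genes integer
count matrix together with each cell's sampling time in hours and optional
cell-type labels.  Library sizes are always recomputed from the matrix, never
trusted from a file.  Supported on-disk layouts are AnnData ``.h5ad``,
CSV (cells x genes with a header row of gene names) plus a metadata table,
and MatrixMarket ``.mtx`` plus a metadata table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnowConfigError",
    "SnowDataError",
    "TimeMap",
    "TimedCountData",
    "compute_library_sizes",
    "normalize_time",
    "load_counts",
    "save_counts",
]


class SnowConfigError(ValueError):
    """A configuration problem (missing column, bad option, degenerate setup)."""


class SnowDataError(ValueError):
    """Invalid data content (negative, non-integer or non-finite counts)."""


@dataclass(frozen=True)
class TimeMap:
    """Affine map between hours and the [0, 1] scale fed to the networks.

    A degenerate map (all observed times identical) normalizes every time to 0
    and is flagged; it is acceptable for inference-only use but rejected for
    training.
    """

    t_min: float
    t_max: float

    @property
    def degenerate(self) -> bool:
        return self.t_max <= self.t_min

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    def normalize(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        if self.degenerate:
            return np.zeros_like(t)
        return (t - self.t_min) / (self.t_max - self.t_min)

    def denormalize(self, t_norm):
        t = np.asarray(t_norm, dtype=float)
        if self.degenerate:
            return np.full_like(t, self.t_min)
        return t * (self.t_max - self.t_min) + self.t_min


def compute_library_sizes(counts: np.ndarray) -> np.ndarray:
    """Per-cell total counts l_c = sum_g x_cg.

    Cells with zero total are reported with a warning: a zero library size
    collapses the count likelihood (the NB mean is rho * l), so such cells are
    dropped before training.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise SnowDataError("counts must be a 2-D matrix")
    if np.any(counts < 0):
        raise SnowDataError("counts contain negative entries")
    lib = counts.sum(axis=1)
    n_zero = int(np.sum(lib == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} cell(s) have zero library size and will be dropped "
            "before training",
            stacklevel=2,
        )
    return lib


def normalize_time(times, for_training: bool = True):
    """Map hours onto [0, 1]; returns the values and the invertible map."""
    t = np.asarray(times, dtype=float)
    t_min, t_max = float(np.min(t)), float(np.max(t))
    tm = TimeMap(t_min, t_max)
    if tm.degenerate:
        if for_training:
            raise SnowConfigError(
                "all sampling times are identical; training requires at least "
                "two distinct times"
            )
        logger.warning("degenerate time map: single observed time %s h", t_min)
    return tm.normalize(t), tm


@dataclass
class TimedCountData:
    """Timed count matrix with validated invariants.

    ``library_sizes`` and ``time_levels`` are derived, not supplied.
    """

    counts: np.ndarray
    times: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray | None = None
    cell_labels: np.ndarray | None = None
    library_sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
            raise SnowDataError("counts must be a C x G matrix with C, G >= 1")
        if not np.all(np.isfinite(counts)):
            bad = np.argwhere(~np.isfinite(counts))[:5]
            raise SnowDataError(f"non-finite counts at (cell, gene) {bad.tolist()}")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[:5]
            raise SnowDataError(f"negative counts at (cell, gene) {bad.tolist()}")
        if not np.allclose(counts, np.round(counts)):
            bad = np.argwhere(counts != np.round(counts))[:5]
            raise SnowDataError(f"non-integer counts at (cell, gene) {bad.tolist()}")
        self.counts = counts.astype(np.int64)

        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_cells,):
            raise SnowDataError("times must have one entry per cell")
        if not np.all(np.isfinite(self.times)):
            raise SnowDataError("times contain non-finite values")

        self.gene_names = np.asarray(self.gene_names, dtype=str)
        if self.gene_names.shape != (self.n_genes,):
            raise SnowDataError("gene_names must have one entry per gene")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(self.n_cells)])
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels, dtype=str)
            if self.cell_labels.shape != (self.n_cells,):
                raise SnowDataError("cell_labels must have one entry per cell")
        self.library_sizes = compute_library_sizes(self.counts)

    # -- derived -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def time_levels(self) -> np.ndarray:
        return np.unique(self.times)

    def drop_zero_cells(self) -> "TimedCountData":
        """Remove cells with zero library size (no-op copy when none)."""
        keep = self.library_sizes > 0
        n_dropped = int(np.sum(~keep))
        if n_dropped:
            logger.info("dropping %d zero-count cell(s)", n_dropped)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self.subset(np.flatnonzero(keep))

    def subset(self, cell_idx) -> "TimedCountData":
        cell_idx = np.asarray(cell_idx)
        return TimedCountData(
            counts=self.counts[cell_idx],
            times=self.times[cell_idx],
            gene_names=self.gene_names,
            cell_ids=self.cell_ids[cell_idx],
            cell_labels=None if self.cell_labels is None else self.cell_labels[cell_idx],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimedCountData):
            return NotImplemented
        labels_eq = (self.cell_labels is None) == (other.cell_labels is None) and (
            self.cell_labels is None or np.array_equal(self.cell_labels, other.cell_labels)
        )
        return (
            np.array_equal(self.counts, other.counts)
            and np.allclose(self.times, other.times, atol=1e-9)
            and np.array_equal(self.gene_names, other.gene_names)
            and labels_eq
        )


# -- readers / writers -------------------------------------------------------

DEFAULT_COUNTS_LAYER = "counts"
LABEL_KEY = "cell_type"


def _read_meta(meta_path: Path, time_key: str, cell_ids: np.ndarray):
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if time_key not in meta.columns:
        raise SnowConfigError(
            f"metadata {meta_path} has no column {time_key!r}; "
            f"available: {list(meta.columns)}"
        )
    meta = meta.loc[[str(c) for c in cell_ids]]
    times = pd.to_numeric(meta[time_key], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise SnowConfigError(f"time column {time_key!r} is not parseable to finite hours")
    labels = meta[LABEL_KEY].to_numpy(dtype=str) if LABEL_KEY in meta.columns else None
    return times, labels


def load_counts(
    path: str | Path,
    time_key: str = "time",
    layer: str | None = None,
    meta: str | Path | None = None,
) -> TimedCountData:
    """Read timed counts from ``.h5ad``, ``.csv`` or ``.mtx``.

    For CSV/MTX a tab-separated metadata table is required (``meta``, or a
    sibling file ``<stem>.obs.tsv``) with cell ids in the first column, the
    sampling time in hours under ``time_key``, and optionally a ``cell_type``
    column.  For h5ad, counts are taken from ``layers['counts']`` when present
    (or ``layer`` if given), else from ``X``; the time is ``obs[time_key]``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if layer is not None:
            if layer not in adata.layers:
                raise SnowConfigError(f"layer {layer!r} not found in {path}")
            counts = adata.layers[layer]
        elif DEFAULT_COUNTS_LAYER in adata.layers:
            counts = adata.layers[DEFAULT_COUNTS_LAYER]
        else:
            counts = adata.X
        if hasattr(counts, "toarray"):
            counts = counts.toarray()
        counts = np.asarray(counts)
        if time_key not in adata.obs.columns:
            raise SnowConfigError(
                f"obs has no column {time_key!r}; available: {list(adata.obs.columns)}"
            )
        times = pd.to_numeric(adata.obs[time_key], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(times)):
            raise SnowConfigError(
                f"time column {time_key!r} is not parseable to finite hours"
            )
        labels = (
            adata.obs[LABEL_KEY].to_numpy(dtype=str)
            if LABEL_KEY in adata.obs.columns
            else None
        )
        return TimedCountData(
            counts=counts,
            times=times,
            gene_names=adata.var_names.to_numpy(dtype=str),
            cell_ids=adata.obs_names.to_numpy(dtype=str),
            cell_labels=labels,
        )

    if suffix in (".csv", ".mtx"):
        meta_path = Path(meta) if meta is not None else path.with_suffix(".obs.tsv")
        if not meta_path.exists():
            raise SnowConfigError(
                f"CSV/MTX input requires a metadata table; {meta_path} not found"
            )
        if suffix == ".csv":
            df = pd.read_csv(path, index_col=0)
            counts = df.to_numpy()
            gene_names = df.columns.to_numpy(dtype=str)
            cell_ids = df.index.to_numpy(dtype=str)
        else:
            from scipy.io import mmread

            counts = np.asarray(mmread(path).todense())
            gene_names = np.array([f"gene{i}" for i in range(counts.shape[1])])
            names_path = path.with_suffix(".genes.txt")
            if names_path.exists():
                gene_names = np.loadtxt(names_path, dtype=str, ndmin=1)
            cell_ids = np.array([f"cell{i}" for i in range(counts.shape[0])])
        times, labels = _read_meta(meta_path, time_key, cell_ids)
        return TimedCountData(
            counts=counts,
            times=times,
            gene_names=gene_names,
            cell_ids=cell_ids,
            cell_labels=labels,
        )

    raise SnowConfigError(f"unsupported input format: {path}")


def save_counts(data: TimedCountData, path: str | Path, time_key: str = "time") -> Path:
    """Write ``data`` as h5ad or CSV (+ sibling ``.obs.tsv``)."""
    path = Path(path)
    if path.suffix.lower() == ".h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=data.counts.astype(np.float64),
            obs=pd.DataFrame(index=pd.Index(data.cell_ids, name="cell")),
            var=pd.DataFrame(index=pd.Index(data.gene_names, name="gene")),
        )
        adata.layers[DEFAULT_COUNTS_LAYER] = data.counts.copy()
        adata.obs[time_key] = data.times
        if data.cell_labels is not None:
            adata.obs[LABEL_KEY] = data.cell_labels
        adata.write_h5ad(path)
        return path
    if path.suffix.lower() == ".csv":
        pd.DataFrame(data.counts, index=data.cell_ids, columns=data.gene_names).to_csv(path)
        meta = pd.DataFrame({time_key: data.times}, index=pd.Index(data.cell_ids, name="cell"))
        if data.cell_labels is not None:
            meta[LABEL_KEY] = data.cell_labels
        meta.to_csv(path.with_suffix(".obs.tsv"), sep="\t")
        return path
    raise SnowConfigError(f"unsupported output format: {path}")
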