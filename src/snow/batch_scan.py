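"""Flagging genes with putative batch effects.

Two empirical, model-free criteria over the per-timepoint structure of the
counts:

* *spurious expression*: a gene's mean normalized expression (empirical count
  fraction x_cg / l_c averaged over the cells of a timepoint) at some
  timepoint is at least ``ratio_threshold`` (default 5) times its mean across
  timepoints;
* *spurious detection*: the same criterion applied to the capture rate (the
  fraction of a timepoint's cells in which the gene is detected at all).

Genes that are almost never seen are excluded first: only genes with mean
normalized expression > 1e-5 and mean capture rate > 5% across timepoints are
considered, which also guarantees the ratio denominators are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SnowConfigError, TimedCountData

__all__ = [
    "BatchFlagReport",
    "capture_rates",
    "mean_normalized_expression",
    "flag_batch_genes",
]


def _per_time(data: TimedCountData):
    levels = data.time_levels
    if any((data.times == t).sum() == 0 for t in levels):  # pragma: no cover
        raise SnowConfigError("empty timepoint")
    return levels


def capture_rates(data: TimedCountData) -> pd.DataFrame:
    """Gene x timepoint fraction of cells with nonzero counts."""
    levels = _per_time(data)
    out = np.empty((data.n_genes, levels.size))
    for j, t in enumerate(levels):
        cells = data.counts[data.times == t]
        out[:, j] = (cells > 0).mean(axis=0)
    return pd.DataFrame(out, index=data.gene_names, columns=levels)


def mean_normalized_expression(data: TimedCountData) -> pd.DataFrame:
    """Gene x timepoint mean of the empirical count fraction x / l."""
    levels = _per_time(data)
    if np.any(data.library_sizes <= 0):
        raise SnowConfigError("zero library sizes present; drop empty cells first")
    frac = data.counts / data.library_sizes[:, None].astype(float)
    out = np.empty((data.n_genes, levels.size))
    for j, t in enumerate(levels):
        out[:, j] = frac[data.times == t].mean(axis=0)
    return pd.DataFrame(out, index=data.gene_names, columns=levels)


@dataclass
class BatchFlagReport:
    """Genes flagged by either criterion, with the offending timepoint."""

    spurious_expression: pd.DataFrame  # columns: gene, ratio, peak_timepoint
    spurious_detection: pd.DataFrame
    filters_applied: dict
    n_genes_considered: int

    def to_frame(self) -> pd.DataFrame:
        ex = self.spurious_expression.assign(criterion="spurious_expression")
        de = self.spurious_detection.assign(criterion="spurious_detection")
        cols = ["gene", "criterion", "ratio", "peak_timepoint"]
        return pd.concat([ex, de], ignore_index=True)[cols]


def _max_over_mean(table: pd.DataFrame) -> pd.DataFrame:
    mean = table.mean(axis=1)
    peak = table.idxmax(axis=1)
    ratio = table.max(axis=1) / mean
    return pd.DataFrame({"ratio": ratio, "peak_timepoint": peak})


def flag_batch_genes(
    data: TimedCountData,
    ratio_threshold: float = 5.0,
    min_mean_expr: float = 1e-5,
    min_mean_capture: float = 0.05,
    inclusive: bool = True,
) -> BatchFlagReport:
    """Apply both max/mean-ratio criteria; the two gene lists are independent
    and may overlap.  ``inclusive`` makes the threshold a >= comparison."""
    if data.time_levels.size < 2:
        raise SnowConfigError("batch scan requires at least two timepoints")
    expr = mean_normalized_expression(data)
    capt = capture_rates(data)
    considered = (expr.mean(axis=1) > min_mean_expr) & (capt.mean(axis=1) > min_mean_capture)
    assert np.all(expr.mean(axis=1)[considered] > 0)  # filters forbid zero means
    cmp = np.greater_equal if inclusive else np.greater

    reports = []
    for table in (expr.loc[considered], capt.loc[considered]):
        stats = _max_over_mean(table)
        hits = stats[cmp(stats["ratio"], ratio_threshold)].reset_index(names="gene")
        reports.append(hits.sort_values("ratio", ascending=False, ignore_index=True))

    return BatchFlagReport(
        spurious_expression=reports[0],
        spurious_detection=reports[1],
        filters_applied={
            "ratio_threshold": ratio_threshold,
            "min_mean_expr": min_mean_expr,
            "min_mean_capture": min_mean_capture,
            "inclusive": inclusive,
        },
        n_genes_considered=int(considered.sum()),
    )
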