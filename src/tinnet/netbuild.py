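"""From denoised ROI time series to binary networks.

A 90x90 (in general ROI x ROI) Pearson correlation matrix is
thresholded by |r| to a target connection density: the E = round(d *
n(n-1)/2) strongest-|r| pairs become edges of an undirected, unweighted
graph. Note that anticorrelations enter by absolute value, so strong
negative coupling also creates edges. Sliding windows (default 20 TRs,
step 1) yield dynamic graph series at a fixed density (default 0.10).
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (BinaryGraph, CorrMatrix, DynamicGraphSeries,
                         TimeSeries)

logger = logging.getLogger(__name__)

#: Connection densities analysed for static networks.
DEFAULT_DENSITY_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)
#: Sliding-window defaults: width in TRs, step in TRs, density.
DEFAULT_WINDOW_WIDTH = 20
DEFAULT_WINDOW_STEP = 1
DEFAULT_DYNAMIC_DENSITY = 0.10


def correlation_matrix(series: TimeSeries) -> CorrMatrix:
    """Pairwise Pearson correlations across channels."""
    if series.n_time < 3:
        raise ValueError("need at least 3 time points")
    sd = series.values.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [series.channel_labels[i] for i in dead]
        raise ValueError(f"zero-variance channel(s): {names}")
    r = np.corrcoef(series.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrMatrix(r, n_time=series.n_time,
                      node_labels=list(series.channel_labels))


def fisher_z(r):
    """Fisher z-transform atanh(r), with r clipped to +/-(1 - 1e-7)."""
    r = np.clip(np.asarray(r, dtype=float), -(1 - 1e-7), 1 - 1e-7)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _edge_order(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by descending |r|, ties by (i, j)."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    absr = np.abs(r[iu, ju])
    order = np.lexsort((ju, iu, -absr))
    return iu[order], ju[order], absr[order]


def threshold_to_density(corr: CorrMatrix,
                         target_density: float) -> BinaryGraph:
    """Keep the E = round(d * n(n-1)/2) largest-|r| pairs as edges.

    Ties crossing the cut boundary are resolved deterministically by
    descending |r| then lexicographic (i, j) order, with a logged note.
    The produced edge sets are nested across increasing densities.
    """
    if not (0 < target_density <= 1):
        raise ValueError("target_density must lie in (0, 1]")
    n = corr.n_nodes
    n_pairs = n * (n - 1) // 2
    n_edges = int(round(target_density * n_pairs))
    ii, jj, absr = _edge_order(corr.r)
    if 0 < n_edges < n_pairs and absr[n_edges - 1] == absr[n_edges]:
        logger.info("tie at the density cut (|r|=%.6g); resolved by "
                    "lexicographic node order", absr[n_edges])
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:n_edges], jj[:n_edges]] = 1
    adj |= adj.T
    return BinaryGraph(adj, node_labels=list(corr.node_labels))


def sliding_windows(series: TimeSeries, width_tr: int,
                    step_tr: int = 1) -> list[TimeSeries]:
    """Consecutive overlapping windows: floor((T - width)/step) + 1 of them."""
    if width_tr > series.n_time:
        raise ValueError(f"window width {width_tr} exceeds series length "
                         f"{series.n_time}")
    if step_tr < 1:
        raise ValueError("step must be >= 1")
    n_win = (series.n_time - width_tr) // step_tr + 1
    return [series.copy_with(series.values[w * step_tr:w * step_tr + width_tr])
            for w in range(n_win)]


def dynamic_graphs(series: TimeSeries,
                   width_tr: int = DEFAULT_WINDOW_WIDTH,
                   density: float = DEFAULT_DYNAMIC_DENSITY,
                   step_tr: int = DEFAULT_WINDOW_STEP) -> DynamicGraphSeries:
    """Per-window correlation -> density threshold -> binary graph.

    Windows containing a zero-variance channel are flagged (``None`` in
    the series) rather than aborting the whole analysis.
    """
    graphs: list[BinaryGraph | None] = []
    for win in sliding_windows(series, width_tr, step_tr):
        try:
            graphs.append(threshold_to_density(correlation_matrix(win),
                                               density))
        except ValueError as exc:
            logger.warning("window flagged: %s", exc)
            graphs.append(None)
    return DynamicGraphSeries(graphs=graphs, window_width_tr=width_tr,
                              step_tr=step_tr,
                              node_labels=list(series.channel_labels))
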