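"""Putative fast-spiking (FS) vs regular-spiking (RS) classification.

Four waveform metrics per unit — spontaneous firing rate, trough-to-peak
duration, trough-to-peak ratio and trough half duration — are min-max
normalised to [0, 1], reduced by PCA to the components covering >= 95% of
the variance, and split into two clusters by Ward hierarchical clustering.
The cluster with the shorter mean trough-to-peak duration is named FS
(putative interneurons); the other RS (putative pyramidal neurons).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = ["METRIC_COLUMNS", "normalize_metrics", "classify_ei"]

METRIC_COLUMNS = [
    "spontaneous_fr",
    "trough_to_peak_s",
    "trough_to_peak_ratio",
    "trough_half_duration_s",
]
VARIANCE_SHARE = 0.95


def normalize_metrics(metrics: pd.DataFrame) -> np.ndarray:
    """Min-max normalise each metric column to [0, 1] exactly."""
    X = metrics[METRIC_COLUMNS].to_numpy(dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    return (X - lo) / span


def classify_ei(metrics: pd.DataFrame) -> pd.Series:
    """Label each unit FS or RS from its waveform metrics.

    Deterministic (Ward linkage has no randomness) and invariant to row
    order.  If all units are metrically identical a single cluster exists;
    every unit is labelled RS and the result carries a ``degenerate`` attr.
    """
    if len(metrics) < 4:
        raise ValueError("need at least 4 units to cluster")
    X = normalize_metrics(metrics)
    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        labels = pd.Series(["RS"] * len(metrics), index=metrics.index, name="ei_label")
        labels.attrs["degenerate"] = True
        return labels
    max_pc = min(X.shape)
    full = PCA(n_components=max_pc).fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, VARIANCE_SHARE - 1e-12) + 1)
    scores = PCA(n_components=min(n_keep, max_pc)).fit_transform(X)
    Z = linkage(scores, method="ward")
    clusters = fcluster(Z, t=2, criterion="maxclust")
    ttp = metrics["trough_to_peak_s"].to_numpy(dtype=float)
    means = {c: ttp[clusters == c].mean() for c in np.unique(clusters)}
    fs_cluster = min(means, key=means.get)
    labels = pd.Series(
        np.where(clusters == fs_cluster, "FS", "RS"), index=metrics.index, name="ei_label"
    )
    labels.attrs["degenerate"] = False
    return labels
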