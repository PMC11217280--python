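"""Transient / persistent light-responsiveness classification.

A unit is light-responsive when a paired two-sided permutation t-test finds
a significant difference between its baseline firing rate FR0 and either
the early-window rate FR1 (transient response) or the steady-state rate FR2
(persistent response).  Records from the three highest stimulus intensities
are pooled (up to 60 rep-level pairs); before pooling, up to 3 outlier
responses per intensity are removed from the early and steady-state records
by the scaled-MAD median rule.  Removing a rep's response record also drops
its baseline partner for that test only, preserving the pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import WindowRates
from .stats import paired_perm_ttest

__all__ = ["ResponsivenessResult", "remove_outliers", "classify_responsiveness",
           "paired_perm_ttest"]

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normal data
ALPHA = 0.05


@dataclass
class ResponsivenessResult:
    unit_id: str
    transient_p: float
    persistent_p: float
    transient_flag: bool
    persistent_flag: bool
    n_transient_pairs: int
    n_persistent_pairs: int
    classifiable: bool = True


def remove_outliers(values, max_remove: int = 3) -> np.ndarray:
    """Indices retained after removing up to ``max_remove`` median-rule outliers.

    A value is an outlier when |v - median| > 3 * 1.4826 * MAD.  If more
    than ``max_remove`` qualify, only the most extreme are removed.  With
    MAD = 0, any value differing from the median counts as an outlier
    (mirroring the common scaled-MAD implementation's degenerate case).
    Returns the retained indices (order-preserving).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need at least 4 values")
    med = np.median(v)
    dev = np.abs(v - med)
    mad = np.median(dev)
    thresh = 3.0 * MAD_SCALE * mad
    outliers = np.flatnonzero(dev > thresh)
    if len(outliers) > max_remove:
        worst = outliers[np.argsort(dev[outliers])[::-1][:max_remove]]
        outliers = worst
    keep = np.setdiff1d(np.arange(len(v)), outliers)
    return keep


def classify_responsiveness(
    rates_by_intensity: dict[float, WindowRates],
    n_highest: int = 3,
    max_outliers: int = 3,
    n_perm: int = 10_000,
    alpha: float = ALPHA,
    seed: int | None = None,
    unit_id: str = "",
) -> ResponsivenessResult:
    """Classify one unit as transiently and/or persistently light-responsive.

    Pools rep-level (FR0, FR1) and (FR0, FR2) pairs over the ``n_highest``
    intensities after per-intensity outlier removal on the response records,
    then runs a paired two-sided permutation t-test per window at
    alpha = 0.05.  Units with fewer than 6 surviving pairs in a window are
    flagged unclassifiable.
    """
    if len(rates_by_intensity) < n_highest:
        raise ValueError(f"need at least {n_highest} intensities")
    top = sorted(rates_by_intensity)[-n_highest:]

    pairs = {"transient": ([], []), "persistent": ([], [])}
    for e_log in top:
        wr = rates_by_intensity[e_log]
        for key, resp in (("transient", wr.fr1), ("persistent", wr.fr2)):
            if len(resp) >= 4:
                keep = remove_outliers(resp, max_remove=max_outliers)
            else:
                keep = np.arange(len(resp))
            pairs[key][0].append(np.asarray(wr.fr0)[keep])
            pairs[key][1].append(np.asarray(resp)[keep])

    results = {}
    ns = {}
    classifiable = True
    for key in ("transient", "persistent"):
        fr0 = np.concatenate(pairs[key][0])
        frx = np.concatenate(pairs[key][1])
        ns[key] = len(fr0)
        if len(fr0) < 6:
            classifiable = False
            results[key] = 1.0
            continue
        results[key] = paired_perm_ttest(frx, fr0, n_perm=n_perm, seed=seed).p

    return ResponsivenessResult(
        unit_id=unit_id,
        transient_p=results["transient"],
        persistent_p=results["persistent"],
        transient_flag=classifiable and results["transient"] <= alpha,
        persistent_flag=classifiable and results["persistent"] <= alpha,
        n_transient_pairs=ns["transient"],
        n_persistent_pairs=ns["persistent"],
        classifiable=classifiable,
    )
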