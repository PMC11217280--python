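"""Probe-track reconstruction and probabilistic anatomical affiliation.

After histology, the probe track is annotated as a cloud of 3-D points in a
standard brain (micrometres, AP/DV/ML axes) and a line is fitted through
them by total least squares.  Each unit is placed at its nearest recording
site on that line.  Because track annotation carries an anisotropic
uncertainty — SDs of (32, 85, 39) um along the rostral-caudal,
dorsal-ventral and medial-lateral axes — a unit's anatomical affiliation is
probabilistic: 100,000 points are drawn from an axis-aligned Gaussian around
its location and the fraction of points landing in each labelled region is
its affiliation probability.  Mass falling outside every labelled region (or
outside the volume) is reported under the reserved label ``"outside"``.

Voxel convention: coordinates are micrometres; a point p maps to voxel index
floor(p / voxel_um), 0-based, on (AP, DV, ML) axes in that order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MAPPING_SDS_UM",
    "LabelVolume",
    "ProbeTrack",
    "AffiliationProbability",
    "fit_track_line",
    "locate_units",
    "affiliation_probability",
    "incidence_per_session",
    "incidence_pooled",
    "write_label_volume",
    "read_label_volume",
]

logger = logging.getLogger(__name__)

#: annotation uncertainty (um) along (rostral-caudal, dorsal-ventral, medial-lateral)
MAPPING_SDS_UM = (32.0, 85.0, 39.0)

OUTSIDE = "outside"


@dataclass
class LabelVolume:
    """Integer-labelled 3-D volume with named regions.

    ``data`` is indexed [AP, DV, ML]; 0 is unlabelled background, positive
    integers are regions named in ``labels`` (name -> integer).
    """

    data: np.ndarray
    voxel_um: float
    labels: dict[str, int]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        self._names = {v: k for k, v in self.labels.items()}

    @property
    def extent_um(self) -> np.ndarray:
        return np.array(self.data.shape, dtype=float) * self.voxel_um

    def label_at(self, points_um: np.ndarray) -> np.ndarray:
        """Integer labels at an (n, 3) array of um coordinates; -1 = out of bounds."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        idx = np.floor(pts / self.voxel_um).astype(int)
        shape = np.array(self.data.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(pts), -1, dtype=int)
        ii = idx[inside]
        out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def name_of(self, label: int) -> str:
        return self._names.get(label, OUTSIDE)


@dataclass
class ProbeTrack:
    """A fitted probe track: point on the line plus a unit direction vector."""

    point: np.ndarray
    direction: np.ndarray
    annotation_points: np.ndarray = field(default=None)

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        self.direction = d / n

    def at(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) at arc-length offset ``s`` (um) along the line."""
        s = np.asarray(s, dtype=float)
        return self.point + np.multiply.outer(s, self.direction)


@dataclass
class AffiliationProbability:
    """Monte-Carlo affiliation of one unit with each labelled region."""

    unit_id: str
    probabilities: dict[str, float]
    n_points: int
    sds_um: tuple[float, float, float]

    def best(self) -> tuple[str, float]:
        name = max(self.probabilities, key=self.probabilities.get)
        return name, self.probabilities[name]

    def mc_se(self, name: str) -> float:
        """Binomial Monte-Carlo standard error of one probability."""
        p = self.probabilities.get(name, 0.0)
        return float(np.sqrt(p * (1 - p) / self.n_points))


def fit_track_line(points_um) -> ProbeTrack:
    """Total-least-squares 3-D line through the track annotation points.

    The line passes through the centroid along the first principal axis of
    the point cloud; its direction is oriented from the first annotation
    point towards the last (typically superficial to deep).
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least two 3-D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0):
        raise ValueError("annotation points are coincident")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(pts[-1] - pts[0], direction) < 0:
        direction = -direction
    return ProbeTrack(point=centroid, direction=direction, annotation_points=pts)


def locate_units(
    track: ProbeTrack,
    channel_offsets_um,
    unit_channels,
) -> tuple[np.ndarray, np.ndarray]:
    """Place each unit at its nearest recording site's position on the track.

    ``channel_offsets_um`` gives each site's arc-length position along the
    fitted line (um, relative to the track reference point); units are
    assigned to sites by ``unit_channels`` (channel index per unit).
    Channels whose offset lies beyond the annotated extent of the track are
    still placed (extrapolated) and flagged.

    Returns (coords (n, 3) um, extrapolated flags (n,) bool).
    """
    offsets = np.asarray(channel_offsets_um, dtype=float)
    chans = np.asarray(unit_channels, dtype=int)
    if np.any(chans < 0) or np.any(chans >= len(offsets)):
        raise IndexError("unit channel index outside the channelmap")
    s = offsets[chans]
    coords = track.at(s)
    if track.annotation_points is not None:
        proj = (track.annotation_points - track.point) @ track.direction
        lo, hi = proj.min(), proj.max()
        extrapolated = (s < lo) | (s > hi)
    else:
        extrapolated = np.zeros(len(s), dtype=bool)
    if np.any(extrapolated):
        logger.warning("locate_units: %d unit(s) placed beyond the annotated track extent",
                       int(extrapolated.sum()))
    return coords, extrapolated


def affiliation_probability(
    coord_um,
    volume: LabelVolume,
    sds_um=MAPPING_SDS_UM,
    n_points: int = 100_000,
    seed: int | None = None,
    unit_id: str = "",
) -> AffiliationProbability:
    """Monte-Carlo affiliation of a unit located at ``coord_um``.

    Draws ``n_points`` from an axis-aligned anisotropic Gaussian centred on
    the unit and reports, per region, the fraction of points whose voxel
    carries that region's label.  Probabilities over the exhaustive label
    set (regions plus "outside") sum to 1 exactly.
    """
    rng = np.random.default_rng(seed)
    coord = np.asarray(coord_um, dtype=float)
    pts = coord + rng.standard_normal((n_points, 3)) * np.asarray(sds_um, dtype=float)
    labels = volume.label_at(pts)
    probs = {name: 0.0 for name in volume.labels}
    probs[OUTSIDE] = 0.0
    values, counts = np.unique(labels, return_counts=True)
    for v, c in zip(values, counts):
        probs[volume.name_of(int(v))] = probs.get(volume.name_of(int(v)), 0.0) + c / n_points
    return AffiliationProbability(
        unit_id=unit_id, probabilities=probs, n_points=n_points, sds_um=tuple(sds_um)
    )


# ---------------------------------------------------------------------------
# incidence statistics


def incidence_per_session(units: pd.DataFrame, flag_column: str) -> pd.DataFrame:
    """Per-session fraction of flagged units, with a mean +/- SD summary row.

    ``units`` needs columns ``session_id`` and ``flag_column`` (boolean).
    Empty sessions (no units) cannot appear by construction; sessions are
    whatever groups the table contains.
    """
    if units.empty:
        raise ValueError("no units supplied")
    per = (
        units.groupby("session_id")[flag_column]
        .agg(fraction="mean", n_units="count")
        .reset_index()
    )
    per.attrs["mean"] = float(per["fraction"].mean())
    per.attrs["sd"] = float(per["fraction"].std(ddof=1)) if len(per) > 1 else 0.0
    return per


def incidence_pooled(
    units: pd.DataFrame,
    flag_column: str,
    affiliations: dict[str, AffiliationProbability],
    min_prob: float | None = None,
) -> pd.DataFrame:
    """Pooled incidence per region: flagged / identified, after hard assignment.

    Each unit is assigned to its maximum-probability region; with
    ``min_prob`` set, units whose winning probability does not exceed it are
    excluded (the standard >0.9 affiliation filter).  Units assigned to "outside" are
    dropped from regional tables.
    """
    rows = []
    for _, row in units.iterrows():
        aff = affiliations[row["unit_id"]]
        region, p = aff.best()
        if min_prob is not None and p <= min_prob:
            continue
        if region == OUTSIDE:
            continue
        rows.append({"unit_id": row["unit_id"], "region": region, "flag": bool(row[flag_column])})
    assigned = pd.DataFrame(rows, columns=["unit_id", "region", "flag"])
    if assigned.empty:
        return pd.DataFrame(columns=["region", "n_flagged", "n_total", "fraction"])
    out = (
        assigned.groupby("region")["flag"]
        .agg(n_flagged="sum", n_total="count")
        .reset_index()
    )
    out["n_flagged"] = out["n_flagged"].astype(int)
    out["fraction"] = out["n_flagged"] / out["n_total"]
    return out


# ---------------------------------------------------------------------------
# NRRD IO (via SimpleITK), with a JSON sidecar holding label names


def write_label_volume(volume: LabelVolume, path) -> None:
    import SimpleITK as sitk

    path = str(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.astype(np.int32)))
    img.SetSpacing((volume.voxel_um,) * 3)
    sitk.WriteImage(img, path)
    with open(path + ".labels.json", "w") as fh:
        json.dump(volume.labels, fh)


def read_label_volume(path) -> LabelVolume:
    import SimpleITK as sitk

    path = str(path)
    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img)
    voxel = float(img.GetSpacing()[0])
    try:
        with open(path + ".labels.json") as fh:
            labels = {k: int(v) for k, v in json.load(fh).items()}
    except FileNotFoundError:
        labels = {f"region_{v}": int(v) for v in np.unique(data) if v > 0}
    return LabelVolume(data=data, voxel_um=voxel, labels=labels)
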