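"""Cluster morphometrics for single-molecule localization microscopy fields.

STORM/PALM experiments yield tables of 2-D localizations (nm). Protein
assemblies appear as dense clusters of localizations; this module groups
them with DBSCAN and quantifies each cluster's size by the radius of
gyration R_g and its shape by the eccentricity Ecc derived from the 2x2
gyration tensor: with eigenvalues l1 >= l2,

    R_g = sqrt(l1 + l2),    Ecc = sqrt(l1 / l2)  (>= 1, 1 = circular).

Condition comparisons follow the per-experiment design: the test statistic
is an unpaired two-sided Student t on the per-experiment medians, never on
pooled localizations (pooling would treat correlated localizations of one
cell as independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from .errors import InvalidModelError

NOISE_LABEL = -1


@dataclass
class LocalizationTable:
    """2-D localizations in nm with frame indices and optional precision.

    ``df`` columns: x_nm, y_nm, frame [, precision_nm]. ``field_area_um2``
    enables per-area densities.
    """

    df: pd.DataFrame
    field_area_um2: float | None = None

    def __post_init__(self):
        required = {"x_nm", "y_nm", "frame"}
        missing = required - set(self.df.columns)
        if missing:
            raise InvalidModelError(f"localization table lacks columns {sorted(missing)}")
        xy = self.df[["x_nm", "y_nm"]].to_numpy(float)
        if len(xy) and not np.isfinite(xy).all():
            raise InvalidModelError("localization coordinates must be finite")
        if len(self.df) and (self.df["frame"].to_numpy() < 0).any():
            raise InvalidModelError("frame indices must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(float)

    @classmethod
    def from_xy(cls, xy: np.ndarray, frame=None, field_area_um2=None) -> "LocalizationTable":
        xy = np.asarray(xy, float).reshape(-1, 2)
        if frame is None:
            frame = np.zeros(len(xy), dtype=int)
        return cls(
            df=pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "frame": frame}),
            field_area_um2=field_area_um2,
        )

    @classmethod
    def read_csv(cls, path, field_area_um2=None, column_map: dict | None = None):
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns=column_map)
        return cls(df=df, field_area_um2=field_area_um2)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def cluster_localizations(
    locs: LocalizationTable, eps: float = 50.0, min_pts: int = 10
) -> np.ndarray:
    """DBSCAN labels for each localization; -1 marks noise.

    Standard DBSCAN on Euclidean x/y: a point with >= ``min_pts``
    neighbours within ``eps`` nm (itself included) is a core point. Border
    points join the cluster that first expands onto them in the
    index-ordered depth-first traversal, which makes labels deterministic
    for a fixed input order.
    """
    if eps <= 0:
        raise InvalidModelError("eps must be positive")
    if min_pts < 1:
        raise InvalidModelError("min_pts must be >= 1")
    if len(locs) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(locs.xy).labels_


@dataclass
class ClusterStats:
    """Morphometrics of one localization cluster."""

    cluster_id: int
    n_locs: int
    centroid: tuple
    rg: float
    ecc: float  # sqrt(l1/l2); inf sentinel for collinear clusters
    eigenvalues: tuple  # (l1, l2), l1 >= l2, nm^2
    degenerate: bool = False

    def ecc_alt(self) -> float:
        """Alternative eccentricity sqrt(1 - l2/l1) in [0, 1)."""
        l1, l2 = self.eigenvalues
        if l1 == 0:
            return 0.0
        return math.sqrt(1.0 - l2 / l1)


def cluster_shape(points: np.ndarray, cluster_id: int = 0) -> ClusterStats:
    """Gyration-tensor morphometrics of one cluster's points.

    The 2x2 second-moment tensor about the centroid (population
    normalisation, divisor N) has eigenvalues l1 >= l2. R_g = sqrt(l1+l2);
    Ecc = sqrt(l1/l2), reported as +inf and flagged when the points are
    collinear (l2 = 0).
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 2:
        raise InvalidModelError("cluster shape needs at least 2 points")
    centroid = pts.mean(axis=0)
    d = pts - centroid
    tensor = d.T @ d / len(pts)
    l2, l1 = np.linalg.eigvalsh(tensor)  # ascending
    l1, l2 = float(max(l1, 0.0)), float(max(l2, 0.0))
    rg = math.sqrt(l1 + l2)
    if l2 <= 0 or l1 / max(l2, 1e-300) > 1e12:
        ecc, degenerate = math.inf, True
    else:
        ecc, degenerate = math.sqrt(l1 / l2), False
    return ClusterStats(
        cluster_id=cluster_id,
        n_locs=len(pts),
        centroid=(float(centroid[0]), float(centroid[1])),
        rg=rg,
        ecc=ecc,
        eigenvalues=(l1, l2),
        degenerate=degenerate,
    )


@dataclass
class FieldSummary:
    """Whole-field cluster statistics."""

    n_clusters: int
    clusters_per_area_um2: float | None
    cluster_stats: pd.DataFrame
    noise_fraction: float
    per_cluster: list = field(default_factory=list)

    def median(self, column: str) -> float:
        return float(self.cluster_stats[column].median())


def summarize_field(
    locs: LocalizationTable,
    labels: np.ndarray,
    field_area_um2: float | None = None,
) -> FieldSummary:
    """Per-cluster stats and field-level densities for a labelled field."""
    labels = np.asarray(labels)
    if len(labels) != len(locs):
        raise InvalidModelError("labels and localizations differ in length")
    area = field_area_um2 if field_area_um2 is not None else locs.field_area_um2
    xy = locs.xy
    stats_list = []
    for cid in sorted(set(labels[labels != NOISE_LABEL].tolist())):
        stats_list.append(cluster_shape(xy[labels == cid], cluster_id=int(cid)))
    frame = pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in stats_list],
            "n_locs": [s.n_locs for s in stats_list],
            "rg_nm": [s.rg for s in stats_list],
            "ecc": [s.ecc for s in stats_list],
        }
    )
    noise_fraction = float((labels == NOISE_LABEL).mean()) if len(labels) else 0.0
    density = (len(stats_list) / area) if area else None
    return FieldSummary(
        n_clusters=len(stats_list),
        clusters_per_area_um2=density,
        cluster_stats=frame,
        noise_fraction=noise_fraction,
        per_cluster=stats_list,
    )


@dataclass
class ComparisonResult:
    """Unpaired two-sided Student t-test on per-experiment medians."""

    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def compare_conditions(medians_a, medians_b) -> ComparisonResult:
    """Compare two conditions on their per-experiment medians.

    Plain equal-variance Student t, two-sided. Inputs are one median per
    independent experiment; pooled per-cluster values are not accepted
    semantics here because clusters within an experiment are correlated.
    Zero pooled variance is handled explicitly: equal means give t = 0,
    p = 1; unequal means give |t| = inf, p = 0.
    """
    a = np.asarray(medians_a, float)
    b = np.asarray(medians_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidModelError(
            "need >= 2 experiments per condition: the unit of replication is "
            "the experiment median, not the localization"
        )
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    dof = na + nb - 2
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return ComparisonResult(
        t=float(t), p=float(p), mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=na, n_b=nb,
    )
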