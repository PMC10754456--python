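"""Clustering of expansion profiles into shape subgroups.

Profiles are interpolated onto a uniform arbitrary timeline of 1..1000,
centred and scaled to unit SD per curve, clustered by Euclidean k-means
with restarts, and the number of clusters chosen with the
Calinski–Harabasz criterion (optionally overridden by a shape-coverage
rule). Cluster names — Convex, Peak, Increase, Paused Start — are assigned
by correlating cluster mean curves with analytic shape templates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

GRID = np.arange(1, 1001, dtype=float)
CH_CAP = 1e12      # sentinel for perfectly separated clusters (W = 0)


def _shape_templates() -> dict[str, np.ndarray]:
    x = np.linspace(0.0, 1.0, len(GRID))
    raw = {
        "Convex": (x - 0.5) ** 2,
        "Peak": -((x - 0.5) ** 2),
        "Increase": x,
        "Paused Start": np.maximum(0.0, x - 0.5),
    }
    return {k: (v - v.mean()) / v.std() for k, v in raw.items()}


@dataclass
class StandardizedCurve:
    sample: str
    values: np.ndarray     # length 1000, mean 0, SD 1

    def __post_init__(self) -> None:
        assert abs(self.values.mean()) < 1e-9
        assert abs(self.values.std() - 1.0) < 1e-9


def standardize_profiles(profiles: dict[str, tuple[np.ndarray, np.ndarray]]
                         ) -> list[StandardizedCurve]:
    """Interpolate each (t, y) profile onto the 1..1000 grid, centre and
    scale to unit SD. Constant profiles are excluded with a warning."""
    out = []
    for sample, (t, y) in profiles.items():
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(t) < 3:
            raise ValueError(f"{sample}: need >= 3 points")
        grid_t = np.linspace(t[0], t[-1], len(GRID))
        v = np.interp(grid_t, t, y)
        sd = v.std()
        if sd == 0:
            warnings.warn(f"{sample}: constant profile excluded")
            continue
        v = (v - v.mean()) / sd
        # one exact re-centring pass guards against float drift
        v = (v - v.mean()) / v.std()
        out.append(StandardizedCurve(sample=sample, values=v))
    return out


@dataclass
class CurvePartition:
    k: int
    samples: tuple[str, ...]
    labels: np.ndarray
    means: np.ndarray              # (k, 1000)
    inertia: float
    ch: float | None = None
    cluster_names: tuple[str, ...] | None = None
    rationale: str | None = None


def kmeans_curves(curves: list[StandardizedCurve],
                  k_candidates=range(2, 7), restarts: int = 5,
                  seed: int = 0) -> dict[int, CurvePartition]:
    """Euclidean k-means on the 1000-point standardized vectors.

    ``restarts`` random initialisations per k; the run with the lowest
    within-cluster sum of squares is retained; deterministic under seed.
    Candidate k exceeding the sample count are skipped with a warning.
    """
    X = np.vstack([c.values for c in curves])
    samples = tuple(c.sample for c in curves)
    out: dict[int, CurvePartition] = {}
    for k in k_candidates:
        if k > len(curves):
            warnings.warn(f"k={k} exceeds the number of curves; skipped")
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                    init="random").fit(X)
        part = CurvePartition(k=k, samples=samples, labels=km.labels_.copy(),
                              means=km.cluster_centers_.copy(),
                              inertia=float(km.inertia_))
        part.ch = calinski_harabasz(X, part.labels)
        out[k] = part
    return out


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH = [B/(k-1)] / [W/(n-k)]: between- over within-cluster dispersion.

    Perfect separation (W = 0) is reported as the capped sentinel CH_CAP.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    k, n = len(ks), len(X)
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    grand = X.mean(axis=0)
    B = W = 0.0
    for c in ks:
        pts = X[labels == c]
        if len(pts) == 0:
            raise ValueError(f"cluster {c} is empty")
        mu = pts.mean(axis=0)
        B += len(pts) * float(np.sum((mu - grand) ** 2))
        W += float(np.sum((pts - mu) ** 2))
    if W == 0:
        return CH_CAP
    return (B / (k - 1)) / (W / (n - k))


def name_clusters(partition: CurvePartition) -> CurvePartition:
    """Assign shape names by maximal correlation of cluster means with the
    analytic templates (one-to-one, Hungarian assignment on -correlation)."""
    templates = _shape_templates()
    names = list(templates)
    corr = np.zeros((partition.k, len(names)))
    for i in range(partition.k):
        m = partition.means[i]
        ms = (m - m.mean()) / (m.std() if m.std() > 0 else 1.0)
        for j, nm in enumerate(names):
            corr[i, j] = float(np.mean(ms * templates[nm]))
    if partition.k <= len(names):
        rows, cols = linear_sum_assignment(-corr)
        assigned = {r: names[c] for r, c in zip(rows, cols)}
    else:
        assigned = {i: names[int(np.argmax(corr[i]))] for i in range(partition.k)}
    partition.cluster_names = tuple(assigned[i] for i in range(partition.k))
    return partition


def covered_shapes(partition: CurvePartition, min_corr: float = 0.7) -> set[str]:
    """Shape templates represented by at least one cluster mean (by
    correlation >= min_corr)."""
    templates = _shape_templates()
    covered = set()
    for i in range(partition.k):
        m = partition.means[i]
        sd = m.std()
        if sd == 0:
            continue
        ms = (m - m.mean()) / sd
        for nm, tpl in templates.items():
            if float(np.mean(ms * tpl)) >= min_corr:
                covered.add(nm)
    return covered


def select_partition(partitions: dict[int, CurvePartition],
                     reference_shapes: set[str] | None = None,
                     ch_tolerance: float = 0.10) -> CurvePartition:
    """Choose k: argmax CH by default; with reference shapes, prefer the
    smallest k within ``ch_tolerance`` of the maximal CH whose clusters
    cover every reference shape. The decision is recorded in
    ``rationale``."""
    if not partitions:
        raise ValueError("no candidate partitions")
    by_ch = max(partitions.values(), key=lambda p: p.ch)
    if not reference_shapes:
        by_ch.rationale = f"argmax CH ({by_ch.ch:.3f}) at k={by_ch.k}"
        return by_ch
    threshold = by_ch.ch * (1.0 - ch_tolerance)
    for k in sorted(partitions):
        p = partitions[k]
        if p.ch >= threshold and reference_shapes <= covered_shapes(p):
            p.rationale = (f"k={p.k} chosen: CH {p.ch:.3f} within "
                           f"{ch_tolerance:.0%} of max {by_ch.ch:.3f} and covers "
                           f"shapes {sorted(reference_shapes)}")
            logger.info(p.rationale)
            return p
    by_ch.rationale = (f"no candidate within {ch_tolerance:.0%} of max CH covers "
                       f"{sorted(reference_shapes)}; argmax CH k={by_ch.k} retained")
    return by_ch
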