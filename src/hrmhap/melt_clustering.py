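"""Cluster normalized melt curves into putative haplotype groups.

The instrument software this emulates exposes three settings: a delta-Tm
threshold (0.05 degC), a curve-shape similarity threshold (70%) and a
temperature-correction allowance (20 grid increments).  Its algorithm is
proprietary, so this module implements an order-independent agglomerative
scheme with the same semantics: two wells may end up in one cluster only if
their melt peaks differ by at most the delta-Tm threshold AND their
normalized curve shapes agree to at least the similarity threshold after an
optimal horizontal alignment of at most the allowed number of grid steps.
Complete linkage makes both constraints hold pairwise across every cluster
and makes the cluster count monotone non-increasing in the delta-Tm
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

from .melt_model import MeltFeatures

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "DifferenceCurve",
    "difference_curves",
    "cluster_curves",
    "cluster_by_group",
    "shape_similarity",
]

_INFEASIBLE = np.inf


@dataclass(frozen=True)
class ClusteringConfig:
    """Settings mirroring the instrument's published clustering knobs.

    delta_tm_threshold: maximum melt-peak gap (degC) within a cluster.
    shape_similarity_threshold: minimum curve-shape similarity, as a
        fraction, where similarity = 1 - mean squared difference of the
        normalized curves over the melt window.
    temperature_correction_steps: maximum horizontal shift (grid increments)
        allowed when comparing shapes, absorbing plate-position temperature
        bias; 0 disables the correction.
    """

    delta_tm_threshold: float = 0.05
    shape_similarity_threshold: float = 0.70
    temperature_correction_steps: int = 20
    reference_selection: str = "largest_cluster_medoid"

    def __post_init__(self) -> None:
        if self.delta_tm_threshold <= 0:
            raise ValueError("delta_tm_threshold must be > 0")
        if not 0 < self.shape_similarity_threshold <= 1:
            raise ValueError("shape_similarity_threshold must be in (0, 1]")
        if self.temperature_correction_steps < 0:
            raise ValueError("temperature_correction_steps must be >= 0")


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of wells into dense integer-labelled clusters (1..k)."""

    group_id: str
    labels: dict[Hashable, int]

    @property
    def cluster_labels(self) -> list[int]:
        return sorted(set(self.labels.values()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[Hashable]:
        return sorted((k for k, v in self.labels.items() if v == label), key=str)


@dataclass(frozen=True)
class DifferenceCurve:
    """Normalized fluorescence difference of a well against a reference well."""

    well: Hashable
    reference: Hashable
    temperatures: np.ndarray
    delta_fluorescence: np.ndarray


def _common_grid(features: Mapping[Hashable, MeltFeatures]) -> np.ndarray:
    lo = max(f.normalized.temperatures[0] for f in features.values())
    hi = min(f.normalized.temperatures[-1] for f in features.values())
    step = min(f.normalized.step for f in features.values())
    if hi <= lo:
        raise ValueError("curves share no overlapping temperature range")
    return np.arange(lo, hi + step / 2, step)


def _resample(features: MeltFeatures, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, features.normalized.temperatures, features.normalized.fluorescence)


def shape_similarity(
    a: np.ndarray,
    b: np.ndarray,
    max_shift: int = 0,
    window: slice | None = None,
) -> float:
    """Curve-shape similarity: 1 - mean squared difference, shift-optimized.

    The second curve may slide by up to ``max_shift`` grid increments in
    either direction; the best (highest) similarity over the allowed shifts
    is returned.  Values are fractions in (-inf, 1]; identical curves give 1.
    """
    if window is None:
        window = slice(None)
    best = -np.inf
    n = len(a)
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            aa, bb = a[shift:], b[: n - shift]
        else:
            aa, bb = a[: n + shift], b[-shift:]
        sub_a = aa[window]
        sub_b = bb[window]
        m = min(len(sub_a), len(sub_b))
        if m == 0:
            continue
        mse = float(np.mean((sub_a[:m] - sub_b[:m]) ** 2))
        best = max(best, 1.0 - mse)
    return best


def difference_curves(
    features: Mapping[Hashable, MeltFeatures],
    reference: Hashable,
) -> list[DifferenceCurve]:
    """Difference plots: each well's normalized curve minus the reference's.

    All curves are resampled to a common temperature grid first.  The
    reference well's own difference curve is identically zero.
    """
    if reference not in features:
        raise KeyError(f"reference well {reference!r} not in collection")
    grid = _common_grid(features)
    ref = _resample(features[reference], grid)
    out = []
    for key in features:
        delta = _resample(features[key], grid) - ref
        if key == reference:
            delta = np.zeros_like(delta)
        out.append(DifferenceCurve(well=key, reference=reference, temperatures=grid, delta_fluorescence=delta))
    return out


def _pairwise_dissimilarity(
    features: Mapping[Hashable, MeltFeatures],
    config: ClusteringConfig,
) -> tuple[list[Hashable], np.ndarray]:
    """Delta-Tm where the shape criterion is met, +inf where it is not."""
    keys = sorted(features, key=str)
    grid = _common_grid(features)
    tms = np.array([features[k].tm for k in keys])
    curves = np.vstack([_resample(features[k], grid) for k in keys])
    # melt window for shape comparison: [tm_min - 2, tm_max + 2]
    lo = max(grid[0], tms.min() - 2.0)
    hi = min(grid[-1], tms.max() + 2.0)
    idx = np.where((grid >= lo) & (grid <= hi))[0]
    window = slice(int(idx[0]), int(idx[-1]) + 1) if len(idx) else slice(None)
    n = len(keys)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = shape_similarity(
                curves[i], curves[j], config.temperature_correction_steps, window
            )
            if sim >= config.shape_similarity_threshold:
                d[i, j] = d[j, i] = abs(tms[i] - tms[j])
            else:
                d[i, j] = d[j, i] = _INFEASIBLE
    return keys, d


def cluster_curves(
    features: Mapping[Hashable, MeltFeatures],
    config: ClusteringConfig = ClusteringConfig(),
    group_id: str = "all",
) -> ClusterAssignment:
    """Complete-linkage agglomeration under the dual Tm/shape criterion.

    Merging proceeds greedily on the smallest complete-linkage distance;
    ties break on the canonical (sorted well id) order, so the partition is
    invariant to input ordering.  Cluster labels are dense, ordered by
    cluster size (largest first) then by smallest member id.
    """
    if not features:
        raise ValueError("empty well group")
    keys, d = _pairwise_dissimilarity(features, config)
    n = len(keys)
    clusters: list[list[int]] = [[i] for i in range(n)]

    def linkage(a: list[int], b: list[int]) -> float:
        return max(d[i, j] for i in a for j in b)

    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...], int, int] | None = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dist = linkage(clusters[x], clusters[y])
                if dist > config.delta_tm_threshold:
                    continue
                tag = (
                    dist,
                    tuple(str(keys[i]) for i in sorted(clusters[x])),
                    tuple(str(keys[i]) for i in sorted(clusters[y])),
                    x,
                    y,
                )
                if best is None or tag[:3] < best[:3]:
                    best = tag
        if best is None:
            break
        _, _, _, x, y = best
        clusters[x] = sorted(clusters[x] + clusters[y])
        del clusters[y]

    clusters.sort(key=lambda c: (-len(c), str(keys[min(c)])))
    labels: dict[Hashable, int] = {}
    for lab, members in enumerate(clusters, start=1):
        for i in members:
            labels[keys[i]] = lab
    return ClusterAssignment(group_id=group_id, labels=labels)


def cluster_by_group(
    features: Mapping[Hashable, MeltFeatures],
    grouping: Mapping[Hashable, str],
    config: ClusteringConfig = ClusteringConfig(),
) -> list[ClusterAssignment]:
    """Cluster wells independently per group (normally per population).

    Labels are local to each group, mirroring instrument "well group"
    analysis where each population is clustered on its own.
    """
    missing = [k for k in features if k not in grouping or not grouping[k]]
    if missing:
        raise ValueError(f"wells missing a group/population id: {sorted(map(str, missing))[:5]}")
    groups: dict[str, dict[Hashable, MeltFeatures]] = {}
    for k, feat in features.items():
        groups.setdefault(grouping[k], {})[k] = feat
    return [
        cluster_curves(members, config, group_id=gid)
        for gid, members in sorted(groups.items())
    ]
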