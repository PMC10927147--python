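"""Distance-based MOTU delimitation.

Two operations: clustering at a fixed K2P threshold, and an automatic scan
that picks the threshold maximising the barcode gap of the induced partition.

Clustering is single linkage: specimens share a MOTU iff they are connected by
a chain of pairs each within the threshold.  Single linkage is the natural
choice for barcode data — BIN/ABGD-family methods are connectivity based —
and it makes the refinement property exact: the partition at a smaller
threshold always refines the partition at a larger one.

The scan scores each candidate threshold by the barcode gap of the induced
partition,

    score(t) = (min between-MOTU distance) - (max within-MOTU chain distance),

where both sides are measured on the single-linkage scale: the between term
is the smallest distance joining two MOTUs, the within term the largest merge
height used inside any MOTU (the largest link of the chain holding a MOTU
together).  Measuring cohesion by chain rather than by cluster diameter keeps
the score meaningful when two species share a haplotype: such a cluster
necessarily spans interspecific divergence end to end, but its chain is held
together by short links, so one sharing pair does not wipe out the gap signal
for the whole library.  Because the partition (hence the score) only changes
at single-linkage merge heights, the scan evaluates each distinct partition
once even when the candidate grid is dense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .io_model import BarcodeAuditError, BarcodeDataset, MotuPartition

__all__ = ["threshold_cluster", "ThresholdScan", "scan_thresholds", "per_group_scan"]

logger = logging.getLogger(__name__)

# Saturated / no-overlap pairs never join a cluster at any plausible K2P
# threshold: treated as effectively infinite distance.
_INF_DISTANCE = 1e12


def _effective(d: np.ndarray) -> np.ndarray:
    out = d.copy()
    out[np.isnan(out)] = _INF_DISTANCE
    return out


def _labels_by_first_appearance(component: np.ndarray) -> list[str]:
    """Map component indices to 'M<k>' labels ordered by first specimen."""
    order: dict[int, int] = {}
    labels = []
    for comp in component:
        if comp not in order:
            order[comp] = len(order) + 1
        labels.append(f"M{order[comp]}")
    return labels


def threshold_cluster(
    dm: DistanceMatrix, t: float, method_name: str | None = None
) -> MotuPartition:
    """Single-linkage clustering of specimens at distance threshold ``t``.

    Specimens i, j share a MOTU iff connected by a chain of pairs with
    d <= t.  Labels are ``M1, M2, ...`` in order of first specimen
    appearance, so output is stable under re-runs.
    """
    if t < 0:
        raise BarcodeAuditError("threshold must be >= 0")
    d = _effective(dm.d)
    adj = csr_matrix(d <= t)
    _, comp = connected_components(adj, directed=False)
    labels = _labels_by_first_appearance(comp)
    return MotuPartition(
        method_name=method_name or f"threshold@{t:g}",
        assignment=dict(zip(dm.ids, labels)),
        threshold=float(t),
    )


@dataclass
class ThresholdScan:
    """Result of a threshold scan.

    ``thresholds``, ``n_motus`` and ``scores`` are aligned arrays over the
    candidate grid; degenerate candidates (single MOTU or all singletons)
    carry score ``-inf``.  ``degenerate`` is set when no candidate produced a
    non-degenerate partition and the single-MOTU fallback was returned.
    """

    thresholds: np.ndarray
    n_motus: np.ndarray
    scores: np.ndarray
    best_threshold: float
    best_partition: MotuPartition
    degenerate: bool = False


def _merge_profile(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-linkage merge heights plus per-step gap-score ingredients.

    Returns ``(heights, max_within, min_between)`` where index k describes the
    partition after k merges: ``max_within[k]`` is the largest merge height
    used inside a cluster (chain cohesion) and ``min_between[k]`` the
    smallest between-cluster distance, which under single linkage equals the
    next merge height.
    """
    n = len(dm)
    d = _effective(dm.d)
    iu = np.triu_indices(n, k=1)
    Z = linkage(d[iu], method="single")
    heights = Z[:, 2]
    max_within = np.concatenate([[0.0], heights])
    min_between = np.append(heights, np.inf)
    return heights, max_within, min_between


def scan_thresholds(
    dm: DistanceMatrix, grid: Sequence[float] | None = None
) -> ThresholdScan:
    """Pick the clustering threshold maximising the partition's barcode gap.

    The default candidate grid is 0 plus the midpoints between consecutive
    distinct pairwise distances.  Ties in score are broken by larger
    threshold, then by fewer MOTUs.  If every candidate is degenerate (all
    distances identical, or all sequences identical) the single-MOTU
    partition is returned with ``degenerate=True``.
    """
    n = len(dm)
    if n < 2:
        raise BarcodeAuditError("threshold scan requires >= 2 specimens")
    heights, max_within, min_between = _merge_profile(dm)
    if grid is None:
        iu = np.triu_indices(n, k=1)
        finite = dm.d[iu]
        finite = np.unique(finite[~np.isnan(finite)])
        mids = (finite[:-1] + finite[1:]) / 2.0 if finite.size > 1 else np.array([])
        cands = np.concatenate([[0.0], mids])
    else:
        cands = np.asarray(sorted(set(float(t) for t in grid)))
        if (cands < 0).any():
            raise BarcodeAuditError("grid thresholds must be >= 0")
    # Partition index after all merges with height <= t.
    ks = np.searchsorted(heights, cands, side="right")
    n_motus = n - ks
    scores = min_between[ks] - max_within[ks]
    degenerate_mask = (n_motus == 1) | (n_motus == n)
    scores = np.where(degenerate_mask, -np.inf, scores)

    if np.all(np.isinf(scores) & (scores < 0)):
        logger.warning("threshold scan degenerate: returning single-MOTU partition")
        t_all = float(heights[-1]) if np.isfinite(heights[-1]) else _INF_DISTANCE
        part = threshold_cluster(dm, t_all, method_name="scan")
        return ThresholdScan(
            thresholds=cands,
            n_motus=n_motus,
            scores=scores,
            best_threshold=t_all,
            best_partition=part,
            degenerate=True,
        )
    order = sorted(
        range(len(cands)),
        key=lambda i: (scores[i], cands[i], -n_motus[i]),
    )
    best = order[-1]
    best_t = float(cands[best])
    part = threshold_cluster(dm, best_t, method_name="scan")
    return ThresholdScan(
        thresholds=cands,
        n_motus=n_motus,
        scores=scores,
        best_threshold=best_t,
        best_partition=part,
    )


def per_group_scan(
    dataset: BarcodeDataset,
    dm: DistanceMatrix,
    group_by: str = "subfamily",
) -> dict[str, ThresholdScan]:
    """Run an independent threshold scan within each metadata group.

    Mirrors per-subfamily delimitation runs, which can settle on different
    thresholds in different clades.  Groups with fewer than two specimens are
    skipped with a warning.
    """
    if group_by not in ("subfamily", "region", "species"):
        raise BarcodeAuditError(f"unknown grouping field {group_by!r}")
    groups: dict[str, list[str]] = {}
    for rec in dataset.records:
        key = getattr(rec, group_by)
        groups.setdefault(key, []).append(rec.specimen_id)
    out: dict[str, ThresholdScan] = {}
    for name in sorted(groups):
        ids = groups[name]
        if len(ids) < 2:
            logger.warning("group %r has < 2 specimens; skipped", name)
            continue
        out[name] = scan_thresholds(dm.submatrix(ids))
    return out
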