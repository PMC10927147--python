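"""Kimura two-parameter distances and barcode-gap statistics.

The K2P model corrects observed divergence for multiple hits while allowing
transitions (A<->G, C<->T) and transversions to occur at different rates:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the proportions of sites differing by a transition and a
transversion, respectively, among the comparable sites of a pair.  Sites where
either sequence carries a gap or an ambiguity code are deleted pairwise.

Distances are stored as proportions throughout; report writers convert to
percent only at the output boundary.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import BarcodeAuditError, BarcodeDataset

__all__ = [
    "SATURATED",
    "UNDEFINED",
    "k2p",
    "DistanceMatrix",
    "distance_matrix",
    "SpeciesSummary",
    "species_summaries",
    "BarcodeGapReport",
    "barcode_gap_report",
]

logger = logging.getLogger(__name__)


class _Marker:
    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return self._name


#: Distance undefined because 1-2P-Q <= 0 or 1-2Q <= 0 (log-domain violation).
SATURATED = _Marker("SATURATED")
#: Distance undefined because the pair shares no comparable site.
UNDEFINED = _Marker("UNDEFINED")

# Base encoding: A=0, G=1 (purines), C=2, T=3 (pyrimidines); code >> 1 gives
# the chemical class, so a substitution is a transition iff the classes match.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes; anything outside A/C/G/T -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(
    n_sites: float, n_ts: float, n_tv: float
) -> float | _Marker:
    if n_sites == 0:
        return UNDEFINED
    P = n_ts / n_sites
    Q = n_tv / n_sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return SATURATED
    return -0.5 * float(np.log(a)) - 0.25 * float(np.log(b)) + 0.0  # avoid -0.0


def k2p(seq_a: str, seq_b: str) -> tuple[float | _Marker, int]:
    """K2P distance between two aligned sequences with pairwise deletion.

    Returns ``(distance, comparable_sites)``.  ``distance`` is a proportion,
    or :data:`SATURATED` when the correction is undefined, or
    :data:`UNDEFINED` when no site is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise BarcodeAuditError(
            f"sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    valid = (a != 255) & (b != 255)
    n_sites = int(valid.sum())
    diff = valid & (a != b)
    transitions = int((diff & ((a >> 1) == (b >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    return _k2p_from_counts(n_sites, transitions, transversions), n_sites


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair comparable-site counts.

    ``d`` holds proportions with ``nan`` marking pairs that are saturated or
    have no comparable sites; ``saturated`` lists the saturated pairs so the
    two cases stay distinguishable (undefined pairs have ``sites == 0``).
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray
    saturated: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise BarcodeAuditError("distance/site matrices must be n x n")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = self.index()
        pos = [idx[sid] for sid in ids]
        sat = frozenset(
            (a, b) for (a, b) in self.saturated if a in set(ids) and b in set(ids)
        )
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(pos, pos)].copy(),
            sites=self.sites[np.ix_(pos, pos)].copy(),
            saturated=sat,
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]


def distance_matrix(dataset: BarcodeDataset) -> DistanceMatrix:
    """All-pairs K2P distance matrix for a dataset.

    Computed blockwise with one-hot base indicators and matrix products so
    libraries of a few thousand sequences remain tractable; saturated and
    no-overlap pairs are recorded, not fatal.
    """
    if len(dataset) < 2:
        raise BarcodeAuditError("distance matrix requires at least 2 records")
    ids = dataset.ids
    codes = np.stack([encode_sequence(r.sequence) for r in dataset.records])
    n = codes.shape[0]
    valid = (codes != 255).astype(np.float32)
    onehot = [(codes == c).astype(np.float32) for c in range(4)]  # A G C T

    sites = valid @ valid.T
    matches = sum(x @ x.T for x in onehot)
    ts_half = onehot[0] @ onehot[1].T + onehot[2] @ onehot[3].T  # A->G, C->T
    transitions = ts_half + ts_half.T
    transversions = sites - matches - transitions

    sites_i = np.rint(sites).astype(np.int64)
    transitions = np.rint(transitions)
    transversions = np.rint(transversions)

    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(sites_i > 0, transitions / np.maximum(sites_i, 1), 0.0)
        Q = np.where(sites_i > 0, transversions / np.maximum(sites_i, 1), 0.0)
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where((a > 0) & (b > 0), -0.5 * np.log(np.maximum(a, 1e-300))
                     - 0.25 * np.log(np.maximum(b, 1e-300)), np.nan)
    d = np.where(sites_i > 0, d, np.nan)
    np.fill_diagonal(d, 0.0)
    d = np.asarray((d + d.T) / 2.0, dtype=np.float64) + 0.0  # symmetrise; kill -0.0

    sat_mask = (sites_i > 0) & ((a <= 0) | (b <= 0))
    np.fill_diagonal(sat_mask, False)
    sat_pairs = frozenset(
        (ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(sat_mask, k=1)))
    )
    if sat_pairs:
        logger.warning("%d sequence pairs are saturated (K2P undefined)", len(sat_pairs))
    return DistanceMatrix(ids=list(ids), d=d, sites=sites_i, saturated=sat_pairs)


@dataclass
class SpeciesSummary:
    """Per-species distance summary.

    ``mean_intra``/``max_intra`` are defined only for species with more than
    one specimen; ``gap`` is True when the species' nearest-neighbour distance
    strictly exceeds its maximum intraspecific distance.
    """

    species: str
    n: int
    mean_intra: float | None
    max_intra: float | None
    min_nn: float
    nn_species: str
    nn_ties: tuple[str, ...] = ()
    gap: bool | None = None
    n_excluded_pairs: int = 0


def species_summaries(
    dm: DistanceMatrix, species_map: Mapping[str, str]
) -> list[SpeciesSummary]:
    """Mean/max intraspecific and minimum nearest-neighbour distances.

    min.NN is specimen-level: the smallest distance from any sequence of the
    focal species to the most similar sequence of any other species.
    Saturated/no-overlap pairs are excluded from every aggregate and counted
    in ``n_excluded_pairs``.  Ties for the nearest neighbour are broken by
    lexicographic species name, with all tied species reported.
    """
    missing = [sid for sid in dm.ids if sid not in species_map]
    if missing:
        raise BarcodeAuditError(f"no species for specimens {missing[:5]}")
    species_arr = np.array([species_map[sid] for sid in dm.ids])
    all_species = sorted({str(sp) for sp in species_arr})
    if len(all_species) < 2:
        raise BarcodeAuditError(
            "species summaries need >= 2 species (no nearest neighbour otherwise)"
        )
    d = dm.d
    summaries: list[SpeciesSummary] = []
    for sp in all_species:
        mask = species_arr == sp
        n = int(mask.sum())
        intra = d[np.ix_(mask, mask)][np.triu_indices(n, k=1)] if n > 1 else np.array([])
        inter = d[np.ix_(mask, ~mask)]
        n_excluded = int(np.isnan(intra).sum()) + int(np.isnan(inter).sum())
        intra = intra[~np.isnan(intra)]
        mean_intra = float(np.mean(intra)) if intra.size else None
        max_intra = float(np.max(intra)) if intra.size else None
        inter_flat = inter.copy()
        other_species = species_arr[~mask]
        finite = ~np.isnan(inter_flat)
        if not finite.any():
            raise BarcodeAuditError(
                f"species {sp!r}: no finite interspecific distance"
            )
        min_nn = float(np.nanmin(inter_flat))
        at_min = np.isclose(inter_flat, min_nn, rtol=0.0, atol=1e-15) & finite
        tied = sorted({str(s) for s in other_species[np.any(at_min, axis=0)]})
        gap = None if max_intra is None else bool(min_nn > max_intra)
        summaries.append(
            SpeciesSummary(
                species=sp,
                n=n,
                mean_intra=mean_intra,
                max_intra=max_intra,
                min_nn=min_nn,
                nn_species=tied[0],
                nn_ties=tuple(tied),
                gap=gap,
                n_excluded_pairs=n_excluded,
            )
        )
    return summaries


@dataclass
class BarcodeGapReport:
    """Distribution statistics over species summaries.

    Each entry of ``stats`` maps a statistic name (``mean_intra``,
    ``max_intra``, ``min_nn``) to its min/max/mean/median over the species for
    which it is defined.  ``proportion_with_gap`` is computed over species
    with a defined gap flag (n > 1); ``below_threshold`` lists species whose
    min.NN falls below ``nn_threshold``.
    """

    stats: dict[str, dict[str, float]]
    n_species: int
    n_with_gap_defined: int
    proportion_with_gap: float
    nn_threshold: float
    below_threshold: list[str]


def barcode_gap_report(
    summaries: Sequence[SpeciesSummary], nn_threshold: float = 0.02
) -> BarcodeGapReport:
    """Aggregate barcode-gap statistics over a set of species summaries."""
    if not summaries:
        raise BarcodeAuditError("barcode_gap_report needs at least one summary")

    def describe(values: list[float]) -> dict[str, float]:
        if not values:
            return {}
        return {
            "min": min(values),
            "max": max(values),
            "mean": statistics.fmean(values),
            "median": statistics.median(values),
        }

    stats = {
        "mean_intra": describe([s.mean_intra for s in summaries if s.mean_intra is not None]),
        "max_intra": describe([s.max_intra for s in summaries if s.max_intra is not None]),
        "min_nn": describe([s.min_nn for s in summaries]),
    }
    with_gap = [s for s in summaries if s.gap is not None]
    proportion = (
        sum(1 for s in with_gap if s.gap) / len(with_gap) if with_gap else float("nan")
    )
    below = sorted(s.species for s in summaries if s.min_nn < nn_threshold)
    return BarcodeGapReport(
        stats=stats,
        n_species=len(summaries),
        n_with_gap_defined=len(with_gap),
        proportion_with_gap=proportion,
        nn_threshold=nn_threshold,
        below_threshold=below,
    )
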