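"""Morphospecies <-> MOTU congruence analysis.

Given a MOTU partition (computed or imported) and the morphospecies
assignment of each specimen, every species falls into one or more of three
categories:

* UNIQUE (category 1): all its specimens form one MOTU private to the species;
* SHARE (category 0): some MOTU holding its specimens also holds specimens of
  another species;
* SPLIT (category k >= 2): its specimens are distributed over k MOTUs.

Splitting and sharing are orthogonal — a species can be both, so the three
category counts may sum to more than the number of species.  The module also
compares partitions from different delimitation methods and emits the case
tables (shared MOTUs with pairwise minimum distances; deep-split species)
used to audit a reference library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io_model import BarcodeAuditError, MotuPartition

__all__ = [
    "SpeciesCongruence",
    "classify",
    "AgreementRecord",
    "agreement",
    "split_case_table",
    "share_case_table",
    "motus_per_species_by_subset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesCongruence:
    """Congruence classification of one species under one method.

    ``category`` follows the 0/1/k coding: 0 = sharing only, 1 = congruent
    (unique MOTU), k >= 2 = split into k MOTUs; ``shares`` is orthogonal to
    splitting.
    """

    species: str
    method_name: str
    n_motus: int
    shares: bool
    category: int


def _species_groups(
    partition: MotuPartition, species_map: Mapping[str, str]
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """(species -> labels of its specimens, label -> species present)."""
    missing = sorted(partition.domain - set(species_map))
    if missing:
        raise BarcodeAuditError(
            f"partition {partition.method_name!r}: specimens without species: "
            f"{missing[:5]}"
        )
    labels_of: dict[str, set[str]] = {}
    species_in: dict[str, set[str]] = {}
    for sid, label in partition.assignment.items():
        sp = species_map[sid]
        labels_of.setdefault(sp, set()).add(label)
        species_in.setdefault(label, set()).add(sp)
    return labels_of, species_in


def classify(
    partition: MotuPartition, species_map: Mapping[str, str]
) -> tuple[list[SpeciesCongruence], dict[str, int | dict[int, int]]]:
    """Classify every species of the partition's domain as unique/share/split.

    Returns the per-species records (sorted by species name) and method
    totals.  ``n_share`` and ``n_split`` may double-count species that both
    share and split; ``split_arity`` breaks the split species down by the
    number of MOTUs they fall into.
    """
    if not partition.assignment:
        raise BarcodeAuditError("cannot classify an empty partition")
    labels_of, species_in = _species_groups(partition, species_map)
    records: list[SpeciesCongruence] = []
    for sp in sorted(labels_of):
        labels = labels_of[sp]
        n_motus = len(labels)
        shares = any(len(species_in[lab]) > 1 for lab in labels)
        category = n_motus if n_motus >= 2 else (0 if shares else 1)
        records.append(
            SpeciesCongruence(
                species=sp,
                method_name=partition.method_name,
                n_motus=n_motus,
                shares=shares,
                category=category,
            )
        )
    split_arity = Counter(r.n_motus for r in records if r.n_motus >= 2)
    totals: dict[str, int | dict[int, int]] = {
        "n_species": len(records),
        "n_motus_total": partition.n_motus(),
        "n_unique": sum(1 for r in records if r.category == 1),
        "n_share": sum(1 for r in records if r.shares),
        "n_split": sum(1 for r in records if r.n_motus >= 2),
        "n_both": sum(1 for r in records if r.shares and r.n_motus >= 2),
        "split_arity": dict(sorted(split_arity.items())),
    }
    return records, totals


@dataclass(frozen=True)
class AgreementRecord:
    """Per-species agreement flags between delimitation methods."""

    species: str
    pairwise: dict[tuple[str, str], bool]
    all_methods: bool


def _signatures(
    partition: MotuPartition, species_map: Mapping[str, str], domain: set[str]
) -> dict[str, tuple[frozenset, frozenset]]:
    """Canonical per-species description of how a method treats each species.

    Two methods agree on a species iff (a) they induce the same set partition
    of its specimens and (b) the same multiset of heterospecific specimens
    (identified by their species) co-occurs with it across its MOTUs.
    """
    groups: dict[str, dict[str, set[str]]] = {}  # species -> label -> members
    label_species: dict[str, Counter] = {}  # label -> species counts in label
    for sid in domain:
        sp = species_map[sid]
        label = partition.assignment[sid]
        groups.setdefault(sp, {}).setdefault(label, set()).add(sid)
        label_species.setdefault(label, Counter())[sp] += 1
    out: dict[str, tuple[frozenset, frozenset]] = {}
    for sp, by_label in groups.items():
        cooccur: Counter = Counter()
        for label in by_label:
            for other_sp, count in label_species[label].items():
                if other_sp != sp:
                    cooccur[other_sp] += count
        sub_partition = frozenset(frozenset(m) for m in by_label.values())
        out[sp] = (sub_partition, frozenset(cooccur.items()))
    return out


def agreement(
    partitions: Sequence[MotuPartition], species_map: Mapping[str, str]
) -> tuple[list[AgreementRecord], dict[tuple[bool, ...], int]]:
    """Cross-method agreement per species, plus Venn-style pattern counts.

    Methods are compared on the intersection of their specimen domains.  The
    Venn counts key each species by the tuple of pairwise-agreement booleans
    (method pairs in input order); cells sum to the number of species in the
    common domain.
    """
    if len(partitions) < 2:
        raise BarcodeAuditError("agreement requires >= 2 partitions")
    names = [p.method_name for p in partitions]
    if len(set(names)) != len(names):
        raise BarcodeAuditError("partitions must have distinct method names")
    domain = set.intersection(*(p.domain for p in partitions))
    if not domain:
        raise BarcodeAuditError("partitions share no specimens")
    full = set.union(*(p.domain for p in partitions))
    if domain != full:
        logger.warning(
            "agreement computed on common domain of %d specimens (%d dropped)",
            len(domain),
            len(full - domain),
        )
    species = sorted({species_map[sid] for sid in domain})
    pairs = list(combinations(range(len(partitions)), 2))
    records: list[AgreementRecord] = []
    venn: dict[tuple[bool, ...], int] = {}
    signatures = [_signatures(p, species_map, domain) for p in partitions]
    for sp in species:
        flags: dict[tuple[str, str], bool] = {}
        for i, j in pairs:
            flags[(names[i], names[j])] = signatures[i][sp] == signatures[j][sp]
        pattern = tuple(flags[(names[i], names[j])] for i, j in pairs)
        venn[pattern] = venn.get(pattern, 0) + 1
        records.append(
            AgreementRecord(species=sp, pairwise=flags, all_methods=all(flags.values()))
        )
    return records, venn


def _pair_min_distance(dm: DistanceMatrix, ids_a: Sequence[str], ids_b: Sequence[str]) -> float:
    idx = dm.index()
    block = dm.d[np.ix_([idx[i] for i in ids_a], [idx[i] for i in ids_b])]
    if np.all(np.isnan(block)):
        return float("nan")
    return float(np.nanmin(block))


def split_case_table(
    partition: MotuPartition,
    species_map: Mapping[str, str],
    dm: DistanceMatrix,
    min_max_intra: float = 0.03,
) -> pd.DataFrame:
    """Species split over >= 2 MOTUs whose max intraspecific distance exceeds
    ``min_max_intra`` (deep splits worth taxonomic scrutiny).

    Columns: species, n (sample size), max_intra, n_motus, motu_labels,
    motu_members.
    """
    idx = dm.index()
    labels_of, _ = _species_groups(partition, species_map)
    rows = []
    for sp in sorted(labels_of):
        if len(labels_of[sp]) < 2:
            continue
        members = [sid for sid in partition.assignment if species_map[sid] == sp]
        pos = [idx[sid] for sid in members if sid in idx]
        block = dm.d[np.ix_(pos, pos)][np.triu_indices(len(pos), k=1)]
        block = block[~np.isnan(block)]
        max_intra = float(np.max(block)) if block.size else float("nan")
        if not (max_intra > min_max_intra):
            continue
        by_label: dict[str, list[str]] = {}
        for sid in members:
            by_label.setdefault(partition.assignment[sid], []).append(sid)
        labels_sorted = sorted(by_label)
        rows.append(
            {
                "species": sp,
                "n": len(members),
                "max_intra": max_intra,
                "n_motus": len(by_label),
                "motu_labels": ";".join(labels_sorted),
                "motu_members": ";".join(
                    ",".join(sorted(by_label[lab])) for lab in labels_sorted
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "n", "max_intra", "n_motus", "motu_labels", "motu_members"]
    )


def share_case_table(
    partition: MotuPartition,
    species_map: Mapping[str, str],
    dm: DistanceMatrix,
) -> pd.DataFrame:
    """MOTUs containing specimens of >= 2 species, with per-species-pair
    minimum distances and a flag for shared identical haplotypes.

    Columns: motu_label, n_species, species (with sample sizes), pair_min_k2p
    (semicolon-separated ``A|B=dist``), identical_haplotypes.
    """
    labels_of, species_in = _species_groups(partition, species_map)
    groups = partition.groups()
    rows = []
    for label in sorted(species_in, key=lambda lab: sorted(species_in[lab])[0]):
        species_here = sorted(species_in[label])
        if len(species_here) < 2:
            continue
        members = groups[label]
        by_species = {
            sp: [sid for sid in members if species_map[sid] == sp] for sp in species_here
        }
        pair_strs = []
        overall_min = float("inf")
        for sp_a, sp_b in combinations(species_here, 2):
            mind = _pair_min_distance(dm, by_species[sp_a], by_species[sp_b]) + 0.0
            overall_min = min(overall_min, mind) if not np.isnan(mind) else overall_min
            pair_strs.append(f"{sp_a}|{sp_b}={mind:.6f}")
        rows.append(
            {
                "motu_label": label,
                "n_species": len(species_here),
                "species": ";".join(f"{sp} (n={len(by_species[sp])})" for sp in species_here),
                "pair_min_k2p": ";".join(pair_strs),
                "identical_haplotypes": bool(overall_min == 0.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["motu_label", "n_species", "species", "pair_min_k2p", "identical_haplotypes"],
    )


def motus_per_species_by_subset(
    partition: MotuPartition,
    species_map: Mapping[str, str],
    subset_a: Iterable[str],
    subset_b: Iterable[str],
) -> dict[str, tuple[int, int]]:
    """Distinct MOTU counts per species within two specimen subsets.

    Typical use: MOTUs detected regionally vs across the full range of each
    species.  A species unsampled in a subset counts 0 there.
    """
    subset_a, subset_b = set(subset_a), set(subset_b)
    for name, subset in (("subset_a", subset_a), ("subset_b", subset_b)):
        extra = subset - partition.domain
        if extra:
            raise BarcodeAuditError(f"{name} contains ids outside partition domain: {sorted(extra)[:5]}")
    out: dict[str, tuple[int, int]] = {}
    all_species = sorted({species_map[sid] for sid in partition.domain})
    for sp in all_species:
        ids = [sid for sid in partition.domain if species_map[sid] == sp]
        count_a = len({partition.assignment[sid] for sid in ids if sid in subset_a})
        count_b = len({partition.assignment[sid] for sid in ids if sid in subset_b})
        out[sp] = (count_a, count_b)
    return out
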