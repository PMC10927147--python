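"""Data model and I/O for DNA-barcode reference libraries.

The central objects are :class:`SpecimenRecord` (one sequenced voucher with its
taxonomic and geographic metadata), :class:`BarcodeDataset` (an aligned
collection of records) and :class:`MotuPartition` (a named assignment of
specimens to molecular operational taxonomic units, whether computed by this
package or imported from an external delimitation such as BOLD BINs, ASAP or
bPTP).

All on-disk formats are plain text: FASTA for sequences, TSV with a header for
specimen metadata and report tables, Newick for trees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BarcodeAuditError",
    "FastaParseError",
    "SchemaError",
    "ReconciliationError",
    "SpecimenRecord",
    "BarcodeDataset",
    "MotuPartition",
    "QualityFilterConfig",
    "RejectedRecord",
    "AUSTRIAN_REGIONS",
    "read_fasta",
    "write_fasta",
    "read_specimen_table",
    "build_dataset",
    "load_dataset",
    "apply_quality_filter",
    "write_newick",
    "to_newick",
]


class BarcodeAuditError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(BarcodeAuditError):
    """Malformed or inconsistent FASTA input."""


class SchemaError(BarcodeAuditError):
    """Metadata table violates the expected column schema."""


class ReconciliationError(BarcodeAuditError):
    """Sequences and metadata cannot be joined one-to-one."""


#: Documented region vocabulary; the region field itself is an open string so
#: the pipeline is usable outside this sampling design.
AUSTRIAN_REGIONS = ("NE_AUSTRIA", "S_AUSTRIA", "W_AUSTRIA", "NON_AUSTRIAN")

_DNA_ALPHABET = set("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced voucher specimen.

    ``sequence`` is an uppercase, aligned DNA string over the IUPAC alphabet
    (gaps allowed); all records in a dataset share the alignment length.
    """

    specimen_id: str
    species: str
    sequence: str
    subfamily: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise BarcodeAuditError("specimen_id must be nonempty")
        if not self.species:
            raise BarcodeAuditError(
                f"specimen {self.specimen_id!r}: species must be nonempty"
            )
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise BarcodeAuditError(
                f"specimen {self.specimen_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )


@dataclass
class BarcodeDataset:
    """An ordered, aligned collection of specimen records."""

    records: list[SpecimenRecord]
    alignment_length: int

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise BarcodeAuditError("alignment_length must be >= 1")
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise BarcodeAuditError(f"duplicate specimen_id {rec.specimen_id!r}")
            seen.add(rec.specimen_id)
            if len(rec.sequence) != self.alignment_length:
                raise BarcodeAuditError(
                    f"specimen {rec.specimen_id!r}: sequence length "
                    f"{len(rec.sequence)} != alignment length {self.alignment_length}; "
                    "sequences must be pre-aligned to a common length"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.specimen_id for rec in self.records]

    def species_map(self) -> dict[str, str]:
        return {rec.specimen_id: rec.species for rec in self.records}

    def subfamily_map(self) -> dict[str, str]:
        return {rec.specimen_id: rec.subfamily for rec in self.records}

    def record(self, specimen_id: str) -> SpecimenRecord:
        for rec in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)

    def subset(self, ids: Iterable[str]) -> "BarcodeDataset":
        wanted = set(ids)
        recs = [r for r in self.records if r.specimen_id in wanted]
        missing = wanted - {r.specimen_id for r in recs}
        if missing:
            raise BarcodeAuditError(f"unknown specimen ids: {sorted(missing)}")
        return BarcodeDataset(recs, self.alignment_length)


@dataclass
class MotuPartition:
    """A named mapping specimen -> MOTU label.

    Labels are opaque: only equality between them matters.  ``threshold`` is
    set only for partitions produced by threshold clustering.
    """

    method_name: str
    assignment: dict[str, str]
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.method_name:
            raise BarcodeAuditError("method_name must be nonempty")
        for sid, label in self.assignment.items():
            if not label:
                raise BarcodeAuditError(
                    f"partition {self.method_name!r}: empty label for {sid!r}"
                )

    @property
    def domain(self) -> set[str]:
        return set(self.assignment)

    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[str, list[str]]:
        """Label -> specimen ids, specimens in insertion order."""
        out: dict[str, list[str]] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, []).append(sid)
        return out


@dataclass(frozen=True)
class QualityFilterConfig:
    """Length/ambiguity retention rule for barcode compliance.

    ``min_length`` counts unambiguous (A/C/G/T) positions, mirroring the
    convention that barcodes shorter than ~500 informative bases are excluded
    from distance analyses.
    """

    min_length: int = 500
    max_ambiguous_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise BarcodeAuditError("min_length must be >= 1")
        if not 0.0 <= self.max_ambiguous_fraction <= 1.0:
            raise BarcodeAuditError("max_ambiguous_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RejectedRecord:
    specimen_id: str
    reason: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and RNA 'U' is mapped to 'T'; alignment gaps
    ('-') are preserved.  Duplicate ids are an error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        first = ""
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first = line
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        out.append((rec.id, seq))
    if dupes:
        raise FastaParseError(f"{path}: duplicate sequence ids: {sorted(set(dupes))}")
    return out


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as handle:
        for sid, seq in pairs:
            handle.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Specimen metadata

_REQUIRED_COLUMNS = ("specimen_id", "species")
_METADATA_COLUMNS = ("specimen_id", "species", "subfamily", "region")


def read_specimen_table(
    path: str | Path,
) -> tuple[list[dict[str, str]], dict[str, MotuPartition]]:
    """Read a specimen metadata TSV.

    Required columns: ``specimen_id``, ``species``.  Optional: ``subfamily``,
    ``region``.  Every further column is treated as an imported MOTU
    partition (e.g. ``bin_id``, ``asap_id``, ``bptp_id``); empty cells
    restrict that partition's domain to the labelled specimens.

    Returns the metadata rows and a mapping method-name -> MotuPartition.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df["specimen_id"].duplicated().any():
        dup = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"].unique())
        raise SchemaError(f"{path}: duplicate specimen ids {dup}")
    rows: list[dict[str, str]] = []
    for _, r in df.iterrows():
        rows.append(
            {
                "specimen_id": r["specimen_id"].strip(),
                "species": r["species"].strip(),
                "subfamily": r.get("subfamily", "").strip() if "subfamily" in df else "",
                "region": r.get("region", "").strip() if "region" in df else "",
            }
        )
    partitions: dict[str, MotuPartition] = {}
    for col in df.columns:
        if col in _METADATA_COLUMNS:
            continue
        assignment = {
            sid.strip(): lab.strip()
            for sid, lab in zip(df["specimen_id"], df[col])
            if lab.strip()
        }
        if assignment:
            partitions[col] = MotuPartition(method_name=col, assignment=assignment)
    return rows, partitions


def build_dataset(
    sequences: Sequence[tuple[str, str]], rows: Sequence[Mapping[str, str]]
) -> BarcodeDataset:
    """Join FASTA sequences with metadata rows on ``specimen_id``.

    The join must be a bijection: any specimen present on one side only is
    reported, never silently dropped.
    """
    seq_map = dict(sequences)
    table_ids = [row["specimen_id"] for row in rows]
    only_table = sorted(set(table_ids) - set(seq_map))
    only_fasta = sorted(set(seq_map) - set(table_ids))
    if only_table or only_fasta:
        raise ReconciliationError(
            "metadata and FASTA do not reconcile; "
            f"in table only: {only_table}; in FASTA only: {only_fasta}"
        )
    lengths = {len(s) for s in seq_map.values()}
    if len(lengths) > 1:
        raise BarcodeAuditError(
            f"sequences have unequal lengths {sorted(lengths)}; "
            "pre-align them (e.g. with MAFFT) to a common length first"
        )
    records = [
        SpecimenRecord(
            specimen_id=row["specimen_id"],
            species=row["species"],
            subfamily=row.get("subfamily", ""),
            region=row.get("region", ""),
            sequence=seq_map[row["specimen_id"]],
        )
        for row in rows
    ]
    return BarcodeDataset(records, alignment_length=lengths.pop())


def load_dataset(
    fasta_path: str | Path, table_path: str | Path
) -> tuple[BarcodeDataset, dict[str, MotuPartition]]:
    """Read and reconcile a FASTA + metadata TSV pair."""
    pairs = read_fasta(fasta_path)
    rows, partitions = read_specimen_table(table_path)
    return build_dataset(pairs, rows), partitions


# ---------------------------------------------------------------------------
# Quality filter

_UNAMBIGUOUS = set("ACGT")


def apply_quality_filter(
    dataset: BarcodeDataset, cfg: QualityFilterConfig | None = None
) -> tuple[BarcodeDataset, list[RejectedRecord]]:
    """Retain records meeting length and ambiguity criteria.

    A record is kept when its count of A/C/G/T positions is at least
    ``cfg.min_length`` and the fraction of ambiguous/gap positions is at most
    ``cfg.max_ambiguous_fraction``.  Idempotent.  An empty result is allowed;
    it is visible from the rejection report.
    """
    cfg = cfg or QualityFilterConfig()
    kept: list[SpecimenRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in dataset.records:
        n_good = sum(1 for ch in rec.sequence if ch in _UNAMBIGUOUS)
        ambiguous_frac = 1.0 - n_good / len(rec.sequence)
        if n_good < cfg.min_length:
            rejected.append(RejectedRecord(rec.specimen_id, "short"))
        elif ambiguous_frac > cfg.max_ambiguous_fraction:
            rejected.append(RejectedRecord(rec.specimen_id, "ambiguous"))
        else:
            kept.append(rec)
    return BarcodeDataset(kept, dataset.alignment_length), rejected


# ---------------------------------------------------------------------------
# Newick

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree) -> str:
    """Serialise an :class:`~barcodeaudit.nj_tree.NJTree` to a Newick string.

    Branch lengths are written with 6 decimal places; labels containing
    Newick metacharacters are single-quoted.
    """
    adjacency = tree.adjacency
    leaf_labels = tree.leaf_labels
    # Root at an internal node when one exists, else at the first node.
    internal = [n for n in sorted(adjacency) if n not in leaf_labels]
    root = internal[0] if internal else sorted(adjacency)[0]

    def render(node: int, parent: int | None) -> str:
        children = [nbr for nbr in sorted(adjacency[node]) if nbr != parent]
        if not children:
            return _quote_label(leaf_labels[node])
        parts = [f"{render(c, node)}:{adjacency[node][c]:.6f}" for c in children]
        label = _quote_label(leaf_labels[node]) if node in leaf_labels else ""
        return "(" + ",".join(parts) + ")" + label

    return render(root, None) + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a tree to ``path`` in Newick format (see :func:`to_newick`)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(to_newick(tree) + "\n")
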