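"""Seeded generator of synthetic DNA-barcode reference libraries.

The generator emulates the statistical structure a barcode-library audit
assumes: several hundred species sampled with uneven effort (1-24 specimens,
median ~5), shallow intraspecific variation (mean pairwise K2P ~0.4%),
well-separated species (nearest-neighbour K2P ~6.5%), plus the pathologies
that make delimitation interesting — haplotype sharing between species pairs,
deep intraspecific splits, and singletons.

Species sit on a star tree: each species' ancestor evolves independently from
a common root along a stem calibrated so the expected interspecific path
length matches the target; specimens then radiate from their species ancestor
with short stems matching the intraspecific target.  Sequences evolve
site-independently under the K2P substitution process (transition rate kappa,
the two transversions rate 1 each, normalised so branch length = expected
substitutions per site), so the K2P distance estimator is asymptotically
unbiased on the output — itself a useful property to test.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    AUSTRIAN_REGIONS,
    BarcodeAuditError,
    BarcodeDataset,
    MotuPartition,
    SpecimenRecord,
    write_fasta,
)

__all__ = ["SimConfig", "SimTruth", "simulate_library", "make_fixture", "FIXTURES"]

_BASES = "AGCT"
# A=0, G=1 are purines; C=2, T=3 pyrimidines (matches distances.encode_sequence)
_TRANSITION_OF = np.array([1, 0, 3, 2])
_TRANSVERSIONS_OF = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])

#: Default sample-size distribution over 1..24 specimens per species:
#: explicit point masses for singletons and doubletons matching a realistic
#: national library, geometric decay beyond, tuned to a median of 5.
_DEFAULT_SIZE_PMF: dict[int, float] = {}
_DEFAULT_SIZE_PMF[1] = 67 / 476
_DEFAULT_SIZE_PMF[2] = 44 / 476
_rest = 1.0 - _DEFAULT_SIZE_PMF[1] - _DEFAULT_SIZE_PMF[2]
_w = {n: 0.82**n for n in range(3, 25)}
_tot = sum(_w.values())
for _n, _v in _w.items():
    _DEFAULT_SIZE_PMF[_n] = _rest * _v / _tot
del _rest, _w, _tot, _n, _v


@dataclass
class SimConfig:
    """Parameters of a synthetic barcode library.

    ``samples_per_species`` may be ``None`` (default distribution above), an
    int (fixed), or a ``{n: probability}`` mapping.  ``subfamilies`` maps
    subfamily name -> species count and must sum to ``n_species``.
    ``scenarios`` counts pathology injections: ``SHARE_PAIR`` (a haplotype of
    one species copied into another, min.NN = 0), ``DEEP_SPLIT`` (a species
    with two sub-clades ``deep_split_factor * target_intra`` apart) and
    ``SINGLETON`` (forced n = 1).
    """

    n_species: int
    samples_per_species: int | dict[int, float] | None = None
    L: int = 658
    kappa: float = 2.0
    target_intra: float = 0.004
    target_inter: float = 0.065
    subfamilies: dict[str, int] | None = None
    scenarios: dict[str, int] = field(default_factory=dict)
    deep_split_factor: float = 10.0
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise BarcodeAuditError("n_species must be >= 1")
        if self.kappa <= 0:
            raise BarcodeAuditError("kappa must be > 0")
        if not 0.0 < self.target_intra < self.target_inter < 0.75:
            raise BarcodeAuditError("need 0 < target_intra < target_inter < 0.75")
        if self.deep_split_factor < 4.0:
            raise BarcodeAuditError("deep_split_factor must be >= 4")
        unknown = set(self.scenarios) - {"SHARE_PAIR", "DEEP_SPLIT", "SINGLETON"}
        if unknown:
            raise BarcodeAuditError(f"unknown scenarios {sorted(unknown)}")
        needed = (
            2 * self.scenarios.get("SHARE_PAIR", 0)
            + self.scenarios.get("DEEP_SPLIT", 0)
            + self.scenarios.get("SINGLETON", 0)
        )
        if needed > self.n_species:
            raise BarcodeAuditError(
                f"scenarios need {needed} species but only {self.n_species} available"
            )
        if self.subfamilies is not None and sum(self.subfamilies.values()) != self.n_species:
            raise BarcodeAuditError("subfamily species counts must sum to n_species")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated library.

    ``partition`` is the morphospecies partition (specimen -> true species).
    ``motu_partition`` is the expected barcode-level partition: SHARE_PAIR
    species are merged (their barcode clouds genuinely overlap, so no
    distance-based method can separate them) and DEEP_SPLIT species are split
    into their two sub-clades.
    """

    partition: MotuPartition  # specimen -> true species, as a MotuPartition
    motu_partition: MotuPartition
    species_of: dict[str, str]
    share_pairs: list[tuple[str, str]]
    deep_splits: dict[str, dict[str, int]]  # species -> specimen -> sub-clade
    singletons: list[str]
    n_transition_events: int
    n_transversion_events: int


class _Evolver:
    """K2P substitution process with event counting."""

    def __init__(self, kappa: float, rng: np.random.Generator) -> None:
        self.p_transition = kappa / (kappa + 2.0)
        self.rng = rng
        self.n_ts = 0
        self.n_tv = 0

    def evolve(self, codes: np.ndarray, branch_length: float) -> np.ndarray:
        """Evolve a coded sequence along a branch (expected subs/site)."""
        out = codes.copy()
        L = len(out)
        n_events = int(self.rng.poisson(branch_length * L))
        if n_events == 0:
            return out
        sites = self.rng.integers(0, L, size=n_events)
        kinds = self.rng.random(n_events) < self.p_transition
        picks = self.rng.integers(0, 2, size=n_events)
        for site, is_ts, pick in zip(sites, kinds, picks):
            cur = out[site]
            if is_ts:
                out[site] = _TRANSITION_OF[cur]
                self.n_ts += 1
            else:
                out[site] = _TRANSVERSIONS_OF[cur, pick]
                self.n_tv += 1
        return out


def _draw_sample_size(cfg: SimConfig, rng: np.random.Generator) -> int:
    spec = cfg.samples_per_species
    if spec is None:
        spec = _DEFAULT_SIZE_PMF
    if isinstance(spec, int):
        return spec
    sizes = np.array(sorted(spec))
    probs = np.array([spec[int(k)] for k in sizes], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(sizes, p=probs))


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def simulate_library(cfg: SimConfig) -> tuple[BarcodeDataset, SimTruth]:
    """Generate a synthetic aligned barcode library plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    evolver = _Evolver(cfg.kappa, rng)

    # scenario allocation: disjoint species, chosen up front
    species_idx = list(range(cfg.n_species))
    picks = rng.permutation(cfg.n_species)
    cursor = 0
    n_single = cfg.scenarios.get("SINGLETON", 0)
    n_deep = cfg.scenarios.get("DEEP_SPLIT", 0)
    n_share = cfg.scenarios.get("SHARE_PAIR", 0)
    singleton_sp = set(picks[cursor : cursor + n_single]); cursor += n_single
    deep_sp = set(picks[cursor : cursor + n_deep]); cursor += n_deep
    share_pairs_idx = [
        (int(picks[cursor + 2 * k]), int(picks[cursor + 2 * k + 1]))
        for k in range(n_share)
    ]
    share_sp = {s for pair in share_pairs_idx for s in pair}

    # subfamily assignment in declared order
    subfam_of: dict[int, str] = {}
    if cfg.subfamilies:
        i = 0
        for name, count in cfg.subfamilies.items():
            for _ in range(count):
                subfam_of[i] = name
                i += 1
    else:
        subfam_of = {i: "Simuliinae" for i in species_idx}

    root = rng.integers(0, 4, size=cfg.L).astype(np.int64)
    stem = max(cfg.target_inter - cfg.target_intra, 0.0) / 2.0
    tip = cfg.target_intra / 2.0
    delta = cfg.deep_split_factor * cfg.target_intra

    records: list[SpecimenRecord] = []
    species_of: dict[str, str] = {}
    deep_splits: dict[str, dict[str, int]] = {}
    specimen_codes: dict[str, np.ndarray] = {}
    specimens_by_species: dict[int, list[str]] = {}

    # Species ancestors.  A SHARE_PAIR recipient is modelled as a recently
    # diverged sister of its donor (ancestor one intraspecific unit away) so
    # that barcode sharing, as in real libraries, comes from species whose
    # whole barcode clouds overlap — not from one alien haplotype parachuted
    # into an otherwise distant species.
    donor_of = {sj: si for si, sj in share_pairs_idx}
    ancestors: dict[int, np.ndarray] = {}
    for si in species_idx:
        if si not in donor_of:
            ancestors[si] = evolver.evolve(root, stem)
    for sj, si in donor_of.items():
        ancestors[sj] = evolver.evolve(ancestors[si], cfg.target_intra)

    for si in species_idx:
        name = f"Geometra sim{si:04d}"
        if si in singleton_sp:
            n = 1
        else:
            n = _draw_sample_size(cfg, rng)
            if si in deep_sp or si in share_sp:
                n = max(n, 2)
        ancestor = ancestors[si]
        clade_of: dict[str, int] = {}
        if si in deep_sp:
            anc_b = evolver.evolve(ancestor, delta)
            n_b = max(1, n // 2)
        else:
            anc_b, n_b = None, 0
        ids = []
        for k in range(n):
            sid = f"SIM{si:04d}-{k + 1:02d}"
            in_b = anc_b is not None and k >= n - n_b
            codes = evolver.evolve(anc_b if in_b else ancestor, tip)
            specimen_codes[sid] = codes
            species_of[sid] = name
            if si in deep_sp:
                clade_of[sid] = 1 if in_b else 0
            ids.append(sid)
        if si in deep_sp:
            deep_splits[name] = clade_of
        specimens_by_species[si] = ids

    share_pairs: list[tuple[str, str]] = []
    for si, sj in share_pairs_idx:
        donor = specimens_by_species[si][0]
        recipient = specimens_by_species[sj][0]
        specimen_codes[recipient] = specimen_codes[donor].copy()
        share_pairs.append((f"Geometra sim{si:04d}", f"Geometra sim{sj:04d}"))

    for si in species_idx:
        for sid in specimens_by_species[si]:
            seq = _decode(specimen_codes[sid])
            if cfg.ambiguity_rate > 0:
                mask = rng.random(cfg.L) < cfg.ambiguity_rate
                seq = "".join("N" if m else ch for ch, m in zip(seq, mask))
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=species_of[sid],
                    subfamily=subfam_of[si],
                    region=str(rng.choice(AUSTRIAN_REGIONS[:3])),
                    sequence=seq,
                )
            )

    # expected barcode-level MOTUs: merge share pairs, split deep species
    motu_of: dict[str, str] = {}
    merged_into = {f"Geometra sim{sj:04d}": f"Geometra sim{si:04d}"
                   for si, sj in share_pairs_idx}
    for sid, sp in species_of.items():
        label = merged_into.get(sp, sp)
        if sp in deep_splits:
            label = f"{sp}/clade{deep_splits[sp][sid]}"
        motu_of[sid] = label

    dataset = BarcodeDataset(records, alignment_length=cfg.L)
    truth = SimTruth(
        partition=MotuPartition(method_name="truth", assignment=dict(species_of)),
        motu_partition=MotuPartition(method_name="truth_motu", assignment=motu_of),
        species_of=species_of,
        share_pairs=share_pairs,
        deep_splits=deep_splits,
        singletons=sorted(
            f"Geometra sim{si:04d}" for si in singleton_sp
        ),
        n_transition_events=evolver.n_ts,
        n_transversion_events=evolver.n_tv,
    )
    return dataset, truth


#: Published fixture configurations (seeds are part of the fixture contract).
FIXTURES: dict[str, SimConfig] = {
    "tiny": SimConfig(n_species=3, samples_per_species=3, seed=101),
    "pathological": SimConfig(
        n_species=10,
        scenarios={"SHARE_PAIR": 2, "DEEP_SPLIT": 2, "SINGLETON": 3},
        seed=202,
    ),
    "paper_scale": SimConfig(
        n_species=476,
        subfamilies={
            "Geometrinae": 13,
            "Archiearinae": 3,
            "Ennominae": 146,
            "Larentiinae": 248,
            "Sterrhinae": 66,
        },
        seed=303,
    ),
}


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write a named fixture (FASTA + metadata TSV + truth TSV + manifest).

    Fixture seeds are fixed, so outputs are reproducible byte for byte.
    Returns the paths written.
    """
    if name not in FIXTURES:
        raise BarcodeAuditError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_library(cfg)

    fasta = out_dir / f"{name}.fasta"
    write_fasta(((r.specimen_id, r.sequence) for r in dataset.records), fasta)

    meta = out_dir / f"{name}.meta.tsv"
    with open(meta, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\tspecies\tsubfamily\tregion\n")
        for r in dataset.records:
            fh.write(f"{r.specimen_id}\t{r.species}\t{r.subfamily}\t{r.region}\n")

    truth_path = out_dir / f"{name}.truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\ttrue_species\tdeep_clade\n")
        for r in dataset.records:
            clade = truth.deep_splits.get(r.species, {}).get(r.specimen_id, "")
            fh.write(f"{r.specimen_id}\t{r.species}\t{clade}\n")

    manifest = out_dir / f"{name}.manifest.json"
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "fixture": name,
                "seed": cfg.seed,
                "n_species": cfg.n_species,
                "n_specimens": len(dataset),
                "alignment_length": cfg.L,
                "scenarios": cfg.scenarios,
                "share_pairs": truth.share_pairs,
                "singletons": truth.singletons,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {"fasta": fasta, "metadata": meta, "truth": truth_path, "manifest": manifest}
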