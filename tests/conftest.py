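import numpy as np
import pytest

from barcodeaudit import BarcodeDataset, DistanceMatrix, SpecimenRecord


def make_dataset(seqs: dict[str, str], species: dict[str, str] | None = None,
                 subfamily: dict[str, str] | None = None) -> BarcodeDataset:
    species = species or {sid: f"Species {sid}" for sid in seqs}
    subfamily = subfamily or {}
    L = len(next(iter(seqs.values())))
    records = [
        SpecimenRecord(
            specimen_id=sid,
            species=species[sid],
            sequence=seq,
            subfamily=subfamily.get(sid, ""),
        )
        for sid, seq in seqs.items()
    ]
    return BarcodeDataset(records, alignment_length=L)


def make_dm(ids, matrix) -> DistanceMatrix:
    d = np.asarray(matrix, dtype=float)
    sites = np.full_like(d, 658.0)
    np.fill_diagonal(sites, 658.0)
    return DistanceMatrix(ids=list(ids), d=d, sites=sites.astype(int))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    from barcodeaudit import make_fixture

    return make_fixture("tiny", tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def pathological_fixture(tmp_path_factory):
    from barcodeaudit import make_fixture

    return make_fixture("pathological", tmp_path_factory.mktemp("patho"))
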