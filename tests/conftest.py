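import warnings

import numpy as np
import pytest

from allergoscope.io import SequenceRecord
from allergoscope.simulate import generate_reference_db, generate_transcriptome_set

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_db():
    """A 6-family x 3-member reference database (length 120), seed 7."""
    db, meta = generate_reference_db(
        n_families=6, members_per_family=3, length=120, seed=7
    )
    return db, meta


@pytest.fixture(scope="session")
def small_transcriptome(small_db):
    """Default 8-fish transcriptome set over the 12-family default DB."""
    db, _ = generate_reference_db(seed=7)
    return db, generate_transcriptome_set(db, seed=8)


# A fixed 5-sequence, 12-column toy MSA; scores are checked against a
# column-by-column hand enumeration.
TOY_MSA = [
    SequenceRecord("s1", "s1", "MKV-LATTEGGA"),
    SequenceRecord("s2", "s2", "MKVALATTEGGA"),
    SequenceRecord("s3", "s3", "MKVALSTTEGCA"),
    SequenceRecord("s4", "s4", "MRVALSTT-GCA"),
    SequenceRecord("s5", "s5", "---ALATTEGGA"),
]


@pytest.fixture()
def toy_msa():
    return list(TOY_MSA)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full synthetic pipeline runs with the same config and seed."""
    from allergoscope.pipeline import RunConfig, run_all

    root = tmp_path_factory.mktemp("pipeline")
    reports = []
    for name in ("runA", "runB"):
        reports.append(run_all(RunConfig(output_dir=root / name, seed=5, synthetic=True)))
    return root / "runA", root / "runB", reports


@pytest.fixture(autouse=True)
def _quiet_separation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="complete or quasi-complete separation")
        yield
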