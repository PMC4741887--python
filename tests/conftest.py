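import numpy as np
import pandas as pd
import pytest

from mirprog.io_formats import CountMatrix, SampleManifest
from mirprog.target_predict import MatureMiRNA

MIR375_SEQ = "UUUGUUCGUUCGGCUCGCGUGA"  # hsa-miR-375 mature, miRBase MIMAT0000728


@pytest.fixture
def mir375() -> MatureMiRNA:
    return MatureMiRNA("hsa-miR-375", MIR375_SEQ)


@pytest.fixture
def mir375_fasta():
    from importlib.resources import files

    return files("mirprog.data") / "mir375.fasta"


@pytest.fixture
def manifest_two_patients() -> SampleManifest:
    rows = []
    for patient in ("P001", "P002"):
        for assay in ("miRNA", "mRNA"):
            for stage in ("normal", "OLP", "OSCC"):
                rows.append(
                    {
                        "sample_id": f"{patient}_{stage}_{assay}",
                        "patient_id": patient,
                        "stage": stage,
                        "assay": assay,
                    }
                )
    return SampleManifest(pd.DataFrame(rows))


def make_mirna_counts(manifest: SampleManifest, values: dict[str, list[int]],
                      library_size: int = 1_000_000) -> CountMatrix:
    """Build a miRNA CountMatrix from {feature: [count per manifest sample]}."""
    sample_ids = [
        s for s in manifest.sample_ids if s.endswith("miRNA")
    ]
    counts = np.array([values[f] for f in values], dtype=np.int64)
    lib = np.maximum(library_size, counts.sum(axis=0))
    return CountMatrix(list(values), sample_ids, counts, lib)


@pytest.fixture
def rng():
    return np.random.default_rng(20150912)
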