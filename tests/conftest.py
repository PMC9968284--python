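import numpy as np
import pandas as pd
import pytest

from viromeflow.io_formats import (
    AbundanceMatrix,
    CohortDesign,
    SampleRecord,
    VirusRecord,
)

FAMILIES = ["Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae", "unknown"]


def random_catalog(rng: np.random.Generator, n: int) -> list[VirusRecord]:
    records = []
    for i in range(n):
        lys = rng.choice([True, False, None])
        records.append(
            VirusRecord(
                virus_id=f"v{i:04d}",
                length=int(rng.integers(1_000, 150_000)),
                circular=bool(rng.random() < 0.1),
                family=str(rng.choice(FAMILIES)),
                viral_class="Caudoviricetes",
                lysogenic=None if lys is None else bool(lys),
                cluster_id=f"VC{int(rng.integers(0, n // 2 + 1))}"
                if rng.random() < 0.5
                else None,
                pvog_hits=int(rng.integers(0, 20)),
            )
        )
    return records


def toy_design(n_subjects: int = 3, n_tp: int = 3, condition: str = "Control") -> CohortDesign:
    samples = []
    for i in range(n_subjects):
        day = 0
        for tp in range(1, n_tp + 1):
            samples.append(
                SampleRecord(
                    sample_id=f"S{i}_T{tp}",
                    subject_id=f"S{i}",
                    condition=condition,
                    timepoint=tp,
                    collection_day=day,
                )
            )
            day += 100
    return CohortDesign(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_matrix():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 0, 1],
            "s2": [0, 20, 5, 0, 0],
            "s3": [3, 3, 3, 3, 0],
        },
        index=[f"v{i}" for i in range(5)],
    )
    return AbundanceMatrix(counts)
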