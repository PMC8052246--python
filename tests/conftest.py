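import numpy as np
import pandas as pd
import pytest

from placsplice.io import ProbeAnnotation, ProbeMatrix, SampleSheet


def make_annotation(probes_per_gene: dict[str, int], chrom: str = "1", spacing: int = 2000) -> ProbeAnnotation:
    rows = []
    start = 1_000_000
    for gene, n in probes_per_gene.items():
        for k in range(n):
            p0 = start + k * spacing
            rows.append((f"{gene}_p{k + 1}", gene, chrom, p0, p0 + 199, k + 1))
        start += 10_000_000
    return ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "gene_id", "chrom", "start", "end", "probe_index"])
    )


def make_matrix(values: dict[str, list[float]], samples: list[str]) -> ProbeMatrix:
    return ProbeMatrix(pd.DataFrame(values, index=samples).T.rename_axis("probe_id"))


def make_sheet(samples: list[str], groups: list[str], ga=None, sex=None, batch=None) -> SampleSheet:
    n = len(samples)
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": groups,
                "gestational_age": ga if ga is not None else [38.0] * n,
                "sex": sex if sex is not None else ["F"] * n,
                "birth_weight": [3000.0] * n,
                "batch": batch if batch is not None else ["b1"] * n,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_gene_annotation():
    return make_annotation({"GA": 2, "GB": 3})


@pytest.fixture
def random_cohort(rng):
    """A small random cohort: 10 genes x 4 probes, 12 samples, pure noise around 10."""
    annotation = make_annotation({f"G{i}": 4 for i in range(10)})
    probes = list(annotation.frame["probe_id"])
    samples = [f"S{i}" for i in range(12)]
    values = pd.DataFrame(
        rng.normal(10.0, 1.0, size=(len(probes), len(samples))),
        index=pd.Index(probes, name="probe_id"),
        columns=samples,
    )
    return ProbeMatrix(values), annotation, samples
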