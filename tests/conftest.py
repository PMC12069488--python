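import numpy as np
import pandas as pd
import pytest

from isomirkit import abundance, simulate
from isomirkit.caller import classify_reads
from isomirkit.reference import HairpinRecord, MatureAnnotation, build_index

# toy hairpin whose 5p mature is the canonical counterpart of the
# miR-411-5p assay sequence (its seed is AGUAGAC at positions 2-8)
TOY_HAIRPIN = "GGAUAGUAGACCGUAUAGCGUACGGGAUU"
TOY_MATURE = "UAGUAGACCGUAUAGCGUACG"


@pytest.fixture
def toy_index():
    hairpin = HairpinRecord("toy-mir-1", "toy-mir-1", TOY_HAIRPIN)
    mature = MatureAnnotation("toy-miR-1-5p", "toy-mir-1", 3, 24, "5p")
    return build_index([hairpin], [mature])


@pytest.fixture(scope="session")
def syn_ref():
    return simulate.generate_reference(10, seed=42)


@pytest.fixture(scope="session")
def classified_matrix(syn_ref):
    """A classified, RPM'd and normalized single-dataset matrix."""
    spec = simulate.CompositionSpec(library_size=20_000, n_samples=3, seed=7)
    reads_by_dataset, truth = simulate.generate_reads(spec, syn_ref)
    reads = reads_by_dataset["ds1"]
    calls, unassigned = classify_reads(reads, syn_ref)
    matrix = abundance.ExpressionMatrix.from_call_table(
        calls, {s: "ds1" for s in reads[0].sample_ids}
    )
    abundance.compute_rpm(matrix)
    abundance.median_of_ratios_normalize(matrix)
    return matrix, truth


def random_matrix(rng, n_rows=12, n_samples=4, n_parents=3, dataset="ds1"):
    """A small random ExpressionMatrix for property checks."""
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(n_rows, n_samples)).astype(float),
        index=[f"row{i}|SEQ{i}" for i in range(n_rows)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    meta = pd.DataFrame(
        {
            "display_name": [f"row{i}" for i in range(n_rows)],
            "sequence": [f"SEQ{i}" for i in range(n_rows)],
            "mature_name": [f"mir-{i % n_parents}" for i in range(n_rows)],
            "variant_class": ["Canonical" if i < n_parents else "Trim3p" for i in range(n_rows)],
            "seed_conserved": [True] * n_rows,
        },
        index=counts.index,
    )
    return abundance.ExpressionMatrix(
        counts=counts, row_meta=meta, sample_datasets={c: dataset for c in counts.columns}
    )
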