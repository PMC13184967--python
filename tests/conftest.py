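import numpy as np
import pandas as pd
import pytest

from ecoassembly.core_io import CommunityMatrix


@pytest.fixture
def tiny_cm() -> CommunityMatrix:
    """3 taxa x 4 samples, 2 treatments x 2 replicates, one timepoint."""
    counts = pd.DataFrame(
        {
            "s1": [10, 5, 0],
            "s2": [8, 6, 1],
            "s3": [0, 2, 12],
            "s4": [1, 3, 11],
        },
        index=["A", "B", "C"],
    )
    meta = pd.DataFrame(
        {
            "treatment": ["glu", "glu", "str", "str"],
            "replicate": ["R1", "R2", "R1", "R2"],
            "timepoint": [0, 0, 0, 0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CommunityMatrix(counts, meta)


@pytest.fixture
def three_tip_tree() -> str:
    """d(A,B)=2, d(A,C)=d(B,C)=4 by hand path-summing."""
    return "((A:1,B:1):1,C:2);"


def random_community_matrix(rng: np.random.Generator, n_taxa: int, n_samples: int,
                            reads: int = 200) -> CommunityMatrix:
    probs = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    counts = np.stack([rng.multinomial(reads, p) for p in probs], axis=1)
    # avoid all-zero samples
    counts[0, counts.sum(axis=0) == 0] = 1
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "treatment": ["T1"] * n_samples,
            "replicate": [f"R{j + 1}" for j in range(n_samples)],
            "timepoint": [0] * n_samples,
        },
        index=samples,
    )
    return CommunityMatrix(pd.DataFrame(counts, index=taxa, columns=samples), meta)
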