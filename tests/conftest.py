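import numpy as np
import pandas as pd
import pytest

from convexpr.io_formats import CountMatrix, GeneRecord, HitRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_count_matrix():
    return CountMatrix(
        species="spA",
        tissue="liver",
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[10, 20], [0, 5], [7, 7]]),
    )


@pytest.fixture
def gene_records():
    return [
        GeneRecord("g1", "t1", "chr1", 100, 600, "+", 120),
        GeneRecord("g1", "t2", "chr1", 100, 900, "+", 300),
        GeneRecord("g2", "t3", "chr1", 5000, 7000, "-", 450),
    ]


def make_hit(query, subject, evalue, bits=100.0):
    return HitRecord(
        query_id=query,
        subject_id=subject,
        percent_identity=90.0,
        alignment_length=100,
        mismatches=5,
        gap_opens=1,
        q_start=1,
        q_end=100,
        s_start=1,
        s_end=100,
        evalue=evalue,
        bit_score=bits,
    )


@pytest.fixture
def random_counts(rng):
    mu = np.exp(rng.normal(4.0, 1.0, 200))
    r = 10.0
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(200, 6))
    return pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(200)],
        columns=[f"s{j}" for j in range(6)],
    )
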