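import numpy as np
import pytest

from apccooc import (
    AlignedPatternCluster,
    CoOccurrenceGraph,
    JointGroup,
    Motif,
    Pattern,
    SequenceRecord,
    SequenceSet,
    SyntheticSpec,
    generate_family,
)


def make_apc(apc_id: str, coverage: list[str], symbols: str = "AAAAA"
             ) -> AlignedPatternCluster:
    """APC stub whose coverage is the given sequence-id set."""
    p = Pattern(symbols=symbols, occurrences=[(sid, 0) for sid in coverage])
    return AlignedPatternCluster(id=apc_id, rows=[symbols], members=[p])


def graph_from_w(W, ids=None) -> CoOccurrenceGraph:
    """Co-occurrence graph directly from a weight matrix (tests only)."""
    W = np.asarray(W, dtype=float)
    n = len(W)
    ids = ids or [f"APC{i + 1}" for i in range(n)]
    return CoOccurrenceGraph(ids=ids, W=W, union_size=np.zeros((n, n), dtype=int))


def block_graph(sizes, intra=1.0, inter=0.0) -> CoOccurrenceGraph:
    """Block-structured graph: full blocks at weight ``intra``, ``inter``
    between blocks."""
    n = sum(sizes)
    W = np.full((n, n), inter, dtype=float)
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = intra
        start += s
    np.fill_diagonal(W, 0.0)
    return graph_from_w(W)


@pytest.fixture(scope="session")
def planted_spec() -> SyntheticSpec:
    """Two joint motifs plus one independent motif (the standard benchmark
    conditions: n=100, length 150, presence 0.7, substitution rate 0.05)."""
    return SyntheticSpec(
        motifs=[
            Motif("KTLHGREVAW", 0.05),
            Motif("DFYPNCQMIG", 0.05),
            Motif("WSREKTYLVH", 0.05),
        ],
        joint_groups=[JointGroup((0, 1), 0.7)],
        independent_probs={2: 0.7},
        n_sequences=100,
        length=150,
        seed=1,
    )


@pytest.fixture(scope="session")
def planted_family(planted_spec):
    return generate_family(planted_spec)


@pytest.fixture()
def toy_seqs() -> SequenceSet:
    return SequenceSet([
        SequenceRecord("s1", "MKTAYIAKQR"),
        SequenceRecord("s2", "MKTAYIDKQR"),
        SequenceRecord("s3", "GGMKTAYIAK"),
    ])
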