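import io

import pytest
from hypothesis import settings

from ognest.og_builder import OG, OGSet
from ognest.simgraph import Hit, symmetrize
from ognest.taxonomy import load_hierarchy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def three_level_hierarchy():
    """LUCA root partitioned into Bacteria and Eukaryota."""
    table = (
        "LUCA\t\tS1,S2,S3,S4\n"
        "Bacteria\tLUCA\tS1,S2\n"
        "Eukaryota\tLUCA\tS3,S4\n"
    )
    return load_hierarchy(io.StringIO(table))


@pytest.fixture
def chain_hierarchy():
    """5-level linear chain: mammals ⊂ vertebrates ⊂ ... ⊂ LUCA."""
    table = (
        "LUCA\t\tS1,S2,S3,S4,S5,S6\n"
        "Eukaryota\tLUCA\tS1,S2,S3,S4,S5\n"
        "Bilateria\tEukaryota\tS1,S2,S3,S4\n"
        "Vertebrates\tBilateria\tS1,S2,S3\n"
        "Mammals\tVertebrates\tS1,S2\n"
    )
    return load_hierarchy(io.StringIO(table))


def graph_from_scores(scores):
    """HitGraph from {(a, b): score}, bypassing the 50-bit filter."""
    hits = []
    for (a, b), s in scores.items():
        hits.append(Hit(a, b, s))
    return symmetrize(hits)


def make_ogset(level, *member_groups):
    return OGSet(
        level=level,
        groups=[
            OG(id=str(i), level=level, members=set(g))
            for i, g in enumerate(member_groups)
        ],
    )


@pytest.fixture
def graph_builder():
    return graph_from_scores


@pytest.fixture
def ogset_builder():
    return make_ogset
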