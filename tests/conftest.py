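"""Shared fixtures: windows, printed haplotypes, toy populations."""

import pytest

from mtcrpop.codec import parse_haplotype
from mtcrpop.haplogroups import packaged_tree
from mtcrpop.io import PopulationSample

CR = ((16024, 16569), (1, 576))
HVS1 = ((16024, 16383),)

B5A_TOKENS = "73-210-263-315.1C-523del-524del-16140-16183C-16189-16266A-16519"
F1A1_TOKENS = "73-249del-263-315.1C-523del-524del-16129-16162-16172-16304-16399-16519"


@pytest.fixture(scope="session")
def cr_window():
    return CR


@pytest.fixture(scope="session")
def tree():
    return packaged_tree()


@pytest.fixture
def b5a():
    return parse_haplotype(B5A_TOKENS, CR, "B5a_common")


@pytest.fixture
def f1a1():
    return parse_haplotype(F1A1_TOKENS, CR, "F1a1_common")


def make_pop(name, rows, ranges=CR):
    """Build a population from (sample_id, token_string) pairs."""
    pop = PopulationSample(name)
    for sid, tokens in rows:
        pop.haplotypes.append(parse_haplotype(tokens, ranges, sid))
    return pop


@pytest.fixture
def toy_2plus2():
    """Two monomorphic populations one difference apart."""
    p1 = make_pop("p1", [("a1", "73"), ("a2", "73")], ((1, 576),))
    p2 = make_pop("p2", [("b1", "73 263"), ("b2", "73 263")], ((1, 576),))
    return p1, p2
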