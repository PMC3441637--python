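import pytest

from denovotx.phylo import SpeciesTree


@pytest.fixture
def tree5() -> SpeciesTree:
    """The five-species backbone used throughout: apes + out-groups."""
    return SpeciesTree.from_newick("((human,chimp),(rhesus,(mouse,dog)));")


@pytest.fixture
def tree3() -> SpeciesTree:
    return SpeciesTree.from_newick("((human,chimp),rhesus);")
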