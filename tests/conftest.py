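import pytest

from phylokit import read_newick

# The four-taxon worked tree used throughout: two cherries, internal
# branches 1 and 4, root branch undefined.
WORKED_NEWICK = "((a:2,b:2):1,(c:1,d:1):4);"


@pytest.fixture
def worked_tree():
    return read_newick(WORKED_NEWICK)
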