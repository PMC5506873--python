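import pytest

from biaslens.core_io import parse_newick
from biaslens import synthetic


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)


@pytest.fixture
def star5():
    return parse_newick("(a:1,b:1,c:1,d:1,e:1);", rooted=True)


@pytest.fixture
def basic_tree():
    return parse_newick("((A:1,B:1):1,C:2);", rooted=True)


@pytest.fixture(scope="session")
def yule16():
    return synthetic.gen_tree(16, seed=16)


@pytest.fixture(scope="session")
def bundle():
    return synthetic.gen_bundle(seed=0)


@pytest.fixture
def fixture_trees():
    """Small trees (<= 8 tips) used by the oracle-equivalence checks."""
    return [
        parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True),
        parse_newick("(a:1,b:1,c:1,d:1,e:1,f:1);", rooted=True),
        parse_newick("((((p:0.2,q:0.4):0.3,r:1.1):0.5,s:2.0):0.1,t:2.5);", rooted=True),
        synthetic.gen_tree(8, seed=3),
        synthetic.gen_tree(7, birth_rate=2.5, seed=11),
    ]
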