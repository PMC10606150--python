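import pytest

from snptree import build_tree, demo_matrix


@pytest.fixture(scope="session")
def demo():
    return demo_matrix()


@pytest.fixture(scope="session")
def demo_result(demo):
    """Full pipeline result on the worked-example matrix (computed once)."""
    return build_tree(demo)
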