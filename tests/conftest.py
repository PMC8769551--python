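import pytest

from abseek import default_tree


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture
def toy_tree_file(tmp_path):
    """Minimal user tree: root plus one 3-member child and its leaves."""
    text = (
        "# code\tparent\tmembers\tlabel\n"
        "R\t\tACDEFGHIKLMNPQRSTVWY\troot\n"
        "small\tR\tAGS\tsmall residues\n"
        "A\tsmall\tA\t\n"
        "G\tsmall\tG\t\n"
        "S\tsmall\tS\t\n"
    )
    path = tmp_path / "toy_tree.tsv"
    path.write_text(text)
    return path


def leaf_query_codes(regions):
    """Spell a sequence as singleton leaf codes of the default tree."""
    return {r: tuple(seq) for r, seq in regions.items()}
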