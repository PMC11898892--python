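import pytest

from hgtscan.screening import ScreenConfig
from hgtscan.synthetic import generate_taxonomy
from hgtscan.taxonomy import Lineage
from hgtscan.tree_classify import ClassifyConfig


@pytest.fixture(scope="session")
def taxonomy():
    """The default toy species taxonomy (208 species, 2 superkingdoms)."""
    return generate_taxonomy()


@pytest.fixture(scope="session")
def classify_config():
    return ClassifyConfig()


@pytest.fixture(scope="session")
def screen_config():
    return ScreenConfig()


def make_lineage(*pairs):
    """Shorthand: make_lineage(("superkingdom","Bacteria"), ...)."""
    return Lineage.from_pairs(pairs)


FUNGAL_Q = Lineage.from_pairs(
    [
        ("superkingdom", "Eukaryota"),
        ("kingdom", "Fungi"),
        ("phylum", "Ascomycota"),
        ("class", "Pezizomycotina"),
        ("order", "Ord1"),
        ("family", "Fam1"),
        ("genus", "Gen1"),
        ("species", "Gen1_spA"),
    ]
)

BACTERIAL = Lineage.from_pairs(
    [
        ("superkingdom", "Bacteria"),
        ("phylum", "Proteobacteria"),
        ("class", "Gammaproteobacteria"),
        ("order", "BOrd"),
        ("family", "BFam"),
        ("genus", "BGen"),
        ("species", "BGen_sp"),
    ]
)
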