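import pytest

from fluencyscreen.taxonomy import LexiconEntry, Taxonomy, default_taxonomy


def entry(canonical, subcats, variants=()):
    return LexiconEntry(canonical, tuple(variants), frozenset(subcats))


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Three subcategories (pets/sea/birds) with single and multi members.

    The eight animals cover all seven non-empty membership patterns, so
    exhaustive segmentation checks exercise every intersection case.
    """
    return Taxonomy(
        [
            entry("dog", {"pets"}, variants=("puppy",)),
            entry("cat", {"pets"}),
            entry("whale", {"sea"}),
            entry("shark", {"sea"}),
            entry("eagle", {"birds"}),
            entry("otter", {"pets", "sea"}),
            entry("penguin", {"sea", "birds"}),
            entry("duck", {"pets", "sea", "birds"}),
        ]
    )


@pytest.fixture(scope="session")
def disjoint_taxonomy():
    """Single-membership subcategories only (no accidental cluster merges)."""
    groups = {
        "pets": ["dog", "cat", "hamster", "rabbit", "ferret"],
        "sea": ["whale", "shark", "squid", "octopus", "eel"],
        "birds": ["eagle", "owl", "crow", "sparrow", "robin"],
        "insects": ["ant", "bee", "wasp", "moth", "beetle"],
        "reptiles": ["snake", "lizard", "gecko", "iguana", "turtle"],
        "farm": ["cow", "pig", "horse", "sheep", "goat"],
    }
    return Taxonomy(
        [entry(name, {sub}) for sub, names in groups.items() for name in names]
    )


@pytest.fixture(scope="session")
def lexicon():
    """The bundled default English animal taxonomy."""
    return default_taxonomy()
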