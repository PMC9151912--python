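import pytest

from pol3atlas.annotation import AnnotationSet, GeneRecord
from pol3atlas.synthetic_data import SimConfig, simulate


@pytest.fixture
def toy_annotation() -> AnnotationSet:
    return AnnotationSet(
        [
            GeneRecord("URS0000AAAA", "chr1", 100, 200, "+",
                       gene_class="tRNA"),
            GeneRecord("URS0000BBBB", "chr1", 1000, 1100, "-",
                       gene_class="SNAR"),
            GeneRecord("URS0000CCCC", "chr2", 50, 120, ".",
                       gene_class="other"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulation shared by read-only tests."""
    cfg = SimConfig(
        n_genes=300, n_enhanced=8, n_occupied=60, n_samples=4,
        n_accessible_background=5, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (expensive; shared, treat as read-only)."""
    return simulate(SimConfig())
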