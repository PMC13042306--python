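import pytest

from taxsieve.simulate import generate_community
from taxsieve.taxonomy import Taxonomy, TaxonomyNode


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """Two genera in one family; genus 20 holds two sister species plus a
    strain, genus 30 one species.  TaxIDs are stable for assertions."""
    return Taxonomy(
        [
            TaxonomyNode(1, 1, "no-rank", "root"),
            TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
            TaxonomyNode(3, 2, "phylum", "Testota"),
            TaxonomyNode(4, 3, "class", "Testia"),
            TaxonomyNode(5, 4, "order", "Testales"),
            TaxonomyNode(10, 5, "family", "Testaceae"),
            TaxonomyNode(20, 10, "genus", "Testus"),
            TaxonomyNode(21, 20, "species", "Testus primus"),
            TaxonomyNode(22, 20, "species", "Testus secundus"),
            TaxonomyNode(23, 21, "strain", "Testus primus T1"),
            TaxonomyNode(30, 10, "genus", "Altus"),
            TaxonomyNode(31, 30, "species", "Altus unicus"),
        ]
    )


@pytest.fixture(scope="session")
def clean_community():
    """Default 10-taxon community used by the recovery and concordance tests."""
    return generate_community(n_taxa=10, seed=11)


@pytest.fixture(scope="session")
def balanced_community():
    """Equal genome lengths and contig counts: the balanced design used for
    reference-ablation experiments."""
    return generate_community(
        n_taxa=10, genome_len_range=(30_000, 30_000), n_fragments_per_genome=10,
        seed=11,
    )
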