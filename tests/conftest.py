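import pytest

from taxafunc import godb
from taxafunc.synthetic_fixtures import FixtureSpec, write_fixture_dir
from taxafunc.types import GoDag, GoTerm, TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """Root -> superkingdom -> genus -> species {2, 4}; strain 3 under 2."""
    return TaxonomyTree(
        {
            1: TaxonNode(1, "no rank", "root"),
            9: TaxonNode(1, "superkingdom", "Bacteria"),
            8: TaxonNode(9, "phylum", "ToyPhylum"),
            7: TaxonNode(8, "genus", "Toyogenus"),
            2: TaxonNode(7, "species", "Toyococcus a"),
            3: TaxonNode(2, "strain", "Toyococcus a str. X"),
            4: TaxonNode(7, "species", "Toyococcus b"),
            5: TaxonNode(2, "no rank", "Toyococcus a unclassified isolate"),
        }
    )


@pytest.fixture(scope="session")
def diamond_dag() -> GoDag:
    """C is_a B is_a A(root), plus C part_of A: two paths from C to A."""
    return GoDag(
        {
            "GO:0000001": GoTerm("A", "biological_process", [], []),
            "GO:0000002": GoTerm("B", "biological_process", ["GO:0000001"], []),
            "GO:0000003": GoTerm(
                "C", "biological_process", ["GO:0000002"], ["GO:0000001"]
            ),
        }
    )


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    # scaled-down dataset so the suite stays fast; statistical acceptance
    # checks build their own full-size specs
    return FixtureSpec(seed=11, n_per_group=3, n_reads=4000)


@pytest.fixture(scope="session")
def fixture_dir(fixture_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture_dir(fixture_spec, out)
    store = godb.build_store(
        godb.read_membership(paths["membership"]),
        godb.read_idmapping(paths["idmapping"]),
        godb.read_gaf(paths["gaf"]),
    )
    paths["store"] = godb.save_store(store, out / "accession_go.sqlite")
    return paths
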