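import pytest

from cazydb.datastore import import_dump, init_store
from cazydb.enrichment import (
    attach_assemblies,
    attach_gtdb_lineage,
    attach_ncbi_lineage,
    attach_uniprot,
)
from cazydb.fixtures import ClusterPlan, FixtureSpec, generate_fixture
from cazydb.formats import read_dump, read_snapshot

#: Base study plan used across the suite: three families (one with a
#: subfamily cell) spread over three kingdoms, with every kind of planted
#: irregularity the importer must handle.
BASE_COUNTS = (
    ("GH5", "Bacteria", 6),
    ("GH5", "Archaea", 4),
    ("GH5_4", "Bacteria", 3),
    ("PL20", "Bacteria", 6),
    ("PL20", "Eukaryota", 6),
    ("CE1", "Bacteria", 5),
    ("CE1", "Eukaryota", 3),
)

STANDARD_SPEC = FixtureSpec(
    family_kingdom_counts=BASE_COUNTS,
    n_multifamily_proteins=2,
    n_redundant_pairs=3,
    n_multitaxon_conflicts=2,
    cluster_plan=ClusterPlan("PL20", (4, 4, 3), within_identity=0.9, between_identity=0.2),
    uniprot_miss_fraction=0.1,
    pdb_per_family=(("CE1", 2), ("PL20", 1)),
    n_candidatus=2,
    n_incomplete=1,
    n_no_assembly=2,
    rng_seed=20220113,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    truth = generate_fixture(STANDARD_SPEC, out)
    return out, truth


@pytest.fixture(scope="session")
def truth(fixture_dir):
    return fixture_dir[1]


@pytest.fixture(scope="session")
def dump_records(fixture_dir):
    records, report = read_dump(fixture_dir[0] / "cazy_dump.tsv")
    assert not report.issues
    return records


def build_store(path, fixture_dir, enrich=True):
    out, _ = fixture_dir
    records, _ = read_dump(out / "cazy_dump.tsv")
    store = init_store(path)
    import_dump(store, records)
    if enrich:
        uniprot, _ = read_snapshot(out / "uniprot.tsv", "uniprot")
        attach_uniprot(store, uniprot)
        ncbi, _ = read_snapshot(out / "ncbi_tax.tsv", "ncbi_tax")
        attach_ncbi_lineage(store, ncbi)
        assemblies, _ = read_snapshot(out / "assembly.tsv", "assembly")
        attach_assemblies(store, assemblies)
        gtdb, _ = read_snapshot(out / "gtdb_tax.tsv", "gtdb_tax")
        attach_gtdb_lineage(store, gtdb)
    return store


@pytest.fixture(scope="session")
def enriched_store(fixture_dir, tmp_path_factory):
    """Read-only store with the full fixture imported and enriched."""
    path = tmp_path_factory.mktemp("db") / "enriched.sqlite"
    store = build_store(path, fixture_dir, enrich=True)
    yield store
    store.close()


@pytest.fixture()
def fresh_store(fixture_dir, tmp_path):
    """Writable store with only the dump imported (per-test copy)."""
    store = build_store(tmp_path / "fresh.sqlite", fixture_dir, enrich=False)
    yield store
    store.close()
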