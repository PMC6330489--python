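import tempfile
from functools import lru_cache
from types import SimpleNamespace

import pytest

import goshare
from goshare import fixtures

CHAIN_OBO = """format-version: 1.2
ontology: test-chain

[Term]
id: GO:0000001
name: apex
namespace: biological_process

[Term]
id: GO:0000002
name: middle
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000001

[Term]
id: GO:0000003
name: tip
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: retired
namespace: biological_process
is_obsolete: true
"""


def write_text(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


def gaf_line(gene_id, symbol, term, evidence="IDA", qualifier="involved_in", aspect="P"):
    return "\t".join(
        ("TESTDB", gene_id, symbol, qualifier, term, "TESTDB:REF:1", evidence,
         "", aspect, "", "", "protein", "taxon:9606", "20180101", "TESTDB", "", "")
    )


@pytest.fixture
def chain_dag(tmp_path):
    """Three-term is_a chain apex <- middle <- tip, plus one obsolete term."""
    return goshare.parse_obo(write_text(tmp_path, "chain.obo", CHAIN_OBO))


@lru_cache(maxsize=None)
def generated_bundle(seed, n_terms=12, n_genes=30, plant_quarantined=False):
    """Generate a synthetic fixture and run it through the parsers once."""
    workdir = tempfile.mkdtemp(prefix=f"goshare-fix-{seed}-")
    manifest = fixtures.generate(
        seed, workdir, n_terms=n_terms, n_genes=n_genes,
        plant_quarantined=plant_quarantined,
    )
    dag = goshare.parse_obo(manifest.files["obo"])
    records = goshare.read_gaf(manifest.files["gaf"])
    index = goshare.build_index(records, dag, propagate=True)
    genes_a, _ = goshare.map_genes(index, manifest.list_a)
    genes_b, _ = goshare.map_genes(index, manifest.list_b)
    return SimpleNamespace(
        manifest=manifest, dag=dag, records=records, index=index,
        genes_a=genes_a, genes_b=genes_b,
    )


@pytest.fixture(scope="session")
def bundle():
    """One representative generated fixture, shared across the session."""
    return generated_bundle(7)


def run_rows(bundle, mode, threshold):
    """Pipeline output normalised for comparison with oracle rows."""
    import warnings

    cfg = goshare.TrapConfig(mode=mode, threshold=threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = goshare.run(
            cfg, bundle.dag, bundle.index, bundle.genes_a,
            bundle.genes_b if mode == "between" else None,
        )
    return [
        (t.term_id, t.category, t.background_genes, t.shared_genes, round(t.score, 9))
        for t in out
    ]


def oracle_rows(manifest, mode, threshold):
    return [
        (r[0], r[1], r[2], tuple(r[3]), round(r[4], 9))
        for r in fixtures.oracle(manifest, mode, threshold)
    ]
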