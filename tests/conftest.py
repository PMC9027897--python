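import pytest

from alulnc import (
    build_gene_models,
    catalog_from_bed,
    load_published_candidates,
    read_bed,
    read_gtf,
    simulate_annotation,
)
from alulnc.discovery import TssRecord


@pytest.fixture(scope="session")
def published_candidates():
    return load_published_candidates()


@pytest.fixture(scope="session")
def sim50(tmp_path_factory):
    """50-gene simulated annotation written to disk and read back through
    the pipeline's own readers (exercises the file dialects, not just the
    in-memory objects)."""
    ann = simulate_annotation(50, seed=1)
    paths = ann.write(tmp_path_factory.mktemp("sim50"))
    genes = build_gene_models(read_gtf(paths["genes_gtf"], "ensembl"))
    catalog = catalog_from_bed(paths["alu_bed"])
    tss = [
        TssRecord(iv.chrom, iv.start, iv.strand)
        for iv, _, _ in read_bed(paths["tss_bed"])
    ]
    return ann, genes, catalog, tss
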