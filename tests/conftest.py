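import pytest

from biosync import Datastore, PipelineConfig, generate_universe
from biosync.datastore import InsertRecord, InsertXref


@pytest.fixture
def store():
    return Datastore()


@pytest.fixture
def gene_config():
    def make(**overrides):
        kwargs = dict(
            pipeline_name="gene_sync",
            species_processed=("rat",),
            registered_assemblies=("GRCr8",),
        )
        kwargs.update(overrides)
        return PipelineConfig(**kwargs)

    return make


@pytest.fixture
def universe():
    return generate_universe(50, species="rat", seed=7)


def seed_gene(store, *, species="rat", symbol="Abc1", ncbi=None, accessions=(),
              hgnc=None, ensembl=None, attribution="gene_sync", ts=0):
    """Insert one active gene with the given identifiers; returns its id."""
    sid = store.allocate_stable_id()
    muts = [InsertRecord(stable_id=sid, species=species, symbol=symbol, ts=ts)]
    if ncbi:
        muts.append(InsertXref(sid, "NCBIGene", ncbi, attribution, ts))
    if hgnc:
        muts.append(InsertXref(sid, "HGNC", hgnc, attribution, ts))
    if ensembl:
        muts.append(InsertXref(sid, "EnsemblGene", ensembl, attribution, ts))
    for acc in accessions:
        muts.append(InsertXref(sid, "SeqAccession", acc, attribution, ts))
    store.apply_atomic(muts)
    return sid
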