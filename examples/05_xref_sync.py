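"""External-ID association import, PharmGKB style.

A tab-delimited file maps PharmGKB accessions to HGNC/NCBI/Ensembl gene
IDs.  Each row is paired with a resident gene by identifier priority
(HGNC first, then NCBI, then Ensembl); the pipeline confirms the
association xref exists or adds it.  On a re-run with one accession
removed from the file, the sweep deletes exactly that association
(1/20 = 5%, at the cap).
"""

from pathlib import Path

from biosync import Datastore, PipelineConfig, generate_universe, write_xref_file
from biosync.pipelines import run_gene_sync, run_xref_sync

out = Path("scratch_example_xref")
out.mkdir(exist_ok=True)

# resident genes come from a prior gene-record import
store = Datastore()
state = generate_universe(20, species="human", seed=9)
run_gene_sync(store, PipelineConfig(pipeline_name="gene_sync",
                                    species_processed=("human",),
                                    registered_assemblies=("GRCr8",)), state)

xref_config = PipelineConfig(pipeline_name="xref_sync", species_processed=("human",))
path = write_xref_file(state, out / "xrefs.tsv")

summary = run_xref_sync(store, xref_config, path)
print(f"first run: {summary.counters.inserted} associations added")

summary = run_xref_sync(store, xref_config, path)
c = summary.counters
print(f"re-run: inserted={c.inserted} unchanged={c.unchanged} deleted={c.deleted}")

lines = path.read_text().splitlines()
dropped = lines[1].split("\t")[0]
path.write_text("\n".join([lines[0]] + lines[2:]) + "\n")
summary = run_xref_sync(store, xref_config, path)
print(f"after dropping {dropped} from the file: deleted={summary.counters.deleted}"
      f" (the sweep removed exactly the vanished association)")
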