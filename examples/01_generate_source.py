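"""Generate a synthetic source universe and one weekly drift step.

The generator stands in for a remote gene database: every record gets an
NCBI-style numeric ID, most get HGNC/Ensembl IDs, and each carries
sequence accessions and a genomic position.  The drift step then emulates
a week of upstream change and hands back the exact manifest of what moved
— the ground truth the sync pipelines are tested against.
"""

from pathlib import Path

from biosync import DriftParams, drift, generate_universe, write_gene_file, write_xref_file

out = Path("scratch_example_source")
out.mkdir(exist_ok=True)

state = generate_universe(200, species="rat", seed=7)
write_gene_file(state, out / "genes.tsv")
write_xref_file(state, out / "xrefs.tsv")
print(f"universe: {len(state)} records -> {out}/genes.tsv, {out}/xrefs.tsv")

params = DriftParams(f_new=0.02, f_changed=0.05, f_removed=0.02)
drifted, manifest = drift(state, params, seed=7)
write_gene_file(drifted, out / "genes.v1.tsv")
print(
    f"drift step: {len(manifest.added)} added, {len(manifest.changed)} changed,"
    f" {len(manifest.removed)} removed (of {len(state)})"
)
# The manifest names each key, so a sync run over genes.v1.tsv can be
# checked record-for-record: inserts must equal `added`, the sweep's
# deletions must equal `removed`.
print("removed keys:", ", ".join(manifest.removed))
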