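"""Drop-and-reload reference oracle.

The incremental engine's correctness claim is that after any sequence of
source drifts, the store holds exactly what a naive drop-and-reload of the
final source snapshot would have produced — except that stable IDs
persist.  This module computes both sides of that equivalence in a common
timestamp-free, stable-ID-free canonical form:

* :func:`reload_content` — what a from-scratch load of a source state
  would contain (the oracle); it never touches a datastore.
* :func:`store_content` — the same canonical view extracted from a live
  store's active records.

The oracle is used only by tests and the acceptance script; the sync path
never calls it.
"""

from __future__ import annotations

from typing import Optional

from .datastore import Datastore
from .matching import normalize_accession
from .synthetic_source import SourceState


def reload_content(state: SourceState) -> dict:
    """Canonical content a drop-and-reload of ``state`` would produce,
    keyed by NCBI gene ID."""
    out = {}
    for rec in state.records.values():
        xrefs = {("NCBIGene", rec.ncbi_gene_id)}
        if rec.hgnc_id:
            xrefs.add(("HGNC", rec.hgnc_id))
        if rec.ensembl_id:
            xrefs.add(("EnsemblGene", rec.ensembl_id))
        for acc in rec.seq_accessions:
            xrefs.add(("SeqAccession", normalize_accession(acc)))
        out[rec.ncbi_gene_id] = {
            "species": rec.species,
            "symbol": rec.symbol,
            "name": rec.name,
            "xrefs": frozenset(xrefs),
            "positions": frozenset(
                (p.assembly, p.chrom, p.start, p.stop, p.strand) for p in rec.positions
            ),
        }
    return out


def store_content(store: Datastore, attribution: str, species: Optional[str] = None) -> dict:
    """The same canonical view over a store's *active* genes, restricted
    to rows carrying ``attribution``.  Timestamps and stable IDs are
    deliberately absent so the view is directly comparable with
    :func:`reload_content`."""
    snap = store.snapshot(attribution=attribution)
    xrefs_by_owner: dict[int, set] = {}
    for x in snap.xrefs:
        xrefs_by_owner.setdefault(x.owner, set()).add((x.xref_db, x.accession))
    pos_by_owner: dict[int, set] = {}
    for p in snap.positions:
        pos_by_owner.setdefault(p.owner, set()).add(
            (p.assembly, p.chrom, p.start, p.stop, p.strand)
        )
    out = {}
    for rec in snap.records:
        if rec.status != "active" or rec.object_type != "gene":
            continue
        if species is not None and rec.species != species:
            continue
        ncbi = [acc for db, acc in xrefs_by_owner.get(rec.stable_id, ()) if db == "NCBIGene"]
        if not ncbi:
            continue  # not sourced by this pipeline
        out[ncbi[0]] = {
            "species": rec.species,
            "symbol": rec.symbol,
            "name": rec.name,
            "xrefs": frozenset(xrefs_by_owner.get(rec.stable_id, set())),
            "positions": frozenset(pos_by_owner.get(rec.stable_id, set())),
        }
    return out


def content_diff(expected: dict, actual: dict) -> list[str]:
    """Human-readable differences between two canonical views; empty when
    equivalent."""
    diffs = []
    for key in sorted(set(expected) | set(actual)):
        if key not in actual:
            diffs.append(f"missing from store: {key}")
        elif key not in expected:
            diffs.append(f"unexpected in store: {key}")
        elif expected[key] != actual[key]:
            for fieldname in ("species", "symbol", "name", "xrefs", "positions"):
                if expected[key][fieldname] != actual[key][fieldname]:
                    diffs.append(
                        f"{key}.{fieldname}: expected {expected[key][fieldname]!r},"
                        f" got {actual[key][fieldname]!r}"
                    )
    return diffs
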