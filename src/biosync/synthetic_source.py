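"""Seeded synthetic source universe with weekly-style drift.

This module stands in for the remote gene databases a sync pipeline would
normally download from, so that every test and example is download-free.
It generates a "truth" universe of gene-like records with internally
consistent identifiers (numeric NCBI-style IDs, ``HGNC:n`` on ~60% of
records, ``ENSG…`` on ~80%, one to three sequence accessions, one position
per registered assembly, and a ``PA…`` accession for the xref dialect),
then evolves it between runs by configurable drift fractions: some records
new, some changed by a single field mutation, some removed.  Every drift
step returns a manifest of exactly which keys were added, changed, and
removed — the ground truth that sync tests check their plans and sweeps
against.

Change mutations are deliberately conservative, the way real weekly
updates are: an accession mutation *appends* a new accession (the old ones
remain valid), a position mutation shifts an interval on the same
chromosome, a symbol mutation renames.  A changed record therefore still
satisfies all three match criteria on the next run.

Everything is a pure function of its inputs and a seed.  A single global
seed is expanded into per-component streams by stable hashing of the
component name, so adding a new generator never perturbs the output of an
existing one.
"""

from __future__ import annotations

import hashlib
import random
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .matching import GenePosition, IncomingGene


def derive_seed(component: str, seed: int) -> int:
    """Expand a global seed into a stable per-component stream seed."""
    digest = hashlib.sha256(f"{component}:{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SourceRecord:
    source_key: str
    species: str
    symbol: str
    name: str
    ncbi_gene_id: str
    hgnc_id: Optional[str]
    ensembl_id: Optional[str]
    pharmgkb_id: Optional[str]
    seq_accessions: tuple[str, ...]
    positions: tuple[GenePosition, ...]
    stable_id: Optional[int] = None  # set once the sink writes IDs back

    def to_incoming(self) -> IncomingGene:
        return IncomingGene(
            source_key=self.source_key,
            species=self.species,
            symbol=self.symbol,
            name=self.name,
            stable_id_claim=self.stable_id,
            ncbi_gene_id=self.ncbi_gene_id,
            hgnc_id=self.hgnc_id,
            ensembl_id=self.ensembl_id,
            seq_accessions=self.seq_accessions,
            positions=self.positions,
        )


@dataclass(frozen=True)
class DriftParams:
    f_new: float = 0.0
    f_changed: float = 0.0
    f_removed: float = 0.0

    def __post_init__(self):
        for name in ("f_new", "f_changed", "f_removed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.f_changed + self.f_removed > 1.0:
            raise ValueError("f_changed + f_removed must not exceed 1")


@dataclass(frozen=True)
class DriftManifest:
    """Ground truth for one drift step: exactly which keys moved."""

    added: tuple[str, ...]
    changed: tuple[str, ...]
    removed: tuple[str, ...]
    changed_fields: dict = field(default_factory=dict)  # key -> mutated field name


@dataclass
class SourceState:
    records: dict[str, SourceRecord]
    version: int = 0
    species: str = "rat"
    assemblies: tuple[str, ...] = ("GRCr8",)
    next_serial: int = 0  # monotonically increasing id counter

    def __len__(self) -> int:
        return len(self.records)

    def incoming(self) -> list[IncomingGene]:
        return [r.to_incoming() for r in self.records.values()]

    def with_stable_ids(self, assignments: dict[str, int]) -> "SourceState":
        """Return a copy with stable IDs written back onto the named
        records — the loop by which the source comes to echo the sink's
        identifiers (as NCBI gene records carry RGD accessions)."""
        records = dict(self.records)
        for key, stable_id in assignments.items():
            if key in records:
                records[key] = replace(records[key], stable_id=stable_id)
        return SourceState(records, self.version, self.species, self.assemblies, self.next_serial)


def _make_record(serial: int, species: str, assemblies: Sequence[str], rng: random.Random) -> SourceRecord:
    key = f"G{serial:06d}"
    positions = tuple(
        GenePosition(
            assembly=asm,
            chrom=str(rng.randint(1, 20)),
            start=(start := rng.randint(1, 90_000_000)),
            stop=start + rng.randint(500, 100_000),
            strand=rng.choice("+-"),
        )
        for asm in assemblies
    )
    return SourceRecord(
        source_key=key,
        species=species,
        symbol=f"Sym{serial}",
        name=f"synthetic gene {serial}",
        ncbi_gene_id=str(100_000 + serial),
        hgnc_id=f"HGNC:{10_000 + serial}" if rng.random() < 0.60 else None,
        ensembl_id=f"ENSG{serial:011d}" if rng.random() < 0.80 else None,
        pharmgkb_id=f"PA{20_000 + serial}",
        seq_accessions=tuple(
            f"NM_{serial * 10 + j:07d}" for j in range(rng.randint(1, 3))
        ),
        positions=positions,
    )


def generate_universe(
    n: int,
    species: str = "rat",
    seed: int = 0,
    assemblies: Sequence[str] = ("GRCr8",),
) -> SourceState:
    """Generate ``n`` internally consistent records, reproducibly."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(derive_seed("universe", seed))
    records = {}
    for serial in range(n):
        rec = _make_record(serial, species, assemblies, rng)
        records[rec.source_key] = rec
    return SourceState(records=records, version=0, species=species,
                       assemblies=tuple(assemblies), next_serial=n)


def drift(state: SourceState, params: DriftParams, seed: int) -> tuple[SourceState, DriftManifest]:
    """Advance the source by one weekly-style step.

    Removes ``round(f_removed·n)`` records, mutates one field on
    ``round(f_changed·n)`` of the survivors, appends ``round(f_new·n)``
    fresh records, and returns the new state (version + 1) together with
    the exact manifest of what happened.
    """
    rng = random.Random(derive_seed(f"drift:{state.version + 1}", seed))
    n = len(state.records)
    n_removed = round(params.f_removed * n)
    n_changed = round(params.f_changed * n)
    n_new = round(params.f_new * n)

    keys = list(state.records)
    removed = sorted(rng.sample(keys, n_removed)) if n_removed else []
    survivors = [k for k in keys if k not in set(removed)]
    changed = sorted(rng.sample(survivors, n_changed)) if n_changed else []

    records = {k: v for k, v in state.records.items() if k not in set(removed)}
    serial = state.next_serial
    changed_fields: dict[str, str] = {}
    for key in changed:
        rec = records[key]
        kind = rng.choice(("position", "accession", "symbol"))
        changed_fields[key] = kind
        if kind == "position" and rec.positions:
            i = rng.randrange(len(rec.positions))
            pos = rec.positions[i]
            delta = rng.randint(1, 5000)
            moved = GenePosition(pos.assembly, pos.chrom, pos.start + delta,
                                 pos.stop + delta, pos.strand)
            records[key] = replace(
                rec, positions=rec.positions[:i] + (moved,) + rec.positions[i + 1:]
            )
        elif kind == "accession":
            # append: old accessions stay valid, so the record still matches
            records[key] = replace(
                rec, seq_accessions=rec.seq_accessions + (f"NM_{9_000_000 + serial:07d}",)
            )
            serial += 1
        else:
            records[key] = replace(rec, symbol=rec.symbol + "r")

    added = []
    for _ in range(n_new):
        rec = _make_record(serial, state.species, state.assemblies, rng)
        serial += 1
        records[rec.source_key] = rec
        added.append(rec.source_key)

    new_state = SourceState(records, state.version + 1, state.species,
                            state.assemblies, serial)
    manifest = DriftManifest(tuple(added), tuple(changed), tuple(removed), changed_fields)
    return new_state, manifest


# ---------------------------------------------------------------------------
# File dialects

GENE_FILE_COLUMNS = (
    "source_key", "species", "symbol", "name", "ncbi_gene_id",
    "seq_accessions", "hgnc_id", "ensembl_id", "positions", "stable_id",
)

XREF_FILE_COLUMNS = (
    "PharmGKB Accession Id", "NCBI Gene ID", "HGNC ID", "Ensembl Id", "Symbol",
)


def _format_positions(positions: Sequence[GenePosition]) -> str:
    return ";".join(f"{p.assembly}:{p.chrom}:{p.start}-{p.stop}:{p.strand}" for p in positions)


def write_gene_file(state: SourceState, path) -> Path:
    """Serialize the gene-record dialect: one TSV row per record, lists
    joined with ``;``, positions as ``assembly:chrom:start-stop:strand``."""
    path = Path(path)
    lines = ["\t".join(GENE_FILE_COLUMNS)]
    for rec in state.records.values():
        lines.append("\t".join([
            rec.source_key, rec.species, rec.symbol, rec.name, rec.ncbi_gene_id,
            ";".join(rec.seq_accessions), rec.hgnc_id or "", rec.ensembl_id or "",
            _format_positions(rec.positions),
            "" if rec.stable_id is None else str(rec.stable_id),
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_xref_file(state: SourceState, path, zip_container: bool = False) -> Path:
    """Serialize the xref-association dialect (PharmGKB genes-file style).

    With ``zip_container`` the TSV is wrapped in a zip archive, mirroring
    the source's ``genes.zip`` distribution.
    """
    path = Path(path)
    lines = ["\t".join(XREF_FILE_COLUMNS)]
    for rec in state.records.values():
        if rec.pharmgkb_id is None:
            continue
        lines.append("\t".join([
            rec.pharmgkb_id, rec.ncbi_gene_id, rec.hgnc_id or "",
            rec.ensembl_id or "", rec.symbol,
        ]))
    text = "\n".join(lines) + "\n"
    if zip_container:
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("genes.tsv", text)
    else:
        path.write_text(text)
    return path


def write_manifest(manifest: DriftManifest, path) -> Path:
    path = Path(path)
    lines = ["change\tsource_key\tfield"]
    for key in manifest.added:
        lines.append(f"added\t{key}\t")
    for key in manifest.changed:
        lines.append(f"changed\t{key}\t{manifest.changed_fields.get(key, '')}")
    for key in manifest.removed:
        lines.append(f"removed\t{key}\t")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Mock endpoint


class MockEndpoint:
    """Batched endpoint over a source state, with failure injection.

    A request for more than ``capacity`` ids always fails (the rate
    limit); otherwise it fails with probability ``p_fail``, returning a
    seeded random strict subset of the requested records.  Unknown ids are
    silently omitted from the return, which the fetcher treats as a
    failure.  Instances with the same state and seed replay identically.
    """

    def __init__(self, state: SourceState, capacity: int, p_fail: float = 0.0, seed: int = 0):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if not (0.0 <= p_fail <= 1.0):
            raise ValueError("p_fail must lie in [0, 1]")
        self._records = dict(state.records)
        self.capacity = capacity
        self.p_fail = p_fail
        self._rng = random.Random(derive_seed("endpoint", seed))
        self.request_count = 0

    def request(self, ids: Sequence[str]) -> tuple[dict, bool]:
        self.request_count += 1
        if len(ids) > self.capacity:
            return {}, False
        known = [i for i in ids if i in self._records]
        if self.p_fail and self._rng.random() < self.p_fail:
            keep = self._rng.sample(known, self._rng.randint(0, max(len(known) - 1, 0))) if known else []
            return {i: self._records[i] for i in keep}, False
        return {i: self._records[i] for i in known}, True


def mock_endpoint(state: SourceState, capacity: int, p_fail: float = 0.0, seed: int = 0) -> MockEndpoint:
    return MockEndpoint(state, capacity, p_fail, seed)
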