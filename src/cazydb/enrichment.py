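"""Attach annotations from snapshot providers to stored proteins.

Each provider is an offline snapshot (a keyed collection loaded by
:mod:`cazydb.formats`) standing behind the same interface a live client
would use: given a set of accessions, return whatever the source knows
about them.  Every ``attach_*`` operation is idempotent and
filter-respecting -- proteins outside the selection criteria are left
bit-identical -- and absent accessions are counted as misses, never
treated as errors.

:func:`run_batched` provides interrupt/resume semantics for long
retrievals: processed keys are persisted to a cache file before the
next batch starts, so a re-run after an interruption processes exactly
the remaining accessions and converges on the same final state.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .datastore import CazymeStore
from .formats import AssemblyMapping, LineageRecord, RANK_ORDER, UniProtEntry
from .selection import SelectionCriteria

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichSummary",
    "BatchSummary",
    "attach_uniprot",
    "attach_ncbi_lineage",
    "attach_gtdb_lineage",
    "attach_assemblies",
    "refresh_sequences",
    "run_batched",
]

DEFAULT_BATCH_SIZE = 150


@dataclass
class EnrichSummary:
    hits: int = 0
    misses: int = 0
    rows_added: int = 0
    rows_updated: int = 0
    unlinkable: int = 0


def _as_mapping(snapshot, key_attr: str) -> dict:
    if isinstance(snapshot, dict):
        return snapshot
    return {getattr(obj, key_attr): obj for obj in snapshot}


def attach_uniprot(
    store: CazymeStore,
    snapshot: Iterable[UniProtEntry] | dict[str, UniProtEntry],
    criteria: SelectionCriteria | None = None,
    fields: Sequence[str] = ("name", "ec", "pdb", "sequence"),
) -> EnrichSummary:
    """Attach UniProt id / protein name / EC numbers / PDB ids / sequence.

    ``fields`` selects what to write: any subset of {"name", "ec",
    "pdb", "sequence"}.  The UniProt id itself is always linked for a
    hit.  A stored sequence is only written when none is present (see
    :func:`refresh_sequences` for version-aware updates).
    """
    criteria = criteria or SelectionCriteria()
    lookup = _as_mapping(snapshot, "accession")
    unknown = set(fields) - {"name", "ec", "pdb", "sequence"}
    if unknown:
        raise ValueError(f"unknown uniprot fields: {sorted(unknown)}")
    summary = EnrichSummary()
    conn = store.conn
    with conn:
        for acc in store.matching_accessions(criteria):
            entry = lookup.get(acc)
            if entry is None:
                summary.misses += 1
                continue
            summary.hits += 1
            cur = conn.execute(
                "INSERT OR IGNORE INTO uniprot_links (accession, uniprot_id, protein_name)"
                " VALUES (?, ?, ?)",
                (acc, entry.uniprot_id,
                 entry.protein_name if "name" in fields else ""),
            )
            summary.rows_added += cur.rowcount
            if "ec" in fields:
                for ec in sorted(entry.ec_numbers):
                    cur = conn.execute(
                        "INSERT OR IGNORE INTO ec_links (accession, ec_number) VALUES (?, ?)",
                        (acc, ec))
                    summary.rows_added += cur.rowcount
            if "pdb" in fields:
                for pdb in sorted(entry.pdb_ids):
                    cur = conn.execute(
                        "INSERT OR IGNORE INTO pdb_links (accession, pdb_id) VALUES (?, ?)",
                        (acc, pdb))
                    summary.rows_added += cur.rowcount
            if "sequence" in fields and entry.sequence:
                cur = conn.execute(
                    "UPDATE proteins SET sequence = ?, sequence_source = 'uniprot',"
                    " sequence_version_date = ? WHERE accession = ? AND sequence IS NULL",
                    (entry.sequence, entry.version_date, acc))
                summary.rows_updated += cur.rowcount
    store.log("uniprot", criteria=",".join(sorted(fields)),
              rows_added=summary.rows_added, rows_updated=summary.rows_updated)
    return summary


def _write_lineage(conn, table: str, key_col: str, key: str, rec: LineageRecord) -> int:
    ranks = dict(rec.ranks)
    row = [ranks.get(r) for r in RANK_ORDER]
    existing = conn.execute(
        f'SELECT kingdom, phylum, class, "order", family, genus, species,'
        f" incomplete, candidatus FROM {table} WHERE {key_col} = ?", (key,)
    ).fetchone()
    new = tuple(row) + (int(rec.incomplete), int(rec.candidatus))
    if existing == new:
        return 0
    conn.execute(
        f"INSERT OR REPLACE INTO {table}"
        f' ({key_col}, kingdom, phylum, class, "order", family, genus, species,'
        f" incomplete, candidatus) VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
        (key, *new),
    )
    return 1


def attach_ncbi_lineage(
    store: CazymeStore,
    tax_snapshot: Iterable[LineageRecord] | dict[str, LineageRecord],
    criteria: SelectionCriteria | None = None,
) -> EnrichSummary:
    """Attach NCBI-taxonomy lineages (kingdom..species) keyed by accession.

    Incomplete and *Candidatus* lineages are stored with their flags set
    so queries can exclude them; they are never dropped here.
    """
    criteria = criteria or SelectionCriteria()
    lookup = _as_mapping(tax_snapshot, "key")
    summary = EnrichSummary()
    with store.conn as conn:
        for acc in store.matching_accessions(criteria):
            rec = lookup.get(acc)
            if rec is None:
                summary.misses += 1
                continue
            summary.hits += 1
            summary.rows_added += _write_lineage(conn, "ncbi_lineages", "accession", acc, rec)
    store.log("ncbi", rows_added=summary.rows_added)
    return summary


def attach_assemblies(
    store: CazymeStore,
    assembly_snapshot: Iterable[AssemblyMapping] | dict[str, AssemblyMapping],
    criteria: SelectionCriteria | None = None,
) -> EnrichSummary:
    """Attach genome-assembly links (accession -> assembly id)."""
    criteria = criteria or SelectionCriteria()
    lookup = _as_mapping(assembly_snapshot, "accession")
    summary = EnrichSummary()
    with store.conn as conn:
        for acc in store.matching_accessions(criteria):
            mapping = lookup.get(acc)
            if mapping is None:
                summary.misses += 1
                continue
            summary.hits += 1
            cur = conn.execute(
                "INSERT OR IGNORE INTO assembly_links (accession, assembly_id) VALUES (?, ?)",
                (acc, mapping.assembly_id))
            summary.rows_added += cur.rowcount
    store.log("ncbi", criteria="assemblies", rows_added=summary.rows_added)
    return summary


def attach_gtdb_lineage(
    store: CazymeStore,
    gtdb_snapshot: Iterable[LineageRecord] | dict[str, LineageRecord],
    criteria: SelectionCriteria | None = None,
) -> EnrichSummary:
    """Attach GTDB lineages, joined through the protein's assembly link.

    A protein without an assembly link cannot be placed in GTDB and is
    counted ``unlinkable``; an assembly absent from the snapshot is a
    miss.  Neither is an error.
    """
    criteria = criteria or SelectionCriteria()
    lookup = _as_mapping(gtdb_snapshot, "key")
    summary = EnrichSummary()
    with store.conn as conn:
        for acc in store.matching_accessions(criteria):
            assemblies = [r[0] for r in conn.execute(
                "SELECT assembly_id FROM assembly_links WHERE accession = ?"
                " ORDER BY assembly_id", (acc,))]
            if not assemblies:
                summary.unlinkable += 1
                continue
            found = False
            for asm in assemblies:
                rec = lookup.get(asm)
                if rec is None:
                    continue
                found = True
                summary.rows_added += _write_lineage(conn, "gtdb_lineages", "assembly_id", asm, rec)
            if found:
                summary.hits += 1
            else:
                summary.misses += 1
    store.log("gtdb", rows_added=summary.rows_added)
    return summary


_VERSION_RE = re.compile(r"\.(\d+)$")


def _version_of(accession: str) -> int:
    m = _VERSION_RE.search(accession)
    return int(m.group(1)) if m else 0


def refresh_sequences(
    store: CazymeStore,
    snapshot: Iterable[UniProtEntry] | dict[str, UniProtEntry],
    criteria: SelectionCriteria | None = None,
    source: str = "uniprot",
) -> EnrichSummary:
    """Update stored sequences when the snapshot carries a newer version.

    "Newer" means a strictly later ISO version date; when the dates are
    equal the accession's version-suffix integer breaks the tie.  A
    protein with no stored sequence always takes the snapshot's.
    Untouched otherwise.
    """
    if source not in ("genbank", "uniprot"):
        raise ValueError("source must be 'genbank' or 'uniprot'")
    criteria = criteria or SelectionCriteria()
    lookup = _as_mapping(snapshot, "accession")
    summary = EnrichSummary()
    with store.conn as conn:
        for acc in store.matching_accessions(criteria):
            entry = lookup.get(acc)
            if entry is None or not entry.sequence:
                summary.misses += 1
                continue
            summary.hits += 1
            stored = conn.execute(
                "SELECT sequence, sequence_version_date FROM proteins WHERE accession = ?",
                (acc,)).fetchone()
            seq, stored_date = stored
            newer = (
                seq is None
                or (entry.version_date or "") > (stored_date or "")
                or ((entry.version_date or "") == (stored_date or "")
                    and seq != entry.sequence
                    and _version_of(entry.accession) > _version_of(acc))
            )
            if newer and seq != entry.sequence:
                conn.execute(
                    "UPDATE proteins SET sequence = ?, sequence_source = ?,"
                    " sequence_version_date = ? WHERE accession = ?",
                    (entry.sequence, source, entry.version_date, acc))
                summary.rows_updated += 1
    store.log(source, criteria="refresh_sequences", rows_updated=summary.rows_updated)
    return summary


@dataclass
class BatchSummary:
    processed: int = 0
    skipped_cached: int = 0
    batches: int = 0


def run_batched(
    provider_fn: Callable[[Sequence[str]], object],
    accessions: Sequence[str],
    batch_size: int = DEFAULT_BATCH_SIZE,
    cache: str | Path | None = None,
) -> BatchSummary:
    """Run a provider over accessions in resumable batches.

    Accessions already listed in the cache file are skipped; each
    completed batch is appended (and flushed) to the cache before the
    next one starts, so a run interrupted mid-way can be resumed and the
    provider receives exactly the unprocessed remainder.  An unreadable
    cache triggers a fresh start with a warning rather than a failure.
    """
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    done: set[str] = set()
    if cache is not None:
        cache = Path(cache)
        if cache.exists():
            try:
                done = set(cache.read_text(encoding="utf-8").split())
            except OSError as exc:
                logger.warning("cache %s unreadable (%s); starting fresh", cache, exc)
                done = set()
        cache.parent.mkdir(parents=True, exist_ok=True)
    summary = BatchSummary()
    pending = [a for a in accessions if a not in done]
    summary.skipped_cached = len(accessions) - len(pending)
    for start in range(0, len(pending), batch_size):
        batch = pending[start:start + batch_size]
        provider_fn(batch)
        summary.processed += len(batch)
        summary.batches += 1
        if cache is not None:
            with open(cache, "a", encoding="utf-8") as fh:
                fh.write("".join(f"{a}\n" for a in batch))
                fh.flush()
    return summary
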