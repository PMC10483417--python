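"""Single-file relational store of CAZyme records.

The store is an SQLite3 database file, so it can be shared, shipped and
queried from any SQLite console alongside this package's API.  The
entity model keeps one row per protein (identified by its versioned
NCBI accession, case-sensitively) and hangs every annotation off it as
link tables under joint-UNIQUE constraints: CAZy family membership,
source-organism taxa, UniProt cross-references, EC numbers, PDB ids,
genome assemblies and NCBI/GTDB lineages.  Link insertion is always
``INSERT OR IGNORE`` against those constraints, which is what makes
every import and enrichment operation idempotent: replaying any input
leaves the database bit-identical.

A protein listed under two different source organisms keeps both taxon
links and additionally gains a row in ``conflicts`` -- the disagreement
is surfaced, never silently resolved.  Every mutating operation appends
exactly one row to the ``retrieval_log`` audit table (UTC ISO-8601
timestamps).
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .formats import DumpRecord, FamilyLabel, classify_accession, parse_family_label, split_organism
from .selection import ProteinView, SelectionCriteria, matches, matches_record

__all__ = [
    "CazymeStore",
    "ImportSummary",
    "StoreIntegrityError",
    "init_store",
    "import_dump",
    "count_cazymes",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS proteins (
    accession TEXT PRIMARY KEY,
    accession_kind TEXT NOT NULL CHECK (accession_kind IN ('genbank', 'refseq')),
    sequence TEXT,
    sequence_source TEXT CHECK (sequence_source IN ('genbank', 'uniprot') OR sequence_source IS NULL),
    sequence_version_date TEXT
);
CREATE TABLE IF NOT EXISTS families (
    label TEXT PRIMARY KEY,
    class_code TEXT NOT NULL,
    family_number INTEGER NOT NULL,
    subfamily_number INTEGER
);
CREATE TABLE IF NOT EXISTS family_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    family_label TEXT NOT NULL REFERENCES families(label),
    UNIQUE (accession, family_label)
);
CREATE TABLE IF NOT EXISTS taxa (
    taxon_id INTEGER PRIMARY KEY AUTOINCREMENT,
    organism TEXT NOT NULL UNIQUE,
    kingdom TEXT NOT NULL,
    genus TEXT NOT NULL,
    species TEXT NOT NULL,
    strain TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS taxon_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    taxon_id INTEGER NOT NULL REFERENCES taxa(taxon_id),
    UNIQUE (accession, taxon_id)
);
CREATE TABLE IF NOT EXISTS uniprot_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    uniprot_id TEXT NOT NULL,
    protein_name TEXT NOT NULL DEFAULT '',
    UNIQUE (accession, uniprot_id)
);
CREATE TABLE IF NOT EXISTS ec_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    ec_number TEXT NOT NULL,
    UNIQUE (accession, ec_number)
);
CREATE TABLE IF NOT EXISTS pdb_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    pdb_id TEXT NOT NULL,
    UNIQUE (accession, pdb_id)
);
CREATE TABLE IF NOT EXISTS assembly_links (
    accession TEXT NOT NULL REFERENCES proteins(accession),
    assembly_id TEXT NOT NULL,
    UNIQUE (accession, assembly_id)
);
CREATE TABLE IF NOT EXISTS ncbi_lineages (
    accession TEXT PRIMARY KEY REFERENCES proteins(accession),
    kingdom TEXT, phylum TEXT, class TEXT, "order" TEXT,
    family TEXT, genus TEXT, species TEXT,
    incomplete INTEGER NOT NULL DEFAULT 0,
    candidatus INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS gtdb_lineages (
    assembly_id TEXT PRIMARY KEY,
    kingdom TEXT, phylum TEXT, class TEXT, "order" TEXT,
    family TEXT, genus TEXT, species TEXT,
    incomplete INTEGER NOT NULL DEFAULT 0,
    candidatus INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS conflicts (
    accession TEXT PRIMARY KEY REFERENCES proteins(accession),
    assignments TEXT NOT NULL,     -- JSON list of organism strings
    first_seen TEXT NOT NULL,
    last_seen TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS retrieval_log (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    source TEXT NOT NULL,
    criteria TEXT NOT NULL DEFAULT '',
    rows_added INTEGER NOT NULL DEFAULT 0,
    rows_updated INTEGER NOT NULL DEFAULT 0
);
"""


class StoreIntegrityError(RuntimeError):
    """The file at the store path is not a usable SQLite database."""


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass
class ImportSummary:
    proteins_new: int = 0
    links_new: int = 0
    skipped_by_filter: int = 0
    conflicts_recorded: int = 0


class CazymeStore:
    """Handle on one database file.  Use :func:`init_store` to obtain one."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        try:
            self.conn.executescript(_SCHEMA)
            self.conn.commit()
        except sqlite3.DatabaseError as exc:
            raise StoreIntegrityError(f"{self.path} is not a valid store: {exc}") from exc

    # -- plumbing ----------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "CazymeStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def log(self, source: str, criteria: str = "",
            rows_added: int = 0, rows_updated: int = 0) -> None:
        """Append one audit-log entry (called once per mutating operation)."""
        self.conn.execute(
            "INSERT INTO retrieval_log (timestamp, source, criteria, rows_added, rows_updated)"
            " VALUES (?, ?, ?, ?, ?)",
            (_utcnow(), source, criteria, rows_added, rows_updated),
        )
        self.conn.commit()

    def log_entries(self) -> list[tuple]:
        return self.conn.execute(
            "SELECT timestamp, source, criteria, rows_added, rows_updated"
            " FROM retrieval_log ORDER BY id"
        ).fetchall()

    # -- reads -------------------------------------------------------------

    def n_proteins(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM proteins").fetchone()[0]

    def accessions(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT accession FROM proteins ORDER BY accession")]

    def protein_views(self) -> list[ProteinView]:
        """Materialize the facets of every protein that criteria can see."""
        fams: dict[str, list[FamilyLabel]] = {}
        for acc, label in self.conn.execute(
                "SELECT accession, family_label FROM family_links ORDER BY accession, family_label"):
            fams.setdefault(acc, []).append(parse_family_label(label))
        orgs: dict[str, list[tuple[str, str]]] = {}
        for acc, kingdom, organism in self.conn.execute(
                "SELECT tl.accession, t.kingdom, t.organism FROM taxon_links tl"
                " JOIN taxa t ON t.taxon_id = tl.taxon_id ORDER BY tl.accession, t.organism"):
            orgs.setdefault(acc, []).append((kingdom, organism))
        ecs: dict[str, set[str]] = {}
        for acc, ec in self.conn.execute("SELECT accession, ec_number FROM ec_links"):
            ecs.setdefault(acc, set()).add(ec)
        return [
            ProteinView(
                accession=acc,
                families=tuple(fams.get(acc, ())),
                organisms=tuple(orgs.get(acc, ())),
                ec_numbers=frozenset(ecs.get(acc, ())),
            )
            for acc in self.accessions()
        ]

    def matching_accessions(self, criteria: SelectionCriteria) -> list[str]:
        return [v.accession for v in self.protein_views() if matches(v, criteria)]

    def conflict_records(self) -> dict[str, list[str]]:
        return {
            acc: json.loads(assignments)
            for acc, assignments in self.conn.execute(
                "SELECT accession, assignments FROM conflicts")
        }

    def fingerprint(self) -> str:
        """Stable digest of all user tables (audit log excluded); used to
        verify bit-level idempotence of replayed operations."""
        import hashlib
        h = hashlib.sha256()
        tables = [r[0] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
            " AND name NOT IN ('retrieval_log', 'sqlite_sequence') ORDER BY name")]
        for table in tables:
            h.update(table.encode())
            for row in self.conn.execute(f'SELECT * FROM "{table}" ORDER BY 1, 2'):
                h.update(repr(row).encode())
        return h.hexdigest()


def init_store(path: str | Path) -> CazymeStore:
    """Create (or re-open) the database at ``path`` with the full schema.

    Opening an existing store is a no-op that preserves content; a file
    that exists but is not SQLite raises :class:`StoreIntegrityError`.
    """
    return CazymeStore(path)


def _ensure_family(conn: sqlite3.Connection, family: FamilyLabel) -> None:
    conn.execute(
        "INSERT OR IGNORE INTO families (label, class_code, family_number, subfamily_number)"
        " VALUES (?, ?, ?, ?)",
        (str(family), family.class_code, family.family_number, family.subfamily_number),
    )


def _ensure_taxon(conn: sqlite3.Connection, kingdom: str, organism: str) -> int:
    genus, epithet, strain = split_organism(organism)
    conn.execute(
        "INSERT OR IGNORE INTO taxa (organism, kingdom, genus, species, strain)"
        " VALUES (?, ?, ?, ?, ?)",
        (organism, kingdom, genus, f"{genus} {epithet}", strain),
    )
    return conn.execute(
        "SELECT taxon_id FROM taxa WHERE organism = ?", (organism,)
    ).fetchone()[0]


def import_dump(
    store: CazymeStore,
    records: Iterable[DumpRecord],
    criteria: SelectionCriteria | None = None,
    source: str = "cazy",
) -> ImportSummary:
    """Import dump records matching ``criteria`` into the store.

    Atomic per call: either every matching record lands or none does.
    Safe to replay -- re-importing any subset changes nothing.  Proteins
    seen under more than one source organism keep every taxon link and
    gain (or extend) a conflict record.
    """
    criteria = criteria or SelectionCriteria()
    summary = ImportSummary()
    conn = store.conn
    now = _utcnow()
    touched: set[str] = set()
    try:
        with conn:  # one transaction; rollback on structural errors
            for rec in records:
                if not matches_record(rec, criteria):
                    summary.skipped_by_filter += 1
                    continue
                cur = conn.execute(
                    "INSERT OR IGNORE INTO proteins (accession, accession_kind) VALUES (?, ?)",
                    (rec.accession, classify_accession(rec.accession)),
                )
                summary.proteins_new += cur.rowcount
                _ensure_family(conn, rec.family)
                cur = conn.execute(
                    "INSERT OR IGNORE INTO family_links (accession, family_label) VALUES (?, ?)",
                    (rec.accession, str(rec.family)),
                )
                summary.links_new += cur.rowcount
                taxon_id = _ensure_taxon(conn, rec.kingdom, rec.organism)
                cur = conn.execute(
                    "INSERT OR IGNORE INTO taxon_links (accession, taxon_id) VALUES (?, ?)",
                    (rec.accession, taxon_id),
                )
                summary.links_new += cur.rowcount
                touched.add(rec.accession)

            # record multi-organism proteins among those touched this import
            for acc in sorted(touched):
                organisms = [r[0] for r in conn.execute(
                    "SELECT t.organism FROM taxon_links tl JOIN taxa t"
                    " ON t.taxon_id = tl.taxon_id WHERE tl.accession = ?"
                    " ORDER BY t.organism", (acc,))]
                if len(organisms) < 2:
                    continue
                existing = conn.execute(
                    "SELECT assignments FROM conflicts WHERE accession = ?", (acc,)
                ).fetchone()
                payload = json.dumps(organisms)
                if existing is None:
                    conn.execute(
                        "INSERT INTO conflicts (accession, assignments, first_seen, last_seen)"
                        " VALUES (?, ?, ?, ?)", (acc, payload, now, now))
                    summary.conflicts_recorded += 1
                elif existing[0] != payload:
                    conn.execute(
                        "UPDATE conflicts SET assignments = ?, last_seen = ?"
                        " WHERE accession = ?", (payload, now, acc))
    except sqlite3.DatabaseError:
        raise
    store.log(source, criteria=json.dumps(criteria.to_dict()),
              rows_added=summary.proteins_new + summary.links_new)
    return summary


def count_cazymes(store: CazymeStore, criteria: SelectionCriteria | None = None) -> int:
    """Count DISTINCT protein accessions matching the criteria.

    A protein in several families counts once under empty criteria and
    once under each family filter that selects it.
    """
    criteria = criteria or SelectionCriteria()
    return len(store.matching_accessions(criteria))
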