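"""Text formats used around the CAZyme database.

This module owns every external plain-text representation the package
reads or writes: the CAZy-style database dump (one family--protein link
per line), the tab-separated annotation snapshots standing in for
UniProt / NCBI Taxonomy / GTDB / assembly lookups, and FASTA sequence
files.  All parsers are strict about the type invariants (family-label
grammar, EC and PDB identifier syntax, lineage rank ordering) but
tolerant of malformed rows: a bad row becomes an :class:`Issue` in an
:class:`IssueReport` rather than an exception, so a single corrupted
line never aborts a multi-million-line import.
"""

from __future__ import annotations

import csv
import io
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CLASS_CODES",
    "KINGDOMS",
    "RANK_ORDER",
    "FamilyLabel",
    "DumpRecord",
    "UniProtEntry",
    "LineageRecord",
    "AssemblyMapping",
    "Issue",
    "IssueReport",
    "FamilyLabelError",
    "parse_family_label",
    "classify_accession",
    "canonical_kingdom",
    "split_organism",
    "parse_dump",
    "read_dump",
    "write_dump",
    "read_snapshot",
    "read_fasta",
    "write_fasta",
]

#: CAZy sequence-based classes: glycoside hydrolases, glycosyltransferases,
#: polysaccharide lyases, carbohydrate esterases, auxiliary activities and
#: (non-catalytic) carbohydrate-binding modules.
CLASS_CODES = ("GH", "GT", "PL", "CE", "AA", "CBM")

#: The five kingdom-level groups CAZy assigns source organisms to.
KINGDOMS = ("Bacteria", "Eukaryota", "Archaea", "Viruses", "unclassified")

#: Canonical order of taxonomic ranks stored for a lineage.  GTDB calls the
#: first rank "domain"; both are stored in the same slot.
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")
_EC_RE = re.compile(r"^\d+\.[\d-]+\.[\d-]+\.[\d-]+$")
_PDB_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_REFSEQ_RE = re.compile(r"^[A-Z]{2}_")
_SEQUENCE_RE = re.compile(r"^[A-Za-z\*]+$")


class FamilyLabelError(ValueError):
    """Raised when a string does not parse under the family-label grammar."""


@dataclass(frozen=True, order=True)
class FamilyLabel:
    """A parsed CAZy family label: class code, family number, optional subfamily.

    The text form is ``CODE<number>`` for a family (``PL20``) and
    ``CODE<number>_<subfamily>`` for a subfamily (``GH5_4``); parsing and
    formatting round-trip losslessly.
    """

    class_code: str
    family_number: int
    subfamily_number: int | None = None

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_CODES:
            raise FamilyLabelError(f"unknown CAZy class code {self.class_code!r}")
        if self.family_number <= 0:
            raise FamilyLabelError("family number must be a positive integer")
        if self.subfamily_number is not None and self.subfamily_number <= 0:
            raise FamilyLabelError("subfamily number must be a positive integer")

    @property
    def family(self) -> "FamilyLabel":
        """The parent family label (self with the subfamily stripped)."""
        if self.subfamily_number is None:
            return self
        return FamilyLabel(self.class_code, self.family_number)

    def __str__(self) -> str:
        base = f"{self.class_code}{self.family_number}"
        if self.subfamily_number is not None:
            return f"{base}_{self.subfamily_number}"
        return base


def parse_family_label(text: str) -> FamilyLabel:
    """Parse ``"GH5_4"`` style text into a :class:`FamilyLabel`.

    Raises :class:`FamilyLabelError` naming the offending token when the
    text does not match ``^(GH|GT|PL|CE|AA|CBM)(\\d+)(_(\\d+))?$``.
    """
    m = _FAMILY_RE.match(text.strip())
    if m is None:
        raise FamilyLabelError(f"not a valid CAZy family label: {text!r}")
    code, fam, sub = m.groups()
    return FamilyLabel(code, int(fam), int(sub) if sub is not None else None)


def classify_accession(accession: str) -> str:
    """Classify an NCBI protein accession as ``"refseq"`` or ``"genbank"``.

    RefSeq protein accessions carry a two-letter + underscore prefix
    (``XP_``, ``WP_``, ``NP_`` ...); everything else is treated as a
    submitter-derived GenBank accession.  Total function: never raises
    for non-empty input.
    """
    if not accession:
        raise ValueError("empty accession")
    return "refseq" if _REFSEQ_RE.match(accession) else "genbank"


_KINGDOM_ALIASES = {k.lower(): k for k in KINGDOMS}


def canonical_kingdom(token: str) -> str:
    """Canonicalize a kingdom token; unknown tokens map to ``unclassified``."""
    return _KINGDOM_ALIASES.get(token.strip().lower(), "unclassified")


def split_organism(organism: str) -> tuple[str, str, str]:
    """Split an organism string into (genus, species epithet, strain).

    First token is the genus, second the species epithet, the remainder
    the strain designation.  Single-token names get the ``"sp."``
    sentinel as epithet.  A leading ``Candidatus`` marker is kept with
    the genus so lineage flags can detect it.
    """
    tokens = organism.split()
    if tokens and tokens[0] == "Candidatus" and len(tokens) > 1:
        tokens = [f"Candidatus {tokens[1]}"] + tokens[2:]
    if not tokens:
        return ("", "sp.", "")
    genus = tokens[0]
    epithet = tokens[1] if len(tokens) > 1 else "sp."
    strain = " ".join(tokens[2:])
    return (genus, epithet, strain)


@dataclass(frozen=True)
class DumpRecord:
    """One family--protein link from the CAZy-style dump."""

    family: FamilyLabel
    kingdom: str
    organism: str
    accession: str

    @property
    def accession_kind(self) -> str:
        return classify_accession(self.accession)

    @property
    def genus(self) -> str:
        return split_organism(self.organism)[0]

    @property
    def species(self) -> str:
        g, e, _ = split_organism(self.organism)
        return f"{g} {e}"


@dataclass(frozen=True)
class Issue:
    """One malformed row: where it was and why it was rejected."""

    line_number: int
    reason: str
    raw: str = ""


@dataclass
class IssueReport:
    """Accumulates row-level problems during a parse without aborting it."""

    issues: list[Issue] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, line_number: int, reason: str, raw: str = "") -> None:
        self.issues.append(Issue(line_number, reason, raw))

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def __len__(self) -> int:
        return len(self.issues)

    def __bool__(self) -> bool:
        return bool(self.issues)


# --------------------------------------------------------------------------
# Dump dialects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DumpDialect:
    """Column order and delimiter of a dump flavour.

    The authoritative dump's exact layout is not fixed in stone, so the
    dialect is pluggable by name; the default carries the four fields a
    CAZy record holds, tab-separated: family, kingdom, organism, accession.
    """

    name: str
    delimiter: str
    columns: tuple[str, ...]  # permutation of (family, kingdom, organism, accession)


DIALECTS: dict[str, DumpDialect] = {
    "tsv4": DumpDialect("tsv4", "\t", ("family", "kingdom", "organism", "accession")),
    "csv4": DumpDialect("csv4", ",", ("family", "kingdom", "organism", "accession")),
}


def get_dialect(name: str) -> DumpDialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise KeyError(
            f"unknown dump dialect {name!r}; known: {sorted(DIALECTS)}"
        ) from None


def parse_dump(
    stream: TextIO | Iterable[str], dialect: str | DumpDialect = "tsv4"
) -> tuple[list[DumpRecord], IssueReport]:
    """Parse a CAZy-style dump stream into records plus an issue report.

    Well-formed lines become :class:`DumpRecord` in input order; malformed
    lines (wrong column count, bad family label, empty accession) are
    collected in the report with their 1-based line number and a reason.
    Unknown kingdom tokens are accepted, mapped to ``unclassified`` and
    logged as warnings, mirroring CAZy's own unclassified group.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    records: list[DumpRecord] = []
    report = IssueReport()
    idx = {c: i for i, c in enumerate(dialect.columns)}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        parts = line.split(dialect.delimiter)
        if len(parts) != len(dialect.columns):
            report.add(lineno, f"expected {len(dialect.columns)} columns, got {len(parts)}", line)
            continue
        fam_text = parts[idx["family"]].strip()
        kingdom_text = parts[idx["kingdom"]].strip()
        organism = parts[idx["organism"]].strip()
        accession = parts[idx["accession"]].strip()
        try:
            family = parse_family_label(fam_text)
        except FamilyLabelError as exc:
            report.add(lineno, str(exc), line)
            continue
        if not accession:
            report.add(lineno, "empty accession", line)
            continue
        kingdom = canonical_kingdom(kingdom_text)
        if kingdom == "unclassified" and kingdom_text.strip().lower() != "unclassified":
            report.warn(
                f"line {lineno}: unknown kingdom {kingdom_text!r} mapped to 'unclassified'"
            )
        records.append(DumpRecord(family, kingdom, organism, accession))
    return records, report


def read_dump(
    path: str | Path, dialect: str | DumpDialect = "tsv4"
) -> tuple[list[DumpRecord], IssueReport]:
    """Read a dump from a plain text file or from the first member of a ZIP."""
    path = Path(path)
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            if not names:
                return [], IssueReport()
            with zf.open(names[0]) as fh:
                text = io.TextIOWrapper(fh, encoding="utf-8")
                return parse_dump(text, dialect)
    with open(path, encoding="utf-8") as fh:
        return parse_dump(fh, dialect)


def write_dump(
    records: Iterable[DumpRecord],
    path: str | Path,
    dialect: str | DumpDialect = "tsv4",
) -> None:
    """Write records in the given dialect; inverse of :func:`parse_dump`."""
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in records:
            values = {
                "family": str(rec.family),
                "kingdom": rec.kingdom,
                "organism": rec.organism,
                "accession": rec.accession,
            }
            fh.write(dialect.delimiter.join(values[c] for c in dialect.columns) + "\n")


# --------------------------------------------------------------------------
# Annotation snapshots
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UniProtEntry:
    """One row of a UniProt-style snapshot keyed by NCBI protein accession."""

    accession: str
    uniprot_id: str = ""
    protein_name: str = ""
    ec_numbers: frozenset[str] = frozenset()
    pdb_ids: frozenset[str] = frozenset()
    sequence: str | None = None
    version_date: str | None = None  # ISO date of the sequence version

    def __post_init__(self) -> None:
        for ec in self.ec_numbers:
            if not _EC_RE.match(ec):
                raise ValueError(f"malformed EC number {ec!r}")
        for pdb in self.pdb_ids:
            if not _PDB_RE.match(pdb):
                raise ValueError(f"malformed PDB id {pdb!r}")
        if self.sequence is not None and not _SEQUENCE_RE.match(self.sequence):
            raise ValueError(f"malformed sequence for {self.accession}")


@dataclass(frozen=True)
class LineageRecord:
    """A taxonomic lineage keyed by protein accession (NCBI flavour) or
    genome assembly id (GTDB flavour).

    ``ranks`` maps rank name to taxon name for the prefix of
    :data:`RANK_ORDER` that is populated.  ``incomplete`` is true when
    the populated ranks stop before species; ``candidatus`` is true iff
    any rank name starts with "Candidatus".
    """

    key: str
    ranks: tuple[tuple[str, str], ...]  # ordered (rank, name)

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if names != list(RANK_ORDER[: len(names)]):
            raise ValueError(
                f"ranks {names} are not a prefix of the canonical rank order"
            )

    @property
    def incomplete(self) -> bool:
        return len(self.ranks) < len(RANK_ORDER)

    @property
    def candidatus(self) -> bool:
        return any(name.startswith("Candidatus") for _, name in self.ranks)

    def rank(self, name: str) -> str | None:
        for r, v in self.ranks:
            if r == name:
                return v
        return None


@dataclass(frozen=True)
class AssemblyMapping:
    """Protein accession to NCBI genome assembly accession."""

    accession: str
    assembly_id: str


_SNAPSHOT_COLUMNS = {
    "uniprot": ("accession", "uniprot_id", "protein_name", "ec_numbers",
                "pdb_ids", "sequence", "version_date"),
    "ncbi_tax": ("accession",) + RANK_ORDER,
    "gtdb_tax": ("assembly_id",) + RANK_ORDER,
    "assembly": ("accession", "assembly_id"),
}

# columns that may be absent from a snapshot without it being rejected
_OPTIONAL_COLUMNS = {"sequence", "version_date"}


class SnapshotFormatError(ValueError):
    """A snapshot file is structurally unusable (missing mandatory columns)."""


def _split_set(cell: str) -> frozenset[str]:
    return frozenset(v.strip() for v in cell.split(",") if v.strip())


def read_snapshot(
    path: str | Path, kind: str
) -> tuple[list[UniProtEntry | LineageRecord | AssemblyMapping], IssueReport]:
    """Load a headered TSV annotation snapshot.

    ``kind`` selects the schema: ``uniprot`` (accession, UniProt id,
    protein name, comma-joined EC numbers and PDB ids, sequence, version
    date), ``ncbi_tax`` / ``gtdb_tax`` (key plus one column per rank),
    or ``assembly`` (accession, assembly id).  Rows violating a type
    invariant become issues; the file still loads.  Duplicate keys are
    resolved last-wins with a warning.
    """
    if kind not in _SNAPSHOT_COLUMNS:
        raise KeyError(f"unknown snapshot kind {kind!r}")
    expected = _SNAPSHOT_COLUMNS[kind]
    report = IssueReport()
    by_key: dict[str, UniProtEntry | LineageRecord | AssemblyMapping] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in expected if c not in header and c not in _OPTIONAL_COLUMNS]
        if missing:
            raise SnapshotFormatError(
                f"snapshot {path} ({kind}) missing mandatory columns: {missing}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                obj = _parse_snapshot_row(row, kind)
            except (ValueError, KeyError) as exc:
                report.add(lineno, str(exc))
                continue
            key = obj.accession if hasattr(obj, "accession") else obj.key  # type: ignore[union-attr]
            if kind == "gtdb_tax":
                key = obj.key  # type: ignore[union-attr]
            if key in by_key:
                report.warn(f"duplicate key {key!r} at line {lineno}; keeping last")
            else:
                order.append(key)
            by_key[key] = obj
    return [by_key[k] for k in order], report


def _parse_snapshot_row(row: dict, kind: str):
    if kind == "uniprot":
        acc = (row.get("accession") or "").strip()
        if not acc:
            raise ValueError("empty accession")
        seq = (row.get("sequence") or "").strip() or None
        date = (row.get("version_date") or "").strip() or None
        return UniProtEntry(
            accession=acc,
            uniprot_id=(row.get("uniprot_id") or "").strip(),
            protein_name=(row.get("protein_name") or "").strip(),
            ec_numbers=_split_set(row.get("ec_numbers") or ""),
            pdb_ids=_split_set(row.get("pdb_ids") or ""),
            sequence=seq,
            version_date=date,
        )
    if kind in ("ncbi_tax", "gtdb_tax"):
        key_col = "accession" if kind == "ncbi_tax" else "assembly_id"
        key = (row.get(key_col) or "").strip()
        if not key:
            raise ValueError(f"empty {key_col}")
        ranks: list[tuple[str, str]] = []
        for rank in RANK_ORDER:
            name = (row.get(rank) or "").strip()
            if not name:
                break  # lineage stops at the first empty rank (prefix rule)
            ranks.append((rank, name))
        return LineageRecord(key=key, ranks=tuple(ranks))
    if kind == "assembly":
        acc = (row.get("accession") or "").strip()
        asm = (row.get("assembly_id") or "").strip()
        if not acc or not asm:
            raise ValueError("assembly mapping row needs accession and assembly_id")
        return AssemblyMapping(acc, asm)
    raise KeyError(kind)


def write_snapshot(rows: Iterable, path: str | Path, kind: str) -> None:
    """Write snapshot rows as headered TSV (inverse of :func:`read_snapshot`)."""
    columns = _SNAPSHOT_COLUMNS[kind]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for obj in rows:
            if kind == "uniprot":
                writer.writerow([
                    obj.accession,
                    obj.uniprot_id,
                    obj.protein_name,
                    ",".join(sorted(obj.ec_numbers)),
                    ",".join(sorted(obj.pdb_ids)),
                    obj.sequence or "",
                    obj.version_date or "",
                ])
            elif kind in ("ncbi_tax", "gtdb_tax"):
                ranks = dict(obj.ranks)
                writer.writerow([obj.key] + [ranks.get(r, "") for r in RANK_ORDER])
            elif kind == "assembly":
                writer.writerow([obj.accession, obj.assembly_id])


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(
    sequences: Iterable[tuple[str, str]] | dict[str, str],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> int:
    """Write (accession, sequence) pairs to FASTA; returns records written."""
    if isinstance(sequences, dict):
        items: Iterator[tuple[str, str]] = iter(sequences.items())
    else:
        items = iter(sequences)
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=acc, description=descriptions.get(acc, ""))
        for acc, seq in items
    ]
    n = SeqIO.write(records, str(path), "fasta")
    return n
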