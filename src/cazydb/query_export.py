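"""Filtered queries, CSV/JSON/FASTA export and summary aggregations.

All output is deterministic: rows are ordered by accession, multi-valued
cells (families, EC numbers, PDB ids) are comma-joined in lexicographic
order, and the writers emit byte-stable files for a fixed input so that
exported artefacts diff cleanly between runs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datastore import CazymeStore
from .formats import parse_family_label, split_organism, write_fasta
from .selection import SelectionCriteria

__all__ = [
    "INCLUDE_FIELDS",
    "query",
    "write_csv",
    "write_json",
    "extract_fasta",
    "FastaExport",
    "summarize",
    "dominant_kingdom",
    "lineage_rollup",
]

#: Optional output fields, mirroring the command-line ``--include`` list.
INCLUDE_FIELDS = (
    "class", "family", "subfamily", "kingdom", "genus", "organism",
    "genbank_sequence", "uniprot_accession", "protein_name", "ec", "pdb",
    "uniprot_sequence",
)


def _joined(values) -> str:
    return ",".join(sorted(set(values)))


def query(
    store: CazymeStore,
    criteria: SelectionCriteria | None = None,
    include_fields: Sequence[str] = (),
) -> pd.DataFrame:
    """Return one row per distinct matching accession.

    By default the table has a single ``accession`` column; each name in
    ``include_fields`` (a subset of :data:`INCLUDE_FIELDS`) adds a column.
    Multi-valued fields are serialized comma-joined and sorted within the
    cell; rows are ordered by accession.
    """
    criteria = criteria or SelectionCriteria()
    unknown = set(include_fields) - set(INCLUDE_FIELDS)
    if unknown:
        raise ValueError(f"unknown include fields: {sorted(unknown)}")
    conn = store.conn
    accs = store.matching_accessions(criteria)
    rows = []
    for acc in accs:
        row: dict[str, str] = {"accession": acc}
        fams = [parse_family_label(r[0]) for r in conn.execute(
            "SELECT family_label FROM family_links WHERE accession = ?", (acc,))]
        organisms = [r for r in conn.execute(
            "SELECT t.kingdom, t.organism FROM taxon_links tl JOIN taxa t"
            " ON t.taxon_id = tl.taxon_id WHERE tl.accession = ?", (acc,))]
        for field in include_fields:
            if field == "class":
                row[field] = _joined(f.class_code for f in fams)
            elif field == "family":
                row[field] = _joined(str(f.family) for f in fams)
            elif field == "subfamily":
                row[field] = _joined(str(f) for f in fams if f.subfamily_number is not None)
            elif field == "kingdom":
                row[field] = _joined(k for k, _ in organisms)
            elif field == "genus":
                row[field] = _joined(split_organism(o)[0] for _, o in organisms)
            elif field == "organism":
                row[field] = _joined(o for _, o in organisms)
            elif field in ("genbank_sequence", "uniprot_sequence"):
                source = field.split("_")[0]
                got = conn.execute(
                    "SELECT sequence FROM proteins WHERE accession = ?"
                    " AND sequence_source = ?", (acc, source)).fetchone()
                row[field] = got[0] if got and got[0] else ""
            elif field == "uniprot_accession":
                row[field] = _joined(r[0] for r in conn.execute(
                    "SELECT uniprot_id FROM uniprot_links WHERE accession = ?", (acc,)))
            elif field == "protein_name":
                row[field] = _joined(r[0] for r in conn.execute(
                    "SELECT protein_name FROM uniprot_links WHERE accession = ?"
                    " AND protein_name != ''", (acc,)))
            elif field == "ec":
                row[field] = _joined(r[0] for r in conn.execute(
                    "SELECT ec_number FROM ec_links WHERE accession = ?", (acc,)))
            elif field == "pdb":
                row[field] = _joined(r[0] for r in conn.execute(
                    "SELECT pdb_id FROM pdb_links WHERE accession = ?", (acc,)))
        rows.append(row)
    columns = ["accession", *include_fields]
    return pd.DataFrame(rows, columns=columns).astype(str) if rows else \
        pd.DataFrame(columns=columns, dtype=str)


def write_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as RFC-4180 CSV (CRLF line endings, minimal quoting)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(table.columns)
        for row in table.itertuples(index=False):
            writer.writerow(row)


def write_json(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as a JSON array of objects keyed by field names."""
    records = table.to_dict(orient="records")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2, sort_keys=False)
        fh.write("\n")


@dataclass
class FastaExport:
    written: int
    skipped_no_sequence: int


def extract_fasta(
    store: CazymeStore,
    criteria: SelectionCriteria | None,
    source: str,
    path: str | Path,
) -> FastaExport:
    """Write a multi-FASTA of matching proteins' sequences from one source.

    ``source`` selects sequences recorded from ``genbank`` or
    ``uniprot``.  Matching proteins without a sequence of that source
    are counted, not erred on.  Records are written in accession order
    with the organism string as description.
    """
    if source not in ("genbank", "uniprot"):
        raise ValueError("source must be 'genbank' or 'uniprot'")
    criteria = criteria or SelectionCriteria()
    conn = store.conn
    pairs: list[tuple[str, str]] = []
    skipped = 0
    descriptions: dict[str, str] = {}
    for acc in store.matching_accessions(criteria):
        got = conn.execute(
            "SELECT sequence FROM proteins WHERE accession = ? AND sequence_source = ?"
            " AND sequence IS NOT NULL", (acc, source)).fetchone()
        if got is None:
            skipped += 1
            continue
        pairs.append((acc, got[0]))
        org = conn.execute(
            "SELECT t.organism FROM taxon_links tl JOIN taxa t ON t.taxon_id = tl.taxon_id"
            " WHERE tl.accession = ? ORDER BY t.organism LIMIT 1", (acc,)).fetchone()
        if org:
            descriptions[acc] = org[0]
    n = write_fasta(pairs, path, descriptions)
    return FastaExport(written=n, skipped_no_sequence=skipped)


def summarize(
    store: CazymeStore,
    row_dim: str = "family",
    col_dim: str = "kingdom",
) -> pd.DataFrame:
    """Contingency table of distinct-accession counts.

    ``row_dim`` is ``"family"`` or ``"class"``; columns are kingdoms.
    Cell (r, k) counts distinct accessions having at least one family in
    r and at least one taxon in kingdom k, so a protein spanning two
    classes contributes once to each class row and row totals may exceed
    the distinct-protein total.
    """
    if row_dim not in ("family", "class"):
        raise ValueError("row_dim must be 'family' or 'class'")
    if col_dim != "kingdom":
        raise ValueError("col_dim must be 'kingdom'")
    cells: dict[tuple[str, str], set[str]] = {}
    for acc, label, kingdom in store.conn.execute(
            "SELECT fl.accession, fl.family_label, t.kingdom"
            " FROM family_links fl"
            " JOIN taxon_links tl ON tl.accession = fl.accession"
            " JOIN taxa t ON t.taxon_id = tl.taxon_id"):
        fam = parse_family_label(label)
        key = fam.class_code if row_dim == "class" else str(fam.family)
        cells.setdefault((key, kingdom), set()).add(acc)
    rows = sorted({r for r, _ in cells})
    cols = sorted({k for _, k in cells})
    data = [[len(cells.get((r, k), ())) for k in cols] for r in rows]
    return pd.DataFrame(data, index=pd.Index(rows, name=row_dim),
                        columns=pd.Index(cols, name=col_dim))


def dominant_kingdom(summary: pd.DataFrame) -> pd.Series:
    """Majority kingdom per row of a :func:`summarize` table (ties -> first
    in column order, which is lexicographic)."""
    return summary.idxmax(axis=1)


def lineage_rollup(
    store: CazymeStore,
    kingdom: str,
    ranks: Sequence[str] = ("phylum", "class", "order", "family"),
    exclude_incomplete: bool = True,
    exclude_candidatus: bool = True,
) -> pd.DataFrame:
    """Per-node distinct-accession counts down the NCBI lineage of one kingdom.

    Returns a long-form table with columns ``rank``, ``path`` (the
    rank names from phylum down, joined by ``;``), ``name`` and
    ``count``.  With no exclusions at intermediate ranks, the counts of
    a node's children sum to the node's count.
    """
    allowed = ("phylum", "class", "order", "family", "genus", "species")
    for r in ranks:
        if r not in allowed:
            raise ValueError(f"unsupported rollup rank {r!r}")
    q = ('SELECT accession, phylum, class, "order", family, genus, species,'
         " incomplete, candidatus FROM ncbi_lineages WHERE kingdom = ?")
    rows = store.conn.execute(q, (kingdom,)).fetchall()
    colmap = {"phylum": 1, "class": 2, "order": 3, "family": 4, "genus": 5, "species": 6}
    node_accs: dict[tuple[str, ...], set[str]] = {}
    for row in rows:
        acc = row[0]
        if exclude_incomplete and row[7]:
            continue
        if exclude_candidatus and row[8]:
            continue
        path: list[str] = []
        for rank in ranks:
            name = row[colmap[rank]]
            if name is None:
                break
            path.append(name)
            node_accs.setdefault(tuple(path), set()).add(acc)
    out = [
        {"rank": ranks[len(path) - 1], "path": ";".join(path),
         "name": path[-1], "count": len(accs)}
        for path, accs in sorted(node_accs.items())
    ]
    return pd.DataFrame(out, columns=["rank", "path", "name", "count"])
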