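"""Queries, writers, FASTA extraction and summary aggregations."""

import csv
import json

import pandas as pd
import pytest

from cazydb.datastore import count_cazymes, import_dump, init_store
from cazydb.enrichment import attach_ncbi_lineage
from cazydb.formats import DumpRecord, LineageRecord, parse_family_label, read_fasta
from cazydb.query_export import (
    dominant_kingdom,
    extract_fasta,
    lineage_rollup,
    query,
    summarize,
    write_csv,
    write_json,
)
from cazydb.selection import SelectionCriteria, compile_criteria


class TestQuery:
    def test_default_is_single_accession_column(self, enriched_store):
        table = query(enriched_store)
        assert list(table.columns) == ["accession"]
        assert len(table) == enriched_store.n_proteins()
        assert list(table.accession) == sorted(table.accession)

    @pytest.mark.parametrize("crit_args", [
        {}, {"families": "PL20"}, {"kingdoms": "Bacteria"},
        {"classes": "GH,CBM"}, {"families": "GH5", "kingdoms": "Archaea"},
    ])
    def test_row_count_equals_count_cazymes(self, enriched_store, crit_args):
        criteria = compile_criteria(crit_args or None)
        table = query(enriched_store, criteria)
        assert len(table) == count_cazymes(enriched_store, criteria)

    def test_requested_fields_become_columns(self, enriched_store):
        table = query(enriched_store, compile_criteria({"classes": "GH,CBM"}),
                      include_fields=("ec", "pdb"))
        assert list(table.columns) == ["accession", "ec", "pdb"]

    def test_multivalued_cell_comma_joined_sorted(self, tmp_path):
        store = init_store(tmp_path / "q.sqlite")
        import_dump(store, [
            DumpRecord(parse_family_label("GH5"), "Bacteria", "Bacillus x", "AAA1.1"),
            DumpRecord(parse_family_label("CBM35"), "Bacteria", "Bacillus x", "AAA1.1"),
        ])
        table = query(store, include_fields=("family",))
        assert len(table) == 1
        assert table.family.iloc[0] == "CBM35,GH5"
        store.close()

    def test_unknown_field_is_configuration_error(self, enriched_store):
        with pytest.raises(ValueError):
            query(enriched_store, include_fields=("no_such_field",))


class TestWriters:
    def test_empty_table_header_only_csv_and_empty_json(self, enriched_store, tmp_path):
        table = query(enriched_store, SelectionCriteria(
            kingdoms=frozenset({"Viruses"})))  # fixture has none
        assert len(table) == 0
        write_csv(table, tmp_path / "empty.csv")
        assert (tmp_path / "empty.csv").read_bytes() == b"accession\r\n"
        write_json(table, tmp_path / "empty.json")
        assert json.loads((tmp_path / "empty.json").read_text()) == []

    def test_csv_round_trip(self, enriched_store, tmp_path):
        table = query(enriched_store, include_fields=("family", "kingdom"))
        path = tmp_path / "out.csv"
        write_csv(table, path)
        back = pd.read_csv(path, dtype=str).fillna("")
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True))

    def test_json_round_trip(self, enriched_store, tmp_path):
        table = query(enriched_store, include_fields=("ec",))
        path = tmp_path / "out.json"
        write_json(table, path)
        records = json.loads(path.read_text())
        assert records == table.to_dict(orient="records")

    def test_field_with_comma_is_quoted(self, tmp_path):
        table = pd.DataFrame([{"accession": "A.1", "family": "CBM35,GH5"}])
        path = tmp_path / "q.csv"
        write_csv(table, path)
        raw = path.read_text()
        assert '"CBM35,GH5"' in raw
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[1] == ["A.1", "CBM35,GH5"]

    def test_writers_byte_stable(self, enriched_store, tmp_path):
        table = query(enriched_store, include_fields=("family",))
        write_csv(table, tmp_path / "a.csv")
        write_csv(table, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestExtractFasta:
    def test_no_sequences_stored_gives_empty_file_and_skip_count(
            self, fresh_store, tmp_path):
        result = extract_fasta(fresh_store, None, "uniprot", tmp_path / "e.fasta")
        assert result.written == 0
        assert result.skipped_no_sequence == fresh_store.n_proteins()

    def test_kingdom_export_excludes_other_kingdoms(self, enriched_store, tmp_path, truth):
        criteria = compile_criteria({"kingdoms": "archaea"})
        path = tmp_path / "archaea.fasta"
        extract_fasta(enriched_store, criteria, "uniprot", path)
        exported = set(read_fasta(path))
        archaeal = {r.accession for r in truth.records if r.kingdom == "Archaea"}
        assert exported <= archaeal and exported

    def test_exported_sequences_equal_stored(self, enriched_store, tmp_path, truth):
        path = tmp_path / "all.fasta"
        extract_fasta(enriched_store, None, "uniprot", path)
        for acc, seq in read_fasta(path).items():
            assert truth.sequences[acc] == seq


def _expected_cells(records, by):
    """Brute-force oracle for summarize: per-accession family x kingdom join."""
    fams: dict[str, set] = {}
    kingdoms: dict[str, set] = {}
    for r in records:
        key = str(r.family.family) if by == "family" else r.family.class_code
        fams.setdefault(r.accession, set()).add(key)
        kingdoms.setdefault(r.accession, set()).add(r.kingdom)
    cells: dict[tuple, set] = {}
    for acc in fams:
        for f in fams[acc]:
            for k in kingdoms[acc]:
                cells.setdefault((f, k), set()).add(acc)
    return {cell: len(accs) for cell, accs in cells.items()}


class TestSummarize:
    @pytest.mark.parametrize("by", ["family", "class"])
    def test_cells_match_brute_force_oracle(self, enriched_store, truth, by):
        table = summarize(enriched_store, row_dim=by)
        expected = _expected_cells(truth.records, by)
        got = {
            (r, k): int(table.loc[r, k])
            for r in table.index for k in table.columns
            if table.loc[r, k] > 0
        }
        assert got == expected

    def test_multiclass_protein_counts_once_per_class(self, tmp_path):
        store = init_store(tmp_path / "s.sqlite")
        import_dump(store, [
            DumpRecord(parse_family_label("GH5"), "Bacteria", "Bacillus x", "AAA1.1"),
            DumpRecord(parse_family_label("CBM35"), "Bacteria", "Bacillus x", "AAA1.1"),
        ])
        table = summarize(store, row_dim="class")
        assert int(table.values.sum()) == 2
        assert count_cazymes(store) == 1
        store.close()

    def test_cell_sums_match_distinct_counts_modulo_conflicts(self, enriched_store, truth):
        # row sums equal the family's distinct count plus one per
        # cross-kingdom conflict inside the family (those count in 2 cells)
        table = summarize(enriched_store, row_dim="family")
        conflicted = set(truth.conflict_accessions)
        for key in table.index:
            base = count_cazymes(enriched_store, compile_criteria({"families": key}))
            fam_conflicts = len({
                r.accession for r in truth.records
                if str(r.family.family) == key and r.accession in conflicted})
            assert int(table.loc[key].sum()) == base + fam_conflicts

    def test_dominance_labels(self, enriched_store):
        table = summarize(enriched_store, row_dim="family")
        dom = dominant_kingdom(table)
        for family in table.index:
            assert table.loc[family, dom[family]] == table.loc[family].max()


class TestLineageRollup:
    def _make_store(self, tmp_path, lineages):
        store = init_store(tmp_path / "r.sqlite")
        records = []
        for i, _ in enumerate(lineages):
            records.append(DumpRecord(
                parse_family_label("GH5"), "Archaea", f"Genus{i} sp.", f"AAA{i}.1"))
        import_dump(store, records)
        attach_ncbi_lineage(store, {
            f"AAA{i}.1": rec for i, rec in enumerate(lineages)})
        return store

    def _lineage(self, acc_i, phylum, family, candidatus=False):
        genus = ("Candidatus " if candidatus else "") + f"Genus{acc_i}"
        return LineageRecord(key=f"AAA{acc_i}.1", ranks=(
            ("kingdom", "Archaea"), ("phylum", phylum), ("class", f"{phylum}ia"),
            ("order", f"{family}ales"), ("family", family), ("genus", genus),
            ("species", f"{genus} sp.")))

    def test_children_sum_to_parent(self, tmp_path):
        lineages = [
            self._lineage(0, "PhylA", "Fam1"), self._lineage(1, "PhylA", "Fam1"),
            self._lineage(2, "PhylA", "Fam2"),
            self._lineage(3, "PhylB", "Fam3"), self._lineage(4, "PhylB", "Fam4"),
        ]
        store = self._make_store(tmp_path, lineages)
        roll = lineage_rollup(store, "Archaea")
        phyla = roll[roll["rank"] == "phylum"].set_index("name")["count"]
        fams = roll[roll["rank"] == "family"]
        assert int(phyla["PhylA"]) == 3 and int(phyla["PhylB"]) == 2
        for phylum in ("PhylA", "PhylB"):
            children = fams[fams.path.str.startswith(phylum)]["count"].sum()
            assert int(children) == int(phyla[phylum])
        store.close()

    def test_all_candidatus_with_exclusion_is_empty(self, tmp_path):
        lineages = [self._lineage(i, "PhylA", "Fam1", candidatus=True) for i in range(3)]
        store = self._make_store(tmp_path, lineages)
        assert lineage_rollup(store, "Archaea").empty
        store.close()

    def test_exclusion_toggle_differs_by_planted_candidatus(self, tmp_path):
        lineages = [self._lineage(0, "PhylA", "Fam1"),
                    self._lineage(1, "PhylA", "Fam1", candidatus=True)]
        store = self._make_store(tmp_path, lineages)
        on = lineage_rollup(store, "Archaea", exclude_candidatus=True)
        off = lineage_rollup(store, "Archaea", exclude_candidatus=False)
        n_on = int(on[on["rank"] == "phylum"]["count"].sum())
        n_off = int(off[off["rank"] == "phylum"]["count"].sum())
        assert n_off - n_on == 1
        store.close()
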