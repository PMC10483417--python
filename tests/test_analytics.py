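"""Survey statistics: representation rates, chi-squared decomposition,
BSR matrices, redundancy, clustering and structural coverage."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cazydb.analytics import (
    DegenerateStatisticError,
    blastp_like_scorer,
    bsr_matrix,
    census_totals,
    chisq_decompose,
    find_redundant_pairs,
    greedy_cluster,
    read_cluster_tsv,
    representation_rates,
    round_half_up,
    structural_coverage,
    table_scorer,
)
from cazydb.fixtures import AMINO_ACIDS


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (1.2999, 1.30), (0.8577, 0.86), (5.225, 5.23), (0.005, 0.01), (2.675, 2.68),
    ])
    def test_half_up_two_decimals(self, value, expected):
        assert round_half_up(value, 2) == expected


class TestRepresentationRates:
    def _table(self):
        return pd.DataFrame([
            {"kingdom": "Archaea", "species_total": 12709, "with_ge1": 665, "with_ge50": 109},
            {"kingdom": "Bacteria", "species_total": 471432, "with_ge1": 14248, "with_ge50": 6128},
            {"kingdom": "Eukaryota", "species_total": 1420577, "with_ge1": 13698, "with_ge50": 456},
            {"kingdom": "Viruses", "species_total": 49675, "with_ge1": 672, "with_ge50": 0},
        ])

    def test_published_kingdom_percentages(self):
        out = representation_rates(self._table()).set_index("kingdom")
        assert out.loc["Archaea", "pct_ge1"] == 5.23
        assert out.loc["Bacteria", "pct_ge50"] == 1.30
        assert out.loc["Eukaryota", "pct_ge1"] == 0.96
        assert out.loc["Archaea", "pct_ge50"] == 0.86

    def test_totals_row_sums_then_applies_formula(self):
        out = representation_rates(self._table()).set_index("kingdom")
        assert int(out.loc["Total", "species_total"]) == 1954393
        assert out.loc["Total", "pct_ge1"] == 1.50
        assert out.loc["Total", "pct_ge50"] == 0.34

    def test_zero_species_zero_count_is_zero_percent(self):
        table = pd.DataFrame([{"kingdom": "X", "species_total": 100,
                               "with_ge1": 0, "with_ge50": 0}])
        out = representation_rates(table).set_index("kingdom")
        assert out.loc["X", "pct_ge1"] == 0.00

    def test_zero_species_nonzero_count_is_domain_error(self):
        table = pd.DataFrame([{"kingdom": "X", "species_total": 0,
                               "with_ge1": 5, "with_ge50": 0}])
        with pytest.raises(ValueError):
            representation_rates(table)


def brute_force_chi2(O, E):
    return sum((o - e) ** 2 / e for o, e in zip(np.ravel(O), np.ravel(E)))


class TestChiSquared:
    def test_two_cell_example_against_formula_oracle(self):
        # O=(10,20), p=(0.5,0.5): E=(15,15), chi2 = 25/15 + 25/15 = 10/3
        dec = chisq_decompose([10, 20], expected_probs=[0.5, 0.5])
        assert dec.chi2 == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert dec.explained_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(dec.expected, [15, 15])

    def test_observed_equals_expected_is_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            chisq_decompose([10, 10], expected_probs=[0.5, 0.5])

    def test_zero_expected_cell_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            chisq_decompose([10, 0], expected_probs=[1.0, 0.0])

    def test_homogeneity_mode_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency
        obs = [120, 30, 15]
        ref = [300, 200, 80]
        dec = chisq_decompose(obs, reference_counts=ref)
        chi2, p, dof, expected = chi2_contingency(np.vstack([obs, ref]), correction=False)
        assert dec.chi2 == pytest.approx(chi2)
        assert dec.p_value == pytest.approx(p)
        assert dec.dof == dof
        assert np.allclose(dec.expected, expected)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_random_tables_match_brute_force(self, data):
        rows = data.draw(st.integers(2, 4))
        cols = data.draw(st.integers(2, 4))
        O = np.array(data.draw(st.lists(
            st.lists(st.integers(1, 500), min_size=cols, max_size=cols),
            min_size=rows, max_size=rows)))
        try:
            dec = chisq_decompose(O)
        except DegenerateStatisticError:
            return
        assert dec.chi2 == pytest.approx(brute_force_chi2(O, dec.expected), rel=1e-12)
        assert dec.explained_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(dec.expected.sum(axis=0), O.sum(axis=0))
        assert np.allclose(dec.expected.sum(axis=1), O.sum(axis=1))
        assert np.all(dec.residuals[O == dec.expected] == 0)


def _random_protein(rng, length=60):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


class TestBsr:
    def test_identical_sequences_bsr_one(self):
        seq = "MKVLLTGAAGFIGSALVRYIINETSDAV"
        m = bsr_matrix({"A.1": seq, "B.1": seq})
        assert np.allclose(m.bsr, 1.0)

    def test_random_pair_scores_low(self):
        # oracle-derived bound: 50 random length-60 pairs max out near 0.12,
        # far below 0.35
        rng = random.Random(11)
        m = bsr_matrix({"A": _random_protein(rng), "B": _random_protein(rng)})
        assert m.bsr[0, 1] < 0.35 and m.bsr[1, 0] < 0.35

    def test_scale_invariance_of_score_ratio(self):
        rng = random.Random(3)
        seqs = {f"S{i}": _random_protein(rng) for i in range(4)}
        base = blastp_like_scorer()
        m1 = bsr_matrix(seqs, scorer=base)
        m2 = bsr_matrix(seqs, scorer=lambda a, b: 7.5 * base(a, b))
        assert np.allclose(m1.bsr, m2.bsr)

    def test_diagonal_exactly_one(self):
        rng = random.Random(5)
        m = bsr_matrix({f"S{i}": _random_protein(rng) for i in range(5)})
        assert np.all(np.diag(m.bsr) == 1.0)

    def test_external_score_table_replaces_scorer(self):
        scores = {("A", "A"): 100.0, ("B", "B"): 200.0,
                  ("A", "B"): 50.0, ("B", "A"): 50.0}
        m = bsr_matrix([("A", ""), ("B", "")], scorer=table_scorer(scores),
                       by_accession=True)
        assert m.bsr[0, 1] == 0.5   # normalized by query A's self-score
        assert m.bsr[1, 0] == 0.25  # asymmetric: query B's self-score differs
        assert m.to_frame().loc["A", "B"] == 0.5

    def test_empty_input_and_zero_self_score_error(self):
        with pytest.raises(ValueError):
            bsr_matrix({})
        with pytest.raises(ValueError):
            bsr_matrix({"A": "MK"}, scorer=lambda a, b: 0.0)


class TestRedundancy:
    def test_planted_pairs_recovered_exactly(self, truth):
        pairs = find_redundant_pairs(truth.sequences)
        assert [(a, b) for a, b, _, _ in pairs] == truth.redundant_pairs
        for a, b, kind_a, kind_b in pairs:
            assert {kind_a, kind_b} <= {"genbank", "refseq"}

    def test_no_duplicates_empty(self):
        assert find_redundant_pairs({"A": "MKV", "B": "MKW"}) == []

    def test_triple_identical_yields_three_pairs(self):
        pairs = find_redundant_pairs({"A.1": "MKV", "B.1": "MKV", "C.1": "MKV"})
        assert [(a, b) for a, b, _, _ in pairs] == [
            ("A.1", "B.1"), ("A.1", "C.1"), ("B.1", "C.1")]

    def test_matches_brute_force_equality_oracle(self, truth):
        seqs = truth.sequences
        oracle = sorted(
            (a, b) for a, b in itertools.combinations(sorted(seqs), 2)
            if seqs[a] == seqs[b])
        assert [(a, b) for a, b, _, _ in find_redundant_pairs(seqs)] == oracle


class TestClustering:
    def test_planted_three_clusters_recovered(self, truth):
        members = {acc for accs in truth.cluster_members.values() for acc in accs}
        cs = greedy_cluster({a: truth.sequences[a] for a in members}, 0.4, 0.8)
        assert cs.as_sets() == set(truth.cluster_members.values())

    def test_all_identical_single_cluster(self):
        cs = greedy_cluster({"A": "MKVLLTGAAG", "B": "MKVLLTGAAG", "C": "MKVLLTGAAG"},
                            0.4, 0.8)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 3

    def test_strict_thresholds_all_singletons(self):
        rng = random.Random(7)
        seqs = {f"S{i}": _random_protein(rng) for i in range(5)}
        cs = greedy_cluster(seqs, 1.0, 1.0)
        assert len(cs.clusters) == 5

    def test_output_is_partition(self, truth):
        members = {acc for accs in truth.cluster_members.values() for acc in accs}
        seqs = {a: truth.sequences[a] for a in members}
        cs = greedy_cluster(seqs, 0.4, 0.8)
        flat = [acc for c in cs.clusters for acc in c]
        assert sorted(flat) == sorted(seqs)  # disjoint and covering

    def test_raising_identity_never_merges_clusters(self, truth):
        members = sorted({acc for accs in truth.cluster_members.values() for acc in accs})
        seqs = {a: truth.sequences[a] for a in members}
        counts = [len(greedy_cluster(seqs, t, 0.8).clusters)
                  for t in (0.2, 0.4, 0.6, 0.8, 0.95)]
        assert counts == sorted(counts)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            greedy_cluster({"A": "MKV"}, 0.0, 0.8)

    def test_cluster_tsv_round_trip(self, truth, tmp_path):
        members = {acc for accs in truth.cluster_members.values() for acc in accs}
        cs = greedy_cluster({a: truth.sequences[a] for a in members}, 0.4, 0.8)
        path = tmp_path / "clusters.tsv"
        cs.write_tsv(path)
        assert read_cluster_tsv(path).as_sets() == cs.as_sets()


class TestStructuralCoverage:
    def test_planted_pdb_counts_per_family(self, enriched_store, truth):
        report = structural_coverage(enriched_store)
        planted = set().union(*truth.pdb_by_family.values())
        fam_members = {}
        for rec in truth.records:
            fam_members.setdefault(str(rec.family), set()).add(rec.accession)
        per_family = report.per_family.set_index("family")
        for family, members in fam_members.items():
            assert per_family.loc[family, "total"] == len(members)
            assert per_family.loc[family, "with_pdb"] == len(members & planted)

    def test_grand_totals_equal_column_sums_for_disjoint_families(self, tmp_path):
        per_family = pd.DataFrame([
            {"family": "CE1", "total": 10, "with_pdb": 2},
            {"family": "CE2", "total": 5, "with_pdb": 0},
        ])
        assert census_totals(per_family) == (15, 2)

    def test_no_pdb_links_all_zero_all_clusters_false(self, fresh_store, truth):
        members = {acc for accs in truth.cluster_members.values() for acc in accs}
        cs = greedy_cluster({a: truth.sequences[a] for a in members}, 0.4, 0.8)
        report = structural_coverage(fresh_store, cs)
        assert report.per_family.with_pdb.sum() == 0
        assert report.cluster_has_structure == [False] * len(cs.clusters)

    def test_cluster_flagged_iff_any_member_has_structure(self, enriched_store, truth):
        members = {acc for accs in truth.cluster_members.values() for acc in accs}
        cs = greedy_cluster({a: truth.sequences[a] for a in members}, 0.4, 0.8)
        report = structural_coverage(enriched_store, cs)
        with_pdb = set().union(*truth.pdb_by_family.values())
        for cluster, flag in zip(cs.clusters, report.cluster_has_structure):
            assert flag == bool(set(cluster) & with_pdb)
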