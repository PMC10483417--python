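"""Family-survey statistics over a CAZyme database.

The survey questions this module answers, and the statistics chosen for
them:

* How well is each kingdom represented?  Representation-rate tables:
  of all species-level taxa in a kingdom, what percentage has at least
  one (or at least fifty) recorded CAZymes.
* Does the CAZyme distribution over kingdoms differ from a reference
  distribution?  A chi-squared test, decomposed per cell into Pearson
  residuals r = (O - E) / sqrt(E); each cell's share of the statistic,
  100 * r^2 / chi2, is its *explained variance* in percent, and these
  shares sum to 100 by construction.
* How diverse is a family's sequence set?  The all-vs-all BLAST Score
  Ratio (BSR): the raw pairwise alignment score divided by the query's
  self-alignment score, 1 for identical sequences and near 0 for
  unrelated ones.  The ratio is query-normalized, so the matrix may be
  asymmetric.
* Which accessions are redundant?  Pairs of byte-identical sequences
  under distinct accessions (typically a GenBank record and its RefSeq
  twin).
* How do sequences group, and which groups have a solved structure?
  A greedy single-representative clustering at identity and coverage
  thresholds, plus per-family / per-cluster structural-coverage counts
  from PDB links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices

from .formats import classify_accession

__all__ = [
    "round_half_up",
    "representation_rates",
    "ChiSqDecomposition",
    "DegenerateStatisticError",
    "chisq_decompose",
    "BsrMatrix",
    "bsr_matrix",
    "blastp_like_scorer",
    "table_scorer",
    "find_redundant_pairs",
    "ClusterSet",
    "greedy_cluster",
    "StructuralCoverage",
    "structural_coverage",
    "census_totals",
]


def round_half_up(value: float, digits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), not banker's rounding."""
    q = Decimal(10) ** -digits
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Representation rates
# --------------------------------------------------------------------------

def representation_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of species-level taxa with >= 1 and >= 50 CAZyme records.

    ``table`` needs columns ``kingdom``, ``species_total``, ``with_ge1``,
    ``with_ge50``.  Adds ``pct_ge1`` / ``pct_ge50`` (half-up, 2 decimals)
    and a ``Total`` row summed before applying the same formula.
    Raises on a kingdom with zero species but a non-zero count.
    """
    required = {"kingdom", "species_total", "with_ge1", "with_ge50"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.copy()
    for _, row in df.iterrows():
        if not 0 <= row.with_ge50 <= row.with_ge1 <= max(row.species_total, row.with_ge1):
            raise ValueError(f"inconsistent counts for {row.kingdom}")
        if row.species_total == 0 and row.with_ge1 > 0:
            raise ValueError(f"{row.kingdom}: zero species but non-zero CAZyme-bearing count")
        if row.with_ge1 > row.species_total:
            raise ValueError(f"{row.kingdom}: more represented species than species")
    totals = pd.DataFrame([{
        "kingdom": "Total",
        "species_total": int(df.species_total.sum()),
        "with_ge1": int(df.with_ge1.sum()),
        "with_ge50": int(df.with_ge50.sum()),
    }])
    df = pd.concat([df, totals], ignore_index=True)

    def pct(n, total):
        return 0.0 if total == 0 else round_half_up(100.0 * n / total, 2)

    df["pct_ge1"] = [pct(n, t) for n, t in zip(df.with_ge1, df.species_total)]
    df["pct_ge50"] = [pct(n, t) for n, t in zip(df.with_ge50, df.species_total)]
    return df


# --------------------------------------------------------------------------
# Chi-squared decomposition
# --------------------------------------------------------------------------

class DegenerateStatisticError(ValueError):
    """chi2 == 0 (observed equals expected everywhere): the explained-
    variance decomposition is undefined."""


@dataclass
class ChiSqDecomposition:
    """A chi-squared test plus its per-cell decomposition.

    ``residuals`` are Pearson residuals (O - E) / sqrt(E);
    ``explained_variance`` is 100 * residual^2 / chi2 per cell, in
    percent, summing to 100 over all cells.
    """

    chi2: float
    dof: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    explained_variance: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()


def chisq_decompose(
    observed,
    expected_probs=None,
    reference_counts=None,
    row_labels: Sequence[str] = (),
    col_labels: Sequence[str] = (),
) -> ChiSqDecomposition:
    """Chi-squared test with Pearson-residual explained-variance matrix.

    Three reference modes:

    * ``expected_probs`` given (1-D observed): goodness-of-fit against
      E_i = N * p_i, dof = k - 1;
    * ``reference_counts`` given (1-D observed): the reference counts are
      stacked with the observed into a 2 x k homogeneity table;
    * neither (2-D observed): test of independence with the standard
      row x column / total expectation, dof = (r - 1)(c - 1).

    Any zero expected cell raises ``ValueError`` advising category
    pooling; a zero statistic raises :class:`DegenerateStatisticError`.
    """
    O = np.asarray(observed, dtype=float)
    if (O < 0).any():
        raise ValueError("observed counts must be non-negative")
    if expected_probs is not None:
        if O.ndim != 1:
            raise ValueError("goodness-of-fit mode needs a 1-D observed vector")
        p = np.asarray(expected_probs, dtype=float)
        if p.shape != O.shape:
            raise ValueError("expected_probs must match observed in length")
        p = p / p.sum()
        E = O.sum() * p
        dof = O.size - 1
    elif reference_counts is not None:
        ref = np.asarray(reference_counts, dtype=float)
        if O.ndim != 1 or ref.shape != O.shape:
            raise ValueError("homogeneity mode needs two count vectors of equal length")
        O = np.vstack([O, ref])
        E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
        dof = O.shape[1] - 1
        if not row_labels:
            row_labels = ("observed", "reference")
    else:
        if O.ndim != 2:
            raise ValueError("independence mode needs a 2-D table")
        E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
        dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    if (E == 0).any():
        raise ValueError(
            "zero expected count in at least one cell; pool sparse categories first")
    residuals = (O - E) / np.sqrt(E)
    chi2 = float((residuals ** 2).sum())
    if chi2 == 0.0:
        raise DegenerateStatisticError(
            "degenerate: zero statistic (observed equals expected everywhere)")
    explained = 100.0 * residuals ** 2 / chi2
    p_value = float(stats.chi2.sf(chi2, dof))
    return ChiSqDecomposition(
        chi2=chi2, dof=dof, p_value=p_value,
        observed=O, expected=E, residuals=residuals,
        explained_variance=explained,
        row_labels=tuple(row_labels), col_labels=tuple(col_labels),
    )


# --------------------------------------------------------------------------
# BLAST Score Ratio
# --------------------------------------------------------------------------

def blastp_like_scorer() -> Callable[[str, str], float]:
    """Raw local-alignment scorer: BLOSUM62, gap open 11, extend 1.

    Returns the highest-scoring local alignment's raw score, the
    quantity the score ratio is built from.
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"

    def score(a: str, b: str) -> float:
        return float(aligner.score(a, b))

    return score


def table_scorer(scores: Mapping[tuple[str, str], float]) -> Callable[[str, str], float]:
    """Scorer backed by an external (query, subject) -> raw score table,
    e.g. parsed from BLAST tabular output; missing pairs score 0."""
    def score_by_key(q: str, s: str) -> float:
        return float(scores.get((q, s), 0.0))
    return score_by_key


@dataclass
class BsrMatrix:
    """All-vs-all score-ratio matrix over one family's sequences.

    ``bsr[i, j] = scores[i, j] / scores[i, i]`` -- normalized by the
    *query* self-score, hence possibly asymmetric.  The diagonal is
    exactly 1.
    """

    accessions: tuple[str, ...]
    scores: np.ndarray
    bsr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bsr, index=list(self.accessions),
                            columns=list(self.accessions))


def bsr_matrix(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    scorer: Callable[[str, str], float] | None = None,
    by_accession: bool = False,
) -> BsrMatrix:
    """Compute the BLAST Score Ratio matrix for a set of sequences.

    ``scorer(a, b)`` must return a raw similarity score with
    ``scorer(a, a) > 0``; the default is the built-in BLOSUM62 local
    scorer.  Pass ``by_accession=True`` when the scorer is keyed by
    accession (e.g. :func:`table_scorer`) rather than by sequence.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise ValueError("need at least one sequence")
    for acc, seq in items:
        if not seq and not by_accession:
            raise ValueError(f"empty sequence for {acc}")
    scorer = scorer or blastp_like_scorer()
    n = len(items)
    scores = np.zeros((n, n))
    for i, (acc_i, seq_i) in enumerate(items):
        for j, (acc_j, seq_j) in enumerate(items):
            scores[i, j] = scorer(acc_i, acc_j) if by_accession else scorer(seq_i, seq_j)
    self_scores = np.diag(scores)
    if (self_scores <= 0).any():
        bad = [items[i][0] for i in np.nonzero(self_scores <= 0)[0]]
        raise ValueError(f"non-positive self-alignment score for {bad}")
    bsr = scores / self_scores[:, None]
    np.fill_diagonal(bsr, 1.0)
    return BsrMatrix(tuple(acc for acc, _ in items), scores, bsr)


# --------------------------------------------------------------------------
# Redundancy
# --------------------------------------------------------------------------

def find_redundant_pairs(
    sequences: Mapping[str, str],
) -> list[tuple[str, str, str, str]]:
    """All unordered accession pairs with byte-identical sequences.

    Returns tuples ``(a, b, kind_a, kind_b)`` with ``a < b``
    lexicographically, sorted; a group of k identical sequences yields
    all k * (k - 1) / 2 pairs.  The kinds annotate whether each member
    is a GenBank or RefSeq accession.
    """
    by_seq: dict[str, list[str]] = {}
    for acc, seq in sequences.items():
        by_seq.setdefault(seq, []).append(acc)
    pairs = []
    for accs in by_seq.values():
        accs = sorted(accs)
        for i in range(len(accs)):
            for j in range(i + 1, len(accs)):
                a, b = accs[i], accs[j]
                pairs.append((a, b, classify_accession(a), classify_accession(b)))
    return sorted(pairs)


# --------------------------------------------------------------------------
# Greedy clustering
# --------------------------------------------------------------------------

def _identity_and_coverage(aligner: PairwiseAligner, a: str, b: str) -> tuple[float, float, float]:
    """Identity over the aligned span and per-sequence span coverage.

    The alignment is global with free end gaps (so terminal overhangs
    are not penalized); identity = identical columns / columns in the
    span between the first and last aligned residue pair; coverage of a
    sequence = residues of that sequence inside the span / its length.
    """
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, 0.0
    matches = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            if a[sa + off] == b[sb + off]:
                matches += 1
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = max(span_a, span_b)  # aligned span incl. internal gaps
    identity = matches / columns if columns else 0.0
    return identity, span_a / len(a), span_b / len(b)


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # free terminal gaps: overhangs are not penalized
    aligner.mode = "global"
    return aligner


@dataclass
class ClusterSet:
    """A disjoint, covering partition of accessions into clusters.

    Each cluster is represented by its founding (longest) member, listed
    first.
    """

    clusters: list[list[str]]
    identity_threshold: float
    coverage_threshold: float

    @property
    def representatives(self) -> list[str]:
        return [c[0] for c in self.clusters]

    def membership(self) -> dict[str, int]:
        return {acc: i for i, c in enumerate(self.clusters) for acc in c}

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.clusters}

    def write_tsv(self, path) -> None:
        """Two-column (representative, member) TSV, the layout common
        cluster tools emit."""
        with open(path, "w", encoding="utf-8") as fh:
            for cluster in self.clusters:
                rep = cluster[0]
                for member in cluster:
                    fh.write(f"{rep}\t{member}\n")


def read_cluster_tsv(path) -> ClusterSet:
    """Load a (representative, member) TSV produced by an external
    clustering tool into a :class:`ClusterSet` (thresholds unknown: -1)."""
    groups: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rep, member = line.rstrip("\n").split("\t")[:2]
            groups.setdefault(rep, [])
            if member != rep:
                groups[rep].append(member)
    clusters = [[rep, *members] for rep, members in groups.items()]
    return ClusterSet(clusters, identity_threshold=-1.0, coverage_threshold=-1.0)


def greedy_cluster(
    sequences: Mapping[str, str],
    identity_threshold: float = 0.4,
    coverage_threshold: float = 0.8,
) -> ClusterSet:
    """Greedy single-representative clustering at identity/coverage thresholds.

    Sequences are visited in order of decreasing length (accession as
    tie-break); each joins the first existing cluster whose
    representative it matches at >= ``identity_threshold`` over >=
    ``coverage_threshold`` of *both* sequences, else it founds a new
    cluster.  The defaults (0.4, 0.8) mark the Twilight-Zone boundary
    below which shared structure cannot be inferred from sequence.
    """
    for t in (identity_threshold, coverage_threshold):
        if not 0.0 < t <= 1.0:
            raise ValueError("thresholds must be in (0, 1]")
    aligner = _global_aligner()
    order = sorted(sequences, key=lambda acc: (-len(sequences[acc]), acc))
    clusters: list[list[str]] = []
    for acc in order:
        seq = sequences[acc]
        placed = False
        for cluster in clusters:
            rep_seq = sequences[cluster[0]]
            if seq == rep_seq:
                identity, cov_a, cov_b = 1.0, 1.0, 1.0
            else:
                identity, cov_a, cov_b = _identity_and_coverage(aligner, rep_seq, seq)
            if (identity >= identity_threshold
                    and cov_a >= coverage_threshold and cov_b >= coverage_threshold):
                cluster.append(acc)
                placed = True
                break
        if not placed:
            clusters.append([acc])
    return ClusterSet(clusters, identity_threshold, coverage_threshold)


# --------------------------------------------------------------------------
# Structural coverage
# --------------------------------------------------------------------------

@dataclass
class StructuralCoverage:
    """Structure census: which families and clusters have a solved structure."""

    per_family: pd.DataFrame               # family, total, with_pdb
    total_members: int
    total_with_pdb: int
    cluster_has_structure: list[bool] = field(default_factory=list)


def structural_coverage(store, clusters: ClusterSet | None = None) -> StructuralCoverage:
    """Count, per family, distinct members and members with >= 1 PDB link.

    With a :class:`ClusterSet` given, additionally flags each cluster by
    whether any member carries a PDB link -- clusters without one are
    candidate targets for structure determination.
    """
    fam_members: dict[str, set[str]] = {}
    for acc, label in store.conn.execute(
            "SELECT accession, family_label FROM family_links"):
        fam_members.setdefault(label, set()).add(acc)
    with_pdb = {r[0] for r in store.conn.execute("SELECT DISTINCT accession FROM pdb_links")}
    rows = [
        {"family": fam, "total": len(members), "with_pdb": len(members & with_pdb)}
        for fam, members in sorted(fam_members.items())
    ]
    per_family = pd.DataFrame(rows, columns=["family", "total", "with_pdb"])
    all_members = set().union(*fam_members.values()) if fam_members else set()
    flags = []
    if clusters is not None:
        flags = [any(acc in with_pdb for acc in cluster) for cluster in clusters.clusters]
    return StructuralCoverage(
        per_family=per_family,
        total_members=len(all_members),
        total_with_pdb=len(all_members & with_pdb),
        cluster_has_structure=flags,
    )


def census_totals(per_family: pd.DataFrame) -> tuple[int, int]:
    """Column sums of a (family, total, with_pdb) census table."""
    return int(per_family["total"].sum()), int(per_family["with_pdb"].sum())
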