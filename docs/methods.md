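# Methods

## The data model

A CAZyme record is a protein identified by its versioned NCBI accession;
the accession string is the unique key and is compared case-sensitively
with its version suffix, so `ABC1.1` and `ABC1.2` are distinct proteins.
RefSeq accessions are recognized by their two-letter + underscore prefix
(`XP_`, `WP_`, `NP_` …); everything else is treated as GenBank. One protein
may carry several CAZy family labels (a multi-domain enzyme annotated
`CE12` and `PL11_1`, say) — family membership is a link table, never a
duplicate protein row.

The store is one SQLite file. Every annotation (family, taxon, UniProt id,
EC number, PDB id, assembly, lineage) is a link table with a joint UNIQUE
constraint over (accession, foreign key), and all writes are
`INSERT OR IGNORE` against those constraints. This one decision buys the
central behavioural guarantee: **every import and enrichment operation is
idempotent**, so replaying an input, updating from a newer dump, or
resuming after an interruption can never create duplicates. Each mutating
operation appends exactly one row to an append-only retrieval log (UTC
ISO-8601 timestamps) for audit.

### Taxonomy conflicts

Source dumps occasionally list the same accession under two different
organisms. The policy here is lossless: both taxon links are kept, the
protein gains a row in the `conflicts` table, and nothing is excluded.
Counting consequences are explicit: a kingdom filter matches a conflicted
protein through *any* of its assignments, so summing per-kingdom counts
over-counts the total by exactly the number of cross-kingdom conflicts.
The test suite asserts this identity on fixtures rather than hiding it.

### Dump dialect and organism parsing

The canonical dump layout is not formally published, so parsing goes
through a named dialect; the default is four tab-separated columns
(family, kingdom, organism, accession), one family–protein link per line.
Organism strings carry only genus, species and an optional strain, so they
are split positionally: first token genus, second the species epithet
(`sp.` sentinel when absent), remainder the strain. A leading `Candidatus`
marker stays attached to the genus so lineage flags can detect it.
Unknown kingdom tokens map to `unclassified` with a warning — the source
classification itself has an unclassified group.

## Selection criteria

Criteria are conjunctive across categories, disjunctive within one.
Two interpretation choices were genuinely open and are resolved as
follows:

* **Family vs subfamily.** A family filter (`GH5`) includes its
  subfamilies (`GH5_4`), because subfamilies are refinements of the
  family; a subfamily filter matches exactly. Use the `subfamilies`
  category when the refinement itself is meant.
* **Organism-group union.** Genus, species and strain filters union with
  *each other* before conjoining with everything else: naming a species
  and a strain in one command means "all strains of that species, plus
  that one extra strain" — the natural reading of mixed organism filters.
  Kingdom remains its own conjunctive category, since it is routinely
  combined restrictively with family filters.

EC-number filters match stored EC annotations exactly (a trailing-dash
EC such as `3.1.1.-` is a legal annotation value, not a wildcard).

## Enrichment providers

External databases are modelled as snapshots: headered TSV files loaded
into keyed collections behind the same lookup interface a live client
would present. Hits write links/values; absent accessions are counted as
misses, never errors. GTDB placement requires an assembly link (GTDB is
keyed by genome assembly), so proteins without one are counted
`unlinkable`. Sequence refresh is version-aware: a stored sequence is
replaced only when the snapshot's ISO version date is strictly newer,
with the accession's version-suffix integer as tie-break — "newer
version" is not defined more precisely by the sources, and date ordering
with a version tie-break is the conservative reading.

Long retrievals run through `run_batched` (default batch size 150,
arbitrary but configurable): processed keys are flushed to a cache file
after each batch, so an interrupted run resumed later processes exactly
the remainder and converges on the same final state. This is asserted by
a property test over random interruption points.

## Statistics

**Representation rates.** percent = 100·n/total rounded *half-up* to two
decimals (1.2999 → 1.30, 0.8577 → 0.86); the totals row sums counts first
and then applies the same formula. Half-up matches how the published
tables this mirrors were rounded; banker's rounding would differ on exact
ties.

**χ² decomposition.** chi2 = Σ(O−E)²/E with E from expected proportions
(goodness of fit, dof k−1), from a reference count vector (homogeneity),
or from the row×column/total product (independence). Pearson residuals
r = (O−E)/√E; a cell's explained variance is V = 100·r²/χ² percent. Only
this squared form makes the contributions sum to 100, which the
implementation asserts to 1e-9. Zero expected cells raise an error
advising category pooling; a zero statistic (O ≡ E) is reported as a
degenerate-statistic error rather than a table of NaNs.

**BSR.** The built-in scorer is the highest-scoring local alignment under
BLOSUM62 with gap open 11 / extend 1 (the classic protein-search
parameterization); BSR(a,b) = S(a,b)/S(a,a). The ratio uses raw scores,
normalized by the query, and is therefore asymmetric; bit-scores differ
from raw scores by an affine transform, so exact replication of a
bit-score-based ratio is supported by feeding an external tabular score
file through `table_scorer`. Where several alignments tie, the highest
raw score is used. Empirically, random length-60 sequences score below
0.12 under this scorer — comfortably below any similarity threshold of
interest.

**Redundancy.** Byte-identical sequence equality, nothing fuzzier: the
point is to find the same molecule deposited under two accessions. A
group of k identical sequences reports all k(k−1)/2 pairs, sorted.

**Greedy clustering.** Sequences are visited longest-first (accession as
tie-break); each joins the first cluster whose *representative* it
matches at ≥ identity over ≥ coverage of both sequences, else founds a
cluster. The alignment is global with free terminal gaps; identity is
identical columns over the aligned span (terminal overhangs excluded,
internal gaps counted), and coverage is the span's share of each
sequence's length, required of both. This is a deliberate, simple
stand-in for k-mer-prefiltered clustering tools: it is exact for the
well-separated regimes the thresholds (default 40 % identity / 80 %
coverage, the Twilight-Zone boundary) are meant for, quadratic in the
number of sequences, and not intended for hundred-thousand-sequence
families — externally computed cluster assignments can be imported from
a two-column (representative, member) TSV instead. Raising the identity
threshold can only split, never merge, clusters (asserted as a
monotonicity property).

**Structural coverage.** Per family: distinct members and members with at
least one PDB link; per cluster: flagged iff any member has one. The
cross-check between a dump-side "structure characterized" annotation and
UniProt-side PDB ids is not produced, because the dump dialect carries no
structure field; with only one structure source loaded there is nothing
to cross-check.

## The synthetic-data generator

`FixtureSpec` → `generate_fixture` emits a dump, all four snapshot files
and a FASTA that are mutually consistent, plus exact ground truth.
Generation is a pure function of the spec (seed included): same spec,
byte-identical files. What it plants, and how:

* **Base records**: the requested count per (family, kingdom) cell, with
  organism names drawn from per-kingdom genus pools.
* **Multi-family proteins**: an existing line from another family is
  absorbed into a host protein (accession, organism and kingdom taken
  from the host), so the line count is unchanged and each plant reduces
  the distinct-protein count by one.
* **Taxonomy conflicts**: an extra line re-lists an accession under an
  organism from a different kingdom — deliberately cross-kingdom so the
  partition-counting identity is exercised.
* **Redundant pairs**: a GenBank record gains a RefSeq twin (`XP_…`) with
  an identical sequence.
* **Sequence clusters**: cluster members are mutated copies of a
  representative with per-site retention chosen so expected pairwise
  identity hits the requested within-cluster level (retention r gives
  pairwise identity ≈ r² plus the 1/20 background); representatives
  descend from a common ancestor at a rate targeting the between-cluster
  level. Defaults (90 % within, 20 % between, length 120) give a wide
  margin around the 40 % clustering threshold.
* **Snapshot imperfections**: a configurable fraction of proteins is
  absent from the UniProt snapshot (misses), some lineages are truncated
  (incomplete) or marked *Candidatus*, and some proteins lack assembly
  mappings (GTDB-unlinkable).

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: realistic family-size and length
distributions, indel variation (mutations are substitutions only, so
cluster coverage is always ~1), genuine taxonomies, biased amino-acid
composition, and dump-format irregularities beyond whole-line corruption.

## Problem sizes and numerical choices

The test and acceptance workloads use fixtures of tens of proteins,
five randomized fixtures × 200 criteria draws (1000 total), 1000 random
contingency tables, 200 sequences for the redundancy oracle, a 12-member
3-cluster family for clustering, and 20 random interruption points —
sizes at which every check is exact and the whole suite runs in seconds.
Alignment-free paths (counting, import, χ²) scale to millions of records;
the quadratic BSR and clustering paths are meant for single families
(tens to hundreds of sequences).

Floating-point tolerances: explained-variance sum asserted to 1e-9
(double-precision accumulation over ≤ 25 cells stays far inside this);
χ² vs the brute-force oracle to 1e-12 relative. Percent rounding is
decimal half-up via `decimal.Decimal`, not binary rounding.
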