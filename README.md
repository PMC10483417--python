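# cazydb

Build a **local, shareable, reproducible relational database of
carbohydrate-active enzymes (CAZymes)** from a CAZy-style plain-text dump,
enrich it offline with taxonomy, sequence, EC-number, genome-assembly and
protein-structure cross-references, and run the family-survey statistics that
such databases exist to answer.

CAZymes catalyse the synthesis, modification and degradation of
polysaccharides and glycoconjugates, and the CAZy classification (glycoside
hydrolases GH, glycosyltransferases GT, polysaccharide lyases PL, carbohydrate
esterases CE, auxiliary activities AA and carbohydrate-binding modules CBM;
families like `PL20`, subfamilies like `GH5_4`) is the standard reference for
annotating them. The public CAZy dump, however, is a flat list of
family–protein links with no query interface. `cazydb` turns such a dump into
a single-file SQLite database — one row per protein, keyed by its versioned
NCBI accession, with family, taxon, UniProt, EC, PDB, assembly and lineage
links hanging off it under joint-UNIQUE constraints — that can be filtered on
import, updated idempotently, queried from this API or any SQLite console, and
shipped to a collaborator as one file.

## What it computes

- **Filtered import and counting.** Selection criteria (classes, families,
  subfamilies, kingdoms, genera, species, strains, EC numbers) are
  conjunctive across categories and disjunctive within one; a family filter
  includes its subfamilies. `count_cazymes` counts *distinct accessions*, so
  a protein in `GH5` and `CBM35` counts once.
- **Representation rates.** Of the species-level taxa in each kingdom, the
  percentage with ≥ 1 (or ≥ 50) recorded CAZymes, rounded half-up to two
  decimals.
- **χ² decomposition.** For an observed-vs-expected kingdom distribution, the
  Pearson residual of each cell is r = (O − E)/√E, and its *explained
  variance* is 100·r²/χ² percent — the cell's share of the statistic; the
  shares sum to 100 by construction.
- **BLAST Score Ratio (BSR) matrices.** For a family's sequences, all-vs-all
  raw local-alignment scores (BLOSUM62, gap open 11, extend 1) normalized by
  the query's self-score: BSR(a,b) = S(a,b)/S(a,a) ∈ [0, 1], 1 on the
  diagonal, possibly asymmetric. An external BLAST tabular score file can
  replace the built-in scorer.
- **Redundancy detection.** Pairs of byte-identical sequences under distinct
  accessions — typically a GenBank record and its RefSeq twin (`XP_`/`WP_`
  prefix).
- **Greedy clustering + structural coverage.** Single-representative greedy
  clustering at identity/coverage thresholds (default 40 % / 80 %, the
  Twilight-Zone boundary), then per-family and per-cluster counts of members
  with at least one PDB structure link — flagging clusters with no solved
  structure as candidate targets for structure determination.

Everything runs offline: external databases are modelled as snapshot files
(headered TSV) behind a provider interface, and a synthetic-fixture module
generates internally consistent dumps, snapshots and FASTA files with exact
ground truth (planted multi-family proteins, taxonomy conflicts, redundant
pairs, sequence clusters at chosen identities).

## Worked example

```sh
# generate a synthetic dataset with known ground truth
cazydb make-fixture demo --seed 5 --redundant-pairs 2
# build a database of bacterial PL20 records only
cazydb build demo/cazy_dump.tsv --families PL20 --kingdoms bacteria -o demo/pl20.db
# attach UniProt-style annotations (EC numbers, PDB ids, sequences)
cazydb get-uniprot demo/pl20.db demo/uniprot.tsv
# export sequences and a query table
cazydb extract-seqs demo/pl20.db uniprot --fasta-file demo/pl20.fasta
cazydb query demo/pl20.db --include family,ec,pdb --csv demo/pl20.csv
```

The build step prints

```
imported 4 new proteins, 8 new links; skipped 22 by filter; 0 taxonomy conflicts recorded
```

— 4 of the fixture's 26 dump lines are bacterial PL20 records, each
contributing one protein row plus a family link and a taxon link; the rest
are excluded by the filter before they touch the database. The enrichment
step prints `hits=4 misses=0 rows_added=6 unlinkable=0`: every matching
protein was found in the snapshot, gaining UniProt/EC links and a sequence.
Re-running either command changes nothing (`imported 0 new proteins ...`) —
imports are idempotent by construction.

From Python, the survey statistics:

```python
>>> from cazydb import chisq_decompose
>>> dec = chisq_decompose([10, 20], expected_probs=[0.5, 0.5])
>>> round(dec.chi2, 4), dec.explained_variance.round(1).tolist()
(3.3333, [50.0, 50.0])
```

Both cells deviate by ±5 from their expectation of 15, so each explains
exactly half of the χ² statistic.

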