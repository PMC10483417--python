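"""Synthetic CAZyme fixtures with controlled ground truth.

Real CAZy dumps and the annotation services behind them are large,
remote and mutable, so every test and demonstration in this package
runs against synthetic data generated here.  A :class:`FixtureSpec`
states exactly what to plant -- record counts per (family, kingdom)
cell, proteins that belong to several families, proteins annotated with
conflicting source organisms, redundant GenBank/RefSeq sequence pairs,
and sequence clusters at chosen identity levels -- and
:func:`generate_fixture` writes an internally consistent set of files
(dump, annotation snapshots, FASTA) together with a
:class:`GroundTruth` that downstream imports must reproduce exactly.

Generation is a pure function of the spec: the same spec (including the
seed) reproduces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .formats import (
    AssemblyMapping,
    DumpRecord,
    LineageRecord,
    RANK_ORDER,
    UniProtEntry,
    parse_family_label,
    split_organism,
    write_dump,
    write_fasta,
    write_snapshot,
)

__all__ = ["ClusterPlan", "FixtureSpec", "GroundTruth", "generate_fixture"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Per-kingdom genus pools; organism names are drawn deterministically from
# these.  Invented names -- the fixture emulates structure, not taxonomy.
_GENUS_POOL = {
    "Bacteria": ["Streptomyces", "Bacillus", "Cellvibrio", "Fibrobacter", "Paenibacillus"],
    "Eukaryota": ["Trichoderma", "Aspergillus", "Fusarium", "Neurospora", "Ustilago"],
    "Archaea": ["Sulfolobus", "Thermococcus", "Haloferax", "Methanosarcina", "Pyrococcus"],
    "Viruses": ["Caudovirus", "Myovirus", "Phagevirus", "Siphovirus", "Podovirus"],
    "unclassified": ["Unculturomonas", "Environmentum", "Metagenomia"],
}
_EPITHET_POOL = ["reesei", "flavus", "lividans", "cellulosa", "fulvus", "maritima", "solfataricus"]
_PHYLUM_POOL = {
    "Bacteria": ["Actinomycetota", "Bacillota", "Pseudomonadota"],
    "Eukaryota": ["Ascomycota", "Basidiomycota"],
    "Archaea": ["Euryarchaeota", "Crenarchaeota", "Nanoarchaeota"],
    "Viruses": ["Uroviricota"],
    "unclassified": ["unclassified phylum"],
}
_EC_POOL = ["4.2.2.14", "3.1.1.-", "3.2.1.4", "3.2.1.8", "2.4.1.-"]


@dataclass(frozen=True)
class ClusterPlan:
    """Plan for planting sequence clusters inside one family.

    ``sizes`` gives the number of members per cluster; members of one
    cluster are mutated copies of a common representative at
    ``within_identity`` expected pairwise identity, while representatives
    of different clusters share roughly ``between_identity``.
    """

    family: str
    sizes: tuple[int, ...]
    within_identity: float = 0.9
    between_identity: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_identity <= 1.0:
            raise ValueError("within_identity must be in [0, 1]")
        if not 0.0 <= self.between_identity <= 1.0:
            raise ValueError("between_identity must be in [0, 1]")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic CAZyme dataset.

    Parameters
    ----------
    family_kingdom_counts
        Base record count for each (family text, kingdom) cell of the dump.
    n_multifamily_proteins
        Number of base records absorbed into an existing protein from a
        different family: the dump line count is unchanged but each plant
        reduces the distinct-accession count by one and gives one protein
        an extra family link.
    n_redundant_pairs
        Pairs of byte-identical sequences planted under distinct
        accessions: an existing GenBank record gains a RefSeq twin (extra
        dump line, extra FASTA record, identical sequence).
    n_multitaxon_conflicts
        Proteins re-listed under a second, different source organism from
        another kingdom (extra dump line per conflict, same accession).
    cluster_plan
        Optional plan for planting sequence clusters in one family.
    sequence_length
        Length of generated amino-acid sequences.
    uniprot_miss_fraction
        Fraction of proteins deliberately absent from the UniProt-style
        snapshot (enrichment misses).
    pdb_per_family
        Number of proteins per family to annotate with a PDB id in the
        UniProt snapshot.
    n_candidatus / n_incomplete
        Lineages in the NCBI-taxonomy snapshot flagged *Candidatus*
        (genus renamed) or truncated before species rank.
    n_no_assembly
        Proteins left out of the assembly mapping (GTDB-unlinkable).
    rng_seed
        Seed; generation is a pure function of the whole spec.
    """

    family_kingdom_counts: tuple[tuple[str, str, int], ...]
    n_multifamily_proteins: int = 0
    n_redundant_pairs: int = 0
    n_multitaxon_conflicts: int = 0
    cluster_plan: ClusterPlan | None = None
    sequence_length: int = 120
    uniprot_miss_fraction: float = 0.0
    pdb_per_family: tuple[tuple[str, int], ...] = ()
    n_candidatus: int = 0
    n_incomplete: int = 0
    n_no_assembly: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for fam, kingdom, n in self.family_kingdom_counts:
            parse_family_label(fam)  # raises on bad label
            if n < 0:
                raise ValueError(f"negative count for ({fam}, {kingdom})")
        for n in (self.n_multifamily_proteins, self.n_redundant_pairs,
                  self.n_multitaxon_conflicts, self.n_candidatus,
                  self.n_incomplete, self.n_no_assembly):
            if n < 0:
                raise ValueError("all plant counts must be >= 0")
        if not 0.0 <= self.uniprot_miss_fraction <= 1.0:
            raise ValueError("uniprot_miss_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generated files contain, for exact downstream verification."""

    n_unique_proteins: int
    n_dump_lines: int
    counts: dict[tuple[str, str], int]            # (family, kingdom) -> distinct accessions
    family_counts: dict[str, int]                 # family -> distinct accessions
    redundant_pairs: list[tuple[str, str]]        # sorted (a, b), a < b
    conflict_accessions: list[str]                # proteins with >= 2 organisms
    cross_kingdom_conflicts: int
    cluster_members: dict[int, frozenset[str]]    # planted cluster id -> accessions
    sequences: dict[str, str]
    organism_of: dict[str, str]                   # first-seen organism per accession
    uniprot_misses: frozenset[str]
    pdb_by_family: dict[str, frozenset[str]]      # family -> accessions with a PDB id
    candidatus_accessions: frozenset[str]
    incomplete_accessions: frozenset[str]
    no_assembly_accessions: frozenset[str]
    records: list[DumpRecord] = field(default_factory=list)


def _mutate(seq: str, keep: float, rng: random.Random) -> str:
    """Substitute each site with probability 1-keep (never to itself)."""
    out = []
    for aa in seq:
        if rng.random() < keep:
            out.append(aa)
        else:
            out.append(rng.choice(AMINO_ACIDS.replace(aa, "")))
    return "".join(out)


def _random_seq(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> GroundTruth:
    """Write dump + snapshots + FASTA for ``spec`` and return the ground truth.

    Files written to ``out_dir``: ``cazy_dump.tsv``, ``uniprot.tsv``,
    ``ncbi_tax.tsv``, ``gtdb_tax.tsv``, ``assembly.tsv``, ``seqs.fasta``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.rng_seed)

    counter = 0

    def next_accession() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:05d}.1"

    def make_organism(kingdom: str) -> str:
        genus = rng.choice(_GENUS_POOL[kingdom])
        epithet = rng.choice(_EPITHET_POOL)
        if rng.random() < 0.3:
            return f"{genus} {epithet} strain {rng.randint(1, 99)}"
        return f"{genus} {epithet}"

    # -- base records ------------------------------------------------------
    lines: list[DumpRecord] = []
    for fam, kingdom, n in spec.family_kingdom_counts:
        family = parse_family_label(fam)
        for _ in range(n):
            lines.append(DumpRecord(family, kingdom, make_organism(kingdom), next_accession()))

    # -- multi-family plants: absorb one line into a protein from another
    #    family (same organism, same kingdom; only the family differs) -----
    families_present = sorted({str(r.family) for r in lines})
    absorbed = 0
    used_as_host: set[str] = set()
    used_as_absorbed: set[int] = set()
    for host_idx in range(len(lines)):
        if absorbed >= spec.n_multifamily_proteins:
            break
        host = lines[host_idx]
        if host.accession in used_as_host:
            continue
        for j in range(len(lines)):
            if j == host_idx or j in used_as_absorbed:
                continue
            if str(lines[j].family) != str(host.family) and lines[j].accession != host.accession:
                lines[j] = DumpRecord(lines[j].family, host.kingdom, host.organism, host.accession)
                used_as_host.add(host.accession)
                used_as_absorbed.add(j)
                absorbed += 1
                break
    if absorbed < spec.n_multifamily_proteins:
        raise ValueError(
            f"cannot plant {spec.n_multifamily_proteins} multi-family proteins: "
            f"only {absorbed} cross-family pairs available in {families_present}"
        )

    # -- multi-taxon conflicts: re-list an accession under an organism from
    #    a different kingdom (extra line) ---------------------------------
    conflict_accessions: list[str] = []
    eligible = [r for r in lines if r.accession not in used_as_host]
    if len(eligible) < spec.n_multitaxon_conflicts:
        raise ValueError("not enough records to plant the requested conflicts")
    other_kingdoms = [k for k in _GENUS_POOL if k != "unclassified"]
    for i in range(spec.n_multitaxon_conflicts):
        base = eligible[i]
        alt_kingdom = next(k for k in other_kingdoms if k != base.kingdom)
        alt_org = make_organism(alt_kingdom)
        lines.append(DumpRecord(base.family, alt_kingdom, alt_org, base.accession))
        conflict_accessions.append(base.accession)

    # -- redundant GenBank/RefSeq pairs ------------------------------------
    redundant_pairs: list[tuple[str, str]] = []
    twin_of: dict[str, str] = {}
    genbank_lines = [
        r for r in lines
        if r.accession_kind == "genbank" and r.accession not in conflict_accessions
        and r.accession not in used_as_host and r.accession not in twin_of.values()
    ]
    seen: set[str] = set()
    candidates = []
    for r in genbank_lines:
        if r.accession not in seen:
            seen.add(r.accession)
            candidates.append(r)
    if len(candidates) < spec.n_redundant_pairs:
        raise ValueError("not enough GenBank records to plant the requested redundant pairs")
    for i in range(spec.n_redundant_pairs):
        base = candidates[i]
        twin = f"XP_{900000 + i}.1"
        lines.append(DumpRecord(base.family, base.kingdom, base.organism, twin))
        twin_of[twin] = base.accession
        redundant_pairs.append(tuple(sorted((base.accession, twin))))

    # -- sequences ---------------------------------------------------------
    accession_order: list[str] = []
    for r in lines:
        if r.accession not in accession_order:
            accession_order.append(r.accession)

    sequences: dict[str, str] = {}
    cluster_members: dict[int, frozenset[str]] = {}
    if spec.cluster_plan is not None:
        plan = spec.cluster_plan
        fam_accs = []
        fam_seen: set[str] = set()
        for r in lines:
            if str(r.family) == plan.family and r.accession not in fam_seen \
                    and r.accession not in twin_of:
                fam_seen.add(r.accession)
                fam_accs.append(r.accession)
        need = sum(plan.sizes)
        if len(fam_accs) < need:
            raise ValueError(
                f"cluster plan needs {need} distinct proteins in {plan.family}, "
                f"fixture has {len(fam_accs)}"
            )
        # Representatives descend from a common ancestor so that the
        # between-cluster identity lands near the requested level
        # (independent random sequences share ~1/20 identity by chance).
        background = 1.0 / len(AMINO_ACIDS)
        keep_between = max(0.0, (plan.between_identity - background) / (1 - background)) ** 0.5
        ancestor = _random_seq(spec.sequence_length, rng)
        pos = 0
        # Pairwise identity between two copies mutated independently from a
        # representative with retention r is ~ r^2; invert for the plant.
        keep_within = max(0.0, (plan.within_identity - background) / (1 - background)) ** 0.5
        for cid, size in enumerate(plan.sizes):
            rep = _mutate(ancestor, keep_between, rng)
            members = []
            for _ in range(size):
                acc = fam_accs[pos]
                pos += 1
                sequences[acc] = _mutate(rep, keep_within, rng)
                members.append(acc)
            cluster_members[cid] = frozenset(members)
    for acc in accession_order:
        if acc in sequences:
            continue
        if acc in twin_of:
            continue  # filled below from the partner
        sequences[acc] = _random_seq(spec.sequence_length, rng)
    for twin, base in twin_of.items():
        sequences[twin] = sequences[base]

    # -- organism / lineage bookkeeping ------------------------------------
    organism_of: dict[str, str] = {}
    kingdom_of: dict[str, str] = {}
    for r in lines:
        organism_of.setdefault(r.accession, r.organism)
        kingdom_of.setdefault(r.accession, r.kingdom)

    candidatus_accessions = frozenset(accession_order[: spec.n_candidatus])
    incomplete_accessions = frozenset(
        accession_order[spec.n_candidatus: spec.n_candidatus + spec.n_incomplete]
    )
    no_assembly_accessions = frozenset(accession_order[-spec.n_no_assembly:]) \
        if spec.n_no_assembly else frozenset()

    lineages: list[LineageRecord] = []
    assembly_rows: list[AssemblyMapping] = []
    gtdb_rows: list[LineageRecord] = []
    assembly_of_org: dict[str, str] = {}
    for acc in accession_order:
        org = organism_of[acc]
        kingdom = kingdom_of[acc]
        genus, epithet, _ = split_organism(org)
        if acc in candidatus_accessions:
            genus = f"Candidatus {genus}"
        phylum = _PHYLUM_POOL[kingdom][hash_name(genus) % len(_PHYLUM_POOL[kingdom])]
        full = [
            ("kingdom", kingdom),
            ("phylum", phylum),
            ("class", f"{phylum[:-1]}ia"),
            ("order", f"{genus}ales"),
            ("family", f"{genus}aceae"),
            ("genus", genus),
            ("species", f"{genus} {epithet}"),
        ]
        if acc in incomplete_accessions:
            full = full[:3]
        lineages.append(LineageRecord(key=acc, ranks=tuple(full)))
        if acc not in no_assembly_accessions:
            if org not in assembly_of_org:
                assembly_of_org[org] = f"GCA_{len(assembly_of_org) + 1:06d}.1"
            assembly_rows.append(AssemblyMapping(acc, assembly_of_org[org]))

    seen_asm: set[str] = set()
    for acc in accession_order:
        org = organism_of[acc]
        asm = assembly_of_org.get(org)
        if asm is None or asm in seen_asm:
            continue
        seen_asm.add(asm)
        genus, epithet, _ = split_organism(org)
        kingdom = kingdom_of[acc]
        phylum = _PHYLUM_POOL[kingdom][hash_name(genus) % len(_PHYLUM_POOL[kingdom])]
        gtdb_rows.append(LineageRecord(key=asm, ranks=(
            ("kingdom", kingdom),
            ("phylum", phylum),
            ("class", f"{phylum[:-1]}ia"),
            ("order", f"{genus}ales"),
            ("family", f"{genus}aceae"),
            ("genus", genus),
            ("species", f"{genus} {epithet}"),
        )))

    # -- UniProt snapshot ---------------------------------------------------
    n_miss = int(round(spec.uniprot_miss_fraction * len(accession_order)))
    uniprot_misses = frozenset(accession_order[-n_miss:]) if n_miss else frozenset()
    pdb_plan = dict(spec.pdb_per_family)
    pdb_by_family: dict[str, set[str]] = {fam: set() for fam in pdb_plan}
    fam_of: dict[str, set[str]] = {}
    for r in lines:
        fam_of.setdefault(r.accession, set()).add(str(r.family))
    pdb_counter = 0
    uniprot_rows: list[UniProtEntry] = []
    for i, acc in enumerate(accession_order):
        if acc in uniprot_misses:
            continue
        pdbs: set[str] = set()
        for fam in sorted(fam_of[acc]):
            want = pdb_plan.get(fam, 0)
            if len(pdb_by_family.get(fam, ())) < want:
                pdb_counter += 1
                pdbs.add(f"{1 + pdb_counter % 9}PD{chr(65 + pdb_counter % 26)}")
                pdb_by_family[fam].add(acc)
        ecs = frozenset([_EC_POOL[i % len(_EC_POOL)]]) if i % 2 == 0 else frozenset()
        uniprot_rows.append(UniProtEntry(
            accession=acc,
            uniprot_id=f"U{acc.replace('.', '_')}",
            protein_name=f"synthetic CAZyme {acc}",
            ec_numbers=ecs,
            pdb_ids=frozenset(pdbs),
            sequence=sequences[acc],
            version_date="2022-01-01",
        ))
    for fam, want in pdb_plan.items():
        if len(pdb_by_family[fam]) < want:
            raise ValueError(f"cannot plant {want} PDB links in family {fam}")

    # -- write files --------------------------------------------------------
    write_dump(lines, out_dir / "cazy_dump.tsv")
    write_snapshot(uniprot_rows, out_dir / "uniprot.tsv", "uniprot")
    write_snapshot(lineages, out_dir / "ncbi_tax.tsv", "ncbi_tax")
    write_snapshot(gtdb_rows, out_dir / "gtdb_tax.tsv", "gtdb_tax")
    write_snapshot(assembly_rows, out_dir / "assembly.tsv", "assembly")
    write_fasta({acc: sequences[acc] for acc in accession_order}, out_dir / "seqs.fasta")

    # -- derive ground-truth counts from the final line set -----------------
    counts: dict[tuple[str, str], int] = {}
    fam_counts: dict[str, set[str]] = {}
    cell_accs: dict[tuple[str, str], set[str]] = {}
    for r in lines:
        cell_accs.setdefault((str(r.family), r.kingdom), set()).add(r.accession)
        fam_counts.setdefault(str(r.family), set()).add(r.accession)
    counts = {cell: len(accs) for cell, accs in cell_accs.items()}

    kingdoms_of: dict[str, set[str]] = {}
    for r in lines:
        kingdoms_of.setdefault(r.accession, set()).add(r.kingdom)
    cross_kingdom = sum(len(ks) - 1 for ks in kingdoms_of.values() if len(ks) > 1)

    return GroundTruth(
        n_unique_proteins=len(accession_order),
        n_dump_lines=len(lines),
        counts=counts,
        family_counts={f: len(a) for f, a in fam_counts.items()},
        redundant_pairs=sorted(redundant_pairs),
        conflict_accessions=conflict_accessions,
        cross_kingdom_conflicts=cross_kingdom,
        cluster_members=cluster_members,
        sequences=sequences,
        organism_of=organism_of,
        uniprot_misses=uniprot_misses,
        pdb_by_family={f: frozenset(a) for f, a in pdb_by_family.items()},
        candidatus_accessions=candidatus_accessions,
        incomplete_accessions=incomplete_accessions,
        no_assembly_accessions=no_assembly_accessions,
        records=lines,
    )


def hash_name(name: str) -> int:
    """Deterministic small hash for pool selection (stable across runs)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h
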