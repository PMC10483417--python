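"""Selection criteria: which CAZymes an operation applies to.

Criteria are conjunctive across categories and disjunctive within a
category: ``families={PL20, PL28} AND kingdoms={Bacteria}`` selects
bacterial proteins that belong to PL20 *or* PL28.  Two refinements
reflect how the labels are used in practice:

* a family filter includes its subfamilies (``GH5`` matches a protein
  annotated ``GH5_4``), while a subfamily filter matches exactly;
* the organism-level categories (genus, species, strain) are unioned
  with each other before conjoining with the rest, so a command naming
  a species and a strain selects all members of the species plus that
  one extra strain.

Kingdom remains its own conjunctive category.  Empty criteria match
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .formats import (
    FamilyLabel,
    FamilyLabelError,
    canonical_kingdom,
    parse_family_label,
    split_organism,
)

__all__ = [
    "SelectionCriteria",
    "ProteinView",
    "CriteriaError",
    "compile_criteria",
    "matches",
    "matches_record",
]

_CATEGORY_KEYS = (
    "classes", "families", "subfamilies", "kingdoms",
    "genera", "species", "strains", "ec_numbers",
)


class CriteriaError(ValueError):
    """Invalid or contradictory selection criteria."""


@dataclass(frozen=True)
class SelectionCriteria:
    classes: frozenset[str] = frozenset()
    families: frozenset[FamilyLabel] = frozenset()
    subfamilies: frozenset[FamilyLabel] = frozenset()
    kingdoms: frozenset[str] = frozenset()
    genera: frozenset[str] = frozenset()
    species: frozenset[str] = frozenset()
    strains: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam.subfamily_number is not None:
                raise CriteriaError(f"{fam} has a subfamily; use the subfamilies category")
        for sub in self.subfamilies:
            if sub.subfamily_number is None:
                raise CriteriaError(f"{sub} lacks a subfamily; use the families category")

    @property
    def is_empty(self) -> bool:
        return all(not getattr(self, f.name) for f in fields(self))

    def to_dict(self) -> dict[str, list[str]]:
        """Serialize to the YAML-schema dict (lists sorted for stability)."""
        out: dict[str, list[str]] = {}
        for key in _CATEGORY_KEYS:
            values = getattr(self, key)
            if values:
                out[key] = sorted(str(v) for v in values)
        return out


def _parse_tokens(key: str, tokens: Iterable[str]):
    values = []
    for tok in tokens:
        tok = str(tok).strip()
        if not tok:
            continue
        if key in ("families", "subfamilies"):
            try:
                values.append(parse_family_label(tok))
            except FamilyLabelError as exc:
                raise CriteriaError(str(exc)) from None
        elif key == "classes":
            up = tok.upper()
            try:
                # validate by constructing a label with family number 1
                FamilyLabel(up, 1)
            except FamilyLabelError:
                raise CriteriaError(f"unknown CAZy class {tok!r}") from None
            values.append(up)
        elif key == "kingdoms":
            values.append(canonical_kingdom(tok))
        else:
            values.append(tok)
    return frozenset(values)


def _split_cli(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [v for v in value.split(",") if v.strip()]
    return [str(v) for v in value]


def compile_criteria(
    cli_args: Mapping[str, object] | None = None,
    yaml_config: str | Path | Mapping | None = None,
) -> SelectionCriteria:
    """Merge command-line tokens and a YAML config into one criteria object.

    ``cli_args`` maps category name to a comma-separated string or a
    sequence; ``yaml_config`` is a path to (or already-loaded mapping of)
    the YAML schema whose top-level keys are the category names, each a
    list of strings.  The two sources are merged by set union per
    category.  Family and subfamily tokens are validated; bad tokens
    raise :class:`CriteriaError`.
    """
    merged: dict[str, set[str]] = {k: set() for k in _CATEGORY_KEYS}
    if yaml_config is not None:
        if isinstance(yaml_config, (str, Path)):
            with open(yaml_config, encoding="utf-8") as fh:
                loaded = yaml.safe_load(fh) or {}
        else:
            loaded = dict(yaml_config)
        if not isinstance(loaded, Mapping):
            raise CriteriaError("YAML config must be a mapping of category -> list")
        for key, value in loaded.items():
            if key not in _CATEGORY_KEYS:
                raise CriteriaError(f"unknown criteria category {key!r} in config")
            if value is None:
                continue
            if isinstance(value, str) or not isinstance(value, Sequence):
                raise CriteriaError(f"category {key!r} must be a list of strings")
            merged[key].update(str(v) for v in value)
    if cli_args:
        for key, value in cli_args.items():
            if key not in _CATEGORY_KEYS:
                raise CriteriaError(f"unknown criteria category {key!r}")
            merged[key].update(_split_cli(value))

    # move misfiled family tokens: a families= token carrying a subfamily is
    # routed to the subfamilies category rather than rejected outright
    fams = _parse_tokens("families", merged["families"])
    return SelectionCriteria(
        classes=_parse_tokens("classes", merged["classes"]),
        families=fams,
        subfamilies=_parse_tokens("subfamilies", merged["subfamilies"]),
        kingdoms=_parse_tokens("kingdoms", merged["kingdoms"]),
        genera=_parse_tokens("genera", merged["genera"]),
        species=_parse_tokens("species", merged["species"]),
        strains=_parse_tokens("strains", merged["strains"]),
        ec_numbers=_parse_tokens("ec_numbers", merged["ec_numbers"]),
    )


@dataclass(frozen=True)
class ProteinView:
    """The facets of one stored protein that criteria can see.

    ``organisms`` holds every (kingdom, organism string) assignment the
    protein carries -- more than one for taxonomy-conflict records; a
    taxon filter matches if *any* assignment matches.
    """

    accession: str
    families: tuple[FamilyLabel, ...] = ()
    organisms: tuple[tuple[str, str], ...] = ()
    ec_numbers: frozenset[str] = frozenset()


def _family_matches(view_families: Sequence[FamilyLabel], crit: SelectionCriteria) -> bool:
    if crit.classes and not any(f.class_code in crit.classes for f in view_families):
        return False
    if crit.families and not any(f.family in crit.families for f in view_families):
        return False
    if crit.subfamilies and not any(f in crit.subfamilies for f in view_families):
        return False
    return True


def _organism_matches(organisms: Sequence[tuple[str, str]], crit: SelectionCriteria) -> bool:
    if crit.kingdoms and not any(k in crit.kingdoms for k, _ in organisms):
        return False
    if crit.genera or crit.species or crit.strains:
        # genus / species / strain are one disjunctive organism group
        def hit(org: str) -> bool:
            genus, epithet, _ = split_organism(org)
            return (
                genus in crit.genera
                or f"{genus} {epithet}" in crit.species
                or org in crit.strains
            )
        if not any(hit(org) for _, org in organisms):
            return False
    return True


def matches(view: ProteinView, criteria: SelectionCriteria) -> bool:
    """Pure, total predicate: does the protein satisfy the criteria?"""
    if not _family_matches(view.families, criteria):
        return False
    if not _organism_matches(view.organisms, criteria):
        return False
    if criteria.ec_numbers and not (view.ec_numbers & criteria.ec_numbers):
        return False
    return True


def matches_record(record, criteria: SelectionCriteria) -> bool:
    """Apply criteria to a single dump record at import time.

    EC filters cannot be evaluated before enrichment and are ignored here.
    """
    crit = replace(criteria, ec_numbers=frozenset())
    view = ProteinView(
        accession=record.accession,
        families=(record.family,),
        organisms=((record.kingdom, record.organism),),
    )
    return matches(view, crit)
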