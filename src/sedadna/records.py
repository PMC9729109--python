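"""Comparison of DNA, macrofossil and pollen taxon records.

Taxon names from the three proxies are first harmonized through a synonym
table (historical genus splits/merges and family renames, e.g. Gramineae ->
Poaceae), then every taxon is placed in one of four overlap categories:

1. genus recorded by DNA and, at genus level, by macrofossils or pollen;
2. genus recorded by DNA whose *family* is recorded by macrofossils or
   pollen (family-level classifications subsuming the genus);
3. taxa only recorded by DNA;
4. taxa only recorded by macrofossils or pollen.

Taxa recorded only above family rank fall into a residual ``unclassifiable``
bucket rather than being forced into 1-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RECORD_TYPES = ("dna", "macrofossil", "pollen")
RANKS = ("genus", "family", "higher")


@dataclass
class RecordSet:
    """Per-proxy sets of (name, rank) observations after harmonization."""

    dna: set[tuple[str, str]] = field(default_factory=set)
    macrofossil: set[tuple[str, str]] = field(default_factory=set)
    pollen: set[tuple[str, str]] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)  # names absent from the synonym map

    def get(self, record_type: str) -> set[tuple[str, str]]:
        return getattr(self, record_type)

    def all_taxa(self) -> set[tuple[str, str]]:
        return self.dna | self.macrofossil | self.pollen


def resolve_synonym(name: str, synonyms: dict[str, str]) -> str:
    """Follow a synonym chain to its canonical form.

    Raises
    ------
    ValueError
        On a cyclic chain.
    """
    seen = [name]
    while name in synonyms and synonyms[name] != name:
        name = synonyms[name]
        if name in seen:
            raise ValueError(f"cyclic synonym chain: {' -> '.join(seen + [name])}")
        seen.append(name)
    return name


def harmonize_taxa(
    records: dict[str, list[tuple[str, str]]], synonyms: dict[str, str]
) -> RecordSet:
    """Map every recorded name to its canonical form.

    ``records`` maps record type ('dna' | 'macrofossil' | 'pollen') to a list
    of (name, rank) observations. Names not covered by the synonym map pass
    through unchanged and are flagged in ``RecordSet.unmapped``.
    """
    out = RecordSet()
    for rtype, entries in records.items():
        if rtype not in RECORD_TYPES:
            raise ValueError(f"unknown record type {rtype!r}")
        target = out.get(rtype)
        for name, rank in entries:
            if not name:
                raise ValueError("empty taxon name")
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} for {name}")
            canonical = resolve_synonym(name, synonyms)
            if canonical == name and name not in synonyms:
                out.unmapped.add(name)
            target.add((canonical, rank))
    return out


def load_synonyms(path) -> dict[str, str]:
    """Synonym TSV with columns (name, canonical)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["name"], df["canonical"]))


def categorize_overlap(
    records: RecordSet, genus_to_family: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each recorded taxon exactly one overlap category.

    ``genus_to_family`` supplies the genus -> family relation needed for
    category 2. Returns (per-taxon table, summary of counts and fractions);
    category counts partition the union of the three record sets.
    """
    fossil = records.macrofossil | records.pollen
    fossil_genera = {n for n, r in fossil if r == "genus"}
    fossil_families = {n for n, r in fossil if r == "family"}
    dna_names = {n for n, _ in records.dna}

    rows = []
    for name, rank in sorted(records.all_taxa()):
        in_dna = (name, rank) in records.dna
        in_fossil = (name, rank) in fossil
        if rank == "higher":
            category = "unclassifiable"
        elif in_dna and rank == "genus" and name in fossil_genera:
            category = "1"
        elif in_dna and rank == "genus" and genus_to_family.get(name) in fossil_families:
            category = "2"
        elif in_dna and rank == "family" and name in fossil_families:
            # family-level DNA call matching a family-level fossil record
            category = "1"
        elif in_dna and not in_fossil:
            category = "3"
        elif in_fossil and not in_dna:
            # a fossil family whose genus was seen by DNA belongs to the
            # overlap already counted under category 2
            if rank == "family" and any(
                genus_to_family.get(g) == name for g in dna_names
            ):
                category = "2"
            else:
                category = "4"
        else:
            category = "1"
        rows.append({"name": name, "rank": rank, "category": category})

    per_taxon = pd.DataFrame(rows, columns=["name", "rank", "category"])
    summary = (
        per_taxon.groupby("category").size().rename("count").reset_index()
    )
    summary["fraction"] = summary["count"] / len(per_taxon)
    return per_taxon, summary
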