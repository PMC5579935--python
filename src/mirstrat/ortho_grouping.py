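"""Grouping of miRNA annotations into cross-species evolutionary characters.

A miRBase-style annotation table lists one record per (species, miRNA)
pair.  To date a human miRNA we need the set of species in which an
evolutionarily related copy is annotated; this module partitions records
into *ortho-groups* — one group per ancestral miRNA — either by
normalized name stem (default) or by shared family identifier, and turns
the partition into the binary presence/absence matrix consumed by the
Dollo-parsimony age estimator.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# First name tokens that ARE the stem, never a species prefix.
_STEM_TOKENS = frozenset({"mir", "mirn", "let", "lin", "bantam", "iab"})

_ARM_SUFFIX = re.compile(r"-(5p|3p)$")
_COPY_SUFFIX = re.compile(r"^(?P<stem>.*?)-(?P<copy>\d+)$")


class MalformedNameError(ValueError):
    """Raised when a miRNA name has no alphanumeric stem."""


@dataclass(frozen=True)
class MirnaRecord:
    """One miRBase-style annotation row."""

    accession: str
    species: str
    name: str
    family_id: Optional[str] = None
    coordinates: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"record {self.accession!r}: species is empty")
        if not self.name:
            raise ValueError(f"record {self.accession!r}: name is empty")


@dataclass
class OrthoGroup:
    """A cross-species set of records treated as one evolutionary character."""

    group_id: str
    members: tuple = ()
    species_set: frozenset = frozenset()

    def human_members(self, human_code: str = "hsa") -> list:
        return [m for m in self.members if m.species == human_code]


def _strip_prefix_and_arm(name: str) -> str:
    s = name.strip().casefold()
    parts = s.split("-")
    if (
        len(parts) >= 2
        and 3 <= len(parts[0]) <= 4
        and parts[0].isalnum()
        and parts[0] not in _STEM_TOKENS
    ):
        s = "-".join(parts[1:])
    s = _ARM_SUFFIX.sub("", s)
    if not any(c.isalnum() for c in s):
        raise MalformedNameError(f"miRNA name {name!r} has no alphanumeric stem")
    return s


def _copy_candidate(base: str) -> Optional[str]:
    """Stem after stripping a trailing numeric copy suffix, or None.

    Only stems that still contain a digit qualify: stripping "-21" from
    "mir-21" would leave the bare family token, which is a gene id, not
    a locus-copy index.
    """
    m = _COPY_SUFFIX.match(base)
    if m and re.search(r"\d", m.group("stem")):
        return m.group("stem")
    return None


def normalize_mirna_name(name: str, species_records: Optional[Iterable[str]] = None) -> str:
    """Normalize a miRNA name to its cross-species stem.

    The species prefix is removed, case is folded, and a mature-arm
    suffix (-5p/-3p) is dropped.  A trailing numeric copy suffix ("-1",
    "-2") is removed only when the resulting stem collides with another
    record of the same species (i.e. the records are locus copies of one
    gene); ``species_records`` supplies the raw names of the other
    same-species records for that check.

    Idempotent: normalizing an already-normalized stem is a no-op.
    """
    base = _strip_prefix_and_arm(name)
    cand = _copy_candidate(base)
    if cand is None or species_records is None:
        return base
    other_bases = set()
    other_cands = set()
    for other in species_records:
        if other == name:
            continue
        try:
            ob = _strip_prefix_and_arm(other)
        except MalformedNameError:
            continue
        other_bases.add(ob)
        oc = _copy_candidate(ob)
        if oc is not None:
            other_cands.add(oc)
    if cand in other_bases or cand in other_cands:
        return cand
    return base


def build_ortho_groups(records: Iterable[MirnaRecord], mode: str = "name") -> list[OrthoGroup]:
    """Partition records into ortho-groups.

    ``mode="name"`` groups by normalized name stem across species;
    ``mode="family"`` groups by shared ``family_id`` (records without a
    family become their own group).  Malformed names are rejected with a
    logged warning.  Single-species groups are valid characters.
    """
    if mode not in ("name", "family"):
        raise ValueError(f"unknown grouping mode: {mode!r}")
    records = list(records)
    by_species: dict[str, list[str]] = defaultdict(list)
    for r in records:
        by_species[r.species].append(r.name)

    groups: dict[str, list[MirnaRecord]] = defaultdict(list)
    n_rejected = 0
    for r in records:
        if mode == "family" and r.family_id:
            key = f"fam:{r.family_id}"
        else:
            try:
                key = normalize_mirna_name(r.name, by_species[r.species])
            except MalformedNameError as exc:
                logger.warning("rejecting record %s: %s", r.accession, exc)
                n_rejected += 1
                continue
            if mode == "family":
                # no family annotation: the record is its own character
                key = f"acc:{r.accession}"
        groups[key].append(r)
    if n_rejected:
        logger.warning("rejected %d records with malformed names", n_rejected)

    out = []
    for key in sorted(groups):
        members = tuple(sorted(groups[key], key=lambda m: (m.species, m.accession)))
        out.append(
            OrthoGroup(
                group_id=key,
                members=members,
                species_set=frozenset(m.species for m in members),
            )
        )
    return out


def presence_matrix(groups: Iterable[OrthoGroup], species_order: Sequence[str]) -> pd.DataFrame:
    """Binary group-by-species presence matrix.

    Species carried by a group but absent from ``species_order`` (for
    example, annotated species lacking divergence-time data) are dropped
    from the profile, with the number of distinct dropped species
    logged.  Entry (g, s) is 1 iff group g has at least one member in
    species s.
    """
    species_order = list(species_order)
    if not species_order:
        raise ValueError("species_order is empty")
    if len(set(species_order)) != len(species_order):
        raise ValueError("species_order contains duplicates")
    groups = list(groups)
    known = set(species_order)
    dropped = set()
    mat = pd.DataFrame(
        0, index=[g.group_id for g in groups], columns=species_order, dtype="int8"
    )
    for g in groups:
        for sp in g.species_set:
            if sp in known:
                mat.at[g.group_id, sp] = 1
            else:
                dropped.add(sp)
    if dropped:
        logger.info(
            "excluded %d species absent from the species order: %s",
            len(dropped),
            ";".join(sorted(dropped)),
        )
    return mat


@dataclass
class FamilyTable:
    """Family membership of human miRNAs.

    A miRNA is a *singleton* iff it belongs to no family or to a family
    with exactly one human member.  ``families`` applies the configured
    minimum-size filter (default: more than four members).
    """

    family_members: dict = field(default_factory=dict)  # family_id -> set of accessions
    universe: set = field(default_factory=set)  # all human accessions considered

    @classmethod
    def from_records(cls, records: Iterable[MirnaRecord], human_code: str = "hsa") -> "FamilyTable":
        fams: dict[str, set[str]] = defaultdict(set)
        universe = set()
        for r in records:
            if r.species != human_code:
                continue
            universe.add(r.accession)
            if r.family_id:
                fams[r.family_id].add(r.accession)
        return cls(family_members=dict(fams), universe=universe)

    def family_of(self, accession: str) -> Optional[str]:
        for fid, members in self.family_members.items():
            if accession in members and len(members) > 1:
                return fid
        return None

    def singletons(self) -> set:
        in_family = set()
        for members in self.family_members.values():
            if len(members) > 1:
                in_family |= members
        return set(self.universe) - in_family

    def families(self, min_size: int = 5) -> dict:
        """Families passing the size filter (``min_size=5`` keeps >4 members)."""
        return {
            fid: set(members)
            for fid, members in self.family_members.items()
            if len(members) >= min_size
        }


def read_mirna_table(path) -> list[MirnaRecord]:
    """Read a tab-delimited annotation table (accession, species, name, family_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = {"accession", "species", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if df["accession"].duplicated().any():
        dup = df["accession"][df["accession"].duplicated()].iloc[0]
        raise ValueError(f"duplicate accession in annotation table: {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        fam = getattr(row, "family_id", "") or None
        records.append(
            MirnaRecord(
                accession=row.accession,
                species=row.species,
                name=row.name,
                family_id=fam,
            )
        )
    return records


def write_groups(path, groups: Iterable[OrthoGroup]) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "n_members": len(g.members),
            "n_species": len(g.species_set),
            "species": ";".join(sorted(g.species_set)),
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def family_table_from_mapping(mapping: Mapping[str, Iterable[str]], universe: Iterable[str]) -> FamilyTable:
    """Build a FamilyTable from an explicit family -> accessions mapping."""
    return FamilyTable(
        family_members={k: set(v) for k, v in mapping.items()},
        universe=set(universe),
    )
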