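"""Metabolite record parsing, kingdom classification and biofluid overlap.

The input format is a compact XML dialect carrying the only fields this
pipeline consumes from metabolome-database exports: the accession, the
display name, the biospecimen locations where the metabolite was
detected, and the biological-disposition sources (microbial kingdom plus
an optional source-taxon name).  One document per biofluid export is the
expected layout, but a document may carry records from several fluids::

    <metabolites>
      <metabolite>
        <accession>M000001</accession>
        <name>butyric acid</name>
        <biospecimen_locations>
          <biospecimen>Feces</biospecimen>
          <biospecimen>Serum</biospecimen>
        </biospecimen_locations>
        <biological_disposition>
          <source kingdom="Bacteria">Clostridium butyricum</source>
          <source kingdom="Bacteria"/>
        </biological_disposition>
      </metabolite>
    </metabolites>

Only records whose disposition mentions bacteria and/or fungi (matched
case-insensitively) are retained; everything else is counted and
dropped.  Source-taxon names are normalized (whitespace collapsed, first
letter capitalized) but genus-only and genus+species forms are kept as
distinct entities.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Biofluid",
    "Kingdom",
    "MetaboliteRecord",
    "KingdomPartition",
    "BiofluidOverlap",
    "SENTINEL_TAXA",
    "normalize_taxon",
    "parse_metabolite_xml",
    "merge_biofluid_collections",
    "partition_by_kingdom",
    "biofluid_overlap",
]


class Biofluid(str, Enum):
    """Human biospecimen compartments tracked for each metabolite."""

    FECES = "FECES"
    SERUM = "SERUM"
    CSF = "CSF"


class Kingdom(str, Enum):
    """Microbial kingdom of the metabolite's biological disposition."""

    BACTERIA = "BACTERIA"
    FUNGI = "FUNGI"


#: Sentinel taxon entities for metabolites whose disposition names a
#: kingdom but no specific organism.
SENTINEL_TAXA = {
    Kingdom.BACTERIA: "Unnamed bacteria",
    Kingdom.FUNGI: "Unnamed fungi",
}

_BIOFLUID_ALIASES = {
    "feces": Biofluid.FECES,
    "faeces": Biofluid.FECES,
    "serum": Biofluid.SERUM,
    "blood": Biofluid.SERUM,
    "csf": Biofluid.CSF,
    "cerebrospinal fluid": Biofluid.CSF,
    "cerebrospinal fluid (csf)": Biofluid.CSF,
}

_WS = re.compile(r"\s+")


def normalize_taxon(name: str) -> str:
    """Trim, collapse internal whitespace and capitalize the first letter."""
    cleaned = _WS.sub(" ", name.strip())
    if not cleaned:
        return cleaned
    return cleaned[0].upper() + cleaned[1:]


def _classify_kingdom(label: str) -> Kingdom | None:
    low = label.lower()
    if "bacteria" in low:
        return Kingdom.BACTERIA
    if "fungi" in low or "fungus" in low:
        return Kingdom.FUNGI
    return None


@dataclass(frozen=True)
class MetaboliteRecord:
    """One metabolite with its biofluids, kingdom sources and source taxa.

    ``kingdoms`` is non-empty for every retained record (records lacking
    a microbial disposition are filtered out at parse time), and
    ``biofluids`` is non-empty.  ``source_taxa`` may be empty when the
    disposition names a kingdom but no organism.
    """

    metabolite_id: str
    name: str
    biofluids: frozenset[Biofluid]
    kingdoms: frozenset[Kingdom]
    source_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.kingdoms:
            raise ValueError(f"record {self.metabolite_id!r}: kingdoms must be non-empty")
        if not self.biofluids:
            raise ValueError(f"record {self.metabolite_id!r}: biofluids must be non-empty")


@dataclass(frozen=True)
class KingdomPartition:
    """Disjoint exhaustive partition of records by producing kingdom."""

    bacteria_only: int
    fungi_only: int
    both: int

    @property
    def total(self) -> int:
        return self.bacteria_only + self.fungi_only + self.both

    def to_dict(self) -> dict[str, int]:
        return {
            "bacteria_only": self.bacteria_only,
            "fungi_only": self.fungi_only,
            "both": self.both,
            "total": self.total,
        }


@dataclass(frozen=True)
class BiofluidOverlap:
    """The seven 3-set Venn region counts over {feces, serum, CSF}."""

    feces_only: int
    serum_only: int
    csf_only: int
    feces_serum: int
    feces_csf: int
    serum_csf: int
    all_three: int

    @property
    def total(self) -> int:
        return (
            self.feces_only
            + self.serum_only
            + self.csf_only
            + self.feces_serum
            + self.feces_csf
            + self.serum_csf
            + self.all_three
        )

    def region(self, fluids: Iterable[Biofluid]) -> int:
        """Count of records detected in exactly the given fluid set."""
        key = frozenset(fluids)
        return {
            frozenset({Biofluid.FECES}): self.feces_only,
            frozenset({Biofluid.SERUM}): self.serum_only,
            frozenset({Biofluid.CSF}): self.csf_only,
            frozenset({Biofluid.FECES, Biofluid.SERUM}): self.feces_serum,
            frozenset({Biofluid.FECES, Biofluid.CSF}): self.feces_csf,
            frozenset({Biofluid.SERUM, Biofluid.CSF}): self.serum_csf,
            frozenset({Biofluid.FECES, Biofluid.SERUM, Biofluid.CSF}): self.all_three,
        }[key]

    def to_dict(self) -> dict[str, int]:
        return {
            "feces_only": self.feces_only,
            "serum_only": self.serum_only,
            "csf_only": self.csf_only,
            "feces_serum": self.feces_serum,
            "feces_csf": self.feces_csf,
            "serum_csf": self.serum_csf,
            "all_three": self.all_three,
            "total": self.total,
        }


def parse_metabolite_xml(source: str | IO[bytes]) -> list[MetaboliteRecord]:
    """Parse a metabolite XML export, keeping microbial records only.

    Parameters
    ----------
    source:
        Path or binary stream of a document in the dialect described in
        the module docstring.

    Returns
    -------
    list of MetaboliteRecord
        Records whose biological disposition mentions bacteria and/or
        fungi.  Records mentioning neither, or with no recognized
        biofluid, are dropped; the drop counts are logged.  Unknown
        biofluid labels produce a warning and are ignored.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        If the document is malformed (the error carries line context).
    """
    tree = etree.parse(source)
    records: list[MetaboliteRecord] = []
    dropped_kingdom = 0
    dropped_biofluid = 0
    for elem in tree.getroot().iter("metabolite"):
        accession = (elem.findtext("accession") or "").strip()
        name = (elem.findtext("name") or "").strip()

        fluids: set[Biofluid] = set()
        for bio in elem.iterfind("biospecimen_locations/biospecimen"):
            label = (bio.text or "").strip()
            fluid = _BIOFLUID_ALIASES.get(label.lower())
            if fluid is None:
                logger.warning(
                    "metabolite %s: unknown biofluid label %r ignored", accession, label
                )
            else:
                fluids.add(fluid)

        kingdoms: set[Kingdom] = set()
        taxa: set[str] = set()
        for src in elem.iterfind("biological_disposition/source"):
            kingdom = _classify_kingdom(src.get("kingdom", ""))
            if kingdom is None:
                continue
            kingdoms.add(kingdom)
            taxon = normalize_taxon(src.text or "")
            if taxon:
                taxa.add(taxon)

        if not kingdoms:
            dropped_kingdom += 1
            continue
        if not fluids:
            dropped_biofluid += 1
            logger.warning("metabolite %s: no recognized biofluid, dropped", accession)
            continue
        records.append(
            MetaboliteRecord(
                metabolite_id=accession,
                name=name,
                biofluids=frozenset(fluids),
                kingdoms=frozenset(kingdoms),
                source_taxa=frozenset(taxa),
            )
        )
    if dropped_kingdom:
        logger.info("dropped %d records without a microbial disposition", dropped_kingdom)
    return records


def merge_biofluid_collections(
    feces: Sequence[MetaboliteRecord],
    serum: Sequence[MetaboliteRecord],
    csf: Sequence[MetaboliteRecord],
) -> list[MetaboliteRecord]:
    """Merge per-biofluid record lists into one deduplicated collection.

    Records sharing a ``metabolite_id`` are merged by union of their
    biofluids, kingdoms and source taxa.  Conflicting display names keep
    the first-seen name, with a warning.  The output is sorted by id.
    """
    merged: dict[str, MetaboliteRecord] = {}
    for rec in [*feces, *serum, *csf]:
        prev = merged.get(rec.metabolite_id)
        if prev is None:
            merged[rec.metabolite_id] = rec
            continue
        if rec.name and prev.name and rec.name != prev.name:
            logger.warning(
                "metabolite %s: conflicting names %r / %r, keeping first",
                rec.metabolite_id,
                prev.name,
                rec.name,
            )
        merged[rec.metabolite_id] = replace(
            prev,
            biofluids=prev.biofluids | rec.biofluids,
            kingdoms=prev.kingdoms | rec.kingdoms,
            source_taxa=prev.source_taxa | rec.source_taxa,
        )
    return [merged[key] for key in sorted(merged)]


def partition_by_kingdom(records: Iterable[MetaboliteRecord]) -> KingdomPartition:
    """Count records produced only by bacteria, only by fungi, or both."""
    bacteria_only = fungi_only = both = 0
    for rec in records:
        has_b = Kingdom.BACTERIA in rec.kingdoms
        has_f = Kingdom.FUNGI in rec.kingdoms
        if has_b and has_f:
            both += 1
        elif has_b:
            bacteria_only += 1
        elif has_f:
            fungi_only += 1
    return KingdomPartition(bacteria_only=bacteria_only, fungi_only=fungi_only, both=both)


def biofluid_overlap(
    records: Iterable[MetaboliteRecord],
    kingdom: Kingdom | str | None = None,
) -> BiofluidOverlap:
    """Venn-region counts of biofluid membership for one kingdom's records.

    ``kingdom=None`` keeps every retained record; otherwise records whose
    kingdom set contains the given kingdom are counted (a record produced
    by both kingdoms contributes to both filters).
    """
    if kingdom is not None:
        try:
            kingdom = Kingdom(kingdom.upper() if isinstance(kingdom, str) else kingdom)
        except ValueError as exc:
            raise ValueError(f"unknown kingdom filter: {kingdom!r}") from exc
    counts: dict[frozenset[Biofluid], int] = {}
    for rec in records:
        if kingdom is not None and kingdom not in rec.kingdoms:
            continue
        counts[rec.biofluids] = counts.get(rec.biofluids, 0) + 1
    F, S, C = Biofluid.FECES, Biofluid.SERUM, Biofluid.CSF
    return BiofluidOverlap(
        feces_only=counts.get(frozenset({F}), 0),
        serum_only=counts.get(frozenset({S}), 0),
        csf_only=counts.get(frozenset({C}), 0),
        feces_serum=counts.get(frozenset({F, S}), 0),
        feces_csf=counts.get(frozenset({F, C}), 0),
        serum_csf=counts.get(frozenset({S, C}), 0),
        all_three=counts.get(frozenset({F, S, C}), 0),
    )
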