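"""Readers and writers for drug-target interaction tables.

The package's native exchange format is a four-column, tab-separated edge
table (``drug_id``, ``drug_name``, ``target_id``, ``target_name``) with a
header row, UTF-8 encoding and LF line endings.  DrugBank-style full-database
XML can be converted into the same table; by convention only *target*
partners of approved drugs are admitted into analysis, because carriers,
transporters and enzymes are not functionally altered by the drug the way a
pharmacological target is.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

EDGE_TABLE_COLUMNS = ("drug_id", "drug_name", "target_id", "target_name")


class SourceCategory(str, enum.Enum):
    """Partner category of an interaction record in DrugBank-style sources."""

    TARGET = "target"
    ENZYME = "enzyme"
    CARRIER = "carrier"
    TRANSPORTER = "transporter"


def canonical(identifier: str) -> str:
    """Canonicalize an identifier: trim whitespace and case-fold.

    Display strings are preserved elsewhere; canonical forms are used for
    matching and deduplication only.
    """
    return identifier.strip().casefold()


@dataclass(frozen=True)
class InteractionRecord:
    """One directed drug -> partner interaction."""

    drug_id: str
    drug_name: str
    target_id: str
    target_name: str
    target_organism: str | None = None
    source_category: SourceCategory = SourceCategory.TARGET

    def __post_init__(self) -> None:
        if not canonical(self.drug_id):
            raise ValueError("drug_id must be non-empty")
        if not canonical(self.target_id):
            raise ValueError("target_id must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical (drug_id, target_id) pair used for deduplication."""
        return (canonical(self.drug_id), canonical(self.target_id))


@dataclass(frozen=True)
class FilterSpec:
    """Admission rules applied when reading DrugBank-style XML.

    ``require_approved`` keeps only drugs whose group list contains the
    token ``approved`` (case-insensitive) -- the machine-readable proxy for
    FDA approval.  ``allowed_partner_categories`` defaults to targets only.
    Self-loops (a compound that is its own target) are retained unless
    ``drop_self_loops`` is set.
    """

    require_approved: bool = True
    allowed_partner_categories: frozenset[SourceCategory] = frozenset(
        {SourceCategory.TARGET}
    )
    drop_self_loops: bool = False

    def __post_init__(self) -> None:
        if not self.allowed_partner_categories:
            raise ValueError("allowed_partner_categories must be non-empty")


@dataclass
class InteractionTable:
    """A deduplicated, deterministically ordered collection of interactions.

    After :meth:`canonicalize`, no two records share a canonical
    (drug_id, target_id) pair and rows are sorted by canonical drug id then
    canonical target id, so downstream runs are reproducible.
    """

    records: list[InteractionRecord] = field(default_factory=list)
    provenance: str = ""

    def canonicalize(self) -> "InteractionTable":
        seen: dict[tuple[str, str], InteractionRecord] = {}
        for rec in self.records:
            seen.setdefault(rec.key, rec)
        ordered = sorted(seen.values(), key=lambda r: r.key)
        return InteractionTable(records=ordered, provenance=self.provenance)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drug_ids(self) -> set[str]:
        return {canonical(r.drug_id) for r in self.records}

    @property
    def target_ids(self) -> set[str]:
        return {canonical(r.target_id) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.drug_id, r.drug_name, r.target_id, r.target_name)
                for r in self.records
            ],
            columns=list(EDGE_TABLE_COLUMNS),
        )


def _localname(element) -> str:
    tag = element.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _child_text(element, name: str) -> str | None:
    for child in element:
        if _localname(child) == name:
            return child.text
    return None


_CATEGORY_CONTAINERS = {
    "targets": SourceCategory.TARGET,
    "enzymes": SourceCategory.ENZYME,
    "carriers": SourceCategory.CARRIER,
    "transporters": SourceCategory.TRANSPORTER,
}


def parse_drugbank_xml(
    xml_source: Union[str, Path, bytes],
    filter_spec: FilterSpec | None = None,
) -> InteractionTable:
    """Parse DrugBank-style full-database XML into an interaction table.

    Parameters
    ----------
    xml_source:
        Path to an XML file, or raw XML bytes.
    filter_spec:
        Admission rules; defaults to approved drugs, target partners only.

    Returns
    -------
    InteractionTable
        One record per admitted (drug, partner) pair, deduplicated and
        deterministically ordered.  Counts of accepted and rejected records
        are logged; nothing is dropped silently.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        If the XML is malformed (the error names the offending position).
    """
    filter_spec = filter_spec or FilterSpec()
    if isinstance(xml_source, bytes):
        root = etree.fromstring(xml_source)
        source_label = "<bytes>"
    else:
        root = etree.parse(str(xml_source)).getroot()
        source_label = str(xml_source)

    records: list[InteractionRecord] = []
    n_drugs_seen = 0
    n_drugs_rejected = 0
    n_partners_rejected = 0

    for drug in root:
        if _localname(drug) != "drug":
            continue
        n_drugs_seen += 1
        groups = [
            (g.text or "").strip().casefold()
            for container in drug
            if _localname(container) == "groups"
            for g in container
            if _localname(g) == "group"
        ]
        if filter_spec.require_approved and "approved" not in groups:
            n_drugs_rejected += 1
            continue

        drug_id = None
        for child in drug:
            if _localname(child) == "drugbank-id":
                if child.get("primary") == "true" or drug_id is None:
                    drug_id = child.text
        drug_name = _child_text(drug, "name") or (drug_id or "")
        if drug_id is None:
            drug_id = drug_name
        if not drug_id:
            n_drugs_rejected += 1
            logger.warning("drug element without id or name skipped")
            continue

        for container in drug:
            category = _CATEGORY_CONTAINERS.get(_localname(container))
            if category is None:
                continue
            for partner in container:
                partner_id = _child_text(partner, "id")
                partner_name = _child_text(partner, "name") or partner_id
                if not partner_id:
                    n_partners_rejected += 1
                    logger.warning(
                        "partner without id under drug %s skipped", drug_id
                    )
                    continue
                if category not in filter_spec.allowed_partner_categories:
                    n_partners_rejected += 1
                    continue
                if filter_spec.drop_self_loops and canonical(
                    drug_name
                ) == canonical(partner_name):
                    n_partners_rejected += 1
                    continue
                records.append(
                    InteractionRecord(
                        drug_id=drug_id,
                        drug_name=drug_name,
                        target_id=partner_id,
                        target_name=partner_name,
                        target_organism=_child_text(partner, "organism"),
                        source_category=category,
                    )
                )

    table = InteractionTable(
        records=records,
        provenance=(
            f"parse_drugbank_xml(source={source_label}, "
            f"require_approved={filter_spec.require_approved}, "
            f"categories={sorted(c.value for c in filter_spec.allowed_partner_categories)})"
        ),
    ).canonicalize()
    logger.info(
        "parsed %s: %d drugs seen, %d drugs rejected by filter, "
        "%d partner records rejected, %d interactions admitted",
        source_label,
        n_drugs_seen,
        n_drugs_rejected,
        n_partners_rejected,
        len(table),
    )
    return table


def read_edge_table(path: Union[str, Path], has_header: bool = True) -> InteractionTable:
    """Read the native tab-separated edge table.

    Expects four columns (drug_id, drug_name, target_id, target_name); names
    may equal ids.  The result is canonicalized (deduplicated and sorted).

    Raises
    ------
    ValueError
        If a line does not have exactly four tab-separated fields; the error
        names the 1-based line number.
    """
    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and has_header:
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            records.append(InteractionRecord(*fields))
    return InteractionTable(
        records=records, provenance=f"read_edge_table({path})"
    ).canonicalize()


def write_edge_table(table: InteractionTable, path: Union[str, Path]) -> None:
    """Write a canonical, deterministic TSV edge table (header + sorted rows)."""
    table = table.canonicalize()
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for rec in table.records:
            handle.write(
                f"{rec.drug_id}\t{rec.drug_name}\t{rec.target_id}\t{rec.target_name}\n"
            )
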