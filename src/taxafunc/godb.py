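"""Accession-to-GO store construction and lookup.

The protein-level classifier reports only the first (representative)
accession of a non-redundant database entry that compiles identical
sequences. To annotate such a hit with GO terms, the annotations of *all*
member accessions of the entry must be attached to the representative:
member accessions are mapped to UniProt ids, UniProt ids to GO terms via a
GAF-style annotation table, and the union is stored under the
representative accession.
"""

from __future__ import annotations

import sqlite3
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from .types import ParseError, check_go_id


@dataclass
class BuildReport:
    """Counters describing what happened during a store build."""

    n_representatives: int = 0
    n_annotated: int = 0
    n_members: int = 0
    rejected_go_rows: int = 0
    not_qualifier_rows: int = 0
    evidence_filtered_rows: int = 0


@dataclass
class AccessionGoStore:
    """Representative accession -> set of GO ids; exact-string keys."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)
    report: BuildReport = field(default_factory=BuildReport)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, accession: str) -> bool:
        return accession in self.mapping


def read_membership(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (representative, member) -> representative -> members."""
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        out.setdefault(fields[0], []).append(fields[1])
    return out


def read_idmapping(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (accession, UniProt accession); many-to-many allowed."""
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        out.setdefault(fields[0], []).append(fields[1])
    return out


def read_gaf(path: str | Path) -> list[tuple[str, str, str, str]]:
    """GAF 2.x-style rows as (uniprot, qualifier, go_id, evidence_code).

    Uses columns 2 (DB object id), 4 (qualifier), 5 (GO id) and 7
    (evidence code); '!' comment lines are skipped.
    """
    rows = []
    for line in open(path):
        if line.startswith("!") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}: GAF row with <5 columns")
        evidence = fields[6] if len(fields) > 6 else ""
        rows.append((fields[1], fields[3], fields[4], evidence))
    return rows


def build_store(
    membership: Mapping[str, Iterable[str]],
    idmapping: Mapping[str, Iterable[str]],
    annotations: Iterable[tuple[str, str, str, str]],
    exclude_evidence: Iterable[str] = (),
) -> AccessionGoStore:
    """Union GO annotations of every entry member under its representative.

    ``annotations`` rows whose qualifier contains ``NOT`` are excluded
    (they assert absence of function). All evidence codes are accepted by
    default; ``exclude_evidence`` filters codes (e.g. ``{"IEA"}``) if the
    user opts in. Representatives with no reachable annotation are absent
    from the store.
    """
    report = BuildReport(n_representatives=len(membership))
    excluded = {e.upper() for e in exclude_evidence}
    uniprot_to_gos: dict[str, set[str]] = {}
    for uniprot, qualifier, go_id, evidence in annotations:
        if "NOT" in [q.upper() for q in qualifier.split("|")]:
            report.not_qualifier_rows += 1
            continue
        if evidence.upper() in excluded:
            report.evidence_filtered_rows += 1
            continue
        if not check_go_id(go_id):
            report.rejected_go_rows += 1
            continue
        uniprot_to_gos.setdefault(uniprot, set()).add(go_id)

    mapping: dict[str, frozenset[str]] = {}
    for representative, members in membership.items():
        member_list = list(members)
        report.n_members += len(member_list)
        gos: set[str] = set()
        for member in member_list:
            for uniprot in idmapping.get(member, ()):
                gos.update(uniprot_to_gos.get(uniprot, ()))
        if gos:
            mapping[representative] = frozenset(gos)
    report.n_annotated = len(mapping)
    return AccessionGoStore(mapping=mapping, report=report)


def query_store(store: AccessionGoStore, accession: str) -> frozenset[str]:
    """Stored GO set for ``accession``; empty set when unknown (exact match)."""
    return store.mapping.get(accession, frozenset())


def save_store(store: AccessionGoStore, path: str | Path, dialect: str = "sqlite") -> Path:
    """Persist the store as a single-file sqlite database or a sorted TSV."""
    path = Path(path)
    if dialect == "sqlite":
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            con.execute(
                "CREATE TABLE accession_go (accession TEXT NOT NULL, go_id TEXT NOT NULL)"
            )
            con.execute("CREATE INDEX idx_acc ON accession_go (accession)")
            rows = [
                (acc, go)
                for acc in sorted(store.mapping)
                for go in sorted(store.mapping[acc])
            ]
            con.executemany("INSERT INTO accession_go VALUES (?, ?)", rows)
            con.commit()
        finally:
            con.close()
    elif dialect == "tsv":
        with open(path, "w") as fh:
            for acc in sorted(store.mapping):
                for go in sorted(store.mapping[acc]):
                    fh.write(f"{acc}\t{go}\n")
    else:
        raise ValueError(f"unknown store dialect {dialect!r}")
    return path


def load_store(path: str | Path) -> AccessionGoStore:
    """Load a store written by :func:`save_store` (dialect auto-detected)."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path, "rb") as fh:
        is_sqlite = fh.read(16).startswith(b"SQLite format 3")
    if is_sqlite:
        con = sqlite3.connect(path)
        try:
            for acc, go in con.execute("SELECT accession, go_id FROM accession_go"):
                mapping.setdefault(acc, set()).add(go)
        finally:
            con.close()
    else:
        for line in open(path):
            if not line.strip():
                continue
            acc, go = line.rstrip("\n").split("\t")
            mapping.setdefault(acc, set()).add(go)
    return AccessionGoStore(
        mapping={k: frozenset(v) for k, v in mapping.items()}
    )
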