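"""Readers and writers for every external file the pipeline touches.

Input dialects: per-read classifier TSV (Kaiju-style verbose or plain
3-column), NCBI-style ``nodes.dmp``/``names.dmp`` taxonomy dumps, OBO 1.2
(go-basic dialect: is_a + part_of only), GMT gene sets, featureCounts-style
count tables and a simple sample-sheet TSV. All outputs are plain TSV with
deterministic formatting so reruns are byte-identical.
"""

from __future__ import annotations

from collections.abc import Iterator
from pathlib import Path

import obonet
import networkx as nx
import pandas as pd

from .types import (
    ClassifiedRead,
    GeneCountTable,
    GeneSet,
    GeneSetCollection,
    GoDag,
    GoTerm,
    ParseError,
    SampleInfo,
    SampleSheet,
    TaxonNode,
    TaxonomyTree,
    ValidationError,
    unique_preserve,
)

#: significant digits used when rendering floats to TSV
FLOAT_FORMAT = "%.6g"


def read_kaiju(path: str | Path, require_accessions: bool = False) -> Iterator[ClassifiedRead]:
    """Stream per-read classifications from a classifier output TSV.

    Verbose (>=6 column) files carry the alignment score, tied best-match
    taxids and tied best protein accessions; plain 3-column files are
    accepted only when ``require_accessions`` is off (taxonomy-only runs).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            status = fields[0]
            if status not in ("C", "U"):
                raise ParseError(
                    f"{path}:{lineno}: malformed status {status!r} (expected C or U)"
                )
            try:
                taxid = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer taxid {fields[2]!r}"
                ) from None
            if require_accessions and status == "C" and len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: verbose output with accession column "
                    "required for functional analysis"
                )
            score: int | None = None
            best_taxids: list[int] = []
            accessions: list[str] = []
            if status == "C" and len(fields) >= 6:
                if fields[3]:
                    try:
                        score = int(fields[3])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-integer score {fields[3]!r}"
                        ) from None
                if fields[4]:
                    try:
                        best_taxids = [int(x) for x in fields[4].split(",") if x]
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-integer best-match taxid list"
                        ) from None
                if fields[5]:
                    accessions = unique_preserve(
                        a for a in fields[5].split(",") if a
                    )
            if status == "U":
                taxid = 0
                accessions = []
            yield ClassifiedRead(
                status=status,
                read_id=fields[1],
                taxid=taxid,
                score=score,
                best_match_taxids=best_taxids,
                accessions=accessions,
            )


def _split_dmp(line: str) -> list[str]:
    # NCBI dump rows: fields delimited by "\t|\t", row terminated by "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def read_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes.dmp/names.dmp-style files."""
    nodes: dict[int, TaxonNode] = {}
    for lineno, line in enumerate(open(nodes_path), start=1):
        if not line.strip():
            continue
        fields = _split_dmp(line)
        if len(fields) < 3:
            raise ParseError(f"{nodes_path}:{lineno}: expected >=3 fields")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise ParseError(f"{nodes_path}:{lineno}: non-integer taxid") from None
        if taxid in nodes:
            raise ValidationError(f"{nodes_path}:{lineno}: duplicate taxid {taxid}")
        nodes[taxid] = TaxonNode(parent=parent, rank=fields[2].strip(), name="")
    names: dict[int, str] = {}
    for lineno, line in enumerate(open(names_path), start=1):
        if not line.strip():
            continue
        fields = _split_dmp(line)
        if len(fields) < 2:
            raise ParseError(f"{names_path}:{lineno}: expected >=2 fields")
        taxid = int(fields[0])
        name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
        if name_class == "scientific name" or taxid not in names:
            names[taxid] = fields[1].strip()
    for taxid, node in nodes.items():
        node.name = names.get(taxid, f"taxid:{taxid}")
    return TaxonomyTree(nodes)


def read_obo(path: str | Path) -> GoDag:
    """Parse a go-basic-dialect OBO file into a :class:`GoDag`.

    Only ``is_a`` and ``relationship: part_of`` edges are kept; any other
    relationship type is ignored. Obsolete terms are retained but flagged.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # malformed stanza, missing id, ...
        raise ParseError(f"{path}: cannot parse OBO file: {exc}") from exc
    terms: dict[str, GoTerm] = {}
    for go_id, data in graph.nodes(data=True):
        if not go_id:
            raise ParseError(f"{path}: stanza without id")
        part_of = []
        for rel in data.get("relationship", []):
            rel_type, _, target = rel.partition(" ")
            if rel_type == "part_of" and target:
                part_of.append(target.split()[0])
        terms[go_id] = GoTerm(
            name=data.get("name", go_id),
            namespace=data.get("namespace"),
            is_a=list(data.get("is_a", [])),
            part_of=part_of,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            alt_ids=list(data.get("alt_id", [])),
        )
    try:
        dag = GoDag(terms)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    # belt-and-braces: the restricted edge set must admit a topological sort
    g = nx.DiGraph(
        (child, parent)
        for child, term in terms.items()
        for parent in term.parents
        if parent in terms
    )
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError(f"{path}: is_a/part_of graph is cyclic")
    return dag


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-matrix-transposed file: name, description, genes..."""
    out = GeneSetCollection()
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
        genes = unique_preserve(g for g in fields[2:] if g)
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
        out[fields[0]] = GeneSet(description=fields[1], genes=genes)
    return out


def read_counts_table(path: str | Path) -> GeneCountTable:
    """Read a featureCounts-style table (Geneid, Chr, Start, End, Strand,
    Length, one column per sample); '#' comment lines are skipped."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["Geneid", "Length"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    meta_cols = [c for c in ("Geneid", "Chr", "Start", "End", "Strand", "Length") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found")
    try:
        lengths = df["Length"].astype(int)
    except ValueError:
        raise ParseError(f"{path}: non-integer Length value") from None
    if (lengths <= 0).any():
        raise ValidationError(f"{path}: Length must be > 0")
    counts = pd.DataFrame(index=df["Geneid"])
    for c in sample_cols:
        try:
            counts[c] = df[c].astype(int).values
        except ValueError:
            raise ParseError(f"{path}: non-integer count in column {c!r}") from None
    if (counts.values < 0).any():
        raise ValidationError(f"{path}: negative count")
    counts.index.name = "Geneid"
    lengths.index = counts.index
    return GeneCountTable(counts=counts, lengths=lengths)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """TSV with header: sample, group, path[, host_column]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample sheet missing column {col!r}")
    base = Path(path).parent
    samples: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        sid = row["sample"]
        if sid in samples:
            raise ValidationError(f"{path}: duplicate sample id {sid!r}")
        raw_path = row.get("path") if isinstance(row.get("path"), str) else None
        # relative paths resolve against the sheet's own directory
        if raw_path is not None and not Path(raw_path).is_absolute():
            raw_path = str(base / raw_path)
        samples[sid] = SampleInfo(
            group=row["group"],
            path=raw_path,
            host_column=row.get("host_column")
            if isinstance(row.get("host_column"), str)
            else None,
        )
    return SampleSheet(samples)


def _render(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def write_tables(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write named DataFrames as deterministic TSVs under ``out_dir``.

    Rows are sorted by index, floats rendered with 6 significant digits,
    so reruns are byte-identical. Returns name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        target = out_dir / f"{name}.tsv"
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
        body = _render(df.sort_index())
        with open(target, "w") as fh:
            fh.write(body)
        written[name] = target
    return written


def count_lines(path: str | Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if line.strip())
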