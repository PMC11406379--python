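"""Shared domain types for the profiling pipeline.

These are thin, validated containers; all heavy lifting lives in the
operation modules. Tables move through the pipeline as pandas objects,
so the types here cover only the entities that need structure beyond a
DataFrame: per-read classifications, the taxonomy forest, the GO DAG,
host count tables, gene-set collections and the sample sheet.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

GO_ID_RE = re.compile(r"^GO:\d{7}$")

SPECIES_RANK = "species"


class TaxafuncError(Exception):
    """Base class for user-facing errors raised by this package."""


class ParseError(TaxafuncError):
    """A file did not conform to its expected dialect."""


class ValidationError(TaxafuncError):
    """Structurally invalid input (cycles, missing parents, bad values)."""


@dataclass(slots=True)
class ClassifiedRead:
    """One read's taxonomic assignment plus tied best protein matches.

    ``status`` is ``"C"`` or ``"U"``. Unclassified reads carry taxid 0 and
    no accessions. ``accessions`` holds the classifier's tied best protein
    accession strings, verbatim (version suffix included).
    """

    status: str
    read_id: str
    taxid: int
    score: int | None = None
    best_match_taxids: list[int] = field(default_factory=list)
    accessions: list[str] = field(default_factory=list)

    @property
    def classified(self) -> bool:
        return self.status == "C"


@dataclass(slots=True)
class TaxonNode:
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """NCBI-style taxid forest: taxid -> (parent, rank, scientific name).

    The root is its own parent. Lookups used by the species rollup
    (nearest species ancestor, lineage) are provided here.
    """

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        self.nodes: dict[int, TaxonNode] = dict(nodes)
        self._validate()
        self._species_cache: dict[int, int | None] = {}

    def _validate(self) -> None:
        for taxid, node in self.nodes.items():
            if node.parent != taxid and node.parent not in self.nodes:
                raise ValidationError(
                    f"taxid {taxid} references absent parent {node.parent}"
                )
        # cycle check by parent-pointer climb with visited marking
        seen_ok: set[int] = set()
        for taxid in self.nodes:
            path = []
            cur = taxid
            while cur not in seen_ok:
                path.append(cur)
                parent = self.nodes[cur].parent
                if parent == cur:  # root
                    break
                if parent in path:
                    raise ValidationError(f"cycle in taxonomy at taxid {parent}")
                cur = parent
            seen_ok.update(path)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid].parent

    def is_root(self, taxid: int) -> bool:
        return self.nodes[taxid].parent == taxid

    def ancestors(self, taxid: int) -> list[int]:
        """Taxids from the node's parent up to (and including) the root."""
        out = []
        cur = taxid
        while not self.is_root(cur):
            cur = self.nodes[cur].parent
            out.append(cur)
        return out

    def species_ancestor(self, taxid: int) -> int | None:
        """The node itself if rank=species, else the nearest ancestor of
        rank species; None when no species node lies at or above ``taxid``."""
        if taxid in self._species_cache:
            return self._species_cache[taxid]
        cur = taxid
        result = None
        while True:
            if self.nodes[cur].rank == SPECIES_RANK:
                result = cur
                break
            if self.is_root(cur):
                break
            cur = self.nodes[cur].parent
        self._species_cache[taxid] = result
        return result

    def lineage(self, taxid: int) -> list[str]:
        """Scientific names from just below the root down to the node."""
        chain = [taxid] + self.ancestors(taxid)
        chain.reverse()
        # drop the root node itself; a root-only ancestry leaves the node
        if len(chain) > 1:
            chain = chain[1:]
        return [self.nodes[t].name for t in chain]


@dataclass(slots=True)
class GoTerm:
    name: str
    namespace: str | None
    is_a: list[str]
    part_of: list[str]
    obsolete: bool = False
    alt_ids: list[str] = field(default_factory=list)

    @property
    def parents(self) -> list[str]:
        return self.is_a + self.part_of


class GoDag:
    """GO terms restricted to is_a / part_of edges (go-basic dialect).

    Obsolete terms are retained but flagged; alternate ids resolve to their
    primary id. Ancestor closures are cached.
    """

    def __init__(self, terms: Mapping[str, GoTerm]):
        self.terms: dict[str, GoTerm] = dict(terms)
        self.alt_to_primary: dict[str, str] = {}
        for go_id, term in self.terms.items():
            for alt in term.alt_ids:
                if alt in self.alt_to_primary and self.alt_to_primary[alt] != go_id:
                    raise ValidationError(f"alternate id {alt} maps to multiple terms")
                self.alt_to_primary[alt] = go_id
        self._closure_cache: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.terms:
            if start in state:
                continue
            stack = [(start, iter(self.terms[start].parents))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self.terms:
                        continue
                    if state.get(parent) == 0:
                        raise ValidationError(
                            f"cycle in GO graph involving {parent}"
                        )
                    if parent not in state:
                        state[parent] = 0
                        stack.append((parent, iter(self.terms[parent].parents)))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms

    def resolve(self, go_id: str) -> str | None:
        """Primary id for ``go_id`` (may be an alt id); None if unknown."""
        if go_id in self.terms:
            return go_id
        return self.alt_to_primary.get(go_id)

    def namespace(self, go_id: str) -> str | None:
        return self.terms[go_id].namespace

    def ancestors(self, go_id: str) -> frozenset[str]:
        """All terms reachable from ``go_id`` via is_a/part_of (excl. self)."""
        if go_id in self._closure_cache:
            return self._closure_cache[go_id]
        out: set[str] = set()
        stack = [p for p in self.terms[go_id].parents if p in self.terms]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(p for p in self.terms[cur].parents if p in self.terms)
        frozen = frozenset(out)
        self._closure_cache[go_id] = frozen
        return frozen


@dataclass
class GeneCountTable:
    """featureCounts-style host gene counts: genes x samples, plus lengths (bp)."""

    counts: pd.DataFrame  # int counts, index = gene ids
    lengths: pd.Series  # bp, aligned to counts.index

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(slots=True)
class GeneSet:
    description: str
    genes: list[str]


class GeneSetCollection(dict):
    """Mapping set name -> GeneSet; no empty sets, genes unique within a set."""

    def __setitem__(self, name: str, value: GeneSet) -> None:
        if not value.genes:
            raise ValidationError(f"gene set {name!r} is empty")
        super().__setitem__(name, value)


@dataclass(slots=True)
class SampleInfo:
    group: str
    path: str | None = None
    host_column: str | None = None


class SampleSheet:
    """Sample id -> (group label, classification file path, host count column)."""

    def __init__(self, samples: Mapping[str, SampleInfo]):
        if not samples:
            raise ValidationError("sample sheet has no samples")
        paths = [s.path for s in samples.values() if s.path]
        if len(paths) != len(set(paths)):
            raise ValidationError("classification file paths must be distinct")
        for sid, info in samples.items():
            if not info.group:
                raise ValidationError(f"sample {sid} has an empty group label")
        self.samples: dict[str, SampleInfo] = dict(samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self.samples[sample_id]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered list of member sample ids."""
        out: dict[str, list[str]] = {}
        for sid, info in self.samples.items():
            out.setdefault(info.group, []).append(sid)
        return out

    def group_of(self, sample_id: str) -> str:
        return self.samples[sample_id].group


def check_go_id(go_id: str) -> bool:
    return bool(GO_ID_RE.match(go_id))


def unique_preserve(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out
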