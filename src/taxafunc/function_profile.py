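"""Protein-level proportional counting and GO functional profiles.

A read with k tied best protein matches contributes 1/k to each accession,
attributed to the read's rolled-up species. Accession counts are annotated
with GO terms from the accession->GO store, the term set of each accession
is closed over is_a/part_of ancestors (each term once, regardless of path
multiplicity), and counts are aggregated per GO term. Percentages are
computed within each GO namespace. Cross tables link GO terms to the
species whose proteins carry them, alongside whole-species group percent
abundances.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .godb import AccessionGoStore, query_store
from .taxonomy_profile import resolve_species
from .types import ClassifiedRead, GoDag, SampleSheet, TaxonomyTree


@dataclass
class ProteinDiagnostics:
    """Reads that resolved to a species but carried no usable accession."""

    reads_without_accession: int = 0
    unannotated_accessions: set = field(default_factory=set)
    obsolete_go_ids: Counter = field(default_factory=Counter)
    unresolved_go_ids: Counter = field(default_factory=Counter)


def proportional_protein_counts(
    reads: Iterable[ClassifiedRead],
    tree: TaxonomyTree,
    diagnostics: ProteinDiagnostics | None = None,
) -> dict[tuple[int, str], float]:
    """One sample's proportional counts: (species taxid, accession) -> count.

    Each species-resolved read adds 1/k to each of its k tied accessions.
    Reads with no species resolution contribute nothing; species-resolved
    reads without accessions are tallied in diagnostics. Per species, the
    sum over accessions equals the species' raw reads bearing accessions.
    """
    diag = diagnostics if diagnostics is not None else ProteinDiagnostics()
    counts: dict[tuple[int, str], float] = defaultdict(float)
    for read in reads:
        if not read.classified:
            continue
        species = resolve_species(read.taxid, tree)
        if species is None:
            continue
        if not read.accessions:
            diag.reads_without_accession += 1
            continue
        share = 1.0 / len(read.accessions)
        for acc in read.accessions:
            counts[(species, acc)] += share
    return dict(counts)


def protein_count_table(
    sample_counts: Mapping[str, Mapping[tuple[int, str], float]]
) -> pd.DataFrame:
    """Stack per-sample proportional counts into a (taxid, accession) x
    sample DataFrame."""
    df = pd.DataFrame(sample_counts).fillna(0.0)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["taxid", "accession"])
    return df.sort_index()


def scale_protein_counts(
    table: pd.DataFrame, species_totals: pd.Series
) -> pd.DataFrame:
    """Percent = 100 * proportional count / total species-mapped reads of
    the sample (global denominator). Zero-total samples give zeros."""
    totals = species_totals.reindex(table.columns)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero species-mapped totals: {list(totals.index[zero])}",
            stacklevel=2,
        )
    return 100.0 * table.div(totals.mask(zero, 1), axis=1)


def propagate_go(
    direct: Iterable[str],
    dag: GoDag,
    diagnostics: ProteinDiagnostics | None = None,
) -> frozenset[str]:
    """Close a direct GO term set over its is_a/part_of ancestors.

    Alternate ids are mapped to their primary term; obsolete terms are
    dropped (tallied); unresolvable ids are skipped (tallied). The result
    is a set, so no term is counted twice however many paths reach it.
    """
    diag = diagnostics if diagnostics is not None else ProteinDiagnostics()
    closure: set[str] = set()
    for go_id in direct:
        primary = dag.resolve(go_id)
        if primary is None:
            diag.unresolved_go_ids[go_id] += 1
            continue
        if dag.terms[primary].obsolete:
            diag.obsolete_go_ids[primary] += 1
            continue
        closure.add(primary)
        closure.update(dag.ancestors(primary))
    return frozenset(closure)


def aggregate_go_counts(
    proteins: pd.DataFrame,
    store: AccessionGoStore,
    dag: GoDag,
    diagnostics: ProteinDiagnostics | None = None,
) -> pd.DataFrame:
    """Aggregate protein counts onto propagated GO terms.

    ``proteins`` is a (taxid, accession) x sample/group table of
    proportional (or scaled) counts. For each row with closure T, the
    row's counts are added to every term of T exactly once. Returns a
    GO x column table with a ``namespace`` column."""
    diag = diagnostics if diagnostics is not None else ProteinDiagnostics()
    go_counts: dict[str, pd.Series] = {}
    closure_cache: dict[str, frozenset[str]] = {}
    for (taxid, accession), row in proteins.iterrows():
        direct = query_store(store, accession)
        if not direct:
            diag.unannotated_accessions.add(accession)
            continue
        if accession in closure_cache:
            closure = closure_cache[accession]
        else:
            closure = propagate_go(direct, dag, diag)
            closure_cache[accession] = closure
        for term in closure:
            if term in go_counts:
                go_counts[term] = go_counts[term] + row
            else:
                go_counts[term] = row.copy()
    if not go_counts:
        out = pd.DataFrame(columns=list(proteins.columns))
        out.insert(0, "namespace", pd.Series(dtype=object))
        out.index.name = "go_id"
        return out
    out = pd.DataFrame(go_counts).T.sort_index()
    out.index.name = "go_id"
    out.insert(0, "namespace", [dag.namespace(g) for g in out.index])
    return out


def namespace_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Percent of each GO term's count within its namespace, per column.

    Input is the output of :func:`aggregate_go_counts` (counts plus a
    ``namespace`` column); namespaces with zero total give zeros."""
    value_cols = [c for c in table.columns if c != "namespace"]
    out = table.copy()
    for namespace, block in table.groupby("namespace", sort=False):
        totals = block[value_cols].sum(axis=0)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"namespace {namespace!r} has zero total in {list(totals.index[zero])}",
                stacklevel=2,
            )
        out.loc[block.index, value_cols] = (
            100.0 * block[value_cols].div(totals.mask(zero, 1), axis=1)
        )
    return out


def group_mean_proteins(proteins: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Average proportional protein counts across the samples of each group
    (averaging happens before GO annotation)."""
    out = {}
    for group, samples in sheet.groups.items():
        cols = [s for s in samples if s in proteins.columns]
        out[group] = proteins[cols].mean(axis=1)
    return pd.DataFrame(out)


def build_cross_tables(
    proteins: pd.DataFrame,
    store: AccessionGoStore,
    dag: GoDag,
    species_group_percents: pd.DataFrame,
    retained_taxids: Iterable[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GO->taxa and taxa->GO cross tables from one underlying pair set.

    A (GO id, species) pair exists when the species has at least one
    annotated protein whose closure contains the GO id. Each view carries
    the species' whole-species percent abundance per group (not just the
    share contributed by proteins under the term). Returns
    (go_to_taxa, taxa_to_go) DataFrames sorted for determinism.
    """
    retained = (
        set(retained_taxids)
        if retained_taxids is not None
        else set(species_group_percents.index)
    )
    pairs: set[tuple[str, int]] = set()
    closure_cache: dict[str, frozenset[str]] = {}
    for (taxid, accession) in proteins.index:
        if taxid not in retained:
            continue
        direct = query_store(store, accession)
        if not direct:
            continue
        closure = closure_cache.get(accession)
        if closure is None:
            closure = propagate_go(direct, dag)
            closure_cache[accession] = closure
        for term in closure:
            pairs.add((term, taxid))

    rows = []
    for term, taxid in sorted(pairs):
        row = {"go_id": term, "go_name": dag.terms[term].name, "taxid": taxid}
        if taxid in species_group_percents.index:
            for group in species_group_percents.columns:
                row[f"percent_{group}"] = species_group_percents.loc[taxid, group]
        rows.append(row)
    go_to_taxa = pd.DataFrame(
        rows,
        columns=["go_id", "go_name", "taxid"]
        + [f"percent_{g}" for g in species_group_percents.columns],
    )
    taxa_to_go = (
        go_to_taxa.sort_values(["taxid", "go_id"]).reset_index(drop=True)
        if not go_to_taxa.empty
        else go_to_taxa.copy()
    )
    return go_to_taxa.reset_index(drop=True), taxa_to_go


def go_terms_of_species(taxa_to_go: pd.DataFrame, taxid: int) -> list[str]:
    """All GO ids associated with a species in the cross table."""
    if taxa_to_go.empty:
        return []
    return sorted(taxa_to_go.loc[taxa_to_go["taxid"] == taxid, "go_id"].unique())


def species_of_go_term(go_to_taxa: pd.DataFrame, go_id: str) -> list[int]:
    """All species taxids whose proteins carry (or propagate to) a GO id."""
    if go_to_taxa.empty:
        return []
    return sorted(go_to_taxa.loc[go_to_taxa["go_id"] == go_id, "taxid"].unique())
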