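"""Species-level abundance profiling.

Reads classified at strain or other below-species nodes are rolled up to
their nearest ancestor of rank ``species``; reads at or above genus level
(no species ancestor) are excluded from the species table and tallied in
diagnostics, as are unclassified reads and unknown taxids. Percent
abundance divides each species count by the sample's total species-mapped
reads (x100); the low-abundance filter drops species below a percentage
threshold in *all* samples but never recomputes the original percentages.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .types import ClassifiedRead, SampleSheet, TaxonomyTree, ValidationError

#: default abundance filter: retain a species if >= this percent in any sample
DEFAULT_ABUNDANCE_THRESHOLD = 0.001


@dataclass
class RollupDiagnostics:
    """Per-sample accounting of reads that do not reach the species table."""

    total_reads: int = 0
    species_reads: int = 0
    unclassified: int = 0
    above_species: int = 0
    unknown_taxid: int = 0
    #: distinct taxids not found in the taxonomy
    unknown_taxids: Counter = field(default_factory=Counter)

    def as_row(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "species_reads": self.species_reads,
            "unclassified": self.unclassified,
            "above_species": self.above_species,
            "unknown_taxid": self.unknown_taxid,
        }


def resolve_species(taxid: int, tree: TaxonomyTree) -> int | None:
    """Species taxid a read's assignment rolls up to, or None."""
    if taxid not in tree:
        return None
    return tree.species_ancestor(taxid)


def rollup_species(
    reads: Iterable[ClassifiedRead], tree: TaxonomyTree
) -> tuple[Counter, RollupDiagnostics]:
    """Aggregate one sample's reads into raw species counts.

    Returns (species taxid -> read count, diagnostics). Conservation:
    species_reads + unclassified + above_species + unknown_taxid equals the
    number of input reads.
    """
    counts: Counter = Counter()
    diag = RollupDiagnostics()
    for read in reads:
        diag.total_reads += 1
        if not read.classified:
            diag.unclassified += 1
            continue
        if read.taxid not in tree:
            diag.unknown_taxid += 1
            diag.unknown_taxids[read.taxid] += 1
            continue
        species = tree.species_ancestor(read.taxid)
        if species is None:
            diag.above_species += 1
            continue
        counts[species] += 1
        diag.species_reads += 1
    return counts, diag


def species_count_table(
    sample_counts: Mapping[str, Counter]
) -> pd.DataFrame:
    """Stack per-sample rollup counters into a species x sample DataFrame."""
    df = pd.DataFrame(sample_counts).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = "taxid"
    return df


def diagnostics_table(diags: Mapping[str, RollupDiagnostics]) -> pd.DataFrame:
    df = pd.DataFrame({s: d.as_row() for s, d in diags.items()}).T
    df.index.name = "sample"
    return df


def percent_abundance(raw: pd.DataFrame) -> pd.DataFrame:
    """100 * count / per-sample species-mapped total; zero-total samples
    produce all-zero columns with a warning."""
    totals = raw.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with no species-level reads: {list(totals.index[zero])}",
            stacklevel=2,
        )
    safe_totals = totals.mask(zero, 1)
    return 100.0 * raw.div(safe_totals, axis=1)


def filter_low_abundance(
    percent: pd.DataFrame, threshold: float = DEFAULT_ABUNDANCE_THRESHOLD
) -> pd.Index:
    """Taxids retained: percent >= threshold in at least one sample.

    The percentages themselves are never recomputed after filtering, so
    retained-species columns generally sum to slightly less than 100.
    At threshold 0 every row is retained (0 >= 0), including all-zero rows.
    """
    if threshold < 0:
        raise ValidationError("abundance threshold must be >= 0")
    keep = (percent >= threshold).any(axis=1)
    return percent.index[keep]


def group_mean_abundance(percent: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Arithmetic mean of per-sample percent abundance within each group."""
    out = {}
    for group, samples in sheet.groups.items():
        missing = [s for s in samples if s not in percent.columns]
        if missing:
            raise ValidationError(f"group {group!r}: samples absent from table: {missing}")
        if not samples:
            raise ValidationError(f"group {group!r} has no samples")
        out[group] = percent[samples].mean(axis=1)
    return pd.DataFrame(out)


def attach_lineage(taxids: Iterable[int], tree: TaxonomyTree) -> dict[int, str]:
    """Semicolon-joined scientific names from below the root down to each
    taxid; unresolvable taxids map to ``"unknown"`` with a warning."""
    out: dict[int, str] = {}
    unknown = []
    for taxid in taxids:
        if taxid not in tree:
            out[taxid] = "unknown"
            unknown.append(taxid)
            continue
        out[taxid] = ";".join(tree.lineage(taxid))
    if unknown:
        warnings.warn(f"unresolvable taxids in lineage lookup: {unknown}", stacklevel=2)
    return out
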