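"""End-to-end orchestration: taxonomy -> function -> differential stats ->
correlation, driven by a single config and sample sheet.

Every stage writes deterministic TSVs; ``run_all`` finishes by writing a
manifest of all produced files with sha256 checksums, so two runs on the
same inputs are byte-identically comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import correlate as corr_mod
from . import diff_stats, function_profile, godb, io_formats, taxonomy_profile
from .types import SampleSheet, TaxafuncError, ValidationError

log = logging.getLogger("taxafunc")


@dataclass
class RunConfig:
    """User-adjustable knobs for a full run."""

    out_dir: str
    nodes_path: str
    names_path: str
    obo_path: str
    store_path: str | None = None
    host_counts_path: str | None = None
    gmt_path: str | None = None
    abundance_threshold: float = 0.001  # percent, profiling-stage filter
    correlation_min_percent: float = 0.01  # percent, correlation-stage filter
    fdr: float = 0.05
    filter_min_count: float = 1
    top_n_genes: int = 100
    seed: int = 0
    dispersion: float | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        for name in ("abundance_threshold", "correlation_min_percent", "fdr",
                     "filter_min_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    manifest_path: Path | None = None
    diagnostics: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_inputs(config: RunConfig, sheet: SampleSheet) -> None:
    paths = [config.nodes_path, config.names_path, config.obo_path]
    for opt in (config.store_path, config.host_counts_path, config.gmt_path):
        if opt:
            paths.append(opt)
    paths += [info.path for info in sheet.samples.values() if info.path]
    for p in paths:
        if p and not Path(p).exists():
            raise TaxafuncError(f"missing input file: {p}")


def run_all(config: RunConfig, sheet: SampleSheet) -> RunResult:
    """Run every applicable stage and write the output directory.

    Single-group runs skip the comparison stages (differential abundance,
    host differential expression, GSEA, correlation) with an explicit log
    line. Returns the table paths and the manifest location.
    """
    _check_inputs(config, sheet)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = RunResult(out_dir=out_dir)
    groups = sheet.groups
    comparative = len(groups) >= 2

    tree = io_formats.read_taxdump(config.nodes_path, config.names_path)
    dag = io_formats.read_obo(config.obo_path)
    store = godb.load_store(config.store_path) if config.store_path else None

    # ---- taxonomy stage -------------------------------------------------
    sample_counts, diags, sample_reads = {}, {}, {}
    for sid in sheet:
        path = sheet[sid].path
        if path is None:
            raise TaxafuncError(f"sample {sid} has no classification file")
        reads = list(io_formats.read_kaiju(path))
        sample_reads[sid] = reads
        counts, diag = taxonomy_profile.rollup_species(reads, tree)
        sample_counts[sid] = counts
        diags[sid] = diag

    raw = taxonomy_profile.species_count_table(sample_counts)
    percent = taxonomy_profile.percent_abundance(raw)
    retained = taxonomy_profile.filter_low_abundance(
        percent, config.abundance_threshold
    )
    removed = raw.index.difference(retained)
    lineages = taxonomy_profile.attach_lineage(raw.index, tree)

    def decorate(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out.insert(0, "name", [tree.name(t) if t in tree else "unknown" for t in df.index])
        out.insert(1, "lineage", [lineages[t] for t in df.index])
        return out

    tables: dict[str, pd.DataFrame] = {
        "species.raw": decorate(raw.loc[retained]),
        "species.percent": decorate(percent.loc[retained]),
        "species.removed": decorate(raw.loc[removed]),
        "diagnostics": taxonomy_profile.diagnostics_table(diags),
    }
    group_percent = None
    if comparative:
        group_percent = taxonomy_profile.group_mean_abundance(percent, sheet)
        tables["species.group"] = decorate(group_percent.loc[retained])

    # ---- function stage -------------------------------------------------
    if store is not None:
        prot_diag = function_profile.ProteinDiagnostics()
        prot_counts = {
            sid: function_profile.proportional_protein_counts(
                sample_reads[sid], tree, prot_diag
            )
            for sid in sheet
        }
        proteins = function_profile.protein_count_table(prot_counts)
        proteins = proteins.loc[
            proteins.index.get_level_values("taxid").isin(retained)
        ]
        species_totals = raw.sum(axis=0)
        protein_pct = function_profile.scale_protein_counts(proteins, species_totals)
        tables["protein.proportional"] = proteins
        tables["protein.percent"] = protein_pct

        go_sample = function_profile.aggregate_go_counts(
            proteins, store, dag, prot_diag
        )
        tables["go.sample.percent"] = function_profile.namespace_percentages(go_sample)
        if comparative:
            group_proteins = function_profile.group_mean_proteins(proteins, sheet)
            go_group = function_profile.aggregate_go_counts(group_proteins, store, dag)
            tables["go.group.percent"] = function_profile.namespace_percentages(go_group)
            ref_percent = group_percent if group_percent is not None else percent
            go2taxa, taxa2go = function_profile.build_cross_tables(
                proteins, store, dag, ref_percent.loc[retained], retained
            )
            tables["go_to_taxa"] = go2taxa
            tables["taxa_to_go"] = taxa2go
        result.diagnostics["protein"] = {
            "reads_without_accession": prot_diag.reads_without_accession,
            "unannotated_accessions": sorted(prot_diag.unannotated_accessions),
            "obsolete_go_ids": dict(prot_diag.obsolete_go_ids),
            "unresolved_go_ids": dict(prot_diag.unresolved_go_ids),
        }
    else:
        log.info("no GO store configured; skipping functional stage")

    # ---- comparative stages --------------------------------------------
    da_result = None
    groups_map = {sid: sheet.group_of(sid) for sid in sheet}
    if comparative:
        da_counts = raw.loc[retained]
        kept = diff_stats.filter_features(
            da_counts, groups_map, config.filter_min_count
        )
        if len(groups) == 2:
            da_result = diff_stats.nb_exact_test(
                da_counts.loc[kept], groups_map, dispersion=config.dispersion
            )
            da_table = da_result.table.copy()
            da_table.insert(0, "name", [tree.name(t) for t in da_table.index])
            tables["da.species"] = da_table
        else:
            pairwise = diff_stats.pairwise_exact_tests(
                da_counts.loc[kept], groups_map, dispersion=config.dispersion
            )
            for (g1, g2), res in pairwise.items():
                t = res.table.copy()
                t.insert(0, "name", [tree.name(x) for x in t.index])
                tables[f"da.species.{g1}_vs_{g2}"] = t
    else:
        log.info("single group: skipping differential abundance")

    # ---- host stages ----------------------------------------------------
    deg_result = None
    tpm_table = None
    if config.host_counts_path:
        host = io_formats.read_counts_table(config.host_counts_path)
        tpm_table = diff_stats.tpm(host)
        tables["host.tpm"] = tpm_table
        if comparative and len(groups) == 2:
            host_groups = {
                s: g for s, g in groups_map.items() if s in host.counts.columns
            }
            kept_genes = diff_stats.filter_features(
                host.counts[list(host_groups)], host_groups, config.filter_min_count
            )
            deg_result = diff_stats.nb_exact_test(
                host.counts.loc[kept_genes, list(host_groups)],
                host_groups,
                dispersion=config.dispersion,
            )
            tables["deg"] = deg_result.table
            if config.gmt_path:
                sets = io_formats.read_gmt(config.gmt_path)
                ranked = deg_result.table["log2FC"].sort_values(ascending=False)
                gsea = diff_stats.gsea_preranked(
                    ranked, sets, seed=config.seed
                )
                tables["gsea"] = gsea
        elif not comparative:
            log.info("single group: skipping host differential expression and GSEA")

    # ---- correlation ----------------------------------------------------
    if deg_result is not None and da_result is not None and tpm_table is not None:
        top_genes = corr_mod.select_top_genes(deg_result.table, config.top_n_genes)
        microbes = corr_mod.select_da_microbes(
            da_result.table,
            percent.loc[retained],
            fdr_cutoff=config.fdr,
            min_percent=config.correlation_min_percent,
        )
        shared = [s for s in tpm_table.columns if s in percent.columns]
        if len(microbes) >= 2 and len(top_genes) >= 2 and len(shared) >= 4:
            cm = corr_mod.spearman_matrix(
                tpm_table.loc[top_genes, shared], percent.loc[microbes, shared]
            )
            tables["correlation.rho"] = cm.rho
            tables["correlation.pvalue"] = cm.pvalue
            tables["correlation.pvalue_bh"] = cm.pvalue_bh
            row_order, col_order = corr_mod.cluster_order(cm)
            tables["correlation.row_order"] = pd.DataFrame({"gene": row_order})
            tables["correlation.col_order"] = pd.DataFrame({"taxid": col_order})
        else:
            log.info(
                "correlation skipped: %d DA microbes, %d genes, %d shared samples",
                len(microbes), len(top_genes), len(shared),
            )

    # ---- write ----------------------------------------------------------
    written = io_formats.write_tables(tables, out_dir, overwrite=config.overwrite)
    result.tables = written
    result.diagnostics["rollup"] = {s: d.as_row() for s, d in diags.items()}
    diag_path = out_dir / "diagnostics.json"
    with open(diag_path, "w") as fh:
        json.dump(result.diagnostics, fh, indent=1, sort_keys=True, default=str)

    manifest = pd.DataFrame(
        sorted(
            (p.name, _sha256(p)) for p in list(written.values()) + [diag_path]
        ),
        columns=["file", "sha256"],
    )
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, lineterminator="\n")
    result.manifest_path = manifest_path
    return result
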