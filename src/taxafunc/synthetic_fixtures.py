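"""Deterministic synthetic inputs with planted signal.

Generates every file dialect the pipeline consumes — taxonomy dump, GO
OBO, accession->GO source tables, GMT gene sets, per-sample classifier
TSVs and a host count table — from a small fixture specification, so the
full pipeline is testable offline. Microbial reads are drawn multinomially
from per-sample species proportions (group proportions differ by the
planted fold changes, with mild lognormal between-sample wobble); host
counts are negative-binomial with planted differentially expressed genes.
All randomness is keyed by (seed, sample) so adding samples never
reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ClassifiedRead, SampleInfo, SampleSheet, ValidationError

BP_ROOT, MF_ROOT, CC_ROOT = "GO:0008150", "GO:0003674", "GO:0005575"

#: GO term carried only by proteins of the up-planted species (taxid 121)
EXCLUSIVE_GO = "GO:1100004"
#: alternate id of EXCLUSIVE_GO, used by one annotation row
EXCLUSIVE_GO_ALT = "GO:1100099"

PLANTED_UP_SPECIES = 121
PLANTED_DOWN_SPECIES = 111


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic dataset.

    Defaults: two groups of five samples, 20,000 reads per sample, one
    species planted 8-fold up and one 8-fold down in the case group, 20%
    of species reads assigned at strain level, 20% of reads with two tied
    best accessions, and host counts with dispersion 0.1 and 4-fold
    planted DEGs.
    """

    seed: int = 0
    groups: tuple[str, str] = ("case", "control")
    n_per_group: int = 5
    n_reads: int = 20_000
    unclassified_frac: float = 0.05
    genus_frac: float = 0.02
    strain_frac: float = 0.2
    tie_frac: float = 0.2
    #: species taxid -> fold change in the first (case) group
    planted_species: dict[int, float] = field(
        default_factory=lambda: {PLANTED_UP_SPECIES: 8.0, PLANTED_DOWN_SPECIES: 0.125}
    )
    #: lognormal sigma of per-sample species-proportion wobble
    proportion_sigma: float = 0.3
    # host side
    n_genes: int = 300
    n_deg_up: int = 10
    n_deg_down: int = 10
    deg_fold: float = 4.0
    host_dispersion: float = 0.1
    host_depth_mean: float = 150.0  # mean NB count per gene

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.planted_species.values()):
            raise ValidationError("planted fold changes must be > 0")
        if self.host_dispersion < 0:
            raise ValidationError("host dispersion must be >= 0")
        total = self.unclassified_frac + self.genus_frac
        if not 0 <= total < 1:
            raise ValidationError("unclassified + genus fractions must sum below 1")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}{i + 1}" for g in self.groups for i in range(self.n_per_group)
        ]

    def group_of(self, sample_id: str) -> str:
        for g in self.groups:
            if sample_id.startswith(g):
                return g
        raise KeyError(sample_id)

    def sample_stream(self, sample_id: str, channel: int = 0) -> np.random.Generator:
        """Generator keyed by (seed, channel, sample index): stable per sample."""
        idx = self.sample_ids.index(sample_id)
        return np.random.default_rng([self.seed, channel, idx])


# ---------------------------------------------------------------------------
# reference bundle: taxonomy, GO DAG, store sources, gene sets

#: taxid -> (parent, rank, name); a ~25-node forest with strains below
#: species, a species-less genus leaf, and two superkingdoms
TAXONOMY_ROSTER: dict[int, tuple[int, str, str]] = {
    1: (1, "no rank", "root"),
    2: (1, "superkingdom", "Bacteria"),
    2759: (1, "superkingdom", "Eukaryota"),
    10: (2, "phylum", "Firmibacterota"),
    11: (2, "phylum", "Bacteroidata"),
    4890: (2759, "phylum", "Ascomycora"),
    100: (10, "genus", "Toyococcus"),
    110: (10, "genus", "Rodentella"),
    120: (11, "genus", "Flavivirga"),
    600: (11, "genus", "Barrenia"),  # species-less genus leaf
    500: (4890, "genus", "Mycotorula"),
    101: (100, "species", "Toyococcus albus"),
    102: (100, "species", "Toyococcus ruber"),
    111: (110, "species", "Rodentella prima"),
    112: (110, "species", "Rodentella secunda"),
    121: (120, "species", "Flavivirga lutea"),
    122: (120, "species", "Flavivirga cyanea"),
    501: (500, "species", "Mycotorula alba"),
    502: (500, "species", "Mycotorula nigra"),
    1011: (101, "strain", "Toyococcus albus str. A1"),
    1012: (101, "no rank", "Toyococcus albus str. A2"),
    1211: (121, "subspecies", "Flavivirga lutea subsp. brevis"),
    5011: (501, "strain", "Mycotorula alba CBS-1"),
}

SPECIES_TAXIDS = [101, 102, 111, 112, 121, 122, 501, 502]

#: baseline species proportions (control group); planted species start low
BASE_PROPORTIONS: dict[int, float] = {
    101: 0.22,
    102: 0.18,
    111: 0.12,
    112: 0.10,
    121: 0.01,
    122: 0.14,
    501: 0.13,
    502: 0.10,
}

#: species -> strain/below-species nodes reads may be assigned to
STRAINS_OF: dict[int, list[int]] = {101: [1011, 1012], 121: [1211], 501: [5011]}

#: genus-level nodes some reads are (unusably) assigned to
GENUS_NODES = [100, 600]

#: GO DAG: id -> (name, namespace, is_a parents, part_of parents)
GO_ROSTER: dict[str, tuple[str, str, list[str], list[str]]] = {
    BP_ROOT: ("biological_process", "biological_process", [], []),
    "GO:1100001": ("metabolic process", "biological_process", [BP_ROOT], []),
    "GO:1100002": ("biosynthetic process", "biological_process", ["GO:1100001"], []),
    # diamond: two paths from polyamine biosynthesis up to metabolic process
    "GO:1100003": (
        "polyamine biosynthetic process",
        "biological_process",
        ["GO:1100002"],
        ["GO:1100001"],
    ),
    EXCLUSIVE_GO: (
        "spermidine biosynthetic process",
        "biological_process",
        ["GO:1100003"],
        [],
    ),
    "GO:1100005": (
        "putrescine biosynthetic process",
        "biological_process",
        ["GO:1100003"],
        [],
    ),
    "GO:1100006": ("transport", "biological_process", [BP_ROOT], []),
    "GO:1100007": ("amino acid metabolic process", "biological_process", ["GO:1100001"], []),
    "GO:1100008": ("response to stress", "biological_process", [BP_ROOT], []),
    "GO:1100010": ("nucleotide metabolic process", "biological_process", ["GO:1100001"], []),
    "GO:1100011": ("cell wall organization", "biological_process", [BP_ROOT], []),
    MF_ROOT: ("molecular_function", "molecular_function", [], []),
    "GO:1200001": ("catalytic activity", "molecular_function", [MF_ROOT], []),
    "GO:1200002": ("transferase activity", "molecular_function", ["GO:1200001"], []),
    "GO:1200003": ("hydrolase activity", "molecular_function", ["GO:1200001"], []),
    "GO:1200004": ("transporter activity", "molecular_function", [MF_ROOT], []),
    CC_ROOT: ("cellular_component", "cellular_component", [], []),
    "GO:1300001": ("membrane", "cellular_component", [CC_ROOT], []),
    "GO:1300002": ("cytoplasm", "cellular_component", [CC_ROOT], []),
    "GO:1300003": ("ribosome", "cellular_component", [CC_ROOT], ["GO:1300002"]),
}

#: obsolete decoy term, retained-but-flagged by the OBO reader
OBSOLETE_GO = "GO:1100009"


def accessions_of(taxid: int) -> list[str]:
    return [f"ACC{taxid}_{i}.1" for i in (1, 2, 3)]


#: direct GO annotations reachable for each representative accession.
#: EXCLUSIVE_GO appears only under species 121; ACC502_3.1 is deliberately
#: unannotated; ACC121_2.1's annotation is reachable only through a
#: non-first member accession and one row uses the alternate id.
PROTEIN_GO: dict[str, list[str]] = {
    "ACC101_1.1": ["GO:1100005", "GO:1200002"],
    "ACC101_2.1": ["GO:1100007"],
    "ACC101_3.1": ["GO:1300001"],
    "ACC102_1.1": ["GO:1100010"],
    "ACC102_2.1": ["GO:1200003"],
    "ACC102_3.1": ["GO:1100006", "GO:1200004"],
    "ACC111_1.1": ["GO:1100007", "GO:1200001"],
    "ACC111_2.1": ["GO:1300002"],
    "ACC111_3.1": ["GO:1100008"],
    "ACC112_1.1": ["GO:1100001"],
    "ACC112_2.1": ["GO:1200002"],
    "ACC112_3.1": ["GO:1300003"],
    "ACC121_1.1": [EXCLUSIVE_GO, "GO:1200002"],
    "ACC121_2.1": [EXCLUSIVE_GO_ALT, "GO:1100005"],
    "ACC121_3.1": ["GO:1300001"],
    "ACC122_1.1": ["GO:1100005"],
    "ACC122_2.1": ["GO:1200003"],
    "ACC122_3.1": ["GO:1100011"],
    "ACC501_1.1": ["GO:1100002"],
    "ACC501_2.1": ["GO:1200001"],
    "ACC501_3.1": ["GO:1300002"],
    "ACC502_1.1": ["GO:1100008"],
    "ACC502_2.1": ["GO:1200004"],
    # ACC502_3.1 unannotated on purpose
}


@dataclass
class ReferenceBundle:
    """In-memory reference data plus the paths it was written to (if any)."""

    nodes_rows: list[tuple[int, int, str]]
    names_rows: list[tuple[int, str]]
    obo_text: str
    membership_rows: list[tuple[str, str]]
    idmapping_rows: list[tuple[str, str]]
    gaf_rows: list[tuple[str, str, str, str]]
    gmt_rows: list[tuple[str, str, list[str]]]
    paths: dict[str, Path] = field(default_factory=dict)


def _obo_text() -> str:
    chunks = ["format-version: 1.2", "ontology: go", ""]
    for go_id, (name, namespace, is_a, part_of) in GO_ROSTER.items():
        chunks.append("[Term]")
        chunks.append(f"id: {go_id}")
        chunks.append(f"name: {name}")
        chunks.append(f"namespace: {namespace}")
        if go_id == EXCLUSIVE_GO:
            chunks.append(f"alt_id: {EXCLUSIVE_GO_ALT}")
        for parent in is_a:
            chunks.append(f"is_a: {parent}")
        for parent in part_of:
            chunks.append(f"relationship: part_of {parent}")
        chunks.append("")
    chunks += [
        "[Term]",
        f"id: {OBSOLETE_GO}",
        "name: outdated polyamine term",
        "namespace: biological_process",
        "is_obsolete: true",
        "",
    ]
    return "\n".join(chunks)


def _host_gene_ids(spec: FixtureSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]


def planted_deg_ids(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    genes = _host_gene_ids(spec)
    return genes[: spec.n_deg_up], genes[spec.n_deg_up : spec.n_deg_up + spec.n_deg_down]


def gen_reference_bundle(spec: FixtureSpec) -> ReferenceBundle:
    """Taxonomy dump rows, OBO text, store source tables and gene sets.

    The store sources exercise the representative-accession union rule:
    every representative has a member accession ``MEM*`` carrying part of
    its annotation, and ``ACC121_2.1`` is annotated *only* through its
    member (plus one row using an alternate GO id).
    """
    for taxid, (parent, rank, _name) in TAXONOMY_ROSTER.items():
        if rank == "strain" and TAXONOMY_ROSTER[parent][1] != "species":
            raise ValidationError(f"strain {taxid} without species parent")
    nodes_rows = [
        (taxid, parent, rank) for taxid, (parent, rank, _n) in TAXONOMY_ROSTER.items()
    ]
    names_rows = [(taxid, name) for taxid, (_p, _r, name) in TAXONOMY_ROSTER.items()]

    membership_rows: list[tuple[str, str]] = []
    idmapping_rows: list[tuple[str, str]] = []
    gaf_rows: list[tuple[str, str, str, str]] = []
    for acc, gos in PROTEIN_GO.items():
        member = "MEM" + acc[3:]
        membership_rows.append((acc, acc))
        membership_rows.append((acc, member))
        uniprot_rep = "UPR" + acc[3:].replace(".", "_")
        uniprot_mem = "UPM" + acc[3:].replace(".", "_")
        # ACC121_2.1: representative itself maps to nothing; annotation
        # reachable only via the member accession
        if acc != "ACC121_2.1":
            idmapping_rows.append((acc, uniprot_rep))
            gaf_rows.append((uniprot_rep, "enables", gos[0], "IEA"))
        idmapping_rows.append((member, uniprot_mem))
        for go in gos:
            gaf_rows.append((uniprot_mem, "enables", go, "IDA"))
    # decoy rows the build must reject / exclude
    gaf_rows.append(("UPR101_1_1", "NOT|enables", "GO:1100008", "IDA"))
    gaf_rows.append(("UPR101_1_1", "enables", "GO:bad", "IDA"))
    # unannotated representative entirely absent from idmapping
    membership_rows.append(("ACC502_3.1", "ACC502_3.1"))

    up, down = planted_deg_ids(spec)
    genes = _host_gene_ids(spec)
    rng = np.random.default_rng([spec.seed, 3])
    null_genes = sorted(
        rng.choice(
            [g for g in genes if g not in up + down], size=15, replace=False
        ).tolist()
    )
    gmt_rows = [
        ("PLANTED_UP", "genes planted up in the case group", list(up)),
        ("PLANTED_DOWN", "genes planted down in the case group", list(down)),
        ("NULL_SET", "random unplanted genes", null_genes),
    ]
    return ReferenceBundle(
        nodes_rows=nodes_rows,
        names_rows=names_rows,
        obo_text=_obo_text(),
        membership_rows=membership_rows,
        idmapping_rows=idmapping_rows,
        gaf_rows=gaf_rows,
        gmt_rows=gmt_rows,
    )


def write_reference_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.dmp",
        "names": out / "names.dmp",
        "obo": out / "go-basic.obo",
        "membership": out / "membership.tsv",
        "idmapping": out / "idmapping.tsv",
        "gaf": out / "annotations.gaf",
        "gmt": out / "genesets.gmt",
    }
    with open(paths["nodes"], "w") as fh:
        for taxid, parent, rank in bundle.nodes_rows:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(paths["names"], "w") as fh:
        for taxid, name in bundle.names_rows:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    paths["obo"].write_text(bundle.obo_text)
    with open(paths["membership"], "w") as fh:
        for rep, member in bundle.membership_rows:
            fh.write(f"{rep}\t{member}\n")
    with open(paths["idmapping"], "w") as fh:
        for acc, uni in bundle.idmapping_rows:
            fh.write(f"{acc}\t{uni}\n")
    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for uni, qualifier, go, evidence in bundle.gaf_rows:
            fields = ["UniProtKB", uni, uni, qualifier, go, "REF:0001", evidence,
                      "", "P", "", "", "protein", "taxon:0", "20230101", "GOA"]
            fh.write("\t".join(fields) + "\n")
    with open(paths["gmt"], "w") as fh:
        for name, desc, genes in bundle.gmt_rows:
            fh.write("\t".join([name, desc] + genes) + "\n")
    bundle.paths = paths
    return paths


# ---------------------------------------------------------------------------
# classifier samples


def sample_proportions(spec: FixtureSpec, group: str, rng: np.random.Generator) -> np.ndarray:
    """Per-sample species proportions: baseline, planted folds in the case
    group, mild lognormal wobble, renormalized."""
    props = np.array([BASE_PROPORTIONS[t] for t in SPECIES_TAXIDS], dtype=float)
    if group == spec.groups[0]:
        for taxid, fold in spec.planted_species.items():
            props[SPECIES_TAXIDS.index(taxid)] *= fold
    if spec.proportion_sigma > 0:
        props = props * rng.lognormal(0.0, spec.proportion_sigma, size=props.size)
    total = props.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("species proportions do not sum to a positive total")
    return props / total


def gen_kaiju_sample(spec: FixtureSpec, sample_id: str) -> list[ClassifiedRead]:
    """Reads of one sample as :class:`ClassifiedRead` records."""
    rng = spec.sample_stream(sample_id, channel=1)
    group = spec.group_of(sample_id)
    props = sample_proportions(spec, group, rng)
    cat_probs = np.concatenate(
        [
            [spec.unclassified_frac, spec.genus_frac],
            (1.0 - spec.unclassified_frac - spec.genus_frac) * props,
        ]
    )
    counts = rng.multinomial(spec.n_reads, cat_probs)
    reads: list[ClassifiedRead] = []
    r = 0
    for _ in range(counts[0]):
        reads.append(ClassifiedRead("U", f"{sample_id}_r{r}", 0))
        r += 1
    for _ in range(counts[1]):
        taxid = int(rng.choice(GENUS_NODES))
        reads.append(
            ClassifiedRead("C", f"{sample_id}_r{r}", taxid, score=90,
                           best_match_taxids=[taxid])
        )
        r += 1
    for i, species in enumerate(SPECIES_TAXIDS):
        accs = accessions_of(species)
        strains = STRAINS_OF.get(species, [])
        for _ in range(counts[2 + i]):
            taxid = species
            if strains and rng.random() < spec.strain_frac:
                taxid = int(rng.choice(strains))
            if rng.random() < spec.tie_frac:
                pair = rng.choice(len(accs), size=2, replace=False)
                accessions = [accs[pair[0]], accs[pair[1]]]
            else:
                accessions = [accs[int(rng.integers(len(accs)))]]
            reads.append(
                ClassifiedRead(
                    "C", f"{sample_id}_r{r}", taxid, score=120,
                    best_match_taxids=[taxid], accessions=accessions,
                )
            )
            r += 1
    # deterministic shuffle so files are not grouped by species
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_kaiju_sample(reads: list[ClassifiedRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for read in reads:
            if read.status == "U":
                fh.write(f"U\t{read.read_id}\t0\n")
            else:
                fh.write(
                    "\t".join(
                        [
                            "C",
                            read.read_id,
                            str(read.taxid),
                            str(read.score or ""),
                            ",".join(str(t) for t in read.best_match_taxids),
                            ",".join(read.accessions),
                        ]
                    )
                    + "\n"
                )
    return path


def gen_kaiju_samples(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> dict[str, list[ClassifiedRead]] | dict[str, Path]:
    """All samples; returns read lists, or written paths when ``out_dir``
    is given."""
    reads = {sid: gen_kaiju_sample(spec, sid) for sid in spec.sample_ids}
    if out_dir is None:
        return reads
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        sid: write_kaiju_sample(rlist, out / f"{sid}.kaiju.tsv")
        for sid, rlist in reads.items()
    }


# ---------------------------------------------------------------------------
# host counts


def gen_host_counts(spec: FixtureSpec) -> pd.DataFrame:
    """featureCounts-style host table (Geneid..Length + one column per
    sample) with NB counts and planted DEGs in the case group."""
    genes = _host_gene_ids(spec)
    rng0 = np.random.default_rng([spec.seed, 2])
    base_mu = rng0.lognormal(np.log(spec.host_depth_mean), 1.0, size=len(genes))
    lengths = rng0.integers(200, 5000, size=len(genes))
    up, down = planted_deg_ids(spec)
    fold = np.ones(len(genes))
    fold[[genes.index(g) for g in up]] = spec.deg_fold
    fold[[genes.index(g) for g in down]] = 1.0 / spec.deg_fold

    table = pd.DataFrame(
        {
            "Geneid": genes,
            "Chr": "chr1",
            "Start": 1,
            "End": lengths,
            "Strand": "+",
            "Length": lengths,
        }
    )
    phi = spec.host_dispersion
    for sid in spec.sample_ids:
        rng = spec.sample_stream(sid, channel=2)
        mu = base_mu * (fold if spec.group_of(sid) == spec.groups[0] else 1.0)
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        table[sid] = rng.poisson(lam)
    return table


def write_host_counts(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Program:featureCounts (synthetic)\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def fixture_sample_sheet(spec: FixtureSpec, kaiju_dir: str | Path | None = None) -> SampleSheet:
    samples = {}
    for sid in spec.sample_ids:
        path = str(Path(kaiju_dir) / f"{sid}.kaiju.tsv") if kaiju_dir else None
        samples[sid] = SampleInfo(group=spec.group_of(sid), path=path, host_column=sid)
    return SampleSheet(samples)


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory consumable by the CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = gen_reference_bundle(spec)
    paths = write_reference_bundle(bundle, out)
    kaiju_dir = out / "kaiju"
    sample_paths = gen_kaiju_samples(spec, kaiju_dir)
    paths.update({f"kaiju:{sid}": p for sid, p in sample_paths.items()})
    paths["host_counts"] = write_host_counts(gen_host_counts(spec), out / "host_counts.tsv")
    sheet_path = out / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample\tgroup\tpath\thost_column\n")
        for sid in spec.sample_ids:
            # paths relative to the sheet keep the directory relocatable
            fh.write(
                f"{sid}\t{spec.group_of(sid)}\tkaiju/{sid}.kaiju.tsv\t{sid}\n"
            )
    paths["sample_sheet"] = sheet_path
    return paths
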