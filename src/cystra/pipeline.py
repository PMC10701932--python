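"""End-to-end orchestration of the synthetic-study pipeline.

One validated configuration document drives every stage:

    simulate panel -> detect clusters -> decompose -> group + events
    -> variant analysis -> simulate reads -> expression -> report

All stage outputs are written under a run directory together with a
manifest (seed, parameters, package version, output checksums); the same
seed reproduces the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cystra
from cystra.align import ScoringScheme
from cystra.cluster import find_clusters
from cystra.expression import (
    SequenceSetMatcher,
    assign_reads,
    collapse_unique,
    compare_libraries,
    contamination_filter,
    length_filter,
    tmm_factors,
)
from cystra.io import gene_sequence, write_bed, write_fasta, write_gff3_trnas
from cystra.repeats import build_unit_panel, decompose_cluster
from cystra.scans import in_silico_pcr, scan_helitron_signals
from cystra.simulate import (
    CHR5_FWD_PRIMER,
    CHR5_REV_PRIMER,
    ClusterSpec,
    ReadSimSpec,
    make_cluster_panel,
    make_reference_loci,
    make_trna_template,
    simulate_reads,
)
from cystra.variants import dedupe_mature, greedy_cluster, stem_mispair_check

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters as one validated document."""

    seed: int = 0
    # cluster detection
    max_gap: int = 1000
    min_genes: int = 2
    # alignment scoring
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    # unit grouping
    group_cut: float = 0.03
    # variant clustering
    variant_threshold: float = 0.97
    # expression
    read_depth: int = 6000
    error_rate: float = 0.01
    contaminant_fraction: float = 0.1
    precursor_fraction: float = 0.1
    charged_factor: float = 2.0
    leader: int = 30
    min_read_len: int = 55
    max_read_len: int = 110
    logratio_trim: float = 0.30
    sum_trim: float = 0.05
    min_assign_score: float = 60.0
    low_quantile: float = 0.10

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if not 0 < self.variant_threshold <= 1:
            raise ValueError("variant_threshold must be in (0, 1]")
        if not 0 < self.group_cut < 1:
            raise ValueError("group_cut must be in (0, 1)")
        if self.read_depth < 1:
            raise ValueError("read_depth must be positive")

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on the bundled synthetic study; return the report.

    Outputs (FASTA/GFF3/BED/TSV/JSON) and a manifest are written under
    ``outdir``.  Raises on any stage error.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scoring = config.scoring
    report: dict = {"seed": config.seed}

    # -- stage 1: synthetic panel -------------------------------------------
    panel = make_cluster_panel(ClusterSpec(seed=config.seed))
    records = [pa.record for _, pa in sorted(panel.items())]
    write_fasta(records, out / "genomes.fasta")
    all_ann = [a for _, pa in sorted(panel.items()) for a in pa.annotations]
    write_gff3_trnas(all_ann, out / "annotations.gff3")

    # -- stage 2: cluster detection -----------------------------------------
    clusters = find_clusters(all_ann, max_gap=config.max_gap, min_genes=config.min_genes)
    write_bed([g for c in clusters for g in c.genes], out / "cluster_genes.bed")
    report["clusters"] = {
        c.seqid: {
            "n_genes": len(c.genes),
            "orientation": c.orientation,
            "spacers": c.spacers,
            "flanking_pseudogenes": [p.gene_id for p in c.flanking_pseudogenes],
        }
        for c in clusters
    }

    # -- stage 3: decomposition ---------------------------------------------
    units = {}
    for acc, pa in sorted(panel.items()):
        genes = [a for a in pa.annotations if a.category == "gene"]
        units[acc] = decompose_cluster(pa.record, genes, cluster_id="chr5-like")
    report["unit_counts"] = {acc: len(us) for acc, us in units.items()}

    # -- stage 4: grouping + structural events ------------------------------
    regions = {acc: pa.record for acc, pa in panel.items()}
    unit_panel = build_unit_panel(regions, units, cut=config.group_cut, scoring=scoring)
    (out / "unit_groups.tsv").write_text(
        "unit\tgroup\n"
        + "".join(f"{k}\t{v}\n" for k, v in sorted(unit_panel.correspondence.items()))
    )
    if unit_panel.tree is not None:
        (out / "units.nwk").write_text(unit_panel.tree.newick() + "\n")
    report["n_unit_groups"] = len(set(unit_panel.correspondence.values()))
    report["structural_events"] = [
        {"accession": e.accession, "kind": e.kind, "affected_units": e.affected_units,
         "size": e.size}
        for e in unit_panel.events
    ]

    # -- stage 5: variant analysis ------------------------------------------
    gene_seqs = [
        (u.gene.gene_id, gene_sequence(panel[acc].record, u.gene))
        for acc in sorted(units)
        for u in units[acc]
    ]
    variants_list = dedupe_mature(gene_seqs)
    groups = greedy_cluster(
        [(members[0], seq) for seq, members in variants_list],
        threshold=config.variant_threshold,
        scoring=scoring,
    )
    template, pairing = make_trna_template(config.seed)
    mispairs = {
        members[0]: stem_mispair_check(seq, template, pairing, scoring)
        for seq, members in variants_list
    }
    report["n_mature_variants"] = len(variants_list)
    report["n_variant_groups"] = len(groups)
    report["n_deviant_variants"] = sum(1 for m in mispairs.values() if not m["canonical"])

    # -- stage 6: expression ------------------------------------------------
    loci = make_reference_loci(seed=config.seed, leader=config.leader)
    sim_spec = ReadSimSpec(
        precursor_fraction=config.precursor_fraction,
        error_rate=config.error_rate,
        charged_factor=config.charged_factor,
        contaminant_fraction=config.contaminant_fraction,
        depth=config.read_depth,
        seed=config.seed,
    )
    libraries, truth = simulate_reads(loci, sim_spec)
    table = collapse_unique(libraries)
    factors = tmm_factors(table, config.logratio_trim, config.sum_trim)
    lib_sizes = table.sum(axis=0).to_dict()
    filtered = length_filter(table, config.min_read_len, config.max_read_len)
    matcher = SequenceSetMatcher([l.precursor_ref for l in loci] + [l.mature_ref for l in loci])
    kept, removed = contamination_filter(filtered, matcher)
    expr = assign_reads(kept, loci, scoring=scoring, min_score=config.min_assign_score)
    expr.normalize(factors, lib_sizes)
    flags = compare_libraries(expr, low_quantile=config.low_quantile)
    flags.to_csv(out / "expression_flags.tsv", sep="\t")
    expr.variants.to_csv(out / "variant_counts.tsv", sep="\t")
    expr.genes.to_csv(out / "gene_counts.tsv", sep="\t")
    report["tmm_factors"] = {k: round(v, 6) for k, v in factors.factors.items()}
    report["n_reads_removed_as_contaminant"] = len(removed)
    report["undetected_variants"] = sorted(flags.index[flags["undetected"]])
    report["read_accounting"] = expr.accounting
    # exact conservation: assigned + variant-only + multimapped + unassigned
    # equals the reads that reached assignment, and filtering accounts for the rest
    report["accounting_balanced"] = all(
        acct["gene_assigned"] + acct["variant_only"] + acct["multimapped"] + acct["unassigned"]
        == int(kept[lib].sum())
        for lib, acct in expr.accounting.items()
    ) and all(
        int(table[lib].sum()) == int(kept[lib].sum()) + _filtered_out(table, kept, lib)
        for lib in table.columns
    )

    # -- stage 7: auxiliary scans -------------------------------------------
    pcr = in_silico_pcr(records, CHR5_FWD_PRIMER, CHR5_REV_PRIMER, max_product=5000)
    report["pcr_product_sizes"] = {p.seqid: p.size for p in pcr}
    motif_ok = {}
    for acc, pa in sorted(panel.items()):
        per_unit = []
        for u in units[acc]:
            hits = scan_helitron_signals(u.seq)
            per_unit.append(sum(1 for h in hits if h.motif == "CTAG[TC]" and h.strand == "+"))
        motif_ok[acc] = per_unit
    report["ctag_motifs_per_unit"] = motif_ok

    # -- manifest ------------------------------------------------------------
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {
        "package_version": cystra.__version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "stage_order": [
            "simulate_panel", "find_clusters", "decompose", "group_units+events",
            "variants", "collapse->tmm->length->contamination->assign->compare",
            "scans",
        ],
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


def _filtered_out(table: pd.DataFrame, kept: pd.DataFrame, lib: str) -> int:
    return int(table[lib].sum()) - int(kept[lib].sum())
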