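"""End-to-end orchestration of the screening workflow.

``run_selection_scan`` drives the coding arm: optional catalog filtering,
the per-gene two-step branch-site test, BH-FDR across genes, the
cross-alignment-method consensus, and BEB site calls on the significant
genes.  ``run_region_annotation`` drives the noncoding arm: coding/
noncoding classification of accelerated regions and their gene assignment
by body, regulatory domain, and TAD.  Both emit TSV tables plus a JSON
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import read_codon_alignment
from .catalog import Disposition, GeneList, OrthologTable, filter_orthology
from .intervals import read_bed, read_gene_annotation
from .regions import (AcceleratedRegion, AssignmentMode, Lineage, TadSet,
                      assign_gene_body, assign_regulatory_domain, assign_tad,
                      build_regulatory_domains, classify_coding, summarize)
from .selection import bh_fdr, consensus, run_gene_test
from .beb import beb_posteriors
from .tree import read_tree

ALIGNMENT_SUFFIXES = (".fasta", ".fa", ".fna", ".phy", ".phylip")


@dataclass
class RunConfig:
    """Configuration of a screening run; see the CLI docs for file syntax."""

    out_dir: str = "hlscan_out"
    seed: int = 1
    # coding arm
    alignment_dir: str | None = None
    tree_file: str | None = None
    foreground_token: str = "#1"
    alpha: float = 0.05
    use_fdr: bool = True
    beb_threshold: float = 0.95
    beb_grid_points: int = 10
    n_starts: int = 3
    reference_taxon: str | None = None
    gene_list: str | None = None
    ortholog_table: str | None = None
    no_reference_list: str | None = None
    max_missing: int = 1
    # noncoding arm
    regions_bed: str | None = None
    tads_bed: str | None = None
    genes_tsv: str | None = None
    exons_bed: str | None = None
    lineage: str = "MAMMAL_TSAR"
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("alpha", "beb_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(path)
        kwargs: dict = {}
        fields = cls.__dataclass_fields__
        for section in cp.sections():
            for key, val in cp[section].items():
                if key not in fields:
                    raise KeyError(f"unknown config key '{key}'")
                typ = fields[key].type
                if typ in ("int", "int | None"):
                    kwargs[key] = int(val)
                elif typ == "float":
                    kwargs[key] = float(val)
                elif typ == "bool":
                    kwargs[key] = cp[section].getboolean(key)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    payload = {"hlscan_version": __version__, "config": asdict(config)}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()
    ).hexdigest()
    payload.update(extra)
    (out / "manifest.json").write_text(json.dumps(payload, indent=2,
                                                  sort_keys=True) + "\n")


def _discover_alignments(root: Path) -> dict[str, dict[str, Path]]:
    """method -> gene_id -> alignment path; flat directories are one
    'default' method, subdirectories are alignment methods."""
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if subdirs:
        return {
            d.name: {f.stem: f for f in sorted(d.iterdir())
                     if f.suffix.lower() in ALIGNMENT_SUFFIXES}
            for d in subdirs
        }
    return {"default": {f.stem: f for f in sorted(root.iterdir())
                        if f.suffix.lower() in ALIGNMENT_SUFFIXES}}


def run_selection_scan(config: RunConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the coding-arm screening; returns (gene table, PSS table).

    Per-gene failures are logged into the run ledger rather than aborting
    the scan.
    """
    if not config.alignment_dir or not config.tree_file:
        raise ValueError("selection scan needs alignment_dir and tree_file")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(config.tree_file, config.foreground_token)

    # optional catalog filtering
    excluded: dict[str, str] = {}
    funnel = None
    if config.gene_list and config.ortholog_table:
        genes = GeneList.from_file(config.gene_list)
        noref = (frozenset(GeneList.from_file(config.no_reference_list).genes)
                 if config.no_reference_list else frozenset())
        table = OrthologTable.from_tsv(config.ortholog_table,
                                       no_reference=noref)
        ledger = filter_orthology(table, genes, max_missing=config.max_missing)
        ledger.to_tsv(out / "filter_ledger.tsv")
        funnel = ledger.counts()
        for g, d in ledger.disposition.items():
            if d != Disposition.ANALYZED:
                excluded[g] = d.value

    methods = _discover_alignments(Path(config.alignment_dir))
    records_by_method: dict[str, list] = {}
    failures: list[dict] = []
    for method, files in methods.items():
        records = []
        for gene_id, path in sorted(files.items()):
            if gene_id in excluded:
                continue
            try:
                aln = read_codon_alignment(path)
                rec = run_gene_test(aln, tree, gene_id=gene_id,
                                    n_starts=config.n_starts)
                rec.alignment_method = method
                rec.foreground_label = config.foreground_token
                records.append(rec)
            except Exception as exc:  # per-gene failures are non-fatal
                failures.append({"gene": gene_id, "method": method,
                                 "error": str(exc)})
        if records:
            qs = bh_fdr([r.p_value for r in records])
            for r, q in zip(records, qs):
                r.q_value = float(q)
        records_by_method[method] = records

    hits = consensus(records_by_method, alpha=config.alpha,
                     use_q=config.use_fdr)

    rows = []
    for method, records in sorted(records_by_method.items()):
        for r in records:
            rows.append({
                "gene_id": r.gene_id, "alignment_method": method,
                "lnL_null": r.lnL_null, "lnL_alt": r.lnL_alt,
                "lrt_stat": r.lrt_stat, "p": r.p_value, "q": r.q_value,
                "kappa": r.params_alt.kappa, "omega0": r.params_alt.omega0,
                "omega2": r.params_alt.omega2, "p0": r.params_alt.p0,
                "p1": r.params_alt.p1, "n_sites": r.n_sites,
                "n_taxa": r.n_taxa, "foreground_label": r.foreground_label,
                "significant_consensus": r.gene_id in hits,
            })
    gene_df = pd.DataFrame(rows)
    gene_df.to_csv(out / "gene_tests.tsv", sep="\t", index=False)

    # BEB on the consensus-significant genes, first method alphabetically
    pss_rows = []
    if hits and records_by_method:
        primary = sorted(records_by_method)[0]
        rec_by_gene = {r.gene_id: r for r in records_by_method[primary]}
        for gene_id in sorted(hits):
            rec = rec_by_gene.get(gene_id)
            if rec is None:
                continue
            aln = read_codon_alignment(methods[primary][gene_id])
            from .selection import fit_m0  # local to avoid cycle at import
            fitted = fit_m0(aln, tree).tree
            posts = beb_posteriors(aln, fitted, rec.params_alt,
                                   grid_points=config.beb_grid_points,
                                   threshold=config.beb_threshold,
                                   reference_taxon=config.reference_taxon)
            for sp in posts:
                pss_rows.append({
                    "gene_id": gene_id,
                    "site_index_alignment": sp.site_index + 1,
                    "site_index_reference": sp.reference_site or "",
                    "post_class0": sp.class_posteriors[0],
                    "post_class1": sp.class_posteriors[1],
                    "post_class2a": sp.class_posteriors[2],
                    "post_class2b": sp.class_posteriors[3],
                    "p_positive": sp.p_positive,
                    "is_pss": sp.is_pss,
                })
    pss_df = pd.DataFrame(pss_rows)
    pss_df.to_csv(out / "pss_sites.tsv", sep="\t", index=False)

    _write_manifest(out, config, {
        "n_methods": len(methods),
        "funnel": funnel,
        "n_consensus_significant": len(hits),
        "failures": failures,
    })
    return gene_df, pss_df


def run_region_annotation(config: RunConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the noncoding arm; returns (assignment table, summary)."""
    if not (config.regions_bed and config.genes_tsv):
        raise ValueError("region annotation needs regions_bed and genes_tsv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    units = read_gene_annotation(config.genes_tsv, config.exons_bed)
    region_ivs = read_bed(config.regions_bed)
    lineage = Lineage(config.lineage)
    regions = [AcceleratedRegion(interval=iv, lineage=lineage)
               for iv in region_ivs]

    gene_chroms = {u.body.chrom for u in units}
    unmatched = sum(1 for r in regions if r.interval.chrom not in gene_chroms)
    warnings = []
    if unmatched:
        warnings.append(
            f"{unmatched} region(s) on chromosomes absent from the "
            "gene annotation"
        )

    classify_coding(regions, units)
    assign_gene_body(regions, units)
    domains = build_regulatory_domains(units, basal_up=config.basal_up,
                                       basal_down=config.basal_down,
                                       max_extension=config.max_extension)
    assign_regulatory_domain(regions, domains)
    if config.tads_bed:
        tads = TadSet(tads=read_bed(config.tads_bed))
        assign_tad(regions, units, tads)

    rows = []
    for r in regions:
        any_mode = False
        for mode in AssignmentMode:
            for g in sorted(r.genes(mode)):
                any_mode = True
                rows.append({"region_id": r.id, "lineage": r.lineage.value,
                             "coding_class": r.coding_class.value,
                             "gene_id": g, "mode": mode.value})
        if not any_mode:
            rows.append({"region_id": r.id, "lineage": r.lineage.value,
                         "coding_class": r.coding_class.value,
                         "gene_id": "", "mode": ""})
    assign_df = pd.DataFrame(rows)
    assign_df.to_csv(out / "region_assignments.tsv", sep="\t", index=False)
    summary_df = summarize(regions)
    summary_df.to_csv(out / "region_summary.tsv", sep="\t", index=False)
    _write_manifest(out, config, {
        "n_regions": len(regions),
        "n_genes": len(units),
        "warnings": warnings,
    })
    return assign_df, summary_df
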