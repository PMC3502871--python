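"""End-to-end orchestration of the screen.

Stages run in order eqtl -> ldproxy -> annotate -> mirscan -> coexpr /
enrich, communicating only through files so each stage is independently
re-runnable; the final ScreenReport is the screen's accounting (counts
per stage, per tissue, per annotation category) assembled from the stage
outputs, with its arithmetic identities asserted at build time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .annotate import (SnpAnnotation, annotate_snp,
                       filter_utr3_in_genes_of_interest, partition_report)
from .config import PipelineConfig
from .core import HaplotypePanel, Variant
from .enrich import CoexpressionSummary, EnrichmentResult, coexpression_filter, \
    enrichment_test
from .eqtl import EqtlResult, cross_tissue_overlap, scan_all_genes
from .ld import find_proxies, merge_leads_and_proxies
from .mirtarget import classify_all, consensus

log = logging.getLogger("mirqtl")

PANEL_CATEGORIES = ("phase_I", "phase_II", "phase_III", "NR_TF", "other_ADME")


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig, stage: str) -> dict[str, object]:
    return {"stage": stage, "config": config_hash(cfg), "seed": cfg.seed}


@dataclass
class ScreenReport:
    """The screen's accounting object, one field per Results-style count."""

    eqtl_counts: dict[str, int]
    eqtl_tested: dict[str, int]
    shared_eqtl_count: int
    n_leads: int
    n_proxies: int
    n_candidates: int
    partition: dict[str, int]
    utr3_in_goi: int
    utr3_goi_genes: int
    consensus_positive: int
    n_consensus_calls: int
    coexpressed: int
    coexpr_assessable: int
    coexpr_proportion: float | None
    enrichment_observed: float | None = None
    enrichment_p: float | None = None

    def __post_init__(self) -> None:
        assert sum(self.partition.values()) == self.n_candidates, \
            "annotation partition does not sum to the candidate count"
        assert self.n_candidates <= self.n_leads + self.n_proxies, \
            "merge accounting violated"
        assert all(v >= 0 for v in self.partition.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tissue, n in self.eqtl_counts.items():
            rows.append((f"eqtls_{tissue}", n))
        rows += [
            ("eqtls_total", sum(self.eqtl_counts.values())),
            ("eqtls_shared_two_tissues", self.shared_eqtl_count),
            ("lead_snps", self.n_leads),
            ("proxy_snps", self.n_proxies),
            ("candidate_snps", self.n_candidates),
        ]
        rows += [(f"annot_{k}", v) for k, v in self.partition.items()]
        rows += [
            ("utr3_in_genes_of_interest", self.utr3_in_goi),
            ("utr3_goi_distinct_genes", self.utr3_goi_genes),
            ("consensus_positive", self.consensus_positive),
            ("consensus_calls", self.n_consensus_calls),
            ("coexpressed_calls", self.coexpressed),
            ("coexpr_assessable_calls", self.coexpr_assessable),
            ("coexpr_proportion",
             "" if self.coexpr_proportion is None else self.coexpr_proportion),
            ("enrichment_observed",
             "" if self.enrichment_observed is None else self.enrichment_observed),
            ("enrichment_p",
             "" if self.enrichment_p is None else self.enrichment_p),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def summary_text(self) -> str:
        lines = ["Screen report", "============="]
        for _, row in self.to_frame().iterrows():
            lines.append(f"{row['quantity']:32s} {row['value']}")
        return "\n".join(lines) + "\n"


def summarize_gene_panel(path_or_df: str | Path | pd.DataFrame
                         ) -> tuple[dict[str, int], int]:
    """Per-category counts of a gene panel TSV with a 'category' column."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) \
        else io.read_tsv(path_or_df)
    counts = {c: 0 for c in PANEL_CATEGORIES}
    for label in df["category"]:
        if label not in counts:
            raise ValueError(f"unknown gene panel category {label!r}")
        counts[label] += 1
    return counts, int(sum(counts.values()))


def _load_manifest(manifest: str | Path | dict) -> tuple[dict, Path]:
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        data = yaml.safe_load(Path(manifest).read_text())
    else:
        data, base = dict(manifest), Path(".")
    required = ("panel", "genes", "utr_fasta", "mir_catalog",
                "genes_of_interest", "expression", "mir_expression")
    missing = [k for k in required if k not in data]
    if missing:
        raise ValueError(f"manifest missing entries: {missing}")
    return data, base


def run_pipeline(cfg: PipelineConfig, manifest: str | Path | dict,
                 out_dir: str | Path) -> ScreenReport:
    """Run the full screen from a manifest of input files.

    Every stage writes its inputs/outputs under ``out_dir``; the report is
    serialized as both a TSV and a human-readable summary, and the whole
    run is deterministic given ``cfg.seed``.
    """
    man, base = _load_manifest(manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = io.read_haplotype_panel(base / man["panel"])
    genotypes = panel.to_genotypes()
    models = io.read_gene_models(base / man["genes"])
    models_by_id = {m.gene_id: m for m in models}
    utr_seqs = io.read_fasta(base / man["utr_fasta"])
    catalog = io.read_mir_catalog(base / man["mir_catalog"])
    goi = list(io.read_tsv(base / man["genes_of_interest"])["gene_id"].astype(str))

    # stage 1: cis-eQTL scan per tissue -------------------------------------
    results_by_tissue: dict[str, list[EqtlResult]] = {}
    tested_by_tissue: dict[str, int] = {}
    for tissue, path in man["expression"].items():
        expr = io.read_expression_tsv(base / path, tissue=tissue)
        res, n_tested = scan_all_genes(models, genotypes, expr, cfg)
        results_by_tissue[tissue] = res
        tested_by_tissue[tissue] = n_tested
        io.write_tsv(_eqtl_frame(res), out / f"eqtl_{tissue}.tsv",
                     _header(cfg, f"eqtl:{tissue}"))
        log.info("eqtl[%s]: %d tested, %d significant", tissue, n_tested,
                 len(res))
    if len(results_by_tissue) >= 2:
        _, shared = cross_tissue_overlap(results_by_tissue)
    else:
        shared = 0

    # stage 2: LD proxy expansion ------------------------------------------
    lead_variants: dict[str, Variant] = {}
    lead_tissue: dict[str, str] = {}
    for tissue, results in results_by_tissue.items():
        for r in results:
            lead_variants.setdefault(r.variant.rsid, r.variant)
            lead_tissue.setdefault(r.variant.rsid, tissue)
    proxy_rows = []
    proxy_rsids: list[str] = []
    snp_tissue: dict[str, str] = dict(lead_tissue)
    for rsid, lead in sorted(lead_variants.items()):
        for p in find_proxies(lead, panel, cfg):
            proxy_rows.append((p.lead_rsid, p.proxy_rsid, p.chrom, p.pos + 1,
                               p.r2, p.d_prime, p.distance_bp, p.source))
            proxy_rsids.append(p.proxy_rsid)
            snp_tissue.setdefault(p.proxy_rsid, lead_tissue[rsid])
    io.write_tsv(pd.DataFrame(proxy_rows, columns=[
        "lead_rsid", "proxy_rsid", "chrom", "pos", "r2", "d_prime",
        "distance", "source"]), out / "proxies.tsv", _header(cfg, "ldproxy"))
    candidates = merge_leads_and_proxies(sorted(lead_variants), proxy_rsids)
    n_unique_proxies = len(set(proxy_rsids) - set(lead_variants))

    # stage 3: functional annotation ---------------------------------------
    variant_of = {v.rsid: v for v in panel.variants}
    annotations: list[SnpAnnotation] = []
    for rsid in candidates:
        v = variant_of.get(rsid, lead_variants.get(rsid))
        if v is None:
            raise ValueError(f"candidate SNP {rsid} not found in the panel")
        annotations.append(annotate_snp(v, models, cfg.flank_bp,
                                        target_genes=set(goi)))
    partition = partition_report(annotations)
    io.write_tsv(pd.DataFrame(
        [(a.rsid, a.gene_id, a.category, a.in_target_gene) for a in annotations],
        columns=["rsid", "gene_id", "category", "in_target_gene"]),
        out / "annotated.tsv", _header(cfg, "annotate"))

    utr3_hits, n_goi_genes = filter_utr3_in_genes_of_interest(annotations, goi)

    # stage 4: allele-specific miRNA site prediction ------------------------
    call_rows = []
    calls_exact, calls_tax = [], []
    predicted_by_snp: dict[str, list[str]] = {}
    for a in utr3_hits:
        model = models_by_id[a.gene_id]
        utr = io.build_utr3_record(model, utr_seqs[a.gene_id])
        v = variant_of[a.rsid]
        for mode, sink in (("exact_match", calls_exact), ("taxonomy", calls_tax)):
            for call in classify_all(utr, v, catalog, mode, cfg.min_match_len,
                                     cfg.rescan_window,
                                     cfg.change_includes_position):
                sink.append(call)
                if call.effect != "none":
                    call_rows.append((
                        call.rsid, call.mir_name, call.algorithm, call.effect,
                        ";".join(sorted({c.site_type for c in call.sites_ref})),
                        ";".join(sorted({c.site_type for c in call.sites_alt})),
                        call.snp_in_seed))
    io.write_tsv(pd.DataFrame(call_rows, columns=[
        "rsid", "mir", "algorithm", "effect", "site_type_ref",
        "site_type_alt", "snp_in_seed"]), out / "calls.tsv",
        _header(cfg, "mirscan"))
    cons = consensus(calls_exact, calls_tax)
    n_positive = sum(1 for c in cons if c.positive_both)
    for c in cons:
        predicted_by_snp[c.rsid] = sorted(c.mir_names_both)

    # stage 5: co-expression and enrichment ---------------------------------
    mir_expr = {tissue: io.read_expression_tsv(base / path, tissue=tissue)
                for tissue, path in man["mir_expression"].items()}
    coexpr = coexpression_filter(predicted_by_snp,
                                 {r: snp_tissue[r] for r in predicted_by_snp},
                                 mir_expr, cfg.coexpression_threshold)
    io.write_tsv(pd.DataFrame(
        [(r.rsid, r.tissue, ";".join(r.mirs_predicted),
          ";".join(r.mirs_expressed), r.coexpressed) for r in coexpr.records],
        columns=["rsid", "tissue", "mirs_predicted", "mirs_expressed",
                 "coexpressed"]), out / "coexpr.tsv", _header(cfg, "coexpr"))

    enr = _maybe_enrichment(cfg, utr3_hits, cons, coexpr, annotations,
                            variant_of, models_by_id, utr_seqs, catalog)

    report = ScreenReport(
        eqtl_counts={t: len(r) for t, r in results_by_tissue.items()},
        eqtl_tested=tested_by_tissue,
        shared_eqtl_count=shared,
        n_leads=len(lead_variants),
        n_proxies=n_unique_proxies,
        n_candidates=len(candidates),
        partition=partition,
        utr3_in_goi=len(utr3_hits),
        utr3_goi_genes=n_goi_genes,
        consensus_positive=n_positive,
        n_consensus_calls=len(cons),
        coexpressed=coexpr.n_coexpressed,
        coexpr_assessable=coexpr.n_assessable_calls,
        coexpr_proportion=coexpr.proportion,
        enrichment_observed=None if enr is None else enr.observed_stat,
        enrichment_p=None if enr is None else enr.empirical_p,
    )
    io.write_tsv(report.to_frame(), out / "report.tsv", _header(cfg, "report"))
    (out / "report.txt").write_text(report.summary_text())
    return report


def _maybe_enrichment(cfg, utr3_hits, cons, coexpr, annotations, variant_of,
                      models_by_id, utr_seqs, catalog) -> EnrichmentResult | None:
    """MAF-matched enrichment when a 3'-UTR background exists."""
    cand_rsids = [a.rsid for a in utr3_hits]
    background_annots = [a for a in annotations
                         if a.category == "utr3" and a.rsid not in cand_rsids
                         and a.gene_id in models_by_id
                         and a.gene_id in utr_seqs]
    if not cand_rsids or not background_annots:
        log.info("enrichment skipped: no 3'-UTR background SNPs available")
        return None
    positive = {c.rsid for c in cons if c.positive_both}
    if cfg.require_coexpression:
        co = {r.rsid for r in coexpr.records if r.coexpressed}
        positive &= co
    cand = [variant_of[r] for r in cand_rsids]
    cand_flags = np.array([r in positive for r in cand_rsids])
    bg, bg_flags = [], []
    for a in background_annots:
        v = variant_of[a.rsid]
        utr = io.build_utr3_record(models_by_id[a.gene_id], utr_seqs[a.gene_id])
        calls_e = classify_all(utr, v, catalog, "exact_match",
                               cfg.min_match_len, cfg.rescan_window,
                               cfg.change_includes_position)
        calls_t = classify_all(utr, v, catalog, "taxonomy", cfg.min_match_len,
                               cfg.rescan_window, cfg.change_includes_position)
        hit = any(c.effect != "none" for c in calls_e) and \
            any(c.effect != "none" for c in calls_t)
        bg.append(v)
        bg_flags.append(hit)
    try:
        return enrichment_test(cand, cand_flags, bg, np.array(bg_flags),
                               cfg.maf_tolerance, cfg.permutations, cfg.seed)
    except ValueError as exc:
        log.info("enrichment skipped: %s", exc)
        return None


def _eqtl_frame(results: list[EqtlResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variant.rsid, r.variant.chrom, r.variant.pos + 1, r.gene_id,
          r.tissue, r.n_used, r.beta, r.se, r.t_stat, r.p_value,
          r.distance_to_gene) for r in results],
        columns=["rsid", "chrom", "pos", "gene_id", "tissue", "n_used",
                 "beta", "se", "t", "p", "distance"])
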