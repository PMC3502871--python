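"""cis-eQTL detection.

Each SNP within the cis window of a gene is tested for association with
that gene's expression by ordinary least squares of expression on the
additive alt-allele dosage, with a two-sided t test on n-2 degrees of
freedom. Significance is a fixed p-value threshold (default 1e-5) with no
further multiple-testing correction, and the window is anchored on the
gene body: distance is measured to the nearest gene boundary, zero inside
the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .core import MISSING, ExpressionMatrix, GeneModel, GenotypeMatrix, Variant

log = logging.getLogger("mirqtl")


@dataclass
class EqtlResult:
    variant: Variant
    gene_id: str
    tissue: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    p_value: float
    distance_to_gene: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.n_used < 3:
            raise ValueError("n_used < 3")


def fit_dosage_regression(dosages: np.ndarray, expression: np.ndarray
                          ) -> tuple[int, float, float, float, float]:
    """OLS of expression on dosage: (n_used, beta, se, t, p).

    Pairs with a missing dosage are dropped; monomorphic dosages are
    untestable.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    keep = (np.asarray(dosages) != MISSING) & np.isfinite(y)
    g, y = g[keep], y[keep]
    n = g.size
    if n < 3:
        raise ValueError(f"only {n} complete pairs; need >= 3")
    if np.ptp(g) == 0:
        raise ValueError("untestable variant: monomorphic dosages")
    fit = stats.linregress(g, y)
    beta, se = float(fit.slope), float(fit.stderr)
    if se > 0:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:  # perfect fit: p at the machine floor
        t = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
        p = 0.0 if beta != 0 else 1.0
    return n, beta, se, t, p


def distance_to_gene(v: Variant, gene: GeneModel) -> int:
    """bp from the SNP to the nearest gene-body boundary; 0 inside."""
    if gene.contains(v.pos):
        return 0
    if v.pos < gene.start:
        return gene.start - v.pos
    return v.pos - (gene.end - 1)


def scan_cis(gene: GeneModel, panel: GenotypeMatrix, expr: ExpressionMatrix,
             cfg: PipelineConfig) -> tuple[list[EqtlResult], int]:
    """Test every variant within the cis window; return the significant
    results (p < cutoff, sorted by p, then distance, then rsid) and the
    number of variants tested."""
    if panel.sample_ids != expr.sample_ids:
        raise ValueError("genotype and expression sample ids differ")
    y = expr.feature(gene.gene_id)
    results: list[EqtlResult] = []
    n_tested = 0
    for j, v in enumerate(panel.variants):
        if v.chrom != gene.chrom:
            continue
        d = distance_to_gene(v, gene)
        if d > cfg.cis_window_bp:
            continue
        n_tested += 1
        try:
            n, beta, se, t, p = fit_dosage_regression(panel.column(j), y)
        except ValueError:
            continue
        if p < cfg.eqtl_p_cutoff:
            results.append(EqtlResult(v, gene.gene_id, expr.tissue,
                                      n, beta, se, t, p, d))
    if n_tested == 0:
        log.info("scan_cis: no variant in the cis window of %s", gene.gene_id)
    results.sort(key=lambda r: (r.p_value, r.distance_to_gene, r.variant.rsid))
    return results, n_tested


def scan_all_genes(genes: list[GeneModel], panel: GenotypeMatrix,
                   expr: ExpressionMatrix, cfg: PipelineConfig
                   ) -> tuple[list[EqtlResult], int]:
    results: list[EqtlResult] = []
    total_tested = 0
    for gene in genes:
        if gene.gene_id not in expr.feature_ids:
            continue
        res, n = scan_cis(gene, panel, expr, cfg)
        results.extend(res)
        total_tested += n
    return results, total_tested


def cross_tissue_overlap(results_by_tissue: dict[str, list[EqtlResult]]
                         ) -> tuple[dict[str, set[str]], int]:
    """Map each eQTL rsid to the set of tissues calling it, and count the
    rsids shared by at least two tissues."""
    if len(results_by_tissue) < 2:
        raise ValueError("need results from at least two tissues")
    tissues_of: dict[str, set[str]] = {}
    for tissue, results in results_by_tissue.items():
        for r in results:
            tissues_of.setdefault(r.variant.rsid, set()).add(tissue)
    n_shared = sum(1 for ts in tissues_of.values() if len(ts) >= 2)
    return tissues_of, n_shared
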