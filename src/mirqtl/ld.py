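"""Linkage-disequilibrium proxy search.

Pairwise LD (r^2 and D') is computed from phased haplotypes by direct
gamete counting, or from unphased genotypes via a two-locus
expectation-maximization over the double-heterozygote phase ambiguity.
Proxies of a lead eQTL are all variants within a window (default 500 kb)
at r^2 at or above the cutoff (default 0.8); leads absent from the panel
are carried forward un-expanded rather than failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .core import MISSING, HaplotypePanel, Variant

log = logging.getLogger("mirqtl")


@dataclass
class ProxyRecord:
    lead_rsid: str
    proxy_rsid: str
    chrom: str
    pos: int
    r2: float
    d_prime: float
    distance_bp: int
    source: str = "phased"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 outside [0, 1]")
        if not 0.0 <= self.d_prime <= 1.0 + 1e-12:
            raise ValueError("d_prime outside [0, 1]")


def _ld_from_freqs(pA: float, pB: float, pAB: float) -> tuple[float, float]:
    """(r^2, D') from alt-allele and joint alt-alt haplotype frequencies."""
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA) <= 0 or min(pB, qB) <= 0:
        raise ValueError("r^2 undefined: monomorphic locus")
    d = pAB - pA * pB
    r2 = d * d / (pA * qA * pB * qB)
    if d > 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    return float(min(r2, 1.0)), float(min(d_prime, 1.0))


def r2_from_haplotypes(hapA: np.ndarray, hapB: np.ndarray
                       ) -> tuple[float, float]:
    """LD between two phased binary haplotype vectors by gamete counting.

    r^2 equals the squared Pearson correlation of the two 0/1 vectors;
    D' = |D| / Dmax with the usual frequency bounds.
    """
    a = np.asarray(hapA, dtype=float)
    b = np.asarray(hapB, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("haplotype vectors must share a length >= 2")
    pA, pB = a.mean(), b.mean()
    pAB = float((a * b).mean())
    return _ld_from_freqs(pA, pB, pAB)


def em_haplotype_freqs(gA: np.ndarray, gB: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 1000
                       ) -> np.ndarray:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab) from
    unphased two-locus genotype dosages.

    Only the double heterozygote (1,1) is phase-ambiguous; the E step
    splits it between AB/ab and Ab/aB in proportion to the current
    products 2*pAB*pab and 2*pAb*paB. Initialization is at linkage
    equilibrium, which makes the all-double-heterozygote input a fixed
    point at (0.25, 0.25, 0.25, 0.25).
    """
    a = np.asarray(gA)
    b = np.asarray(gB)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep].astype(int), b[keep].astype(int)
    n = a.size
    if n < 2:
        raise ValueError("need at least two individuals with complete data")
    if not 0.0 < a.mean() / 2.0 < 1.0 or not 0.0 < b.mean() / 2.0 < 1.0:
        raise ValueError("r^2 undefined: monomorphic locus")

    # unambiguous haplotype counts and the double-het count
    counts = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        counts[ga, gb] += 1
    n_dh = counts[1, 1]
    # gamete contributions (AB, Ab, aB, ab) per unambiguous genotype class
    base = np.zeros(4)
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for key, (cAB, cAb, caB, cab) in contrib.items():
        c = counts[key]
        base += c * np.array([cAB, cAb, caB, cab], dtype=float)

    pA = a.mean() / 2.0
    pB = b.mean() / 2.0
    freqs = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                      (1 - pA) * (1 - pB)])
    total = 2.0 * n
    for _ in range(max_iter):
        w_cis = 2.0 * freqs[0] * freqs[3]
        w_trans = 2.0 * freqs[1] * freqs[2]
        denom = w_cis + w_trans
        frac = 0.5 if denom == 0 else w_cis / denom
        new = base + n_dh * np.array([frac, 1 - frac, 1 - frac, frac])
        new /= total
        if np.max(np.abs(new - freqs)) < tol:
            return new
        freqs = new
    raise RuntimeError(
        f"EM did not converge in {max_iter} iterations; last iterate {freqs}"
    )


def r2_from_genotypes(gA: np.ndarray, gB: np.ndarray) -> tuple[float, float]:
    """LD from unphased dosages via the two-locus EM."""
    freqs = em_haplotype_freqs(gA, gB)
    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    return _ld_from_freqs(pA, pB, freqs[0])


def find_proxies(lead: Variant, panel: HaplotypePanel, cfg: PipelineConfig
                 ) -> list[ProxyRecord]:
    """All panel variants within the LD window at r^2 >= the cutoff.

    The lead itself is excluded; a lead absent from the panel yields an
    empty list (it is carried forward with no reliable proxies). Sorted by
    descending r^2, then distance.
    """
    try:
        j_lead = panel.index_of(lead.rsid)
    except KeyError:
        log.info("find_proxies: lead %s absent from panel; no reliable proxies",
                 lead.rsid)
        return []
    hap_lead = panel.column(j_lead)
    out: list[ProxyRecord] = []
    for j, v in enumerate(panel.variants):
        if j == j_lead or v.chrom != lead.chrom:
            continue
        dist = abs(v.pos - lead.pos)
        if dist > cfg.ld_window_bp:
            continue
        col = panel.column(j)
        if np.ptp(col) == 0 or np.ptp(hap_lead) == 0:
            continue
        r2, dp = r2_from_haplotypes(hap_lead, col)
        if r2 >= cfg.ld_r2_cutoff:
            out.append(ProxyRecord(lead.rsid, v.rsid, v.chrom, v.pos,
                                   r2, dp, dist, source="phased"))
    out.sort(key=lambda p: (-p.r2, p.distance_bp, p.proxy_rsid))
    return out


def merge_leads_and_proxies(leads: list[str], proxies: list[str]) -> list[str]:
    """Deduplicated union of lead and proxy rsids, leads first, stable order.

    A SNP that is both a lead and a proxy counts once; leads with no
    proxies are retained.
    """
    seen: set[str] = set()
    merged: list[str] = []
    for rsid in list(leads) + list(proxies):
        if rsid not in seen:
            seen.add(rsid)
            merged.append(rsid)
    return merged
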