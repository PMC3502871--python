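"""Tissue co-expression filtering and MAF-matched enrichment testing.

A predicted miRNA supports a candidate SNP only if it was probed by the
tissue's expression platform and detected above the threshold (strictly
positive by default). Enrichment of miRNA targeting among candidate SNPs
is assessed against MAF-matched random 3'-UTR SNPs with a one-sided
empirical p-value, (1 + #{null >= observed}) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, Variant

log = logging.getLogger("mirqtl")


@dataclass
class CoexpressionRecord:
    rsid: str
    tissue: str
    mirs_predicted: list[str]
    mirs_expressed: list[str]
    coexpressed: bool
    n_assessable: int


@dataclass
class CoexpressionSummary:
    records: list[CoexpressionRecord]
    n_coexpressed: int
    n_assessable_calls: int
    proportion: float | None  # None when no call has an assessable miR


@dataclass
class EnrichmentResult:
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    B: int
    maf_tolerance: float
    seed: int

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if len(self.null_stats) != self.B:
            raise ValueError("null_stats length != B")
        if not (1.0 / (self.B + 1) <= self.empirical_p <= 1.0):
            raise ValueError("empirical_p outside [1/(B+1), 1]")


def coexpression_filter(predicted_by_snp: dict[str, list[str]],
                        tissue_by_snp: dict[str, str],
                        mir_expr: dict[str, ExpressionMatrix],
                        threshold: float = 0.0,
                        probed_set: set[str] | None = None
                        ) -> CoexpressionSummary:
    """Which candidate SNPs have at least one predicted miRNA expressed in
    the SNP's own tissue.

    A miRNA counts as expressed iff it is in ``probed_set`` (the platform's
    probe list; defaults to the features of the expression table) and its
    value is strictly above ``threshold``. miRNAs never probed are dropped
    from both numerator and denominator, and a call with no probed miRNA is
    not assessable: the summary proportion is over assessable calls, or
    None when there are none.
    """
    records: list[CoexpressionRecord] = []
    for rsid in sorted(predicted_by_snp):
        tissue = tissue_by_snp[rsid]
        if tissue not in mir_expr:
            raise ValueError(f"no miRNA expression table for tissue {tissue!r}")
        expr = mir_expr[tissue]
        probed = probed_set if probed_set is not None else set(expr.feature_ids)
        predicted = sorted(set(predicted_by_snp[rsid]))
        assessable = [m for m in predicted if m in probed]
        expressed = [m for m in assessable
                     if m in expr.feature_ids
                     and float(expr.feature(m).mean()) > threshold]
        records.append(CoexpressionRecord(rsid, tissue, predicted, expressed,
                                          bool(expressed), len(assessable)))
    assessable_calls = [r for r in records if r.n_assessable > 0]
    n_co = sum(1 for r in assessable_calls if r.coexpressed)
    prop = n_co / len(assessable_calls) if assessable_calls else None
    return CoexpressionSummary(records, n_co, len(assessable_calls), prop)


def maf_matched_resample(candidates: list[Variant], background: list[Variant],
                         tolerance: float, B: int, seed: int
                         ) -> list[np.ndarray]:
    """B index sets into ``background``, one MAF-matched draw per candidate.

    Each candidate draws uniformly from its tolerance bin; within one
    resample draws are without replacement while the bin allows it, with a
    logged with-replacement fallback for exhausted bins. Each candidate
    owns an independent RNG stream (SeedSequence([seed, candidate index])),
    so extending the candidate list never perturbs earlier draws.
    """
    if not background:
        raise ValueError("background is empty")
    mafs_bg = np.array([v.maf for v in background])
    bins: list[np.ndarray] = []
    unmatched = []
    for c in candidates:
        idx = np.nonzero(np.abs(mafs_bg - c.maf) <= tolerance + 1e-12)[0]
        if idx.size == 0:
            unmatched.append(c.rsid)
        bins.append(idx)
    if unmatched:
        raise ValueError(f"no MAF-matched background SNP for: {unmatched}")

    # one independent stream per candidate, consumed in buffered blocks
    rngs = [np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            for i in range(len(candidates))]
    buffers: list[list[int]] = [[] for _ in candidates]
    cursors = [0] * len(candidates)

    def next_raw(i: int) -> int:
        if cursors[i] >= len(buffers[i]):
            buffers[i] = rngs[i].integers(len(bins[i]), size=1024).tolist()
            cursors[i] = 0
        cursors[i] += 1
        return buffers[i][cursors[i] - 1]

    fell_back = False
    resamples: list[np.ndarray] = []
    for _ in range(B):
        used: set[int] = set()
        draw = np.empty(len(candidates), dtype=np.int64)
        for i, bin_idx in enumerate(bins):
            pick = None
            cap = 4 * len(bin_idx) + 8  # rejection bound before fallback
            for _attempt in range(cap):
                cand = int(bin_idx[next_raw(i)])
                if cand not in used:
                    pick = cand
                    break
            if pick is None:  # bin exhausted: with-replacement fallback
                pick = int(bin_idx[next_raw(i)])
                fell_back = True
            used.add(pick)
            draw[i] = pick
        resamples.append(draw)
    if fell_back:
        log.info("maf_matched_resample: exhausted bin(s); fell back to "
                 "with-replacement draws")
    return resamples


def enrichment_test(candidates: list[Variant], candidate_targeted: np.ndarray,
                    background: list[Variant], background_targeted: np.ndarray,
                    tolerance: float = 0.05, B: int = 999, seed: int = 0
                    ) -> EnrichmentResult:
    """One-sided MAF-matched enrichment of miRNA targeting.

    The statistic is the proportion of SNPs with at least one (optionally
    co-expressed) consensus-positive miRNA; ``*_targeted`` carry that flag
    per SNP. Each null replicate recomputes the statistic on a MAF-matched
    resample of the background.
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    cand_flags = np.asarray(candidate_targeted, dtype=bool)
    bg_flags = np.asarray(background_targeted, dtype=bool)
    if len(cand_flags) != len(candidates) or len(bg_flags) != len(background):
        raise ValueError("targeted flags do not align with variant lists")
    observed = float(cand_flags.mean())
    resamples = maf_matched_resample(candidates, background, tolerance, B, seed)
    null_stats = np.array([float(bg_flags[idx].mean()) for idx in resamples])
    p = (1.0 + int((null_stats >= observed - 1e-12).sum())) / (B + 1.0)
    return EnrichmentResult(observed, null_stats, p, B, tolerance, seed)
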