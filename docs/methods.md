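# Methods

`mirqtl` implements an in-silico screen for common SNPs that plausibly
modulate a gene's mRNA level by interfering with microRNA (miRNA)
targeting of its 3'-UTR. The screen chains five stages; each is a library
module with a file-level CLI wrapper, and a synthetic-data module
generates every input class with planted ground truth so the whole chain
is testable without external datasets.

## Pipeline model

**1. cis-eQTL detection.** For each gene, every SNP whose distance to the
gene body (nearest boundary; zero inside) is at most `cis_window_bp`
(default 500 kb) is tested by ordinary least squares of expression *y* on
the additive alt-allele dosage *g* ∈ {0,1,2}:

    y_i = α + β g_i + ε_i,   ε_i ~ N(0, σ²)

with a two-sided t test on n−2 degrees of freedom. Significance is the
fixed threshold `eqtl_p_cutoff` (default 1e-5) with no further
multiple-testing correction — the cutoff itself is the screen's
correction, sized to the number of SNPs expected in a 500 kb window.
Missing genotypes are dropped pairwise; monomorphic dosages are
untestable by construction. The published eQTL sources used heterogeneous
association methods that they do not restate; OLS on dosage is this
package's transparent stand-in, and it is the model the calibration tests
assume. Ties in the output ordering resolve by ascending p, then
distance, then rsid.

**2. LD proxy expansion.** Lead eQTLs are expanded to all panel variants
within `ld_window_bp` (default 500 kb) at r² ≥ `ld_r2_cutoff` (default
0.8). From phased haplotypes, with alt-allele frequencies p_A, p_B and
joint alt–alt haplotype frequency p_AB:

    D = p_AB − p_A p_B
    r² = D² / (p_A(1−p_A) p_B(1−p_B))
    D' = |D| / D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B) if D>0
                               else min(p_A p_B, (1−p_A)(1−p_B))

r² equals the squared Pearson correlation of the two binary haplotype
vectors (asserted against an independent oracle in the tests). For
unphased input a two-locus EM resolves the double-heterozygote phase
ambiguity: initialization at linkage equilibrium (p_AB = p_A p_B),
E step splitting each double heterozygote between cis and trans phase in
proportion to 2·p_AB·p_ab versus 2·p_Ab·p_aB, convergence when the
largest frequency change is below 1e-8 (cap 1000 iterations, error on
non-convergence). The equilibrium start makes the all-double-heterozygote
input a fixed point at (¼,¼,¼,¼) — the honest answer for data that carry
no phase information. Leads absent from the panel are carried forward
un-expanded ("no reliable proxies") rather than failing; lead and proxy
sets are merged by rsid with duplicates counted once.

Note on EM accuracy: the EM estimate is the exact MLE (verified against a
profile-likelihood grid search), but phase ambiguity leaves irreducible
sampling noise of sd ≈ 0.01 in r² at n = 500 individuals, so consistency
with the phased value is checked on the mean absolute deviation over
replicates, not per replicate.

**3. Functional annotation.** Each candidate SNP receives exactly one of
eight categories — 3'-UTR, 5'-UTR, intronic, coding synonymous, coding
non-synonymous, upstream, downstream, intergenic — against single-
transcript gene models. UTRs are derived by exon−CDS subtraction with
strand-aware 5'/3' assignment. When a SNP touches several genes the
precedence coding > utr3 > utr5 > intronic > upstream > downstream >
intergenic applies, chosen so the screen's target class (3'-UTR) is never
shadowed by an intron call from an overlapping gene; ties at equal
precedence resolve to the smallest gene_id. Upstream/downstream flanks
default to `flank_bp` = 2000 bp (the original annotation tool's window is
undocumented; the value is declared in config and surfaced in report
headers). Coding effects translate the affected codon under the standard
genetic code (NCBI table 1), complementing alleles for minus-strand
genes. Only 3'-UTR SNPs inside the declared genes of interest proceed;
3'-UTR SNPs of nearby genes are excluded.

**4. Allele-specific miRNA site prediction.** Two algorithms, run
independently and intersected.

*Seed-site taxonomy* (TargetScan-style): a site is an exact occurrence of
the sequence implied by the miRNA seed — with S = reverse complement of
miR positions 2–8 (RNA→DNA), the 7mer-m8 site is S, the 8mer is S + "A",
and the 7mer-A1 is reverse complement of positions 2–7 + "A"; the A sits
opposite miR position 1 and is not itself paired. At a shared locus only
the longest type is reported (an 8mer subsumes its contained 7mers).
6mer sites are excluded entirely per the screen's conservative 7-mer
cutoff.

*Seed-anchored exact match* (FASTA-alignment-style): a hit requires
perfect Watson–Crick pairing of UTR bases to miR positions 2–7, extended
contiguously toward the miR 3' end until the first mismatch, positive
when the matched length reaches `min_match_len` (default 7). A 7-mer
contiguous match from position 2 necessarily covers position 8, so every
hit is typed 8mer or 7mer-m8 by the A opposite position 1, keeping the
two algorithms' site records comparable; the raw match length is carried
separately. No G:U wobble, no context/conservation scoring, no
thermodynamics in either mode.

*SNP effect*: both alleles are applied to a ±`rescan_window` (default 25)
nt window around the SNP — the longest site is 8 nt, so the window is
conservative — and the per-allele site lists for each miRNA are diffed:
alt-only site → create; ref-only → abolish; sites on both alleles
differing in type or start → change (configurable to type-only);
identical → none. Windows truncated at the UTR edge are simply not
matches (no padding). A `snp_in_seed` flag records whether the SNP falls
in the seed-pairing span of an implicated site — preserving the published
screen's distinction for a SNP interacting from outside the seed.
A SNP is *consensus-positive* when each algorithm yields at least one
non-none effect; the per-SNP miRNA intersection is reported alongside.

**5. Co-expression and enrichment.** A predicted miRNA supports a SNP
only if the miRNA was probed by the tissue's expression platform and its
value is strictly above `coexpression_threshold` (default 0, i.e.
strictly positive — presence/absence semantics). Unprobed miRNAs leave
both numerator and denominator; a SNP with no probed predicted miRNA is
not assessable, and the summary proportion is over assessable SNPs (None
when there are none). Enrichment of targeting among the candidates is
tested against MAF-matched random 3'-UTR SNPs: the statistic is the
proportion of SNPs with ≥1 consensus-positive (optionally co-expressed)
miRNA; each of B (default 999) null replicates redraws, per candidate,
one background SNP with |ΔMAF| ≤ `maf_tolerance` (default 0.05), without
replacement within a replicate while the bin allows (logged
with-replacement fallback otherwise); the one-sided empirical p is
(1 + #{null ≥ observed}) / (B + 1), which can never be exactly zero.
Each candidate owns an independent RNG stream derived as
SeedSequence([seed, candidate index]), so appending a candidate never
perturbs existing draws — this makes the monotonicity property (adding a
targeted candidate cannot increase the p-value) hold exactly, not just in
expectation.

## Synthetic data

Generators are pure functions of their seed; scenario code derives one
child stream per purpose via SeedSequence([seed, stream index]) so adding
a generator never shifts the others.

- **Genotypes**: Hardy–Weinberg draws P(0,1,2) = ((1−q)², 2q(1−q), q²) at
  the stated MAF q.
- **Two-locus haplotypes**: the 4-class multinomial with D = sign ·
  sqrt(r²_target · p_A(1−p_A)p_B(1−p_B)); infeasible (p_A, p_B, r²)
  combinations error with the achievable maximum.
- **Expression**: y = βg + ε with Gaussian ε — additive, no covariates,
  chosen so OLS recovery is exactly calibrated.
- **3'-UTRs**: i.i.d. background at a target GC content,
  rejection-sampled (bounded retries, explicit failure) until the
  taxonomy scan of the reference sequence recovers exactly the planted
  site list for the whole catalog; the SNP's alleles are then chosen,
  again under rejection, to realize the requested effect
  (create/abolish/change/none) and nothing else. "Change" is realized as
  8mer → 7mer-m8 by mutating the terminal A. Ground truth records the
  expected effect under both algorithms — a planted 7mer-A1 site is
  invisible to the exact-match mode (it lacks 7 contiguous pairs from
  position 2), so its abolition is truthfully "none" there.
- **miRNA catalogs**: length-22 sequences with pairwise distinct seeds
  and, additionally, no site string of one member contained in a site
  string of another — two seeds sharing positions 2–7 share a 7mer-A1
  site, which would make a site-clean background impossible to realize.
- **miRNA expression**: presence/absence tables; detected miRNAs strictly
  above threshold, others at zero.

What the generators deliberately do not emulate: genome-wide LD
structure, expression covariance/batch effects, population
stratification, realistic UTR composition or conservation, isoform
diversity. Passing tests therefore demonstrate correctness of the
screen's logic under its stated model, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite exercises: scanner–oracle equivalence on 500 random
UTR/catalog fixtures (mostly 50–400 nt × 2–15 miRNAs, plus ten at
2000 nt × 50); the generator loop on 500 seeded planted-effect scenarios
(200 nt, 6 miRNAs); eQTL null calibration on 2000 variants at n = 200
(KS vs Uniform at α = 0.01, ≤3 variants past 1e-5), power on 100 seeds at
β = 1, σ = 0.5, MAF 0.3, n = 200 (≥95 detections), and bias over 200
replicates (within 3 MC-se); LD against the squared-Pearson oracle on 100
random panels plus the worked 40/10/10/40 table (r² = 0.36, D' = 0.6) and
EM consistency over 100 replicates at n = 500; enrichment null
calibration over 200 seeded runs at B = 999 with 27 candidates against
250 background SNPs at targeting rate 0.3 (rejection at α = 0.05 within
three binomial sd — the 27-SNP proportion is discrete, which makes the
empirical p slightly conservative by design).

Other fixed choices: internal coordinates are 0-based half-open with
conversion at every format boundary; only biallelic SNPs enter the
pipeline (indels/multi-allelics are logged and dropped); 3'-UTR sequences
are stored in mRNA sense orientation with a genomic coordinate map
handling minus-strand reversal; floating output is written at 6
significant digits; every stage TSV carries the config hash and seed in
header comments.

## Known limitations

- One transcript per gene; no isoform-aware annotation.
- No covariate adjustment or latent-factor correction in the eQTL scan.
- Seed-anchored prediction only: no 3'-supplementary pairing, bulged or
  non-canonical sites, no flanking-context effects (a SNP outside every
  seed span classifies as "none" even though such SNPs can matter in
  vivo).
- The enrichment statistic operates on presence/absence of targeting;
  it does not weight by site strength or miRNA abundance.
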