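"""Synthetic input generation with planted ground truth.

Every input class of the screen is generated with controlled statistical
structure: Hardy-Weinberg genotypes at stated MAFs, two-locus haplotypes
at a target r^2, expression with planted additive eQTL effects and
Gaussian noise, 3'-UTR sequences with planted seed sites and an allele
pair realizing a requested effect (create/abolish/change/none), and
presence/absence miRNA expression tables. Each generator is a pure
function of its seed; scenario-level code derives one child stream per
purpose via ``SeedSequence([seed, stream_index])`` so adding a generator
never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    HaplotypePanel,
    MicroRNA,
    Utr3Record,
    Variant,
)
from .mirtarget import SITE_WIDTH, SeedSiteCall, scan_taxonomy, site_sequence

BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def child_seed(master: int, stream: int) -> np.random.SeedSequence:
    """Deterministic child stream: SeedSequence([master, stream])."""
    return np.random.SeedSequence([int(master), int(stream)])


# ---------------------------------------------------------------------------
# Genotypes and haplotypes


def gen_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """HWE dosages: P(0,1,2) = ((1-maf)^2, 2 maf (1-maf), maf^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf {maf} outside (0, 0.5]")
    if n < 2:
        raise ValueError("need at least 2 samples")
    q = maf
    p = 1.0 - q
    return _rng(seed).choice(3, size=n, p=[p * p, 2 * p * q, q * q]).astype(np.int8)


def max_r2(pA: float, pB: float, sign: int = 1) -> float:
    """Largest achievable r^2 for given allele frequencies and D sign."""
    qA, qB = 1 - pA, 1 - pB
    dmax = min(pA * qB, qA * pB) if sign > 0 else min(pA * pB, qA * qB)
    return dmax**2 / (pA * qA * pB * qB)


def haplotype_frequencies(pA: float, pB: float, target_r2: float,
                          sign: int = 1) -> np.ndarray:
    """Frequencies of haplotypes (AB, Ab, aB, ab) implied by the target r^2.

    D = sign * sqrt(target_r2 * pA qA pB qB); raises with the achievable
    maximum when the combination is infeasible.
    """
    if not 0.0 <= target_r2 <= 1.0:
        raise ValueError("target_r2 outside [0, 1]")
    qA, qB = 1 - pA, 1 - pB
    r2m = max_r2(pA, pB, sign)
    if target_r2 > r2m + 1e-12:
        raise ValueError(
            f"target r2={target_r2} infeasible for pA={pA}, pB={pB} "
            f"(r2max={r2m:.6g})"
        )
    d = sign * np.sqrt(target_r2 * pA * qA * pB * qB)
    freqs = np.array([pA * pB + d, pA * qB - d, qA * pB - d, qA * qB + d])
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def gen_haplotype_pair(n_haplotypes: int, pA: float, pB: float,
                       target_r2: float, sign: int = 1, seed=0,
                       chrom: str = "chr1", positions: tuple[int, int] = (0, 1),
                       rsids: tuple[str, str] = ("rsA", "rsB"),
                       alleles: tuple[tuple[str, str], tuple[str, str]] = (
                           ("A", "G"), ("C", "T"))) -> HaplotypePanel:
    """Draw a two-variant phased panel from the 4-class multinomial."""
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (diploid pairs)")
    freqs = haplotype_frequencies(pA, pB, target_r2, sign)
    classes = _rng(seed).choice(4, size=n_haplotypes, p=freqs)
    # class -> (allele at A, allele at B); A=alt at locus A (frequency pA)
    a = np.isin(classes, (0, 1)).astype(np.int8)
    b = np.isin(classes, (0, 2)).astype(np.int8)
    hap_ids = [f"s{i}_{k}" for i in range(n_haplotypes // 2) for k in (1, 2)]
    variants = [
        Variant(chrom, positions[0], rsids[0], *alleles[0], maf=min(pA, 1 - pA)),
        Variant(chrom, positions[1], rsids[1], *alleles[1], maf=min(pB, 1 - pB)),
    ]
    return HaplotypePanel(hap_ids, variants, np.stack([a, b], axis=1))


def gen_expression_with_eqtl(dosages: np.ndarray, beta: float, sigma: float,
                             seed) -> np.ndarray:
    """y_i = beta * g_i + eps_i with eps ~ Normal(0, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    g = np.asarray(dosages, dtype=float)
    return beta * g + _rng(seed).normal(0.0, sigma, size=g.shape)


# ---------------------------------------------------------------------------
# miRNA catalogs and expression tables


def gen_mir_catalog(k: int, seed=0, length: int = 22) -> list[MicroRNA]:
    """k mature sequences with pairwise distinct, non-nested seed sites.

    Beyond distinct 7-mer seeds (positions 2-8), no site string (8mer,
    7mer_m8 or 7mer_A1) of one catalog member may contain or equal a site
    string of another: otherwise one miRNA's planted site would
    unavoidably embed a second miRNA's site (e.g. two seeds sharing
    positions 2-7 share the 7mer_A1 site) and a site-clean background
    could never be realized.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = _rng(seed)
    rna = np.array(list("ACGU"))
    site_sets: list[set[str]] = []
    catalog: list[MicroRNA] = []
    while len(catalog) < k:
        seq = "".join(rng.choice(rna, size=length))
        if len(set(seq[1:8])) < 2:  # degenerate monomer-run seed
            continue
        cand = MicroRNA(f"sim-miR-{len(catalog) + 1}", seq)
        sites = {site_sequence(cand, t) for t in ("8mer", "7mer_m8", "7mer_A1")}
        clash = any(s1 in s2 or s2 in s1
                    for prev in site_sets for s1 in prev for s2 in sites)
        if clash:
            continue
        site_sets.append(sites)
        catalog.append(cand)
    return catalog


def gen_mir_expression(catalog: list[MicroRNA], tissue: str,
                       detected: list[str], seed=0,
                       threshold: float = 0.0) -> ExpressionMatrix:
    """Presence/absence miRNA table: detected miRs strictly above threshold,
    all others at 0."""
    names = [m.name for m in catalog]
    if len(set(detected)) != len(detected):
        raise ValueError("duplicate names in detected subset")
    unknown = set(detected) - set(names)
    if unknown:
        raise ValueError(f"detected miRs not in catalog: {sorted(unknown)}")
    rng = _rng(seed)
    values = np.zeros((1, len(names)))
    for j, name in enumerate(names):
        if name in detected:
            values[0, j] = threshold + 1.0 + rng.uniform(0.0, 9.0)
    return ExpressionMatrix(["pool"], names, values, tissue=tissue)


# ---------------------------------------------------------------------------
# 3'-UTRs with planted sites


@dataclass
class SnpSpec:
    """Requested SNP placement and allelic effect for gen_utr_with_sites.

    effect 'abolish'/'change' target a planted site (``site_index``);
    'create' plants the site on the alt allele at ``position``; 'none'
    puts the SNP in background sequence.
    """

    effect: str = "none"
    mir: MicroRNA | None = None
    site_type: str = "7mer_m8"  # for create
    site_index: int = 0  # for abolish/change
    position: int | None = None
    rsid: str = "rs_sim"
    maf: float = 0.3


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a generated UTR."""

    sites: list[tuple[str, str, int]]  # (mir_name, site_type, utr offset)
    snp_offset: int | None
    mir_name: str | None
    effect_taxonomy: str
    effect_exact: str


def _site_set(calls: list[SeedSiteCall]) -> set[tuple[str, str, int]]:
    return {(c.mir_name, c.site_type, c.utr_start) for c in calls}


def _seed_offsets(site_type: str, start: int) -> list[int]:
    """UTR offsets within the seed-pairing part of a site at ``start``."""
    width = SITE_WIDTH[site_type]
    end = start + width
    if site_type in ("8mer", "7mer_A1"):
        end -= 1  # the terminal A pairs miR position 1, not the seed
    return list(range(start, end))


def gen_utr_with_sites(length: int,
                       planted: list[tuple[MicroRNA, str, int]],
                       snp_spec: SnpSpec | None = None,
                       gc_content: float = 0.5, seed=0,
                       catalog: list[MicroRNA] | None = None,
                       gene_id: str = "geneX", chrom: str = "chr1",
                       genomic_start: int = 0,
                       max_attempts: int = 200
                       ) -> tuple[Utr3Record, Variant | None, PlantedTruth]:
    """Background sequence at the given GC with exact planted sites.

    The background is rejection-sampled so that, for every catalog miRNA,
    the taxonomy scan of the reference sequence recovers exactly the
    planted site list; the SNP's alleles are then chosen (again under
    rejection) to realize the requested effect and nothing else.
    """
    catalog = list(catalog) if catalog is not None else []
    for mir, _, _ in planted:
        if mir.name not in {m.name for m in catalog}:
            catalog.append(mir)
    if snp_spec and snp_spec.mir and \
            snp_spec.mir.name not in {m.name for m in catalog}:
        catalog.append(snp_spec.mir)

    spans = []
    for mir, stype, pos in planted:
        w = SITE_WIDTH[stype]
        if pos < 0 or pos + w > length:
            raise ValueError(f"planted site at {pos} does not fit in UTR")
        spans.append((pos, pos + w))
    for (s1, e1) in spans:
        for (s2, e2) in spans:
            if (s1, e1) != (s2, e2) and s1 < e2 and s2 < e1:
                raise ValueError("planted sites overlap")

    rng = _rng(seed)
    p_gc = gc_content / 2.0
    probs = [(1 - gc_content) / 2, p_gc, p_gc, (1 - gc_content) / 2]

    expected_ref = {(mir.name, stype, pos) for mir, stype, pos in planted}

    for _ in range(max_attempts):
        seq = rng.choice(BASES, size=length, p=probs)
        for mir, stype, pos in planted:
            site = site_sequence(mir, stype)
            seq[pos:pos + len(site)] = list(site)
        result = _try_realize_snp(seq, snp_spec, expected_ref, catalog,
                                  length, rng)
        if result is None:
            continue
        seq, snp_offset, ref_base, alt_base, effect_exact = result
        sequence = "".join(seq)
        utr = Utr3Record(gene_id, sequence,
                         np.arange(genomic_start, genomic_start + length),
                         chrom=chrom, strand="+")
        variant = None
        if snp_spec is not None:
            variant = Variant(chrom, genomic_start + snp_offset, snp_spec.rsid,
                              ref_base, alt_base, maf=snp_spec.maf)
        truth = PlantedTruth(sorted(expected_ref), snp_offset,
                             snp_spec.mir.name if snp_spec and snp_spec.mir else None,
                             snp_spec.effect if snp_spec else "none",
                             effect_exact)
        return utr, variant, truth
    raise RuntimeError(
        f"could not realize a clean UTR in {max_attempts} attempts; "
        "try a longer UTR or fewer catalog miRNAs"
    )


def _try_realize_snp(seq: np.ndarray, spec: SnpSpec | None,
                     expected_ref: set, catalog: list[MicroRNA],
                     length: int, rng: np.random.Generator):
    """Place the SNP on one background draw; None means redraw background."""

    def scan_set(s: np.ndarray) -> set:
        return _site_set(scan_taxonomy("".join(s), catalog))

    if spec is None:
        if scan_set(seq) != expected_ref:
            return None
        return seq, None, "A", "C", "none"

    planted_sorted = sorted(expected_ref)

    if spec.effect == "create":
        site = site_sequence(spec.mir, spec.site_type)
        pos = spec.position
        if pos is None:
            raise ValueError("create effect needs an explicit position")
        seed_offs = _seed_offsets(spec.site_type, pos)
        created = (spec.mir.name, spec.site_type, pos)
        for off in rng.permutation(seed_offs):
            site_base = site[off - pos]
            for ref_base in rng.permutation([b for b in "ACGT" if b != site_base]):
                trial = seq.copy()
                trial[pos:pos + len(site)] = list(site)
                trial[off] = ref_base
                alt = trial.copy()
                alt[off] = site_base
                if scan_set(trial) == expected_ref and \
                        scan_set(alt) == expected_ref | {created}:
                    exact = "none" if spec.site_type == "7mer_A1" else "create"
                    return trial, int(off), ref_base, site_base, exact
        return None

    if spec.effect in ("abolish", "change"):
        mir_name, stype, pos = planted_sorted[spec.site_index] \
            if spec.mir is None else next(
                t for t in planted_sorted if t[0] == spec.mir.name)
        target = (mir_name, stype, pos)
        if spec.effect == "change":
            if stype != "8mer":
                raise ValueError("change effect requires a planted 8mer site")
            off = pos + 7  # the A opposite miR position 1
            expected_alt = (expected_ref - {target}) | {(mir_name, "7mer_m8", pos)}
            candidates = [b for b in "CGT"]
        else:
            offs = _seed_offsets(stype, pos)
            off = int(rng.choice(offs))
            expected_alt = expected_ref - {target}
            candidates = [b for b in "ACGT" if b != seq[off]]
        for alt_base in rng.permutation(candidates):
            alt = seq.copy()
            alt[off] = alt_base
            if scan_set(seq) == expected_ref and scan_set(alt) == expected_alt:
                if spec.effect == "change":
                    exact = "change"
                else:
                    exact = "none" if stype == "7mer_A1" else "abolish"
                return seq, int(off), str(seq[off]), alt_base, exact
        return None

    if spec.effect == "none":
        if scan_set(seq) != expected_ref:
            return None
        blocked = np.zeros(length, dtype=bool)
        for _, stype, pos in planted_sorted:
            lo = max(0, pos - 8)
            hi = min(length, pos + SITE_WIDTH[stype] + 8)
            blocked[lo:hi] = True
        free = np.nonzero(~blocked)[0]
        if len(free) == 0:
            raise ValueError("no background position available for a neutral SNP")
        offs = [spec.position] if spec.position is not None \
            else list(rng.permutation(free))
        for off in offs:
            ref_base = str(seq[off])
            for alt_base in rng.permutation([b for b in "ACGT" if b != ref_base]):
                alt = seq.copy()
                alt[off] = alt_base
                if scan_set(alt) == expected_ref:
                    return seq, int(off), ref_base, alt_base, "none"
        return None

    raise ValueError(f"unknown snp effect {spec.effect!r}")


# ---------------------------------------------------------------------------
# Whole-scenario generation


@dataclass
class GeneScenario:
    """One gene cassette: a planted cis-eQTL whose 3'-UTR proxy carries a
    planted miRNA-site effect."""

    gene_id: str
    tissue: str = "liver"
    beta: float = 1.0
    sigma: float = 0.5
    lead_maf: float = 0.3
    target_r2: float = 1.0
    site_type: str = "8mer"
    snp_effect: str = "abolish"
    mir_index: int = 0
    n_decoys: int = 4


@dataclass
class ScenarioSpec:
    """Complete synthetic study: genes, samples, miRNA catalog, tissues."""

    n_samples: int = 200
    n_mirs: int = 8
    utr_length: int = 300
    gc_content: float = 0.5
    tissues: dict[str, list[str] | str] = field(
        default_factory=lambda: {"liver": "all"})
    genes: list[GeneScenario] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        genes = [GeneScenario(**g) for g in raw.pop("genes", [])]
        return cls(genes=genes, **raw)


#: genomic layout constants for generated gene cassettes (bp)
_GENE_SPACING = 2_000_000
_EXON_OFFSET = 10_000
_UTR5_LEN = 300
_CDS_LEN = 600


def simulate_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Generate the full fixture set for a scenario and write it to disk.

    Writes a phased VCF panel, per-tissue expression TSVs, a GTF, the
    3'-UTR FASTA, the miRNA catalog and per-tissue miRNA expression
    tables, plus a manifest consumed by ``run_pipeline`` and a ground
    truth JSON for validation.
    """
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = gen_mir_catalog(spec.n_mirs, child_seed(spec.seed, 0))
    n_hap = 2 * spec.n_samples

    models: list[GeneModel] = []
    utr_seqs: dict[str, str] = {}
    all_variants: list[tuple[Variant, np.ndarray]] = []
    truth: dict = {"genes": {}}
    expr_cols: dict[str, dict[str, np.ndarray]] = {t: {} for t in spec.tissues}

    for gi, g in enumerate(spec.genes):
        base = gi * _GENE_SPACING + 1_000_000
        exon_start = base + _EXON_OFFSET
        cds_start = exon_start + _UTR5_LEN
        cds_end = cds_start + _CDS_LEN
        exon_end = cds_end + spec.utr_length
        model = GeneModel(g.gene_id, "chr1", "+",
                          exons=[(exon_start, exon_end)],
                          cds=[(cds_start, cds_end)])
        models.append(model)

        mir = catalog[g.mir_index % len(catalog)]
        site_pos = spec.utr_length // 2
        planted = [] if g.snp_effect == "create" else \
            [(mir, g.site_type, site_pos)]
        snp = SnpSpec(effect=g.snp_effect, mir=mir, site_type=g.site_type,
                      position=site_pos if g.snp_effect == "create" else None,
                      rsid=f"rs_utr_{g.gene_id}", maf=min(g.lead_maf, 0.5))
        utr, proxy, planted_truth = gen_utr_with_sites(
            spec.utr_length, planted, snp, spec.gc_content,
            child_seed(spec.seed, 10 + gi), catalog,
            gene_id=g.gene_id, chrom="chr1", genomic_start=cds_end)
        utr_seqs[g.gene_id] = utr.sequence

        lead_pos = exon_start - 1_000  # upstream of the TSS, inside the flank
        pair = gen_haplotype_pair(
            n_hap, g.lead_maf, g.lead_maf, g.target_r2, 1,
            child_seed(spec.seed, 20 + gi), chrom="chr1",
            positions=(lead_pos, proxy.pos),
            rsids=(f"rs_lead_{g.gene_id}", proxy.rsid),
            alleles=(("A", "G"), (proxy.ref_allele, proxy.alt_allele)))
        all_variants.append((pair.variants[0], pair.column(0)))
        all_variants.append((proxy, pair.column(1)))

        rng = _rng(child_seed(spec.seed, 30 + gi))
        decoy_positions = sorted(
            rng.choice(np.arange(base + 1_000, base + 400_000), size=g.n_decoys,
                       replace=False))
        for di, dpos in enumerate(decoy_positions):
            dmaf = float(rng.uniform(0.1, 0.5))
            dos = gen_genotypes(spec.n_samples, dmaf,
                                rng.integers(0, 2**31 - 1))
            # random phase split of the dosage into two haplotypes
            h1 = np.where(dos == 2, 1, np.where(dos == 1,
                                                rng.integers(0, 2, spec.n_samples),
                                                0)).astype(np.int8)
            h2 = (dos - h1).astype(np.int8)
            hap = np.empty(n_hap, dtype=np.int8)
            hap[0::2], hap[1::2] = h1, h2
            dv = Variant("chr1", int(dpos), f"rs_bg_{g.gene_id}_{di}",
                         "C", "T", maf=min(dmaf, 1 - dmaf))
            all_variants.append((dv, hap))

        lead_dosage = pair.column(0)[0::2] + pair.column(0)[1::2]
        for ti, tissue in enumerate(spec.tissues):
            beta = g.beta if tissue == g.tissue else 0.0
            expr_cols[tissue][g.gene_id] = gen_expression_with_eqtl(
                lead_dosage, beta, g.sigma,
                child_seed(spec.seed, 100 + 10 * gi + ti))

        truth["genes"][g.gene_id] = {
            "lead_rsid": f"rs_lead_{g.gene_id}",
            "proxy_rsid": proxy.rsid,
            "tissue": g.tissue,
            "beta": g.beta,
            "target_r2": g.target_r2,
            "mir": mir.name,
            "effect_taxonomy": planted_truth.effect_taxonomy,
            "effect_exact": planted_truth.effect_exact,
            "planted_sites": planted_truth.sites,
            "snp_offset": planted_truth.snp_offset,
        }

    # assemble the position-sorted panel
    all_variants.sort(key=lambda t: t[0].pos)
    variants = [v for v, _ in all_variants]
    alleles = np.stack([col for _, col in all_variants], axis=1) \
        if all_variants else np.zeros((n_hap, 0), dtype=np.int8)
    hap_ids = [f"s{i}_{k}" for i in range(spec.n_samples) for k in (1, 2)]
    panel = HaplotypePanel(hap_ids, variants, alleles)
    io.write_haplotype_panel(panel, out / "panel.vcf")

    sample_ids = [f"s{i}" for i in range(spec.n_samples)]
    manifest = {
        "panel": "panel.vcf",
        "genes": "genes.gtf",
        "utr_fasta": "utr3.fa",
        "mir_catalog": "mir_catalog.tsv",
        "genes_of_interest": "genes_of_interest.tsv",
        "expression": {},
        "mir_expression": {},
    }
    for ti, tissue in enumerate(spec.tissues):
        cols = expr_cols[tissue]
        gene_ids = [g.gene_id for g in spec.genes]
        values = np.stack([cols[gid] for gid in gene_ids], axis=1)
        expr = ExpressionMatrix(sample_ids, gene_ids, values, tissue=tissue)
        io.write_expression_tsv(expr, out / f"expr_{tissue}.tsv")
        manifest["expression"][tissue] = f"expr_{tissue}.tsv"

        detected = spec.tissues[tissue]
        if detected == "all":
            detected = [m.name for m in catalog]
        mir_expr = gen_mir_expression(catalog, tissue, detected,
                                      child_seed(spec.seed, 200 + ti))
        io.write_expression_tsv(mir_expr, out / f"mir_expr_{tissue}.tsv")
        manifest["mir_expression"][tissue] = f"mir_expr_{tissue}.tsv"

    io.write_gtf(models, out / "genes.gtf")
    io.write_fasta(utr_seqs, out / "utr3.fa")
    io.write_mir_catalog(catalog, out / "mir_catalog.tsv")
    goi = "\n".join(["gene_id"] + [g.gene_id for g in spec.genes]) + "\n"
    (out / "genes_of_interest.tsv").write_text(goi)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
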