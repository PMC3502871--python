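"""Readers and writers for the formats the pipeline touches.

VCF (phased GT), GTF2.2 and BED12 gene models, FASTA 3'-UTR sequences,
and tab-delimited tables (expression matrices, miRNA catalogs, stage
results). Native coordinate conventions are converted to the internal
0-based half-open convention on read and restored on write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DNA,
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    HaplotypePanel,
    MicroRNA,
    Utr3Record,
    Variant,
    compute_maf,
)

log = logging.getLogger("mirqtl")

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# VCF haplotype panels


def read_haplotype_panel(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a haplotype panel.

    Only biallelic SNPs are kept; indels and multi-allelic records are
    skipped with a logged count. Any unphased or missing genotype raises,
    naming the offending record.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    hap_ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    last_pos: dict[str, int] = {}
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1 \
                or rec.REF not in DNA or alts[0] not in DNA:
            n_skipped += 1
            continue
        rsid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if rec.CHROM in last_pos and rec.POS <= last_pos[rec.CHROM]:
            raise ValueError(f"positions not strictly increasing at {rsid}")
        last_pos[rec.CHROM] = rec.POS
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a1, a2, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise ValueError(f"unphased genotype for sample {samples[i]} at {rsid}")
            if a1 < 0 or a2 < 0:
                raise ValueError(f"missing genotype for sample {samples[i]} at {rsid}")
            col[2 * i], col[2 * i + 1] = a1, a2
        variants.append(
            Variant(rec.CHROM, rec.POS - 1, rsid, rec.REF, alts[0],
                    maf=_folded(col.mean()))
        )
        columns.append(col)
    vcf.close()
    if n_skipped:
        log.info("read_haplotype_panel: skipped %d non-SNP/multi-allelic records",
                 n_skipped)
    alleles = (np.stack(columns, axis=1) if columns
               else np.zeros((len(hap_ids), 0), dtype=np.int8))
    return HaplotypePanel(hap_ids, variants, alleles, n_skipped=n_skipped)


def _folded(p: float) -> float:
    return min(float(p), 1.0 - float(p))


def write_haplotype_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a phased VCF v4.2 text file."""
    sample_ids = [hid.rsplit("_", 1)[0] for hid in panel.haplotype_ids[0::2]]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for j, v in enumerate(panel.variants):
        col = panel.column(j)
        gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}"
                        for i in range(len(sample_ids)))
        lines.append(f"{v.chrom}\t{v.pos + 1}\t{v.rsid}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotype_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased dosages as a VCF (0/0, 0/1, 1/1, ./.)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(v.chrom for v in g.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids))
    for j, v in enumerate(g.variants):
        gts = "\t".join(gt_of[int(d)] for d in g.column(j))
        lines.append(f"{v.chrom}\t{v.pos + 1}\t{v.rsid}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene models: GTF2.2 and BED12


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF or BED12, deciding by content.

    Both dialects yield identical internal models for equivalent records.
    """
    path = Path(path)
    first = ""
    with path.open() as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    nfields = len(first.rstrip("\n").split("\t"))
    if nfields == 12:
        return read_bed12(path)
    return read_gtf(path)


def read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    strand: dict[str, str] = {}
    chrom: dict[str, str] = {}
    transcripts: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GTF line: {line.strip()!r}")
            feature = f[2]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attrs(f[8])
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"GTF record without gene_id: {line.strip()!r}")
            transcripts.setdefault(gid, set()).add(attrs.get("transcript_id", gid))
            iv = (int(f[3]) - 1, int(f[4]))  # 1-based closed -> half-open
            (exons if feature == "exon" else cds).setdefault(gid, []).append(iv)
            strand[gid] = f[6]
            chrom[gid] = f[0]
    models = []
    for gid in chrom:
        if len(transcripts[gid]) > 1:
            raise ValueError(f"{gid}: multiple transcripts not supported")
        if gid not in exons:
            raise ValueError(f"{gid}: transcript has CDS but no exon lines")
        models.append(GeneModel(gid, chrom[gid], strand[gid],
                                exons[gid], cds.get(gid, [])))
    return models


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    lines = []
    for m in models:
        for s, e in m.exons:
            lines.append(_gtf_line(m, "exon", s, e))
        for s, e in m.cds:
            lines.append(_gtf_line(m, "CDS", s, e))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_line(m: GeneModel, feature: str, s: int, e: int) -> str:
    attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
    return (f"{m.chrom}\tmirqtl\t{feature}\t{s + 1}\t{e}\t.\t{m.strand}\t"
            f"{'0' if feature == 'CDS' else '.'}\t{attrs}")


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError(f"BED12 line with {len(f)} fields: {line.strip()!r}")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + off, start + off + size)
                     for off, size in zip(starts, sizes)]
            cds = []
            if thick_e > thick_s:
                for s, e in exons:
                    cs, ce = max(s, thick_s), min(e, thick_e)
                    if cs < ce:
                        cds.append((cs, ce))
            models.append(GeneModel(name, chrom, strand, exons, cds))
    return models


def write_bed12(models: list[GeneModel], path: str | Path) -> None:
    lines = []
    for m in models:
        start, end = m.start, m.end
        if m.cds:
            thick_s = min(s for s, _ in m.cds)
            thick_e = max(e for _, e in m.cds)
        else:
            thick_s = thick_e = start
        sizes = ",".join(str(e - s) for s, e in m.exons)
        offs = ",".join(str(s - start) for s, _ in m.exons)
        lines.append(f"{m.chrom}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\t"
                     f"{thick_s}\t{thick_e}\t0\t{len(m.exons)}\t{sizes}\t{offs}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA 3'-UTRs


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def build_utr3_record(model: GeneModel, sense_sequence: str) -> Utr3Record:
    """Attach a sense-orientation 3'-UTR sequence to its genomic map."""
    positions: list[int] = []
    for s, e in model.utr3:
        positions.extend(range(s, e))
    if model.strand == "-":
        positions = positions[::-1]
    if len(positions) != len(sense_sequence):
        raise ValueError(
            f"{model.gene_id}: UTR sequence length {len(sense_sequence)} != "
            f"annotated 3'-UTR length {len(positions)}"
        )
    return Utr3Record(model.gene_id, sense_sequence, np.asarray(positions),
                      chrom=model.chrom, strand=model.strand)


# ---------------------------------------------------------------------------
# Tab-delimited tables


def write_tsv(df: pd.DataFrame, path: str | Path,
              header: dict[str, object] | None = None) -> None:
    """Write a result table with optional '# key: value' header comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_expression_tsv(path: str | Path, tissue: str = "other") -> ExpressionMatrix:
    """Samples x features TSV; first column holds sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy(float), tissue=tissue)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_mir_catalog(path: str | Path) -> list[MicroRNA]:
    """miRNA catalog TSV with columns name, mature_sequence (RNA or DNA)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"name", "mature_sequence"} <= set(df.columns):
        raise ValueError("miR catalog needs columns 'name' and 'mature_sequence'")
    return [MicroRNA(str(r["name"]), str(r["mature_sequence"]))
            for _, r in df.iterrows()]


def write_mir_catalog(catalog: list[MicroRNA], path: str | Path) -> None:
    df = pd.DataFrame({"name": [m.name for m in catalog],
                       "mature_sequence": [m.mature_sequence for m in catalog]})
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[Variant]:
    df = read_tsv(path)
    return [Variant(str(r["chrom"]), int(r["pos"]) - 1, str(r["rsid"]),
                    str(r["ref"]), str(r["alt"]), maf=float(r.get("maf", 0.0)))
            for _, r in df.iterrows()]


def write_variants_tsv(variants: list[Variant], path: str | Path,
                       header: dict[str, object] | None = None) -> None:
    df = pd.DataFrame({
        "rsid": [v.rsid for v in variants],
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos + 1 for v in variants],  # 1-based on disk
        "ref": [v.ref_allele for v in variants],
        "alt": [v.alt_allele for v in variants],
        "maf": [v.maf for v in variants],
    })
    write_tsv(df, path, header=header)
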