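"""Readers and writers for the pipeline's on-disk formats.

FASTA (80-column wrap), GFF3 (gene + CDS features, 1-based closed
coordinates), FASTQ (PHRED+33, constant quality), minimal VCF 4.2 for
SNPs, and TSV/BED/JSON for blocks, windows, truth tables, presence
matrices and run manifests. Internal coordinates are 0-based half-open
everywhere; conversion happens only at the GFF3/VCF boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .anchor_align import AlignmentBlock, SharedSequenceRecord
from .divergence import SnpRecord, SvRecord, WindowStat
from .simgenome import GeneModel, GenomeAssembly, SimRead


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(path, records: list[tuple[str, str]], wrap: int = 80) -> None:
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in records)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(path, reads: list[SimRead], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def read_fastq(path) -> list[SimRead]:
    return [SimRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path, assembly: GenomeAssembly) -> None:
    """gene + CDS rows per gene model; GFF3 is 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in assembly.chromosomes:
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(assembly.genes, key=lambda g: (g.chrom, g.start)):
            start, end = g.start + 1, g.end
            fh.write(f"{g.chrom}\tbathypan\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tbathypan\tCDS\t{start}\t{end}\t.\t"
                     f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(GeneModel(attrs.get("ID", ""), f[0],
                                   int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def attach_cds(assembly: GenomeAssembly) -> None:
    from .simgenome import _fill_cds
    _fill_cds(assembly)


# ---------------------------------------------------------------------------
# VCF / TSV / BED
# ---------------------------------------------------------------------------

def write_vcf(path, snps: list[SnpRecord], contigs: dict[str, int]) -> None:
    """Minimal VCF 4.2: CHROM/POS/REF/ALT, 1-based positions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s.ref_chrom}\t{s.position + 1}\t.\t{s.ref_base}\t"
                     f"{s.alt_base}\t.\tPASS\tSTRAIN={s.query_strain}\n")


def blocks_to_frame(blocks: list[AlignmentBlock]) -> pd.DataFrame:
    return pd.DataFrame([{
        "ref_chrom": b.ref_chrom, "ref_start": b.ref_start,
        "ref_end": b.ref_end, "qry_chrom": b.qry_chrom,
        "qry_start": b.qry_start, "qry_end": b.qry_end, "strand": b.strand,
        "aligned_length": b.aligned_length, "identity": round(b.identity, 6),
        "n_mismatch": b.n_mismatch, "n_gapcols": b.n_gapcols,
        "class": b.class_label} for b in blocks])


def write_blocks_tsv(path, blocks: list[AlignmentBlock]) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def write_windows_tsv(path, windows: list[WindowStat]) -> None:
    pd.DataFrame([{
        "chrom": w.chrom, "start": w.start, "end": w.end,
        "n_variants": w.n_variants, "density": w.density,
        "ratio": w.ratio} for w in windows]).to_csv(path, sep="\t", index=False)


def write_svs_tsv(path, svs: list[SvRecord]) -> None:
    pd.DataFrame([{
        "type": s.type, "ref_chrom": s.ref_chrom, "ref_start": s.ref_start,
        "ref_end": s.ref_end, "qry_start": s.qry_start, "qry_end": s.qry_end,
        "strain": s.query_strain} for s in svs]).to_csv(path, sep="\t",
                                                        index=False)


def write_bed(path, intervals: list[tuple[str, int, int]],
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            label = names[i] if names else f"region{i}"
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def write_chords_json(path, records: list[SharedSequenceRecord]) -> None:
    payload = [{
        "strain_a": r.strain_a, "strain_b": r.strain_b,
        "start_a": r.start_a, "end_a": r.end_a,
        "start_b": r.start_b, "end_b": r.end_b,
        "length": r.length, "identity": round(r.identity, 6)} for r in records]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_presence_tsv(path, matrix) -> None:
    matrix.matrix.to_csv(path, sep="\t", index_label="strain")


def write_truth_tables(outdir, truth, prefix: str = "truth") -> None:
    outdir = Path(outdir)
    if truth.snps:
        pd.DataFrame(truth.snps, columns=[
            "chrom", "parent_pos", "child_pos", "ref", "alt"]).to_csv(
            outdir / f"{prefix}_snps.tsv", sep="\t", index=False)
    if truth.svs:
        pd.DataFrame(truth.svs, columns=[
            "type", "chrom", "parent_start", "parent_end",
            "child_start", "child_end"]).to_csv(
            outdir / f"{prefix}_svs.tsv", sep="\t", index=False)
    if truth.mixture_origins:
        pd.DataFrame(truth.mixture_origins, columns=[
            "read_id", "strain", "chrom", "pos", "strand"]).to_csv(
            outdir / f"{prefix}_read_origins.tsv", sep="\t", index=False)


def write_manifest(path, config, seed: int, extras: dict | None = None) -> None:
    from dataclasses import asdict, is_dataclass
    payload = {
        "seed": seed,
        "config": asdict(config) if is_dataclass(config) else dict(config),
    }
    if extras:
        payload.update(extras)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
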