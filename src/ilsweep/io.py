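"""Readers and writers for the plain-text genomics formats used here.

ILS tracks travel as bedGraph (4 columns) or an extended 5-column TSV that
carries the aligned fraction; called regions as BED (0-based half-open) or
GFF3 (1-based inclusive); interval sets as BED with a chrom.sizes companion;
haplotype panels as uncompressed VCF (written directly, read through pysam);
alignments as FASTA through Biopython.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import HaplotypePanel
from .intervals import IntervalSet
from .regions import IlsTrack, RegionSet

__all__ = [
    "read_ils_track",
    "write_ils_track",
    "read_bed",
    "write_bed",
    "write_gff3",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
    "read_haplotype_panel_vcf",
    "write_haplotype_panel_vcf",
]


def write_ils_track(track: IlsTrack, path, bedgraph: bool = False) -> None:
    """Write a windowed ILS track as 5-column TSV (or plain 4-column bedGraph)."""
    w = track.windows
    cols = [w["start"], w["end"], w["ils"]]
    names = ["start", "end", "ils"]
    if not bedgraph:
        cols.append(w["aligned_fraction"])
        names.append("aligned_fraction")
    df = pd.DataFrame(dict(zip(names, cols)))
    df.insert(0, "chrom", track.chrom)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_ils_track(path, chrom: str | None = None) -> IlsTrack:
    """Read a track written by :func:`write_ils_track` (bedGraph or 5-column)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "ils"]
        df["aligned_fraction"] = 1.0
    elif df.shape[1] == 5:
        df.columns = ["chrom", "start", "end", "ils", "aligned_fraction"]
    else:
        raise ValueError("expected 4 or 5 tab-separated columns")
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("track file must describe exactly one chromosome")
    return IlsTrack(str(chroms[0]), df.drop(columns="chrom").reset_index(drop=True))


def write_bed(intervals, path, chrom: str | None = None) -> None:
    """Write an IntervalSet or RegionSet as BED (0-based half-open)."""
    if isinstance(intervals, RegionSet):
        df = intervals.intervals[["start", "end", "label"]].copy()
        df.insert(0, "chrom", intervals.chrom)
        if "mean_ils" in intervals.intervals:
            df["score"] = intervals.intervals["mean_ils"]
    else:
        df = pd.DataFrame({"start": intervals.starts, "end": intervals.ends})
        df.insert(0, "chrom", chrom if chrom is not None else intervals.chrom)
        if intervals.labels is not None:
            df["label"] = list(intervals.labels)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bed(path, chrom: str | None = None) -> IntervalSet:
    """Read a BED file into an :class:`IntervalSet` (one chromosome)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "label"})
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("BED file must describe exactly one chromosome (pass chrom=)")
    labels = tuple(df["label"]) if "label" in df.columns else None
    return IntervalSet(str(chroms[0]), df["start"].to_numpy(), df["end"].to_numpy(), labels)


def write_gff3(regions: RegionSet, path, source: str = "ilsweep", feature: str = "region") -> None:
    """Write called regions as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in regions.intervals.iterrows():
            attrs = f"ID={r['label']};mean_ils={r['mean_ils']:.4f}"
            fh.write(
                f"{regions.chrom}\t{source}\t{feature}\t{int(r['start']) + 1}\t"
                f"{int(r['end'])}\t.\t.\t.\t{attrs}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{int(length)}\n")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_haplotype_panel_vcf(panel: HaplotypePanel, path, chrom: str | None = None) -> None:
    """Write a haplotype panel as an uncompressed, phased VCF.

    Haplotypes are paired into diploid samples; an odd haplotype becomes a
    final haploid (hemizygous) sample.  All sites are biallelic A/G SNVs —
    the analyses here use only the 0/1 allele indicators.
    """
    chrom = chrom or (panel.chrom or "chrX")
    n_hap = panel.n_haplotypes
    n_dip = n_hap // 2
    samples = [f"S{i + 1}" for i in range(n_dip + (n_hap % 2))]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = int(panel.positions[-1]) + 1 if panel.n_sites else 1
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(panel.n_sites):
            alleles = panel.haplotypes[:, j]
            gts = [f"{alleles[2 * i]}|{alleles[2 * i + 1]}" for i in range(n_dip)]
            if n_hap % 2:
                gts.append(str(alleles[-1]))
            fh.write(
                f"{chrom}\t{int(panel.positions[j]) + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_haplotype_panel_vcf(path, population: str = "") -> HaplotypePanel:
    """Read a (plain or bgzipped) VCF into a haplotype panel.

    Diploid genotypes contribute two haplotypes, haploid calls one; only
    biallelic sites are accepted.
    """
    vf = pysam.VariantFile(os.fspath(path))
    positions = []
    rows = []
    chrom = ""
    for rec in vf.fetch() if vf.index is not None else vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"site at {rec.pos} is not biallelic")
        chrom = rec.chrom
        alleles = []
        for sample in rec.samples.values():
            gt = sample["GT"]
            for a in gt:
                if a is None:
                    raise ValueError(f"missing genotype at {rec.pos}")
                alleles.append(a)
        positions.append(rec.pos - 1)  # VCF is 1-based
        rows.append(alleles)
    vf.close()
    if not rows:
        return HaplotypePanel(np.array([], dtype=np.int64), np.zeros((0, 0), dtype=np.int8), population, chrom)
    hap = np.array(rows, dtype=np.int8).T
    return HaplotypePanel(np.array(positions), hap, population, chrom)
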