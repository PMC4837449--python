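"""Readers and writers for the standard formats the pipeline consumes.

FASTA via pyfaidx, VCF and SAM via pysam, tabular outputs via pandas.
All TSV writers use 0-based `start` and 1-based `end` columns for SNVs,
matching BED-style conventions.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam
from pyfaidx import Fasta

from .genome import CnvProfile, PersonalGenome, Variant

import numpy as np

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_personal_genome",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_cnv_tsv",
    "write_cnv_tsv",
]


def read_fasta(path: str) -> dict[str, str]:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_vcf(path: str) -> list[Variant]:
    """Load diploid variant calls; GT is required, multi-allelic sites take
    the first ALT (the rest are dropped with a warning on the record)."""
    out: list[Variant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            gt = tuple(min(int(a), 1) for a in gt)
            out.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    genotype=gt,
                    phased=bool(sample.phased),
                )
            )
    return out


def write_vcf(path: str, variants: list[Variant], contigs: dict[str, int],
              sample: str = "SAMPLE") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            sep = "|" if v.phased else "/"
            gt = sep.join(str(g) for g in v.genotype)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    """BED intervals (0-based half-open), first three columns required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "name"})
    return df


def write_personal_genome(genome: PersonalGenome, outdir: str) -> None:
    """Per-haplotype FASTA plus a liftover-block TSV."""
    os.makedirs(outdir, exist_ok=True)
    for h in (1, 2):
        write_fasta(
            os.path.join(outdir, f"haplotype{h}.fa"),
            {c: genome.sequence(c, h) for c in sorted(genome.haplotypes)},
        )
    rows = []
    for chrom in sorted(genome.maps):
        for h in (1, 2):
            for hap_start, ref_start, length in genome.coord_map(chrom, h).blocks:
                rows.append((chrom, hap_start, ref_start, length, h))
    pd.DataFrame(
        rows, columns=["chrom", "hap_start", "ref_start", "length", "haplotype"]
    ).to_csv(os.path.join(outdir, "liftover.tsv"), sep="\t", index=False)


def write_counts_tsv(path: str, counts) -> None:
    rows = [
        (
            c.chrom,
            c.pos - 1,
            c.pos,
            c.ref_allele,
            c.alt_allele,
            c.n_ref,
            c.n_alt,
            c.n_other,
            c.allelic_ratio if c.n > 0 else float("nan"),
        )
        for c in counts
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "ref", "alt", "n_ref", "n_alt", "n_other",
                 "allelic_ratio"],
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str):
    from .mapping import AllelicCount

    df = pd.read_csv(path, sep="\t")
    return [
        AllelicCount(
            chrom=r.chrom,
            pos=int(r.end),
            ref_allele=r.ref,
            alt_allele=r.alt,
            n_ref=int(r.n_ref),
            n_alt=int(r.n_alt),
            n_other=int(r.n_other),
        )
        for r in df.itertuples()
    ]


def write_cnv_tsv(path: str, profile: CnvProfile) -> None:
    rows = []
    for chrom, track in sorted(profile.normalized_depth.items()):
        for i, d in enumerate(track):
            rows.append((chrom, i * profile.window_size,
                         (i + 1) * profile.window_size, d))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "normalized_depth"]).to_csv(
        path, sep="\t", index=False
    )


def read_cnv_tsv(path: str) -> CnvProfile:
    df = pd.read_csv(path, sep="\t")
    window = int((df["end"] - df["start"]).iloc[0])
    tracks = {}
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        n_win = int(grp["end"].max() // window)
        track = np.full(n_win, 1.0)
        idx = (grp["start"] // window).to_numpy()
        track[idx] = grp["normalized_depth"].to_numpy()
        tracks[str(chrom)] = track
    return CnvProfile(window_size=window, normalized_depth=tracks)
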