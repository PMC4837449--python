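"""Synthetic fixtures: diploid genomes, reads and truth tables.

The generator emulates the data the pipeline is built for, fully
self-contained: a random reference with phased heterozygous SNVs (and
optionally short indels), reads drawn from the two haplotypes so that
per-site reference-allele proportions follow a beta-binomial around each
site's true ratio (rho = 0 gives plain binomial sampling), optional
sequencing errors, planted allele-specific sites with a chosen ratio, and
an optional segmental duplication engineered to provoke ambiguous mapping
at one het SNV.

Heterozygous SNVs are spaced at least two read lengths apart so each read
overlaps a single SNV, making the per-site read counts exactly the
beta-binomial draws the detection null assumes — a closed loop for
parameter-recovery tests.  Everything is a deterministic function of the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ReadAlignment, align_reads_to_haplotype
from .genome import PersonalGenome, Variant, build_diploid

__all__ = ["DuplicationSpec", "SimulationConfig", "SimulatedSample",
           "simulate_sample", "simulate_reads", "simulate_counts",
           "align_sample_reads", "write_sample"]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DuplicationSpec:
    """A near-exact paralog of one het SNV's neighbourhood.

    A window of ``length`` bases centred on a dedicated het SNV is copied to
    the end of the chromosome, carrying the SNV's *alternate* allele (the
    shared allele).  ``n_divergent`` adjacent bases are mutated in the copy
    at ``divergent_offset`` bases left of the SNV; reads whose window misses
    them align to both loci and multimap.  With a two-mismatch budget,
    ``n_divergent`` >= 3 makes divergence-covering reads unique.
    """

    length: int = 120
    divergent_offset: int = 30
    n_divergent: int = 3


@dataclass
class SimulationConfig:
    genome_length: int = 20_000
    n_het_snvs: int = 40
    indel_rate: float = 0.0  # het indels per SNV interval
    duplication: DuplicationSpec | None = None
    depth: int = 50
    read_length: int = 50
    rho: float = 0.0
    n_planted_as: int = 0
    planted_ratio: float = 0.9
    error_rate: float = 0.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self):
        for name in ("indel_rate", "rho", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        spacing = 2 * self.read_length + 10
        margin = 2 * (self.read_length + 10)
        needed = self.n_het_snvs * spacing + 2 * margin
        if self.duplication is not None:
            needed += self.duplication.length + spacing + 2 * self.read_length
        if needed > self.genome_length:
            raise ValueError(
                f"genome_length {self.genome_length} too small for "
                f"{self.n_het_snvs} SNVs (need >= {needed})"
            )
        if self.n_planted_as > self.n_het_snvs:
            raise ValueError("more planted AS sites than het SNVs")


@dataclass
class SimulatedSample:
    config: SimulationConfig
    reference: dict[str, str]
    variants: list[Variant]
    genome: PersonalGenome
    truth: pd.DataFrame  # chrom, pos, ref, alt, true_ratio, is_as, in_duplication
    dup_snv_pos: int | None = None
    reads: list[tuple[str, str, int]] = field(default_factory=list)

    def het_snvs(self) -> list[Variant]:
        return [v for v in self.variants if v.is_het and v.is_snv]


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """Random reference + phased variants + truth table, seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = list(rng.choice(BASES, size=L))
    R = config.read_length
    spacing = 2 * R + 10
    margin = 2 * (R + 10)

    n_sites = config.n_het_snvs
    positions0 = [margin + i * spacing for i in range(n_sites)]  # 0-based

    variants: list[Variant] = []
    truth_rows = []
    as_flags = np.zeros(n_sites, dtype=bool)
    as_flags[: config.n_planted_as] = True
    rng.shuffle(as_flags)

    dup_pos0 = None
    dup = config.duplication
    if dup is not None:
        dup_pos0 = positions0[-1]

    for i, p0 in enumerate(positions0):
        ref_base = seq[p0]
        alt_base = _mutate(ref_base, rng)
        variants.append(
            Variant(config.chrom, p0 + 1, ref_base, alt_base, (0, 1), phased=True)
        )
        ratio = config.planted_ratio if as_flags[i] else 0.5
        truth_rows.append(
            (config.chrom, p0 + 1, ref_base, alt_base, ratio, bool(as_flags[i]),
             p0 == dup_pos0)
        )

    # het indels between SNV intervals (phased, ALT on haplotype 2)
    n_indels = int(round(config.indel_rate * n_sites))
    for j in range(n_indels):
        p0 = positions0[j] + spacing // 2
        anchor = seq[p0]
        if rng.integers(0, 2) == 0:  # insertion
            ins = "".join(rng.choice(BASES, size=2))
            variants.append(
                Variant(config.chrom, p0 + 1, anchor, anchor + ins, (0, 1), True)
            )
        else:  # 2-bp deletion
            ref = "".join(seq[p0 : p0 + 3])
            variants.append(
                Variant(config.chrom, p0 + 1, ref, ref[0], (0, 1), True)
            )

    # engineered paralog: copy of the dup SNV's neighbourhood with the
    # alternate allele, diverged at a block of adjacent bases
    if dup is not None:
        half = dup.length // 2
        window = seq[dup_pos0 - half : dup_pos0 + dup.length - half]
        center = half
        dup_var = variants[n_sites - 1]
        window[center] = truth_rows[-1][3]  # alt allele is shared
        for k in range(dup.n_divergent):
            off = center - dup.divergent_offset - k
            window[off] = _mutate(window[off], rng)
        insert_at = L - dup.length - R
        seq[insert_at : insert_at + dup.length] = window
        # re-check no variant falls into the overwritten tail
        assert positions0[-1] + spacing < insert_at

    reference = {config.chrom: "".join(seq)}
    variants.sort(key=lambda v: v.pos)
    genome = build_diploid(reference, variants, seed=config.seed)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "true_ratio", "is_as",
                 "in_duplication"],
    )
    return SimulatedSample(
        config=config, reference=reference, variants=variants, genome=genome,
        truth=truth, dup_snv_pos=None if dup_pos0 is None else dup_pos0 + 1,
    )


def simulate_reads(sample: SimulatedSample) -> list[tuple[str, str, int]]:
    """Reads around each het SNV: (read_id, sequence, true haplotype).

    Per site, the reference-allele proportion is drawn beta-binomially: a
    site-level probability p ~ Beta with mean = true ratio and the
    configured rho (degenerate at the ratio when rho = 0), then each of
    ``depth`` reads picks the haplotype carrying the reference allele with
    probability p.  Starts are uniform over windows covering the SNV;
    sequencing errors flip bases independently at ``error_rate``.
    """
    cfg = sample.config
    rng = np.random.default_rng(cfg.seed + 1)
    R = cfg.read_length
    genome = sample.genome
    reads: list[tuple[str, str, int]] = []
    for row in sample.truth.itertuples():
        ratio = row.true_ratio
        if cfg.rho > 0:
            a = ratio * (1 - cfg.rho) / cfg.rho
            b = (1 - ratio) * (1 - cfg.rho) / cfg.rho
            p_site = rng.beta(a, b) if a > 0 and b > 0 else float(ratio)
        else:
            p_site = ratio
        # haplotype 1 carries REF (planted variants are phased 0|1)
        hap_of_ref = 1
        for j in range(cfg.depth):
            from_ref = rng.random() < p_site
            hap = hap_of_ref if from_ref else 3 - hap_of_ref
            hp = genome.lift_to_hap(row.chrom, hap, row.pos - 1)
            hap_seq = genome.sequence(row.chrom, hap)
            start = int(rng.integers(max(0, hp - R + 1), hp + 1))
            start = min(start, len(hap_seq) - R)
            chars = list(hap_seq[start : start + R])
            if cfg.error_rate > 0:
                errs = np.flatnonzero(rng.random(R) < cfg.error_rate)
                for e in errs:
                    chars[e] = _mutate(chars[e], rng)
            reads.append((f"r_{row.pos}_{j}", "".join(chars), hap))
    sample.reads = reads
    return reads


def simulate_counts(
    n_sites: int,
    depth: int,
    rho: float,
    seed: int,
    ratio: float = 0.5,
    chrom: str = "chrS",
):
    """Direct beta-binomial allelic counts, bypassing reads and alignment.

    The cheap route for estimator calibration at scale: per site, k_ref is
    beta-binomial(depth, mean=ratio, rho).  Returns AllelicCount objects on
    synthetic coordinates.
    """
    from .mapping import AllelicCount

    rng = np.random.default_rng(seed)
    if rho > 0:
        a = ratio * (1 - rho) / rho
        b = (1 - ratio) * (1 - rho) / rho
        p = rng.beta(a, b, size=n_sites)
    else:
        p = np.full(n_sites, ratio)
    k = rng.binomial(depth, p)
    return [
        AllelicCount(chrom=chrom, pos=i + 1, ref_allele="A", alt_allele="C",
                     n_ref=int(k[i]), n_alt=int(depth - k[i]))
        for i in range(n_sites)
    ]


def align_sample_reads(
    sample: SimulatedSample,
    reads: list[tuple[str, str, int]] | None = None,
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Map simulated reads to both haplotypes with the fixture aligner."""
    if reads is None:
        reads = sample.reads or simulate_reads(sample)
    pairs = [(rid, seq) for rid, seq, _ in reads]
    alns = []
    for h in (1, 2):
        targets = {c: sample.genome.sequence(c, h) for c in sample.reference}
        alns.append(align_reads_to_haplotype(pairs, targets, h))
    return alns[0], alns[1]


def write_sample(sample: SimulatedSample, outdir: str) -> None:
    """FASTA + VCF + truth TSV (+ FASTQ and per-haplotype SAM if reads exist)."""
    import os

    from . import io as apio
    from .align import write_sam

    os.makedirs(outdir, exist_ok=True)
    apio.write_fasta(os.path.join(outdir, "reference.fa"), sample.reference)
    contigs = {c: len(s) for c, s in sample.reference.items()}
    apio.write_vcf(os.path.join(outdir, "sample.vcf"), sample.variants, contigs)
    sample.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    if sample.reads:
        with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
            for rid, seq, _ in sample.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        a1, a2 = align_sample_reads(sample)
        hap_contigs = {
            h: {c: len(sample.genome.sequence(c, h)) for c in sample.reference}
            for h in (1, 2)
        }
        write_sam(os.path.join(outdir, "hap1.sam"), a1, hap_contigs[1])
        write_sam(os.path.join(outdir, "hap2.sam"), a2, hap_contigs[2])
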