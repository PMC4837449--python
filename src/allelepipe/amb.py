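"""Ambiguous-mapping-bias (AMB) read filtering by haplotype-swap simulation.

At a locus with sequence homology elsewhere in the genome, reads carrying
one allele may align ambiguously (and be discarded by unique mapping) while
reads carrying the other allele map cleanly, producing a spurious allelic
imbalance.  The filter detects this per read: every uniquely mapped read
overlapping heterozygous SNVs (an "O read") is turned into simulated reads
("S reads") covering every alternative allele combination at those SNVs;
the S reads are re-mapped to the other parental haplotype with the same
mismatch budget and uniqueness rule.  If any S read multimaps, or maps
uniquely somewhere other than the equivalent position, the O read is
removed.  O reads whose observed base matches neither allele at some SNV
are removed as likely sequencing errors.

Removal is per read, never per site, so robust allele-specific signal at a
locus survives even when some of its reads are biased.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import FixtureAligner, ReadAlignment
from .genome import PersonalGenome, Variant
from .mapping import _SnvIndex

__all__ = [
    "ORead",
    "SRead",
    "enumerate_s_reads",
    "classify_o_read",
    "filter_reads",
    "MAX_SNVS_PER_READ",
]

MAX_SNVS_PER_READ = 5  # O reads over more het SNVs are dropped outright


@dataclass(frozen=True)
class OverlappedSnv:
    offset: int  # position within the read
    variant: Variant
    own_allele: str  # base this haplotype carries
    other_allele: str  # base the other haplotype carries
    other_hap_pos: int  # SNV position on the other haplotype


@dataclass
class ORead:
    """An original read together with the het SNVs it overlaps."""

    alignment: ReadAlignment
    overlapped: list[OverlappedSnv]

    @property
    def h(self) -> int:
        return len(self.overlapped)

    @property
    def observed_alleles(self) -> list[str]:
        return [self.alignment.sequence[s.offset] for s in self.overlapped]


@dataclass(frozen=True)
class SRead:
    parent_id: str
    pattern: tuple[int, ...]  # 1 where the allele was swapped
    sequence: str


def enumerate_s_reads(o: ORead) -> list[SRead]:
    """All 2^h - 1 haplotype variants of an O read.

    Each S read differs from the original only at overlapped SNV positions,
    where a subset of alleles is swapped to the other haplotype's base.
    """
    if o.h == 0:
        raise ValueError("O read overlaps no heterozygous SNV")
    if o.h > MAX_SNVS_PER_READ:
        raise ValueError(f"O read overlaps {o.h} > {MAX_SNVS_PER_READ} het SNVs")
    seq = o.alignment.sequence
    out = []
    for mask in range(1, 2**o.h):
        pattern = tuple((mask >> i) & 1 for i in range(o.h))
        chars = list(seq)
        for bit, s in zip(pattern, o.overlapped):
            if bit:
                chars[s.offset] = s.other_allele
        out.append(SRead(parent_id=o.alignment.read_id, pattern=pattern,
                         sequence="".join(chars)))
    return out


def classify_o_read(
    o: ORead,
    s_mappings: list[tuple[list[tuple[str, int, int]], bool]],
) -> tuple[bool, str | None]:
    """Decide keep/remove from the S reads' alignments to the other haplotype.

    ``s_mappings`` holds, per S read, the (best hits, multimapped) pair from
    the aligner.  Returns ``(keep, reason)``; reasons are ``amb_multi``
    (some S read multimaps), ``amb_displaced`` (some S read maps uniquely
    elsewhere) or ``seq_error`` (an observed base matches neither allele).
    S reads with no hit at all do not trigger removal.
    """
    for base, s in zip(o.observed_alleles, o.overlapped):
        v = s.variant
        if base not in (v.ref_allele, v.alt_allele):
            return False, "seq_error"
    if len(s_mappings) != 2**o.h - 1:
        raise ValueError(
            f"expected {2 ** o.h - 1} S-read mappings, got {len(s_mappings)}"
        )
    anchor = o.overlapped[0]
    expected = (
        o.alignment.chrom,
        anchor.other_hap_pos - anchor.offset,
    )
    for hits, multi in s_mappings:
        if multi:
            return False, "amb_multi"
        if not hits:
            continue  # unmapped S read: kept, logged by the caller
        chrom, start, _ = hits[0]
        if (chrom, start) != expected:
            return False, "amb_displaced"
    return True, None


def _build_o_reads(
    chosen: list[ReadAlignment],
    genome: PersonalGenome,
    het_snvs: list[Variant],
) -> tuple[list[ORead], list[ReadAlignment]]:
    """Split retained alignments into O reads and reads free of het SNVs."""
    index = _SnvIndex(genome, het_snvs)
    o_reads, untouched = [], []
    for aln in chosen:
        overlaps = index.overlapping(aln.chrom, aln.haplotype, aln.start, aln.end)
        if not overlaps:
            untouched.append(aln)
            continue
        other = 2 if aln.haplotype == 1 else 1
        entries = []
        liftable = True
        for hap_pos, v, own in overlaps:
            alleles = genome.snv_alleles_on_haps(v)
            other_allele = alleles[other - 1]
            other_hp = genome.lift_to_hap(v.chrom, other, v.start)
            if other_hp is None:
                liftable = False
                break
            entries.append(
                OverlappedSnv(
                    offset=hap_pos - aln.start,
                    variant=v,
                    own_allele=own,
                    other_allele=other_allele,
                    other_hap_pos=other_hp,
                )
            )
        if not liftable:
            untouched.append(aln)
            continue
        o_reads.append(ORead(alignment=aln, overlapped=entries))
    return o_reads, untouched


def filter_reads(
    chosen: list[ReadAlignment],
    genome: PersonalGenome,
    het_snvs: list[Variant],
) -> tuple[list[ReadAlignment], Counter]:
    """Remove AMB and sequencing-error reads from arbitrated alignments.

    Returns the kept alignments plus a Counter of removal reasons
    (``amb_multi``, ``amb_displaced``, ``seq_error``, ``excluded_complex``)
    and the audit count ``s_unmapped`` (kept reads with some unmapped
    S read).  The filter is idempotent.
    """
    o_reads, untouched = _build_o_reads(chosen, genome, het_snvs)
    aligners = {
        h: FixtureAligner({c: genome.sequence(c, h) for c in genome.haplotypes})
        for h in (1, 2)
    }
    kept = list(untouched)
    reasons: Counter = Counter()
    for o in o_reads:
        if o.h > MAX_SNVS_PER_READ:
            reasons["excluded_complex"] += 1
            continue
        other = 2 if o.alignment.haplotype == 1 else 1
        s_reads = enumerate_s_reads(o)
        s_mappings = [aligners[other].align(s.sequence) for s in s_reads]
        keep, reason = classify_o_read(o, s_mappings)
        if keep:
            if any(not hits and not multi for hits, multi in s_mappings):
                reasons["s_unmapped"] += 1
            kept.append(o.alignment)
        else:
            reasons[reason] += 1
    return kept, reasons
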