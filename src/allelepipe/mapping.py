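"""Arbitration of per-haplotype alignments and allelic counting at het SNVs.

Each read is aligned independently to both haplotypes of the personal
genome; the better (fewer-mismatch) alignment wins, ties are broken by a
seeded fair coin, and reads that multimap anywhere or need more than two
mismatches are dropped.  Allelic counts then tally, at every heterozygous
SNV, how many retained reads carry the reference vs the alternate base —
the allelic ratio n_ref/(n_ref+n_alt) is the quantity all downstream
statistics run on.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from collections import Counter

import numpy as np

from .align import MAX_MISMATCHES, ReadAlignment
from .genome import PersonalGenome, Variant

__all__ = ["AllelicCount", "arbitrate", "count_alleles"]


@dataclass
class AllelicCount:
    """Read tallies at one heterozygous SNV.

    ``n`` counts informative reads only (ref + alt); reads carrying a third
    base are recorded in ``n_other`` and never enter the allelic ratio.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    n_ref: int = 0
    n_alt: int = 0
    n_other: int = 0

    @property
    def n(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def allelic_ratio(self) -> float:
        if self.n == 0:
            raise ZeroDivisionError("no informative reads")
        return self.n_ref / self.n

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def arbitrate(
    alns_hap1: list[ReadAlignment],
    alns_hap2: list[ReadAlignment],
    seed: int,
) -> tuple[list[ReadAlignment], Counter]:
    """Choose one alignment per read between the two haplotypes.

    Returns the chosen alignments and a Counter of drop reasons
    (``multimapped``, ``too_many_mismatches``).  Tie-breaking consumes one
    draw from a seeded generator per tied read, in sorted read-id order, so
    the outcome is a deterministic function of the seed.
    """
    by_id: dict[str, dict[int, ReadAlignment]] = {}
    for aln in list(alns_hap1) + list(alns_hap2):
        by_id.setdefault(aln.read_id, {})[aln.haplotype] = aln

    rng = np.random.default_rng(seed)
    chosen: list[ReadAlignment] = []
    drops: Counter = Counter()
    for read_id in sorted(by_id):
        alns = by_id[read_id]
        if any(a.multimapped for a in alns.values()):
            drops["multimapped"] += 1
            continue
        valid = {h: a for h, a in alns.items() if a.mismatches <= MAX_MISMATCHES}
        if not valid:
            drops["too_many_mismatches"] += 1
            continue
        if len(valid) == 1:
            chosen.append(next(iter(valid.values())))
            continue
        a1, a2 = valid[1], valid[2]
        if a1.mismatches < a2.mismatches:
            chosen.append(a1)
        elif a2.mismatches < a1.mismatches:
            chosen.append(a2)
        else:
            chosen.append(a1 if rng.integers(0, 2) == 0 else a2)
    return chosen, drops


class _SnvIndex:
    """Per (chrom, haplotype) sorted index of het-SNV haplotype positions."""

    def __init__(self, genome: PersonalGenome, het_snvs: list[Variant]):
        self._pos: dict[tuple[str, int], list[int]] = {}
        self._var: dict[tuple[str, int], list[tuple[Variant, str]]] = {}
        self.skipped: list[Variant] = []
        for v in het_snvs:
            if not v.is_snv:
                continue
            entries = []
            for h in (1, 2):
                hp = genome.lift_to_hap(v.chrom, h, v.start)
                entries.append(hp)
            if any(hp is None for hp in entries):
                self.skipped.append(v)  # inside a sample deletion
                continue
            alleles = genome.snv_alleles_on_haps(v)
            for h, hp in zip((1, 2), entries):
                key = (v.chrom, h)
                self._pos.setdefault(key, []).append(hp)
                self._var.setdefault(key, []).append((v, alleles[h - 1]))
        for key in self._pos:
            order = np.argsort(self._pos[key], kind="stable")
            self._pos[key] = [self._pos[key][i] for i in order]
            self._var[key] = [self._var[key][i] for i in order]

    def overlapping(self, chrom: str, haplotype: int, start: int, end: int):
        """(hap_pos, Variant, hap_allele) for het SNVs inside [start, end)."""
        key = (chrom, haplotype)
        pos = self._pos.get(key, [])
        lo = bisect_left(pos, start)
        hi = bisect_right(pos, end - 1)
        return [
            (pos[i], self._var[key][i][0], self._var[key][i][1])
            for i in range(lo, hi)
        ]


def count_alleles(
    chosen: list[ReadAlignment],
    genome: PersonalGenome,
    het_snvs: list[Variant],
) -> list[AllelicCount]:
    """Tally ref/alt/other bases carried by retained reads at each het SNV.

    A read contributes once per SNV it overlaps, by the base at the SNV's
    position on the haplotype the read was assigned to.  SNVs that cannot be
    lifted onto both haplotypes (they fall inside a sample deletion) are
    skipped.
    """
    index = _SnvIndex(genome, het_snvs)
    counts: dict[tuple[str, int], AllelicCount] = {}
    for v in het_snvs:
        if v.is_snv and v not in index.skipped:
            counts[(v.chrom, v.pos)] = AllelicCount(
                chrom=v.chrom, pos=v.pos,
                ref_allele=v.ref_allele, alt_allele=v.alt_allele,
            )
    for aln in chosen:
        for hap_pos, v, _ in index.overlapping(
            aln.chrom, aln.haplotype, aln.start, aln.end
        ):
            base = aln.sequence[hap_pos - aln.start]
            c = counts[(v.chrom, v.pos)]
            if base == v.ref_allele:
                c.n_ref += 1
            elif base == v.alt_allele:
                c.n_alt += 1
            else:
                c.n_other += 1
    return [counts[k] for k in sorted(counts)]
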