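"""Diploid personal genome construction and coordinate liftover.

A personal genome is built by incorporating an individual's variants (SNVs
and short indels) into a reference assembly, producing two haplotype
sequences per chromosome.  Reads are later aligned to each haplotype
separately, which removes the systematic advantage reads carrying the
reference allele enjoy when mapped to a haploid reference (reference bias).

Coordinates are 0-based half-open internally; VCF I/O converts to and from
1-based positions at the boundary.  Liftover between haplotype and reference
coordinates is exact and indel-aware, stored as sorted alignment blocks.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "CoordinateMap",
    "PersonalGenome",
    "CnvProfile",
    "build_diploid",
    "cnv_profile",
    "filter_snvs_by_cnv",
    "OverlappingVariantsError",
    "ReferenceMismatchError",
]


class OverlappingVariantsError(ValueError):
    """Raised when two variants would edit overlapping reference bases on one haplotype."""

    def __init__(self, sites):
        self.sites = list(sites)
        super().__init__(f"overlapping variants on one haplotype at: {self.sites}")


class ReferenceMismatchError(ValueError):
    """Raised when a variant's REF allele does not match the reference sequence."""


@dataclass(frozen=True)
class Variant:
    """A diploid variant call.

    ``pos`` is the 1-based reference position of the first REF base, as in
    VCF.  ``genotype`` is a pair of allele indices (0 = REF, 1 = ALT);
    ``phased`` marks whether the pair is ordered (``0|1``) or not (``0/1``).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]
    phased: bool

    def __post_init__(self):
        if not all(g in (0, 1) for g in self.genotype):
            raise ValueError(f"genotype indices must be 0 or 1, got {self.genotype}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def start(self) -> int:
        """0-based start on the reference."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.pos - 1 + len(self.ref_allele)


class CoordinateMap:
    """Monotone haplotype<->reference map stored as alignment blocks.

    Each block is ``(hap_start, ref_start, length)`` with both coordinates
    0-based; within a block positions correspond one-to-one.  Haplotype
    positions falling between blocks lie inside insertions and have no
    reference equivalent; reference positions between blocks were deleted
    from the haplotype.
    """

    def __init__(self, blocks: list[tuple[int, int, int]]):
        self.blocks = sorted(blocks)
        self._hap_starts = [b[0] for b in self.blocks]
        self._ref_starts = [b[1] for b in self.blocks]

    def to_ref(self, hap_pos: int) -> int | None:
        """Map a haplotype position to the reference; None inside insertions."""
        i = bisect_right(self._hap_starts, hap_pos) - 1
        if i < 0:
            return None
        h, r, ln = self.blocks[i]
        if hap_pos < h + ln:
            return r + (hap_pos - h)
        return None

    def to_hap(self, ref_pos: int) -> int | None:
        """Map a reference position to the haplotype; None inside deletions."""
        i = bisect_right(self._ref_starts, ref_pos) - 1
        if i < 0:
            return None
        h, r, ln = self.blocks[i]
        if ref_pos < r + ln:
            return h + (ref_pos - r)
        return None


@dataclass
class PersonalGenome:
    """Two haplotype sequences per chromosome plus coordinate maps.

    ``phase_assignments`` records, for every unphased heterozygote, which
    haplotype received the ALT allele — a deterministic function of ``seed``.
    """

    haplotypes: dict[str, tuple[str, str]]
    maps: dict[str, tuple[CoordinateMap, CoordinateMap]]
    variants: dict[str, list[Variant]]
    hap_alleles: dict[str, dict[int, tuple[str, str]]]
    phase_assignments: dict[tuple[str, int], int]
    seed: int

    def sequence(self, chrom: str, haplotype: int) -> str:
        return self.haplotypes[chrom][haplotype - 1]

    def coord_map(self, chrom: str, haplotype: int) -> CoordinateMap:
        return self.maps[chrom][haplotype - 1]

    def lift(self, chrom: str, haplotype: int, position: int) -> int | None:
        """Haplotype position -> reference position (0-based); None if the
        position lies inside a haplotype-specific insertion."""
        seq = self.sequence(chrom, haplotype)
        if not (0 <= position < len(seq)):
            raise IndexError(
                f"position {position} out of bounds for {chrom} hap{haplotype} "
                f"(length {len(seq)})"
            )
        return self.coord_map(chrom, haplotype).to_ref(position)

    def lift_to_hap(self, chrom: str, haplotype: int, ref_position: int) -> int | None:
        """Reference position -> haplotype position; None inside a deletion."""
        return self.coord_map(chrom, haplotype).to_hap(ref_position)

    def het_snvs(self, chrom: str | None = None) -> list[Variant]:
        chroms = [chrom] if chrom is not None else sorted(self.variants)
        out = []
        for c in chroms:
            out.extend(v for v in self.variants.get(c, []) if v.is_het and v.is_snv)
        return out

    def snv_alleles_on_haps(self, v: Variant) -> tuple[str, str]:
        """The base carried by (hap1, hap2) at a het SNV."""
        return self.hap_alleles[v.chrom][v.pos]


def _apply_to_haplotype(ref_seq: str, edits: list[tuple[Variant, str]], chrom: str):
    """Apply (variant, allele) edits to one haplotype; returns (seq, CoordinateMap)."""
    overlaps = []
    last_end = -1
    for v, _ in edits:
        if v.start < last_end:
            overlaps.append((chrom, v.pos))
        last_end = max(last_end, v.end)
    if overlaps:
        raise OverlappingVariantsError(overlaps)

    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    ref_cursor = 0
    hap_cursor = 0
    for v, allele in edits:
        if v.ref_allele != ref_seq[v.start : v.end]:
            raise ReferenceMismatchError(
                f"{chrom}:{v.pos} REF {v.ref_allele!r} != reference "
                f"{ref_seq[v.start: v.end]!r}"
            )
        gap = v.start - ref_cursor
        if gap > 0:
            parts.append(ref_seq[ref_cursor : v.start])
            blocks.append((hap_cursor, ref_cursor, gap))
            hap_cursor += gap
            ref_cursor = v.start
        if allele == v.ref_allele:
            parts.append(v.ref_allele)
            blocks.append((hap_cursor, ref_cursor, len(v.ref_allele)))
            hap_cursor += len(v.ref_allele)
        else:
            parts.append(allele)
            # SNVs and the shared leading base of an indel still correspond
            # one-to-one; the inserted/deleted tail breaks the block.
            shared = 0
            while (
                shared < min(len(v.ref_allele), len(allele))
                and v.ref_allele[shared] == allele[shared]
            ):
                shared += 1
            if v.is_snv:
                blocks.append((hap_cursor, ref_cursor, 1))
            elif shared > 0:
                blocks.append((hap_cursor, ref_cursor, shared))
            hap_cursor += len(allele)
        ref_cursor = v.end
    if ref_cursor < len(ref_seq):
        parts.append(ref_seq[ref_cursor:])
        blocks.append((hap_cursor, ref_cursor, len(ref_seq) - ref_cursor))
    return "".join(parts), CoordinateMap(blocks)


def build_diploid(
    reference: dict[str, str], variants: list[Variant], seed: int
) -> PersonalGenome:
    """Incorporate an individual's variants into the reference, one haplotype
    per phased allele.

    Phased genotypes place allele ``genotype[0]`` on haplotype 1 and
    ``genotype[1]`` on haplotype 2.  Unphased heterozygotes are assigned to a
    haplotype uniformly at random, reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if v.chrom not in reference:
            raise KeyError(f"variant chromosome {v.chrom!r} absent from reference")
        by_chrom.setdefault(v.chrom, []).append(v)

    haplotypes, maps, var_out, hap_alleles = {}, {}, {}, {}
    phase_assignments: dict[tuple[str, int], int] = {}
    for chrom in sorted(reference):
        vs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos)
        edits1: list[tuple[Variant, str]] = []
        edits2: list[tuple[Variant, str]] = []
        alleles_here: dict[int, tuple[str, str]] = {}
        for v in vs:
            g = v.genotype
            if v.is_het and not v.phased:
                # random phasing: which haplotype carries genotype[0]
                flip = int(rng.integers(0, 2))
                if flip:
                    g = (g[1], g[0])
                phase_assignments[(chrom, v.pos)] = 2 if g[1] == 1 else 1
            a1 = v.alt_allele if g[0] == 1 else v.ref_allele
            a2 = v.alt_allele if g[1] == 1 else v.ref_allele
            edits1.append((v, a1))
            edits2.append((v, a2))
            if v.is_het and v.is_snv:
                alleles_here[v.pos] = (a1, a2)
        seq1, map1 = _apply_to_haplotype(reference[chrom], edits1, chrom)
        seq2, map2 = _apply_to_haplotype(reference[chrom], edits2, chrom)
        haplotypes[chrom] = (seq1, seq2)
        maps[chrom] = (map1, map2)
        var_out[chrom] = vs
        hap_alleles[chrom] = alleles_here
    return PersonalGenome(
        haplotypes=haplotypes,
        maps=maps,
        variants=var_out,
        hap_alleles=hap_alleles,
        phase_assignments=phase_assignments,
        seed=seed,
    )


@dataclass
class CnvProfile:
    """Windowed read depth normalized to the genome-wide average.

    Windows with normalized depth outside (low, high) betray copy-number
    changes, where read-count imbalance mimics allele-specific signal.
    """

    window_size: int
    normalized_depth: dict[str, np.ndarray]

    def depth_at(self, chrom: str, ref_pos: int) -> float | None:
        track = self.normalized_depth.get(chrom)
        if track is None:
            return None
        w = ref_pos // self.window_size
        if w >= len(track):
            return None
        return float(track[w])


def cnv_profile(depth_per_base: dict[str, np.ndarray], window_size: int) -> CnvProfile:
    """Average depth per window divided by the genome-wide mean depth."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    window_means: dict[str, np.ndarray] = {}
    all_means = []
    for chrom, depth in depth_per_base.items():
        depth = np.asarray(depth, dtype=float)
        n_win = int(np.ceil(len(depth) / window_size))
        means = np.array(
            [depth[i * window_size : (i + 1) * window_size].mean() for i in range(n_win)]
        )
        window_means[chrom] = means
        all_means.append(means)
    genome_mean = float(np.concatenate(all_means).mean()) if all_means else 0.0
    if genome_mean == 0.0:
        raise ValueError("zero genome-wide depth")
    return CnvProfile(
        window_size=window_size,
        normalized_depth={c: m / genome_mean for c, m in window_means.items()},
    )


def filter_snvs_by_cnv(
    snvs: list[Variant],
    profile: CnvProfile,
    low: float = 0.5,
    high: float = 1.5,
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Remove SNVs in windows of abnormal depth (< low or > high, strict).

    Boundary values are retained.  SNVs in windows the profile does not
    cover are retained and logged.
    """
    retained, removed = [], []
    for v in snvs:
        d = profile.depth_at(v.chrom, v.start)
        if d is None:
            logger.info("CNV profile does not cover %s:%d; SNV retained", v.chrom, v.pos)
            retained.append(v)
        elif d < low:
            removed.append((v, "low"))
        elif d > high:
            removed.append((v, "high"))
        else:
            retained.append(v)
    return retained, removed
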