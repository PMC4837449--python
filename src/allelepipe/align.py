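"""Read alignments and the built-in exhaustive aligner used for fixtures.

Real data is expected to arrive as per-haplotype SAM/BAM from an external
short-read aligner run with unique mapping and at most two mismatches.  The
aligner here serves synthetic fixture genomes only: it scans every offset of
every target sequence for Hamming-distance hits (no indel alignment, forward
strand), which on kilobase-scale fixtures is exact and fast enough, and lets
multi-mapping be decided by a global uniqueness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

__all__ = ["ReadAlignment", "FixtureAligner", "read_sam", "write_sam"]

MAX_MISMATCHES = 2

_BASE_TO_U8 = {b: np.uint8(i) for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class ReadAlignment:
    """A single gapless alignment of a read to one haplotype.

    ``start`` is 0-based on the haplotype sequence.  ``mismatches`` counts
    substitutions against the haplotype; alignments with more than two are
    never retained, and ``multimapped`` reads are dropped outright.
    """

    read_id: str
    haplotype: int
    chrom: str
    start: int
    sequence: str
    mismatches: int
    multimapped: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


class FixtureAligner:
    """Exhaustive unique-alignment search over a set of named sequences.

    ``targets`` maps a name (e.g. a chromosome) to its sequence.  ``align``
    returns ``(hits, multimapped)`` where hits are ``(name, start,
    mismatches)`` at the minimal observed mismatch count <= max_mismatches;
    a read is multimapped when more than one locus achieves that minimum.
    """

    def __init__(self, targets: dict[str, str], max_mismatches: int = MAX_MISMATCHES):
        self.max_mismatches = max_mismatches
        self._targets = {name: _encode(seq) for name, seq in targets.items()}

    def hits(self, read_seq: str) -> list[tuple[str, int, int]]:
        """All loci within the mismatch budget, unfiltered."""
        q = _encode(read_seq)
        r = len(q)
        found: list[tuple[str, int, int]] = []
        for name, t in self._targets.items():
            n_off = len(t) - r + 1
            if n_off <= 0:
                continue
            mism = np.zeros(n_off, dtype=np.int32)
            for j in range(r):
                mism += t[j : j + n_off] != q[j]
                # cheap early exit once every offset is over budget
                if j % 16 == 15 and mism.min() > self.max_mismatches + (r - j - 1):
                    break
            ok = np.flatnonzero(mism <= self.max_mismatches)
            found.extend((name, int(o), int(mism[o])) for o in ok)
        return found

    def align(self, read_seq: str) -> tuple[list[tuple[str, int, int]], bool]:
        found = self.hits(read_seq)
        if not found:
            return [], False
        best = min(m for _, _, m in found)
        best_hits = [h for h in found if h[2] == best]
        return best_hits, len(best_hits) > 1


def align_reads_to_haplotype(
    reads: list[tuple[str, str]],
    haplotype_seqs: dict[str, str],
    haplotype: int,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[ReadAlignment]:
    """Align (read_id, sequence) pairs to one haplotype's chromosomes.

    Unique best hits become alignments.  Reads whose best hit is shared by
    multiple loci on this haplotype are suppressed — no record is emitted,
    matching how unique-mapping short-read aligners behave.  That silence is
    precisely what creates ambiguous mapping bias: the read may still align
    cleanly (and be kept) on the other haplotype.
    """
    aligner = FixtureAligner(haplotype_seqs, max_mismatches)
    out = []
    for read_id, seq in reads:
        best_hits, multi = aligner.align(seq)
        if not best_hits or multi:
            continue
        chrom, start, mism = best_hits[0]
        out.append(
            ReadAlignment(
                read_id=read_id,
                haplotype=haplotype,
                chrom=chrom,
                start=start,
                sequence=seq,
                mismatches=mism,
            )
        )
    return out


def read_sam(path: str, haplotype: int) -> list[ReadAlignment]:
    """Load gapless alignments from SAM/BAM; NM tag supplies mismatch counts.

    Reads flagged secondary or with mapping quality 0 are marked multimapped.
    """
    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    haplotype=haplotype,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    sequence=rec.query_sequence,
                    mismatches=int(nm),
                    multimapped=rec.is_secondary or rec.mapping_quality == 0,
                )
            )
    return out


def write_sam(path: str, alignments: list[ReadAlignment],
              contigs: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.sequence
            rec.reference_name = aln.chrom
            rec.reference_start = aln.start
            rec.cigarstring = f"{len(aln.sequence)}M"
            rec.mapping_quality = 0 if aln.multimapped else 255
            rec.flag = 256 if aln.multimapped else 0
            rec.set_tag("NM", aln.mismatches)
            fh.write(rec)
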