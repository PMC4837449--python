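"""Enrichment of allele-specific SNVs in genomic annotations, and MAF spectra.

Allele-specific SNVs are compared against matched control SNVs — accessible
(sufficiently covered) heterozygous sites that tested non-allele-specific —
with Fisher's exact test per annotation.  Two counting modes exist:
"collapsed" counts each variant site once across the cohort (AS if AS in at
least one individual), "expanded" counts each (site, individual) occurrence,
which is population-aware and rewards consistency across genomes.  Elements
are then classified from the expanded odds ratio: significantly enriched
(Bonferroni p <= 0.05, OR >= 1.5) elements are "allele-specific",
significantly depleted ones (OR < 1.5) are "balanced", the rest
"indeterminate".

The MAF analysis compares the population-frequency spectra of AS and
control sites and tests rare-variant (MAF <= 0.5%) enrichment with a 2x2
Fisher test, a proxy for differential purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

__all__ = [
    "SnvOccurrence",
    "EnrichmentResult",
    "occurrences_frame",
    "collapse",
    "expand",
    "fisher_enrichment",
    "classify",
    "enrich",
    "maf_spectrum",
    "RARE_MAF",
]

RARE_MAF = 0.005
OCC_COLUMNS = ["chrom", "pos", "ref", "alt", "individual", "status", "assay", "maf"]


@dataclass(frozen=True)
class SnvOccurrence:
    """One accessible het SNV in one individual.

    ``status`` is "as" (allele-specific) or "control" (accessible but
    non-allele-specific in that individual); ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    individual: str
    status: str
    assay: str = "ase"
    maf: float | None = None

    def __post_init__(self):
        if self.status not in ("as", "control"):
            raise ValueError(f"status must be 'as' or 'control', got {self.status!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF must lie in [0, 0.5], got {self.maf}")


def occurrences_frame(occurrences: list[SnvOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.chrom, o.pos, o.ref, o.alt, o.individual, o.status, o.assay,
             np.nan if o.maf is None else o.maf)
            for o in occurrences
        ],
        columns=OCC_COLUMNS,
    )


_SITE = ["chrom", "pos", "ref", "alt"]


def collapse(occurrences: pd.DataFrame) -> pd.DataFrame:
    """One row per unique site; AS wins over control across individuals."""
    if occurrences.empty:
        return occurrences.drop(columns=["individual"], errors="ignore")
    grouped = occurrences.groupby(_SITE, as_index=False).agg(
        status=("status", lambda s: "as" if (s == "as").any() else "control"),
        maf=("maf", "first"),
        assay=("assay", "first"),
    )
    return grouped


def expand(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Identity pass with validation: each (site, individual, assay) once."""
    key = _SITE + ["individual", "assay"]
    dup = occurrences.duplicated(subset=key)
    if dup.any():
        rows = occurrences.loc[dup, key].head().to_dict("records")
        raise ValueError(f"duplicate occurrence rows, e.g. {rows}")
    return occurrences.copy()


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio (a d)/(b c) and two-sided hypergeometric p.

    Returns (nan, p) when the odds ratio is undefined (zero in b or c) —
    callers flag these "NA".
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return odds, float(p)


def classify(
    odds_ratio: float,
    p_bonferroni: float,
    or_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> str:
    """allele-specific / balanced / indeterminate from the corrected test."""
    if math.isnan(odds_ratio):
        return "indeterminate"
    if p_bonferroni <= p_threshold:
        return "allele-specific" if odds_ratio >= or_threshold else "balanced"
    return "indeterminate"


@dataclass
class EnrichmentResult:
    annotation: str
    mode: str
    a: int  # AS inside the annotation
    b: int  # control inside
    c: int  # AS outside
    d: int  # control outside
    odds_ratio: float
    p: float
    p_bonferroni: float
    classification: str


def _trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in bed.itertuples():
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end)
    return trees


def _membership(table: pd.DataFrame, trees: dict[str, IntervalTree]) -> np.ndarray:
    out = np.zeros(len(table), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
        tree = trees.get(str(chrom))
        if tree is not None and tree.overlaps_point(pos - 1):
            out[i] = True
    return out


def enrich(
    occurrences: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    mode: str = "expanded",
    or_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher enrichment of AS vs control SNVs per annotation.

    The Bonferroni family is the set of annotations tested in this run.
    Annotation intervals are BED-style (0-based half-open) on reference
    coordinates; a site counts once per annotation however many intervals
    it touches.
    """
    if mode == "collapsed":
        table = collapse(occurrences)
    elif mode == "expanded":
        table = expand(occurrences)
    else:
        raise ValueError(f"mode must be 'collapsed' or 'expanded', got {mode!r}")
    n_tests = max(len(annotations), 1)
    is_as = (table["status"] == "as").to_numpy()
    results = []
    for name, bed in annotations.items():
        inside = _membership(table, _trees(bed))
        a = int((is_as & inside).sum())
        b = int((~is_as & inside).sum())
        c = int((is_as & ~inside).sum())
        d = int((~is_as & ~inside).sum())
        odds, p = fisher_enrichment(a, b, c, d)
        p_bon = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                annotation=name, mode=mode, a=a, b=b, c=c, d=d,
                odds_ratio=odds, p=p, p_bonferroni=p_bon,
                classification=classify(odds, p_bon, or_threshold, p_threshold),
            )
        )
    return results


def results_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    suffix = {"collapsed": "_c", "expanded": "_e"}
    rows = []
    for r in results:
        s = suffix[r.mode]
        rows.append(
            {
                "annotation": r.annotation,
                f"AS{s}": r.a, f"nonAS{s}": r.b,
                f"AS.out{s}": r.c, f"nonAS.out{s}": r.d,
                f"OR{s}": r.odds_ratio, f"p{s}": r.p, f"p.bon{s}": r.p_bonferroni,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)


def maf_spectrum(
    occurrences: pd.DataFrame,
    bin_width: float = RARE_MAF,
    rare_maf: float = RARE_MAF,
) -> tuple[pd.DataFrame, float, float, int]:
    """MAF histograms of AS vs control sites plus the rare-variant 2x2 test.

    Sites without a MAF are excluded (their number is returned).  The Fisher
    table is rare (MAF <= rare_maf) vs non-rare against AS vs control;
    OR < 1 means AS sites are depleted of rare variants relative to
    controls.
    """
    table = collapse(occurrences)
    missing = int(table["maf"].isna().sum())
    table = table.dropna(subset=["maf"])
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    rows = []
    for status, grp in table.groupby("status"):
        hist, _ = np.histogram(grp["maf"], bins=edges)
        for lo, count in zip(edges[:-1], hist):
            rows.append((status, round(float(lo), 10), int(count)))
    spectrum = pd.DataFrame(rows, columns=["status", "maf_bin", "count"])
    is_as = table["status"] == "as"
    rare = table["maf"] <= rare_maf
    odds, p = fisher_enrichment(
        int((is_as & rare).sum()), int((~is_as & rare).sum()),
        int((is_as & ~rare).sum()), int((~is_as & ~rare).sum()),
    )
    return spectrum, odds, p, missing
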