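"""Parent-child inheritance of allele-specific behaviour in a trio.

At SNVs called allele-specific in both members of a pair, the reference
allelic ratios of parent and child are compared.  Sites qualify under two
scenarios: (1) heterozygous in all three trio members, or (2) heterozygous
in the two compared members and homozygous (either allele) in the third.
Similarity is summarized by Pearson's r — preferred over the regression
slope beta as the single-trio stand-in for heritability — with beta
reported alongside (child regressed on parent; for the parent-parent
comparison the maternal ratio is the independent variable by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress, pearsonr

from .detection import ASCall

logger = logging.getLogger(__name__)

__all__ = ["TrioPair", "select_shared", "heritability"]

Genotypes = dict[tuple[str, int], tuple[int, int]]  # (chrom, pos) -> GT of one member


def _is_het(gt: tuple[int, int]) -> bool:
    return gt[0] != gt[1]


def _is_hom(gt: tuple[int, int]) -> bool:
    return gt[0] == gt[1]


def select_shared(
    calls_a: list[ASCall],
    calls_b: list[ASCall],
    genotypes: dict[str, Genotypes],
    member_a: str,
    member_b: str,
    third: str,
) -> list[tuple[str, int]]:
    """Sites allele-specific in both compared members under scenario 1 or 2.

    Scenario 1: het in all three members.  Scenario 2: het in the compared
    pair, homozygous in the third.  Sites with a missing genotype in any
    member are skipped and logged.
    """
    as_a = {c.count.key for c in calls_a if c.significant}
    as_b = {c.count.key for c in calls_b if c.significant}
    shared = []
    for key in sorted(as_a & as_b):
        gts = []
        missing = False
        for member in (member_a, member_b, third):
            gt = genotypes.get(member, {}).get(key)
            if gt is None:
                logger.info("missing genotype for %s at %s; site skipped", member, key)
                missing = True
                break
            gts.append(gt)
        if missing:
            continue
        ga, gb, gt3 = gts
        if _is_het(ga) and _is_het(gb) and (_is_het(gt3) or _is_hom(gt3)):
            shared.append(key)
    return shared


@dataclass
class TrioPair:
    """One pairwise comparison: ratio vectors and their similarity."""

    label: str
    sites: list[tuple[str, int]]
    x: np.ndarray  # independent member (parent, or mother for parent-parent)
    y: np.ndarray
    r: float
    r_p: float
    beta: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def heritability(
    calls_x: list[ASCall],
    calls_y: list[ASCall],
    sites: list[tuple[str, int]],
    label: str = "pair",
) -> TrioPair:
    """Pearson r and regression slope of y's ratios on x's at shared sites."""
    if len(sites) < 3:
        raise ValueError("need at least 3 shared sites")
    ratio_x = {c.count.key: c.count.allelic_ratio for c in calls_x if c.count.n > 0}
    ratio_y = {c.count.key: c.count.allelic_ratio for c in calls_y if c.count.n > 0}
    x = np.array([ratio_x[s] for s in sites])
    y = np.array([ratio_y[s] for s in sites])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in allelic ratios")
    r, r_p = pearsonr(x, y)
    beta = linregress(x, y).slope
    return TrioPair(label=label, sites=list(sites), x=x, y=y,
                    r=float(r), r_p=float(r_p), beta=float(beta))
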