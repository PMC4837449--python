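"""Diploid construction, liftover and the CNV depth filter."""

import numpy as np
import pytest

from allelepipe.genome import (
    OverlappingVariantsError,
    ReferenceMismatchError,
    Variant,
    build_diploid,
    cnv_profile,
    filter_snvs_by_cnv,
)

REF = {"chr1": "ACGTACGT"}


def test_het_snv_substitution_per_phase():
    v = Variant("chr1", 3, "G", "T", (0, 1), phased=True)
    g = build_diploid(REF, [v], seed=0)
    assert g.sequence("chr1", 1) == "ACGTACGT"
    assert g.sequence("chr1", 2) == "ACTTACGT"
    assert g.snv_alleles_on_haps(v) == ("G", "T")


def test_deletion_shifts_coordinates():
    # 2-bp deletion TA -> T applied to haplotype 1
    v = Variant("chr1", 4, "TA", "T", (1, 0), phased=True)
    g = build_diploid(REF, [v], seed=0)
    assert len(g.sequence("chr1", 1)) == 7
    # hap1 position 4 (0-based; 5th base) is reference position 5 (6th base)
    assert g.lift("chr1", 1, 4) == 5
    assert g.sequence("chr1", 2) == REF["chr1"]


def test_insertion_has_no_reference_equivalent():
    v = Variant("chr1", 4, "T", "TGG", (1, 1), phased=True)
    g = build_diploid(REF, [v], seed=0)
    assert len(g.sequence("chr1", 1)) == 10
    assert g.lift("chr1", 1, 3) == 3  # the shared anchor base
    assert g.lift("chr1", 1, 4) is None  # inside the insertion
    assert g.lift("chr1", 1, 6) == 4  # first base after the insertion


def test_variant_free_lift_is_identity():
    g = build_diploid(REF, [], seed=0)
    for p in range(8):
        assert g.lift("chr1", 1, p) == p
        assert g.lift_to_hap("chr1", 2, p) == p


def test_lift_out_of_bounds_raises():
    g = build_diploid(REF, [], seed=0)
    with pytest.raises(IndexError):
        g.lift("chr1", 1, 99)


def test_unphased_phasing_deterministic_in_seed():
    vs = [
        Variant("chr1", p, REF["chr1"][p - 1], "A" if REF["chr1"][p - 1] != "A" else "C",
                (0, 1), phased=False)
        for p in (2, 3, 5, 6, 8)
    ]
    g1 = build_diploid(REF, vs, seed=17)
    g2 = build_diploid(REF, vs, seed=17)
    assert g1.haplotypes == g2.haplotypes
    assert g1.phase_assignments == g2.phase_assignments
    # a different seed eventually flips some assignment
    flipped = any(
        build_diploid(REF, vs, seed=s).phase_assignments != g1.phase_assignments
        for s in range(5)
    )
    assert flipped


def test_overlapping_variants_rejected_with_sites():
    vs = [
        Variant("chr1", 3, "GTA", "G", (1, 1), phased=True),
        Variant("chr1", 4, "T", "A", (1, 1), phased=True),
    ]
    with pytest.raises(OverlappingVariantsError) as e:
        build_diploid(REF, vs, seed=0)
    assert ("chr1", 4) in e.value.sites


def test_reference_mismatch_names_position():
    with pytest.raises(ReferenceMismatchError, match="chr1:3"):
        build_diploid(REF, [Variant("chr1", 3, "A", "T", (0, 1), True)], seed=0)


def _random_variants(rng, ref, n):
    """Non-overlapping random SNVs/indels for round-trip property tests."""
    out, cursor = [], 1
    for _ in range(n):
        pos = cursor + int(rng.integers(1, 6))
        if pos + 4 > len(ref):
            break
        kind = rng.integers(0, 3)
        base = ref[pos - 1]
        if kind == 0:  # SNV
            alt = "ACGT"[(("ACGT".index(base)) + 1) % 4]
            out.append(Variant("chr1", pos, base, alt, (1, 0), True))
            cursor = pos + 1
        elif kind == 1:  # insertion
            out.append(Variant("chr1", pos, base, base + "AC", (1, 0), True))
            cursor = pos + 1
        else:  # 2-bp deletion
            out.append(Variant("chr1", pos, ref[pos - 1 : pos + 2], base, (1, 0), True))
            cursor = pos + 3
    return out


@pytest.mark.parametrize("seed", range(6))
def test_lift_round_trip_identity_random_indels(seed):
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=300))
    variants = _random_variants(rng, ref, 20)
    g = build_diploid({"chr1": ref}, variants, seed=seed)
    hap = g.sequence("chr1", 1)
    for p in range(len(hap)):
        r = g.lift("chr1", 1, p)
        if r is not None:
            assert g.lift_to_hap("chr1", 1, r) == p
    # reverting: every mappable haplotype base equals the reference base,
    # except at applied SNV sites
    snv_starts = {v.start for v in variants if v.is_snv}
    for p in range(len(hap)):
        r = g.lift("chr1", 1, p)
        if r is not None and r not in snv_starts:
            assert hap[p] == ref[r]


def test_cnv_profile_uniform_and_spike():
    depth = {"chr1": np.full(1000, 10.0)}
    prof = cnv_profile(depth, window_size=100)
    assert np.allclose(prof.normalized_depth["chr1"], 1.0)
    depth["chr1"][200:300] = 20.0
    prof = cnv_profile(depth, window_size=100)
    assert prof.normalized_depth["chr1"][2] == pytest.approx(2.0 / 1.1)


def test_cnv_profile_duplicated_region_exceeds_threshold():
    # 2x depth over a tenth of the genome: brute-force window means
    depth = np.full(2000, 10.0)
    depth[:200] = 20.0
    prof = cnv_profile({"chr1": depth}, window_size=100)
    expected_mean = depth.reshape(-1, 100).mean(axis=1).mean()
    assert np.allclose(
        prof.normalized_depth["chr1"], depth.reshape(-1, 100).mean(axis=1) / expected_mean
    )
    assert (prof.normalized_depth["chr1"][:2] > 1.5).all()


def test_cnv_zero_depth_errors():
    with pytest.raises(ValueError):
        cnv_profile({"chr1": np.zeros(100)}, window_size=10)


def test_cnv_filter_strict_inequalities():
    from allelepipe.genome import CnvProfile

    prof = CnvProfile(
        window_size=100,
        normalized_depth={"chr1": np.array([1.0, 1.6, 0.5, 1.5, 0.4])},
    )
    snvs = [Variant("chr1", 50 + 100 * i, "A", "C", (0, 1), True) for i in range(5)]
    retained, removed = filter_snvs_by_cnv(snvs, prof)
    retained_pos = {v.pos for v in retained}
    assert retained_pos == {50, 250, 350}  # windows at 1.0, 0.5, 1.5 kept
    reasons = {v.pos: why for v, why in removed}
    assert reasons == {150: "high", 450: "low"}
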