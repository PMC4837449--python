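"""PWM scanning, exact score p-values and motif-disruption correlation."""

import itertools

import numpy as np
import pytest

from allelepipe.motif import (
    PWM,
    DisruptionRecord,
    ScoreDistribution,
    correlate_disruption,
    diff_occurrence,
    disruption_records,
    read_pwms,
    revcomp,
    scan_window,
    score_pvalue,
)


def pwm_from_consensus(consensus, strength=0.91, motif_id="m"):
    rows = []
    for base in consensus:
        row = [(1 - strength) / 3] * 4
        row["ACGT".index(base)] = strength
        rows.append(row)
    return PWM(motif_id, np.array(rows))


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))
    with pytest.raises(ValueError):
        PWM("neg", np.array([[1.2, -0.2, 0.0, 0.0]]))


def test_diff_occurrence_basics():
    pwm = PWM("m", np.array([[0.9, 0.05, 0.03, 0.02]]))
    rec = diff_occurrence(pwm, 0, "A", "C")
    assert rec.diff_freq == pytest.approx(0.85)
    swapped = diff_occurrence(pwm, 0, "C", "A")
    assert swapped.diff_freq == pytest.approx(-0.85)
    equal = PWM("e", np.array([[0.4, 0.4, 0.1, 0.1]]))
    assert diff_occurrence(equal, 0, "A", "C").diff_freq == 0


def test_diff_occurrence_reverse_strand_complements():
    pwm = PWM("m", np.array([[0.7, 0.1, 0.1, 0.1]]))
    # '-' strand: T complements to A, G to C
    rec = diff_occurrence(pwm, 0, "T", "G", strand="-")
    assert rec.ref_freq == pytest.approx(0.7)
    assert rec.alt_freq == pytest.approx(0.1)


def test_diff_occurrence_offset_bounds():
    pwm = pwm_from_consensus("ACG")
    with pytest.raises(IndexError):
        pwm.frequency(3, "A")


@pytest.mark.parametrize("seed", range(4))
def test_dp_pvalue_matches_enumeration(seed):
    """Exact DP survival equals brute force over all 4^L background sequences."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 6))
    mat = rng.dirichlet(np.ones(4), size=L)
    pwm = PWM(f"r{seed}", mat)
    dist = ScoreDistribution(pwm)
    scores = {}
    for seq in itertools.product("ACGT", repeat=L):
        s = "".join(seq)
        scores[s] = dist.score_units(s)
    for q in (0.1, 0.5, 0.9):
        threshold = int(np.quantile(list(scores.values()), q))
        brute = sum(0.25**L for s, u in scores.items() if u >= threshold)
        assert dist.survival_units(threshold) == pytest.approx(brute, abs=1e-12)


def test_pvalue_extremes():
    pwm = pwm_from_consensus("ACGT")
    dist = ScoreDistribution(pwm)
    assert dist.survival(-1e6) == 1.0
    assert dist.survival(1e6) == 0.0
    assert score_pvalue(pwm, None, -1e6) == 1.0


def test_consensus_scores_maximal():
    pwm = pwm_from_consensus("ACGTACG", strength=0.97)
    dist = ScoreDistribution(pwm)
    cons = dist.score_units(pwm.consensus())
    others = [dist.score_units("".join(s))
              for s in itertools.islice(itertools.product("ACGT", repeat=7), 512)]
    assert cons >= max(others)


def test_scan_finds_planted_consensus():
    # a 10-mer is the shortest motif whose consensus can reach p <= 1e-6
    # under a uniform background (4^-10 ~ 9.5e-7)
    rng = np.random.default_rng(5)
    pwm = pwm_from_consensus("ACGTTGCATG", strength=0.97)
    flank = "".join(rng.choice(list("ACGT"), size=59))
    window = (flank[:20] + pwm.consensus() + flank[30:])[:59]
    hits = scan_window(window, pwm, p_max=1e-6, center=23)
    assert any(h.start == 20 and h.strand == "+" for h in hits)


def test_random_window_has_no_hits():
    rng = np.random.default_rng(6)
    pwm = pwm_from_consensus("ACGTTGCATG", strength=0.97)
    window = "".join(rng.choice(list("ACGT"), size=59))
    # p <= 1e-6 on an 8-mer essentially requires the consensus; a random
    # window of 59 bp almost surely lacks it
    hits = scan_window(window, pwm, p_max=1e-6)
    starts = {window[h.start : h.end] for h in hits if h.strand == "+"}
    assert all(s == pwm.consensus() for s in starts)


def test_palindrome_strand_symmetry():
    pwm = pwm_from_consensus("ACGT", strength=0.95)  # ACGT is its own revcomp
    assert revcomp(pwm.consensus()) == pwm.consensus()
    rng = np.random.default_rng(7)
    window = "".join(rng.choice(list("ACGT"), size=21)) + "ACGT" + "".join(
        rng.choice(list("ACGT"), size=20)
    )
    hits = scan_window(window, pwm, p_max=1e-3)
    fwd = {(h.start, round(h.score, 6)) for h in hits if h.strand == "+"}
    rev = {(h.start, round(h.score, 6)) for h in hits if h.strand == "-"}
    assert fwd == rev


def test_allele_gain_changes_hit_list():
    pwm = pwm_from_consensus("ACGTTGCATG", strength=0.97)
    rng = np.random.default_rng(8)
    flank = "".join(rng.choice(list("ACGT"), size=80))
    # reference breaks the consensus at the centre; alternate completes it
    motif_ref = "ACGATGCATG"  # A at offset 3 instead of T
    left = flank[:26]
    window = (left + motif_ref + flank[36:])[:59]
    center = 29
    assert window[center] == "A"
    recs = disruption_records(window, "A", "T", pwm, allelic_ratio=0.2)
    assert recs  # the alt allele gains the motif
    assert recs[0].diff_freq < 0  # reference allele is the disruptive one


def test_correlation_exact_and_noisy():
    recs = [
        DisruptionRecord("m", rf, 0.5, 0.5 + (rf - 0.5) / 2)
        for rf in np.linspace(0.1, 0.9, 9)
    ]
    r, p = correlate_disruption(recs)
    assert r == pytest.approx(1.0)
    flipped = [DisruptionRecord("m", x.alt_freq, x.ref_freq, x.allelic_ratio)
               for x in recs]
    r2, _ = correlate_disruption(flipped)
    assert r2 == pytest.approx(-1.0)

    rng = np.random.default_rng(9)
    diffs = rng.uniform(-0.9, 0.9, size=400)
    ratios = np.clip(0.5 + 0.4 * diffs + rng.normal(0, 0.05, size=400), 0, 1)
    noisy = [DisruptionRecord("m", 0.5 + d / 2, 0.5 - d / 2, ra)
             for d, ra in zip(diffs, ratios)]
    r3, p3 = correlate_disruption(noisy)
    expected = 1 / np.sqrt(1 + 0.05**2 / (0.4**2 * np.var(diffs)))
    assert abs(r3 - expected) < 0.05
    assert p3 < 1e-10


def test_correlation_input_validation():
    recs = [DisruptionRecord("m", 0.5, 0.5, 0.5)] * 5
    with pytest.raises(ValueError):
        correlate_disruption(recs[:2])
    with pytest.raises(ValueError):
        correlate_disruption(recs)  # zero variance


def test_read_pwms_roundtrip(tmp_path):
    path = tmp_path / "motifs.txt"
    path.write_text(
        ">m1\n0.7\t0.1\t0.1\t0.1\n0.25\t0.25\t0.25\t0.25\n"
        ">m2\nA\t0.1\t0.2\t0.3\t0.4\n"
    )
    pwms = read_pwms(str(path))
    assert [p.motif_id for p in pwms] == ["m1", "m2"]
    assert pwms[0].length == 2
    assert pwms[1].frequency(0, "T") == pytest.approx(0.4)
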