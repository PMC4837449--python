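"""Two-tailed beta-binomial test, simulation FDR and allele-specific calling."""

import numpy as np
import pytest

from allelepipe.genome import CnvProfile
from allelepipe.mapping import AllelicCount
from allelepipe.detection import (
    call_as,
    fdr_cutoff,
    min_accessible_reads,
    simulate_null,
    two_tailed_p,
)
from allelepipe.simulate import simulate_counts
import pandas as pd


def make_count(k, n, pos=1, chrom="c"):
    return AllelicCount(chrom, pos, "A", "C", k, n - k)


def test_extreme_imbalance_p():
    assert two_tailed_p(6, 6, 0.0) == pytest.approx(2 / 64)
    assert two_tailed_p(0, 6, 0.0) == pytest.approx(2 / 64)


def test_central_value_capped_at_one():
    for rho in (0.0, 0.2):
        assert two_tailed_p(10, 20, rho) == 1.0


def test_two_tailed_symmetry():
    for k, n, rho in [(2, 9, 0.0), (3, 15, 0.1), (0, 7, 0.3)]:
        assert two_tailed_p(k, n, rho) == pytest.approx(two_tailed_p(n - k, n, rho))


def test_null_simulation_matches_exact_tail():
    # at n = 6 and rho = 0, P[p <= 2/64] is exactly 2/64 (k in {0, 6})
    sites = [make_count(3, 6, pos=i + 1) for i in range(500)]
    null = simulate_null(sites, 0.0, iterations=200, seed=9)
    pooled = np.concatenate(null.pvalues)
    frac = (pooled <= 2 / 64 + 1e-12).mean()
    assert frac == pytest.approx(2 / 64, abs=3 * np.sqrt((2 / 64) * (62 / 64) / pooled.size))


def test_null_simulation_seed_reproducible():
    sites = [make_count(3, 10, pos=i + 1) for i in range(50)]
    a = simulate_null(sites, 0.1, 10, seed=4)
    b = simulate_null(sites, 0.1, 10, seed=4)
    for x, y in zip(a.pvalues, b.pvalues):
        assert np.array_equal(x, y)


def test_fdr_target_one_accepts_everything():
    sites = [make_count(5, 10, pos=i + 1) for i in range(20)]
    null = simulate_null(sites, 0.0, 5, seed=1)
    obs = np.linspace(0.01, 1.0, 20)
    res = fdr_cutoff(obs, null, target=1.0)
    assert res.n_observed_positives == 20
    assert res.p_cutoff == 1.0


def test_fdr_null_calibration():
    # data drawn from the null: calls stay near target fraction or below
    counts = simulate_counts(2_000, 30, 0.0, seed=21)
    calls, fdr = call_as(counts, 0.0, "rna", seed=22)
    n_sig = sum(c.significant for c in calls)
    # observed positives at cutoff satisfy null_mean/observed <= 0.05
    if n_sig:
        assert fdr.n_null_positives_mean / fdr.n_observed_positives <= 0.05


def test_planted_signal_power():
    rng = np.random.default_rng(2)
    nulls = simulate_counts(10_000, 100, 0.0, seed=3)
    planted = [
        make_count(int(k), 100, pos=i + 1, chrom="p")
        for i, k in enumerate(rng.binomial(100, 0.95, size=100))
    ]
    calls, _ = call_as(nulls + planted, 0.0, "rna", seed=4)
    sig = {c.count.key for c in calls if c.significant}
    power = sum(1 for c in planted if c.key in sig) / 100
    assert power >= 0.95
    fdp = len(sig - {c.key for c in planted}) / max(1, len(sig))
    assert fdp <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / max(1, len(sig)))


@pytest.mark.parametrize("p_cutoff,rho,expected", [(0.05, 0.0, 6), (0.01, 0.0, 8)])
def test_min_accessible_reads_exact(p_cutoff, rho, expected):
    # 2 * 0.5^6 = 0.03125 <= 0.05 while 2 * 0.5^5 = 0.0625 > 0.05, etc.
    th = min_accessible_reads(p_cutoff, rho)
    assert th.N == expected
    assert th.min_reads == max(6, expected)


def test_min_accessible_reads_monotone_in_rho():
    last = 0
    for rho in (0.0, 0.05, 0.1, 0.2, 0.3):
        n = min_accessible_reads(0.01, rho).N
        assert n >= last
        last = n


def test_balanced_data_yields_no_calls():
    counts = [make_count(k, 12, pos=i + 1) for i, k in enumerate([5, 6, 7, 6, 5, 6])]
    calls, _ = call_as(counts, 0.0, "rna", seed=5)
    assert not any(c.significant for c in calls)
    assert len(calls) == len(counts)  # every SNV reported once


def test_min_reads_floor_flagged():
    counts = [make_count(5, 5, pos=1), make_count(30, 30, pos=2)]
    calls, _ = call_as(counts, 0.0, "rna", seed=6)
    by_pos = {c.count.pos: c for c in calls}
    assert "min_reads" in by_pos[1].filters and not by_pos[1].significant
    assert by_pos[2].significant


def test_peak_filter_for_chip():
    counts = [make_count(30, 30, pos=100), make_count(30, 30, pos=5000)]
    peaks = pd.DataFrame({"chrom": ["c"], "start": [50], "end": [200]})
    calls, _ = call_as(counts, 0.0, "chip", peaks=peaks, seed=7)
    by_pos = {c.count.pos: c for c in calls}
    assert by_pos[100].significant
    assert not by_pos[5000].significant and "peak" in by_pos[5000].filters
    assert by_pos[5000].p_value is not None  # tested, then filtered


def test_chip_without_peaks_skips_filter():
    counts = [make_count(30, 30, pos=100)]
    calls, _ = call_as(counts, 0.0, "chip", peaks=None, seed=7)
    assert calls[0].significant


def test_cnv_filter_excludes_abnormal_depth():
    counts = [make_count(30, 30, pos=50), make_count(30, 30, pos=250)]
    cnv = CnvProfile(window_size=100, normalized_depth={"c": np.array([1.0, 1.0, 2.0])})
    calls, _ = call_as(counts, 0.0, "rna", cnv=cnv, seed=8)
    by_pos = {c.count.pos: c for c in calls}
    assert by_pos[50].significant
    assert not by_pos[250].significant and "cnv" in by_pos[250].filters


def test_binomial_overcalls_on_overdispersed_data():
    """With real overdispersion, the binomial test (rho = 0) calls strictly
    more sites than the beta-binomial at the same nominal cutoff; at rho = 0
    the two tests are the same test and call identical sets."""
    counts = simulate_counts(10_000, 60, 0.12, seed=30)
    cutoff = 0.01
    p_binom = np.array([two_tailed_p(c.n_ref, c.n, 0.0) for c in counts])
    p_bb = np.array([two_tailed_p(c.n_ref, c.n, 0.12) for c in counts])
    assert (p_binom <= cutoff).sum() > (p_bb <= cutoff).sum()
    assert np.all((p_bb <= cutoff) <= (p_binom <= cutoff))  # nested sets

    counts0 = simulate_counts(5_000, 60, 0.0, seed=31)
    p_binom0 = np.array([two_tailed_p(c.n_ref, c.n, 0.0) for c in counts0])
    p_bb0 = np.array([two_tailed_p(c.n_ref, c.n, 1e-9) for c in counts0])
    assert np.array_equal(p_binom0 <= cutoff, p_bb0 <= cutoff)
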