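"""Complexity score, TFBS density, length/conservation/signal summaries."""

import math

import numpy as np
import pytest

from starr_audit import (
    GenomicInterval,
    IntervalSet,
    MotifNetwork,
    SignalTrack,
    TfbsHit,
    complexity_score,
    conservation_distribution,
    length_summary,
    peak_signal_strength,
    tfbs_density,
)
from starr_audit.metrics import HitIndex, hits_in_element


def hit(s, m, chrom="chr1"):
    return TfbsHit(GenomicInterval(chrom, s, s + 10), m)


@pytest.fixture
def network():
    # m1 has degree 4, m2 degree 2, m3 isolated (absent)
    return MotifNetwork(
        [("m1", "a"), ("m1", "b"), ("m1", "c"), ("m1", "d"), ("m2", "a"), ("m2", "b")]
    )


class TestComplexity:
    def test_hand_worked_value(self, network):
        """300-bp element, 6 hits over motifs with degrees {4, 2}:
        N_TFBS = 2 per 100 bp, D = 3, complexity = ln 7."""
        el = GenomicInterval("chr1", 0, 300)
        hits = [hit(i * 30, "m1") for i in range(3)] + [hit(100 + i * 30, "m2") for i in range(3)]
        assert complexity_score(el, hits, network) == pytest.approx(math.log(7))

    def test_no_hits_zero(self, network):
        assert complexity_score(GenomicInterval("chr1", 0, 300), [], network) == 0.0

    def test_isolated_motifs_zero(self, network):
        el = GenomicInterval("chr1", 0, 300)
        hits = [hit(10, "unknown_x"), hit(50, "unknown_y")]
        assert complexity_score(el, hits, network) == 0.0
        assert network.unknown_motifs == {"unknown_x", "unknown_y"}

    def test_monotone_in_hit_count_and_degree(self, network):
        el = GenomicInterval("chr1", 0, 1000)
        scores = [
            complexity_score(el, [hit(20 * i, "m2") for i in range(n)], network)
            for n in range(1, 6)
        ]
        assert np.all(np.diff(scores) > 0)
        low = complexity_score(el, [hit(0, "m2")], network)  # degree 2
        high = complexity_score(el, [hit(0, "m1")], network)  # degree 4
        assert high > low

    def test_unique_motif_dedup(self, network):
        """A motif hitting many times contributes its degree once to D."""
        el = GenomicInterval("chr1", 0, 100)
        many_m1 = [hit(i * 12, "m1") for i in range(5)]
        one_each = [hit(0, "m1"), hit(30, "m2")]
        d_many = 4.0  # unique motifs {m1}
        n_many = 5 / 1.0
        assert complexity_score(el, many_m1, network) == pytest.approx(
            math.log(n_many * d_many + 1)
        )
        d_mixed = 3.0  # {m1, m2}
        assert complexity_score(el, one_each, network) == pytest.approx(
            math.log(2 / 1.0 * d_mixed + 1)
        )

    def test_log_base_configurable(self, network):
        el = GenomicInterval("chr1", 0, 300)
        hits = [hit(i * 30, "m1") for i in range(3)] + [hit(100 + i * 30, "m2") for i in range(3)]
        assert complexity_score(el, hits, network, log_base=10) == pytest.approx(
            math.log10(7)
        )


class TestTfbsDensity:
    def test_arithmetic(self):
        els = IntervalSet([GenomicInterval("chr1", 0, 250)])
        hits = [hit(i * 40, "m") for i in range(5)]
        assert tfbs_density(els, hits) == pytest.approx(2.0)

    def test_no_hits_zero(self):
        assert tfbs_density(IntervalSet([GenomicInterval("chr1", 0, 100)]), []) == 0.0

    def test_scale_invariance(self):
        els1 = IntervalSet([GenomicInterval("chr1", 0, 250)])
        hits1 = [hit(i * 40, "m") for i in range(5)]
        els2 = IntervalSet(
            [GenomicInterval("chr1", 0, 250), GenomicInterval("chr1", 1000, 1250)]
        )
        hits2 = hits1 + [hit(1000 + i * 40, "m") for i in range(5)]
        assert tfbs_density(els1, hits1) == pytest.approx(tfbs_density(els2, hits2))

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            tfbs_density(IntervalSet(), [])


def test_hit_index_matches_linear_scan(rng):
    hits = [
        TfbsHit(GenomicInterval("chr1", int(s), int(s) + int(l)), f"m{int(s) % 7}")
        for s, l in zip(rng.integers(0, 50_000, 500), rng.integers(5, 40, 500))
    ]
    index = HitIndex(hits)
    for s, l in zip(rng.integers(0, 50_000, 30), rng.integers(50, 2000, 30)):
        el = GenomicInterval("chr1", int(s), int(s) + int(l))
        got = {h.interval.start for h in hits_in_element(el, index)}
        want = {h.interval.start for h in hits_in_element(el, hits)}
        assert got == want


class TestLengthSummary:
    def test_examples(self):
        s = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 400),
             GenomicInterval("chr1", 500, 800)]
        )
        out = length_summary(s)
        assert out == {"mean": 200.0, "median": 200.0, "n": 3}

    def test_even_count_midpoint_median(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 500)])
        assert length_summary(s)["median"] == 200.0

    def test_single_element(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 123)])
        out = length_summary(s)
        assert out["mean"] == out["median"] == 123.0


class TestConservationAndStrength:
    def test_constant_track(self):
        track = SignalTrack.from_dense({"chr1": np.full(100, 1.7)}, step=10)
        els = IntervalSet([GenomicInterval("chr1", 100, 200)])
        scores, uncovered = conservation_distribution(els, track)
        assert np.all(scores == 1.7) and len(scores) == 100 and uncovered == 0

    def test_uncovered_bases_counted(self):
        track = SignalTrack.from_dense({"chr1": np.ones(10)}, step=10)  # covers [0,100)
        els = IntervalSet([GenomicInterval("chr1", 50, 150)])
        scores, uncovered = conservation_distribution(els, track)
        assert len(scores) == 50 and uncovered == 50

    def test_two_group_mean(self):
        vals = np.concatenate([np.zeros(10), np.full(10, 2.0)])
        track = SignalTrack.from_dense({"chr1": vals}, step=10)
        els = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)])
        scores, _ = conservation_distribution(els, track)
        assert scores.mean() == pytest.approx(1.0)

    @pytest.mark.parametrize("factor, expected", [(1.0, 1.0), (3.0, 3.0), (0.0, 0.0)])
    def test_peak_signal_strength(self, factor, expected):
        signal = SignalTrack.from_dense({"chr1": np.full(100, factor)}, step=10, library_size=50.0)
        inp = SignalTrack.from_dense({"chr1": np.ones(100)}, step=10, library_size=50.0)
        peak = GenomicInterval("chr1", 100, 400)
        assert peak_signal_strength(peak, signal, inp) == pytest.approx(expected)


def test_planted_complexity_ordering(small_bundle):
    """Peak-hosting active CRMs are planted with denser, better-connected
    TFBSs, so their complexity exceeds peak-free CRMs (C > A ≈ B)."""
    from scipy.stats import mannwhitneyu

    b = small_bundle
    index = HitIndex(b.tfbs_hits)
    net = b.network
    cats = b.category_elements()
    c_scores = [complexity_score(el, index, net) for el in cats["C"]]
    ab_scores = [complexity_score(el, index, net) for el in list(cats["A"]) + list(cats["B"])]
    p = mannwhitneyu(c_scores, ab_scores, alternative="greater").pvalue
    assert p < 0.01
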