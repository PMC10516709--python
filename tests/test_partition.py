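"""Category A-F base partition: worked example, brute-force oracle,
conservation identities, element-level pairing statistics."""

import numpy as np
import pytest

from starr_audit import (
    CATEGORIES,
    GenomeSpec,
    GenomicInterval,
    IntervalSet,
    containment_class,
    cross_sample_activity,
    match_peaks_to_crms,
    partition_genome,
    peaks_per_crm,
)


def iv(s, e, chrom="chr1", id=None):
    return GenomicInterval(chrom, s, e, id=id)


def brute_force_counts(genome, active, nonactive, noncrms, peaks):
    """Literal per-base labeling loop — the independent oracle."""
    counts = {c: 0 for c in CATEGORIES}
    for chrom, size in genome.chrom_sizes.items():
        in_peak = np.zeros(size, dtype=bool)
        for p in peaks.merge():
            if p.chrom == chrom:
                in_peak[p.start : p.end] = True
        label = np.full(size, "", dtype=object)
        for s, name in ((active, "act"), (nonactive, "non"), (noncrms, "ncr")):
            for el in s:
                if el.chrom == chrom:
                    label[el.start : el.end] = name
        analyzable = np.zeros(size, dtype=bool)
        for r in genome.analyzable_regions:
            if r.chrom == chrom:
                analyzable[r.start : r.end] = True
        for pos in range(size):
            if not analyzable[pos]:
                continue
            cls, pk = label[pos], in_peak[pos]
            if cls == "act":
                counts["C" if pk else "B"] += 1
            elif cls == "non":
                counts["D" if pk else "A"] += 1
            else:
                counts["E" if pk else "F"] += 1
    return counts


def random_scenario(rng, size=4000):
    """A random valid CRM/non-CRM cover of one small chromosome plus peaks."""
    genome = GenomeSpec({"chr1": size})
    cuts = np.unique(rng.integers(1, size, rng.integers(3, 12)))
    bounds = [0, *cuts.tolist(), size]
    classes = rng.integers(0, 3, len(bounds) - 1)  # 0 active, 1 non-active, 2 non-CRM
    sets = {0: [], 1: [], 2: []}
    for (s, e), c in zip(zip(bounds[:-1], bounds[1:]), classes):
        sets[int(c)].append(iv(s, e))
    n_peaks = rng.integers(0, 8)
    peaks = IntervalSet(
        iv(int(s), min(int(s) + int(l), size))
        for s, l in zip(rng.integers(0, size - 1, n_peaks), rng.integers(1, size // 3, n_peaks))
    )
    return genome, IntervalSet(sets[0]), IntervalSet(sets[1]), IntervalSet(sets[2]), peaks


class TestPartitionGenome:
    def test_worked_example(self):
        """1-kb genome with one active CRM, one non-active CRM and two peaks."""
        genome = GenomeSpec({"chr1": 1000})
        result = partition_genome(
            genome,
            IntervalSet([iv(100, 300)]),
            IntervalSet([iv(500, 700)]),
            IntervalSet([iv(0, 100), iv(300, 500), iv(700, 1000)]),
            IntervalSet([iv(250, 450), iv(600, 900)]),
        )
        assert result.base_counts == {"A": 100, "B": 150, "C": 50, "D": 100, "E": 350, "F": 250}
        assert sum(result.base_counts.values()) == 1000

    def test_no_peaks_degenerate(self):
        genome = GenomeSpec({"chr1": 1000})
        r = partition_genome(
            genome,
            IntervalSet([iv(100, 300)]),
            IntervalSet([iv(500, 700)]),
            IntervalSet([iv(0, 100), iv(300, 500), iv(700, 1000)]),
            IntervalSet(),
        )
        assert r.base_counts["C"] == r.base_counts["D"] == r.base_counts["E"] == 0
        assert r.base_counts["B"] == 200 and r.base_counts["F"] == 600

    def test_saturating_peaks(self):
        genome = GenomeSpec({"chr1": 1000})
        r = partition_genome(
            genome,
            IntervalSet([iv(100, 300)]),
            IntervalSet([iv(500, 700)]),
            IntervalSet([iv(0, 100), iv(300, 500), iv(700, 1000)]),
            IntervalSet([iv(0, 1000)]),
        )
        assert r.base_counts["A"] == r.base_counts["B"] == r.base_counts["F"] == 0

    def test_overlapping_element_sets_rejected(self):
        genome = GenomeSpec({"chr1": 100})
        with pytest.raises(ValueError, match="overlap"):
            partition_genome(
                genome,
                IntervalSet([iv(0, 60)]),
                IntervalSet([iv(50, 100)]),
                IntervalSet(),
                IntervalSet(),
            )

    def test_coverage_gap_rejected(self):
        genome = GenomeSpec({"chr1": 100})
        with pytest.raises(ValueError, match="gap"):
            partition_genome(
                genome, IntervalSet([iv(0, 40)]), IntervalSet(), IntervalSet([iv(50, 100)]), IntervalSet()
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            genome, act, non, ncr, peaks = random_scenario(rng)
            result = partition_genome(genome, act, non, ncr, peaks, with_assignments=False)
            assert result.base_counts == brute_force_counts(genome, act, non, ncr, peaks)

    def test_unassessed_peak_bases_reported(self):
        genome = GenomeSpec(
            {"chr1": 1000},
            analyzable_regions=IntervalSet([iv(0, 800)]),
        )
        r = partition_genome(
            genome,
            IntervalSet([iv(100, 300)]),
            IntervalSet(),
            IntervalSet([iv(0, 100), iv(300, 800)]),
            IntervalSet([iv(700, 900)]),  # 100 bases beyond the analyzable end
        )
        assert r.unassessed_peak_bases == 100
        assert r.base_counts["E"] == 100

    def test_input_order_permutation_safe(self):
        rng = np.random.default_rng(3)
        genome, act, non, ncr, peaks = random_scenario(rng)
        base = partition_genome(genome, act, non, ncr, peaks, with_assignments=False)
        shuffled = IntervalSet(list(peaks)[::-1])
        again = partition_genome(genome, act, non, ncr, shuffled, with_assignments=False)
        assert base.base_counts == again.base_counts

    def test_assignment_tables_sum_to_base_counts(self, small_bundle):
        b = small_bundle
        r = partition_genome(
            b.genome, b.active_crms(), b.nonactive_crms(), b.noncrms, b.peaks
        )
        pa = r.peak_assignments
        for cat in "CDE":
            assert int(pa[cat].sum()) == r.base_counts[cat]
        assert int(pa["outside_analyzable"].sum()) == r.unassessed_peak_bases
        ca = r.crm_assignments
        for cat in "ABCD":
            assert int(ca[cat].sum()) == r.base_counts[cat]

    def test_strict_mode_shrinks_c_and_d(self):
        genome = GenomeSpec({"chr1": 1000})
        args = (
            IntervalSet([iv(100, 300)]),
            IntervalSet([iv(500, 700)]),
            IntervalSet([iv(0, 100), iv(300, 500), iv(700, 1000)]),
            IntervalSet([iv(250, 450), iv(600, 900)]),
        )
        default = partition_genome(genome, *args)
        strict = partition_genome(genome, *args, strict_element_rule=True)
        # neither peak passes the reciprocal rule here, so strict C=D=0
        assert strict.base_counts["C"] == 0 and strict.base_counts["D"] == 0
        assert default.base_counts["C"] == 50 and default.base_counts["D"] == 100


class TestElementPairing:
    def test_reciprocal_pairing_examples(self):
        crms = IntervalSet([iv(100, 300, id="crm")])
        assert match_peaks_to_crms(IntervalSet([iv(250, 450, id="p")]), crms) == []
        pairs = match_peaks_to_crms(IntervalSet([iv(150, 350, id="p")]), crms)
        assert len(pairs) == 1
        assert match_peaks_to_crms(IntervalSet(), crms) == []

    @pytest.mark.parametrize(
        "peak, crm, expected",
        [((50, 350), (100, 300), "full"), ((150, 350), (100, 300), "partial"),
         ((100, 300), (100, 300), "full")],
    )
    def test_containment(self, peak, crm, expected):
        assert containment_class(iv(*peak), iv(*crm)) == expected

    def test_peaks_per_crm_counts_distinct(self):
        crm = iv(0, 1000, id="c")
        pairs = [(iv(0, 600, id="p1"), crm), (iv(400, 1000, id="p2"), crm)]
        assert peaks_per_crm(crm, pairs) == 2
        assert peaks_per_crm(iv(2000, 3000, id="other"), pairs) == 0


class TestCrossSampleActivity:
    def test_fractions(self):
        d = {"x": {"c1", "c2"}}
        c = {"y": {"c1"}, "z": set(), "x": set()}
        m = cross_sample_activity(d, c)
        assert m.loc["x", "y"] == pytest.approx(50.0)
        assert m.loc["x", "z"] == 0.0
        assert m.loc["x", "x"] == 0.0

    def test_full_overlap_and_empty_row(self):
        m = cross_sample_activity({"x": {"c1"}, "w": set()}, {"y": {"c1"}})
        assert m.loc["x", "y"] == pytest.approx(100.0)
        assert np.isnan(m.loc["w", "y"])  # undefined when D(x) is empty
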