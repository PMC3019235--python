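"""Splicing detection is checked against an exhaustive brute-force oracle
that enumerates every junction pair and triple directly from the rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txseq import splicing as spl
from txseq.io_formats import JunctionRecord


def J(chrom, start, end, a=5, b=5, strand="+"):
    return JunctionRecord(chrom, start, end, strand, {"a": a, "b": b})


def full_coverage(length=100_000):
    return {"chr1": np.ones(length, dtype=np.int32)}


def exon_coverage(introns, length=100_000):
    """Coverage over everything except the given intron intervals."""
    cov = np.ones(length, dtype=np.int32)
    for s, e in introns:
        cov[s:e] = 0
    return {"chr1": cov}


def oracle_detect(junctions, coverage, sample=None, min_support=2):
    """Brute-force enumeration over all pairs/triples of junctions."""
    js = [j for j in junctions if j.count(sample) >= min_support]
    events = set()
    for j1, j2, j3 in itertools.permutations(js, 3):
        if (j1.chrom == j2.chrom == j3.chrom
                and j1.start == j3.start and j2.end == j3.end
                and j1.end < j2.start and j3.start < j2.start
                and j1.end < j3.end):
            events.add(("exon_skipping", j1.chrom,
                        ((j1.start, j1.end), (j2.start, j2.end)),
                        (j3.start, j3.end)))
    for j1, j2 in itertools.permutations(js, 2):
        if j1.chrom != j2.chrom:
            continue
        cov = coverage[j1.chrom]
        if j1.end == j2.end and j1.start > j2.start:  # j1 shorter intron
            if (cov[j2.start:j1.start] > 0).all():
                etype = "alt_5ss" if j1.strand != "-" else "alt_3ss"
                events.add((etype, j1.chrom, ((j1.start, j1.end),),
                            (j2.start, j2.end)))
        if j1.start == j2.start and j1.end < j2.end:  # j1 shorter intron
            if (cov[j1.end:j2.end] > 0).all():
                etype = "alt_3ss" if j1.strand != "-" else "alt_5ss"
                events.add((etype, j1.chrom, ((j1.start, j1.end),),
                            (j2.start, j2.end)))
    return events


def as_keyset(events):
    return {(e.event_type, e.chrom, e.inclusion_junctions,
             e.exclusion_junction) for e in events}


class TestDetection:
    def test_skipping_triple_detected(self):
        js = [J("chr1", 1000, 2000, 5), J("chr1", 2100, 3000, 4),
              J("chr1", 1000, 3000, 3)]
        cov = exon_coverage([(1000, 2000), (2100, 3000)])
        events = spl.detect_events(js, cov, sample="a")
        assert len(events) == 1
        ev = events[0]
        assert ev.event_type == "exon_skipping"
        assert ev.region == (2000, 2100)
        assert ev.inclusion_junctions == ((1000, 2000), (2100, 3000))
        assert ev.exclusion_junction == (1000, 3000)

    def test_low_exclusion_support_not_detected(self):
        js = [J("chr1", 1000, 2000, 5), J("chr1", 2100, 3000, 4),
              J("chr1", 1000, 3000, 1)]
        events = spl.detect_events(js, full_coverage(), sample="a")
        assert [e for e in events if e.event_type == "exon_skipping"] == []

    def test_alt5_requires_full_coverage(self):
        js = [J("chr1", 1000, 3000, 5), J("chr1", 1200, 3000, 5)]
        cov = full_coverage()
        events = spl.detect_events(js, cov, sample="a")
        assert [e.event_type for e in events] == ["alt_5ss"]
        assert events[0].region == (1000, 1200)
        cov["chr1"][1100] = 0  # a hole between the alternative donors
        assert spl.detect_events(js, cov, sample="a") == []

    def test_alt3_shared_donor(self):
        js = [J("chr1", 1000, 2000, 5), J("chr1", 1000, 2300, 5)]
        events = spl.detect_events(js, full_coverage(), sample="a")
        assert [e.event_type for e in events] == ["alt_3ss"]
        assert events[0].region == (2000, 2300)
        assert events[0].inclusion_junctions == ((1000, 2000),)

    def test_minus_strand_swaps_labels(self):
        js = [J("chr1", 1000, 2000, 5, strand="-"),
              J("chr1", 1000, 2300, 5, strand="-")]
        events = spl.detect_events(js, full_coverage(), sample="a")
        assert [e.event_type for e in events] == ["alt_5ss"]

    def test_twelve_junction_set_matches_oracle(self):
        js = [
            J("chr1", 1000, 2000, 5, 0), J("chr1", 2100, 3000, 4, 1),
            J("chr1", 1000, 3000, 3, 2), J("chr1", 1000, 2300, 2, 0),
            J("chr1", 5000, 6000, 9, 9), J("chr1", 5500, 6000, 2, 0),
            J("chr1", 5000, 5800, 1, 1), J("chr1", 8000, 9000, 2, 2),
            J("chr2", 1000, 2000, 5, 5), J("chr2", 1000, 2000 + 500, 5, 0),
            J("chr2", 900, 2000, 3, 3), J("chr2", 2100, 3000, 0, 1),
        ]
        coverage = {"chr1": np.ones(100_000, dtype=np.int32),
                    "chr2": np.ones(100_000, dtype=np.int32)}
        coverage["chr2"][950] = 0
        for sample in ("a", "b", None):
            detected = spl.detect_events(js, coverage, sample=sample)
            assert as_keyset(detected) == oracle_detect(js, coverage, sample)

    def test_randomized_sets_match_oracle(self):
        rng = np.random.default_rng(17)
        boundaries = [1000, 1500, 2000, 2600, 3300, 4100, 5000]
        for _ in range(20):
            n = rng.integers(4, 10)
            js = []
            seen = set()
            for _ in range(n):
                s, e = sorted(rng.choice(boundaries, size=2, replace=False))
                if (s, e) in seen:
                    continue
                seen.add((s, e))
                js.append(J("chr1", int(s), int(e),
                            int(rng.integers(0, 6)), int(rng.integers(0, 6))))
            cov = full_coverage(10_000)
            for pos in rng.choice(10_000, size=5):
                cov["chr1"][pos] = 0
            detected = spl.detect_events(js, cov, sample=None)
            assert as_keyset(detected) == oracle_detect(js, cov, None)

    def test_detection_monotone_in_counts(self):
        js = [J("chr1", 1000, 2000, 2, 0), J("chr1", 2100, 3000, 2, 0),
              J("chr1", 1000, 3000, 2, 0)]
        before = as_keyset(spl.detect_events(js, full_coverage(), sample=None))
        boosted = [J("chr1", j.start, j.end, j.counts["a"] + 3,
                     j.counts["b"] + 2) for j in js]
        after = as_keyset(spl.detect_events(boosted, full_coverage(), sample=None))
        assert before <= after

    def test_combined_superset_of_per_sample(self):
        rng = np.random.default_rng(3)
        boundaries = [1000, 1500, 2000, 2600, 3300]
        js = []
        for s, e in itertools.combinations(boundaries, 2):
            js.append(J("chr1", s, e, int(rng.integers(0, 4)),
                        int(rng.integers(0, 4))))
        cov = full_coverage(10_000)
        combined = as_keyset(spl.detect_events(js, cov, sample=None))
        for sample in ("a", "b"):
            assert as_keyset(spl.detect_events(js, cov, sample=sample)) \
                <= combined


def fisher_enumeration(table):
    """Oracle: two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, row1, col1)
        if px <= obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


class TestDifferentialSplicing:
    def make_event(self, inc_a, exc_a, inc_b, exc_b):
        ev = spl.ASEvent(
            event_type="exon_skipping", chrom="chr1", strand="+",
            inclusion_junctions=((1000, 2000), (2100, 3000)),
            exclusion_junction=(1000, 3000), region=(2000, 2100))
        ev.inclusion_counts = {"a": inc_a, "b": inc_b}
        ev.exclusion_counts = {"a": exc_a, "b": exc_b}
        return ev

    def test_equal_ratios_null(self):
        ev = self.make_event(10.0, 20, 10.0, 20)
        res = spl.test_differential_splicing([ev], "a", "b")
        assert res.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_worked_example(self):
        # inclusion junctions (10, 12) average 11; (30, 34) average 32
        js = [J("chr1", 1000, 2000, 10, 30), J("chr1", 2100, 3000, 12, 34),
              J("chr1", 1000, 3000, 20, 10)]
        cov = exon_coverage([(1000, 2000), (2100, 3000)])
        events = spl.detect_events(js, cov, sample=None)
        spl.event_counts(events, js, ["a", "b"])
        res = spl.test_differential_splicing(events, "a", "b")
        row = res.loc[0]
        assert (row.incA, row.excA, row.incB, row.excB) == (11, 20, 32, 10)
        assert row.odds_ratio == pytest.approx(5.82, abs=0.01)
        assert row.p == pytest.approx(
            fisher_enumeration([[11, 20], [32, 10]]), rel=1e-9)

    def test_fifty_random_tables_match_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            table = rng.integers(0, 30, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            _, p = stats.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(fisher_enumeration(table), rel=1e-9)

    def test_half_away_rounding(self):
        ev = self.make_event(10.5, 20, 2.5, 20)
        table = spl.fisher_table(ev, "a", "b")
        assert table[0, 0] == 11 and table[1, 0] == 3

    def test_zero_margin(self):
        ev = self.make_event(0.0, 0, 5.0, 10)
        res = spl.test_differential_splicing([ev], "a", "b")
        assert res.loc[0, "p"] == 1.0
        assert np.isnan(res.loc[0, "odds_ratio"])

    def test_haldane_correction_on_zero_cell(self):
        ev = self.make_event(0.0, 20, 10.0, 20)
        res = spl.test_differential_splicing([ev], "a", "b")
        expected = ((10.5 / 20.5) / (0.5 / 20.5))
        assert res.loc[0, "odds_ratio"] == pytest.approx(expected)

    def test_symmetry_properties(self):
        table = np.array([[11, 20], [32, 10]])
        _, p = stats.fisher_exact(table)
        _, p_swapped = stats.fisher_exact(table[::-1, ::-1])
        assert p == pytest.approx(p_swapped)
        or1 = spl._sample_odds_ratio(table)
        or2 = spl._sample_odds_ratio(table[:, ::-1])
        assert or1 == pytest.approx(1.0 / or2)

    def test_bh_within_event_type(self):
        events = [self.make_event(10.0, 20, 30.0, 5) for _ in range(3)]
        alt = spl.ASEvent("alt_5ss", "chr1", "+", ((1000, 2000),),
                          (900, 2000), (900, 1000))
        alt.inclusion_counts = {"a": 10.0, "b": 30.0}
        alt.exclusion_counts = {"a": 20, "b": 5}
        res = spl.test_differential_splicing(events + [alt], "a", "b")
        skip = res[res.event_type == "exon_skipping"]
        assert np.allclose(skip["q"], skip["p"])  # 3 equal p-values
        assert res[res.event_type == "alt_5ss"]["q"].iloc[0] == \
            pytest.approx(res[res.event_type == "alt_5ss"]["p"].iloc[0])


class TestSyntheticRecovery:
    def test_planted_events_detected_and_significant(self, default_sim,
                                                     default_fragments):
        from txseq import novel_tu as ntu

        config, bundle, reads = default_sim
        chrom_lengths = {c: bundle.genome.length(c)
                         for c in bundle.genome.chroms}
        coverage = ntu.coverage_from_fragments(default_fragments, chrom_lengths)
        events = spl.detect_events(reads.junctions, coverage, sample=None)
        spl.event_counts(events, reads.junctions, list(config.samples))
        res = spl.test_differential_splicing(events, *config.samples)
        truth = bundle.truth.as_events
        qualifying = hits = 0
        for _, row in truth.iterrows():
            match = res[(res.event_type == row.event_type)
                        & (res.region_start == row.region_start)
                        & (res.region_end == row.region_end)]
            assert len(match) == 1, f"planted event missing: {row.gene_id}"
            if row.event_type != "exon_skipping":
                continue  # planted odds shift >= 3 only for skipping
            total = match[["incA", "excA", "incB", "excB"]].sum(axis=1).iloc[0]
            if total >= 100:
                qualifying += 1
                hits += bool(match["p"].iloc[0] < 0.01)
        assert qualifying > 0
        assert hits / qualifying >= 0.9
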