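"""Junction-based alternative-splicing detection and differential testing.

Only the three junction-definable event classes are handled: exon skipping,
alternative 5' splice site and alternative 3' splice site. Reads over
intronic regions and assembled first/last exons are deliberately not used,
so intron retention and terminal-exon events are out of scope by
construction.

Detection rules (counts evaluated in the dataset where the event is
declared — a single sample, or the combined dataset with summed counts):

* exon skipping: junction triple J1=[d,a1), J2=[d2,a), J3=[d,a) with
  a1 < d2 (the skipped exon is [a1,d2)), all three supported by >=2
  fragments;
* alt splice-site events: a junction pair sharing one boundary, both
  supported by >=2 fragments, with every base between the two alternative
  splice sites covered by >=1 fragment. On the '+' strand a shared intron
  end (acceptor) with distinct starts is an alternative 5' site and a
  shared start a 3' site; '-' strand junctions swap the labels; unstranded
  junctions use the '+' convention.

For the two-sample test the exon-skipping inclusion count is the mean of
the two inclusion junctions, rounded half away from zero (Fisher's exact
test needs integers); alt events use the two junction counts directly. The
odds ratio is oriented second-sample-over-first, inclusion-over-exclusion.
For alt events "inclusion" is the junction with the shorter intron (the one
keeping more exonic sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, JunctionRecord

MIN_JUNCTION_SUPPORT = 2
DEFAULT_FDR = 0.01

EXON_SKIPPING = "exon_skipping"
ALT_5SS = "alt_5ss"
ALT_3SS = "alt_3ss"


@dataclass
class ASEvent:
    event_type: str
    chrom: str
    strand: str
    #: exon skipping: (J1, J2) intron intervals; alt events: (inclusion,)
    inclusion_junctions: tuple[tuple[int, int], ...]
    #: exon skipping: exclusion junction; alt events: the alternative junction
    exclusion_junction: tuple[int, int]
    #: skipped exon, or the region between the alternative splice sites
    region: tuple[int, int]
    gene_id: str | None = None
    #: per-sample counts, filled by ``event_counts``
    inclusion_counts: dict[str, float] = field(default_factory=dict)
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.inclusion_junctions,
                self.exclusion_junction)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _covered(coverage: Mapping[str, np.ndarray], chrom: str,
             start: int, end: int) -> bool:
    cov = coverage.get(chrom)
    if cov is None or end > len(cov):
        return False
    return bool((cov[start:end] > 0).all())


def detect_events(
    junctions: Sequence[JunctionRecord],
    coverage: Mapping[str, np.ndarray],
    sample: str | None = None,
    min_support: int = MIN_JUNCTION_SUPPORT,
) -> list[ASEvent]:
    """Detect AS events in one dataset (``sample=None`` = combined counts).

    ``coverage`` maps chromosome -> per-base fragment coverage of the same
    dataset, used for the 100%-coverage requirement of alt-site events.
    """
    events: dict[tuple, ASEvent] = {}
    by_chrom: dict[str, list[JunctionRecord]] = {}
    for j in junctions:
        if j.count(sample) >= min_support:
            by_chrom.setdefault(j.chrom, []).append(j)

    for chrom, js in by_chrom.items():
        by_start: dict[int, list[JunctionRecord]] = {}
        by_end: dict[int, list[JunctionRecord]] = {}
        for j in js:
            by_start.setdefault(j.start, []).append(j)
            by_end.setdefault(j.end, []).append(j)

        # exon skipping: J3=[d,a) excludes the exon; J1=[d,a1), J2=[d2,a)
        for j3 in js:
            for j1 in by_start.get(j3.start, []):
                if j1.end >= j3.end:
                    continue
                for j2 in by_end.get(j3.end, []):
                    if j2.start <= j1.end or j2.start <= j3.start:
                        continue
                    ev = ASEvent(
                        event_type=EXON_SKIPPING, chrom=chrom,
                        strand=j3.strand,
                        inclusion_junctions=((j1.start, j1.end),
                                             (j2.start, j2.end)),
                        exclusion_junction=(j3.start, j3.end),
                        region=(j1.end, j2.start),
                    )
                    events.setdefault(ev.key, ev)

        # alt splice sites: pairs sharing one boundary + full coverage between
        for shared, group in by_end.items():
            group = sorted(group, key=lambda j: j.start)
            for i in range(len(group)):
                for k in range(i + 1, len(group)):
                    short, long = group[k], group[i]  # larger start = shorter intron
                    if not _covered(coverage, chrom, long.start, short.start):
                        continue
                    etype = ALT_5SS if short.strand != "-" else ALT_3SS
                    ev = ASEvent(
                        event_type=etype, chrom=chrom, strand=short.strand,
                        inclusion_junctions=((short.start, short.end),),
                        exclusion_junction=(long.start, long.end),
                        region=(long.start, short.start),
                    )
                    events.setdefault(ev.key, ev)
        for shared, group in by_start.items():
            group = sorted(group, key=lambda j: j.end)
            for i in range(len(group)):
                for k in range(i + 1, len(group)):
                    short, long = group[i], group[k]  # smaller end = shorter intron
                    if not _covered(coverage, chrom, short.end, long.end):
                        continue
                    etype = ALT_3SS if short.strand != "-" else ALT_5SS
                    ev = ASEvent(
                        event_type=etype, chrom=chrom, strand=short.strand,
                        inclusion_junctions=((short.start, short.end),),
                        exclusion_junction=(long.start, long.end),
                        region=(short.end, long.end),
                    )
                    events.setdefault(ev.key, ev)

    return sorted(events.values(),
                  key=lambda e: (e.chrom, e.region, e.event_type))


def event_counts(
    events: Sequence[ASEvent],
    junctions: Sequence[JunctionRecord],
    samples: Sequence[str],
) -> list[ASEvent]:
    """Fill per-sample inclusion/exclusion counts on detected events.

    Exon-skipping inclusion is the mean of the two inclusion junctions
    (kept as a float here; rounding to an integer happens at test time).
    """
    lookup: dict[tuple[str, int, int], JunctionRecord] = {
        (j.chrom, j.start, j.end): j for j in junctions
    }
    for ev in events:
        for s in samples:
            incs = [lookup[(ev.chrom, a, b)].count(s)
                    if (ev.chrom, a, b) in lookup else 0
                    for a, b in ev.inclusion_junctions]
            ev.inclusion_counts[s] = float(np.mean(incs))
            key = (ev.chrom, *ev.exclusion_junction)
            ev.exclusion_counts[s] = lookup[key].count(s) if key in lookup else 0
    return list(events)


def assign_genes(events: Sequence[ASEvent], genes: Sequence[GeneModel]) -> None:
    """Assign each event to the gene whose span contains its exclusion
    junction; events containable in no (or no single) gene keep None."""
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        s, e = g.span
        spans.setdefault(g.chrom, []).append((s, e, g.gene_id))
    for ev in events:
        js, je = ev.exclusion_junction
        hits = [gid for s, e, gid in spans.get(ev.chrom, ())
                if s <= js and je <= e]
        ev.gene_id = hits[0] if len(hits) == 1 else None


def fisher_table(ev: ASEvent, sample_a: str, sample_b: str) -> np.ndarray:
    """2x2 table [[incA, excA], [incB, excB]] with the exon-skipping
    inclusion average rounded half away from zero."""
    inc_a = _round_half_away(ev.inclusion_counts[sample_a])
    inc_b = _round_half_away(ev.inclusion_counts[sample_b])
    return np.array([[inc_a, ev.exclusion_counts[sample_a]],
                     [inc_b, ev.exclusion_counts[sample_b]]], dtype=np.int64)


def _sample_odds_ratio(table: np.ndarray) -> float:
    """(incB/excB) / (incA/excA); Haldane 0.5 correction when any cell is 0."""
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float((t[1, 0] / t[1, 1]) / (t[0, 0] / t[0, 1]))


def test_differential_splicing(
    events: Sequence[ASEvent],
    sample_a: str,
    sample_b: str,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Fisher's exact test per event; BH correction within each event type.

    A table with a zero margin carries no information: p = 1 and the odds
    ratio is reported missing.
    """
    rows = []
    for ev in events:
        table = fisher_table(ev, sample_a, sample_b)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p, oratio = 1.0, np.nan
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
            oratio = _sample_odds_ratio(table)
        rows.append({
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "region_start": ev.region[0],
            "region_end": ev.region[1],
            "gene_id": ev.gene_id if ev.gene_id is not None else "",
            "incA": int(table[0, 0]), "excA": int(table[0, 1]),
            "incB": int(table[1, 0]), "excB": int(table[1, 1]),
            "odds_ratio": oratio,
            "p": p,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["sig"] = pd.Series(dtype=bool)
        return out
    out["q"] = np.nan
    for etype, grp in out.groupby("event_type"):
        out.loc[grp.index, "q"] = multipletests(grp["p"], method="fdr_bh")[1]
    out["sig"] = out["q"] <= fdr
    return out
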