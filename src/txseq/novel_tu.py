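"""Novel transcribed-unit discovery: a simplified coverage/junction
assembler, the four-filter definition of a novel TU, external-evidence
annotation, and differential testing of TUs alongside genes.

The assembler is deliberately simple — maximal covered runs become blocks,
and blocks are joined when a sufficiently supported junction connects them.
It stands in for a statistical path-significance assembler, which is an
upstream dependency of this stage, not its contribution. The reusable part
is the filter/evidence stack:

1. at least 1000 bp from any known gene boundary;
2. length >= 500 bp;
3. at least 40 fragments per kb of assembled length;
4. less than 50% of bases overlapped by repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, merge, overlap_length, total_length
from .io_formats import AlignedFragment, GeneModel, ScoreTrack
from .polyadenylation import PolyASite

MIN_GENE_DISTANCE = 1000
MIN_TU_LENGTH = 500
MIN_FRAGMENTS_PER_KB = 40.0
MAX_REPEAT_FRACTION = 0.5
MIN_EST_COVERAGE = 0.5
MIN_JOIN_SUPPORT = 2


@dataclass
class AssembledTranscript:
    chrom: str
    blocks: list[Interval]
    fragment_count: int = 0
    strand: str = "."

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def length(self) -> int:
        return total_length(self.blocks)


@dataclass
class NovelTU:
    chrom: str
    blocks: list[Interval]
    fragment_count: int
    distance_to_gene: float
    repeat_fraction: float
    strand: str = "."
    polya_supported: bool = False
    est_coverage: float = 0.0
    mean_conservation: float | None = None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def length(self) -> int:
        return total_length(self.blocks)

    @property
    def fragments_per_kb(self) -> float:
        return 1000.0 * self.fragment_count / self.length

    @property
    def est_supported(self) -> bool:
        return self.est_coverage >= MIN_EST_COVERAGE

    @property
    def tu_id(self) -> str:
        return f"TU:{self.chrom}:{self.start}-{self.end}"


def implied_coverage_depth(fragments_per_kb: float,
                           fragment_length: float) -> float:
    """Mean per-base coverage implied by a fragments-per-kb expression
    threshold when each fragment spans ``fragment_length`` bases."""
    return fragments_per_kb * fragment_length / 1000.0


def coverage_from_fragments(
    fragments: Sequence[AlignedFragment],
    chrom_lengths: Mapping[str, int],
    unique_only: bool = True,
) -> dict[str, np.ndarray]:
    """Per-base fragment coverage arrays (aligned blocks only, so mate holes
    and junction gaps contribute nothing)."""
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for frag in fragments:
        if unique_only and not frag.unique:
            continue
        arr = cov.get(frag.chrom)
        if arr is None:
            continue
        for s, e in frag.blocks:
            arr[s:min(e, len(arr))] += 1
    return cov


def assemble_transcripts(
    coverage: Mapping[str, np.ndarray],
    junctions: Sequence,
    fragments: Sequence[AlignedFragment],
    min_join_support: int = MIN_JOIN_SUPPORT,
    sample: str | None = None,
) -> list[AssembledTranscript]:
    """Coverage islands joined through sufficiently supported junctions.

    A junction [s, e) connects the island containing base s-1 to the island
    containing base e when its support in the chosen dataset is at least
    ``min_join_support``.
    """
    out: list[AssembledTranscript] = []
    for chrom in sorted(coverage):
        islands = _covered_islands(coverage[chrom])
        if not islands:
            continue
        parent = list(range(len(islands)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        idx = _IslandIndex(islands)
        for j in junctions:
            if j.chrom != chrom or j.count(sample) < min_join_support:
                continue
            a = idx.containing(j.start - 1)
            b = idx.containing(j.end)
            if a is not None and b is not None and a != b:
                parent[find(a)] = find(b)

        groups: dict[int, list[Interval]] = {}
        for i, iv in enumerate(islands):
            groups.setdefault(find(i), []).append(iv)
        for blocks in groups.values():
            out.append(AssembledTranscript(chrom=chrom, blocks=sorted(blocks)))

    _count_supporting_fragments(out, fragments)
    return sorted(out, key=lambda t: (t.chrom, t.start))


def _covered_islands(cov: np.ndarray) -> list[Interval]:
    mask = cov > 0
    if not mask.any():
        return []
    diffs = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(diffs[mask[diffs + 1]] + 1)
    ends = list(diffs[~mask[diffs + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(cov))
    return list(zip(starts, ends))


class _IslandIndex:
    def __init__(self, islands: list[Interval]):
        self._starts = np.array([s for s, _ in islands])
        self._ends = np.array([e for _, e in islands])

    def containing(self, pos: int) -> int | None:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        if i >= 0 and self._starts[i] <= pos < self._ends[i]:
            return i
        return None


def _count_supporting_fragments(transcripts: list[AssembledTranscript],
                                fragments: Sequence[AlignedFragment]) -> None:
    by_chrom: dict[str, list[AssembledTranscript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        starts = np.array([t.start for t in ts])
        for frag in fragments:
            if frag.chrom != chrom or not frag.unique:
                continue
            i = int(np.searchsorted(starts, frag.end, side="right")) - 1
            while i >= 0 and ts[i].end > frag.start:
                if any(bs < e and s < be
                       for s, e in ts[i].blocks
                       for bs, be in frag.blocks):
                    ts[i].fragment_count += 1
                i -= 1


def filter_novel_tus(
    transcripts: Sequence[AssembledTranscript],
    genes: Sequence[GeneModel],
    repeats: Mapping[str, Sequence[Interval]],
    min_distance: int = MIN_GENE_DISTANCE,
    min_length: int = MIN_TU_LENGTH,
    min_fragments_per_kb: float = MIN_FRAGMENTS_PER_KB,
    max_repeat_fraction: float = MAX_REPEAT_FRACTION,
    min_fragments_absolute: int | None = None,
) -> list[NovelTU]:
    """Apply the four novel-TU criteria to assembled transcripts.

    The expression criterion defaults to the per-kilobase reading (40
    fragments per kb); pass ``min_fragments_absolute`` to use an absolute
    fragment count instead.
    """
    gene_bounds: dict[str, list[Interval]] = {}
    for g in genes:
        gene_bounds.setdefault(g.chrom, []).append(g.span)
    for chrom in gene_bounds:
        gene_bounds[chrom] = merge(gene_bounds[chrom])

    out: list[NovelTU] = []
    for t in transcripts:
        length = t.length
        if length < min_length or length == 0:
            continue
        dist = _distance_to_nearest(gene_bounds.get(t.chrom, []), t.start, t.end)
        if dist < min_distance:
            continue
        if min_fragments_absolute is not None:
            if t.fragment_count < min_fragments_absolute:
                continue
        elif 1000.0 * t.fragment_count / length < min_fragments_per_kb:
            continue
        rep = overlap_length(t.blocks, list(repeats.get(t.chrom, []))) / length
        if rep >= max_repeat_fraction:
            continue
        out.append(NovelTU(
            chrom=t.chrom, blocks=list(t.blocks),
            fragment_count=t.fragment_count,
            distance_to_gene=dist, repeat_fraction=rep, strand=t.strand,
        ))
    return out


def _distance_to_nearest(bounds: Sequence[Interval], start: int, end: int) -> float:
    """Distance from [start, end) to the nearest gene span; 0 if overlapping."""
    if not bounds:
        return float("inf")
    best = float("inf")
    for s, e in bounds:
        if s < end and start < e:
            return 0.0
        best = min(best, s - end if s >= end else start - e)
    return best


def annotate_tu_evidence(
    tus: Sequence[NovelTU],
    polya_sites: Sequence[PolyASite],
    ests: Mapping[str, Sequence[Interval]],
    conservation: ScoreTrack | None,
) -> list[NovelTU]:
    """PolyA support (a site's representative position inside the TU), EST
    coverage fraction, and mean conservation over scored bases."""
    for tu in tus:
        for site in polya_sites:
            if site.chrom == tu.chrom and any(
                    s <= site.position < e for s, e in tu.blocks):
                tu.polya_supported = True
                if tu.strand == ".":
                    tu.strand = site.strand
                break
        est_ivs = list(ests.get(tu.chrom, []))
        tu.est_coverage = (overlap_length(tu.blocks, est_ivs) / tu.length
                           if tu.length else 0.0)
        if conservation is not None:
            tu.mean_conservation = conservation.mean_over(tu.chrom, tu.blocks)
    return list(tus)


def tu_table(tus: Sequence[NovelTU]) -> pd.DataFrame:
    rows = []
    for tu in tus:
        rows.append({
            "tu_id": tu.tu_id,
            "chrom": tu.chrom,
            "start": tu.start,
            "end": tu.end,
            "length": tu.length,
            "fragments": tu.fragment_count,
            "fragments_per_kb": tu.fragments_per_kb,
            "distance_to_gene": tu.distance_to_gene,
            "repeat_fraction": tu.repeat_fraction,
            "polya_supported": tu.polya_supported,
            "est_coverage": tu.est_coverage,
            "est_supported": tu.est_supported,
            "mean_conservation": (np.nan if tu.mean_conservation is None
                                  else tu.mean_conservation),
        })
    return pd.DataFrame(rows)


def tu_count_matrix(
    tus: Sequence[NovelTU],
    fragments: Sequence[AlignedFragment],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Per-sample fragment counts (any overlap) for each TU."""
    counts = pd.DataFrame(0, index=[t.tu_id for t in tus],
                          columns=list(samples), dtype=int)
    by_chrom: dict[str, list[NovelTU]] = {}
    for t in tus:
        by_chrom.setdefault(t.chrom, []).append(t)
    for frag in fragments:
        if not frag.unique or frag.sample not in counts.columns:
            continue
        for t in by_chrom.get(frag.chrom, ()):
            if t.start < frag.end and frag.start < t.end and any(
                    bs < e and s < be
                    for s, e in t.blocks for bs, be in frag.blocks):
                counts.at[t.tu_id, frag.sample] += 1
    return counts


def test_tu_differential(
    gene_counts: pd.DataFrame,
    tu_counts: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Row-bind TU counts to gene counts, quantile normalize the combined
    matrix, run the NB exact test, and report the TU subset."""
    from .expression import nb_exact_test, quantile_normalize

    combined = pd.concat([gene_counts, tu_counts])
    normalized = quantile_normalize(combined)
    results = nb_exact_test(normalized, fdr=fdr)
    mask = results["feature"].isin(tu_counts.index)
    return results[mask].reset_index(drop=True)


def write_tu_bed12(tus: Sequence[NovelTU], path) -> None:
    """BED12 with fragments-per-kb (rounded, capped at 1000) as score."""
    with open(path, "w") as fh:
        for tu in sorted(tus, key=lambda t: (t.chrom, t.start)):
            sizes = ",".join(str(e - s) for s, e in tu.blocks)
            offsets = ",".join(str(s - tu.start) for s, e in tu.blocks)
            score = min(1000, int(round(tu.fragments_per_kb)))
            fh.write("\t".join(map(str, [
                tu.chrom, tu.start, tu.end, tu.tu_id, score, tu.strand,
                tu.start, tu.end, "0", len(tu.blocks), sizes, offsets,
            ])) + "\n")
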