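"""Readers and writers for the external formats the pipeline touches.

One coordinate convention holds everywhere inside the package: 0-based,
half-open. GTF (1-based inclusive) and SAM (1-based) are converted at the
boundary; BED, bedGraph and our own TSV outputs are native.

The protocol is unstranded: strand on a fragment is never inferred from its
alignment orientation. Strand information enters only through annotation
(GTF, junction tables) or through polyA-tail logic downstream.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .intervals import Interval, merge, total_length

logger = logging.getLogger(__name__)

#: SAM tag whose value > 1 marks a multi-mapping record. The 20-location
#: multiread cap is applied upstream of this package; here a fragment is
#: "unique" unless the declared indicator says otherwise.
MULTIMAP_TAG = "NH"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings with an optional repeat annotation.

    Repeat intervals are half-open. When the sequence itself is soft-masked
    (lowercase), ``from_fasta`` derives the repeat intervals from case.
    """

    chroms: dict[str, str]
    repeats: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.repeats.items():
            n = len(self.chroms[chrom])
            for s, e in ivs:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"repeat interval [{s},{e}) out of bounds on {chrom} (len {n})"
                    )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clamped to the chromosome bounds."""
        seq = self.chroms[chrom]
        return seq[max(0, start):max(0, end)]

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        chroms: dict[str, str] = {}
        repeats: dict[str, list[Interval]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            chroms[rec.id] = seq
            ivs = _lowercase_runs(seq)
            if ivs:
                repeats[rec.id] = ivs
        return cls(chroms=chroms, repeats=repeats)

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self.chroms[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def _lowercase_runs(seq: str) -> list[Interval]:
    runs: list[Interval] = []
    start = None
    for i, c in enumerate(seq):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]  # sorted, non-overlapping, genomic order

    @property
    def length(self) -> int:
        return total_length(self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: list[Transcript]

    @property
    def span(self) -> Interval:
        starts = [t.exons[0][0] for t in self.transcripts]
        ends = [t.exons[-1][1] for t in self.transcripts]
        return (min(starts), max(ends))

    @property
    def exonic_union(self) -> list[Interval]:
        """Union of exonic bases over all isoforms."""
        return merge(iv for t in self.transcripts for iv in t.exons)


@dataclass
class AlignedFragment:
    """One sequenced cDNA fragment: paired-end mates are merged into a single
    fragment so that a fragment is the unit of all counting."""

    fragment_id: str
    sample: str
    chrom: str
    blocks: list[Interval]  # sorted, non-overlapping
    unique: bool = True
    paired: bool = False
    #: intron intervals implied by N gaps within a read (not by mate gaps)
    junctions: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return total_length(self.blocks)


@dataclass
class JunctionRecord:
    chrom: str
    start: int  # intron start, 0-based
    end: int    # intron end, half-open
    strand: str = "."
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"junction end {self.end} <= start {self.start}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative junction support")

    def count(self, sample: str | None = None) -> int:
        """Support in one sample, or summed over all samples (combined)."""
        if sample is None:
            return sum(self.counts.values())
        return self.counts.get(sample, 0)


class ScoreTrack:
    """Per-base numeric scores over explicit intervals; unscored bases are
    missing (excluded from means), not zero."""

    def __init__(self, entries: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._entries: dict[str, list[tuple[int, int, float]]] = {
            chrom: sorted((int(s), int(e), float(v)) for s, e, v in ivs)
            for chrom, ivs in entries.items()
        }
        self._starts = {
            chrom: [s for s, _, _ in ivs] for chrom, ivs in self._entries.items()
        }

    def mean_over(self, chrom: str, intervals: Sequence[Interval]) -> float | None:
        """Mean score over the scored bases of ``intervals``; None if no base
        of the intervals is scored."""
        entries = self._entries.get(chrom)
        if not entries:
            return None
        starts = self._starts[chrom]
        tot = 0.0
        n = 0
        for qs, qe in intervals:
            i = max(0, bisect_right(starts, qs) - 1)
            for s, e, v in entries[i:]:
                if s >= qe:
                    break
                ov = min(e, qe) - max(s, qs)
                if ov > 0:
                    tot += v * ov
                    n += ov
        return tot / n if n else None

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "ScoreTrack":
        entries: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                entries.setdefault(chrom, []).append((int(s), int(e), float(v)))
        return cls(entries)

    @classmethod
    def from_fixedstep_wig(cls, path: str | os.PathLike) -> "ScoreTrack":
        entries: dict[str, list[tuple[int, int, float]]] = {}
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("track"):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wig is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                else:
                    entries.setdefault(chrom, []).append((pos, pos + span, float(line)))
                    pos += step
        return cls(entries)

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._entries):
                for s, e, v in self._entries[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    pass


def parse_gene_models(gtf_path: str | os.PathLike) -> list[GeneModel]:
    """Parse exon records of a GTF into GeneModel objects.

    1-based inclusive GTF coordinates become 0-based half-open. Transcripts
    with internally overlapping exons are rejected with a diagnostic;
    malformed lines are reported with their line numbers and skipped.
    """
    exons: dict[tuple[str, str], dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("GTF line %d: expected 9 fields, got %d — skipped",
                               lineno, len(fields))
                continue
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError:
                logger.warning("GTF line %d: non-numeric coordinates — skipped", lineno)
                continue
            attrs = _parse_gtf_attributes(fields[8])
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id")
            if not gid or not tid:
                logger.warning("GTF line %d: missing gene_id/transcript_id — skipped",
                               lineno)
                continue
            key = (gid, tid)
            rec = exons.setdefault(
                key, {"chrom": fields[0], "strand": fields[6], "exons": []}
            )
            rec["exons"].append((start, end))

    genes: dict[str, GeneModel] = {}
    for (gid, tid), rec in exons.items():
        ivs = sorted(rec["exons"])
        if any(ivs[i][1] > ivs[i + 1][0] for i in range(len(ivs) - 1)):
            logger.warning("transcript %s of gene %s has overlapping exons — rejected",
                           tid, gid)
            continue
        gene = genes.get(gid)
        if gene is None:
            gene = GeneModel(gene_id=gid, chrom=rec["chrom"],
                             strand=rec["strand"], transcripts=[])
            genes[gid] = gene
        gene.transcripts.append(Transcript(transcript_id=tid, exons=ivs))
    return [g for g in genes.values() if g.transcripts]


def _parse_gtf_attributes(s: str) -> dict[str, str]:
    attrs = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        k, _, v = part.partition(" ")
        attrs[k] = v.strip().strip('"')
    return attrs


_ALLOWED_CIGAR = {0, 1, 2, 3, 4}  # M I D N S


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[list[Interval], list[Interval]]:
    """Aligned blocks and spanned junction introns from a CIGAR at 0-based pos.

    M and D extend the current block (a deletion is not a junction); N closes
    it and records the gap as a spanned junction; I and S consume no
    reference.
    """
    blocks: list[Interval] = []
    junctions: list[Interval] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op not in _ALLOWED_CIGAR:
            raise FormatError(f"CIGAR op {op} outside supported subset M/I/D/N/S")
        if op in (0, 2):  # M, D consume reference
            cur += length
        elif op == 3:  # N
            blocks.append((cur_start, cur))
            junctions.append((cur, cur + length))
            cur += length
            cur_start = cur
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks, junctions


def parse_alignments(
    sam_path: str | os.PathLike,
    sample: str,
    multimap_tag: str = MULTIMAP_TAG,
) -> list[AlignedFragment]:
    """Read a (text) SAM file into AlignedFragments, merging mates by name.

    Records with CIGAR operations outside M/I/D/N/S are rejected with a
    diagnostic. A fragment is flagged non-unique when any of its records
    carries ``multimap_tag`` with value > 1.
    """
    frags: dict[str, AlignedFragment] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                blocks, junctions = _blocks_from_cigar(
                    rec.reference_start, rec.cigartuples or []
                )
            except FormatError as exc:
                logger.warning("read %s rejected: %s", rec.query_name, exc)
                continue
            if not blocks:
                continue
            unique = True
            if rec.has_tag(multimap_tag) and int(rec.get_tag(multimap_tag)) > 1:
                unique = False
            frag = frags.get(rec.query_name)
            if frag is None:
                frags[rec.query_name] = AlignedFragment(
                    fragment_id=rec.query_name,
                    sample=sample,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    unique=unique,
                    paired=rec.is_paired,
                    junctions=junctions,
                )
                order.append(rec.query_name)
            else:
                if frag.chrom != rec.reference_name:
                    logger.warning("mates of %s on different chromosomes — second skipped",
                                   rec.query_name)
                    continue
                frag.blocks = merge(frag.blocks + blocks)
                frag.junctions = sorted(set(frag.junctions) | set(junctions))
                frag.unique = frag.unique and unique
                frag.paired = True
    return [frags[name] for name in order]


def parse_bed12_fragments(path: str | os.PathLike, sample: str) -> list[AlignedFragment]:
    """BED12 rows as fragments; block gaps are recorded as spanned junctions."""
    out: list[AlignedFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                logger.warning("BED12 line %d: fewer than 12 fields — skipped", lineno)
                continue
            chrom, start, name = f[0], int(f[1]), f[3]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            junctions = [
                (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
            ]
            out.append(AlignedFragment(
                fragment_id=name, sample=sample, chrom=chrom, blocks=blocks,
                unique=True, paired=False, junctions=junctions,
            ))
    return out


def parse_junctions(path: str | os.PathLike,
                    samples: Sequence[str]) -> list[JunctionRecord]:
    """BED-like junction table: chrom, intron start, intron end, strand,
    then one count column per sample."""
    out: list[JunctionRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "chrom\t")):
                continue
            f = line.rstrip("\n").split("\t")
            counts = {s: int(c) for s, c in zip(samples, f[4:])}
            out.append(JunctionRecord(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                      strand=f[3], counts=counts))
    return out


def write_junctions(records: Iterable[JunctionRecord],
                    samples: Sequence[str],
                    path: str | os.PathLike) -> None:
    recs = sorted(records, key=lambda j: (j.chrom, j.start, j.end))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\t" + "\t".join(samples) + "\n")
        for j in recs:
            counts = "\t".join(str(j.count(s)) for s in samples)
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{counts}\n")


def parse_bed_intervals(path: str | os.PathLike) -> dict[str, list[Interval]]:
    """BED3+ → per-chromosome merged interval lists (repeats, ESTs)."""
    raw: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            raw.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {chrom: merge(ivs) for chrom, ivs in raw.items()}


def write_bed_intervals(intervals: Mapping[str, Sequence[Interval]],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def parse_go_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column gene→term TSV into a gene→set-of-terms map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.split()[:2]
            out.setdefault(gene, set()).add(term)
    return out


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results_table(df: pd.DataFrame, path: str | os.PathLike,
                        sort_by: Sequence[str] | None = None,
                        float_precision: int | None = None) -> None:
    """Deterministic TSV: fixed column order, stable row sort. By default
    floats are written at full (round-tripping) precision so the table
    re-reads to identical values; pass ``float_precision`` to truncate."""
    out = df.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="mergesort")
    fmt = None if float_precision is None else f"%.{float_precision}g"
    try:
        out.to_csv(path, sep="\t", index=False, float_format=fmt)
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}") from exc


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
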