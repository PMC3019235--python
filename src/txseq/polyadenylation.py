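"""PolyA-site calling from tail-bearing reads.

The stage takes reads that failed genomic alignment, looks for a polyA tail
(a terminal run of >=6 A at the 3' end or >=6 T at the 5' end — the protocol
is unstranded so the tail can present either way), trims the run, remaps the
trimmed sequence requiring a unique genomic hit with at most one mismatch,
filters internal-priming artifacts caused by genomic adenosine runs
immediately downstream of the putative cleavage site, chains nearby cleavage
sites (single linkage at <=15 bp) into polyA sites, and annotates the
canonical AAUAAA/AUUAAA signal within 50 bp upstream.

Conventions (documented, configurable where noted):

* the tail is an uninterrupted terminal run only — no mismatches inside it;
* the cleavage position is the first genomic base past the last transcribed
  base: alignment end for '+' sites, alignment start - 1 for '-' sites;
* the internal-priming scan covers the 10 strand-sense bases immediately
  downstream of the cleavage position;
* the signal search covers the 50 strand-sense bases immediately upstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import GenomeSequence

MIN_TAIL_RUN = 6
MIN_TRIMMED_LEN = 25
CLUSTER_GAP = 15
SIGNAL_WINDOW = 50
PRIMING_WINDOW = 10

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PolyATailRead:
    read_id: str
    tail_side: str  # 'A3' (A-run at 3') or 'T5' (T-run at 5')
    tail_length: int
    trimmed_seq: str

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed_seq)


@dataclass
class CleavageSite:
    chrom: str
    position: int  # first genomic base past the last transcribed base
    strand: str
    support: int


@dataclass
class PolyASite:
    chrom: str
    strand: str
    position: int  # representative cleavage position
    members: list[int]
    support: int
    signal: str = "none"  # 'AAUAAA' | 'AUUAAA' | 'none'
    signal_offset: int | None = None  # strand-sense distance upstream (>0)


@dataclass
class AlignmentTally:
    """Bookkeeping for the remapping step (both tallies are reported because
    downstream site counts may be quoted filtered or unfiltered)."""
    placed: int = 0
    unplaced: int = 0
    multi: int = 0
    priming_rejected: int = 0


def _terminal_run(seq: str, base: str, from_end: bool) -> int:
    n = 0
    it = reversed(seq) if from_end else iter(seq)
    for c in it:
        if c.upper() != base:
            break
        n += 1
    return n


def detect_and_trim_tail(
    read_id: str,
    seq: str,
    min_run: int = MIN_TAIL_RUN,
    min_trimmed: int = MIN_TRIMMED_LEN,
) -> PolyATailRead | None:
    """Detect and strip a polyA tail; None if no qualifying tail or the
    trimmed remainder is shorter than ``min_trimmed``.

    The maximal terminal run is taken; if both ends qualify the longer run
    wins (ties go to the 3' A-run).
    """
    if not seq:
        return None
    a3 = _terminal_run(seq, "A", from_end=True)
    t5 = _terminal_run(seq, "T", from_end=False)
    if a3 < min_run and t5 < min_run:
        return None
    if a3 >= t5:
        side, tail = "A3", a3
        trimmed = seq[:-tail]
    else:
        side, tail = "T5", t5
        trimmed = seq[tail:]
    if len(trimmed) < min_trimmed:
        return None
    return PolyATailRead(read_id=read_id, tail_side=side,
                         tail_length=tail, trimmed_seq=trimmed)


# ---------------------------------------------------------------------------
# naive unique aligner (toy genomes only)
# ---------------------------------------------------------------------------

def _find_exact(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


class NaiveUniqueAligner:
    """Seed-and-extend aligner for trimmed polyA reads on toy genomes.

    With at most one mismatch allowed, one half of the read must match
    exactly; exact half-hits (forward and reverse-complement) seed full
    verification. A read is placed only when exactly one genomic location
    over both strands matches with <=1 mismatch.
    """

    def __init__(self, genome: GenomeSequence, max_mismatches: int = 1):
        self.max_mismatches = max_mismatches
        self._fwd = {c: seq.upper() for c, seq in genome.chroms.items()}

    def hits(self, seq: str) -> list[tuple[str, int, bool]]:
        """All (chrom, start, is_forward) locations matching with at most
        ``max_mismatches`` mismatches (early exit after the second hit)."""
        seq = seq.upper()
        found: set[tuple[str, int, bool]] = set()
        for query, is_fwd in ((seq, True), (revcomp(seq), False)):
            half = len(query) // 2
            seeds = [(query[:half], 0), (query[half:], half)]
            for chrom, ref in self._fwd.items():
                for needle, offset in seeds:
                    for pos in _find_exact(ref, needle):
                        start = pos - offset
                        if start < 0 or start + len(query) > len(ref):
                            continue
                        window = ref[start:start + len(query)]
                        if _mismatches(window, query, self.max_mismatches) \
                                <= self.max_mismatches:
                            found.add((chrom, start, is_fwd))
            if len(found) > 1:
                return sorted(found)
        return sorted(found)

    def place(self, seq: str) -> tuple[str, int, bool] | None:
        """Unique location of ``seq``, or None (ambiguous or absent)."""
        hits = self.hits(seq)
        return hits[0] if len(hits) == 1 else None


def _cleavage_from_alignment(tail_side: str, chrom: str, start: int, end: int,
                             forward: bool) -> tuple[str, int, str]:
    """Map tail side x alignment orientation to (chrom, cleavage, strand).

    A-tail at 3' on a forward alignment means the transcript runs with the
    genome: '+' strand, cleavage at the alignment end. The other three cases
    mirror.
    """
    if tail_side == "A3":
        plus = forward
    else:  # T5 presentation is the reverse complement of the mRNA end
        plus = not forward
    if plus:
        return chrom, end, "+"
    return chrom, start - 1, "-"


def align_trimmed_unique(
    reads: list[PolyATailRead],
    genome: GenomeSequence,
    max_mismatches: int = 1,
) -> tuple[list[CleavageSite], AlignmentTally]:
    """Place trimmed reads uniquely and reduce them to cleavage sites with
    per-position support counts."""
    aligner = NaiveUniqueAligner(genome, max_mismatches=max_mismatches)
    tally = AlignmentTally()
    support: Counter[tuple[str, int, str]] = Counter()
    for read in reads:
        hits = aligner.hits(read.trimmed_seq)
        if len(hits) != 1:
            if len(hits) > 1:
                tally.multi += 1
            else:
                tally.unplaced += 1
            continue
        chrom, start, forward = hits[0]
        end = start + len(read.trimmed_seq)
        chrom, pos, strand = _cleavage_from_alignment(
            read.tail_side, chrom, start, end, forward)
        if not (0 <= pos <= genome.length(chrom)):
            tally.unplaced += 1
            continue
        tally.placed += 1
        support[(chrom, pos, strand)] += 1
    sites = [
        CleavageSite(chrom=c, position=p, strand=s, support=n)
        for (c, p, s), n in sorted(support.items())
    ]
    return sites, tally


def internal_priming_filter(
    site: CleavageSite,
    genome: GenomeSequence,
    window: int = PRIMING_WINDOW,
    min_run: int = MIN_TAIL_RUN,
) -> bool:
    """True (keep) unless the ``window`` strand-sense bases immediately
    downstream of the cleavage position contain a run of >= ``min_run`` A."""
    if site.strand == "+":
        downstream = genome.fetch(site.chrom, site.position, site.position + window)
    else:
        downstream = revcomp(
            genome.fetch(site.chrom, site.position - window + 1, site.position + 1))
    run = best = 0
    for c in downstream.upper():
        run = run + 1 if c == "A" else 0
        best = max(best, run)
    return best < min_run


def cluster_cleavage_sites(
    sites: list[CleavageSite],
    max_gap: int = CLUSTER_GAP,
) -> list[PolyASite]:
    """Single-linkage chaining of cleavage sites at <= ``max_gap`` bp into
    polyA sites, per chromosome and strand.

    The representative is the most-supported member (leftmost on ties);
    support is the sum over members.
    """
    out: list[PolyASite] = []
    by_group: dict[tuple[str, str], list[CleavageSite]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda s: s.position)
        chain: list[CleavageSite] = []
        for s in group:
            if chain and s.position - chain[-1].position > max_gap:
                out.append(_finish_cluster(chrom, strand, chain))
                chain = []
            chain.append(s)
        if chain:
            out.append(_finish_cluster(chrom, strand, chain))
    return out


def _finish_cluster(chrom: str, strand: str, chain: list[CleavageSite]) -> PolyASite:
    rep = max(chain, key=lambda s: (s.support, -s.position))
    return PolyASite(
        chrom=chrom, strand=strand, position=rep.position,
        members=[s.position for s in chain],
        support=sum(s.support for s in chain),
    )


_SIGNALS = (("AATAAA", "AAUAAA"), ("ATTAAA", "AUUAAA"))


def annotate_polya_signal(
    site: PolyASite,
    genome: GenomeSequence,
    window: int = SIGNAL_WINDOW,
) -> PolyASite:
    """Annotate the hexamer signal nearest the cleavage site within the
    upstream ``window`` (AAUAAA preferred on distance ties); mutates and
    returns the site."""
    if site.strand == "+":
        upstream = genome.fetch(site.chrom, site.position - window, site.position)
    else:
        upstream = revcomp(
            genome.fetch(site.chrom, site.position + 1, site.position + 1 + window))
    upstream = upstream.upper()
    best: tuple[int, int] | None = None  # (distance from cleavage, priority)
    best_name = "none"
    for priority, (dna, rna) in enumerate(_SIGNALS):
        idx = upstream.rfind(dna)
        while idx != -1:
            distance = len(upstream) - (idx + len(dna))
            key = (distance, priority)
            if best is None or key < best:
                best = key
                best_name = rna
            idx = upstream.rfind(dna, 0, idx + len(dna) - 1)
    site.signal = best_name
    site.signal_offset = best[0] if best else None
    return site


def call_polya_sites(
    read_seqs: list[tuple[str, str]],
    genome: GenomeSequence,
    min_run: int = MIN_TAIL_RUN,
    min_trimmed: int = MIN_TRIMMED_LEN,
    cluster_gap: int = CLUSTER_GAP,
    signal_window: int = SIGNAL_WINDOW,
    priming_window: int = PRIMING_WINDOW,
) -> tuple[list[PolyASite], dict[str, int]]:
    """Full stage: detect/trim, unique remap, priming filter, cluster,
    annotate. Returns annotated sites plus a tally dict."""
    tail_reads = []
    for name, seq in read_seqs:
        r = detect_and_trim_tail(name, seq, min_run=min_run, min_trimmed=min_trimmed)
        if r is not None:
            tail_reads.append(r)
    sites, tally = align_trimmed_unique(tail_reads, genome)
    kept = []
    for s in sites:
        if internal_priming_filter(s, genome, window=priming_window, min_run=min_run):
            kept.append(s)
        else:
            tally.priming_rejected += s.support
    clusters = cluster_cleavage_sites(kept, max_gap=cluster_gap)
    for c in clusters:
        annotate_polya_signal(c, genome, window=signal_window)
    stats = {
        "input_reads": len(read_seqs),
        "tail_reads": len(tail_reads),
        "placed_reads": tally.placed,
        "unplaced_reads": tally.unplaced,
        "priming_rejected_reads": tally.priming_rejected,
        "polya_sites": len(clusters),
        "polya_sites_with_signal": sum(1 for c in clusters if c.signal != "none"),
    }
    return clusters, stats
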