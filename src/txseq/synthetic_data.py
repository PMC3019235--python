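"""Synthetic two-sample embryo-style RNA-seq data with full truth tables.

The generator emulates the statistical structure the analysis stages assume:

* non-overlapping multi-exon genes whose exons make up a configurable
  fraction of gene bases (default 1/20), so pre-mRNA molecules inflate
  intronic reads disproportionally;
* two unstranded samples with per-sample pre-mRNA molecule fractions
  (defaults chosen to bracket ~18% and ~34% intronic-of-genic fragments);
* 3'-biased sampling along mature transcripts (weight proportional to
  exp(position/lambda) toward the 3' end — a qualitative stand-in for the
  linear-amplification artifact, not a claim about its exact shape);
* pre-mRNA fragments sampled uniformly over gene spans, with molecules
  weighted by length when converted to fragment probabilities;
* polyA-tailed reads at true cleavage sites with planted AAUAAA/AUUAAA
  signals, presented half as A-runs at the 3' end and half as T-runs at the
  5' end (unstranded), plus internal-priming artifacts at planted genomic
  A-runs;
* intergenic novel TUs with configurable polyA/EST/conservation evidence and
  filter-failing decoys;
* planted differential expression, exon skipping, and alternative 5'/3'
  splice-site events with known inclusion odds.

Everything is driven by one config and one seed; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, merge, total_length
from .io_formats import (
    GeneModel, GenomeSequence, JunctionRecord, ScoreTrack, Transcript,
    write_bed_intervals, write_fastq, write_junctions,
)
from .polyadenylation import revcomp

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 1
    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    samples: tuple[str, str] = ("blastocysts", "degeneratives")

    gene_count: int = 60
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length_range: tuple[int, int] = (80, 140)
    exon_base_fraction: float = 1.0 / 20.0
    intergenic_gap: tuple[int, int] = (800, 2000)

    #: pre-mRNA molecule fraction per sample; defaults bracket the ~18% and
    #: ~34% intronic-of-genic targets under exon fraction 1/20
    premrna_fraction: tuple[float, float] = (0.0116, 0.0271)
    expression_mu: float = 3.0
    expression_sigma: float = 1.0
    bias_lambda: float = 300.0

    fragments_per_sample: int = 50_000
    fragment_length_mean: float = 122.0
    fragment_length_sd: float = 15.0
    fragment_length_min: int = 60
    paired_min_length: int = 105
    paired_prob: float = 0.5
    read_length: int = 45

    polya_read_rate: float = 0.03
    polya_tail_min: int = 6
    polya_tail_geom_p: float = 0.3
    polya_trimmed_range: tuple[int, int] = (30, 55)
    signal_aataaa_fraction: float = 0.7
    signal_attaaa_fraction: float = 0.2
    internal_priming_count: int = 4
    internal_priming_reads: int = 8

    novel_tu_count: int = 12
    decoy_tu_count: int = 4
    #: real TUs expressed (almost) only in the second sample
    de_tu_count: int = 2
    tu_length_range: tuple[int, int] = (600, 1500)
    tu_frags_per_kb: tuple[float, float] = (60.0, 120.0)
    tu_gene_buffer: int = 1500
    tu_polya_fraction: float = 0.5
    tu_est_fraction: float = 0.65
    tu_conserved_fraction: float = 0.5

    repeat_density: float = 0.03
    repeat_length_range: tuple[int, int] = (100, 400)

    de_gene_count: int = 8
    de_fold_change: float = 4.0
    as_expression_boost: float = 4.0
    skip_event_count: int = 6
    skip_inclusion_prob_a: float = 0.5
    skip_inclusion_odds_shift: float = 3.0
    alt5_event_count: int = 3
    alt3_event_count: int = 3
    alt_long_prob_a: float = 0.5
    alt_long_odds_shift: float = 2.0
    alt_ext_length: int = 60

    go_term_count: int = 25
    go_terms_per_gene: tuple[int, int] = (1, 4)
    enriched_term: str = "GO:9999999"

    def __post_init__(self) -> None:
        for name in ("exon_base_fraction", "polya_read_rate", "repeat_density",
                     "tu_polya_fraction", "tu_est_fraction",
                     "tu_conserved_fraction", "paired_prob",
                     "skip_inclusion_prob_a", "alt_long_prob_a",
                     "signal_aataaa_fraction", "signal_attaaa_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name}={v} outside [0, 1]")
        for v in self.premrna_fraction:
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"premrna_fraction {v} outside [0, 1]")
        if self.de_fold_change <= 0:
            raise SimulationError("de_fold_change must be > 0")
        if len(self.samples) != 2:
            raise SimulationError("exactly two samples are supported")


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PlannedTU:
    tu_id: str
    chrom: str
    start: int
    end: int
    kind: str  # 'real' | 'decoy_close' | 'decoy_short' | 'decoy_lowcov' | 'decoy_repeat'
    target_fpk: float
    polya: bool
    est: bool
    conserved: bool
    de: bool = False  # expressed only in the second sample

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTables:
    genes: pd.DataFrame
    cleavage_sites: pd.DataFrame
    false_sites: pd.DataFrame
    tus: pd.DataFrame
    as_events: pd.DataFrame
    enriched_term: str
    #: filled by simulate_fragments
    expression: pd.DataFrame | None = None
    fragment_labels: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class GenomeBundle:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    repeats: dict[str, list[Interval]]
    ests: dict[str, list[Interval]]
    conservation: ScoreTrack
    go_annotations: dict[str, set[str]]
    planned_tus: list[PlannedTU]
    truth: TruthTables
    #: per-gene sampling parameters, keyed by gene id
    gene_params: dict[str, dict] = field(default_factory=dict)
    #: (chrom, intron start, intron end) -> annotated strand
    junction_strand: dict[tuple[str, int, int], str] = field(default_factory=dict)


@dataclass
class SimulatedFragment:
    fragment_id: str
    chrom: str
    blocks: list[Interval]
    junctions: list[Interval]
    paired: bool
    premrna: bool
    feature: str  # gene id, TU id


@dataclass
class ReadsBundle:
    config: SimulationConfig
    fragments: dict[str, list[SimulatedFragment]]
    polya_reads: dict[str, list[tuple[str, str]]]
    junctions: list[JunctionRecord]
    truth: TruthTables


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome_and_annotation(config: SimulationConfig) -> GenomeBundle:
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    seqs = {name: rng.integers(0, 4, size=n)
            for name, n in zip(chrom_names, config.chrom_lengths)}

    structures = [_gene_structure(rng, config) for _ in range(config.gene_count)]
    as_plan = _plan_as_events(rng, config)

    tu_plan = _plan_tus(rng, config)
    placements, tu_placements = _place_features(rng, config, chrom_names,
                                                structures, tu_plan)

    genes: list[GeneModel] = []
    gene_rows = []
    cleavage_rows = []
    junction_strand: dict[tuple[str, int, int], str] = {}
    as_rows = []
    gene_params: dict[str, dict] = {}

    theta = rng.lognormal(config.expression_mu, config.expression_sigma,
                          size=config.gene_count)
    de_ids = _pick_de_genes(rng, config, as_plan)

    for gi, (chrom, offset, exon_lens, intron_lens) in enumerate(placements):
        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _assemble_exons(offset, exon_lens, intron_lens)
        transcripts = [Transcript(transcript_id=f"{gene_id}.t1", exons=exons)]
        as_type = as_plan.get(gi)
        event_row = None
        p_t1 = (1.0, 1.0)  # probability a mature molecule is isoform .t1
        if as_type is not None:
            alt_exons, event_row = _alternative_isoform(
                gene_id, chrom, strand, exons, as_type, config)
            transcripts.append(Transcript(transcript_id=f"{gene_id}.t2",
                                          exons=alt_exons))
            if as_type == "exon_skipping":
                # .t1 is the inclusion isoform
                p_t1 = (event_row["inc_prob_a"], event_row["inc_prob_b"])
            else:
                # .t2 is the long (inclusion-junction) isoform
                p_t1 = (1 - event_row["inc_prob_a"], 1 - event_row["inc_prob_b"])
        gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                         transcripts=transcripts)
        genes.append(gene)
        for t in transcripts:
            for js, je in t.introns:
                junction_strand[(chrom, js, je)] = strand
        if event_row is not None:
            as_rows.append(event_row)

        th = float(theta[gi])
        if as_type is not None:
            # AS genes sit in the upper expression range so the planted
            # junction depth comfortably exceeds the detection threshold
            th = max(th, math.exp(config.expression_mu)) \
                * config.as_expression_boost
        fold = 1.0
        if gene_id in de_ids:
            fold = (config.de_fold_change if de_ids[gene_id] == "up"
                    else 1.0 / config.de_fold_change)
        span = gene.span
        cleavage, signal = _plant_polya_context(rng, seqs[chrom], span, strand,
                                                config)
        cleavage_rows.append({"chrom": chrom, "position": cleavage,
                              "strand": strand, "signal": signal,
                              "feature": gene_id})
        gene_params[gene_id] = {
            "theta_a": th, "theta_b": th * fold, "strand": strand,
            "as_type": as_type, "p_t1": p_t1,
        }
        gene_rows.append({
            "gene_id": gene_id, "chrom": chrom, "start": span[0],
            "end": span[1], "strand": strand, "theta_a": th,
            "theta_b": th * fold, "is_de": gene_id in de_ids,
            "fold_change": fold, "as_type": as_type or "",
        })

    planned_tus = _finalize_tus(rng, config, tu_plan, tu_placements)
    for tu in planned_tus:
        if tu.polya:
            cleavage = tu.end - 30
            signal = _plant_signal(rng, seqs[tu.chrom], cleavage, "+", config)
            _scrub_a_runs(seqs[tu.chrom], cleavage - 8, cleavage + 12)
            cleavage_rows.append({"chrom": tu.chrom, "position": cleavage,
                                  "strand": "+", "signal": signal,
                                  "feature": tu.tu_id})

    false_rows = _plant_priming_runs(rng, config, chrom_names, seqs,
                                     genes, planned_tus)
    repeats = _plant_repeats(rng, config, chrom_names, seqs, genes, planned_tus)
    ests = _est_track(rng, planned_tus)
    conservation = _conservation_track(rng, genes, planned_tus)
    go_annotations, enriched_term = _go_annotations(rng, config,
                                                    [g.gene_id for g in genes],
                                                    set(de_ids))

    genome = GenomeSequence(
        chroms={c: _to_string(seqs[c], repeats.get(c, [])) for c in chrom_names},
        repeats=repeats,
    )
    truth = TruthTables(
        genes=pd.DataFrame(gene_rows),
        cleavage_sites=pd.DataFrame(cleavage_rows),
        false_sites=pd.DataFrame(false_rows),
        tus=pd.DataFrame([vars(t) for t in planned_tus]),
        as_events=pd.DataFrame(as_rows),
        enriched_term=enriched_term,
    )
    return GenomeBundle(
        config=config, genome=genome, genes=genes, repeats=repeats, ests=ests,
        conservation=conservation, go_annotations=go_annotations,
        planned_tus=planned_tus, truth=truth, gene_params=gene_params,
        junction_strand=junction_strand,
    )


def _gene_structure(rng, config) -> tuple[list[int], list[int]]:
    lo, hi = config.exons_per_gene
    n = int(rng.integers(lo, hi + 1))
    elo, ehi = config.exon_length_range
    exon_lens = [int(rng.integers(elo, ehi + 1)) for _ in range(n)]
    exonic = sum(exon_lens)
    e = config.exon_base_fraction
    intron_total = exonic * (1.0 - e) / e * float(rng.uniform(0.95, 1.05))
    if n > 1:
        props = rng.dirichlet(np.ones(n - 1))
        base = 150
        remaining = max(intron_total - base * (n - 1), 0)
        intron_lens = [base + int(round(remaining * p)) for p in props]
    else:
        intron_lens = []
    return exon_lens, intron_lens


def _assemble_exons(offset: int, exon_lens: Sequence[int],
                    intron_lens: Sequence[int]) -> list[Interval]:
    exons = []
    pos = offset
    for i, ln in enumerate(exon_lens):
        exons.append((pos, pos + ln))
        pos += ln
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons


def _plan_as_events(rng, config) -> dict[int, str]:
    """Assign event types to gene indices (at most one event per gene)."""
    total = (config.skip_event_count + config.alt5_event_count
             + config.alt3_event_count)
    if total > config.gene_count:
        raise SimulationError("more AS events requested than genes")
    chosen = rng.choice(config.gene_count, size=total, replace=False)
    plan: dict[int, str] = {}
    i = 0
    for _ in range(config.skip_event_count):
        plan[int(chosen[i])] = "exon_skipping"; i += 1
    for _ in range(config.alt5_event_count):
        plan[int(chosen[i])] = "alt5"; i += 1
    for _ in range(config.alt3_event_count):
        plan[int(chosen[i])] = "alt3"; i += 1
    return plan


def _alternative_isoform(gene_id, chrom, strand, exons, as_type, config):
    """Second isoform + truth row for one planted event.

    The planted skip/alt exon sits next to the 3' end of the transcript,
    where the 3'-biased coverage keeps junction support high.
    """
    n = len(exons)
    p_a = (config.skip_inclusion_prob_a if as_type == "exon_skipping"
           else config.alt_long_prob_a)
    shift = (config.skip_inclusion_odds_shift if as_type == "exon_skipping"
             else config.alt_long_odds_shift)
    odds_b = p_a / (1 - p_a) * shift
    p_b = odds_b / (1 + odds_b)
    if as_type == "exon_skipping":
        k = n - 2 if strand == "+" else 1  # one exon in from the 3' end
        alt = exons[:k] + exons[k + 1:]
        row = {
            "gene_id": gene_id, "chrom": chrom, "strand": strand,
            "event_type": "exon_skipping",
            "j1_start": exons[k - 1][1], "j1_end": exons[k][0],
            "j2_start": exons[k][1], "j2_end": exons[k + 1][0],
            "j3_start": exons[k - 1][1], "j3_end": exons[k + 1][0],
            "region_start": exons[k][0], "region_end": exons[k][1],
            "inc_prob_a": p_a, "inc_prob_b": p_b,
        }
        return alt, row
    ext = config.alt_ext_length
    if as_type == "alt5":
        # extend an internal exon's end into the following intron: the two
        # junctions share their end (the downstream acceptor on '+')
        k = n - 3 if strand == "+" else 1
        k = max(min(k, n - 2), 0)
        s, e = exons[k]
        alt = list(exons)
        alt[k] = (s, e + ext)
        row = {
            "gene_id": gene_id, "chrom": chrom, "strand": strand,
            "event_type": "alt_5ss" if strand == "+" else "alt_3ss",
            "j1_start": e + ext, "j1_end": exons[k + 1][0],
            "j2_start": e, "j2_end": exons[k + 1][0],
            "j3_start": -1, "j3_end": -1,
            "region_start": e, "region_end": e + ext,
            "inc_prob_a": p_a, "inc_prob_b": p_b,
        }
        return alt, row
    # alt3: pull an internal exon's start into the preceding intron: the two
    # junctions share their start (the upstream donor on '+')
    k = n - 2 if strand == "+" else 1
    k = max(min(k, n - 1), 1)
    s, e = exons[k]
    alt = list(exons)
    alt[k] = (s - ext, e)
    row = {
        "gene_id": gene_id, "chrom": chrom, "strand": strand,
        "event_type": "alt_3ss" if strand == "+" else "alt_5ss",
        "j1_start": exons[k - 1][1], "j1_end": s - ext,
        "j2_start": exons[k - 1][1], "j2_end": s,
        "j3_start": -1, "j3_end": -1,
        "region_start": s - ext, "region_end": s,
        "inc_prob_a": p_a, "inc_prob_b": p_b,
    }
    return alt, row


def _plan_tus(rng, config) -> list[dict]:
    plan = []
    decoy_kinds = ["decoy_close", "decoy_short", "decoy_lowcov", "decoy_repeat"]
    for i in range(config.novel_tu_count + config.decoy_tu_count):
        kind = "real" if i < config.novel_tu_count \
            else decoy_kinds[(i - config.novel_tu_count) % len(decoy_kinds)]
        lo, hi = config.tu_length_range
        length = int(rng.integers(lo, hi + 1))
        if kind == "decoy_short":
            length = 300
        flo, fhi = config.tu_frags_per_kb
        fpk = float(rng.uniform(flo, fhi))
        if kind == "decoy_lowcov":
            fpk = 10.0
        de = kind == "real" and i < config.de_tu_count
        if de:
            # strongly expressed in one sample only, like the reported
            # X-linked TU with a four-hundred-fold normalized-count gap
            fpk = max(fpk, 400.0)
        plan.append({
            "kind": kind, "length": length, "fpk": fpk, "de": de,
            "polya": bool(rng.random() < config.tu_polya_fraction),
            "est": bool(rng.random() < config.tu_est_fraction),
            "conserved": bool(rng.random() < config.tu_conserved_fraction),
        })
    return plan


def _place_features(rng, config, chrom_names, structures, tu_plan):
    """Lay genes and TUs along the chromosomes left to right; 'close' decoy
    TUs are attached 300 bp downstream of a gene afterwards (inside the
    1000 bp buffer, so the distance filter must reject them)."""
    features = [("gene", i) for i in range(len(structures))]
    features += [("tu", i) for i in range(len(tu_plan))
                 if tu_plan[i]["kind"] != "decoy_close"]
    order = rng.permutation(len(features))

    placements: list[tuple] = [None] * len(structures)
    tu_placements: list[tuple | None] = [None] * len(tu_plan)
    ci = 0
    cursor = 2000
    for idx in order:
        kind, i = features[idx]
        if kind == "gene":
            exon_lens, intron_lens = structures[i]
            span = sum(exon_lens) + sum(intron_lens)
            gap = int(rng.integers(*config.intergenic_gap))
        else:
            span = tu_plan[i]["length"]
            gap = config.tu_gene_buffer + 100
        while cursor + gap + span + config.tu_gene_buffer + 2000 > \
                config.chrom_lengths[ci]:
            ci += 1
            cursor = 2000
            if ci >= len(chrom_names):
                need = sum(sum(el) + sum(il) for el, il in structures)
                raise SimulationError(
                    "genome too small for the requested features; increase "
                    f"chrom_lengths (genic bases alone need ~{need})")
        start = cursor + gap
        if kind == "gene":
            placements[i] = (chrom_names[ci], start, *structures[i])
        else:
            tu_placements[i] = (chrom_names[ci], start, start + span)
        cursor = start + span
        if kind == "tu":
            cursor += config.tu_gene_buffer

    gi = 0
    for i, plan in enumerate(tu_plan):
        if plan["kind"] != "decoy_close":
            continue
        chrom, offset, exon_lens, intron_lens = placements[gi % len(placements)]
        gene_end = offset + sum(exon_lens) + sum(intron_lens)
        tu_placements[i] = (chrom, gene_end + 300,
                            gene_end + 300 + plan["length"])
        gi += 1
    return placements, tu_placements


def _pick_de_genes(rng, config, as_plan) -> dict[str, str]:
    candidates = [i for i in range(config.gene_count) if i not in as_plan]
    if config.de_gene_count > len(candidates):
        raise SimulationError("not enough non-AS genes for the DE plan")
    chosen = rng.choice(candidates, size=config.de_gene_count, replace=False)
    out = {}
    for rank, gi in enumerate(sorted(int(x) for x in chosen)):
        out[f"G{gi:04d}"] = "up" if rank % 2 == 0 else "down"
    return out


def _finalize_tus(rng, config, tu_plan, tu_placements) -> list[PlannedTU]:
    out = []
    for i, (plan, placed) in enumerate(zip(tu_plan, tu_placements)):
        chrom, start, end = placed
        out.append(PlannedTU(
            tu_id=f"NTU{i:03d}", chrom=chrom, start=start, end=end,
            kind=plan["kind"], target_fpk=plan["fpk"],
            polya=plan["polya"] and plan["kind"] == "real",
            est=plan["est"], conserved=plan["conserved"], de=plan["de"],
        ))
    return out


def _plant_signal(rng, seq: np.ndarray, cleavage: int, strand: str,
                  config) -> str:
    """Write a polyA signal hexamer 15-35 nt upstream of the cleavage
    position (transcript sense); returns the signal name."""
    r = rng.random()
    if r < config.signal_aataaa_fraction:
        hexamer, name = "AATAAA", "AAUAAA"
    elif r < config.signal_aataaa_fraction + config.signal_attaaa_fraction:
        hexamer, name = "ATTAAA", "AUUAAA"
    else:
        return "none"
    d = int(rng.integers(15, 36))
    if strand == "+":
        start = cleavage - d - 6
        _write_bases(seq, start, hexamer)
    else:
        start = cleavage + d + 1
        _write_bases(seq, start, revcomp(hexamer))
    return name


def _plant_polya_context(rng, seq: np.ndarray, span: Interval, strand: str,
                         config) -> tuple[int, str]:
    """Cleavage position at the transcript 3' end plus a planted signal;
    scrubs incidental A-runs around the cleavage site."""
    if strand == "+":
        cleavage = span[1]
        _scrub_a_runs(seq, cleavage - 8, cleavage + 12)
    else:
        cleavage = span[0] - 1
        _scrub_t_runs(seq, cleavage - 11, cleavage + 9)
    signal = _plant_signal(rng, seq, cleavage, strand, config)
    return cleavage, signal


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _write_bases(seq: np.ndarray, start: int, bases: str) -> None:
    for i, b in enumerate(bases):
        if 0 <= start + i < len(seq):
            seq[start + i] = _BASE_CODE[b]


def _scrub_a_runs(seq: np.ndarray, start: int, end: int, code: int = 0) -> None:
    """Cap runs of the given base at 3 within [start, end)."""
    run = 0
    for i in range(max(start, 0), min(end, len(seq))):
        if seq[i] == code:
            run += 1
            if run > 3:
                seq[i] = 1  # C
                run = 0
        else:
            run = 0


def _scrub_t_runs(seq: np.ndarray, start: int, end: int) -> None:
    _scrub_a_runs(seq, start, end, code=3)


def _plant_priming_runs(rng, config, chrom_names, seqs, genes, tus):
    """Genomic A-run artifacts in intergenic space, far from real features."""
    keepout: dict[str, list[Interval]] = {c: [] for c in chrom_names}
    for g in genes:
        s, e = g.span
        keepout[g.chrom].append((s - 500, e + 500))
    for t in tus:
        keepout[t.chrom].append((t.start - 500, t.end + 500))
    keepout = {c: merge(v) for c, v in keepout.items()}

    rows = []
    placed = 0
    attempts = 0
    while placed < config.internal_priming_count and attempts < 10_000:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(2000, len(seqs[chrom]) - 2000))
        if any(s <= pos < e for s, e in keepout[chrom]):
            continue
        _write_bases(seqs[chrom], pos, "A" * 8)
        keepout[chrom] = merge(keepout[chrom] + [(pos - 200, pos + 200)])
        rows.append({"chrom": chrom, "position": pos})
        placed += 1
    return rows


def _plant_repeats(rng, config, chrom_names, seqs, genes, tus):
    """Random repeat intervals avoiding genes and non-decoy TUs; the
    repeat-decoy TU gets 60% of its bases covered."""
    keepout: dict[str, list[Interval]] = {c: [] for c in chrom_names}
    for g in genes:
        s, e = g.span
        keepout[g.chrom].append((s - 100, e + 100))
    for t in tus:
        if t.kind != "decoy_repeat":
            keepout[t.chrom].append((t.start - 100, t.end + 100))
    keepout = {c: merge(v) for c, v in keepout.items()}

    repeats: dict[str, list[Interval]] = {c: [] for c in chrom_names}
    for t in tus:
        if t.kind == "decoy_repeat":
            cover = int(0.6 * t.length)
            repeats[t.chrom].append((t.start, t.start + cover))
    for chrom in chrom_names:
        n_target = int(config.repeat_density * len(seqs[chrom])
                       / np.mean(config.repeat_length_range))
        attempts = 0
        placed = 0
        while placed < n_target and attempts < 20 * n_target + 100:
            attempts += 1
            ln = int(rng.integers(*config.repeat_length_range))
            pos = int(rng.integers(0, len(seqs[chrom]) - ln))
            if any(s < pos + ln and pos < e for s, e in keepout[chrom]):
                continue
            repeats[chrom].append((pos, pos + ln))
            placed += 1
    return {c: merge(v) for c, v in repeats.items() if v}


def _est_track(rng, tus) -> dict[str, list[Interval]]:
    """ESTs covering ~70% of EST-flagged TUs and ~30% of the others (the
    latter stay below the 50% support threshold)."""
    ests: dict[str, list[Interval]] = {}
    for t in tus:
        frac = 0.7 if t.est else 0.3
        ln = int(frac * t.length)
        start = t.start + (t.length - ln) // 2
        ests.setdefault(t.chrom, []).append((start, start + ln))
    return {c: merge(v) for c, v in ests.items()}


def _conservation_track(rng, genes, tus) -> ScoreTrack:
    entries: dict[str, list[tuple[int, int, float]]] = {}
    for g in genes:
        s, e = g.span
        entries.setdefault(g.chrom, []).append((s, e, float(rng.uniform(0.4, 0.7))))
    for t in tus:
        v = float(rng.uniform(0.75, 0.95)) if t.conserved \
            else float(rng.uniform(0.02, 0.15))
        entries.setdefault(t.chrom, []).append((t.start, t.end, v))
    return ScoreTrack(entries)


def _go_annotations(rng, config, gene_ids, de_ids):
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_term_count)]
    lo, hi = config.go_terms_per_gene
    annotations: dict[str, set[str]] = {}
    for gid in gene_ids:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        annotations[gid] = {terms[int(i)] for i in chosen}
    # one term enriched in the DE set
    extras = [g for g in gene_ids if g not in de_ids]
    bonus = rng.choice(len(extras), size=min(2, len(extras)), replace=False)
    for gid in sorted(de_ids) + [extras[int(i)] for i in bonus]:
        annotations[gid].add(config.enriched_term)
    return annotations, config.enriched_term


def _to_string(codes: np.ndarray, repeats: list[Interval]) -> str:
    arr = BASES[codes].copy()
    for s, e in repeats:
        arr[s:e] = np.char.lower(arr[s:e])
    return "".join(arr)


# ---------------------------------------------------------------------------
# fragments, polyA reads, junction table
# ---------------------------------------------------------------------------

def simulate_fragments(config: SimulationConfig,
                       bundle: GenomeBundle) -> ReadsBundle:
    rng = np.random.default_rng(config.seed + 1)
    junction_strand = bundle.junction_strand
    upper_seqs = {c: s.upper() for c, s in bundle.genome.chroms.items()}

    fragments: dict[str, list[SimulatedFragment]] = {}
    polya_reads: dict[str, list[tuple[str, str]]] = {}
    junction_counts: dict[str, dict[tuple[str, int, int], int]] = {}
    expr_rows: dict[str, dict[str, int]] = {}

    for si, sample in enumerate(config.samples):
        frags, reads, jcounts, expr = _simulate_sample(
            rng, config, bundle, sample, si, upper_seqs)
        fragments[sample] = frags
        polya_reads[sample] = reads
        junction_counts[sample] = jcounts
        expr_rows[sample] = expr

    # artifact reads at planted genomic A-runs, split across samples
    for i, row in enumerate(bundle.truth.false_sites.to_dict("records")):
        sample = config.samples[i % len(config.samples)]
        seq = upper_seqs[row["chrom"]]
        for k in range(config.internal_priming_reads):
            m = int(rng.integers(*config.polya_trimmed_range))
            tail = config.polya_tail_min + int(rng.geometric(
                config.polya_tail_geom_p)) - 1
            body = seq[row["position"] - m: row["position"]]
            read = body + "A" * tail
            if rng.random() < 0.5:
                read = revcomp(read)
            polya_reads[sample].append((f"fp:{row['chrom']}:{row['position']}:{k}",
                                        read))

    all_keys = sorted({k for jc in junction_counts.values() for k in jc})
    junctions = [
        JunctionRecord(
            chrom=chrom, start=s, end=e,
            strand=junction_strand.get((chrom, s, e), "."),
            counts={sample: junction_counts[sample].get((chrom, s, e), 0)
                    for sample in config.samples},
        )
        for chrom, s, e in all_keys
    ]

    expression = pd.DataFrame(expr_rows).fillna(0).astype(int)
    expression.index.name = "feature"
    truth = bundle.truth
    truth.expression = expression
    truth.fragment_labels = {
        sample: pd.DataFrame(
            [{"fragment_id": f.fragment_id, "feature": f.feature,
              "premrna": f.premrna} for f in fragments[sample]])
        for sample in config.samples
    }
    return ReadsBundle(config=config, fragments=fragments,
                       polya_reads=polya_reads, junctions=junctions,
                       truth=truth)


def _simulate_sample(rng, config, bundle, sample, sample_index, upper_seqs):
    p_pre = config.premrna_fraction[sample_index]
    genes = bundle.genes
    params = bundle.gene_params

    mature_len = {}
    span_len = {}
    weights = []
    for g in genes:
        pr = params[g.gene_id]
        lens = [t.length for t in g.transcripts]
        mature_len[g.gene_id] = float(np.mean(lens))
        s, e = g.span
        span_len[g.gene_id] = float(e - s)
        theta = pr["theta_a"] if sample_index == 0 else pr["theta_b"]
        weights.append(theta * ((1 - p_pre) * mature_len[g.gene_id]
                                + p_pre * span_len[g.gene_id]))
    weights = np.asarray(weights)

    tu_expected = np.array([
        0.0 if (t.de and sample_index == 0)
        else t.target_fpk * t.length / 1000.0
        for t in bundle.planned_tus
    ])
    n_tu = rng.poisson(tu_expected) if len(tu_expected) else np.array([], dtype=int)
    n_gene_total = max(config.fragments_per_sample - int(n_tu.sum()), 0)
    if len(weights) and weights.sum() > 0:
        n_gene = rng.multinomial(n_gene_total, weights / weights.sum())
    else:
        n_gene = np.zeros(len(weights), dtype=int)

    frags: list[SimulatedFragment] = []
    reads: list[tuple[str, str]] = []
    jcounts: dict[tuple[str, int, int], int] = {}
    expr: dict[str, int] = {}
    serial = 0

    for g, n in zip(genes, n_gene):
        if n == 0:
            expr[g.gene_id] = 0
            continue
        pr = params[g.gene_id]
        q_pre = (p_pre * span_len[g.gene_id]
                 / (p_pre * span_len[g.gene_id]
                    + (1 - p_pre) * mature_len[g.gene_id]))
        n_pre = int(rng.binomial(n, q_pre))
        n_mat = int(n) - n_pre
        expr[g.gene_id] = n_mat

        serial = _emit_mature(rng, config, g, pr, n_mat, sample, frags,
                              jcounts, serial, sample_index)
        serial = _emit_premrna(rng, config, g, n_pre, sample, frags, serial)
        _emit_polya_reads(rng, config, upper_seqs, g, n_mat, reads)

    for tu, n in zip(bundle.planned_tus, n_tu):
        for _ in range(int(n)):
            ln = _fragment_length(rng, config, tu.length)
            start = tu.start + int(rng.integers(0, tu.length - ln + 1))
            blocks, junction_ivs, paired = _paired_blocks(
                rng, config, [(start, start + ln)])
            frags.append(SimulatedFragment(
                fragment_id=f"{sample}:f{serial}", chrom=tu.chrom,
                blocks=blocks, junctions=junction_ivs, paired=paired,
                premrna=False, feature=tu.tu_id))
            serial += 1
        if tu.polya and (int(n) > 0 or not tu.de):
            cleavage = tu.end - 30
            seq = upper_seqs[tu.chrom]
            n_pa = max(6, int(rng.binomial(int(n), 3 * config.polya_read_rate)))
            for k in range(n_pa):
                m = int(rng.integers(*config.polya_trimmed_range))
                tail = config.polya_tail_min + int(
                    rng.geometric(config.polya_tail_geom_p)) - 1
                read = seq[cleavage - m:cleavage] + "A" * tail
                if rng.random() < 0.5:
                    read = revcomp(read)
                reads.append((f"pa:{tu.tu_id}:{sample}:{k}", read))

    return frags, reads, jcounts, expr


def _fragment_length(rng, config, upper: int) -> int:
    ln = int(round(rng.normal(config.fragment_length_mean,
                              config.fragment_length_sd)))
    return max(config.fragment_length_min, min(ln, upper))


def _map_transcript_interval(exons, u: int, v: int) -> list[Interval]:
    """Genomic blocks of the left-to-right transcript interval [u, v)."""
    blocks = []
    off = 0
    for s, e in exons:
        ln = e - s
        a = max(u - off, 0)
        b = min(v - off, ln)
        if a < b:
            blocks.append((s + a, s + b))
        off += ln
        if off >= v:
            break
    return blocks


def _slice_blocks(blocks, a: int, b: int) -> list[Interval]:
    """Sub-blocks covering footprint bases [a, b) of a block list."""
    return _map_transcript_interval(blocks, a, b)


def _paired_blocks(rng, config, blocks):
    """Optionally reduce a fragment footprint to its two mate reads.

    Returns (aligned blocks, junction introns), where junctions are the
    block gaps that fall *within* a read (the unsequenced inter-mate hole is
    not evidence for anything).
    """
    ln = total_length(blocks)
    paired = ln >= config.paired_min_length and rng.random() < config.paired_prob
    if paired:
        m1 = _slice_blocks(blocks, 0, config.read_length)
        m2 = _slice_blocks(blocks, ln - config.read_length, ln)
        junction_ivs = _gaps(m1) + _gaps(m2)
        return sorted(m1 + m2), junction_ivs, True
    return list(blocks), _gaps(blocks), False


def _gaps(blocks) -> list[Interval]:
    return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]


def _emit_mature(rng, config, gene, pr, n_mat, sample, frags, jcounts,
                 serial, sample_index):
    if n_mat == 0:
        return serial
    iso_full = gene.transcripts[0]
    iso_alt = gene.transcripts[1] if len(gene.transcripts) > 1 else None
    p_first = pr["p_t1"][sample_index] if iso_alt is not None else 1.0
    n_first = int(rng.binomial(n_mat, p_first)) if iso_alt is not None else n_mat
    for iso, count in ((iso_full, n_first),
                       (iso_alt, n_mat - n_first if iso_alt else 0)):
        if iso is None or count == 0:
            continue
        length = iso.length
        for _ in range(count):
            ln = _fragment_length(rng, config, length)
            u5 = _biased_start(rng, config, length - ln)
            if gene.strand == "+":
                u = u5
            else:
                u = length - u5 - ln
            fp_blocks = _map_transcript_interval(iso.exons, u, u + ln)
            blocks, junction_ivs, paired = _paired_blocks(rng, config, fp_blocks)
            for iv in junction_ivs:
                jcounts[(gene.chrom, iv[0], iv[1])] = \
                    jcounts.get((gene.chrom, iv[0], iv[1]), 0) + 1
            frags.append(SimulatedFragment(
                fragment_id=f"{sample}:f{serial}", chrom=gene.chrom,
                blocks=blocks, junctions=junction_ivs, paired=paired,
                premrna=False, feature=gene.gene_id))
            serial += 1
    return serial


def _biased_start(rng, config, max_start: int) -> int:
    """Start position in [0, max_start] with weight exp(u / lambda): higher
    coverage toward the transcript 3' end."""
    if max_start <= 0:
        return 0
    lam = config.bias_lambda
    r = rng.random()
    z = math.expm1(max_start / lam)
    return min(int(lam * math.log1p(r * z)), max_start)


def _emit_premrna(rng, config, gene, n_pre, sample, frags, serial):
    s, e = gene.span
    for _ in range(n_pre):
        ln = _fragment_length(rng, config, e - s)
        start = s + int(rng.integers(0, e - s - ln + 1))
        blocks, junction_ivs, paired = _paired_blocks(
            rng, config, [(start, start + ln)])
        frags.append(SimulatedFragment(
            fragment_id=f"{sample}:f{serial}", chrom=gene.chrom,
            blocks=blocks, junctions=junction_ivs, paired=paired,
            premrna=True, feature=gene.gene_id))
        serial += 1
    return serial


def _emit_polya_reads(rng, config, upper_seqs, gene, n_mat, reads):
    n_pa = int(rng.binomial(n_mat, config.polya_read_rate)) if n_mat else 0
    if n_pa == 0:
        return
    seq = upper_seqs[gene.chrom]
    s, e = gene.span
    for k in range(n_pa):
        m = int(rng.integers(*config.polya_trimmed_range))
        tail = config.polya_tail_min + int(
            rng.geometric(config.polya_tail_geom_p)) - 1
        if gene.strand == "+":
            body = seq[e - m:e]
        else:
            body = revcomp(seq[s:s + m])
        read = body + "A" * tail
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append((f"pa:{gene.gene_id}:{k}", read))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write("\t".join(map(str, [
                        g.chrom, "txseq_sim", "exon", s + 1, e, ".",
                        g.strand, ".", attrs])) + "\n")


def _cigar(blocks: list[Interval]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(fragments: Sequence[SimulatedFragment],
              chrom_lengths: dict[str, int], path) -> None:
    """Mapped fragments as headered text SAM; paired fragments become two
    mate records sharing a name."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for f in fragments:
            if f.paired and len(f.blocks) >= 2:
                mid = _mate_split(f)
                m1, m2 = f.blocks[:mid], f.blocks[mid:]
                for flag, blocks, mate in ((0x1 | 0x40, m1, m2),
                                           (0x1 | 0x80, m2, m1)):
                    fh.write("\t".join(map(str, [
                        f.fragment_id, flag, f.chrom, blocks[0][0] + 1, 255,
                        _cigar(blocks), "=", mate[0][0] + 1, 0, "*", "*"]))
                        + "\n")
            else:
                fh.write("\t".join(map(str, [
                    f.fragment_id, 0, f.chrom, f.blocks[0][0] + 1, 255,
                    _cigar(f.blocks), "*", 0, 0, "*", "*"])) + "\n")


def _mate_split(f: SimulatedFragment) -> int:
    """Index splitting a paired fragment's blocks into its two mates (the
    widest non-junction gap)."""
    junction_set = set(f.junctions)
    best, width = 1, -1
    for i in range(len(f.blocks) - 1):
        gap = (f.blocks[i][1], f.blocks[i + 1][0])
        if gap in junction_set:
            continue
        if gap[1] - gap[0] > width:
            best, width = i + 1, gap[1] - gap[0]
    return best


def write_simulation(outdir, bundle: GenomeBundle, reads: ReadsBundle) -> dict:
    """Write every simulation artifact to ``outdir``; returns a manifest."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    cfg = bundle.config
    manifest: dict[str, str] = {}

    def path(name):
        manifest[name] = os.path.join(str(outdir), name)
        return manifest[name]

    bundle.genome.to_fasta(path("genome.fa"))
    write_gtf(bundle.genes, path("genes.gtf"))
    write_bed_intervals(bundle.repeats, path("repeats.bed"))
    write_bed_intervals(bundle.ests, path("ests.bed"))
    bundle.conservation.to_bedgraph(path("conservation.bedGraph"))
    with open(path("go_annotations.tsv"), "w") as fh:
        for gene in sorted(bundle.go_annotations):
            for term in sorted(bundle.go_annotations[gene]):
                fh.write(f"{gene}\t{term}\n")

    chrom_lengths = {c: len(s) for c, s in bundle.genome.chroms.items()}
    for sample in cfg.samples:
        write_sam(reads.fragments[sample], chrom_lengths,
                  path(f"{sample}.sam"))
        write_fastq(reads.polya_reads[sample], path(f"{sample}.polya.fastq"))
    write_junctions(reads.junctions, list(cfg.samples), path("junctions.tsv"))

    truth = reads.truth
    truth.genes.to_csv(path("truth/genes.tsv"), sep="\t", index=False)
    truth.cleavage_sites.to_csv(path("truth/cleavage_sites.tsv"), sep="\t",
                                index=False)
    truth.false_sites.to_csv(path("truth/false_sites.tsv"), sep="\t",
                             index=False)
    truth.tus.to_csv(path("truth/novel_tus.tsv"), sep="\t", index=False)
    truth.as_events.to_csv(path("truth/as_events.tsv"), sep="\t", index=False)
    if truth.expression is not None:
        truth.expression.to_csv(path("truth/expression.tsv"), sep="\t")
    for sample, df in truth.fragment_labels.items():
        df.to_csv(path(f"truth/fragments_{sample}.tsv"), sep="\t", index=False)
    with open(path("config.txt"), "w") as fh:
        for f_ in fields(cfg):
            fh.write(f"{f_.name} = {getattr(cfg, f_.name)}\n")
    return manifest


def as_aligned_fragments(reads: ReadsBundle, sample: str):
    """View one sample's simulated fragments as io-layer AlignedFragments."""
    from .io_formats import AlignedFragment

    return [
        AlignedFragment(
            fragment_id=f.fragment_id, sample=sample, chrom=f.chrom,
            blocks=list(f.blocks), unique=True, paired=f.paired,
            junctions=list(f.junctions),
        )
        for f in reads.fragments[sample]
    ]


def simulate(config: SimulationConfig) -> tuple[GenomeBundle, ReadsBundle]:
    """Convenience wrapper: genome + annotation + reads in one call."""
    bundle = simulate_genome_and_annotation(config)
    reads = simulate_fragments(config, bundle)
    return bundle, reads
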