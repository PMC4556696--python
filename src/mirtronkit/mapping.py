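"""Exact-match read placement with iterative 3' trimming.

Reads that fail to map are trimmed one 3' nucleotide per iteration (up
to ``max_iterations``, never below ``min_len``) and re-searched; a read
is reported at the first iteration at which its prefix matches anywhere
in the genome, with ALL placements at that iteration retained.  The
trimmed 3' suffix is preserved — it is the substrate for untemplated-
addition calling downstream.

Only exact matching is supported; the ``mismatches`` field exists for
forward compatibility and values > 0 are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mirtronkit.io_formats import Genome, IntronRecord, ReadBatch, revcomp

import pandas as pd


@dataclass(frozen=True)
class MappingConfig:
    min_len: int = 17
    max_iterations: int = 4
    mismatches: int = 0

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.mismatches != 0:
            raise ValueError("only exact matching (mismatches=0) is supported")


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class AlignedRead:
    sequence: str
    matched_prefix_len: int
    placements: list[Placement]
    trimmed_suffix: str
    count: int
    library_id: str

    @property
    def multi(self) -> bool:
        return len(self.placements) > 1

    @property
    def weight(self) -> float:
        """Fractional weight per placement (1 / number of placements)."""
        return 1.0 / len(self.placements)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


class GenomeIndex:
    """Exact-match seed index: every forward-strand k-mer -> positions.

    Queries verify the full needle by extension, so results equal a full
    substring scan as long as the needle is at least k long (guaranteed
    because k is the mapping length floor).
    """

    def __init__(self, genome: Genome, k: int = 17):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome:
            seq = genome.sequence(chrom)
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def find(self, needle: str) -> list[tuple[str, int]]:
        """All (chrom, pos) where the forward genome contains needle."""
        if len(needle) < self.k:
            raise ValueError("needle shorter than index k")
        hits = []
        for chrom, pos in self._index.get(needle[: self.k], ()):
            if self.genome.sequence(chrom).startswith(needle, pos):
                hits.append((chrom, pos))
        return hits


def map_iterative(
    batch: ReadBatch,
    genome: Genome,
    cfg: MappingConfig = MappingConfig(),
    index: GenomeIndex | None = None,
) -> tuple[list[AlignedRead], list[str]]:
    """Place collapsed reads on both genome strands, trimming iteratively.

    Returns (aligned reads, unmapped sequences).  A minus-strand
    placement covers the genomic interval whose reverse complement
    equals the matched prefix.  A prebuilt ``GenomeIndex`` may be
    supplied to amortize indexing across libraries.
    """
    if index is None:
        index = GenomeIndex(genome, cfg.min_len)
    aligned: list[AlignedRead] = []
    unmapped: list[str] = []
    for seq in sorted(batch.species):
        count = batch.species[seq]
        hit = None
        for n_trim in range(cfg.max_iterations + 1):
            prefix = seq[: len(seq) - n_trim] if n_trim else seq
            if len(prefix) < cfg.min_len:
                break
            rc = revcomp(prefix)
            placements = []
            for chrom, i in index.find(prefix):
                placements.append(Placement(chrom, i, i + len(prefix), "+"))
            for chrom, i in index.find(rc):
                placements.append(Placement(chrom, i, i + len(prefix), "-"))
            if placements:
                hit = AlignedRead(
                    sequence=seq,
                    matched_prefix_len=len(prefix),
                    placements=placements,
                    trimmed_suffix=seq[len(prefix):],
                    count=count,
                    library_id=batch.library_id,
                )
                break
        if hit is None:
            unmapped.append(seq)
        else:
            aligned.append(hit)
    return aligned, unmapped


@dataclass
class PlacedRead:
    """One placement of a read species expressed in intron sense coordinates.

    ``sense_start``/``sense_end`` are offsets from the splice donor
    (position 0); ``sense_end`` is the templated 3' end of the matched
    prefix.  ``trimmed_suffix`` carries any 3' nucleotides removed
    during iterative mapping (always untemplated relative to this
    placement).
    """

    sense_start: int
    sense_end: int
    sequence: str
    trimmed_suffix: str
    count: int
    weight: float
    library_id: str
    lib_class: str


@dataclass
class LocusReadSummary:
    intron: IntronRecord
    reads: list[PlacedRead] = field(default_factory=list)
    # sense-strand placements that cross an intron boundary; excluded from
    # mirtron evidence but retained for splice-anchored tail analysis
    # (sense coordinates may extend outside [0, intron length))
    junction_reads: list[PlacedRead] = field(default_factory=list)
    antisense_count: float = 0.0
    junction_overlap_count: float = 0.0

    def class_total(self, lib_class: str) -> float:
        return sum(r.count * r.weight for r in self.reads if r.lib_class == lib_class)

    @property
    def n_distinct_stacks(self) -> int:
        return len({(r.sense_start, r.sense_end) for r in self.reads})


def assign_to_introns(
    aligned: list[AlignedRead],
    introns: list[IntronRecord],
    lib_classes: dict[str, str],
    unique_only: bool = False,
) -> dict[str, LocusReadSummary]:
    """Bucket read placements into per-intron summaries.

    A placement is assigned to an intron iff it lies fully inside the
    intron on the sense strand of the host gene.  Antisense placements
    and placements spanning an intron boundary (junction overlap) are
    tallied but excluded from mirtron evidence.  Multi-mapped reads
    contribute fractional weight 1/n_placements unless ``unique_only``.
    """
    by_chrom: dict[str, list[IntronRecord]] = {}
    for intr in introns:
        by_chrom.setdefault(intr.chrom, []).append(intr)

    summaries: dict[str, LocusReadSummary] = {
        intr.locus_id: LocusReadSummary(intron=intr) for intr in introns
    }
    for ar in aligned:
        if unique_only and ar.multi:
            continue
        w = ar.weight
        for p in ar.placements:
            for intr in by_chrom.get(p.chrom, ()):
                if p.end <= intr.start or p.start >= intr.end:
                    continue
                summ = summaries[intr.locus_id]
                if intr.strand == "+":
                    s0, s1 = p.start - intr.start, p.end - intr.start
                else:
                    s0, s1 = intr.end - p.end, intr.end - p.start
                if p.start < intr.start or p.end > intr.end:
                    summ.junction_overlap_count += ar.count * w
                    if p.strand == intr.strand:
                        summ.junction_reads.append(
                            PlacedRead(
                                sense_start=s0,
                                sense_end=s1,
                                sequence=ar.sequence[: ar.matched_prefix_len],
                                trimmed_suffix=ar.trimmed_suffix,
                                count=ar.count,
                                weight=w,
                                library_id=ar.library_id,
                                lib_class=lib_classes[ar.library_id],
                            )
                        )
                    continue
                if p.strand != intr.strand:
                    summ.antisense_count += ar.count * w
                    continue
                summ.reads.append(
                    PlacedRead(
                        sense_start=s0,
                        sense_end=s1,
                        sequence=ar.sequence[: ar.matched_prefix_len],
                        trimmed_suffix=ar.trimmed_suffix,
                        count=ar.count,
                        weight=w,
                        library_id=ar.library_id,
                        lib_class=lib_classes[ar.library_id],
                    )
                )
    return summaries


def placements_table(aligned: list[AlignedRead]) -> pd.DataFrame:
    """Flat TSV-ready dump of placements."""
    rows = []
    for ar in aligned:
        for p in ar.placements:
            rows.append(
                {
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "sequence": ar.sequence,
                    "trimmed_suffix": ar.trimmed_suffix,
                    "count": ar.count,
                    "multi": ar.multi,
                    "library_id": ar.library_id,
                }
            )
    cols = [
        "chrom", "start", "end", "strand", "sequence",
        "trimmed_suffix", "count", "multi", "library_id",
    ]
    return pd.DataFrame(rows, columns=cols)
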