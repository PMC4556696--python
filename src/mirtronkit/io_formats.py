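"""Readers and writers for the external formats the pipeline touches.

Conventions enforced here and relied on everywhere downstream:

* all genomic intervals are 0-based half-open;
* BED input needs no coordinate shift;
* sequences are stored in DNA space (U normalized to T at ingest);
* all strand flips happen in this module — downstream arm/terminus
  logic operates in sense-of-host-gene orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_LIB_CLASSES = frozenset({"total", "ago_ip", "control_ip", "input"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An in-memory genome: chromosome id -> uppercase DNA sequence.

    ``fetch`` returns the reverse complement for minus-strand queries, so
    callers always receive sequence in the requested sense orientation.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand (sense orientation)."""
        if not 0 <= start <= end <= len(self._seqs[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        seq = self._seqs[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq


def read_genome_fasta(path: str | Path) -> Genome:
    """Load a FASTA genome into memory."""
    return Genome(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class IntronRecord:
    """A host-gene intron in genomic coordinates.

    ``intron_index`` is the 1-based ordinal in transcription order;
    ``host_intron_count`` the total introns in the host gene. Donor and
    acceptor dinucleotides are in the sense of the host gene, so a
    canonical intron reads GT...AG regardless of genomic strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str
    intron_index: int
    host_intron_count: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"intron end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.host_intron_count < self.intron_index:
            raise ValueError(
                "host_intron_count must be >= intron_index "
                f"({self.host_intron_count} < {self.intron_index})"
            )

    @property
    def locus_id(self) -> str:
        return f"{self.host_gene}|{self.intron_index}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def donor_dinucleotide(self, genome: Genome) -> str:
        """First two intronic nt in gene sense ('GT' for canonical introns)."""
        if self.strand == "+":
            return genome.fetch(self.chrom, self.start, self.start + 2, "+")
        return genome.fetch(self.chrom, self.end - 2, self.end, "-")

    def acceptor_dinucleotide(self, genome: Genome) -> str:
        """Last two intronic nt in gene sense ('AG' for canonical introns)."""
        if self.strand == "+":
            return genome.fetch(self.chrom, self.end - 2, self.end, "+")
        return genome.fetch(self.chrom, self.start, self.start + 2, "-")

    def sense_sequence(self, genome: Genome) -> str:
        return genome.fetch(self.chrom, self.start, self.end, self.strand)


def read_introns_bed(path: str | Path) -> list[IntronRecord]:
    """Parse introns from BED6.

    The name field must encode ``host_gene|intron_index|host_intron_count``.
    Lines with a malformed name field are rejected with a logged warning;
    an interval with end <= start is a hard error naming the line.
    """
    records = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                logger.warning("line %d: fewer than 6 BED fields; rejected", lineno)
                n_rejected += 1
                continue
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(
                    f"line {lineno}: intron end <= start ({line!r})"
                )
            parts = name.split("|")
            if len(parts) != 3:
                logger.warning(
                    "line %d: name field %r does not encode "
                    "host_gene|intron_index|host_intron_count; rejected",
                    lineno,
                    name,
                )
                n_rejected += 1
                continue
            try:
                idx, total = int(parts[1]), int(parts[2])
            except ValueError:
                logger.warning("line %d: non-integer intron ordinal in %r; rejected", lineno, name)
                n_rejected += 1
                continue
            records.append(
                IntronRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    host_gene=parts[0],
                    intron_index=idx,
                    host_intron_count=total,
                )
            )
    if n_rejected:
        logger.warning("rejected %d malformed intron lines", n_rejected)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_introns_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(introns, key=lambda r: (r.chrom, r.start, r.end)):
            name = f"{r.host_gene}|{r.intron_index}|{r.host_intron_count}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one small-RNA library."""

    library_id: str
    species: str
    tissue: str
    lib_class: str
    adapter: str | None = None

    def __post_init__(self):
        if self.lib_class not in VALID_LIB_CLASSES:
            raise ValueError(
                f"lib_class {self.lib_class!r} not in {sorted(VALID_LIB_CLASSES)}"
            )


def read_manifest(path: str | Path) -> list[LibraryMeta]:
    """Read a library manifest TSV (library_id, species, tissue, lib_class[, adapter])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"library_id", "species", "tissue", "lib_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["library_id"].duplicated().any():
        dup = df.loc[df["library_id"].duplicated(), "library_id"].tolist()
        raise ValueError(f"duplicate library ids in manifest: {dup}")
    out = []
    for row in df.itertuples(index=False):
        adapter = getattr(row, "adapter", "") or None
        out.append(
            LibraryMeta(
                library_id=row.library_id,
                species=row.species,
                tissue=row.tissue,
                lib_class=row.lib_class,
                adapter=adapter,
            )
        )
    return out


def write_manifest(libraries: Iterable[LibraryMeta], path: str | Path) -> None:
    rows = [
        {
            "library_id": m.library_id,
            "species": m.species,
            "tissue": m.tissue,
            "lib_class": m.lib_class,
            "adapter": m.adapter or "",
        }
        for m in libraries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ReadBatch:
    """Collapsed read species for one library: (sequence -> count)."""

    library_id: str
    species: dict[str, int] = field(default_factory=dict)
    n_dropped_short: int = 0
    n_dropped_badchar: int = 0

    def add(self, sequence: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("read count must be >= 1")
        self.species[sequence] = self.species.get(sequence, 0) + count

    @property
    def total_reads(self) -> int:
        return sum(self.species.values())

    def __len__(self) -> int:
        return len(self.species)


def _clip_adapter(seq: str, adapter: str | None) -> str:
    """Clip at the leftmost exact occurrence of the 3' adapter."""
    if adapter:
        i = seq.find(adapter)
        if i >= 0:
            return seq[:i]
    return seq


def read_small_rna(
    path: str | Path,
    manifest_entry: LibraryMeta,
    adapter: str | None = None,
    min_len: int = 17,
) -> ReadBatch:
    """Ingest a small-RNA library from FASTQ or collapsed FASTA.

    Collapsed-FASTA headers carry counts as ``id_xN``; a header without
    the suffix defaults to count 1 with a logged notice.  The 3' adapter
    (per-library manifest field unless given explicitly) is clipped at
    its leftmost exact occurrence; reads shorter than ``min_len`` after
    clipping are dropped and tallied, as are reads with non-ACGTUN
    characters.  U is normalized to T; duplicates are collapsed.
    """
    if adapter is None:
        adapter = manifest_entry.adapter
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    batch = ReadBatch(library_id=manifest_entry.library_id)
    n_default_count = 0
    for rec in SeqIO.parse(str(path), fmt):
        count = 1
        if fmt == "fasta":
            tail = rec.id.rsplit("_x", 1)
            if len(tail) == 2 and tail[1].isdigit():
                count = int(tail[1])
            else:
                n_default_count += 1
        seq = str(rec.seq).upper().replace("U", "T")
        if set(seq) - set("ACGTN"):
            batch.n_dropped_badchar += count
            continue
        seq = _clip_adapter(seq, adapter)
        if len(seq) < min_len:
            batch.n_dropped_short += count
            continue
        batch.add(seq, count)
    if n_default_count:
        logger.info(
            "%s: %d FASTA headers lacked an _xN count suffix; count defaulted to 1",
            manifest_entry.library_id,
            n_default_count,
        )
    return batch


def write_collapsed_fasta(batch: ReadBatch, path: str | Path, rna: bool = False) -> None:
    """Write a ReadBatch as collapsed FASTA with ``id_xN`` count headers."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sorted(batch.species), 1):
            out = seq.replace("T", "U") if rna else seq
            fh.write(f">r{i}_x{batch.species[seq]}\n{out}\n")


def write_table(table: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write an output table as TSV: header row, UTF-8, deterministic order.

    Floats are written with 6 significant digits; a write-then-read
    round-trip through :func:`read_table` preserves values to 1e-6
    relative precision.
    """
    if sort_by:
        table = table.sort_values(sort_by, kind="mergesort")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
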