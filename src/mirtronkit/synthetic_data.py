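"""Synthetic genomes, planted mirtron loci, small-RNA libraries, and
tissue expression tables with known ground truth.

The generator emulates the statistical structure of real small-RNA
data over intron annotations: splice-defined duplex reads with 2-nt 3'
overhangs, mature/star strand asymmetry, hairpin-loop reads present in
total-RNA but never Ago-IP libraries, untemplated 3' U/A tailing at
splice-defined 3p ends, 5'-G decapitation at splice-defined 5p ends,
5' jitter at non-splice-defined termini, uniform background degradation
reads over bulk introns, and tissue expression matrices with planted
correlated/discordant mirtron-host regimes.

Every emitted read is traceable through the truth ledger to
{locus + arm, loop, background}, so recovery tests can compare pipeline
output against planted truth using only public files plus the ledger.

All outputs are deterministic functions of the config (including its
seed): identical configs give byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mirtronkit.io_formats import (
    Genome,
    IntronRecord,
    LibraryMeta,
    ReadBatch,
    revcomp,
    write_collapsed_fasta,
    write_genome_fasta,
    write_introns_bed,
    write_manifest,
    write_table,
)

MIRTRON_SUBTYPES = ("conventional", "5p_tailed", "3p_tailed", "two_tailed")
PLANT_CLASSES = MIRTRON_SUBTYPES + ("canonical",)

_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Simulation knobs.  Defaults are the study conditions used by the
    bundled tests and the acceptance script; see docs/methods.md for the
    rationale behind each value."""

    seed: int = 0
    # genome / annotation
    n_bulk_genes: int = 30
    bulk_intron_count_mean: float = 5.0      # 1 + Poisson(mean - 1)
    host_intron_count_mean: float = 15.0     # mirtron hosts: ~3x bulk
    intron_len_log_mean: float = 5.5         # lognormal, mode ~150-250 nt
    intron_len_log_sigma: float = 0.8
    intron_len_min: int = 80
    intron_len_max: int = 4000
    exon_len_range: tuple[int, int] = (100, 300)
    minus_strand_frac: float = 0.3
    # planted loci
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "conventional": 3,
            "5p_tailed": 3,
            "3p_tailed": 3,
            "two_tailed": 3,
            "canonical": 6,
        }
    )
    hairpin_len_mean: dict[str, float] = field(
        default_factory=lambda: {
            "conventional": 83.0,
            "5p_tailed": 63.0,
            "3p_tailed": 61.0,
            "two_tailed": 69.0,
            "canonical": 60.0,
        }
    )
    hairpin_len_sd: dict[str, float] = field(
        default_factory=lambda: {
            "conventional": 9.7,
            "5p_tailed": 9.9,
            "3p_tailed": 7.8,
            "two_tailed": 10.0,
            "canonical": 4.3,
        }
    )
    tail5_length_range: tuple[int, int] = (10, 3000)   # log-uniform
    tail3_length_range: tuple[int, int] = (10, 300)
    two_tailed_offset_range: tuple[int, int] = (10, 100)
    loop_len: int = 18
    mature_len: int = 22
    duplex_gc_bias: float = 0.6       # fraction of G/C in stem arms
    fivep_g_frac: float = 0.4         # G share within the GC fraction on 5p arm
    stem_mismatch_rate: float = 0.1
    overhang_3p: int = 2
    # read phenomenology
    star_asymmetry: float = 10.0      # mature:star ratio
    loop_read_rate: float = 0.05      # loop reads per locus read, total libs
    jitter5: dict[int, float] = field(
        default_factory=lambda: {0: 0.8, 1: 0.1, -1: 0.1}
    )
    uridylation_prob: float = 0.25    # per 3p read at splice-defined 3p ends
    adenylation_prob: float = 0.10
    tail_len_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.35, 3: 0.10}
    )
    decapitation_prob: float = 0.20   # per 5p read at splice-defined 5p ends
    background_rate: float = 2.0      # reads per kb of bulk intron per library
    depth_per_library: int = 30000
    locus_weight_sigma: float = 0.5   # lognormal spread of locus abundance
    confounding_tails: bool = False   # genomic seq downstream of AG equals tail
    # expression
    tissues: tuple[str, ...] = (
        "brain", "heart", "kidney", "liver", "lung", "muscle", "spleen",
    )
    discordant_frac: float = 0.25
    expression_noise_sigma: float = 0.2
    expression_log_mean: float = 3.0
    expression_log_sigma: float = 1.0

    def validate(self) -> None:
        for name, p in [
            ("uridylation_prob", self.uridylation_prob),
            ("adenylation_prob", self.adenylation_prob),
            ("decapitation_prob", self.decapitation_prob),
            ("loop_read_rate", self.loop_read_rate),
            ("discordant_frac", self.discordant_frac),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.uridylation_prob + self.adenylation_prob > 1.0:
            raise ValueError("uridylation_prob + adenylation_prob must be <= 1")
        if self.overhang_3p < 0:
            raise ValueError("overhang_3p must be >= 0")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class_counts must be non-negative")
        if abs(sum(self.jitter5.values()) - 1.0) > 1e-9:
            raise ValueError("jitter5 probabilities must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["exon_len_range"] = list(self.exon_len_range)
        d["tail5_length_range"] = list(self.tail5_length_range)
        d["tail3_length_range"] = list(self.tail3_length_range)
        d["two_tailed_offset_range"] = list(self.two_tailed_offset_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in (
            "exon_len_range", "tail5_length_range",
            "tail3_length_range", "two_tailed_offset_range", "tissues",
        ):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("jitter5", "tail_len_probs"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class PlantedLocus:
    """Ground truth for one planted hairpin locus."""

    locus_id: str
    subtype: str                       # mirtron subtype or 'canonical'
    chrom: str
    strand: str
    hairpin_genomic: tuple[int, int]
    hairpin_len: int
    intron: IntronRecord | None        # None for canonical loci
    hairpin_in_intron: tuple[int, int] | None  # sense coords
    mature_arm: str                    # '5p' or '3p'
    mature_len: int
    arm_len: int
    splice5_defined: bool
    splice3_defined: bool
    expression_regime: str             # 'correlated' | 'discordant'

    def sense_hairpin_seq(self, genome: Genome) -> str:
        return genome.fetch(self.chrom, *self.hairpin_genomic, self.strand)

    def read_genomic(self, s: int, e: int) -> tuple[int, int]:
        """Genomic interval of hairpin-sense offsets [s, e)."""
        g0, g1 = self.hairpin_genomic
        if self.strand == "+":
            return (g0 + s, g0 + e)
        return (g1 - e, g1 - s)

    @property
    def fivep_read(self) -> tuple[int, int]:
        return (0, self.mature_len)

    @property
    def threep_read(self) -> tuple[int, int]:
        return (self.hairpin_len - self.mature_len, self.hairpin_len)

    @property
    def loop_interval(self) -> tuple[int, int]:
        return (self.arm_len, self.hairpin_len - self.arm_len)


@dataclass
class TruthSet:
    genome: Genome
    introns: list[IntronRecord]
    planted: list[PlantedLocus]
    bulk_introns: list[IntronRecord]
    config: SimConfig

    def mirtrons(self) -> list[PlantedLocus]:
        return [p for p in self.planted if p.subtype != "canonical"]

    def canonical(self) -> list[PlantedLocus]:
        return [p for p in self.planted if p.subtype == "canonical"]


def _random_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    return "".join(rng.choice(_NT, size=n, p=probs))


def _sample_intron_len(rng: np.random.Generator, cfg: SimConfig) -> int:
    while True:
        l = int(np.exp(rng.normal(cfg.intron_len_log_mean, cfg.intron_len_log_sigma)))
        if cfg.intron_len_min <= l <= cfg.intron_len_max:
            return l


def _build_hairpin(rng: np.random.Generator, cfg: SimConfig, hairpin_len: int,
                   force_gt_start: bool, force_ag_end: bool,
                   start_u: bool) -> str:
    """Construct a hairpin whose arms are reverse-complementary (with a
    configured mismatch rate), leaving a 2-nt 3' overhang at both duplex
    ends.  The loop is poly-A so it cannot extend the stem."""
    ll = cfg.loop_len
    arm = (hairpin_len - ll) // 2
    ll = hairpin_len - 2 * arm  # absorb odd lengths into the loop
    gc = cfg.duplex_gc_bias
    pg = gc * cfg.fivep_g_frac * 2 if cfg.fivep_g_frac <= 0.5 else gc
    probs = np.array([
        (1 - gc) * 0.4,            # A
        gc * (1 - cfg.fivep_g_frac),  # C
        gc * cfg.fivep_g_frac,     # G  (5p arm G-rich -> 3p arm C-rich)
        (1 - gc) * 0.6,            # T
    ])
    probs = probs / probs.sum()
    fivep = list(_random_seq(rng, arm, probs))
    if force_gt_start:
        fivep[0], fivep[1] = "G", "T"
    elif start_u:
        fivep[0] = "T"
    fivep = "".join(fivep)
    # 3p arm: positions 0..arm-3 pair 5p positions arm-3..0 (2-nt 3'
    # overhang at each duplex end); last two 3p nt are unpaired.
    paired = revcomp(fivep[: arm - 2])
    free2 = "AG" if force_ag_end else "".join(rng.choice(["C", "A"], size=2))
    threep = list(paired + free2)
    # plant mismatches in the stem interior (keep 3 pairs at each stem end)
    n_pairs = arm - 2
    interior = list(range(3, n_pairs - 3))
    n_mm = int(round(cfg.stem_mismatch_rate * n_pairs))
    if n_mm and interior:
        for pos in rng.choice(interior, size=min(n_mm, len(interior)), replace=False):
            partner = fivep[n_pairs - 1 - pos]
            bad = {"A": "A", "C": "C", "G": "G", "T": "T"}[partner]
            threep[pos] = bad  # identical nt never pairs with its partner
    loop = "A" * ll
    return fivep + loop + "".join(threep)


def build_truth(config: SimConfig) -> TruthSet:
    """Assemble a toy genome with bulk introns and planted loci.

    Conventional hairpins span donor GT to acceptor AG exactly;
    5p-tailed hairpins end at the acceptor; 3p-tailed hairpins start at
    the donor; two-tailed hairpins keep both ends >= 5 nt from the
    splice sites.  Canonical (Drosha-type) hairpins are planted in
    exonic sequence, outside any annotated intron.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    pieces: list[str] = []
    cursor = 0
    introns: list[IntronRecord] = []
    bulk: list[IntronRecord] = []
    planted: list[PlantedLocus] = []

    def emit_gene(gene_id: str, strand: str, sense_seq: str,
                  sense_introns: list[tuple[int, int]],
                  n_total_introns: int) -> list[IntronRecord]:
        nonlocal cursor
        gstart = cursor
        glen = len(sense_seq)
        out = []
        for ordinal, (a, b) in enumerate(sense_introns, 1):
            if strand == "+":
                s, e = gstart + a, gstart + b
            else:
                s, e = gstart + glen - b, gstart + glen - a
            out.append(
                IntronRecord(
                    chrom=chrom, start=s, end=e, strand=strand,
                    host_gene=gene_id, intron_index=ordinal,
                    host_intron_count=n_total_introns,
                )
            )
        pieces.append(sense_seq if strand == "+" else revcomp(sense_seq))
        cursor += glen + 50
        pieces.append(_random_seq(rng, 50))  # intergenic spacer
        return out

    def make_intron_seq(length: int) -> str:
        body = _random_seq(rng, length - 4)
        return "GT" + body + "AG"

    def exon_seq(length: int, lead: str = "") -> str:
        return lead + _random_seq(rng, length - len(lead))

    # --- bulk genes ---
    for g in range(config.n_bulk_genes):
        n_introns = 1 + rng.poisson(max(config.bulk_intron_count_mean - 1, 0))
        strand = "-" if rng.random() < config.minus_strand_frac else "+"
        seq_parts = [exon_seq(rng.integers(*config.exon_len_range))]
        ivs = []
        pos = len(seq_parts[0])
        for _ in range(n_introns):
            il = _sample_intron_len(rng, config)
            ivs.append((pos, pos + il))
            seq_parts.append(make_intron_seq(il))
            pos += il
            ex = exon_seq(rng.integers(*config.exon_len_range))
            seq_parts.append(ex)
            pos += len(ex)
        recs = emit_gene(f"BULK{g:03d}", strand, "".join(seq_parts), ivs, n_introns)
        introns.extend(recs)
        bulk.extend(recs)

    # --- mirtron host genes: one planted locus per gene ---
    def sample_hairpin_len(subtype: str) -> int:
        mean = config.hairpin_len_mean[subtype]
        sd = config.hairpin_len_sd[subtype]
        min_len = max(50, config.loop_len + 2 * (config.mature_len - 4))
        while True:
            h = int(round(rng.normal(mean, sd)))
            if min_len <= h <= 500:
                return h

    def log_uniform(lo: int, hi: int) -> int:
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

    counter = 0
    for subtype in MIRTRON_SUBTYPES:
        for _ in range(config.class_counts.get(subtype, 0)):
            counter += 1
            gene_id = f"HOST{counter:03d}"
            strand = "-" if rng.random() < config.minus_strand_frac else "+"
            n_introns = 1 + rng.poisson(max(config.host_intron_count_mean - 1, 0))
            mirtron_ordinal = int(rng.integers(1, n_introns + 1))
            h = sample_hairpin_len(subtype)
            gt_start = subtype in ("conventional", "3p_tailed")
            ag_end = subtype in ("conventional", "5p_tailed")
            hp = _build_hairpin(rng, config, h, gt_start, ag_end,
                                start_u=not gt_start)
            if subtype == "conventional":
                intron_seq, h5 = hp, 0
            elif subtype == "5p_tailed":
                t5 = log_uniform(*config.tail5_length_range)
                intron_seq = "GT" + _random_seq(rng, t5 - 2) + hp
                h5 = t5
            elif subtype == "3p_tailed":
                t3 = log_uniform(*config.tail3_length_range)
                intron_seq = hp + _random_seq(rng, t3 - 2) + "AG"
                h5 = 0
            else:  # two_tailed
                t5 = int(rng.integers(*config.two_tailed_offset_range))
                t3 = int(rng.integers(*config.two_tailed_offset_range))
                intron_seq = (
                    "GT" + _random_seq(rng, t5 - 2) + hp
                    + _random_seq(rng, t3 - 2) + "AG"
                )
                h5 = t5
            ilen = len(intron_seq)
            # assemble the gene: exons around every intron; the mirtron
            # intron is at position `mirtron_ordinal`
            seq_parts = []
            ivs = []
            pos = 0
            first_exon = exon_seq(rng.integers(*config.exon_len_range))
            seq_parts.append(first_exon)
            pos += len(first_exon)
            mirtron_iv = None
            for k in range(1, n_introns + 1):
                if k == mirtron_ordinal:
                    iseq = intron_seq
                else:
                    iseq = make_intron_seq(_sample_intron_len(rng, config))
                ivs.append((pos, pos + len(iseq)))
                if k == mirtron_ordinal:
                    mirtron_iv = (pos, pos + len(iseq))
                seq_parts.append(iseq)
                pos += len(iseq)
                lead = ""
                if k == mirtron_ordinal and ag_end:
                    # engineer the sequence just past the acceptor so that
                    # untemplated tails never match the genome -- unless
                    # confounding mode is on, where it equals a U-tail.
                    lead = "TTT" if config.confounding_tails else "CGC"
                ex = exon_seq(rng.integers(*config.exon_len_range), lead=lead)
                seq_parts.append(ex)
                pos += len(ex)
            recs = emit_gene(gene_id, strand, "".join(seq_parts), ivs, n_introns)
            introns.extend(recs)
            bulk.extend(r for r in recs if r.intron_index != mirtron_ordinal)
            mirtron_rec = next(
                r for r in recs if r.intron_index == mirtron_ordinal
            )
            h3 = h5 + h
            if mirtron_rec.strand == "+":
                hpg = (mirtron_rec.start + h5, mirtron_rec.start + h3)
            else:
                hpg = (mirtron_rec.end - h3, mirtron_rec.end - h5)
            arm = (h - config.loop_len) // 2
            planted.append(
                PlantedLocus(
                    locus_id=mirtron_rec.locus_id,
                    subtype=subtype,
                    chrom=chrom,
                    strand=mirtron_rec.strand,
                    hairpin_genomic=hpg,
                    hairpin_len=h,
                    intron=mirtron_rec,
                    hairpin_in_intron=(h5, h3),
                    mature_arm="5p" if rng.random() < 0.5 else "3p",
                    mature_len=min(config.mature_len, arm),
                    arm_len=arm,
                    splice5_defined=gt_start,
                    splice3_defined=ag_end,
                    expression_regime=(
                        "discordant" if rng.random() < config.discordant_frac
                        else "correlated"
                    ),
                )
            )

    # --- canonical miRNA loci in intergenic/exonic space ---
    for c in range(config.class_counts.get("canonical", 0)):
        counter += 1
        h = sample_hairpin_len("canonical")
        hp = _build_hairpin(rng, config, h, False, False, start_u=True)
        strand = "-" if rng.random() < config.minus_strand_frac else "+"
        flank_l = _random_seq(rng, 100)
        flank_r = _random_seq(rng, 100)
        sense = flank_l + hp + flank_r
        gstart = cursor
        pieces.append(sense if strand == "+" else revcomp(sense))
        cursor += len(sense) + 50
        pieces.append(_random_seq(rng, 50))
        if strand == "+":
            hpg = (gstart + 100, gstart + 100 + h)
        else:
            hpg = (gstart + 100, gstart + 100 + h)  # symmetric flanks
        arm = (h - config.loop_len) // 2
        planted.append(
            PlantedLocus(
                locus_id=f"CANON{c:03d}",
                subtype="canonical",
                chrom=chrom,
                strand=strand,
                hairpin_genomic=hpg,
                hairpin_len=h,
                intron=None,
                hairpin_in_intron=None,
                mature_arm="5p" if rng.random() < 0.5 else "3p",
                mature_len=min(config.mature_len, arm),
                arm_len=arm,
                splice5_defined=False,
                splice3_defined=False,
                expression_regime="correlated",
            )
        )

    genome = Genome({chrom: "".join(pieces)})
    introns.sort(key=lambda r: (r.chrom, r.start))
    bulk.sort(key=lambda r: (r.chrom, r.start))
    return TruthSet(
        genome=genome, introns=introns, planted=planted,
        bulk_introns=bulk, config=config,
    )


def _locus_weights(truth: TruthSet, rng: np.random.Generator) -> np.ndarray:
    cfg = truth.config
    return np.exp(rng.normal(0.0, cfg.locus_weight_sigma, size=len(truth.planted)))


def simulate_reads(
    truth: TruthSet,
    manifest: list[LibraryMeta],
    config: SimConfig | None = None,
) -> tuple[dict[str, ReadBatch], pd.DataFrame]:
    """Emit per-library collapsed reads plus a truth-annotated ledger.

    Per library the configured depth is distributed multinomially over
    (locus, arm) emission channels, loop channels (total libraries
    only), and background degradation (the only channel for control-IP
    libraries), so per-library totals equal the configured depth
    exactly.  5' jitter applies only to termini that are not
    splice-defined; splice-defined 5' ends are exact except for
    decapitation, and splice-defined 3' ends gain untemplated U/A tails.
    """
    if config is None:
        config = truth.config
    if not manifest:
        raise ValueError("manifest must list at least one library")
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    weights = _locus_weights(truth, rng)
    # per-locus dominant-arm split
    r = cfg.star_asymmetry
    p_mature, p_star = r / (1 + r), 1 / (1 + r)

    bulk_kb = sum(i.length for i in truth.bulk_introns) / 1000.0
    bulk_lens = np.array([i.length for i in truth.bulk_introns], dtype=float)
    bulk_probs = bulk_lens / bulk_lens.sum() if len(bulk_lens) else None

    jitter_offsets = np.array(sorted(cfg.jitter5), dtype=int)
    jitter_probs = np.array([cfg.jitter5[int(o)] for o in jitter_offsets])
    tail_lens = np.array(sorted(cfg.tail_len_probs), dtype=int)
    tail_len_probs = np.array([cfg.tail_len_probs[int(l)] for l in tail_lens])

    batches: dict[str, ReadBatch] = {}
    ledger_rows: list[dict] = []

    for lib in manifest:
        lib_key = zlib.crc32(lib.library_id.encode()) % (2**31)
        lib_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed % (2**31), 7, lib_key])
        )
        channels: list[tuple[str, int, str]] = []  # (kind, locus index, arm)
        w: list[float] = []
        if lib.lib_class == "control_ip":
            if cfg.background_rate == 0:
                # a noiseless world has an empty control IP
                batches[lib.library_id] = ReadBatch(library_id=lib.library_id)
                continue
            channels.append(("background", -1, ""))
            w.append(1.0)
        else:
            for i, loc in enumerate(truth.planted):
                wm = weights[i] * (p_mature if loc.mature_arm == "5p" else p_star)
                ws = weights[i] * (p_star if loc.mature_arm == "5p" else p_mature)
                channels.append(("arm", i, "5p"))
                w.append(wm)
                channels.append(("arm", i, "3p"))
                w.append(ws)
                if lib.lib_class == "total" and cfg.loop_read_rate > 0:
                    channels.append(("loop", i, ""))
                    w.append(weights[i] * cfg.loop_read_rate)
            if lib.lib_class in ("total", "input") and cfg.background_rate > 0:
                # background expectation is absolute (reads per kb of bulk
                # intron); the planted-locus channels share the remaining depth
                bg_frac = min(
                    cfg.background_rate * bulk_kb / cfg.depth_per_library, 0.9
                )
                locus_total = float(np.sum(w))
                if locus_total > 0:
                    w = [x * (1 - bg_frac) / locus_total for x in w]
                    channels.append(("background", -1, ""))
                    w.append(bg_frac)
                else:
                    channels = [("background", -1, "")]
                    w = [1.0]
        w_arr = np.array(w)
        counts = lib_rng.multinomial(cfg.depth_per_library, w_arr / w_arr.sum())

        batch = ReadBatch(library_id=lib.library_id)
        for (kind, idx, arm), n in zip(channels, counts):
            if n == 0:
                continue
            if kind == "background":
                _emit_background(truth, lib, int(n), lib_rng, batch, ledger_rows)
            elif kind == "loop":
                loc = truth.planted[idx]
                s, e = loc.loop_interval
                seq = loc.sense_hairpin_seq(truth.genome)[s:e]
                batch.add(seq, int(n))
                ledger_rows.append(_ledger(lib, seq, int(n), "loop", loc, ""))
            else:
                _emit_arm_reads(
                    truth, truth.planted[idx], arm, lib, int(n), lib_rng,
                    cfg, jitter_offsets, jitter_probs, tail_lens,
                    tail_len_probs, batch, ledger_rows,
                )
        batches[lib.library_id] = batch

    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "library_id", "sequence", "count", "origin", "locus_id",
            "arm", "modification",
        ],
    )
    return batches, ledger


def _ledger(lib, seq, n, origin, loc, arm, modification=""):
    return {
        "library_id": lib.library_id,
        "sequence": seq,
        "count": n,
        "origin": origin,
        "locus_id": "" if loc is None else loc.locus_id,
        "arm": arm,
        "modification": modification,
    }


def _emit_background(truth, lib, n, rng, batch, ledger_rows):
    if not truth.bulk_introns:
        return
    lens = np.array([i.length for i in truth.bulk_introns], dtype=float)
    idx = rng.choice(len(truth.bulk_introns), size=n, p=lens / lens.sum())
    read_lens = rng.integers(17, 26, size=n)
    collapsed: dict[str, int] = {}
    for i, rl in zip(idx, read_lens):
        intr = truth.bulk_introns[i]
        rl = min(rl, intr.length)
        off = int(rng.integers(0, intr.length - rl + 1))
        seq = intr.sense_sequence(truth.genome)[off : off + rl]
        collapsed[seq] = collapsed.get(seq, 0) + 1
    for seq, c in sorted(collapsed.items()):
        batch.add(seq, c)
        ledger_rows.append(_ledger(lib, seq, c, "background", None, ""))


def _emit_arm_reads(truth, loc, arm, lib, n, rng, cfg, jitter_offsets,
                    jitter_probs, tail_lens, tail_len_probs, batch,
                    ledger_rows):
    """Emit n reads from one arm of one locus with terminal phenomenology."""
    hp = loc.sense_hairpin_seq(truth.genome)
    h = loc.hairpin_len
    m = loc.mature_len
    if arm == "5p":
        base_s, base_e = 0, m
        splice_defined_5 = loc.splice5_defined
        splice_defined_3_end = False
    else:
        base_s, base_e = h - m, h
        splice_defined_5 = False
        splice_defined_3_end = loc.splice3_defined

    origin = "mature" if arm == loc.mature_arm else "star"

    # 5' end variants
    if splice_defined_5:
        n_decap = rng.binomial(n, cfg.decapitation_prob)
        five_variants = [(0, n - n_decap, ""), (1, n_decap, "decap")]
    else:
        jn = rng.multinomial(n, jitter_probs)
        five_variants = [
            (int(o), int(c), f"jitter{int(o):+d}" if o else "")
            for o, c in zip(jitter_offsets, jn)
            if c > 0
        ]

    # sense sequence around the hairpin for jitter beyond its bounds
    g0, g1 = loc.hairpin_genomic
    lo_ext, hi_ext = 5, 5
    if loc.strand == "+":
        ctx = truth.genome.fetch(
            loc.chrom, g0 - lo_ext, g1 + hi_ext, "+"
        )
    else:
        ctx = truth.genome.fetch(loc.chrom, g0 - hi_ext, g1 + lo_ext, "-")
    # ctx[lo_ext + k] == hairpin sense position k

    for off5, cnt, mod5 in five_variants:
        if cnt <= 0:
            continue
        s = base_s + off5  # decapitation is the +1 variant itself
        core = ctx[lo_ext + s : lo_ext + base_e]
        if not splice_defined_3_end:
            if cnt > 0:
                batch.add(core, cnt)
                ledger_rows.append(
                    _ledger(lib, core, cnt, origin, loc, arm, mod5)
                )
            continue
        # untemplated tails at the splice-defined 3p end
        n_u = rng.binomial(cnt, cfg.uridylation_prob)
        rem = cnt - n_u
        pa = (
            cfg.adenylation_prob / (1 - cfg.uridylation_prob)
            if cfg.uridylation_prob < 1
            else 0.0
        )
        n_a = rng.binomial(rem, min(pa, 1.0))
        n_plain = cnt - n_u - n_a
        if n_plain:
            batch.add(core, n_plain)
            ledger_rows.append(_ledger(lib, core, n_plain, origin, loc, arm, mod5))
        for letter, n_mod in (("T", n_u), ("A", n_a)):
            if n_mod == 0:
                continue
            ln_counts = rng.multinomial(n_mod, tail_len_probs)
            for tl, c in zip(tail_lens, ln_counts):
                if c == 0:
                    continue
                seq = core + letter * int(tl)
                mod = ";".join(x for x in (mod5, f"tail:{letter * int(tl)}") if x)
                batch.add(seq, int(c))
                ledger_rows.append(_ledger(lib, seq, int(c), origin, loc, arm, mod))


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    truth: TruthSet,
    tissues: list[str] | None = None,
    config: SimConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Tissue expression tables: host gene at three levels plus mirtron RPMM.

    Correlated loci have mirtron abundance proportional to host
    spliced-junction RPM times multiplicative log-normal noise;
    discordant loci are tissue-masked (expressed in 1-2 tissues while
    the host stays broad).  Host levels are mutually consistent by
    construction: junction RPM <= flanking-exon RPKM <= gene RPKM.
    """
    cfg = config or truth.config
    tissues = list(tissues or cfg.tissues)
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    rng = np.random.default_rng(cfg.seed + 2)
    loci = truth.mirtrons()
    nT = len(tissues)

    rows_j, rows_f, rows_g, rows_m, rows_truth = [], [], [], [], []
    for loc in loci:
        base = np.exp(rng.normal(cfg.expression_log_mean,
                                 cfg.expression_log_sigma, size=nT))
        junction = base
        flank = junction * rng.uniform(1.0, 2.0, size=nT)
        gene = flank * rng.uniform(1.0, 1.5, size=nT)
        scale = np.exp(rng.normal(0.0, 0.5))
        noise = np.exp(rng.normal(0.0, cfg.expression_noise_sigma, size=nT))
        if loc.expression_regime == "correlated":
            mirtron = scale * junction * noise
        else:
            mask = np.zeros(nT)
            k = int(rng.integers(1, 3))
            mask[rng.choice(nT, size=k, replace=False)] = 1.0
            mirtron = scale * mask * np.exp(
                rng.normal(cfg.expression_log_mean, 0.3, size=nT)
            ) * noise
        rows_j.append([loc.locus_id, *junction])
        rows_f.append([loc.locus_id, *flank])
        rows_g.append([loc.locus_id, *gene])
        rows_m.append([loc.locus_id, *mirtron])
        rows_truth.append([loc.locus_id, loc.expression_regime])

    cols = ["locus_id", *tissues]
    out = {
        "host_junction_rpm": pd.DataFrame(rows_j, columns=cols),
        "host_flank_rpkm": pd.DataFrame(rows_f, columns=cols),
        "host_gene_rpkm": pd.DataFrame(rows_g, columns=cols),
        "mirtron_rpmm": pd.DataFrame(rows_m, columns=cols),
        "expression_truth": pd.DataFrame(
            rows_truth, columns=["locus_id", "regime"]
        ),
    }
    return out


def truth_homology(truth_a: TruthSet, truth_b: TruthSet) -> dict[str, str]:
    """Ground-truth intron homology between two simulated 'species':
    planted mirtrons are paired in order within each subtype."""
    homology: dict[str, str] = {}
    for subtype in MIRTRON_SUBTYPES:
        a = [p for p in truth_a.mirtrons() if p.subtype == subtype]
        b = [p for p in truth_b.mirtrons() if p.subtype == subtype]
        for pa, pb in zip(a, b):
            homology[pa.locus_id] = pb.locus_id
    return homology


def default_manifest(
    species: str = "synthetic",
    n_total: int = 4,
    n_ago: int = 2,
    n_control: int = 1,
    n_input: int = 1,
    tissues: tuple[str, ...] | None = None,
) -> list[LibraryMeta]:
    tissues = tissues or ("brain", "heart", "liver", "kidney")
    libs = []
    spec_classes = (
        [("total", n_total), ("ago_ip", n_ago),
         ("control_ip", n_control), ("input", n_input)]
    )
    i = 0
    for lib_class, n in spec_classes:
        for k in range(n):
            libs.append(
                LibraryMeta(
                    library_id=f"{lib_class}_{k}",
                    species=species,
                    tissue=tissues[i % len(tissues)],
                    lib_class=lib_class,
                )
            )
            i += 1
    return libs


def truth_table(truth: TruthSet) -> pd.DataFrame:
    rows = []
    for p in truth.planted:
        rows.append(
            {
                "locus_id": p.locus_id,
                "subtype": p.subtype,
                "chrom": p.chrom,
                "strand": p.strand,
                "hairpin_start": p.hairpin_genomic[0],
                "hairpin_end": p.hairpin_genomic[1],
                "hairpin_len": p.hairpin_len,
                "mature_arm": p.mature_arm,
                "mature_len": p.mature_len,
                "splice5_defined": p.splice5_defined,
                "splice3_defined": p.splice3_defined,
                "expression_regime": p.expression_regime,
            }
        )
    return pd.DataFrame(rows)


def write_simulation(
    outdir: str | Path,
    truth: TruthSet,
    manifest: list[LibraryMeta],
    batches: dict[str, ReadBatch],
    ledger: pd.DataFrame,
    expression: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write every simulation artifact into ``outdir``."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    write_genome_fasta(truth.genome, outdir / "genome.fa")
    write_introns_bed(truth.introns, outdir / "introns.bed")
    write_manifest(manifest, outdir / "manifest.tsv")
    for lib_id, batch in batches.items():
        write_collapsed_fasta(batch, outdir / "reads" / f"{lib_id}.fa")
    write_table(truth_table(truth), outdir / "truth" / "planted.tsv",
                sort_by=["locus_id"])
    write_table(ledger, outdir / "truth" / "ledger.tsv")
    if expression:
        for name, df in expression.items():
            write_table(df, outdir / f"{name}.tsv")
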