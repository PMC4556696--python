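"""End-to-end orchestration: simulate -> map -> annotate -> terminal
analysis -> locus features -> expression -> report.

Every stage reads only declared inputs and writes TSV outputs into the
run directory; the resolved configuration is serialized alongside for
provenance.  A single global seed fans out into named per-stage
substreams so that one stage's sampling never perturbs another's.
Runs are deterministic: same config, same bytes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirtronkit import io_formats as io
from mirtronkit import synthetic_data as synth
from mirtronkit.expression_stats import ago_enrichment, shuffle_envelope
from mirtronkit.hairpin_annotation import (
    AnnotationCriteria,
    MirtronCall,
    annotate,
    calls_table,
)
from mirtronkit.locus_features import (
    intron_length_hist,
    logo_matrix,
    LogoConfig,
    mfe_comparison,
    host_intron_count_stats,
    premirna_length_stats,
)
from mirtronkit.mapping import (
    GenomeIndex,
    MappingConfig,
    assign_to_introns,
    map_iterative,
    placements_table,
)
from mirtronkit.terminal_analysis import (
    collect_3p_tail_calls,
    end_profiles_table,
    summarize_tails,
    xu_table,
)

logger = logging.getLogger(__name__)

CONFIDENT_TIERS = ("confident_duplex", "confident_agoip", "rescue_a", "rescue_b")


@dataclass
class RunConfig:
    outdir: str
    # either simulate...
    sim: synth.SimConfig | None = None
    # ...or consume existing inputs
    genome_fa: str | None = None
    introns_bed: str | None = None
    manifest_tsv: str | None = None
    reads_dir: str | None = None
    criteria: AnnotationCriteria = field(default_factory=AnnotationCriteria)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    seed: int = 0
    unique_only: bool = False
    fold_backend: str = "proxy"


@dataclass
class RunResult:
    calls: list[MirtronCall]
    summaries: dict
    report: pd.DataFrame
    truth: synth.TruthSet | None = None


def substream(seed: int, name: str) -> int:
    """Stable per-stage sub-seed derived from the global seed."""
    import zlib

    return (seed % (2**31 - 1)) * 1000003 % (2**31) ^ (
        zlib.crc32(name.encode()) % (2**20)
    )


def run_all(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    expression = None
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=substream(config.seed, "sim"))
        truth = synth.build_truth(sim_cfg)
        manifest = synth.default_manifest()
        batches, ledger = synth.simulate_reads(truth, manifest)
        expression = synth.simulate_expression(truth)
        synth.write_simulation(outdir / "sim", truth, manifest, batches, ledger,
                               expression)
        sim_cfg.to_yaml(outdir / "sim" / "config.yaml")
        genome_fa = outdir / "sim" / "genome.fa"
        introns_bed = outdir / "sim" / "introns.bed"
        manifest_tsv = outdir / "sim" / "manifest.tsv"
        reads_dir = outdir / "sim" / "reads"
    else:
        for name in ("genome_fa", "introns_bed", "manifest_tsv", "reads_dir"):
            if getattr(config, name) is None:
                raise FileNotFoundError(f"run_all without sim requires {name}")
        genome_fa = Path(config.genome_fa)
        introns_bed = Path(config.introns_bed)
        manifest_tsv = Path(config.manifest_tsv)
        reads_dir = Path(config.reads_dir)
    for p in (genome_fa, introns_bed, manifest_tsv, reads_dir):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")

    # --- load ---
    genome = io.read_genome_fasta(genome_fa)
    introns = io.read_introns_bed(introns_bed)
    manifest = io.read_manifest(manifest_tsv)
    lib_classes = {m.library_id: m.lib_class for m in manifest}

    # --- map ---
    index = GenomeIndex(genome, config.mapping.min_len)
    aligned = []
    lib_mapped_totals: dict[str, float] = {}
    for m in manifest:
        path = Path(reads_dir) / f"{m.library_id}.fa"
        if not path.exists():
            path = Path(reads_dir) / f"{m.library_id}.fastq"
        batch = io.read_small_rna(path, m)
        al, un = map_iterative(batch, genome, config.mapping, index)
        aligned.extend(al)
        lib_mapped_totals[m.library_id] = sum(a.count for a in al)
        logger.info(
            "%s: %d species mapped, %d unmapped", m.library_id, len(al), len(un)
        )
    io.write_table(placements_table(aligned), outdir / "placements.tsv",
                   sort_by=["chrom", "start", "sequence", "library_id"])

    # --- annotate ---
    summaries = assign_to_introns(aligned, introns, lib_classes,
                                  unique_only=config.unique_only)
    calls = annotate(genome, introns, summaries, config.criteria,
                     config.fold_backend)
    io.write_table(calls_table(calls), outdir / "calls.tsv")
    confident = [c for c in calls if c.tier in CONFIDENT_TIERS]

    # --- terminal analysis ---
    io.write_table(end_profiles_table(confident), outdir / "endprofiles.tsv")
    tail_calls = []
    for c in confident:
        if c.subtype in ("conventional", "5p_tailed"):
            tail_calls.extend(collect_3p_tail_calls(c, summaries[c.locus_id]))
    tails = summarize_tails(tail_calls)
    io.write_table(tails, outdir / "tails.tsv")
    xu = xu_table(confident)
    io.write_table(xu, outdir / "xu.tsv")

    # --- locus features ---
    call_class = {c.locus_id: c.subtype for c in confident}
    lengths_by_class: dict[str, list[int]] = {"bulk": []}
    for intr in introns:
        cls = call_class.get(intr.locus_id, "bulk")
        lengths_by_class.setdefault(cls, []).append(intr.length)
    io.write_table(
        intron_length_hist(lengths_by_class).reset_index(),
        outdir / "lengths.tsv",
    )

    fivep_tailed = [c for c in confident if c.subtype == "5p_tailed"]
    logo_rows = []
    if fivep_tailed:
        seqs = [
            (c.intron.sense_sequence(genome), c.hairpin[0]) for c in fivep_tailed
        ]
        lm = logo_matrix(seqs, LogoConfig(anchor="fivep_5prime", window=30))
        lm.insert(0, "anchor", "fivep_5prime")
        logo_rows.append(lm)
        bulk_seqs = [
            (intr.sense_sequence(genome), intr.length - 65)
            for intr in introns
            if intr.locus_id not in call_class and 50 <= intr.length <= 3000
        ]
        bm = logo_matrix(bulk_seqs, LogoConfig(anchor="fivep_5prime", window=30))
        bm.insert(0, "anchor", "bulk_minus65")
        logo_rows.append(bm)
    if logo_rows:
        io.write_table(pd.concat(logo_rows), outdir / "logos.tsv")

    mfe_row = None
    if confident:
        rng = np.random.default_rng(substream(config.seed, "mfe"))
        case_seqs = [
            c.intron.sense_sequence(genome)[c.hairpin[0]: c.hairpin[1]]
            for c in confident
        ]
        pool = build_control_pool(
            [intr for intr in introns if intr.locus_id not in call_class],
            genome, [len(s) for s in case_seqs], rng,
        )
        mfe = mfe_comparison(case_seqs, pool,
                             seed=substream(config.seed, "mfe_sample"),
                             fold_backend=config.fold_backend)
        mfe_row = {
            "case_mean_per_base": float(np.mean(mfe.case_scores)),
            "control_mean_per_base": float(np.mean(mfe.control_scores)),
            "matched": mfe.matched,
            "p": mfe.test_p,
        }
        io.write_table(pd.DataFrame([mfe_row]), outdir / "mfe.tsv")

    gene_counts: dict[str, int] = {}
    mirtron_hosts = set()
    for intr in introns:
        gene_counts[intr.host_gene] = intr.host_intron_count
        if intr.locus_id in call_class:
            mirtron_hosts.add(intr.host_gene)
    counts_by_class = {
        "bulk": [n for g, n in gene_counts.items() if g not in mirtron_hosts],
        "mirtron_host": [n for g, n in gene_counts.items() if g in mirtron_hosts],
    }
    ic_stats = host_intron_count_stats(counts_by_class)
    io.write_table(
        pd.DataFrame([dataclasses.asdict(s) for s in ic_stats]),
        outdir / "introncounts.tsv",
    )

    premirna_by_class: dict[str, list[int]] = {}
    for c in confident:
        premirna_by_class.setdefault(c.subtype, []).append(c.premirna_length)
    if truth is not None:
        premirna_by_class["canonical"] = [
            p.hairpin_len for p in truth.canonical()
        ]
    premirna = premirna_length_stats(premirna_by_class)
    io.write_table(premirna, outdir / "premirna_lengths.tsv")

    # --- expression ---
    corr = None
    if expression is not None:
        mir = expression["mirtron_rpmm"].set_index("locus_id")
        host = expression["host_junction_rpm"].set_index("locus_id")
        corr = shuffle_envelope(
            mir, host, seed=substream(config.seed, "shuffle")
        )
        io.write_table(
            pd.DataFrame(
                {"locus_id": corr.pair_r.index, "pearson_r": corr.pair_r.values}
            ),
            outdir / "correlations.tsv",
        )

    rpm = locus_rpm_by_library(confident, lib_mapped_totals)
    enrich = None
    if not rpm.empty:
        group_map = {m.library_id: m.lib_class for m in manifest}
        enrich = ago_enrichment(rpm, group_map)
        io.write_table(enrich.pairwise, outdir / "agoip.tsv")

    # --- report ---
    report_rows = []

    def add(metric: str, value) -> None:
        report_rows.append({"metric": metric, "value": value})

    tier_tally: dict[tuple[str, str], int] = {}
    for c in calls:
        tier_tally[(c.subtype, c.tier)] = tier_tally.get((c.subtype, c.tier), 0) + 1
    for (subtype, tier), n in sorted(tier_tally.items()):
        add(f"calls/{subtype}/{tier}", n)
    add("calls/confident_total", len(confident))
    for _, row in tails.iterrows():
        add(f"tails/{row['category']}", round(float(row["fraction"]), 6))
    if len(xu):
        add("xu/n_loci", len(xu))
        add("xu/median_frac_xU", round(float(xu["frac_xU"].median()), 6))
    for _, row in premirna.iterrows():
        if row["n"] > 0 and np.isfinite(row["mean"]):
            add(f"premirna_mean/{row['class']}", round(float(row["mean"]), 2))
    if mfe_row is not None:
        add("mfe/case_mean_per_base", round(mfe_row["case_mean_per_base"], 4))
        add("mfe/control_mean_per_base", round(mfe_row["control_mean_per_base"], 4))
    if corr is not None:
        add("correlation/median_r", round(float(corr.pair_r.median()), 4))
        add("correlation/median_p", float(corr.median_p))
        add("correlation/inside_envelope", corr.inside_envelope)
    if enrich is not None:
        for _, row in enrich.pairwise.iterrows():
            add(
                f"agoip/p_holm/{row['group_a']}_vs_{row['group_b']}",
                float(row["p_holm"]),
            )
    report = pd.DataFrame(report_rows, columns=["metric", "value"])
    io.write_table(report, outdir / "report.tsv")
    return RunResult(calls=calls, summaries=summaries, report=report, truth=truth)


def build_control_pool(
    bulk_introns,
    genome,
    case_lengths: list[int],
    rng: np.random.Generator,
    per_intron: int = 1,
) -> list[str]:
    """Control sequences for stability comparisons: subsequences of bulk
    introns with lengths drawn from the case length list, so matching by
    100-nt bins always succeeds when the pool is large enough."""
    if not case_lengths:
        return []
    pool = []
    for intr in bulk_introns:
        seq = intr.sense_sequence(genome)
        for _ in range(per_intron):
            L = int(case_lengths[int(rng.integers(len(case_lengths)))])
            if len(seq) < L:
                continue
            off = int(rng.integers(0, len(seq) - L + 1))
            pool.append(seq[off : off + L])
    return pool


def locus_rpm_by_library(
    calls: list[MirtronCall],
    lib_totals: dict[str, float],
) -> pd.DataFrame:
    """Reads-per-million matrix (loci x libraries) from call arm buckets."""
    rows = {}
    for c in calls:
        if c.buckets is None:
            continue
        per_lib: dict[str, float] = {}
        for r in c.buckets.fivep + c.buckets.threep:
            per_lib[r.library_id] = per_lib.get(r.library_id, 0.0) + r.count * r.weight
        rows[c.locus_id] = per_lib
    df = pd.DataFrame(rows).T
    if df.empty:
        return df
    for lib, total in lib_totals.items():
        if lib not in df.columns:
            df[lib] = 0.0
    df = df.fillna(0.0)[sorted(lib_totals)]
    totals = pd.Series(lib_totals).reindex(df.columns)
    # a library with no mapped reads has no measurable abundance
    rpm = df / totals.replace(0, np.nan) * 1e6
    return rpm.fillna(0.0)
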