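"""Comparative sequence/structure/host-gene statistics for called loci.

Covers intron-length histograms, anchored nucleotide logos, hairpin
stability (energy per base) against length-matched control introns,
host-gene intron-count statistics with outlier-trimmed means, pre-miRNA
length summaries, and seed-based conservation/mimicry.

Seed definitions follow the field's standard offsets: the 7-mer seed is
mature nucleotides 2-8, the 6-mer seed nucleotides 2-7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirtronkit.hairpin_annotation import MirtronCall, fold_hairpin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# intron length histograms


def intron_length_hist(
    lengths_by_class: dict[str, list[int]],
    classes: tuple[str, ...] | None = None,
    bin_size: int = 100,
    pool_above: int = 15000,
) -> pd.DataFrame:
    """Per-class intron-length counts in fixed bins, with one pooled bin
    for everything above ``pool_above`` (species-dependent cap)."""
    if classes is None:
        classes = tuple(lengths_by_class)
    unknown = set(lengths_by_class) - set(classes)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    edges = list(range(0, pool_above + bin_size, bin_size))
    labels = [f"[{a},{a + bin_size})" for a in edges[:-1]] + [f">={pool_above}"]
    rows = {}
    for cls in classes:
        counts = np.zeros(len(labels), dtype=int)
        for l in lengths_by_class.get(cls, []):
            if l >= pool_above:
                counts[-1] += 1
            else:
                counts[l // bin_size] += 1
        rows[cls] = counts
    df = pd.DataFrame(rows, index=labels).T
    df.index.name = "class"
    return df


# ---------------------------------------------------------------------------
# anchored nucleotide logos


@dataclass(frozen=True)
class LogoConfig:
    anchor: str = "acceptor_3prime"  # fivep_5prime | threep_5prime | acceptor_3prime
    control_anchor_offset: int = -65  # from the intron 3' end, for bulk introns
    window: int = 30                  # nt on each side of the anchor

    def __post_init__(self):
        if self.window < 10:
            raise ValueError("window must be >= 10")


def logo_matrix(
    sequences_with_anchors: list[tuple[str, int]],
    cfg: LogoConfig = LogoConfig(),
) -> pd.DataFrame:
    """Position x {A,C,G,U} frequency matrix around per-sequence anchors.

    Out-of-range positions are skipped per sequence, so column
    denominators vary; every covered column sums to 1 and carries an
    explicit coverage count.  Zero-coverage columns are flagged with
    coverage 0 and NaN frequencies (never silently propagated).
    """
    positions = range(-cfg.window, cfg.window + 1)
    counts = {p: {"A": 0, "C": 0, "G": 0, "U": 0} for p in positions}
    coverage = {p: 0 for p in positions}
    for seq, anchor in sequences_with_anchors:
        seq = seq.upper().replace("T", "U")
        for p in positions:
            i = anchor + p
            if 0 <= i < len(seq) and seq[i] in "ACGU":
                counts[p][seq[i]] += 1
                coverage[p] += 1
    rows = []
    for p in positions:
        cov = coverage[p]
        row = {"position": p, "coverage": cov}
        for nt in "ACGU":
            row[nt] = counts[p][nt] / cov if cov else float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["position", "coverage", "A", "C", "G", "U"])


# ---------------------------------------------------------------------------
# energy-per-base comparison with length-matched controls


@dataclass
class MfeComparison:
    case_scores: np.ndarray       # energy per base, one per case sequence
    control_scores: np.ndarray
    matched: bool
    test_p: float
    mean_difference: float        # case mean - control mean


def sample_length_matched(
    case_lengths: list[int],
    pool_lengths: list[int],
    rng: np.random.Generator,
    bin_size: int = 100,
) -> list[int]:
    """Indices into the pool matching the case length distribution in
    ``bin_size`` bins, sampled without replacement.  Bins short of pool
    take everything available (deficit logged)."""
    pool_bins: dict[int, list[int]] = {}
    for i, l in enumerate(pool_lengths):
        pool_bins.setdefault(l // bin_size, []).append(i)
    need: dict[int, int] = {}
    for l in case_lengths:
        need[l // bin_size] = need.get(l // bin_size, 0) + 1
    chosen: list[int] = []
    for b in sorted(need):
        avail = pool_bins.get(b, [])
        k = need[b]
        if len(avail) < k:
            logger.warning(
                "length bin %d: need %d controls, pool has %d", b, k, len(avail)
            )
            chosen.extend(avail)
        else:
            chosen.extend(rng.choice(avail, size=k, replace=False).tolist())
    return sorted(chosen)


def mfe_comparison(
    case_seqs: list[str],
    control_pool: list[str],
    seed: int = 0,
    fold_backend: str = "proxy",
    bin_size: int = 100,
) -> MfeComparison:
    """Energy-per-base of case hairpins vs length-matched control
    sequences, with a two-sample t-test on the means.

    If the control pool is smaller than the case set the whole pool is
    used unmatched (``matched=False``).
    """
    rng = np.random.default_rng(seed)
    pool = [s for s in control_pool if 30 <= len(s) <= 1000]
    case_seqs = [s for s in case_seqs if len(s) >= 30]
    if len(pool) < len(case_seqs):
        controls = pool
        matched = False
    else:
        idx = sample_length_matched(
            [len(s) for s in case_seqs], [len(s) for s in pool], rng, bin_size
        )
        controls = [pool[i] for i in idx]
        matched = True

    def per_base(seqs: list[str]) -> np.ndarray:
        return np.array(
            [fold_hairpin(s, backend=fold_backend).energy_score / len(s) for s in seqs]
        )

    case_scores = per_base(case_seqs)
    control_scores = per_base(controls)
    if len(case_scores) and len(control_scores):
        t = stats.ttest_ind(case_scores, control_scores, equal_var=False)
        p = float(t.pvalue)
    else:
        p = float("nan")
    return MfeComparison(
        case_scores=case_scores,
        control_scores=control_scores,
        matched=matched,
        test_p=p,
        mean_difference=float(case_scores.mean() - control_scores.mean())
        if len(case_scores) and len(control_scores)
        else float("nan"),
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide composition (Eulerian-path
    method: shuffle the outgoing-edge lists, fixing a final edge per
    vertex to reach the terminal, then walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick, for each vertex except the terminal, a final edge lying on a
    # path to the terminal (sampling until the chosen final edges form a
    # tree into `last`, per Altschul-Erikson)
    vertices = list(edges)
    for _ in range(1000):
        finals = {}
        for v in vertices:
            if v == last and not edges[v]:
                continue
            finals[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = finals.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:
        return seq  # degenerate composition; give up gracefully
    out_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v in finals:
            rest.remove(finals[v])
        rng.shuffle(rest)
        if v in finals and v != last:
            rest.append(finals[v])
        elif v in finals:
            rest.append(finals[v])
        out_edges[v] = rest[::-1]  # pop() from the end = walk order
    walk = [seq[0]]
    cur = seq[0]
    while out_edges.get(cur):
        cur = out_edges[cur].pop()
        walk.append(cur)
    res = "".join(walk)
    return res if len(res) == len(seq) else seq


# ---------------------------------------------------------------------------
# host-gene intron counts


@dataclass
class IntronCountStats:
    label: str
    n_genes: int
    trimmed_mean: float
    untrimmed_mean: float
    ranksum_p_vs_bulk: float | None
    low_n: bool


def trimmed_mean(values: list[int] | np.ndarray, trim_frac: float = 0.02) -> float:
    """Mean after removing the top ``trim_frac`` fraction of values."""
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(len(v) * trim_frac))
    return float(v[: len(v) - k].mean()) if len(v) else float("nan")


def host_intron_count_stats(
    counts_by_class: dict[str, list[int]],
    bulk_label: str = "bulk",
    trim_frac: float = 0.02,
) -> list[IntronCountStats]:
    """Outlier-trimmed mean intron counts per class, with a Wilcoxon
    rank-sum test against bulk genes."""
    if bulk_label not in counts_by_class:
        raise ValueError(f"counts_by_class must include {bulk_label!r}")
    bulk = np.asarray(counts_by_class[bulk_label], dtype=float)
    out = []
    for label, counts in counts_by_class.items():
        arr = np.asarray(counts, dtype=float)
        if label == bulk_label or len(arr) == 0:
            p = None
        else:
            p = float(stats.mannwhitneyu(arr, bulk, alternative="two-sided").pvalue)
        out.append(
            IntronCountStats(
                label=label,
                n_genes=len(arr),
                trimmed_mean=trimmed_mean(arr, trim_frac),
                untrimmed_mean=float(arr.mean()) if len(arr) else float("nan"),
                ranksum_p_vs_bulk=p,
                low_n=len(arr) < 3,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pre-miRNA lengths


def premirna_length_stats(
    lengths_by_class: dict[str, list[int]],
    canonical_label: str = "canonical",
) -> pd.DataFrame:
    """Mean/SD of hairpin length per class with a two-sided Mann-Whitney
    test against the canonical class."""
    canonical = np.asarray(lengths_by_class.get(canonical_label, []), dtype=float)
    rows = []
    for label, lengths in lengths_by_class.items():
        arr = np.asarray(lengths, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        if label == canonical_label or len(arr) == 0 or len(canonical) == 0:
            p = float("nan")
        else:
            p = float(
                stats.mannwhitneyu(arr, canonical, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "class": label,
                "n": len(arr),
                "mean": float(arr.mean()) if len(arr) else float("nan"),
                "sd": sd,
                "p_vs_canonical": p,
                "low_n": len(arr) < 2,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n", "mean", "sd", "p_vs_canonical", "low_n"])


# ---------------------------------------------------------------------------
# seeds


def _mature_sequence(call: MirtronCall) -> str:
    return call.fivep_seq if call.mature_arm == "5p" else call.threep_seq


def seed7(mature: str) -> str:
    return mature[1:8]


def seed6(mature: str) -> str:
    return mature[1:7]


def seed_conservation(
    calls_a: list[MirtronCall],
    calls_b: list[MirtronCall],
    intron_homology: dict[str, str],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Cross-species conservation of mirtron seeds.

    A pair is sequence-and-position conserved iff the introns are
    homologous AND the 7-mer seeds (mature nt 2-8) are identical;
    homologous pairs with differing seeds are positional-only.
    Returns (conserved_pairs, positional_only_pairs).
    """
    by_id_b = {c.locus_id: c for c in calls_b}
    conserved, positional = [], []
    for ca in calls_a:
        partner = intron_homology.get(ca.locus_id)
        if partner is None or partner not in by_id_b:
            continue
        cb = by_id_b[partner]
        ma, mb = _mature_sequence(ca), _mature_sequence(cb)
        if len(ma) >= 8 and len(mb) >= 8 and seed7(ma) == seed7(mb):
            conserved.append((ca.locus_id, cb.locus_id))
        else:
            positional.append((ca.locus_id, cb.locus_id))
    return conserved, positional


def seed_mimics(
    calls: list[MirtronCall],
    reference_seeds: dict[str, str],
) -> pd.DataFrame:
    """Mirtrons whose 6-mer seed (mature nt 2-7) equals a reference
    miRNA seed.  Mature species shorter than 8 nt are skipped."""
    rows = []
    for call in calls:
        mature = _mature_sequence(call).replace("U", "T")
        if len(mature) < 8:
            rows.append(
                {"locus_id": call.locus_id, "reference_id": "", "seed": "",
                 "skipped_short": True}
            )
            continue
        s = seed6(mature)
        for ref_id, ref_seed in sorted(reference_seeds.items()):
            if ref_seed.upper().replace("U", "T") == s:
                rows.append(
                    {"locus_id": call.locus_id, "reference_id": ref_id,
                     "seed": s, "skipped_short": False}
                )
    return pd.DataFrame(
        rows, columns=["locus_id", "reference_id", "seed", "skipped_short"]
    )
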