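"""Hairpin folding, duplex-geometry inference, and tiered mirtron calling.

The annotation logic reconstructs, per intron, the pre-miRNA hairpin
implied by the small-RNA read stacks: the hairpin 5' end is the dominant
5p read start (snapped to the splice donor when within tolerance), the
3' end the dominant 3p templated end (snapped to the acceptor likewise).
Subtype follows from which hairpin ends abut splice sites; confidence
follows from read-depth criteria:

* ``confident_duplex`` — >= 50 total duplex reads (mature + star) with
  >= 5 star-strand reads and acceptable dicing geometry;
* ``confident_agoip`` — >= 100 mature-arm reads of which >= 20 from
  Ago-IP libraries;
* ``rescue_a`` — <= 3 star reads but >= 20 Ago-IP reads;
* ``rescue_b`` — 3-4 star reads with >= 10 Ago-IP reads and >= 100
  total reads;
* ``candidate`` — >= 10 total reads, insufficient for the above;
* ``rejected`` — everything else.

Tiers are evaluated in that order; the first match wins.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirtronkit.io_formats import Genome, IntronRecord
from mirtronkit.mapping import LocusReadSummary, PlacedRead

logger = logging.getLogger(__name__)

SUBTYPES = ("conventional", "5p_tailed", "3p_tailed", "two_tailed")
TIERS = (
    "confident_duplex",
    "confident_agoip",
    "rescue_a",
    "rescue_b",
    "candidate",
    "rejected",
)

# Evidence for mirtron calling: the control IP is a negative control and
# never contributes.
EVIDENCE_CLASSES = frozenset({"total", "ago_ip", "input"})

MIN_FOLD_LEN = 20
MAX_FOLD_LEN = 1000
MIN_HAIRPIN_LOOP = 3
HAIRPIN_LOOP_PENALTY = 4.0
_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


@dataclass
class HairpinFold:
    sequence: str
    pair_table: list[int]  # partner index, or -1 if unpaired
    energy_score: float
    loop_interval: tuple[int, int] | None

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table) if j > i)


def _fold_proxy(seq: str) -> HairpinFold:
    """Weighted base-pair-maximization scorer with a helix-opening
    penalty: G:C=-3, A:U=-2, G:U=-1; +4 charged once per helix (a
    maximal run of stacked pairs), which covers the +4 hairpin-loop
    charge for the innermost helix and penalizes isolated pairs so that
    random sequence does not score as structured.  Minimum hairpin loop
    size 3; deterministic tie-breaking (leftmost pairing wins)."""
    n = len(seq)
    INF = math.inf
    e = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + 1, n):
            v = _PAIR_ENERGY.get((seq[i], seq[j]))
            if v is not None:
                e[i, j] = v

    # W[i][j]: best energy of [i..j], empty structure allowed (<= 0).
    # WP[i][j]: best energy of [i..j] with at least one pair.
    # V[i][j]: best energy of [i..j] with (i,j) paired.
    W = np.zeros((n + 2, n + 2))
    WP = np.full((n + 1, n + 1), INF)
    V = np.full((n + 1, n + 1), INF)
    for d in range(MIN_HAIRPIN_LOOP + 1, n):  # span length j - i
        for i in range(n - d):
            j = i + d
            if e[i, j] < INF:
                # (i, j) either stacks on (i+1, j-1) for free, closes a
                # hairpin loop (+4: this helix's charge), or opens a new
                # helix over an inner structure (+4)
                inner = HAIRPIN_LOOP_PENALTY
                if V[i + 1, j - 1] < inner:
                    inner = V[i + 1, j - 1]
                if (
                    j - i - 1 > MIN_HAIRPIN_LOOP
                    and WP[i + 1, j - 1] + HAIRPIN_LOOP_PENALTY < inner
                ):
                    inner = WP[i + 1, j - 1] + HAIRPIN_LOOP_PENALTY
                V[i, j] = e[i, j] + inner
            best = WP[i + 1, j]
            lo = i + MIN_HAIRPIN_LOOP + 1
            if lo <= j:
                cand = V[i, lo : j + 1] + W[lo + 1 : j + 2, j]
                m = cand.min()
                if m < best:
                    best = m
            WP[i, j] = best
            W[i, j] = min(0.0, best)

    pair = [-1] * n

    def trace_W(i: int, j: int) -> None:
        if i >= j or W[i, j] >= 0.0:
            return
        trace_WP(i, j)

    def trace_WP(i: int, j: int) -> None:
        while i < j:
            lo = i + MIN_HAIRPIN_LOOP + 1
            hit = False
            for l in range(lo, j + 1):
                if V[i, l] < INF and abs(V[i, l] + W[l + 1, j] - WP[i, j]) < 1e-9:
                    trace_V(i, l)
                    trace_W(l + 1, j)
                    hit = True
                    break
            if hit:
                return
            i += 1  # i unpaired

    def trace_V(i: int, j: int) -> None:
        # iterative along the stacked helix to bound recursion depth
        while True:
            pair[i], pair[j] = j, i
            target = V[i, j] - e[i, j]
            if V[i + 1, j - 1] < INF and abs(target - V[i + 1, j - 1]) < 1e-9:
                i, j = i + 1, j - 1  # stacked pair
                continue
            if (
                WP[i + 1, j - 1] < INF
                and abs(target - (WP[i + 1, j - 1] + HAIRPIN_LOOP_PENALTY)) < 1e-9
            ):
                trace_WP(i + 1, j - 1)  # new helix (or helices) inside
            # else: hairpin loop, nothing inside
            return

    score = min(0.0, WP[0, n - 1]) if n > 1 else 0.0
    if score < 0.0:
        trace_WP(0, n - 1)
    return HairpinFold(
        sequence=seq,
        pair_table=pair,
        energy_score=float(score),
        loop_interval=_loop_interval(pair),
    )


def _loop_interval(pair: list[int]) -> tuple[int, int] | None:
    """Innermost unpaired interval enclosed by the outermost helix."""
    best = None
    for i, j in enumerate(pair):
        if j > i and all(p == -1 for p in pair[i + 1 : j]):
            iv = (i + 1, j)
            if best is None or (iv[1] - iv[0]) > (best[1] - best[0]):
                best = iv
    return best


def _fold_rnafold(seq: str) -> HairpinFold:
    """Thermodynamic backend via the RNAfold executable, if installed."""
    rna = seq.replace("T", "U")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True,
        check=True,
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split()[0]
    energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    pair = [-1] * len(seq)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pair[i], pair[j] = j, i
    return HairpinFold(seq, pair, energy, _loop_interval(pair))


def fold_hairpin(seq: str, backend: str = "proxy") -> HairpinFold:
    """Predict a nested secondary structure and an energy-like score.

    ``backend='proxy'`` (default) uses the deterministic built-in
    weighted base-pair-maximization scorer; ``backend='rnafold'``
    shells out to RNAfold when available.  Lower scores mean more
    stable structures under both backends.
    """
    seq = seq.upper().replace("U", "T")
    if not MIN_FOLD_LEN <= len(seq) <= MAX_FOLD_LEN:
        raise ValueError(
            f"sequence length {len(seq)} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]"
        )
    if backend == "proxy":
        return _fold_proxy(seq)
    if backend == "rnafold":
        if shutil.which("RNAfold") is None:
            raise RuntimeError("RNAfold executable not found on PATH")
        return _fold_rnafold(seq)
    raise ValueError(f"unknown fold backend {backend!r}")


@dataclass(frozen=True)
class AnnotationCriteria:
    """Read-evidence and geometry thresholds for mirtron calling."""

    min_duplex_reads: int = 50
    min_star_reads: int = 5
    ago_rescue_min_mature: int = 100
    ago_rescue_min_agoip: int = 20
    rescue_a_max_star: int = 3
    rescue_a_min_agoip: int = 20
    rescue_b_star_range: tuple[int, int] = (3, 4)
    rescue_b_min_agoip: int = 10
    rescue_b_min_total: int = 100
    min_candidate_total: int = 10
    min_overhang: int = -1
    max_overhang: int = 4
    min_duplex_pairs: int = 12
    splice_tolerance: int = 1
    two_tailed_min_offset: int = 5
    arm_end_tolerance: int = 3


@dataclass
class DuplexGeometry:
    fivep_interval: tuple[int, int]  # sense coords within the intron
    threep_interval: tuple[int, int]
    overhang_dicer_end: int | None
    overhang_open_end: int | None
    n_duplex_pairs: int = 0


@dataclass
class ArmBuckets:
    """Reads bucketed relative to an inferred hairpin extent (sense coords)."""

    hairpin: tuple[int, int]
    fivep_interval: tuple[int, int]
    threep_interval: tuple[int, int]
    fivep: list[PlacedRead] = field(default_factory=list)
    threep: list[PlacedRead] = field(default_factory=list)
    loop: list[PlacedRead] = field(default_factory=list)
    other: list[PlacedRead] = field(default_factory=list)

    def weighted(self, reads: list[PlacedRead], lib_class: str | None = None) -> float:
        return sum(
            r.count * r.weight
            for r in reads
            if lib_class is None or r.lib_class == lib_class
        )


@dataclass
class MirtronCall:
    locus_id: str
    intron: IntronRecord
    subtype: str
    ambiguous_subtype: bool
    hairpin: tuple[int, int]  # sense coords within the intron
    hairpin_genomic: tuple[int, int]
    premirna_length: int
    duplex: DuplexGeometry | None
    dicing_ok: bool
    dicing_reason: str
    tier: str
    n_mature: float
    n_star: float
    n_loop: float
    n_ago_ip: float
    n_total: float
    mature_arm: str  # '5p' or '3p'
    fivep_seq: str
    threep_seq: str
    buckets: ArmBuckets | None = None


def _stack_key(r: PlacedRead) -> tuple[int, int]:
    return (r.sense_start, r.sense_end)


def define_hairpin_extent(
    intron: IntronRecord,
    summary: LocusReadSummary,
    criteria: AnnotationCriteria = AnnotationCriteria(),
) -> ArmBuckets | None:
    """Infer the hairpin interval from read stacks and bucket the reads.

    The dominant read stack and the dominant non-overlapping stack define
    the two arms; ends are snapped to splice sites within
    ``splice_tolerance``.  Returns None when fewer than two distinct,
    non-overlapping stacks exist (no duplex can be formed).
    """
    reads = [r for r in summary.reads if r.lib_class in EVIDENCE_CLASSES]
    stacks: dict[tuple[int, int], float] = {}
    for r in reads:
        stacks[_stack_key(r)] = stacks.get(_stack_key(r), 0.0) + r.count * r.weight
    if len(stacks) < 2:
        return None

    # Dominant stack; ties broken toward the lower coordinate.
    d1 = min(stacks, key=lambda k: (-stacks[k], k))

    def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    partners = {
        k: v
        for k, v in stacks.items()
        if overlap(k, d1) < 0.5 * min(k[1] - k[0], d1[1] - d1[0])
    }
    if not partners:
        return None
    d2 = min(partners, key=lambda k: (-partners[k], k))

    fivep_iv, threep_iv = sorted([d1, d2])
    L = intron.length
    h5 = 0 if fivep_iv[0] <= criteria.splice_tolerance else fivep_iv[0]
    h3 = L if L - threep_iv[1] <= criteria.splice_tolerance else threep_iv[1]

    buckets = ArmBuckets(
        hairpin=(h5, h3), fivep_interval=fivep_iv, threep_interval=threep_iv
    )
    tol = criteria.arm_end_tolerance
    for r in summary.reads:
        if abs(r.sense_start - h5) <= tol and r.sense_start < threep_iv[0]:
            buckets.fivep.append(r)
        elif abs(r.sense_end - h3) <= tol and r.sense_end > fivep_iv[1]:
            buckets.threep.append(r)
        elif r.sense_start >= fivep_iv[1] and r.sense_end <= threep_iv[0]:
            buckets.loop.append(r)
        else:
            buckets.other.append(r)
    return buckets


def classify_subtype(
    intron: IntronRecord,
    hairpin: tuple[int, int],
    criteria: AnnotationCriteria = AnnotationCriteria(),
) -> tuple[str, bool]:
    """Classify biogenesis subtype from hairpin-to-splice-site offsets.

    Returns (subtype, ambiguous_flag).  Offsets in the open band between
    ``splice_tolerance`` and ``two_tailed_min_offset`` are resolved to
    the nearest status and flagged ambiguous.
    """
    h5, h3 = hairpin
    if not (0 <= h5 < h3 <= intron.length):
        raise ValueError("hairpin interval must lie within the intron")
    d5 = h5
    d3 = intron.length - h3

    def status(d: int) -> tuple[str, bool]:
        if d <= criteria.splice_tolerance:
            return "abut", False
        if d >= criteria.two_tailed_min_offset:
            return "free", False
        near_abut = (d - criteria.splice_tolerance) <= (
            criteria.two_tailed_min_offset - d
        )
        return ("abut" if near_abut else "free"), True

    s5, a5 = status(d5)
    s3, a3 = status(d3)
    table = {
        ("abut", "abut"): "conventional",
        ("free", "abut"): "5p_tailed",
        ("abut", "free"): "3p_tailed",
        ("free", "free"): "two_tailed",
    }
    return table[(s5, s3)], (a5 or a3)


def assess_duplex(
    fold: HairpinFold,
    buckets: ArmBuckets,
    criteria: AnnotationCriteria = AnnotationCriteria(),
) -> tuple[DuplexGeometry, bool, str]:
    """Pair the dominant 5p/3p species through the fold and measure both
    duplex-end 3' overhangs (positive = 3' overhang).

    The "open" end pairs the 5p 5' terminus with the 3p 3' terminus (the
    hairpin base); the "Dicer" end pairs the 5p 3' terminus with the 3p
    5' terminus (loop side).  Each arm-arm base pair implies an overhang
    through the duplex register; the reported overhang is the median
    over all pairs, which is exact for a clean duplex and robust to
    local slippage of the predicted structure around mismatches.
    ``dicing_ok`` requires both overhangs within the acceptance window
    and >= ``min_duplex_pairs`` base pairs between the arms.
    """
    h5 = buckets.hairpin[0]
    a5, b5 = (x - h5 for x in buckets.fivep_interval)
    a3, b3 = (x - h5 for x in buckets.threep_interval)
    pair = fold.pair_table
    n = len(pair)
    a5 = max(0, a5)
    b3 = min(n, b3)

    duplex_pairs = [
        (i, pair[i])
        for i in range(a5, min(b5, n))
        if a3 <= pair[i] < b3
    ]
    n_pairs = len(duplex_pairs)

    if duplex_pairs:
        d_open = [(b3 - 1 - j) - (i - a5) for i, j in duplex_pairs]
        d_dicer = [(b5 - 1 - i) - (j - a3) for i, j in duplex_pairs]
        overhang_open = int(math.floor(float(np.median(d_open)) + 0.5))
        overhang_dicer = int(math.floor(float(np.median(d_dicer)) + 0.5))
    else:
        overhang_open = overhang_dicer = None

    geom = DuplexGeometry(
        fivep_interval=buckets.fivep_interval,
        threep_interval=buckets.threep_interval,
        overhang_dicer_end=overhang_dicer,
        overhang_open_end=overhang_open,
        n_duplex_pairs=n_pairs,
    )
    if n_pairs < criteria.min_duplex_pairs:
        return geom, False, "arms_not_paired_in_stem"
    if overhang_open is None or overhang_dicer is None:
        return geom, False, "terminal_pairing_undetermined"
    for oh in (overhang_open, overhang_dicer):
        if not criteria.min_overhang <= oh <= criteria.max_overhang:
            return geom, False, "overhang_outside_window"
    return geom, True, "ok"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def apply_criteria(
    n_mature: float,
    n_star: float,
    n_ago_ip: float,
    n_total: float,
    dicing_ok: bool,
    criteria: AnnotationCriteria = AnnotationCriteria(),
) -> str:
    """Assign a confidence tier from weighted evidence counts.

    Counts are rounded half-up before threshold comparison.  Tier order:
    confident_duplex, confident_agoip, rescue_a, rescue_b, candidate,
    rejected; the first satisfied tier wins.
    """
    for v in (n_mature, n_star, n_ago_ip, n_total):
        if v < 0:
            raise ValueError("evidence counts must be non-negative")
    mature = _round_half_up(n_mature)
    star = _round_half_up(n_star)
    ago = _round_half_up(n_ago_ip)
    total = _round_half_up(n_total)
    duplex = mature + star

    c = criteria
    if dicing_ok and duplex >= c.min_duplex_reads and star >= c.min_star_reads:
        return "confident_duplex"
    if dicing_ok and mature >= c.ago_rescue_min_mature and ago >= c.ago_rescue_min_agoip:
        return "confident_agoip"
    if dicing_ok and star <= c.rescue_a_max_star and ago >= c.rescue_a_min_agoip:
        return "rescue_a"
    lo, hi = c.rescue_b_star_range
    if (
        dicing_ok
        and lo <= star <= hi
        and ago >= c.rescue_b_min_agoip
        and total >= c.rescue_b_min_total
    ):
        return "rescue_b"
    if total >= c.min_candidate_total:
        return "candidate"
    return "rejected"


def annotate_locus(
    intron: IntronRecord,
    summary: LocusReadSummary,
    genome: Genome,
    criteria: AnnotationCriteria = AnnotationCriteria(),
    fold_backend: str = "proxy",
) -> MirtronCall | None:
    """Run extent inference, folding, duplex assessment, and tiering on
    one intron.  Returns None when no duplex can be formed."""
    buckets = define_hairpin_extent(intron, summary, criteria)
    if buckets is None:
        return None
    h5, h3 = buckets.hairpin
    subtype, ambiguous = classify_subtype(intron, (h5, h3), criteria)

    w5 = buckets.weighted(
        [r for r in buckets.fivep if r.lib_class in EVIDENCE_CLASSES]
    )
    w3 = buckets.weighted(
        [r for r in buckets.threep if r.lib_class in EVIDENCE_CLASSES]
    )
    mature_arm = "5p" if w5 >= w3 else "3p"
    n_mature, n_star = (w5, w3) if mature_arm == "5p" else (w3, w5)
    mature_reads = buckets.fivep if mature_arm == "5p" else buckets.threep
    n_ago = buckets.weighted(mature_reads, "ago_ip")
    n_loop = buckets.weighted(
        [r for r in buckets.loop if r.lib_class in EVIDENCE_CLASSES]
    )
    n_other = buckets.weighted(
        [r for r in buckets.other if r.lib_class in EVIDENCE_CLASSES]
    )
    n_total = n_mature + n_star + n_loop + n_other

    sense = intron.sense_sequence(genome)
    hp_seq = sense[h5:h3]
    # Folding only changes the outcome for loci whose evidence could reach
    # a dicing-gated tier; low-evidence loci resolve to candidate/rejected
    # either way, so skip the (costly) fold for them.
    ceiling = apply_criteria(n_mature, n_star, n_ago, n_total, True, criteria)
    if ceiling in ("candidate", "rejected"):
        geom, dicing_ok, reason = None, False, "not_folded_low_evidence"
    elif MIN_FOLD_LEN <= len(hp_seq) <= MAX_FOLD_LEN:
        fold = fold_hairpin(hp_seq, backend=fold_backend)
        geom, dicing_ok, reason = assess_duplex(fold, buckets, criteria)
    else:
        geom, dicing_ok, reason = None, False, "hairpin_length_out_of_bounds"

    tier = apply_criteria(n_mature, n_star, n_ago, n_total, dicing_ok, criteria)

    if intron.strand == "+":
        hp_genomic = (intron.start + h5, intron.start + h3)
    else:
        hp_genomic = (intron.end - h3, intron.end - h5)

    return MirtronCall(
        locus_id=intron.locus_id,
        intron=intron,
        subtype=subtype,
        ambiguous_subtype=ambiguous,
        hairpin=(h5, h3),
        hairpin_genomic=hp_genomic,
        premirna_length=h3 - h5,
        duplex=geom,
        dicing_ok=dicing_ok,
        dicing_reason=reason,
        tier=tier,
        n_mature=n_mature,
        n_star=n_star,
        n_loop=n_loop,
        n_ago_ip=n_ago,
        n_total=n_total,
        mature_arm=mature_arm,
        fivep_seq=sense[buckets.fivep_interval[0] : buckets.fivep_interval[1]],
        threep_seq=sense[buckets.threep_interval[0] : buckets.threep_interval[1]],
        buckets=buckets,
    )


def annotate(
    genome: Genome,
    introns: list[IntronRecord],
    summaries: dict[str, LocusReadSummary],
    criteria: AnnotationCriteria = AnnotationCriteria(),
    fold_backend: str = "proxy",
) -> list[MirtronCall]:
    """Annotate every intron with at least two distinct read stacks.

    A failure on one locus never aborts the run; the locus is logged and
    skipped.  Output order is deterministic (chrom, start).
    """
    calls = []
    for intron in sorted(introns, key=lambda r: (r.chrom, r.start, r.end)):
        summary = summaries.get(intron.locus_id)
        if summary is None or summary.n_distinct_stacks < 2:
            continue
        try:
            call = annotate_locus(intron, summary, genome, criteria, fold_backend)
        except Exception:
            logger.exception("locus %s errored during annotation", intron.locus_id)
            continue
        if call is not None:
            calls.append(call)
    tally: dict[tuple[str, str], int] = {}
    for c in calls:
        tally[(c.subtype, c.tier)] = tally.get((c.subtype, c.tier), 0) + 1
    for (subtype, tier), n in sorted(tally.items()):
        logger.info("annotate: %s / %s: %d loci", subtype, tier, n)
    return calls


def calls_table(calls: list[MirtronCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "chrom": c.intron.chrom,
                "strand": c.intron.strand,
                "subtype": c.subtype,
                "ambiguous_subtype": c.ambiguous_subtype,
                "tier": c.tier,
                "hairpin_start": c.hairpin_genomic[0],
                "hairpin_end": c.hairpin_genomic[1],
                "premirna_length": c.premirna_length,
                "n_mature": round(c.n_mature, 3),
                "n_star": round(c.n_star, 3),
                "n_loop": round(c.n_loop, 3),
                "n_ago_ip": round(c.n_ago_ip, 3),
                "n_total": round(c.n_total, 3),
                "mature_arm": c.mature_arm,
                "overhang_open": "" if c.duplex is None else c.duplex.overhang_open_end,
                "overhang_dicer": "" if c.duplex is None else c.duplex.overhang_dicer_end,
                "dicing_ok": c.dicing_ok,
                "fivep_seq": c.fivep_seq,
                "threep_seq": c.threep_seq,
            }
        )
    cols = [
        "locus_id", "chrom", "strand", "subtype", "ambiguous_subtype", "tier",
        "hairpin_start", "hairpin_end", "premirna_length",
        "n_mature", "n_star", "n_loop", "n_ago_ip", "n_total", "mature_arm",
        "overhang_open", "overhang_dicer", "dicing_ok", "fivep_seq", "threep_seq",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("locus_id", kind="mergesort").reset_index(drop=True)
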