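"""Terminal heterogeneity, untemplated 3' additions, and 5'-G decapitation.

The splice acceptor provides an external reference for the primary-
processed 3p species of conventional and 5'-tailed mirtrons: any read
nucleotides 3' of the acceptor AG are called untemplated regardless of
whether they happen to match the downstream genomic sequence (splice-
anchored calling).  Termini that are not splice-defined are referenced
to the modal templated read end instead.

5'-G decapitation ("xU"): splice-defined 5p species begin at the donor
G; reads starting exactly one nucleotide inside (on the donor U) are
guanine-decapitated.  Locus-level xU fractions are reported only for
loci with at least ``min_reads`` 5p reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from mirtronkit.hairpin_annotation import MirtronCall
from mirtronkit.mapping import LocusReadSummary, PlacedRead

OFFSET_WINDOW = 5  # offsets outside [-5, +5] pool into the edge bins

TAIL_CATEGORIES = (
    "none", "monoU", "diU", "multiU", "monoA", "diA", "mixed", "other",
)

# which (arm, terminus) is defined by a splice site, per subtype
_SPLICE_DEFINED = {
    ("conventional", "5p", "5prime"): "splice_donor",
    ("conventional", "3p", "3prime"): "splice_acceptor",
    ("3p_tailed", "5p", "5prime"): "splice_donor",
    ("5p_tailed", "3p", "3prime"): "splice_acceptor",
}


@dataclass
class EndProfile:
    locus_id: str
    arm: str              # '5p' | '3p'
    terminus: str         # '5prime' | '3prime'
    reference: int        # sense coordinate within the intron
    provenance: str       # splice_donor | splice_acceptor | dominant_read
    offset_histogram: dict[int, float] = field(default_factory=dict)
    n_reads: float = 0.0


@dataclass
class TailCall:
    sequence: str
    templated_end: int    # sense coordinate of the templated 3' end
    tail_seq: str
    tail_category: str
    count: int
    weight: float
    library_id: str


@dataclass
class XuSummary:
    locus_id: str
    n_5p_reads: float
    frac_GU: float
    frac_xU: float
    frac_other: float
    min_reads: int = 10


def _arm_reads(call: MirtronCall, arm: str) -> list[PlacedRead]:
    if call.buckets is None:
        raise ValueError("call carries no read buckets")
    return call.buckets.fivep if arm == "5p" else call.buckets.threep


def end_offset_profile(
    call: MirtronCall, arm: str, terminus: str
) -> EndProfile | None:
    """Read-weighted histogram of terminal offsets against the reference.

    Negative offsets are upstream (lower sense coordinate) of the
    reference; mass outside the +/-5 window pools into the edge bins.
    Untemplated suffixes never contribute to 3' offsets because offsets
    are computed on templated ends.  Returns None for an empty arm.
    """
    if arm not in ("5p", "3p") or terminus not in ("5prime", "3prime"):
        raise ValueError("arm must be 5p/3p and terminus 5prime/3prime")
    reads = _arm_reads(call, arm)
    if not reads:
        return None
    provenance = _SPLICE_DEFINED.get((call.subtype, arm, terminus))
    ends = [
        (r.sense_start if terminus == "5prime" else r.sense_end, r.count * r.weight)
        for r in reads
    ]
    if provenance == "splice_donor":
        ref = 0
    elif provenance == "splice_acceptor":
        ref = call.intron.length
    else:
        provenance = "dominant_read"
        totals: dict[int, float] = {}
        for pos, w in ends:
            totals[pos] = totals.get(pos, 0.0) + w
        ref = min(totals, key=lambda p: (-totals[p], p))
    hist: dict[int, float] = {}
    total = 0.0
    for pos, w in ends:
        off = max(-OFFSET_WINDOW, min(OFFSET_WINDOW, pos - ref))
        hist[off] = hist.get(off, 0.0) + w
        total += w
    hist = {k: v / total for k, v in sorted(hist.items())}
    return EndProfile(
        locus_id=call.locus_id,
        arm=arm,
        terminus=terminus,
        reference=ref,
        provenance=provenance,
        offset_histogram=hist,
        n_reads=total,
    )


def categorize_tail(tail_seq: str) -> str:
    if not tail_seq:
        return "none"
    letters = set(tail_seq)
    if letters == {"T"}:
        return {1: "monoU", 2: "diU"}.get(len(tail_seq), "multiU")
    if letters == {"A"}:
        return {1: "monoA", 2: "diA"}.get(len(tail_seq), "other")
    if letters <= {"T", "A"}:
        return "mixed"
    return "other"


def call_untemplated_tail(
    read: PlacedRead, reference_end: int, anchored: bool
) -> TailCall:
    """Call the untemplated 3' extension of one read.

    When anchored (splice-defined 3p end), every nucleotide 3' of the
    reference — templated or not — is tail; genome match is ignored.
    Nucleotides removed as ``trimmed_suffix`` during mapping are always
    tail.  A read ending at or before the reference has tail 'none'.
    """
    # anchored: reference is the acceptor AG edge, so genome-matching
    # nucleotides past it are still tail; unanchored: reference is the
    # modal templated end, so only over-extension plus the mapping-stage
    # trimmed suffix counts.  Both reduce to "everything 3' of the
    # reference" because the caller picks the reference accordingly.
    past = max(0, read.sense_end - reference_end)
    templated_tail = read.sequence[len(read.sequence) - past :] if past else ""
    tail = templated_tail + read.trimmed_suffix
    return TailCall(
        sequence=read.sequence + read.trimmed_suffix,
        templated_end=read.sense_end,
        tail_seq=tail,
        tail_category=categorize_tail(tail),
        count=read.count,
        weight=read.weight,
        library_id=read.library_id,
    )


def collect_3p_tail_calls(
    call: MirtronCall,
    summary: LocusReadSummary,
    anchored: bool | None = None,
) -> list[TailCall]:
    """Tail calls for every read on the locus's 3p arm.

    Junction-spanning sense reads whose 5' end matches the 3p arm are
    included: in splice-anchored mode their genomic extension past the
    acceptor is tail by definition.  ``anchored`` defaults to True
    exactly when the subtype's 3p end is splice-defined.
    """
    if anchored is None:
        anchored = call.subtype in ("conventional", "5p_tailed")
    if call.buckets is None:
        raise ValueError("call carries no read buckets")
    arm_start = call.buckets.threep_interval[0]
    reads = list(call.buckets.threep)
    reads += [
        r
        for r in summary.junction_reads
        if abs(r.sense_start - arm_start) <= 3
        and r.sense_end > call.intron.length
    ]
    if not reads:
        return []
    if anchored:
        ref = call.intron.length
    else:
        totals: dict[int, float] = {}
        for r in reads:
            totals[r.sense_end] = totals.get(r.sense_end, 0.0) + r.count * r.weight
        ref = min(totals, key=lambda p: (-totals[p], p))
    return [call_untemplated_tail(r, ref, anchored) for r in reads]


def summarize_tails(
    calls: list[TailCall], min_category_frac: float = 0.01
) -> pd.DataFrame:
    """Read-weighted tail-category fractions, pooled over the given calls.

    Categories below ``min_category_frac`` of total reads are merged
    into 'others'; fractions sum to 1.
    """
    if not calls:
        return pd.DataFrame(columns=["category", "fraction", "n_reads"])
    weights: dict[str, float] = {}
    total = 0.0
    for tc in calls:
        w = tc.count * tc.weight
        weights[tc.tail_category] = weights.get(tc.tail_category, 0.0) + w
        total += w
    rows = []
    others = 0.0
    for cat in TAIL_CATEGORIES:
        if cat not in weights:
            continue
        frac = weights[cat] / total
        if frac <= min_category_frac and cat != "none":
            others += frac
        else:
            rows.append({"category": cat, "fraction": frac, "n_reads": weights[cat]})
    if others > 0:
        rows.append({"category": "others", "fraction": others, "n_reads": others * total})
    return pd.DataFrame(rows, columns=["category", "fraction", "n_reads"])


def xu_frequency(call: MirtronCall, min_reads: int = 10) -> XuSummary | None:
    """Fraction of unmodified (GU), guanine-decapitated (xU), and other
    5p reads at a splice-donor-defined locus.

    Reads are classified by alignment start: at the donor G -> GU; at
    donor+1 (missing the G) -> xU; anything else -> other.  Returns
    None (undefined) when the locus has fewer than ``min_reads``
    5p reads.  Raises for subtypes whose 5p end is not splice-defined.
    """
    if call.subtype not in ("conventional", "3p_tailed"):
        raise ValueError(
            "xU is defined only for splice-donor-defined 5p arms "
            f"(subtype {call.subtype})"
        )
    reads = _arm_reads(call, "5p")
    n = sum(r.count * r.weight for r in reads)
    if n < min_reads:
        return None
    gu = sum(r.count * r.weight for r in reads if r.sense_start == 0)
    xu = sum(r.count * r.weight for r in reads if r.sense_start == 1)
    return XuSummary(
        locus_id=call.locus_id,
        n_5p_reads=n,
        frac_GU=gu / n,
        frac_xU=xu / n,
        frac_other=(n - gu - xu) / n,
        min_reads=min_reads,
    )


def end_profiles_table(calls: list[MirtronCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        for arm in ("5p", "3p"):
            for terminus in ("5prime", "3prime"):
                prof = end_offset_profile(call, arm, terminus)
                if prof is None:
                    continue
                for off, frac in prof.offset_histogram.items():
                    rows.append(
                        {
                            "locus_id": prof.locus_id,
                            "arm": arm,
                            "terminus": terminus,
                            "provenance": prof.provenance,
                            "offset": off,
                            "fraction": frac,
                            "n_reads": prof.n_reads,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "arm", "terminus", "provenance",
            "offset", "fraction", "n_reads",
        ],
    )


def xu_table(calls: list[MirtronCall], min_reads: int = 10) -> pd.DataFrame:
    rows = []
    for call in calls:
        if call.subtype not in ("conventional", "3p_tailed"):
            continue
        xs = xu_frequency(call, min_reads)
        if xs is None:
            continue
        rows.append(
            {
                "locus_id": xs.locus_id,
                "n_5p_reads": xs.n_5p_reads,
                "frac_GU": xs.frac_GU,
                "frac_xU": xs.frac_xU,
                "frac_other": xs.frac_other,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "n_5p_reads", "frac_GU", "frac_xU", "frac_other"],
    )
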