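"""Expression normalization, mirtron-host correlation, and Ago-IP
enrichment statistics.

Correlation analysis: per mirtron-host pair, the Pearson correlation of
expression across matched tissues; an empirical alpha = 0.99 confidence
envelope built from 100 re-analyses with shuffled tissue labels (the
host matrix's labels are permuted, preserving the mirtron marginal);
and a two-tailed one-sample Wilcoxon test of the observed correlation
median against zero.

Ago-IP enrichment: per-group cumulative distributions of
log2(RPM + 0.1) (the 0.1 RPM offset keeps zero-read loci plottable on
log scales), excluding loci with zero reads in every library of the
comparison, with pairwise Welch t-tests Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UNITS = ("RPMM", "RPKM", "RPM", "raw")


@dataclass
class ExpressionMatrix:
    """Loci x samples abundance with a declared unit.

    RPMM: reads per million mapped miRNA reads; RPKM: reads per
    kilobase per million mapped; RPM: reads per million mapped.
    """

    values: pd.DataFrame           # index: locus_id, columns: samples
    unit: str
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")


def normalize(
    raw_counts: pd.DataFrame,
    mode: str,
    denominators: dict[str, float],
    lengths_kb: pd.Series | None = None,
) -> ExpressionMatrix:
    """Scale raw counts to RPMM / RPM / RPKM.

    value = count / denominator * 1e6, additionally divided by feature
    length in kb for RPKM.  A zero denominator yields an all-zero
    column with a warning rather than NaNs.
    """
    if mode not in ("RPMM", "RPKM", "RPM"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if (raw_counts.values < 0).any():
        raise ValueError("negative counts")
    if mode == "RPKM" and lengths_kb is None:
        raise ValueError("RPKM requires feature lengths")
    out = {}
    for col in raw_counts.columns:
        denom = denominators[col]
        if denom == 0:
            import logging

            logging.getLogger(__name__).warning(
                "zero denominator for sample %s; column set to 0", col
            )
            out[col] = np.zeros(len(raw_counts))
            continue
        v = raw_counts[col].to_numpy(dtype=float) / denom * 1e6
        if mode == "RPKM":
            v = v / lengths_kb.reindex(raw_counts.index).to_numpy(dtype=float)
        out[col] = v
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=raw_counts.index), unit=mode
    )


# ---------------------------------------------------------------------------
# mirtron-host correlation


@dataclass
class CorrelationResult:
    pair_r: pd.Series                  # per-locus Pearson r
    n_dropped_flat: int                # zero-variance pairs dropped
    quantile_grid: np.ndarray | None = None
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    observed_quantiles: np.ndarray | None = None
    inside_envelope: bool | None = None
    median_p: float | None = None
    n_shuffles: int = 0


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices."""
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = (am * bm).sum(axis=1)
    den = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def host_correlations(
    mirtron_expr: pd.DataFrame,
    host_expr: pd.DataFrame,
    tissues: list[str] | None = None,
) -> CorrelationResult:
    """Pearson r per mirtron-host pair across matched tissues.

    Pairs with zero variance in either vector are dropped (counted),
    never assigned r = 0.  Requires >= 3 shared tissues.
    """
    if tissues is None:
        tissues = [c for c in mirtron_expr.columns if c in host_expr.columns]
    if len(tissues) < 3:
        raise ValueError("need at least 3 shared tissues")
    shared = mirtron_expr.index.intersection(host_expr.index)
    m = mirtron_expr.loc[shared, tissues].to_numpy(dtype=float)
    h = host_expr.loc[shared, tissues].to_numpy(dtype=float)
    var_ok = (m.std(axis=1) > 0) & (h.std(axis=1) > 0)
    r = _pearson_rows(m[var_ok], h[var_ok])
    return CorrelationResult(
        pair_r=pd.Series(r, index=shared[var_ok]),
        n_dropped_flat=int((~var_ok).sum()),
    )


def shuffle_envelope(
    mirtron_expr: pd.DataFrame,
    host_expr: pd.DataFrame,
    tissues: list[str] | None = None,
    n_shuffles: int = 100,
    alpha: float = 0.99,
    seed: int = 0,
    quantile_grid: np.ndarray | None = None,
) -> CorrelationResult:
    """Observed correlation distribution with an empirical confidence
    envelope from tissue-label shuffles.

    Each shuffle permutes the host matrix's tissue labels (one
    permutation per shuffle, shared by all pairs) and recomputes every
    pair correlation; the envelope is the central ``alpha`` band of the
    shuffled distributions' quantiles, evaluated on a fixed quantile
    grid.  ``median_p`` is a two-tailed one-sample Wilcoxon test of the
    observed r distribution's location against zero.
    """
    if tissues is None:
        tissues = [c for c in mirtron_expr.columns if c in host_expr.columns]
    if len(tissues) < 3:
        raise ValueError("need at least 3 shared tissues for label shuffling")
    obs = host_correlations(mirtron_expr, host_expr, tissues)
    r = obs.pair_r.to_numpy()
    if quantile_grid is None:
        quantile_grid = np.linspace(0.05, 0.95, 19)

    rng = np.random.default_rng(seed)
    shared = mirtron_expr.index.intersection(host_expr.index)
    m = mirtron_expr.loc[shared, tissues].to_numpy(dtype=float)
    h = host_expr.loc[shared, tissues].to_numpy(dtype=float)
    var_ok = (m.std(axis=1) > 0) & (h.std(axis=1) > 0)

    shuffle_q = np.empty((n_shuffles, len(quantile_grid)))
    for s in range(n_shuffles):
        perm = rng.permutation(len(tissues))
        hs = h[:, perm]
        ok = var_ok  # permutation preserves variance
        rs = _pearson_rows(m[ok], hs[ok])
        shuffle_q[s] = np.quantile(rs, quantile_grid)

    if n_shuffles > 0:
        # Global (curve-wise) envelope: the band is center +/- c * scale
        # per quantile, with c the alpha-quantile of each shuffle curve's
        # maximum standardized deviation.  Unlike a pointwise band, a
        # null curve falls fully inside with probability ~alpha, which is
        # what "inside the alpha-envelope" asserts.
        center = np.median(shuffle_q, axis=0)
        scale = np.maximum(shuffle_q.std(axis=0), 1e-8)
        d = np.max(np.abs(shuffle_q - center) / scale, axis=1)
        c = float(np.quantile(d, alpha))
        lo = center - c * scale
        hi = center + c * scale
        obs_q = np.quantile(r, quantile_grid)
        inside = bool(np.all((obs_q >= lo) & (obs_q <= hi)))
    else:
        lo = hi = obs_q = None
        inside = None

    if len(r) and np.any(r != 0):
        median_p = float(stats.wilcoxon(r, alternative="two-sided").pvalue)
    else:
        median_p = float("nan")

    return CorrelationResult(
        pair_r=obs.pair_r,
        n_dropped_flat=obs.n_dropped_flat,
        quantile_grid=quantile_grid,
        envelope_lo=lo,
        envelope_hi=hi,
        observed_quantiles=obs_q,
        inside_envelope=inside,
        median_p=median_p,
        n_shuffles=n_shuffles,
    )


# ---------------------------------------------------------------------------
# expression breadth


BREADTH_BINS = ((0, 0), (1, 1), (2, 5), (6, 10), (11, 20), (21, 99), (100, None))


def expression_breadth(
    expr: pd.DataFrame,
    cutoff: float,
) -> pd.DataFrame:
    """Per-locus count of samples with expression strictly above
    ``cutoff``, plus the binned histogram.

    The conventional cutoffs are 5 RPM for mirtrons and 20 RPM for
    canonical miRNAs (a locus at exactly the cutoff is not expressed).
    """
    breadth = (expr > cutoff).sum(axis=1)

    def bin_label(n: int) -> str:
        for lo, hi in BREADTH_BINS:
            if hi is None and n >= lo:
                return f">={lo}"
            if hi is not None and lo <= n <= hi:
                return str(lo) if lo == hi else f"{lo}-{hi}"
        return "?"

    return pd.DataFrame(
        {
            "locus_id": expr.index,
            "breadth": breadth.to_numpy(),
            "bin": [bin_label(int(n)) for n in breadth],
        }
    )


# ---------------------------------------------------------------------------
# Ago-IP enrichment


@dataclass
class EnrichmentResult:
    transformed: pd.DataFrame          # loci x groups, log2(RPM + offset)
    n_excluded_allzero: int
    pairwise: pd.DataFrame             # group_a, group_b, t, p_raw, p_holm
    offset: float = 0.1


def ago_enrichment(
    locus_rpm: pd.DataFrame,
    group_map: dict[str, str],
    offset: float = 0.1,
) -> EnrichmentResult:
    """Per-group transformed expression and pairwise enrichment tests.

    Replicate libraries within a group are combined (mean RPM).  Loci
    with zero reads across every library of the comparison are excluded
    and counted.  Values are log2(RPM + offset); group differences are
    Welch t-tests with Holm-adjusted p-values.
    """
    missing = [c for c in locus_rpm.columns if c not in group_map]
    if missing:
        raise ValueError(f"group_map does not cover libraries: {missing}")
    groups = sorted(set(group_map.values()))
    combined = {}
    for g in groups:
        libs = [c for c in locus_rpm.columns if group_map[c] == g]
        if not libs:
            raise ValueError(f"group {g} has no libraries")
        combined[g] = locus_rpm[libs].mean(axis=1)
    comb = pd.DataFrame(combined)
    nonzero = comb.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    comb = comb.loc[nonzero]
    transformed = np.log2(comb + offset)

    rows = []
    raw_ps = []
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    for a, b in pairs:
        t = stats.ttest_ind(transformed[a], transformed[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t.statistic)})
        raw_ps.append(float(t.pvalue))
    if raw_ps:
        adj = multipletests(raw_ps, method="holm")[1]
    else:
        adj = []
    for row, p, ph in zip(rows, raw_ps, adj):
        row["p_raw"] = p
        row["p_holm"] = float(ph)
    return EnrichmentResult(
        transformed=transformed,
        n_excluded_allzero=n_excluded,
        pairwise=pd.DataFrame(
            rows, columns=["group_a", "group_b", "t", "p_raw", "p_holm"]
        ),
        offset=offset,
    )


def holm_adjust(pvalues: list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    return multipletests(pvalues, method="holm")[1]
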