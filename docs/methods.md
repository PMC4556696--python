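# Methods

This note documents the models, conventions, parameter choices, and
known limitations behind mirtronkit. It is the package's own account of
its science; every empirical statement here is recomputed by the test
suite or by `scripts/acceptance.py`.

## Coordinates, strands, and formats

All genomic intervals are 0-based half-open. BED6 intron input needs no
coordinate shift; the name field encodes
`host_gene|intron_index|host_intron_count` (transcription-order,
1-based ordinal). Sequences are held in DNA space — U is normalized to
T at ingest — and genome comparisons always happen in DNA space; a
writer flag reports sequences in RNA space where useful. All strand
flips are confined to the I/O layer: every downstream computation works
in sense-of-host-gene coordinates, with the splice donor at position 0
and the acceptor at the intron length. Collapsed FASTA counts use the
common `id_xN` header convention; a header without the suffix defaults
to count 1 with a logged notice. Non-canonical splice dinucleotides are
warned about, not dropped, so annotation errors degrade gracefully.
Adapters are a per-library manifest field with no default, clipped at
the leftmost exact occurrence; reads shorter than 17 nt after clipping
are dropped and tallied.

## Mapping

Exact matching only, with iterative 3' trimming: up to 4 single-
nucleotide trims, retaining ≥ 17 nt, reporting all placements at the
first (fewest-trim) iteration that matches either strand. The exact
floor and iteration count are the standard settings for this kind of
meta-analysis; a `mismatches` field exists for forward compatibility
but values > 0 are rejected. Matching is backed by a 17-mer seed index
with full verification, so results are identical to a naive substring
scan (property-tested against one). Multi-mapped reads are kept with
all placements and contribute fractional weight 1/n_placements to locus
evidence (a `unique_only` switch drops them); weighted sums are rounded
half-up before threshold comparisons. Reads spanning an intron boundary
on the sense strand go to a junction bin: they never count as mirtron
evidence, but they are retained because splice-anchored tail calling
needs reads that run through the acceptor when an untemplated tail
happens to match the downstream exon.

## Hairpin extent, subtype, and duplex geometry

The extent heuristic is deliberately simple and deterministic: the
dominant read stack and the dominant stack overlapping it by less than
half a read define the arms (ties break toward the lower coordinate);
ends snap to splice sites within 1 nt (`splice_tolerance`), reflecting
the ±1 terminal heterogeneity typical of splice-defined ends. Reads are
then bucketed 5p / 3p (termini within 3 nt of the hairpin ends), loop
(fully between the arms), or other.

Subtype follows from which hairpin ends abut splice sites. Offsets in
the open band between `splice_tolerance` (1 nt) and
`two_tailed_min_offset` (5 nt) are resolved to the nearer status and
flagged ambiguous rather than silently classified — the band boundary
is a package choice, since "directly abutting" has no universal numeric
definition.

Overhangs are measured through the duplex register: every arm–arm base
pair in the fold implies an overhang at each duplex end, and the median
over pairs is reported. This is exact for a clean duplex and robust to
local slippage of the predicted structure around planted or natural
mismatches, unlike extrapolating from the terminal base pair alone.
Acceptance window [−1, +4] nt: wide enough for the canonical 2-nt 3'
overhang and the occasional 4-nt case seen at real loci, strict enough
to reject degradation stacks; ≥ 12 arm–arm base pairs are additionally
required. Folding is skipped for loci whose evidence cannot reach a
dicing-gated tier — the tier outcome is provably identical, since
`candidate` and `rejected` do not consult geometry.

## The folding scorer

The default backend is a deterministic Nussinov-style dynamic program
with weighted pairs (G:C = −3, A:U = −2, G:U = −1), minimum hairpin
loop 3, and a +4 charge per helix (each maximal run of stacked pairs
pays it once; for the innermost helix this is the hairpin-loop charge).
Charging per helix rather than only per hairpin loop penalizes isolated
pairs, without which a base-pair maximizer scores random sequence
almost as well as designed stems and cannot discriminate hairpins from
shuffled controls. The DP is exact (verified against brute-force
enumeration of all nested structures on short sequences) and its
traceback is deterministic with leftmost-pairing tie-breaks, so folds
are identical across runs and platforms. The scorer accepts sequences
of 20–1000 nt. Scores are energy-like (lower = more stable) but are
not free energies; `backend="rnafold"` shells out to RNAfold when a
thermodynamic engine is wanted. All structure-based statistics in the
package only use score *comparisons*, never absolute values.

## Terminal analysis

Splice-anchored tail calling: for subtypes whose 3p end is
splice-defined, the acceptor AG edge is an external reference for the
primary-processed species, so every read nucleotide 3' of it is called
untemplated regardless of genome match; nucleotides removed as a
trimmed suffix during mapping are always tail. For non-splice-defined
ends the reference is the modal templated end, so only over-extension
plus the trimmed suffix counts. Tail categories are monoU/diU/multiU,
monoA/diA, mixed (U+A), other; categories at ≤ 1% of reads pool into
"others". Offset profiles are read-weighted (species-weighting is the
alternative; read-weighting was chosen as the natural abundance
measure) over a ±5 nt window with edge pooling. xU ("guanine-
decapitated") fractions are defined only for splice-donor-defined 5p
arms (conventional, 3'-tailed) with ≥ 10 5p reads: reads starting at
the donor G are GU, at donor+1 are xU, anything else (≥ 2 nt inside or
upstream of the donor) is other.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions assumed throughout. It emulates:

* a toy single-chromosome genome of plus- and minus-strand genes (30%
  minus) with canonical GT..AG introns; bulk intron lengths are
  log-normal (mode ~150–250 nt) clipped to [80, 4000] nt — the real
  length distribution's heavy tail is truncated at toy scale;
* planted hairpins built from a sampled arm and its reverse complement
  (10% interior mismatch rate, 3 intact pairs at each stem end, poly-A
  loop of 18 nt so the loop cannot extend the stem), leaving exact 2-nt
  3' overhangs at both duplex ends; hairpin lengths are normal per
  class — conventional 83 ± 9.7 nt, 5'-tailed 63 ± 9.9, 3'-tailed
  61 ± 7.8, two-tailed 69 ± 10, canonical 60 ± 4.3 — mirroring the
  characteristic long-conventional/tight-canonical contrast;
* 5' tails log-uniform on [10, 3000] nt, mature species of up to 22 nt,
  mature:star asymmetry 10:1, loop reads at 5% of locus depth in
  total-RNA libraries only (never Ago-IP), control-IP libraries
  receiving only background degradation (and nothing at all when the
  background rate is zero), uniform background reads over bulk introns
  at 2 reads/kb/library;
* terminal phenomenology: untemplated U tails (p = 0.25) and A tails
  (p = 0.10) of length 1–3 at splice-defined 3p ends, engineered so the
  downstream exon never matches the tail (a confounding mode makes it
  match, to exercise the splice-anchor rule); 5'-G decapitation
  (p = 0.20) at splice-defined 5p ends; 5' jitter ({0: .8, +1: .1,
  −1: .1}) at termini that are *not* splice-defined. Confining jitter
  to non-splice-defined ends is a deliberate simplification: it makes
  each planted rate identifiable from one terminus class, at the cost
  of understating the (small) heterogeneity real splice-defined ends
  show;
* tissue expression with correlated loci (mirtron RPMM proportional to
  host junction RPM times log-normal noise, σ = 0.2) and discordant
  loci (tissue-masked to 1–2 of 7 tissues while the host stays broad);
  host gene RPKM ≥ flanking-exon RPKM ≥ junction RPM by construction.

Per library, the configured depth is distributed multinomially over
emission channels, so library totals are exact and every read is
traceable through the emitted ledger to {locus + arm, loop,
background}. Identical configurations (including the seed) give
byte-identical outputs. The generator does **not** model sequencing
error, quality scores, PCR duplication, isoform structure, or realistic
chromosome counts — so passing tests demonstrate the pipeline's logic
and calibration, not robustness to platform noise.

## Statistical choices

* Pearson correlations are computed per mirtron–host pair across
  matched tissues; zero-variance pairs are dropped and counted, never
  assigned r = 0.
* The α = 0.99 empirical envelope shuffles the host matrix's tissue
  labels (one permutation per shuffle, shared across pairs; the mirtron
  marginal is preserved) 100 times and evaluates distribution quantiles
  on a fixed grid (5th–95th percentile, 19 points). The band is a
  *global* (curve-wise) envelope — center ± c·scale per quantile with c
  the α-quantile of each shuffled curve's maximum standardized
  deviation — so a null curve falls entirely inside with probability
  ≈ α. A pointwise band at the same nominal level would be crossed far
  too often by chance when "inside" means "inside everywhere"; the
  calibration test asserts the global band's coverage empirically.
* The deviation of the observed correlation median from zero uses a
  two-tailed one-sample Wilcoxon test.
* Ago-IP enrichment transforms combined (mean-RPM over replicate
  libraries) group values as log2(RPM + 0.1); the 0.1 offset keeps
  zero-read loci on log scales. Loci with zero reads in every library
  of the comparison are excluded and counted. Group differences are
  Welch t-tests with Holm adjustment (statsmodels).
* Energy-per-base comparisons sample control introns without
  replacement to match the case length distribution in 100-nt bins
  (deficits logged; a pool smaller than the case set is used whole,
  flagged unmatched) and test the mean difference with a Welch t-test.
  Dinucleotide shuffles use the Eulerian-path (Altschul–Erikson)
  construction, preserving exact dinucleotide composition.
* Host intron-count contrasts use the top-2% trimmed mean (outlier
  genes with extreme intron counts otherwise dominate) and two-sided
  Wilcoxon rank-sum tests against bulk genes. Pre-miRNA length
  contrasts use Mann–Whitney tests against the canonical class; the
  test is configurable since distributional assumptions are weak at
  small n.
* Seeds: 7-mer = mature nt 2–8 for cross-species conservation (with
  positional-only homologous matches reported separately), 6-mer =
  nt 2–7 for mimicry against reference miRNA seeds — the field's
  standard offsets.

## Reproducibility and problem sizes

A single global seed fans out into named per-stage substreams, so
changing one stage's sampling does not perturb another's; full runs are
byte-identical under a fixed seed and single-threaded by contract. The
bundled analyses use deliberately compact problem sizes — tens of
planted loci, libraries of 10–30k reads, genomes of a few hundred kb —
chosen so the complete suite and the acceptance script run in seconds
to minutes on one CPU while keeping every statistical check (binomial
CIs at ≥ 2000 reads per locus, 50-pair sign tests, 100-pair correlation
sets over 7 tissues, 50-replicate calibration) at the scale its power
calculation assumes.

## Known limitations

The extent heuristic assumes two dominant, largely non-overlapping
arms; loci whose mature and star species overlap heavily (offset
duplexes) are skipped as unable to form a duplex. Hairpins longer than
1000 nt are not folded and fail the geometry gate with an explicit
reason. The annotation is fully automatic: borderline calls are flagged
(ambiguous subtype, dicing-failure reasons) rather than manually
vetted. Canonical miRNA loci are treated as external references
(expression, seeds, length contrasts); the package does not re-annotate
them. Conservation analysis consumes an externally supplied intron
homology map; no alignment is performed.
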