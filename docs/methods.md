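# Methods

## Coordinate conventions

All coordinates are 0-based, half-open, in transcript space. The CDS
interval includes the stop codon, so the stop codon is
`sequence[cds_end-3 : cds_end]` and the 5′UTR / CDS / 3′UTR partition is
`[0, cds_start) / [cds_start, cds_end) / [cds_end, L)`. Footprints are
located by their 5′-most aligned base ("position 0" of the read). Reading
frames extend mathematically upstream of the start codon (Python's modulo
keeps `(pos − cds_start) mod 3` in {0,1,2} for negative operands), so
positions in the 5′UTR get consistent frames. RNA input is normalized to
the DNA alphabet (U→T, upper-case) at load time.

Reverse-strand records in transcriptome alignments are dropped and counted
rather than rescued: footprints aligned to a transcriptome are sense-strand
by construction. Missing NM/NH tags default to 0 mismatches / 1 hit with a
logged warning so that simplified synthetic SAMs load cleanly. Reads whose
3′ end extends past the transcript end are kept as long as the 5′ end is in
range; an anchor that falls outside the transcript drops that read from the
profile (a per-anchor decision, not a load error).

## Anchors, filters, normalization

The P-site codon starts 12 nt and the A-site codon 15 nt downstream of the
footprint 5′ end; a read whose 5′ end is 15 nt upstream of the stop codon
therefore has the stop codon in its A-site. Alignment-quality gating keeps
unique mappers (NH = 1) with at most 2 mismatches. Transcript-level gating
requires ≥ 16 CDS reads and ≥ 10 % of CDS positions covered, both
inclusive at the boundary; the gate is evaluated on the unstratified
profile and then applied to all length strata of that transcript.
Normalization divides every position by the mean CDS count of the same
anchor-mode profile, so the normalized CDS mean is exactly 1 and metagene
curves are in units of "fold of mean CDS occupancy". Metagene averaging
uses per-offset denominators: a transcript contributes at distance *d*
from the anchor codon only when that position exists within its bounds.

## Pausing index and context classes

The pausing index is the mean 5′-end count over the window [−15, −12]
(inclusive; both termination peaks) relative to the stop codon's first nt,
divided by the mean CDS count. It is scale-invariant and uses no
pseudocounts; a single-peak window ([−15, −15]) is available via the
`stop_window` argument for sensitivity analyses. The 3′UTR relative
density is the per-nt 3′UTR count over the per-nt CDS count, with
stop-window positions excluded from the 3′UTR tally. High/Low pausing
classes, where needed, are the top and bottom quartiles of the index
distribution — the literature reports the contrast without printing a
cutoff, so a quartile split is declared here as the package's convention.

Stop-codon context is classified from the 9 nt immediately 5′ of the stop
codon (the same width as the MPRA inserts): GA-rich when (G+A)/9 ≥ 7/9,
C-rich when C/9 ≥ 5/9, GA-rich taking precedence. These thresholds are
composition cutoffs chosen by the package (the field describes "GA-rich"
and "C-rich" elements qualitatively); both are configurable.

## eRF1 peak calling

A site is a termination-peak candidate when its count is **strictly**
greater than `fold_threshold` (default 10) times the mean of a centered
120-nt window, computed over in-range positions and **including** the
candidate site. Self-inclusive centered windows are the conservative
reading of a sliding-window rule and keep the threshold well defined at
transcript edges. Transcripts with < 10 total eRF1 reads are skipped. Runs
of candidates within 2 nt collapse to the maximal-count site (5′-most on
ties) — deliberately narrower than the 3-nt spacing of the −15/−12
doublet, which must survive as two peaks. `shifted_stop` names the
*positional* offset of a stop codon overlapping the A-site codon (`minus1`
= stop starts 1 nt 5′, checked first; `plus1` = 1 nt 3′); the
ribosome-frameshift vocabulary is the negation of this offset, so the raw
offset is emitted alongside the label. The termination drop ratio is the
mean Ribo-seq density over 60 nt downstream of the A-site codon divided by
60 nt upstream, excluding the codon itself from both flanks.

## uORF calling

Candidates are all 5′UTR AUGs paired with their first in-frame stop codon,
searching into the CDS when necessary (overlapping uORFs); nested
candidates are all retained, and near-cognate starts are excluded. The
frame test pairs, per codon *j*, the P-site count at `start+3j` with the
counts at `+1` and `+2`, and applies a one-sided (greater) Wilcoxon
signed-rank test per off-frame position. Pairing within codon positions —
rather than an unpaired rank-sum — controls per-position depth and is the
stricter reading of a two-sample frame comparison. Zero differences are
dropped before ranking (all-zero input gives p = 1); absolute differences
are midranked, and the null distribution is computed **exactly** for
n ≤ 25 pairs by dynamic programming over doubled midranks (equivalent to
enumerating all 2ⁿ sign assignments, ties handled exactly), with a
tie-corrected, continuity-corrected normal approximation above. The two
p-values are combined by Stouffer's method with equal weights
(z = (z₁+z₂)/√2; p of exactly 1 clipped just below 1), and
Benjamini–Hochberg adjustment runs jointly across all candidates from all
transcripts; `robust` flags q < 0.05. Candidates need ≥ 2 codons and ≥ 8
anchored reads inside `[start, stop)` to be testable.

## MPRA analysis

Inserts must be exactly 9 nt over {A,C,G,T}; rejections are tallied by
reason (wrong length vs ambiguous bases), and optional exact flank
matching extracts inserts from longer reads. RPM is count/total × 10⁶ per
fraction. M/P = (rpm_mono + pc)/(rpm_poly + pc) with a 0.5-RPM pseudocount
by default; with pc = 0, variants absent from either fraction are reported
missing rather than 0 or ∞ (how the original analysis handled absent
variants is not stated, so the pseudocount is a package decision and is
configurable). The positional codon matrix averages M/P over variants
carrying a given 3-mer at each of the seven 3-mer start offsets 0..6 —
all offsets, not just codon slots, since composition effects carry no
frame information; frame-restricted summaries (offsets mod 3, frame 0 in
frame with the upstream ORF) derive from the same matrix. Cells without
support are missing, not zero. Variants are distinct 9-mers; duplicate
reads are counted, not collapsed (no UMIs).

## Synthetic data

The generators produce the statistical structure the analyses assume, with
ground truth for every planted signal. Study conditions (defaults):

- **Transcripts** — random sequences, ATG at `cds_start`, stop codon at
  `cds_end−3`, no accidental in-frame CDS stops (resampled away). Lengths:
  5′UTR 60–120 nt, CDS 150–450 nt, 3′UTR 60–180 nt — scaled-down
  transcripts that keep every geometric feature (both UTRs, ≥ 48 codons)
  while making multi-seed panels cheap. Half the transcripts receive a
  designed 9-mer immediately 5′ of the stop codon (GA-rich: letters from
  {G,A}; C-rich: 80 % C), populating both context classes.
- **Pausing** — multiplier = 1 + 20 × GA-fraction of the upstream 9-mer
  (`context` mode), or log-uniform in [1, 50] (`loguniform` mode) for
  parameter-recovery experiments. The slope is a free parameter (no
  quantitative value is published); 20 separates designed GA (~21×) from
  designed C (~3×) contexts decisively while keeping multipliers in the
  plausible 1–50× range.
- **Ribo-seq** — Poisson(depth = 5) elongation 5′ ends at every CDS
  position (uniform: the analyses normalize by CDS mean, so codon-specific
  dwell times are an optional extension, not a default); a terminating
  component with total mean depth × multiplier at offsets −15/−12 (split
  0.7/0.3, no smearing by default; a smear half-width is configurable);
  footprint lengths 28–31 nt elongating, 30–31/20–23 nt terminating
  (50/50 mix); 3′UTR leak reads at rate 0.5 × depth / multiplier with
  frame-uniform 5′ ends (encoding degraded 3-nt periodicity as placement,
  not mechanism — no quantitative leak model is published, so the scale is
  a free parameter). 5′UTR background equals the CDS depth (factor 1.0),
  which keeps the uORF null frame-uniform at the configured depth and
  makes "k-fold in-frame enrichment" unambiguous (in-frame mean k × depth
  vs off-frame depth); planted uORFs add frame-0 reads P-site-anchored on
  their codons.
- **eRF1-seq** — Poisson(50) reads per termination site with 5′ ends at
  site − 15, over Poisson(0.1)/nt CDS background. Sites: every annotated
  stop, planted contained-uORF stops (probability 0.3/transcript), orphan
  5′UTR stops (0.7/transcript, stop codons not tied to a planted uORF),
  and out-of-frame CDS stops (0.3/transcript, placements that would create
  an in-frame stop are resampled). The 0.3/0.7 uORF/orphan mix makes
  ~30 % of 5′UTR termination sites uORF-matched, the regime the matching
  analysis is meant to quantify.
- **MPRA** — 10⁴ distinct 9-mers, ~10⁶ reads per fraction; per-variant
  total ~ Poisson(2 × depth / N) split binomially with P(monosome) = 0.9
  for inserts with an in-frame stop and 0.18 otherwise (a 5-fold planted
  partition), optionally shifted by insert G+A content.

Everything is byte-deterministic under a fixed seed. What the simulations
do **not** emulate: codon-level dwell-time variation, ribosome collisions,
mRNA-stability differences between MPRA variants, ligation/PCR biases, and
mechanistic 3′UTR ribosome sliding. Tests passing on these data therefore
establish that the estimators recover the signals they target under the
stated noise model — not that real libraries are free of the biases above.

## Numerical choices and degenerate inputs

Exactly 10× the window mean is *not* a peak (strict inequality); exactly
16 CDS reads and exactly 10 % coverage *do* pass the transcript gate.
Normalization of an all-zero CDS, frame fractions of an empty region, RPM
of an empty fraction, and a pausing index without CDS reads raise errors;
an empty 3′UTR, a fraction-absent MPRA variant (at pc = 0), an untestable
uORF candidate (< 2 codons), and a 5′UTR-peak match fraction without
5′UTR peaks are reported missing (`None`/NaN) instead. BH q-values come
from statsmodels; the Wilcoxon exact distribution and the peak caller are
implemented here and cross-checked in the tests against brute-force
enumeration and a naive window-by-window reimplementation respectively.

## Problem sizes

The acceptance script and test suite run on simulated panels sized to
exercise every statistical claim with comfortable margins: 200 transcripts
at depth 5 for metagene geometry, 500 for pausing-index recovery
(Spearman ρ ≥ 0.8 observed ≈ 0.97), 100-transcript panels for peak-caller
calibration, ~1000 null candidates for uORF type-I error, and
10⁴-variant/10⁶-read MPRA libraries. These sizes are the package's
standard simulation conditions; all are configurable.
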