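# riboterm

Tools for profiling **terminating ribosomes** from ribosome-profiling data.

When translation ends, the stop codon sits in the ribosomal A-site and the
ribosome pauses while release factors act. On high-resolution ribosome
profiling this leaves footprints whose 5′ ends pile up at **−15 nt** (stop
codon decoded in the A-site) and **−12 nt** (forward-shifted,
post-termination state) from the stop codon's first nucleotide, in two
length populations (long 30–31 nt, short 20–23 nt). The strength of this
pause varies across mRNAs and depends on the coding sequence immediately
upstream of the stop codon; mRNAs that do not pause shed more ribosomes
into the 3′UTR. `riboterm` implements the downstream computations needed
to study this behaviour:

- **Anchor assignment and metagene analysis** — footprints are mapped to a
  single position (5′ end, P-site = 5′ + 12, A-site = 5′ + 15, or 3′ end);
  per-transcript densities are normalized by mean CDS occupancy and
  averaged at fixed distances from the start/stop codon. Transcripts with
  < 16 CDS reads or < 10 % of CDS positions covered are excluded, and
  multimapped or > 2-mismatch alignments are discarded.
- **Stop-codon pausing index** — per mRNA, mean footprint density at the
  5′-end window [−15, −12] around the stop codon divided by the mean CDS
  density: PI = (Σ_{d=−15..−12} c(stop+d) / 4) / (Σ_CDS c / L_CDS). The
  ratio factors out mRNA abundance and translation efficiency.
- **eRF1-seq termination peaks** — for profiling libraries restricted to
  eRF1-bound (terminating) ribosomes, a site is a termination peak when
  its count strictly exceeds 10× the mean of a centered 120-nt window
  (transcripts with < 10 total reads excluded). Peaks are annotated with
  mRNA region, reading frame, A-site codon, shifted-stop status (a stop
  codon ±1 nt of the A-site codon), downstream/upstream Ribo-seq density
  drop, and matching against uORF termination sites.
- **uORF calling** — every 5′UTR AUG is paired with its first in-frame
  stop; per-codon in-frame P-site counts are compared to each off-frame
  position with a one-sided exact Wilcoxon signed-rank test, the two
  p-values combined by Stouffer's method (z = (z₁+z₂)/√2), and candidates
  called at Benjamini–Hochberg FDR < 0.05.
- **MPRA analysis** — 9-nt random-insert reporter libraries partitioned
  between monosome and polysome fractions: insert gating, per-fraction
  counting and RPM, per-variant M/P ratio, and positional codon matrices
  (mean M/P per 3-mer per insert offset) that expose in-frame stop codons
  and composition effects.
- **Stop-context stratification** — classify the 9 nt upstream of the stop
  codon as GA-rich / C-rich / other by base composition and stratify
  pausing indices and metagenes by class.
- **Synthetic data** — generators for transcriptomes, Ribo-seq and
  eRF1-seq footprints, and MPRA libraries with ground-truth tables for
  every planted signal, used throughout the test suite.

## Worked example

Simulate a Ribo-seq dataset and compute stop-codon pausing indices:

```bash
riboterm simulate --preset ribo --seed 3 --n-transcripts 30 --out-prefix sim/rb
# wrote 30 transcripts, 61857 reads under sim/rb.*
riboterm metagene --fasta sim/rb.fa --annotation sim/rb.cds.tsv \
    --reads sim/rb.reads.tsv --align-to stop --offsets "-20:5" --out mg.tsv
# metagene over 30 transcripts -> mg.tsv
riboterm pausing --fasta sim/rb.fa --annotation sim/rb.cds.tsv \
    --reads sim/rb.reads.tsv --out pa.tsv
# 30 pausing records -> pa.tsv
```

`mg.tsv` holds the mean CDS-normalized density per offset from the stop
codon; values hover around 1 inside the CDS (that is the unit after
normalization) and spike at −15/−12 where terminating footprints
accumulate:

```
offset	mean_density	n_transcripts
-20	1.0237377800591159	30
-19	0.99801907606197	30
```

`pa.tsv` has one row per mRNA with its pausing index, 3′UTR relative
density, and GA/C context class. The same library API is available in
Python (`riboterm.stop_pausing_index`, `riboterm.call_termination_peaks`,
`riboterm.call_uorfs`, ...).

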