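# Methods

## Problem and model

Translation initiation on most mRNAs requires the eIF4F helicase subunit
eIF4A to unwind secondary structure in the 5' leader (5' UTR) ahead of the
scanning ribosome.  Hippuristanol locks eIF4A in a closed conformation and
blocks its RNA binding, so mRNAs whose ribosome recruitment depends most on
eIF4A lose translation efficiency (TE) first when the drug is applied.
`leaderscan` implements the computational side of that experiment: classify
genes by their TE response, then ask which 5'-leader features — length,
secondary-structure stability, nucleotide composition, G-quadruplex
propensity — distinguish the responsive (DOWN) class from the unresponsive
background, and design synthetic reporter leaders that probe those features
causally.

TE for a gene is footprint density over RNA density, `TE = RPKM_ribo /
RPKM_rna`.  Classification uses the standard two-sided rule on a
differential-TE table: BH-adjusted p >= 0.05 is non-significant (the
boundary is assigned conservatively to NS); below it the sign of the log2
fold change gives UP or DOWN.  The three labels partition all tested genes.

## Representative transcripts and leaders

One transcript represents each gene: the APPRIS principal isoform, ties
broken by highest RNA-seq TPM, then by lexicographically smaller transcript
id so the choice is order-independent.  Genes without any principal tag
fall back to highest TPM — the same tie-break one level down; APPRIS
simply never saw some annotations, and dropping such genes would bias the
background toward well-annotated loci.  The leader is the transcript
prefix ending one base before the annotated CDS start.  Annotation is
consumed in transcript coordinates (the FASTA is transcript-level);
version suffixes are stripped for id matching because FASTA/GTF dialects
disagree routinely.  Leaders that are empty, from non-coding transcripts,
or >10% N are kept in the catalog but excluded from feature statistics
(their features are undefined or unreliable).

## Feature panel

* Composition: percentages over non-N bases; T and U are equivalent;
  pyrimidine content is C+U.  A positional GC profile splits the leader
  into near-equal bins (remainder to the 5' end).
* MFE: minimum free energy of the optimal secondary structure under the
  nearest-neighbor Turner model at 37 °C, computed by ViennaRNA behind a
  single adapter (`mfe_global`).  The package's contribution is the
  feature pipeline, not a folding algorithm, so the engine is delegated
  and swappable; unstructurable sequences report 0.0.  Sequences longer
  than 10 kb are folded in full (truncation would silently change MFE).
* Length-normalised MFE is MFE/length.  The corrected MFE is the residual
  of MFE against a least-squares background model
  `MFE ~ a + b1*length + b2*GC%` fitted on >= 50 background leaders:
  more negative residual = more structure than expected for that length
  and composition.  A linear residual is our reading of
  "composition-corrected stability"; other corrections exist, so no
  real-data claims are attached to this column.
* Sliding-window MFE: 20-nt windows advanced 2 nt, profiling local
  structure along the leader.

## G4Hunter

Implemented from scratch (it is part of the contribution).  Each base in a
run of n consecutive Gs scores +min(n,4); C runs score the negative; A/U/N
score 0 and N breaks runs.  Window means (25 nt, step 1) at or above the
threshold 1.4 (inclusive) are merged when they overlap or abut; a region's
span is the union of its windows, untrimmed — the simplest reproducible
convention.  Since the scanned molecule is single-stranded mRNA, only
G-rich regions count as quadruplexes; C-rich troughs are reported
separately.  Group density is the pooled ratio: total regions over total
leader nucleotides, per 1000 nt.

Enrichment of a gene class (e.g. the DOWN genes) is judged against an
empirical null: 1000 equal-count groups of transcripts sampled without
replacement from the background catalog, pooled density per draw, and
`z = (observed − null mean) / null SD`.  "Equally sized" means equal
transcript count, the plain reading; equal-nucleotide grouping would
conflate density with length.  The sampling pool is sorted internally so
the draw sequence depends only on the seed, never on input row order.  The
observed group stays in the pool by default (`exclude_group` flips this;
with a small group either convention moves z by far less than its own
seed-to-seed spread).

## Group statistics

Per-feature class comparisons report medians, one-way ANOVA with Tukey's
pairwise adjustment, and Kruskal–Wallis alongside — leader lengths are
heavy-tailed, so the nonparametric companion guards the parametric
p-values.  Classes with fewer than two members get NaN for their pairwise
tests instead of failing the whole comparison (the UP class is typically
tiny).

## Reporter designer

Inserts of exact length (24 nt "Short", 148 nt "Long") are drawn
position-wise from a target composition and rejected whole whenever a
forbidden motif (ATG in either T/U spelling), an internal NdeI/MluI site,
or a composition deviation beyond tolerance appears.  Whole-sequence
rejection, rather than local repair, preserves the i.i.d. per-position
distribution.  Tolerance is 5% of length but at least one base: exact
composition matching at 24 nt is combinatorially brittle.  The default
panel crosses Short/Long with three composition strata — LoC (~15% C,
~50% GC), HiC (~35% C, ~50% GC), HiGC (~35% C, ~70% GC); the numeric
targets are this package's calibration of the coarse low/high strata —
three distinct inserts each, plus three G-free controls (CAU-1, CA-1,
CA-2, drawn from {A,C,U} or {A,C}; G-free sequences cannot form
G-quadruplexes).  The NdeI flank itself contains ATG; the prohibition
applies to the insert only.  Fixed seeds give bit-identical panels.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not raw sequencing reads.  Defaults are the emulated study conditions:

* 2000 genes, 10% in a "responsive" regime (about 200 genes — the same
  order as the responsive class in the motivating experiment).
* Leader lengths log-normal with median 363 nt (responsive) vs 138 nt
  (background), log-sd 0.6 — right-skewed like real UTR lengths, medians
  set to the values the analysis should recover.
* Compositions: responsive ~35.0% C / 54.2% GC, background ~31.5% C /
  52.1% GC.
* G4 planting: telomere-like G3 blocks inserted k ~ Poisson(rate ×
  length/1000) times, rate 1.2/kb responsive vs 0.15/kb background,
  giving a controllable true density difference for z-score recovery.
* Counts: negative binomial (gamma–Poisson), RNA mean proportional to
  TPM × CDS length scaled to a 2M-read RNA library and a 5M-read
  footprint library; Ribo means carry a per-gene baseline TE and a −1
  log2 TE shift in responsive genes under treatment only.
* 4 replicates per condition, NB dispersion 0.005.  The synthetic-mode
  test is a deliberately plain Welch t on replicate log2 TE with BH
  adjustment — no dispersion shrinkage — so the default variability is
  set at the clean, cell-line-replicate end of the scale; a power
  analysis shows the planted −1 shift is then recovered for the large
  majority of responsive genes, which is the regime the downstream group
  statistics need.  With dispersions typical of noisier designs a
  moderated count model (e.g. DESeq2, which the real-data path ingests)
  would be required instead; the plain test makes no claim to its power.
* Counts use a 0.5 pseudocount before log-ratios (synthetic mode only).

What the generator does not emulate: read-level artifacts (rRNA, UMI
structure, P-site offsets), isoform-level expression shifts, correlated
features beyond the planted regime differences, and any relationship
between leader structure and the planted TE effect other than regime
membership.  Passing recovery tests therefore show the pipeline's
statistics are correct and calibrated, not that the biological effect
sizes are realistic.

## Numerical conventions

GTF input is 1-based inclusive; internal arithmetic 0-based half-open;
all reported positions 1-based.  Percentages are computed at full
precision and rounded to two decimals only in output files.  Seeded
`numpy` generators drive every stochastic step; identical seeds give
bit-identical outputs, including emitted files.  Degenerate inputs fail
loudly: empty/all-N composition, zero library size, constant background
regressors (the offending column is named), a constant resampling null.

## Worked-example stand-in

The canonical worked example is the 4EBP2 (EIF4EBP2) 5' leader, known by
its summary descriptors: 297 nt, 75% GC, 35% C, strongly structured
(MFE about −165 kcal/mol).  The real sequence is not redistributed here;
`synthetic_refs.synthetic_4ebp2_like_leader` builds a synthetic stand-in
matching the length and composition descriptors exactly, which exercises
the composition code paths against known values.  Its MFE is whatever the
folding engine computes for the shuffled arrangement and is not compared
against the real leader's value; the folding adapter is instead verified
against RNAfold command-line results recorded as fixtures before the
adapter was written.

## Problem sizes

Default analysis scale is 2000 genes; the recovery check repeats the full
pipeline over 20 seeds at that scale, the resampling calibration uses 50
seeds × 1000 iterations on a 300-gene catalog, and the designer fuzz
draws 10,000 inserts.  These sizes were chosen to make every statistical
claim measurable with comfortable margins while keeping a full run in
minutes on one core.

## Known limitations

* The corrected-MFE column is one defensible correction, not a standard.
* The simple TE test is for synthetic data only; real analyses must
  supply an external differential-TE table.
* G4Hunter region refinement (re-scoring merged regions to trim them) is
  not applied; spans are union spans, which are slightly wider.
* Leaders are single-isoform by construction; genes whose isoforms differ
  in 5' UTR are represented by the principal isoform only.
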