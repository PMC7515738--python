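# leaderscan

Feature analysis of mRNA 5' leaders under eIF4A inhibition.

Hippuristanol blocks the RNA-binding activity of the translation
initiation helicase eIF4A.  mRNAs differ sharply in how much their
ribosome recruitment depends on eIF4A, and that dependency is written in
the 5' leader (5' UTR).  `leaderscan` is a reusable pipeline for the
computational half of such experiments, aimed at people analysing
matched ribosome-profiling / RNA-seq data:

* **catalog** — pick one representative transcript per gene (APPRIS
  principal isoform, TPM tie-break) and extract 5' leaders from a
  transcript FASTA + annotation.
* **te** — translation efficiency `TE = RPKM_ribo / RPKM_rna`,
  UP/DOWN/NS classification (`padj >= 0.05` → NS, else sign of the log2
  fold change), Spearman fold-change concordance between studies, and a
  simple Welch-t TE test for synthetic data.
* **features** — leader length, base / GC / pyrimidine composition,
  positional GC profile, ViennaRNA minimum free energy (global, per-nt,
  background-corrected, 20-nt/2-nt sliding windows).
* **g4** — a from-scratch G4Hunter: per-base G/C run scores capped at
  ±4, 25-nt window means, threshold 1.4, merged regions, density per
  1000 nt.
* **stats** — per-class medians with ANOVA/Tukey (Kruskal–Wallis
  co-reported) and a resampling null for G4 density: 1000 equally sized
  random transcript groups, `z = (observed − null mean)/null SD`.
* **designer** — constrained random reporter leaders (24 or 148 nt,
  target composition, no ATG, NdeI/MluI flanks, G-free controls).
* **simulate** — a complete synthetic study (toy transcriptome + NB
  count tables with a planted TE decrease confined to a long/C-rich/G4-
  seeded leader regime) so the whole pipeline runs with no downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic study and run every stage from the shell:

```sh
leaderscan simulate --genes 2000 --seed 42 --out study/
leaderscan catalog --fasta study/transcripts.fa --gtf study/annotation.gtf \
    --appris study/appris.tsv --tpm study/tpm.tsv --out study/out
leaderscan classify --counts study/counts.tsv --out study/te.tsv
leaderscan g4 --leaders study/out/leaders.fa --out study/out
leaderscan features --leaders study/out/leaders.fa --out study/out
```

or from Python:

```python
from leaderscan import (SimulationConfig, simulate_transcriptome,
                        simulate_counts, simple_te_test)

cfg = SimulationConfig(n_genes=2000, seed=42)
study = simulate_transcriptome(cfg)
result = simple_te_test(simulate_counts(study))
print(result["class_label"].value_counts().to_dict())
```

which prints

```
{'NS': 1801, 'DOWN': 181, 'UP': 18}
```

181 genes classified DOWN out of 2000 — the pipeline recovers most of
the ~200 genes the generator planted with a −1 log2 TE shift.  Feeding the classified genes into the
group statistics recovers the planted leader differences: the DOWN class
median leader is ~350 nt vs ~140 nt for NS, ~3 percentage points richer
in C, and its pooled G4 density sits several null SDs above random
transcript groups (z ≫ 0).

The classification rule itself, on a single gene:

```python
from leaderscan import classify_gene
classify_gene(0.01, -0.5)   # ('DOWN', frozenset())
classify_gene(0.20, -1.0)   # ('NS', frozenset())
```

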