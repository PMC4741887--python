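# mirprog

Integrative miRNA–mRNA screening of premalignant progression in paired
tissue series (adjacent normal → oral lichen planus → oral squamous cell
carcinoma), for transcriptomics analysts working with deeply sequenced but
replicate-free designs: one small-RNA and one mRNA library per patient per
stage, typically from only two patients.

The package implements, as a tested and reusable pipeline:

- **Quantification** — RPKM (10⁹·C/(N·L)) for mRNA and counts-per-million
  (10⁶·C/N) for miRNA tags; fold changes as log₂ ratios with a pseudocount.
- **Replicate-free differential expression** — the Audic–Claverie exact
  count test. Conditional on count *x* in a library of *N₁* mapped tags,
  the count *y* in an independent library of *N₂* tags follows

  p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),  r = N₂/N₁,

  the negative-binomial law NB(x+1, 1/(1+r)); the two-sided p doubles the
  smaller tail. p-values are Benjamini–Hochberg adjusted per contrast.
- **Progression screening** — a feature is called only if its change is
  sign-consistent across both stage transitions, passes a two-fold cutoff
  on the extreme (normal vs carcinoma) contrast with FDR control, and every
  patient agrees on the direction.
- **Consensus target prediction** — genes predicted by ≥ k prediction-tool
  exports, intersected with the progressively up-regulated genes, then
  required to carry a canonical seed site (6mer / 7mer-A1 / 7mer-m8 / 8mer)
  in their 3′-UTR, ranked by peak abundance and anti-correlation with the
  miRNA; plus a regulator→target narrowing step for downstream effectors.
- **Validation statistics** — 2^−ΔΔCt relative qPCR quantification, the
  weighted immunohistochemistry score c = a×b, Spearman rank correlation
  and the Mann–Whitney U test (exact by enumeration for small samples).
- **A synthetic-data generator** with planted ground truth (suppressed
  miRNAs, rising target genes, seeded UTRs, noisy tool exports), so the
  whole analysis is testable end to end without any external download.

## Worked example

Run the full simulated analysis (generation, screen, target cascade,
validation) with one command:

```sh
mirprog run-all --out-dir demo_run --seed 1
```

which prints the planted-truth recovery metrics of the run:

```json
{"n_called": 11, "n_false_calls": 1, "n_pairs_eligible": 20,
 "n_pairs_planted": 20, "n_pairs_recovered": 20, "n_planted": 10,
 "n_recovered": 10, "pair_recovery": 1.0, "screen_fdr": 0.0909...,
 "sensitivity": 1.0}
```

Reading: all 10 planted progressively suppressed miRNAs were recovered by
the screen, one decoy was called alongside them (9% of calls), and all 20
planted miRNA→target pairs survived the full prediction cascade
(consensus → up-regulated intersection → seed filter). `demo_run/`
contains every intermediate artifact: count tables, the manifest, UTR and
mature-miRNA FASTA, per-tool gene lists, seed-site tables (BED-like,
1-based inclusive), ranked candidates, validation statistics and a
versioned `report.json`; reruns with the same seed are byte-identical.

The seed arithmetic itself is a one-liner. For miR-375
(5′-UUUGUUCGUUCGGCUCGCGUGA-3′, the packaged fixture):

```python
>>> from mirprog import MatureMiRNA, derive_seed_matches
>>> derive_seed_matches(MatureMiRNA("hsa-miR-375", "UUUGUUCGUUCGGCUCGCGUGA"))
{'6mer': 'GAACAA', '7mer-m8': 'CGAACAA', '7mer-A1': 'GAACAAA', '8mer': 'CGAACAAA'}
```

`GAACAAA` is the documented miR-375 binding heptamer in the KLF5 3′-UTR,
and `mirprog scan-utr` locates it at nt 482–488 of the packaged (synthetic
stand-in) KLF5-like UTR.

Other subcommands: `mirprog simulate | screen | predict-targets |
scan-utr | validate-stats | report`. Exit code 2 signals an input
validation error.

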