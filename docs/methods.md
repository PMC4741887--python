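# Methods

## Study design and what the pipeline assumes

The pipeline targets paired tissue series — adjacent normal mucosa, a
chronic premalignant inflammation stage (oral lichen planus, OLP), and
oral squamous cell carcinoma (OSCC) — profiled per patient with one
small-RNA library and one mRNA library per stage. There are no biological
replicates: each (patient, stage, assay) cell is a single library. All
inference is therefore per-library-pair (the replicate-free exact test
below) plus consistency requirements across transitions and across
patients, not a dispersion-estimating model.

Stages carry the fixed order normal < OLP < OSCC. Samples are tied
together by a manifest (sample → patient, stage, assay); every reader
validates against it.

## Quantification

- mRNA: RPKM, `1e9 * C / (N * L)` with C the unique-mapping read count,
  N the sample's total mapped reads and L the transcript length in bp.
- miRNA: counts per million mapped tags, `1e6 * C / N` (tag counts have
  no meaningful length term).
- Fold change: `log2((a + c) / (b + c))` on normalised values with
  pseudocount c = 0.5 by default. The pseudocount makes zeros finite and
  defines 0/0 as fold change 0; it is the only place zeros are special.

## Replicate-free differential expression

Between two libraries the test is the Audic–Claverie exact count test:
conditional on count x in a library of N1 tags, the count y in an
independent library of N2 tags has

    p(y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),    r = N2/N1,

which is the negative-binomial law NB(x+1, 1/(1+r)). The point probability
is evaluated in log space (log-gamma), tails through the NB CDF/SF, safe
for counts up to 1e7. The two-sided p doubles the smaller tail, capped at
1 (the conventional choice; note this definition conditions on x and is
not exactly symmetric under swapping the two libraries — the point
probabilities satisfy p(y|x; N1,N2) = (N1/N2) p(x|y; N2,N1) instead).
p-values within one contrast family are Benjamini–Hochberg adjusted
(statsmodels backend, property-tested against a direct step-up oracle).

A feature is called differential between two libraries when |log2 fold|
≥ 1 (the two-fold cutoff) and q ≤ 0.05. Both thresholds are exposed.

## Progression screening

Per patient, a feature's three stage values yield two transition log2
ratios (normal→OLP, OLP→OSCC) and an overall ratio (normal→OSCC). The
call is

- `down` iff both transitions are negative (a transition of exactly 0
  breaks monotonicity unless `allow_flat_transition`), |overall| ≥ 1, and
  the exact test on the extreme contrast (normal vs OSCC) passes the FDR
  threshold; symmetric for `up`; else `none`.
- The statistical test runs only on the extreme contrast; OLP enters
  through the monotonicity requirement. This encodes "progressive" as a
  monotone trend without inventing a trend test for n = 3.
- A strict mode (`strict_transitions`) additionally requires each
  transition to pass the two-fold cutoff on its own; default off, because
  with a per-stage effect of ±1.5 log2 the per-transition requirement
  roughly halves sensitivity while the overall contrast keeps it.
- BH adjustment is computed over all features within one patient's
  extreme contrast, before thresholding.
- A feature is reported only when every patient's call agrees on the
  direction (consensus veto).

## Target-prediction cascade

For a screened-down miRNA:

1. **Consensus**: keep genes appearing in ≥ k of the supplied per-tool
   prediction exports (k = 3 by default). Tools are never called; their
   exports are plain gene lists, because database versions drift and the
   integration logic is the point.
2. **Intersection** with the progressively up-regulated genes (a
   suppressed miRNA's direct targets are expected to rise).
3. **Seed filter**: the gene's 3′-UTR must contain a canonical seed site
   of at least the configured class (default ≥ 7mer). Site classes, with
   the mature miRNA written 5′→3′ and match strings on the UTR sense
   strand: 6mer = revcomp(nt 2–7); 7mer-m8 = revcomp(nt 2–8); 7mer-A1 =
   revcomp(nt 2–7)+A; 8mer = revcomp(nt 2–8)+A. The trailing A is the
   literal adenosine opposite miRNA position 1. Coordinates are 1-based
   inclusive; overlapping matches at a locus collapse to the most
   specific class (8mer > 7mer-m8 ≥ 7mer-A1 > 6mer). Only the sense
   strand is scanned — UTRs are sense-strand by contract.
4. **Ranking**: primary key descending peak expression (the most abundant
   candidate first), secondary ascending anti-correlation, gene-symbol
   tie-break. Anti-correlation is the Pearson correlation between the
   gene's and the miRNA's per-patient stage-wise log2 ratios relative to
   the normal stage (OLP/normal and OSCC/normal, two points per patient).
   Defined this way, a perfectly opposed pair scores exactly −1; a flat
   profile has zero variance, an undefined correlation (NaN), and ranks
   after all defined values. (Correlating the two *successive-transition*
   ratios instead is degenerate: with two points per patient the sign
   reflects only the ordering of the two transitions, and a mirrored
   falling/rising pair scores +1.)
5. **Downstream narrowing**: intersect the up-regulated gene list with a
   regulator's curated target list (e.g. a pathway-analysis export read as
   a plain gene list) to propose downstream effectors.

Gene symbols are compared case-insensitively after uppercasing, with no
alias resolution — the cascade intersects symbol lists directly.

## Validation statistics

- qPCR: ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt = mean case ΔCt
  − mean control ΔCt (single mean calibrator when several controls);
  fold = 2^−ΔΔCt.
- IHC weighted score c = a·b with a binning percent positive cells
  ({<5, 5–25, 25–50, 50–75, >75}% → 0–4) and b the staining intensity
  0–3. The printed bin boundaries overlap; they are resolved as half-open
  lower-inclusive intervals (25% → grade 2) for determinism.
- Spearman correlation: Pearson on mid-ranks, p from the large-sample
  t approximation with n−2 df; zero rank variance is an error.
- Mann–Whitney U from rank sums with mid-rank ties; exact two-sided p by
  enumerating all C(n1+n2, n1) group labelings when n1+n2 ≤ 12 (default),
  otherwise normal approximation with tie and continuity correction.
- Three-group qPCR comparisons (ANOVA with post-hoc pairwise tests) are
  out of scope; the pipeline reports descriptive group summaries and the
  two-group rank test only.

## Synthetic-data generator

The generator emulates the paired design with planted truth. Counts are
negative binomial: mean = baseline_i · 2^(δ_i·s) · patient_effect, with
stage index s ∈ {0,1,2} and var = μ + φμ². Defaults: 2 patients, 500
miRNAs with 10 planted at δ = −1.5 log2/stage, 5 000 genes with 2 planted
rising targets per planted miRNA (δ = +1.5), depth 10⁶, φ = 0.1. The
per-stage geometric effect makes planted trajectories monotone by
construction; decoys have δ = 0.

Baseline abundances are heavy-tailed lognormal. Decoy miRNAs: median ~30
tags, log-sd 1.5 (real small-RNA libraries are strongly skewed — a few
dominant species absorb most tags while hundreds of annotated miRNAs sit
at low counts). Planted miRNAs: median ~1000, log-sd 0.5 — the biological
archetype is a highly expressed, progressively silenced suppressor miRNA.
Decoy genes median ~20, planted targets median ~200 (abundant targets are
what the ranking step is designed to surface). Library sizes equal the
configured depth; counted features sum to less, as mapped tags always
exceed the annotated subset.

UTRs are i.i.d. uniform ACGT; each planted pair receives its miRNA's
7mer-A1 or 8mer match string at a recorded position, and every other UTR
is regenerated until it carries no ≥7mer match for any planted miRNA (a
cleaning step so chance hits do not contaminate the planted truth).
Prediction exports include each true target with probability 0.9 per tool
and each decoy with probability 0.02, across 6 tools. Validation tables
shift case-group Ct values by −log2(fold) with Gaussian noise (sd 0.3
cycles) and draw IHC percent/intensity so cases stochastically dominate
controls, with two correlated markers per sample.

Everything is driven by one integer seed through `numpy.random.default_rng`
streams; equal seeds give bit-identical outputs.

What the generator does **not** emulate: mapping artifacts, GC/length
biases, inter-patient biological variability of baselines (baselines are
shared across patients; only a small lognormal patient factor and NB noise
differ), cross-correlated miRNA families, and sequence-composition realism
of UTRs. Passing tests therefore demonstrate the pipeline's logic and
calibration under a controlled noise model, not performance on real
libraries.

## Calibration and a known limitation

On Poisson null pairs the exact test is calibrated-to-conservative
(measured rejection at 0.05: ≈3.2% at mean 5, ≈4.4% at mean 50, ≈5.1% at
mean 500). Under the generator's negative-binomial counts (φ = 0.1) the
Poisson assumption is violated and the test is anticonservative: abundant
features reach tiny p-values from biological-scale noise, so FDR control
within the screen shifts from the q-threshold to the fold-change and
monotonicity filters. Consequence, measured on the default design: the
screen recovers 9–10 of 10 planted miRNAs per run, but on average ~2 of
~500 decoys are also called (both patients showing a coincident monotone
two-fold drift), i.e. a realized false-discovery fraction around 10–20%
of calls. This is an intrinsic property of running a replicate-free
Poisson-based test on overdispersed data, and the generator deliberately
exposes it; analysts wanting stricter control should raise
`min_abs_log2fc` or enable `strict_transitions` (at a sensitivity cost).

## Problem sizes and numerical choices

The default simulated design (500 + 5 000 features, 12 libraries, ~2 s
end to end) is the scale at which all planted-truth checks run; oracle
equivalence suites use 1 000 random scanner cases and 10 000 null pairs
per Poisson mean. Tolerances: probability sums to 1 within 1e-9; oracle
comparisons to float precision; stochastic recovery checks use 3-SE
binomial bounds. Ties and degenerate inputs: mid-ranks everywhere ranks
appear; zero-variance correlations are errors (Spearman) or NaN ranked
last (candidate ranking); 0/0 fold changes are 0; flat transitions break
monotonicity unless explicitly allowed.
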