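# Methods

## The inference chain

The package reconstructs a classic microarray-era inference chain from
paired case/control expression profiles to a competing-endogenous-RNA
(ceRNA) network. The chain is, in order:

1. **Preprocessing.** Genes whose log2 intensity never strictly exceeds a
   background floor (default 4.0, in at least 1 sample) are removed.
   miRNA arrays are quantile-normalized: the value at rank *k* in every
   sample becomes the mean across samples of each sample's *k*-th order
   statistic; ties within a sample receive the mean of the reference values
   at their tied ranks, which makes the transform idempotent and
   rank-preserving. lncRNA/mRNA arrays pass through unchanged by default
   (they are assumed already vendor-normalized; `Config.normalize_lnc_mrna`
   switches quantile normalization on).
2. **Differential screening.** Per gene, the two-sided paired *t*-test over
   case/control sample pairs and the fold change 2^|Δmean| of the log2
   group means. A gene passes at linear FC strictly > 2.0 (lncRNA/mRNA) or
   > 1.5 (miRNA) and p ≤ 0.05. No multiple-testing correction is applied by
   default, matching the screening practice the pipeline emulates;
   Benjamini–Hochberg is available behind `Config.apply_bh`. Zero-variance
   genes are reported with a `degenerate` flag (p evaluated at
   machine-limit variance) rather than dropped.
3. **Enrichment.** Upper-tail hypergeometric probability
   P(X ≥ k) for k DE genes among K term members in a universe of N with n
   DE genes. The universe is the background-filtered gene set. Term maps
   are user-supplied two-column TSVs; no GO DAG propagation is performed.
4. **Co-expression (CNC) network.** Pearson correlation over all arrays
   (case and control pooled) for every cross-biotype pair among DE-passing
   genes; an edge is kept at |r| strictly > 0.90 and p strictly < 0.01,
   with p from t = r·√((n−2)/(1−r²)) on n−2 df. Pooling both groups is a
   deliberate choice (the emulated design leaves it open); note that group
   mean shifts then contribute to correlation, which is exactly what makes
   co-expression networks over DE genes permissive — the ceRNA intersection
   downstream is what restores specificity.
5. **Target evidence.** (a) miRNA targeting by the canonical 7mer seed
   rule: exact occurrence of the DNA reverse complement of miRNA positions
   2–8 in an mRNA 3′UTR or a lncRNA transcript. (b) cis lncRNA targets:
   lncRNA–mRNA pairs whose genomic intervals lie within a 10 kb gap
   (inclusive, strand-blind, 0 for overlap). (c) trans lncRNA targets: an
   11-mer seed-and-extend ungapped local aligner (match +1, mismatch −3,
   X-drop 10, minimum identity 0.90, minimum length 20). This is a
   transparent, fully testable screen with BLAT-like defaults; it performs
   the same role as a default-parameter BLAT similarity screen without
   gapped alignment or genome-scale indexing. (d) TF binding: IUPAC
   consensus or PWM scanning of the window from 2000 bp upstream to 500 bp
   downstream of each lncRNA's transcription start (strand-aware; the TSS
   of a − strand gene is its interval end − 1). PWM windows score
   Σ log2(p/0.25) and hit at ≥ 0.8 of the motif's maximum score.
6. **ceRNA construction.** The five-step intersection: (1) negatively
   correlated miRNA–mRNA pairs where the mRNA carries a seed match;
   (2) negatively correlated miRNA–lncRNA pairs where the lncRNA carries a
   seed match (its miRNA response element); (3) positively correlated
   lncRNA–mRNA pairs; (4) lncRNA–mRNA pairs sharing a miRNA across (1)
   and (2); (5) the intersection of (3) and (4). All edge types use the
   same |r|/p thresholds; all nodes must be DE-passing.
7. **Validation statistics.** 2^−ΔΔCt relative quantification with
   per-biotype reference genes (U6-like for miRNA, actin-like otherwise):
   ΔCt = Ct_gene − mean(Ct_refs) per sample, ΔΔCt against the control-group
   ΔCt mean (so the control mean fold is 1 by construction), p from a
   two-sided pooled two-sample *t*-test on ΔCt (fold-scale testing behind a
   flag; ΔCt-scale is statistically preferable because ΔCt is the
   approximately normal quantity). Study power for the two-sample design is
   computed exactly from the noncentral t distribution,
   ncp = d·√(n/2), df = 2n−2 — at d = 1.523, n = 8/group, α = 0.05,
   two-tailed, this gives 0.808 (0.81 at two decimals).

## The synthetic generator

No real microarray data ships with the package; every analysis runs on the
generator in `cerna_forge.simulate`, which emulates the study design and
records everything it plants in a `TruthTable`.

* **Design.** Three log2-intensity matrices (lncRNA/mRNA/miRNA) over the
  same paired samples; 10 pairs by default. Baselines are N(8, 1.5²) per
  gene, i.i.d. N(0, 0.3²) noise per measurement.
* **Differential expression.** Planted DE genes receive ±`de_log2fc`
  (default 2.0) added to case samples.
* **ceRNA triplets.** Each planted triplet has one latent regulator level
  per *sample pair*, loading +λ on the miRNA and −λ on the lncRNA and
  mRNA, with λ chosen so the implied correlation
  λ²/(λ²+σ²) equals `implied_r` (default 0.95). The latent level is
  matched within a pair — the shared biological state of two matched
  animals — so it cancels in paired differences and planted co-expression
  does not mask planted differential expression; across pooled samples it
  produces the (+,−,−) sign pattern the ceRNA construction screens for.
  Triplet members are forced DE by default, with the miRNA shifted opposite
  to its lncRNA/mRNA partners so group shifts reinforce rather than destroy
  the planted signs.
* **Sequences.** Uniform-composition random nucleotides; each planted seed
  site writes the reverse complement of the triplet miRNA's seed into the
  target at a recorded offset, and TF consensus motifs are written into
  lncRNA promoter windows. Default lengths: 22 nt miRNAs, 400 nt lncRNA
  transcripts, 300 nt 3′UTRs, 2500 nt promoter windows.
* **Scale.** Default pools are 500 lncRNAs, 800 mRNAs, 300 miRNAs with 20
  DE genes per biotype — desk-scale but platform-like proportions. The DE
  fraction (~4%) matters: quantile normalization assumes most genes are
  unchanged, and a generator with a large DE fraction would make the
  normalization itself distort planted correlations.
* **qPCR.** Ct tables with per-sample global shifts (cancelled by reference
  normalization), reference genes with zero effect, and a gene with planted
  log2 effect *e* giving case-vs-control ΔΔCt ≈ −e, hence mean fold ≈ 2^e.

**What the generator does not emulate:** probe-level artifacts, scanner
noise, intensity-dependent variance, batch structure, correlated null genes,
non-uniform sequence composition, isoform structure, or the intensity
distributions of any real platform. Recovery results on this generator
demonstrate that the pipeline's screens compose correctly around planted
signal at realistic noise levels — not that the thresholds are well
calibrated for any particular real dataset.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere (GFF3 input converted at the
  boundary); expression is log2 scale throughout; id matching is exact and
  case-sensitive.
* Threshold boundaries follow the screening conventions exactly as printed
  in the emulated design: FC strict (>), DE p inclusive (≤), |r| strict
  (>), correlation p strict (<), cis window inclusive (≤ 10 kb).
* |r| = 1 maps to p = 0 exactly; −log10 p in volcano output is capped
  (default 300) with a flag.
* Correlations with zero-variance vectors are an error at the kernel level;
  the network builder excludes such genes with a log entry.
* Hypergeometric tails use the survival function of the exact
  distribution, not a normal approximation; ties in enrichment p are broken
  lexicographically by term id for determinism.
* PWM log-odds use a 10⁻³ probability floor so motifs with zero cells keep
  finite scores.
* The paired t statistic with zero-variance nonzero differences is
  evaluated at machine-limit variance and flagged, keeping such genes
  auditable instead of silently dropped.
* All generators are pure functions of `(spec, seed)`; derived stage seeds
  are offsets of the spec seed.

## Problem sizes

Tests and the reproduction script run the full pipeline on the default
generator (1600 genes, 20 samples) across 20 independent datasets, verify
the ceRNA intersection against an exhaustive triple-loop oracle on 50
random instances of up to 200 genes, and check the statistical kernels
against numerical-integration and Smith–Waterman oracles on 1000 random
inputs each. These sizes keep a complete run in tens of seconds while
leaving the sampling error of recovery estimates well below the margins
asserted.

## Known limitations

* The trans-target aligner is ungapped; diverged similarities that require
  indels are invisible to it.
* Only the 7mer seed class is implemented (the `match_type` field is the
  extension point for 6mer/8mer classes).
* Enrichment treats term maps as flat; ontology-aware propagation would
  change K and k for nested GO terms.
* With 3 sample pairs (the pooled-n=6 regime the emulated design used for
  its CNC network), correlation screening at |r| > 0.90 retains ~1% of
  null pairs by construction of the p < 0.01 cut; the low-power warning the
  network builder logs for n < 8 is there for a reason.
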