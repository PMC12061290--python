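# Methods

## Barcode model and demultiplexing

A cell barcode is the concatenation of four whitelist segments (6+6+6+10 bp
= 28 bp) read from position 0 of the barcode-bearing mate (read 1 by
default; the mate and segment order are configurable since the assay
description fixes only the 5′ placement). The canonical identifier joins
corrected segments with `+` in read order.

Correction capacity is governed by each segment whitelist's minimum
pairwise Hamming distance: at distance ≥ 3, every sequence within one
mismatch of an entry has a unique nearest entry, so one-mismatch rescue is
unambiguous. `build_whitelist` measures this exactly and warns below 3;
the ambiguity policy itself lives in demux, which rejects ties rather than
breaking them (no quality-weighted tie-break is defined).

The quality gate "barcode quality < 10 removed" is interpreted as the
**minimum** base quality over the 28 prefix bases (strictest reading); a
mean-quality mode is provided because the statistic is not pinned down.
Gating precedes correction. Segments are corrected independently, so up to
four single-base errors (one per segment) can be rescued. Correction uses a
precomputed distance-≤1 neighbor table, which is exactly equivalent to an
exhaustive Hamming scan (property-tested against one).

## Fragments and scATAC QC

Tn5 tagmentation duplicates 9 bp at each insertion; the raw template
[start, end) becomes [start+4, end−5), so every corrected fragment is 9 bp
shorter than its template and templates under 10 bp are dropped (counted).
Coordinates are 0-based half-open throughout; insertion sites are the
fragment start and end−1. Mapping quality < 2 is filtered before pairing;
chrY/chrM are excluded case-insensitively via an alias list; duplicates are
collapsed on (chrom, start, end, barcode) with a count, keeping identical
coordinates from different cells distinct.

TSS enrichment follows the common fold-over-flank recipe (the source
protocol defers to a published framework's default): insertion counts in a
strand-oriented ±2 kb window around all TSSs, score = mean over the central
101 bp divided by the mean over the outermost 100 bp of each flank, with
the background floored at 0.1 to avoid division by zero. Cells pass QC with
TSS score > 10 **and** unique fragments > 1500, both strict.

## RNA matrix

Cells with < 500 transcripts or > 20% mitochondrial counts (identifier
prefix, default `mt-`) are removed; the two filters commute. Normalization
is `ln(CPM/100 + 1)` = ln(counts-per-10k + 1), so a cell expressing a
single gene maps it to ln(10001) ≈ 9.2105. HVGs are ranked by
variance/mean dispersion z-scored within 20 equal-frequency mean bins
(bin count unstated upstream; fixed here), ties broken by gene identifier.
Gene-set scores use the mean-minus-binned-control construction (25 bins,
50 seeded controls per set gene); the ribosomal-protein score applies it to
`Rps*`/`Rpl*` genes. Scores operate on the ln-normalized matrix only — the
upstream total-UMI regression and per-gene clipping are deliberately not
reproduced (documented divergence). The matched-pair co-expression score is
the per-gene product of two cell-type mean normalized profiles.

## CCAT entropy

CCAT approximates network (signaling) entropy as the per-cell Pearson
correlation between expression and PPI connectome degree over shared genes
(≥ 10 required). Degrees are used raw by default (log-degree available);
the score is invariant to per-cell positive affine transforms. Cross-species
matrices are first projected through the homology weight matrix W: binary
incidence over (source gene, human gene) pairs, each human-gene **column**
normalized to sum 1 — "normalized to one human gene" is read as
per-human-gene normalization; row-normalization is the flagged alternative.
Mouse-only analyses may pass an identity map. The full signaling-entropy
rate that CCAT approximates is out of scope.

## Pseudo-cells and neighbor-voting AUROC

Pseudo-cells sum raw counts over seeded, disjoint groups of exactly `size`
(default 100) cells from one cluster; remainders are dropped (configurable
to absorb), sub-size clusters skipped. Summing-then-normalizing was chosen
over averaging normalized values (unstated upstream; flagged).

Matching: over shared (optionally HVG-restricted) genes, each B sample's
Spearman correlations to all A samples are rank-standardized to [0, 1];
the vote of B sample b for A type t is its mean standardized correlation to
A samples of type t; the (t, s) entry is the Mann–Whitney AUROC (average
ranks on ties) of those votes for B samples of type s versus the rest.
Rank-based throughout, hence invariant to monotone transforms. Pairs with
AUROC strictly > 0.9 count as consistent. Types with < 2 samples are
excluded.

## Optimal transport

Couplings between adjacent timepoints minimize
⟨C, π⟩ + ε·KL(π‖a⊗b) + λ₁·KL(π1‖a) + λ₂·KL(πᵀ1‖b), with a the
growth-weighted source distribution (growth defaults to 1 ⇒ uniform;
`growth_iters = 1` means no re-estimation loop), b uniform over target
cells, and C the squared Euclidean distance on the top 30 joint principal
components of the ln-normalized HVG matrix, normalized by its median (the
cost space is unstated upstream; raw gene space is available). The solver
is log-domain Sinkhorn scaling with the unbalanced exponent λ/(λ+ε),
tolerance 1e-8 on the dual change, max 5000 iterations; non-convergence is
reported in a flag, not raised. The KL(π‖a⊗b) form of the entropy term
makes the large-ε limit the outer product a⊗b.

The returned coupling is rescaled to total mass 1 (the raw unbalanced
minimizer sits ~1–2% below 1 because the λ₁ = 1 source penalty is soft;
the raw mass is kept as a diagnostic). Every downstream operation —
row-normalized Markov composition, ancestor pull-back, membership — is
invariant to that rescaling. With λ₂ = 50 the column sums stay within 1%
of the uniform target marginal.

Long-range couplings are Markov products of row-normalized factors;
pull-back propagates the normalized target indicator backward and
re-normalizes per timepoint, so composed and sequential pull-back agree to
float precision. Trajectory membership applies the strict > 0.00025 rule to
the normalized ancestor distribution. Ancestor divergence is
0.5·Σ|pᵢ−qᵢ| ∈ [0, 1]. Gene trends are distribution-weighted mean
expression per timepoint. Driver ranking is the per-gene Pearson
correlation with a fate-probability vector (from pull-forward distributions
or an external file — macrostate detection itself is out of scope);
zero-variance genes rank last as undefined.

## Synthetic data: what it emulates and what it does not

The generators state one fixed world per stage:

- **Reads**: whitelists rejection-sampled to pairwise Hamming ≥ 3
  (24/24/24/96 entries — the Tn5 plate has 96 wells; bead-round sizes are
  a desk-scale choice), 50-bp reads, 0.1% substitution rate. Errored bases
  get Q14 and clean bases Q37, so errors pass the Q10 gate and exercise
  the rescue path. No indels, quality ramps, or chimeras.
- **Alignments**: a four-chromosome toy genome; "good" cells place 90% of
  2500 fragments within N(0, 25 bp) of a TSS, background cells 300 uniform
  fragments; planted duplicate pairs; a sprinkle of chrY/chrM fragments.
  Separation is deliberately wide, so passing QC here establishes the
  plumbing and thresholds, not discriminative power at realistic depth.
- **Time course**: 4 timepoints × 500 cells, one root splitting into
  branches A/B at the second timepoint; negative-binomial counts
  (gamma–Poisson, dispersion 0.1, library size 3000) around log-mean
  programs; 40 drivers per branch gaining +1 log-mean per stage; 50 hub
  genes boosted +1.5 in a 25% "high-potency" population wired as
  connectome hubs; RP and cell-cycle modules pulsing at fixed stages.
  Branches are fully separated by design, so ancestor recovery ≈ 1 is the
  expected outcome, not a measured sensitivity; no doublets, ambient RNA,
  batch effects, or growth-rate asymmetry.

A green test on these fixtures establishes correctness of the computations
and thresholds on a world with known truth; it does not establish
performance on real data.

## Numerical choices

- Hamming distances computed exactly (vectorized byte comparison).
- TSS background floor 0.1; zero-fragment cells score 0 and are flagged.
- HVG/qcut bins deduplicate degenerate edges; z-score falls back to 0 for
  single-gene bins.
- Pearson/Spearman zero-variance vectors: CCAT scores NaN (flagged),
  neighbor voting assigns zero correlation (all ties ⇒ AUROC 0.5),
  driver correlation ranks NaN last.
- Sinkhorn runs entirely in log space; deterministic given inputs.
- All randomness flows through `numpy.random.default_rng(seed)`; file
  outputs use deterministic gzip (no name/mtime) so identical seeds give
  byte-identical artifacts.

## Known limitations

- The TSS-enrichment construction and the OT cost space are reasonable
  defaults for procedures the upstream description leaves to external
  frameworks; absolute score values depend on those choices.
- CCAT is implemented from its documented definition (transcriptome–
  connectome correlation), not by porting SCENT internals.
- The neighbor-voting implementation covers the cell-type replicability
  AUROC only, not gene-set variants.
- Peak calling, LSI, clustering, embedding, velocity, and macrostate
  detection are intentionally absent — published tools own those stages.
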