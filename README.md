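# fatemap

A toolkit for the bespoke computational stages of chemically induced
multi-lineage trans-differentiation (iMT) single-cell studies, where mouse
embryonic fibroblasts are converted into several somatic lineages at once
and profiled over a multi-week time course with combinatorial-barcode
Microwell scATAC-seq and scRNA-seq.

It covers the two places where off-the-shelf pipelines stop:

**scATAC preprocessing for combinatorial split-pool barcoding.** A nucleus
is identified by a 28-bp prefix on the barcode-bearing mate — three 6-bp
bead-round segments plus one 10-bp Tn5-plate segment. The toolkit models
the read structure and per-segment whitelists, gates on barcode base
quality (< Q10 removed), corrects each segment independently allowing one
mismatch (ambiguous corrections rejected), trims the prefix, applies the
Tn5 +4/−5 insertion-site shift ([s, e) → [s+4, e−5)), deduplicates
fragments per cell, excludes chrY/chrM, and computes per-cell TSS
enrichment, keeping cells with TSS score > 10 and > 1500 unique fragments.

**Quantitative fate dynamics.**

- *CCAT potency entropy*: per cell, the Pearson correlation between the
  expression vector and the degree vector of a PPI connectome, after
  projecting through a cross-species homology weight matrix `W`
  (binary homology incidence, each human-gene column normalized to sum 1).
- *Cell-type matching across platforms*: pseudo-cells summed from 100 cells
  per cluster, neighbor voting on the cross-dataset Spearman network, and
  the strict mean-AUROC > 0.9 consistency rule.
- *Time-course ancestor inference*: unbalanced entropic optimal transport
  between adjacent timepoints, minimizing
  `⟨C, π⟩ + ε·KL(π‖a⊗b) + λ₁·KL(π1‖a) + λ₂·KL(πᵀ1‖b)`
  with λ₁ = 1, λ₂ = 50, ε = 0.05 (log-domain Sinkhorn scaling); Markov
  composition of couplings, ancestor pull-back, the strict 0.00025
  trajectory-membership threshold, ancestor divergence as half the total
  variation distance, distribution-weighted gene trends, and driver-gene
  ranking by correlation with fate probabilities.

scRNA support stages: ≥ 500-transcript and ≤ 20%-mito cell QC,
`ln(CPM/100 + 1)` normalization, mean-binned-dispersion HVG selection,
control-bin gene-set scores (cell cycle, ribosomal proteins), and the
per-gene product score for matched cell-type pairs.

A first-class synthetic-data module generates every input — barcoded reads
with per-base errors, toy paired alignments with known insertion sites, and
multi-timepoint count matrices with planted branching, drivers, and a
high-connectome-degree population — each with a ground-truth table.

## Worked example

```python
from fatemap import (SimConfig, simulate_reads, demux_fastq,
                     simulate_timecourse, normalize_ln_cpm100,
                     OTParams, fit_chain, pull_back, ancestor_divergence)

cfg = SimConfig(seed=1, n_read_pairs=100_000, error_rate=0.001)
wl, truth, _, _ = simulate_reads(cfg, out_r1="r1.fastq.gz", out_r2="r2.fastq.gz")
stats, assignments = demux_fastq("r1.fastq.gz", "r2.fastq.gz", wl)
print(stats.assigned, stats.total)          # 99988 100000

adata, truth_tc, edges, homology = simulate_timecourse(SimConfig(seed=1))
normalize_ln_cpm100(adata)
chain = fit_chain(adata, params=OTParams())  # lambda1=1, lambda2=50, eps=0.05
obs = adata.obs
targets = list(obs.index[(obs.timepoint == "D35") & (obs.branch == "A")])
ancestors = pull_back(targets, chain, "D35")
p = ancestors["D6"].probabilities
print(p[(obs.loc[p.index, "branch"] == "A").to_numpy()].sum())  # 1.000
```

At a 0.1% per-base error rate, 99,988 of 100,000 read pairs are assigned
(the remainder carry ≥ 2 errors in one segment and are uncorrectable), and
every assignment matches the simulator's truth barcode. On the planted
two-branch time course, pulling the branch-A terminal cells back through
the couplings places essentially all ancestor mass (1.000) on branch-A
cells at the first post-split timepoint, and the A-vs-B ancestor
divergence (0.5 × total variation) is 1.000 — fully separated lineages.

The same stages are available from the shell:

```sh
fatemap simulate reads --seed 1 --out-dir sim/
fatemap demux --r1 sim/r1.fastq.gz --r2 sim/r2.fastq.gz --whitelist-dir sim/ --out-dir demux/
fatemap simulate alignments --seed 1 --out-dir aln/
fatemap fragments --bam aln/alignments.sam --tss aln/tss.bed --out-dir frags/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on seeded synthetic data — 100k-read
demultiplexing with truth comparison, fragment construction and cell QC,
normalization and HVG selection, homology-weighted CCAT, pseudo-cell
AUROC matching, and the two-branch ancestor pull-back — logging each
stage's summary statistics to stderr and writing the results file.
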