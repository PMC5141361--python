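# mirpathnet

Reconstruction of mixed transcriptional / post-transcriptional regulatory
networks from matched miRNA and gene expression profiles of two or more
sample classes — e.g. a disease cohort against two control tissues.

The package is aimed at systems-biology analysts who have (i) summarized
log2 expression matrices for genes and miRNAs, (ii) pathway topologies as
typed edge lists, (iii) miRNA target-prediction and validated-target tables
and (iv) TF→miRNA / TF→gene regulation catalogs, and want a reproducible,
seedable pipeline that turns them into a single annotated regulatory
network. A seeded synthetic-data generator with known ground truth makes
every stage testable without any external download.

## Method

For each case-vs-control comparison, run independently and then merged:

1. **Feature filtering.** miRNAs weakly expressed (mean below the 25%
   empirical quantile of per-feature means) and/or poorly variable
   (Shannon entropy of the profile, 10 equal-width bins, below 1.4 bits)
   are removed.
2. **Anticorrelation-supported targeting.** Predicted miRNA→gene pairs
   (prediction score ≥ 0.8) are kept when Pearson *r* < −0.5 with
   Benjamini–Hochberg FDR < 0.1 over the tested family.
3. **miRNA-augmented pathway analysis.** Pathway graphs are enriched with
   validated and supported miRNA→target edges, moralized, triangulated
   (min-fill) and decomposed into a junction tree. Two permutation
   statistics computed under the pathway's Gaussian graphical model — a
   mean statistic *T*<sub>m</sub> = (n₁n₂/n) · d′K̂d (d the class mean
   difference, K̂ the pooled GGM concentration) and a variance statistic
   (log-likelihood ratio of class-specific vs. pooled GGM fits) — flag
   deregulated pathways at q ≤ 0.1 (either test). Within significant
   pathways, leaf-to-leaf clique paths are scored by the mean of
   −log₁₀ min(p<sub>mean</sub>, p<sub>var</sub>) over their cliques; the
   union of the top 10 paths (the *meta-pathway*) is re-analyzed and the
   upper quartile of its path scores is reported.
4. **Feed-forward circuits.** TF–miRNA–gene triangles of two topologies
   (TF master: TF→miRNA, TF→gene, miRNA⊣gene; miRNA master: miRNA⊣TF,
   miRNA⊣gene, TF→gene) are enumerated from the catalogs, kept when all
   three pairwise |r| ≥ 0.5, classified coherent/incoherent by sign
   algebra, and linked to the pathway-derived network when they share a
   node with it.
5. **Assembly.** Per-comparison networks are merged by union on node id and
   (src, dst, edge-type); every node carries one log2 fold-change slot per
   comparison and a provenance set. Exports: GraphML and JSON (lossless),
   SIF (Cytoscape-loadable topology).

## Worked example

```bash
python examples/03_pathway_analysis.py
```

prints, for the default synthetic study (three 25-node pathways, a 5-gene
path in `pw1` shifted by +1.5 σ in the case class, 30 samples per class):

```
pw1: q_mean=0.006 q_var=0.824 <-- significant
pw2: q_mean=0.208 q_var=0.824
pw3: q_mean=0.060 q_var=0.102 <-- significant
top path in pw1: score=2.70, nodes=['G0001', 'G0002', 'G0003', 'G0004', 'G0005']
planted path:    ['G0001', 'G0002', 'G0003', 'G0004', 'G0005']
```

The planted pathway is flagged (q_mean = 0.006; `pw3` is a false positive
of this particular seed) and the top-scoring clique path coincides exactly
with the planted cascade; its score 2.70 is the permutation floor
−log₁₀(1/501) at 500 permutations. The other examples
(`examples/01…05_*.py`) walk through filtering, target support, circuit
discovery and the full pipeline the same way, each printing the recovery of
the planted truth.

The CLI mirrors the pipeline for shell use:

```bash
mirpathnet simulate --seed 1 --out bundle/
mirpathnet run-all --config config.yaml --seed 1 --verbose
```

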