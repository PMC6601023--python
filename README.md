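# mirpath

Reusable, tested pipeline for in-silico discovery of miRNA target pathways in
disease tissue — built around the leiomyoma/myometrium paired-cohort design,
but generic over any paired case/control study with a candidate miR.

It answers four questions a systems-biology analyst asks in sequence:

1. **Which miRs are aberrantly expressed?** Paired differential-expression
   screen on a features × samples matrix with patient-matched case/control
   samples: per-pair fold changes (geometric mean of ratios, reported as a
   magnitude ≥ 1 plus a direction), paired t-test on log2 differences,
   Benjamini–Hochberg FDR, FC cut-off filtering, and complete-linkage
   Euclidean clustering.
2. **Do the miR's predicted targets overlap known disease genes?** Exact
   hypergeometric upper-tail test: for a universe of N genes, K predicted
   targets and n disease genes sharing k, p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)
   (equivalently a one-sided Fisher exact test). The default universe of
   19,000 ≈ annotated human protein-coding genes and is printed in every
   report.
3. **Do the targets predict disease genes through the interaction network?**
   Seed-based propagation on a STRING-style confidence-weighted network:
   either a one-step naïve-Bayes evidence sum s(g) = Σ_{u∈seeds∩N(g)}
   log(1 + w(g,u)), or random walk with restart
   F ← αW′F + (1−α)F₀ on the symmetrically normalized adjacency
   W′ = D^(−1/2) W D^(−1/2). Candidates are ranked and validated by the AUC
   against a held-out disease gene list (rank-sum formula, midrank ties),
   with label-permutation and permuted-seed nulls.
4. **Do the follow-up assays confirm it?** Comparative-Ct (2^(−ΔΔCt))
   relative quantification, wound-closure percentages, gel-contraction
   ratios, and exact small-sample tests (enumerated Mann–Whitney U and
   Wilcoxon signed-rank, Student/Welch t — including a summary-statistic
   mode for published mean ± SEM tables).

A synthetic-data module generates every input — scale-free networks with a
planted disease module, seed/validation gene sets with controlled overlaps,
paired log-normal expression with planted fold changes, Ct tables with known
group shifts — so the whole pipeline is testable end to end with no
downloads.

## Worked example

Generate a synthetic cohort and run each stage:

```bash
mirpath simulate --seed 1 --out demo
mirpath diffexpr --values demo/expression.tsv --meta demo/metadata.tsv --out demo/de.tsv
# -> wrote DE report for 500 features to demo/de.tsv
mirpath prioritize --network demo/network.tsv --seeds demo/seed_genes.txt \
    --validation demo/validation_genes.txt --out demo/prio
# -> AUC 0.7034 (11 positives, method naive_bayes)
mirpath assay --ct demo/ct.tsv --out demo/assay.json
```

The DE summary reports that the FC ≥ 1.5 + p < 0.05 filter keeps exactly the
6 planted features (`"fc_1.5": {"raw": 6, "with_p": 6}`). The prioritization
summary shows the planted module is recovered well above chance (AUC 0.7034
for 11 held-out validation genes, the one seed∩validation gene excluded from
the positives). The assay output recovers the planted 1.6-cycle shift:

```json
"delta_delta_ct": 1.584,  "rel_expression": 0.334
```

i.e. the target is expressed at about one-third the control level.

In the library, the canonical target/disease gene-set overlap test reads:

```python
>>> from mirpath import hypergeometric_tail
>>> round(hypergeometric_tail(N=19000, K=378, n=109, k=7), 3)
0.006
```

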