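# floranet

Network inference for early flower development: the combined action of
master-regulator transcription factors and microRNAs on the
transcription-factor genes of the *Arabidopsis thaliana* floral program.

`floranet` is for systems biologists who have (or simulate) per-TF ChIP
peak tables, stage-series mRNA/miRNA expression, miRNA-target tables,
and domain translatomes, and who want to go from those tables to a typed
regulatory "meta-network" and its quantitative readouts:

* **Target assignment** — a gene is a TF target when a binding event
  (peak summit, else midpoint) lies within 3 kb of its strand-aware TSS;
  co-binding is scored by base-pair Jaccard, co-regulation by a
  hypergeometric test of target overlap.
* **Meta-network** — a directed graph with node roles {regulator, miRNA,
  TF target} and edge types {binds, silences}, assembled from target
  assignments and a miRNA→mRNA table.
* **Motif census** — autoregulation, feedback pairs, and the 13
  connected directed triad classes, with enrichment z-scores and
  empirical p-values against degree-preserving, edge-type-restricted
  rewiring nulls (the feed-forward-loop topology is triad 030T).
* **Feed-forward loops** — triples where a regulator binds both a miRNA
  and that miRNA's target TF; classified *coherent/incoherent* from arm
  signs (the miRNA arm is always repressive: indirect sign =
  −sign(regulator→miRNA); coherent iff it equals the direct-arm sign),
  and *dynamic* when the miRNA is differentially expressed or a binding
  score changes ≥ 2-fold across stages.
* **Robustness** — betweenness-cascading attack curves; connectivity
  loss 1 − R/R0 over originally connected pairs; KS comparison of the
  network with vs without miRNA-mediated edges.
* **Domain-specific genes** — ANOVA + 2-fold classification of AP1/AP3/AG
  translatomes into five organ categories, floral-quartet target sets,
  and the fraction of domain-specific genes bound by ≥ 2 TFs.
* **Binding→expression model** — Lasso fit of inter-domain log2 fold
  change on normalized per-TF binding scores,
  `Y_i = Σ_j β_j x_ij + ε_i`, penalty chosen by 5×10-fold
  cross-validation (one-SE rule).
* **Synthetic data** — a generator that plants all of the above (network
  scale 15 regulators / 144 miRNAs / 674 TF genes with 422 + 273 typed
  edges, FFLs with a known dynamic fraction, hubs, domain categories,
  PPI enrichment, sparse regression truth) and exports the ground truth
  for exact scoring.

See `docs/methods.md` for the full model description, parameter
defaults, and limitations.

## Worked example

Simulate a study at the published scale and run the whole pipeline:

```bash
floranet simulate --seed 1 --outdir demo/data
floranet run --config run.json      # {"data_dir": "demo/data", "out_dir": "demo/out", "seed": 1}
```

or drive the library directly:

```python
from floranet import (GeneratorConfig, generate_all, assign_targets,
                      build_meta_network, motif_enrichment, find_ffls)

bundle = generate_all(GeneratorConfig(seed=1))
peaks = [p for plist in bundle.peaks.values() for p in plist]
assignments = assign_targets(peaks, bundle.annotation)   # 3 kb TSS rule
```

On seed 1 the pipeline reports (as printed by `scripts/acceptance.py`):

```
meta_network_nodes            788
tf_mirna_edges                422      # regulator -> miRNA binding
mirna_tf_edges                273      # miRNA -> TF silencing
autoregulator_count           11 / 15
ffl_count                     170
ffl_motif_z                   4.13     # 030T vs 200 rewired networks
dynamic_ffl_percent_planted   74.0     # planted truth: 74.0
domain_specific_gene_count    1013
domain_bound_fraction_percent 66.9     # bound by >= 2 TFs
lasso_selected_tf_count       4        # exact planted support
lasso_coefficient_rmse        0.052
```

Reading: the assembled meta-network reproduces the planted study scale
exactly; the FFL topology is significantly enriched over the
degree-preserving null (z ≈ 4); 74% of planted loops are recovered as
developmentally dynamic, matching the planted fraction; the domain
classifier recovers all 1013 planted category genes, of which 66.9% are
bound by at least two regulators; and the Lasso recovers exactly the
four planted nonzero TF coefficients with RMSE ≈ 0.05.

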