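# assemblage

Community-succession analysis for plastisphere microbiomes — the
microbial biofilms that colonize plastic substrates in lakes and other
waterbodies — built for marker-gene (ASV-level) surveys spanning several
sites, substrate types and colonization times.

Given an ASV count table, sample metadata (lake, day, polymer, fraction),
a phylogeny and optional environmental variables, the package computes:

- **Alpha diversity**: species richness and rooted Faith's PD, with
  grouped trajectories over colonization time.
- **Beta-diversity partitioning**: Bray–Curtis and Sørensen
  dissimilarities, Baselga's decomposition β_SOR = β_sim + β_SNE, and the
  turnover/nestedness dominance statistic β_ratio = β_sim/β_SOR (> 0.5:
  species turnover dominates; < 0.5: nestedness).
- **Assembly-process inference**: abundance-weighted βMNTD, the βNTI
  tip-shuffle null (|βNTI| > 2 ⇒ selection, sign separating heterogeneous
  from homogeneous), Raup–Crick with Bray–Curtis (|RC| > 0.95 ⇒ dispersal
  limitation / homogenizing dispersal, else drift), and per-group process
  fractions with homogenizing vs differentiating aggregates.
- **Succession statistics**: time-decay of similarity (log–log turnover
  rate), sequential multi-factor PERMANOVA with interactions and strata,
  Mantel tests against environmental distances, and a convergence-trend
  statistic (per-lake slope of cross-polymer dissimilarity against day —
  negative means communities on different polymers grow alike).
- **A synthetic study generator** reproducing the 4-lake × 8-polymer ×
  5-day design (160 plastisphere + 40 water samples) with controllable
  lake-pool divergence, temporal convergence, polymer selectivity and
  known assembly regimes, so every stage can be validated against ground
  truth without downloads.

`docs/methods.md` documents every model and default.

## Worked example

Partition beta diversity for a pair with 5 shared taxa, 3 unique to one
community and 1 unique to the other, then infer assembly processes on a
clade-filtered (selection-regime) synthetic lake:

```python
import numpy as np
from assemblage import (DesignConfig, NullConfig, RegimeConfig,
                        generate_study, sorensen_partition)
from assemblage.nullmodels import assembly_analysis, process_fractions

p = sorensen_partition(np.array([1]*5 + [1]*3 + [0]),
                       np.array([1]*5 + [0]*3 + [1]))
print(f"beta_SOR={p.beta_sor:.4f} = turnover {p.beta_sim:.4f} "
      f"+ nestedness {p.beta_sne:.4f}; beta_ratio={p.beta_ratio:.4f}")

design = DesignConfig(n_lakes=1, polymers=("PP", "PE", "PVC", "PS", "PLA"),
                      days=(3, 15, 60), n_taxa=200, sequencing_depth=1500,
                      seed=5)
regime = RegimeConfig(pool_divergence=0.0, convergence_rate=0.0,
                      polymer_effect=0.0,
                      assembly_regime="homogeneous_selection")
table, metadata, tree, env, truth = generate_study(design, regime)
result = assembly_analysis(table, tree, metadata,
                           NullConfig(n_null=199, seed=9),
                           pair_filter={"fraction": "plastisphere"})
print(process_fractions(result, metadata, group_by=["lake"]).round(3))
```

prints

```
beta_SOR=0.2857 = turnover 0.1667 + nestedness 0.1190; beta_ratio=0.5833
lake  heterogeneous_selection  homogeneous_selection  dispersal_limitation  \
  L1                    0.019                    0.8                   0.0
homogenizing_dispersal  drift  n_pairs  deterministic  stochastic  ...
                 0.076  0.105      105          0.819       0.181
```

The pair's dissimilarity is mostly species replacement (β_ratio 0.58 >
0.5). On the selection-regime lake, 80% of plastisphere pairs have
βNTI < −2 — communities phylogenetically far closer than the tip-shuffle
null expects — so homogeneous selection is (correctly) the modal
assembly process.

The `examples/` directory holds one short script per capability
(simulation, alpha, beta partition, assembly inference, succession
statistics), each printing its numbers with a line on what they mean.

## Command line

A thin CLI mirrors the library:

```sh
assemblage simulate --out sim/ --seed 1
assemblage assembly --table sim/abundance.tsv --metadata sim/metadata.tsv \
    --tree sim/tree.nwk --pairs-out pairs.tsv --fractions-out fractions.tsv
assemblage run --config run.yaml --out results/
```

`run` executes simulate → alpha → beta → assembly → time-decay →
PERMANOVA → Mantel → convergence from one YAML config with one master
seed (per-stage seeds are derived deterministically) and writes stage
TSVs plus a machine-readable `summary.json`. Exit codes: 0 ok, 2
validation error, 3 stage failure.

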