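# phyloherb

Tools for asking how a host plant's **phylogenetic isolation** and **origin**
(native vs. exotic) shape the richness, compositional dissimilarity, and
specialization of its insect herbivore fauna across local plant–herbivore
assemblages.

The package implements the full analysis chain as reusable, tested stages:

1. **`phyloherb.datasets`** — domain types (interaction tables, plant/
   herbivore records, assemblages), CSV/YAML I/O, the assemblage eligibility
   filters (≥5 plants, ≥5 herbivores, ≥10 species, ≥3 exotics, ≥1 native;
   unknown-origin and herbivore-free plants removed), and endophage/exophage
   guild splitting.
2. **`phyloherb.phylo`** — dated ultrametric phylogenies (Newick via
   dendropy), polytomy grafting of missing species at genus/family MRCAs
   with ultrametricity preserved, patristic distance matrices, and per-plant
   phylogenetic isolation (mean distance to co-occurring natives, in Myr).
3. **`phyloherb.metrics`** — per-plant herbivore richness, mean Jaccard
   `(b+c)/(a+b+c)` and Simpson `min(b,c)/(min(b,c)+a)` dissimilarity versus
   co-occurring natives, and the standardized Kullback–Leibler specialization
   index d′ with an *exact* integer minimum (the allocation objective is
   separable and convex, so greedy marginal allocation attains it).
4. **`phyloherb.glmm`** — random-intercept GLMMs fitted by adaptive
   Gauss–Hermite quadrature: Poisson/log with a total-richness offset for
   richness, weighted binomial/logit for the dissimilarity means,
   Gaussian/identity for mean d′.  Includes the interaction likelihood-ratio
   test, the fixed-effects fallback with McFadden pseudo-R² when the random
   intercept carries no variance, and Nakagawa-style marginal/conditional R².
5. **`phyloherb.simulate`** — seeded synthetic datasets (Yule trees with
   clustered taxonomy; herbivores whose attack probability decays with
   phylogenetic distance from their origin host) so every stage is testable
   end to end without external data.
6. **`phyloherb.cli` / `phyloherb.pipeline`** — orchestration and a CLI.

## CLI

```sh
phyloherb simulate --seed 7 --out data/sim            # synthetic dataset
phyloherb validate data/sim                           # eligibility report
phyloherb graft   --tree data/sim/tree.nwk --dataset data/sim --out out/
phyloherb metrics --dataset data/sim --out out/       # plant_metrics.csv
phyloherb fit     --metrics out/plant_metrics.csv --out out/
phyloherb run     --dataset data/sim --out out/       # full chain, all scopes
```

`run` writes `plant_metrics.csv`, `models.csv`, `lrt.csv`, `r2.csv`,
eligibility/removal logs, a run manifest, and a plain-text summary of the
effect signs per guild scope.  Fixed seeds give byte-identical outputs.

Datasets are described by a YAML manifest pointing at a Newick tree, plant
and herbivore metadata CSVs (`species,genus,family,origin` /
`species,guild`), and one interaction CSV per assemblage (edge-list
`plant,herbivore[,count]` or incidence-matrix dialect).

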