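# mobkit

A community-ecology toolkit for **active methane-oxidizing bacteria (MOB)**
profiled by *pmoA* amplicon sequencing — the kind of dataset produced by
DNA stable-isotope probing (¹³CH₄) incubations of wetland soils. It provides
a tested, reproducible pipeline for the four analyses such studies chain
together:

1. **CH₄ oxidation kinetics** — methane oxidation potential (MOP) from
   headspace depletion series, assuming linear kinetics:

   `MOP = Δppmv · 10⁻⁶ · V(L) · (16 / 22.4) · 273/(273+T) · 10⁶ / (m_soil · Δt)`

   in μg CH₄ g⁻¹ dry soil h⁻¹, with every constant (headspace volume, soil
   mass, incubation temperature) carried by the data object.
2. **Diversity and ordination** — rarefaction, richness and Faith's PD,
   Bray–Curtis, PCoA, ANOSIM, Kruskal–Wallis / Mann–Whitney group tests,
   correlations, Benjamini–Hochberg correction, and a nonparametric
   differential-abundance screen.
3. **Community assembly partitioning** — phylogenetic null models: ses-MPD,
   βMNTD and its z-score **βNTI**, the Bray–Curtis Raup–Crick metric
   **RC_bray**, and the five-way process classification
   (βNTI < −2 → homogeneous selection; βNTI > 2 → variable selection;
   otherwise RC > 0.95 → dispersal limitation, RC < −0.95 → homogenizing
   dispersal, else undominated/drift).
4. **Co-occurrence networks** — compositionally aware sparse inference
   (CLR transform → per-node lasso neighborhood selection → StARS stability
   selection), sub-networks per habitat, topology (degree, betweenness,
   clustering, centralization), Louvain modules, **Zi–Pi** node roles
   (thresholds 2.5 / 0.6), module-abundance vs. function regressions, and
   natural-connectivity robustness curves under random or targeted node
   removal.

A first-class `synthetic_data` module generates phylogenies, habitat-
structured OTU tables with **known assembly regimes**, compositional counts
with **planted association networks**, and noisy CH₄ depletion series, so
every stage has a ground-truth recovery test without any sequence download.

## Worked example

```python
from mobkit import assembly, diversity, kinetics, synthetic_data as sd

# a nominal microcosm: 40,000 ppmv CH4 consumed linearly at 9 %/day
series = sd.simulate_depletion(40000, 0.09, 12, noise_sd=0, seed=1)
res = kinetics.methane_oxidation_potential(series)
t90 = kinetics.time_to_fraction_consumed(series, 0.9)

# four sites x 9 samples under variable selection, classified blind
tree = sd.simulate_tree(500, seed=0)
table, meta, truth = sd.simulate_communities(
    tree, sd.CommunitySimConfig(regime="variable_selection", seed=0))
an = diversity.anosim(diversity.bray_curtis(table), meta["site"],
                      n_permutations=999, seed=0)
bnti = assembly.beta_nti(table, tree, n_null=199, seed=0)
rc = assembly.raup_crick_bray(table, n_null=199, seed=0)
pairs = assembly.classify_assembly_processes(
    bnti.merge(rc, on=["sample_a", "sample_b"]))
frac = assembly.process_fractions(pairs, meta["wetland_type"])
```

This prints:

```
MOP  = 2.069 ug CH4 g-1 h-1   (C1=40000 ppmv, C2=0 ppmv, 288 h)
t90  = 240.0 h
ANOSIM across sites: r = 1.000, p = 0.001
         n_pairs    VS    HS   DL    HD   UD
natural      153  45.8  31.4  3.3  15.7  3.9
paddy        153  45.8   7.2  2.0  39.9  5.2
```

Reading the output: the microcosm consumed 90 % of its CH₄ after 240 h at a
potential of ≈2.1 μg g⁻¹ h⁻¹; the planted between-site selection produces a
maximal ANOSIM separation (r = 1, permutation floor p = 0.001); and the
process partition attributes the plurality of within-habitat community
turnover to selection (VS between differently-selected sites, HS within),
as planted. Note within one wetland type the two sites still carry
different optima, so VS dominates the within-type pair sets.

## Command line

```bash
mobkit simulate --out fixtures --regime variable_selection --seed 1
mobkit kinetics --gas fixtures/gas.csv --out kinetics.tsv
mobkit diversity --table fixtures/otu_table.tsv --tree fixtures/tree.nwk \
    --metadata fixtures/metadata.csv --out diversity_out
mobkit assembly  --table fixtures/otu_table.tsv --tree fixtures/tree.nwk \
    --metadata fixtures/metadata.csv --out assembly_out --n-null 999
mobkit network   --table fixtures/otu_table.tsv --out network_out
mobkit run --config config.yaml       # full pipeline + manifest
```

`mobkit run` executes every stage on either ingested files or a synthetic
study design (4 sites × 2 wetland types × 9 samples, 500 OTUs, 1,172
reads/sample), writes tab-separated outputs per stage, and records a
`manifest.json` with per-stage seeds and SHA-256 checksums; the same config
reproduces every output byte-for-byte.

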