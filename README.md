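# rhizoecol

Community-ecology analyses for rhizosphere amplicon surveys: who assembles
the root-zone microbiome, how much of that assembly is stochastic, and which
taxa form its stable core.

The package implements, as one tested pipeline over ASV feature tables
(samples × taxa counts), the analysis chain used in maize-genotype
rhizosphere studies:

* **Diversity** — richness / Chao1 / Shannon (with the 0.005% overall
  abundance filter), Bray–Curtis distances, PCoA, one-way PERMANOVA, and
  within- vs between-group similarity contrasts.
* **Neutral community model** — Sloan's model predicts a taxon's occurrence
  frequency from its metacommunity relative abundance *p* through the
  stationary beta distribution Beta(*Nm·p*, *Nm·(1−p)*); the package fits
  *Nm* by least squares on the occurrence–abundance cloud and puts a
  999-replicate taxon-bootstrap band around the fitted curve.
* **Assembly-process partition** — a phylogenetic-bin null-model analysis:
  per sample pair and bin, the beta net relatedness index (βNRI, a z-score
  of abundance-weighted βMPD against a within-bin taxa-shuffle null) and the
  modified Raup–Crick metric (RC, a null-standardised Bray–Curtis rank in
  [−1, 1]) classify the pair into heterogeneous selection (βNRI > 1.96),
  homogeneous selection (βNRI < −1.96), dispersal limitation (RC > 0.95),
  homogenising dispersal (RC < −0.95) or drift, and abundance-weighted
  aggregation yields per-group process fractions.
* **Co-occurrence networks** — Spearman screen with BH correction, edges at
  |ρ| > 0.6 and q < 0.05, Louvain modules, topology summaries, Zi–Pi node
  roles (module hubs Zi > 2.5, connectors Pi > 0.62) and keystone taxa.
* **Core microbiome** — Venn intersection of per-group keystone sets, the
  prevalence ≥ 85% OR mean relative abundance ≥ 0.1% core rule, and global
  (Needleman–Wunsch) matching of cultured-isolate 16S reads to ASV
  sequences.
* **Synthetic surveys** — a generator with known ground truth (log-series
  metacommunity, Sloan-stationary neutral sampling, birth–death phylogeny,
  clade-level selection, sequence evolution), so every stage has a
  parameter-recovery oracle.

## Worked example

`analysis/` contains the numbered drivers; each writes its tables under
`results/` and prints what it found. Running them in order on the bundled
synthetic survey (150 taxa, 4 genotype groups × 20 samples, depth 1000,
immigration m = 0.5, a ×5 fitness boost on one clade in genotype MIX):

```
$ python analysis/01_simulate_survey.py
$ python analysis/02_diversity.py
PERMANOVA: F=2.79, R2=0.099, p=0.001 (genotype structure driven by the injected clade selection)
$ python analysis/03_neutral_model.py
MIX: Nm=274 (m=0.274), R2=0.962 over 133 taxa
NSS: Nm=563 (m=0.563), R2=0.979 over 138 taxa
...
$ python analysis/04_assembly_processes.py
drift dominates (96.7%), matching the stochastic-assembly regime; ...
$ python analysis/05_networks_keystones.py
G1: 103 nodes, 622 edges, diameter 6, 9 modules, keystones: ['ASV_core']
...
$ python analysis/06_core_microbiome.py
top candidate ASV_core (prevalence 100.0%, mean abundance 2.47%) — planted hub recovered: True
isolate vs ASV_core: 20 mismatches over 427 columns (95.32% identity)
```

Reading the output: the PERMANOVA detects the genotype-level clade
selection (R² ≈ 0.10, p = 0.001) while within-genotype assembly stays
drift-dominated (DR ≈ 97%), exactly as the generative model dictates —
uniform selection within a group separates groups without creating
within-group selection calls. The neutral fit recovers the immigration
regime (the unselected genotypes fit with *Nm* ≈ 500, the true value;
the selected genotype departs). The network/keystone/core chain recovers
the planted ubiquitous hub taxon, and the isolate match reports the
20-substitution structure planted in the synthetic 16S read.

## Layout

```
src/rhizoecol/     library: io, simulate, diversity, neutral, assembly,
                   network, core
analysis/          numbered drivers writing results/
scripts/           acceptance.py (headline-number recomputation)
tests/             pytest suite incl. calibration/acceptance tests
docs/methods.md    model and design notes
```
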