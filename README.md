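# ecoassembly

Quantitative partitioning of microbial community assembly processes for
dense, replicated 16S time series — and a synthetic community generator
with known assembly regimes to verify every stage of the analysis.

## Who this is for

Microbial ecologists with a taxon-by-sample count table, a rooted
phylogeny over the taxa, and a replicated treatment x timepoint design,
who want to ask: *is community turnover driven by deterministic selection
or by stochastic processes (dispersal, drift) — and does the answer differ
between abundant and rare taxa, between treatments, and over time?*

## What it computes

**Process partitioning** (the core). For every pair of communities:

- βMNTD — abundance-weighted mean distance from each taxon to its nearest
  relative in the other community, on the phylogeny;
- βNTI = (βMNTD_obs − mean_null) / sd_null against a taxa-label-shuffle
  null; βNTI < −2 ⇒ homogeneous selection, βNTI > +2 ⇒ variable selection;
- RC_bray for the non-selection pairs — the rank of the observed
  Bray–Curtis dissimilarity within a null that reassembles both
  communities at observed richness and depth from the regional pool,
  scaled to [−1, 1]; RC > +0.95 ⇒ dispersal limitation, RC < −0.95 ⇒
  homogenizing dispersal, otherwise undominated (drift).

Pair classifications aggregate into percentage tables stratified by
comparison class (within replicates / between treatments), subcommunity
(all / main > 1% / rare < 0.1% mean relative abundance) and timepoint.
SES.MPD screens individual samples for phylogenetic clustering.

**Around the core:** TSS normalisation, Bray–Curtis, UPGMA clustergrams,
nMDS/PCoA ordination, PERMDISP, ANOSIM, Procrustes/PROTEST, inverse
Simpson and Margalef indices, trajectory distances, replicate overlap,
IndVal indicator species analysis (IndVal > 0.5, p < .05 screen), and
time-delayed local similarity (eLSA-style) association networks with
permutation significance, BH FDR and global vs local-only edge scope.

**Synthetic communities.** `ecoassembly.synthetic_community` generates
phylogenies, phylogenetically conserved traits and replicated count
tables under five named regimes (homogeneous_selection,
variable_selection, dispersal_limitation, homogenizing_dispersal, drift),
plus planted time-lagged couplings for network benchmarks. The regimes
are statistical stand-ins whose expected βNTI / RC_bray signatures are
known, which makes the whole pipeline testable without any sequencing
data. See `docs/methods.md` for the model and its assumptions.

## Worked example

Generate a dispersal-limitation fixture (two treatments, disjoint
replicate pools) and partition its assembly processes:

```sh
ecoassembly synth --regime dispersal_limitation --n-taxa 30 \
    --n-treatments 2 --n-timepoints 6 --reads 500 --seed 3 --out fx
ecoassembly partition --counts fx/counts.tsv --metadata fx/metadata.tsv \
    --tree fx/tree.nwk --nulls 99 --seed 1 --out pairs.tsv
```

which prints

```
           variable_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
all_pairs                 0.0                    0.0             88.888889                     0.0    11.111111
```

Read: of the within-replicate sample pairs, 88.9% are classified as
dispersal limitation — the planted regime (replicates drawing from
disjoint taxon pools diverge taxonomically, RC_bray → +1, without
diverging phylogenetically, |βNTI| ≤ 2) — and the remainder fall into
undominated; no pair is attributed to selection. `pairs.tsv` holds the
per-pair βMNTD, βNTI, RC_bray and process labels behind these numbers.

The same analysis runs end to end from a YAML config
(`ecoassembly run --config config.yaml`), producing a report bundle
(pairs.tsv, partition.tsv, ordination.tsv, diversity.tsv, indval.tsv,
edges.tsv, network_summary.tsv, summary.json) that is byte-identical
across runs with the same seed.

As a library:

```python
from ecoassembly import (read_community, patristic_matrix, tss_normalize)
from ecoassembly.assembly_null_models import pair_table, partition_processes

cm = read_community("counts.tsv", "metadata.tsv")
pdm = patristic_matrix(open("tree.nwk").read(), cm.taxa_ids)
pairs = pair_table(cm, pdm, "within_replicates", n_null=999, seed=1)
print(partition_processes(pairs))
```

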