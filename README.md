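# exomewalker

Network-aware prioritization of candidate disease genes in whole-exome
sequencing (WES) data.

A filtered exome still leaves hundreds of genes carrying rare,
predicted-pathogenic variants, and variant evidence alone rarely singles out
the causal one. When a disease is genetically heterogeneous — a *disease-gene
family* of genes whose mutation causes the same clinical picture — the
family's members tend to cluster in the protein–protein association (PPA)
interactome. `exomewalker` exploits that: it ranks candidate genes by fusing
**variant-level evidence** (rarity and predicted pathogenicity) with
**network proximity to the known family members**, measured by a random walk
with restart.

## The method

**Variant score.** Each variant passing the filters (on-target effect class,
known minor allele frequency ≤ 1%, alternate genotype) is scored

> variant score = frequency score × pathogenicity score ∈ [0, 1]

where the frequency score falls linearly from 1 at MAF 0 to 0 at MAF 2%
(novel variants score 1), and the pathogenicity score is the most
deleterious of the available SIFT (as 1 − sift), PolyPhen-2 and
MutationTaster predictions for missense variants (0.6 when none is
available), or a class default for other protein-altering classes. Per gene,
the best variant score is used; under an autosomal-recessive compound-het
model, the mean of the two best.

**Walk score.** With the column-normalized adjacency matrix **W** of the
confidence-filtered PPA network and a seed vector **p₀** uniform over the
*m* family members, the random walk with restart

> p_{t+1} = (1 − r) **W** p_t + r p₀,  r = 0.7

has the stationary solution p∞ = r (**I** − (1 − r)**W**)⁻¹ p₀. With
**R** = r(**I** − (1−r)**W**)⁻¹ precomputed, p∞ is the mean of the *m* seed
columns of **R** — O(mn) per query. p∞[i] measures gene *i*'s global
proximity to the seed set.

**Fusion.** A logistic model, trained with 10-fold cross validation on
labeled examples and averaged over folds, maps (gene variant score, walk
percentile) to the final score in (0, 1). Ranking is ordinal: descending
score, ties broken alphabetically, unique consecutive ranks.

**Benchmarking.** The spike-in harness inserts a known pathogenic variant
into a background exome, seeds the walk with the rest of the gene's family
(leave-one-out), and measures how often the true gene ranks in the top 1,
10 or 50.

## Worked example

`python examples/spike_in_benchmark.py` runs the full synthetic study —
a 300-gene network with 20 planted 5-gene disease-gene families, 5
background exomes of 1000 variants, one spike-in per family per background —
and prints:

```
100 runs (20 families x 5 backgrounds)

ranking key   top-1   top-10  top-50  mean candidates
exomewalker    0.60    1.00    1.00     186.1
variant        0.05    0.30    1.00     186.1
walk           0.02    1.00    1.00     186.1
```

Out of ~186 genes that survive filtering per exome, variant evidence alone
recovers the spiked gene in the top 10 only 30% of the time — it ties or
trails the background's equally rare loss-of-function decoys. The walk finds
the family's network neighborhood (top-10 = 1.00) but cannot pick the causal
gene within it (top-1 = 0.02); the fused score does both. See
`examples/prioritize_exome.py` for a single ranked exome with the per-gene
component scores and seed-interaction paths, and `examples/network_walk.py`
and `examples/variant_scoring.py` for the two scores in isolation.

The same pipeline is scriptable from the shell:

```bash
exomewalker prioritize --vcf exome.vcf --network string_edges.tsv \
    --seeds family_genes.txt --moi AR --out ranked.tsv
```

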