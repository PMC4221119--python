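# Methods

## Model

The package treats disease-gene prioritization in one exome as two
independent sources of evidence per gene, fused at the end.

**Network proximity.** The PPA network is an undirected graph over genes
with a confidence in [0, 1] per association edge; only edges at or above a
threshold (default 0.7, the usual "high-confidence" STRING cutoff) are kept.
After thresholding, the adjacency is *binary* by default: the walk treats a
retained association of confidence 0.71 the same as one of 0.99.
Confidence-weighted normalization is available (`weighted=True` in
`build_transition_matrix`) but is not the default, since thresholding
already enforces a quality floor and binary weighting keeps the transition
semantics of the classical random-walk prioritizers. Genes isolated by the
filter are dropped — a zero column would break column-stochasticity — and
the drop is visible in the network's gene list.

The walk itself: restart probability r = 0.7 (default throughout),
stationary profile computed by a closed-form linear solve. Below 2000
network genes the resolvent **R** = r(**I** − (1−r)**W**)⁻¹ is materialized
densely; above, the LU factorization of (**I** − (1−r)**W**) is kept and
seed columns are produced by back-substitution. Both routes satisfy the same
contract and are cross-checked against power iteration (tolerance 1e-10 L1,
cap 10 000 iterations), which is also the independent oracle in the tests.
The system is nonsingular for every r > 0 because the spectral radius of
(1−r)**W** is 1−r < 1.

Candidate genes absent from the network get walk score 0 and an
`off_network` flag; they stay in the ranking through their variant score
rather than being silently discarded.

**Variant evidence.** Scores and filters are as in the README. Numerical
choices worth stating:

- The frequency map on [0, 2%] is linear, `1 − maf/0.02`. Only the
  endpoints are principled (novel → 1, ≥ 2% → 0); linear is the simplest
  monotone continuous interpolation and is isolated in `frequency_score`
  if a different shape is wanted.
- A variant's MAF is the maximum over all `maf_*` columns present in the
  annotation sidecar — the most conservative reading of multiple frequency
  sources. The sidecar reader can mask named MAF columns, which the
  benchmark uses to withhold a frequency source from background variants.
- "Most deleterious prediction" means max over (1 − sift), polyphen,
  mutation_taster, each used only when present; 0.6 when all three are
  absent (a deliberate compromise between treating unscored variants as
  benign or as fully pathogenic).
- Class defaults for non-missense protein-altering variants (nonsense 0.95,
  frameshift 0.95, splice site 0.90, in-frame indel 0.85) live in a
  configurable table, not in code paths.
- Mode-of-inheritance rules: AD admits HET and HOM_ALT; AR needs one
  HOM_ALT or ≥ 2 distinct HETs assumed in trans (phase is unknowable from a
  single sample). When an AR gene has both mechanisms, the gene score is the
  larger of the homozygous maximum and the compound-het mean — the package's
  resolution of a case the scoring rules underdetermine.
- Hemizygous X calls are treated as HOM_ALT; there is no sex-aware logic.

**Fusion.** Logistic regression on (gene variant score, walk feature) with
stratified k-fold cross validation (default 10), small fixed L2 penalty
(C = 10) so separable data cannot blow up the coefficients, and arithmetic
averaging of the fold models' coefficients into the final model
(prediction averaging over fold models is available behind
`averaging="predictions"`). The walk feature is by default the gene's
*percentile* among all network genes' stationary probabilities rather than
the raw value: raw p∞ entries scale as 1/n and are not comparable across
networks, while the percentile is scale-free. Raw mode is retained for
fidelity experiments. With the surrogate training data the fitted weights
are large and the fused score saturates near 1 for strong candidates; the
*ranking* — the quantity the method is evaluated on — is unaffected by the
saturation.

The package cannot ship a model trained on real curated disease/benign
variants, so the default model is a clearly-labeled surrogate fit on the
synthetic labeled generator (2000 + 2000 examples, effect size 0.8, seed
20001, recorded in the model provenance). Anyone with a labeled set can
train and serialize their own model (`train_combiner`, JSON schema v1).

**Ranking.** Ordinal: descending score, ties alphabetical by gene
identifier, unique consecutive ranks. Tie-breaking is not cosmetic — rare
LOF variants with no frequency record produce genuine score ties — and the
alphabetical rule models a researcher working through equally scored
candidates in a fixed order. Output formatting is fixed at 6 significant
digits for reproducible diffs.

## Synthetic study design

The generators in `exomewalker.simulate` define the study conditions used by
the tests and the acceptance script.

- **Network**: 300 genes, 20 planted modules of 5 genes (the disease-gene
  families), intra-module edge probability 0.8 with confidences in
  [0.75, 1.0), background edge probability 0.01 with confidences in
  [0.4, 1.0) so that part of the background is removed by the 0.7 filter.
  Small components are stitched to the giant component through random
  anchors so the walk reaches every retained gene.
- **Exomes**: 1000 variants per background exome; ~49% on-target, of which
  ~10% are loss-of-function — mirroring, at fixture scale, the
  ~100 genuine LOF variants a real genome carries, which is precisely what
  makes variant-only ranking ambiguous. MAF mixture: 30% absent (novel),
  20% common (uniform on (0.01, 0.5]), 50% rare (uniform on (0, 0.01]).
  Missense predictions are noisy views of a latent deleteriousness
  (Beta(0.7, 2.2)), each tool present with probability 0.8.
- **Spike-ins**: one record per family with the target gene drawn uniformly
  at random. Uniform drawing matters: spiking the alphabetically first
  member of each family would bias the alphabetical tie-break toward the
  spiked gene and inflate variant-only recovery from ~0.3 to ~1.0 at top-10.
  The spiked variant is a novel damaging missense (PolyPhen 0.95,
  MutationTaster 0.90, no frequency record); heterozygous under AD/no-model,
  homozygous under AR.
- **Labeled examples** for the fusion model: each feature drawn from
  Beta(1.2 + 3e, 1.2) for disease and Beta(1.2, 1.2 + 3e) for benign, with
  e the effect size; e = 0 is exactly class-blind, features are independent
  so each carries its own signal.

What the fixtures do **not** emulate: real allele-frequency spectra and
linkage structure, transcript-level annotation ambiguity, correlated errors
among prediction tools, the hub-dominated degree distribution of the real
interactome, and families whose genes do *not* cluster in the network (the
known failure mode of association-based prioritization). Passing the suite
therefore shows the machinery is correct and that fusion beats either signal
alone *when the clustering assumption holds* — not that real-data recovery
rates are reproduced.

## Problem sizes and runtime

Default scales (300-gene network, 100 spike-in runs of 1000-variant exomes,
4000 training examples) were chosen so the whole test suite runs in a few
seconds and the acceptance script in under ten on one CPU, while keeping
~190 candidate genes per exome so that ranking is a real discrimination
task. The walk matrix is precomputed once per (network, r) and shared across
all benchmark runs.

## Known limitations

- Annotations are consumed, never computed: there is no transcript mapping,
  and indels are handled only by bi-allelic splitting.
- Single-sample semantics only; no pedigree or multi-sample segregation
  filtering, no de novo model.
- The compound-het assumption (any two HETs in trans) overcalls AR
  candidacy in genes with several rare heterozygous variants.
- Dense resolvent precomputation is O(n³); beyond ~20k genes a sparse
  iterative treatment would be needed, which is out of scope.
- The default fusion model is a synthetic surrogate; absolute fused-score
  values are not calibrated probabilities for real data.
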