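"""Spike-in benchmark: how often is the true disease gene recovered?

For each of 20 planted disease-gene families a known-pathogenic variant is
inserted into 5 synthetic background exomes and the spiked gene is ranked
with the rest of its family as seeds (leave-one-out).  Top-k recovery is
compared across three ranking keys: the fused score, the variant score
alone, and the walk score alone.
"""

import exomewalker as ew
from exomewalker.prioritize import RankKey

cfg = ew.FixtureConfig(rng_seed=11)
net, families = ew.generate_network(cfg)
backgrounds = [
    ew.generate_exome(cfg, genes=list(net.genes), seed=1100 + i) for i in range(5)
]
records = ew.make_spike_records(families, seed=42)
model = ew.default_model()

results = ew.run_benchmark_all(records, families, backgrounds, net, model)

print(f"{results[RankKey.EXOMEWALKER].n_runs} runs "
      f"({len(records)} families x {len(backgrounds)} backgrounds)\n")
print("ranking key   top-1   top-10  top-50  mean candidates")
for key, r in results.items():
    print(f"{key.value:12s}  {r.top1:5.2f}   {r.top10:5.2f}   {r.top50:5.2f}"
          f"   {r.mean_postfilter_genes:7.1f}")

# The fused score recovers far more spiked genes at the top of the list than
# variant-only ranking, which drowns among equally rare, equally damaging
# background variants; walk-only ranking finds the family neighborhood but
# loses top-1 precision without the variant evidence.
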