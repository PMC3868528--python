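"""Crossover assurance, spore viability, nondisjunction and conversions.

Simulates a crossover-control-defective regime (15% achiasmate meioses,
backup segregation rescuing 90% of them, ~30% spore death) and prints the
E-class distribution with the Poisson assurance test plus the phenotype
summary. Expect an E0 excess over the Poisson null, ~70% spore viability,
~1.5% disome tetrads and a few percent gene-conversion tetrads.
"""

import tetracross as tc

config = tc.dmc1_hed1_like(n_tetrads=3000, seed=3)
result = tc.simulate_tetrads(config)
mmap = config.map

dist = tc.crossover_classes(result.tetrads, mmap)
print("crossover classes (4-viable Mendelian tetrads):")
for k, count in enumerate(dist.counts):
    print(f"  E{k}: {count}")
res = tc.assurance_test(dist)
print(
    f"E0 {res.observed_e0}/{res.n} = {100 * res.observed_fraction:.1f}% vs "
    f"Poisson {100 * res.expected_fraction:.1f}% for mean {res.mean_CO:.2f} CO; "
    f"P(excess) = {res.p_excess:.2g}"
)
print("A significant excess of E0 tetrads means crossover assurance is failing.\n")

viab = tc.viability_distribution(result.tetrads)
print(f"viable-spore classes 4..0: "
      f"{[viab.counts[k] for k in (4, 3, 2, 1, 0)]}")
print(f"spore viability: {viab.viability_pct:.1f}%")

disomes = tc.score_disomes(result.tetrads, mmap)
print(f"disome tetrads (BOTH at the centromere-linked marker): "
      f"{disomes.n_flagged}/{disomes.n_tetrads} = {100 * disomes.fraction:.2f}% "
      "(meiosis I nondisjunction)")

crosstab = tc.conversion_crosstab(result.tetrads, mmap)
print(f"gene-conversion tetrads: {int(crosstab.table[:, 0].sum())}/{crosstab.n} "
      f"= {100 * crosstab.conversion_fraction:.1f}% "
      f"(E0 subset: {100 * crosstab.e0_conversion_fraction:.1f}%)")
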