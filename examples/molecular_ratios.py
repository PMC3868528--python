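"""Template-bias and crossover-outcome arithmetic on gel quantitations.

Takes interhomolog vs intersister double-Holliday-junction signals and
crossover/non-crossover ratios for a wild type and a homolog-bias-defective
mutant at two recombination hotspots, and asks how much of the crossover
shortfall predicted from the lost homolog bias is made up by the elevated
crossover fraction (the crossover-bias compensation model).
"""

import tetracross as tc

# (IH/IS wt, CO/NCO wt, IH/IS mut, CO/NCO mut, observed CO fold reduction)
hotspots = {
    "artificial hotspot": (5.7, 1.4, 0.22, 1.8, 3.5),
    "natural hotspot": (4.5, 1.0, 0.15, 4.9, 2.1),
}

print("CO/NCO ratio from a selected-recombinant crossover fraction of 70%: "
      f"{tc.co_fraction_to_ratio(0.70):.2f}\n")

for name, (ih_wt, co_wt, ih_mut, co_mut, observed) in hotspots.items():
    wt = tc.BiasSummary(ih_wt, tc.co_ratio_to_fraction(co_wt))
    mut = tc.BiasSummary(ih_mut, tc.co_ratio_to_fraction(co_mut))
    res = tc.compensation_model(wt, mut, observed_fold_reduction=observed)
    print(f"{name}:")
    print(f"  IH/IS ratio {ih_wt} -> {ih_mut} "
          f"({tc.fold_change(ih_wt, ih_mut):.0f}-fold bias loss); "
          f"IH fraction {wt.ih_fraction:.2f} -> {mut.ih_fraction:.2f}")
    print(f"  CO fraction {wt.co_fraction:.2f} -> {mut.co_fraction:.2f}")
    print(f"  predicted crossover level (bias terms only): "
          f"{res.predicted_relative_co:.2f} of wild type "
          f"({res.predicted_fold_reduction:.1f}-fold reduction)")
    print(f"  observed reduction: {observed}-fold")
    print(f"  share of apparent compensation from crossover bias: "
          f"{100 * res.fraction_of_apparent:.0f}% "
          f"(unexplained: {100 * res.unexplained_fraction:.0f}%)\n")

print("The unexplained remainder implies a second feedback process beyond")
print("crossover-outcome bias (e.g. additional recombination initiation).")
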