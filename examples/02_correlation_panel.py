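"""Pearson correlation panel of the nine index columns.

Simulates the 43-genotype heat-stress preset, computes the index table
and prints the starred correlation panel.  Two structural facts hold on
any dataset: SSI and YSI correlate at exactly -1.00 (SSI is a
decreasing affine map of YSI), and every third column correlates with
SSI and YSI at equal magnitude and opposite sign.
"""

import stresskit as sk

pairs = sk.simulate_preset("paper_heat_clusters", seed=1)
idx = sk.compute_indices(pairs)
cm = sk.pearson_matrix(idx.matrix())

print(f"n = {cm.n} genotypes, stress intensity SI = {idx.si:.3f}\n")
print(cm.formatted().to_string())
print("\n** p < 0.01, * p < 0.05 (two-sided t test on n-2 df)")
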