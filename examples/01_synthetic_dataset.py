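"""Generate a synthetic regulatory system and its expression time series.

Samples a random directed 10-gene network, simulates five experiments of
21 observations with process noise, and prints the shapes plus the gold
edges.  This is the input every later stage consumes.
"""

import aesgrn

system = aesgrn.sample_network(n=10, density=0.15, seed=42)
dataset = aesgrn.simulate_dataset(system, b=21, k=5, sigma=0.02, seed=42)

print(f"genes:        {dataset.gene_names}")
print(f"experiments:  {dataset.n_experiments} x {dataset.n_observations} observations")
print(f"gold edges:   {system.gold.n_positive()} of {10 * 9} possible")
for (reg, tgt), _ in sorted(system.gold.labels.items())[:5]:
    i, j = system.gene_names.index(reg), system.gene_names.index(tgt)
    print(f"  {reg} -> {tgt}  (weight {system.weights[i, j]:+.3f})")
print("...")
print("Each weight is the signed strength with which the regulator pushes")
print("its target's next expression value; these edges are what inference")
print("will try to recover from the time series alone.")
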