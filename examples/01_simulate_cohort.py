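"""Generate a synthetic cortical cohort with planted structure.

The default configuration plants three co-expression modules (one shared,
one male-only, one silenced in definite AD), ten fold-change DEGs in the
frontal pole, and couples the four clinical traits to GSK3B expression.
"""

from adsexnet import default_config, simulate_cohort

expr, meta, truth = simulate_cohort(default_config(seed=1))

print(f"expression: {expr.n_genes} genes x {expr.n_samples} samples")
print(meta.table.groupby(["sex", "stage"]).size().unstack(fill_value=0))
print(f"planted modules: { {k: len(v) for k, v in truth.module_genes.items()} }")
print(f"planted DEGs: {len(truth.deg_table)} (region {truth.deg_table['region'].iloc[0]})")
print(f"trait driver: {truth.trait_driver.gene}")
# Each subject contributes one sample per region; the stage table above
# shows roughly 15 subjects per sex per stage under the uniform default.
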