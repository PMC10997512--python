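"""Disease states, eigengene contributions, modules and driver genes.

Runs the gene-level half of the pipeline on a reduced synthetic cohort:
samples are grouped into disease states by the landscape's basin
boundaries, differentially expressed genes are classified pro- or
anti-disease by the quadrant rule, and transition-driver genes are
screened by correlating expression with the potential near the unstable
points.
"""
import numpy as np

from cmlstate import gene_analysis
from cmlstate.statespace import build_state_space, coordinate_series, \
    normalize_expression
from cmlstate.synthetic import (SyntheticConfig, default_true_potential,
                                generate_cohort)

cfg = SyntheticConfig(seed=3, n_genes=2500)
counts, table, truth = generate_cohort(cfg)
model = build_state_space(counts, table)
coords = coordinate_series(model, table)
pot = default_true_potential()

# state assignment uses the planted landscape mapped onto latent truth here
import pandas as pd
x = pd.DataFrame({"coordinate": [truth["x_per_sample"][s]
                                 for s in coords.index]}, index=coords.index)
assigned = gene_analysis.assign_disease_states(x, pot, table)
print("samples per disease state:")
print(assigned.state.value_counts().to_string())

hs = assigned.index[assigned.state == "Hs"]
ls = assigned.index[assigned.state == "Ls"]
sub = counts.loc[normalize_expression(counts).var(axis=1).nlargest(300).index]
de = gene_analysis.differential_expression(sub, table, hs, ls,
                                           comparison="Ls_vs_Hs")
sig = de[de.padj < 0.05]
print(f"\nLs vs Hs: {len(sig)} significant genes of {len(de)} tested")

rec, mean_vec = gene_analysis.eigengene_contribution(
    sig[sig.index.isin(model.genes)], model)
print(rec["class"].value_counts().to_string())
print(f"net contribution vector (v1, contribution) = "
      f"({mean_vec[0]:.4f}, {mean_vec[1]:.4f})")
print("a positive net contribution means the late-state expression changes "
      "push samples toward disease (pro-CML), as expected at Ls.")

cml = coords[coords.cohort == "CML"]
drivers = gene_analysis.find_transition_drivers(
    normalize_expression(counts), x.loc[cml.index], pot, list(sig.index))
n_drv = drivers.groupby("window").driver.sum()
print(f"\ntransition drivers (|r|>0.5, p<0.05) per window:\n"
      f"{n_drv.to_string()}")
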