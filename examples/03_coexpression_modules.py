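"""Cluster differential transcripts into temporally coherent modules.

Builds the signed co-expression network on the variance-stabilized DET
expression, transforms it to topological overlap, clusters, and summarizes
each module by its eigengene profile over the three time points.
"""

import pandas as pd

from retrodyn import coexpress, de, simulate

counts, meta, truth = simulate.simulate_counts(simulate.default_design(seed=1))
sf = de.size_factors(counts)
res = de.nb_lrt(counts, meta, sf)
dets = sorted(res.table.index[res.table["is_det"]])
expr = de.vst(counts.loc[dets], sf)

st = coexpress.pick_soft_threshold(expr)
beta = st.beta if not st.warning else 30
print(f"soft threshold beta = {beta} (scale-free criterion met: {not st.warning})")

adj = coexpress.signed_adjacency(expr, beta)
tom = coexpress.tom_similarity(adj)
part = coexpress.detect_modules(tom, dets)
print(f"{part.n_modules} modules, sizes {part.module_sizes}; "
      f"{part.unassigned_fraction():.1f}% of DETs unassigned")

eig, var, profiles = coexpress.module_eigengenes(expr, part, meta["time"])
print("\neigengene means per time group (rows = modules):")
print(profiles.round(2).to_string())
print("\nA positive peak at 45min marks the transient module; monotone rises")
print("and falls at 24h mark the late induction and repression modules.")

# compare with the planted labels
truth_series = pd.Series({t: truth.module_labels[t] for t in dets})
ct = pd.crosstab(truth_series, part.labels)
print("\nplanted-vs-detected contingency:")
print(ct.to_string())
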