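"""GO enrichment of the DET list, the modules, and their combinations.

Shows the two enrichment layers: hypergeometric term enrichment of the DET
list against all tested transcripts (with the strict FDR < 1e-4 filter),
then the module-vs-DET z-score that asks which module (or union of
modules) concentrates each term, with best-predictor assignment.
"""

from retrodyn import coexpress, de, go, simulate

study = simulate.simulate_study(simulate.default_design(seed=1))
sf = de.size_factors(study.counts)
res = de.nb_lrt(study.counts, study.meta, sf)
dets = set(res.table.index[res.table["is_det"]])
universe = set(res.table.index)

rec = go.hypergeom_enrich(dets, study.term_map, universe)
kept = go.filter_terms(rec, fdr_max=1e-4)
print(f"{len(kept)} of {len(rec)} tested terms enriched in the DET list at FDR < 1e-4")

rollup, _ = go.rollup_processes(set(kept["term"]), study.category_map)
print("\nprocess rollup of the DET-derived terms:")
print(rollup.round(1).to_string(index=False))

# modules and their combinations
expr = de.vst(study.counts.loc[sorted(dets)], sf)
tom = coexpress.tom_similarity(coexpress.signed_adjacency(expr, 30))
part = coexpress.detect_modules(tom, sorted(dets))
groups = go.enumerate_module_groups(part.module_sets(), sorted(part.module_sizes))
print(f"\n{len(groups)} module groups from {part.n_modules} modules:", sorted(groups))

records = go.module_group_enrichment(groups, dets, study.term_map)
enriched = records[records["enriched"]]
assignment, counts = go.best_predictor_assignment(records)
print(f"{len(enriched)} (group, term) pairs pass FDR < 1e-4 and z > 2")
print("best-predictor term counts per group (each term credited once,")
print("to the group where its z-score is highest):")
print(counts.to_string())
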