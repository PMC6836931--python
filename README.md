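# retrodyn

Dynamic transcriptomic retro-analysis of an acute surgical (sham) response.

Cardiac surgery models — thoracotomy, suture placement, chest closure —
trigger a systemic inflammatory reaction of their own, which confounds any
downstream comparison against ischemia–reperfusion injury. `retrodyn`
implements an analytical pipeline for characterising that sham effect from a
three-time-point bulk RNA-seq design (0 min, 45 min, 24 h post-surgery,
eight animals per time point) and for inferring the upstream signalling
network that most plausibly drove the observed transcriptional response. It
is a library for people analysing small time-course RNA-seq designs who
want the full chain — from counts to an upstream regulator hypothesis — as
tested, scriptable Python.

## What it computes

1. **Differential expression** — counts are modelled as negative binomial,
   `Var = μ + αμ²`, with median-of-ratios size factors. A likelihood-ratio
   test compares per-time-group means against one shared mean; `LRT/df` is
   referred to `F(df, N − k)` (the small-sample reference for an estimated
   dispersion) and BH-corrected. Transcripts with FDR < 0.05 are the DETs.
2. **Co-expression modules** — on the variance-stabilised DET expression, a
   signed adjacency `a_ij = ((1 + cor_ij)/2)^β` (β picked by a scale-free
   topology criterion) is transformed to the topological overlap measure and
   clustered (average linkage, static cut, minimum module size); each module
   is summarised by its eigengene (first PC) over time.
3. **GO enrichment** — hypergeometric term enrichment with BH FDR and a
   strict FDR < 10⁻⁴ filter; plus a module-vs-DET enrichment z-score

       z = (x − 0.5 − B·n/N) / √(n · B/N · (1 − B/N))

   where a term seen `x` times in a module group of size `n` is compared to
   its count `B` among all `N` DETs (enriched when FDR passes and z > 2).
   Module combinations are enumerated as unions and each term credited to
   the group with the highest z.
4. **TF over-representation** — each transcription factor's target set is
   scored against the DET list with a one-tailed Fisher exact test
   (`F = −ln p`, kept when F > 20) and a continuity-corrected binomial
   z-score; TFs form five nested groups by |z| (cuts 35/25/15/10/2).
5. **Network retro-analysis** — each TF group seeds a PPI subnetwork grown
   greedily (the outside node with the largest summed edge confidence joins
   first) through a +5/+10/+20/+30/+40-node schedule. Every layer's GO
   profile is scored against the DET-derived terms: sensitivity = % of DET
   terms recovered, specificity = % of network terms shared. The layer with
   sensitivity ≥ 40% and growth ≥ 150% that maximises specificity is the
   selected upstream network, then split by k-means into core / secondary /
   peripheral tiers.

A first-class synthetic-data module generates the whole input bundle with
planted ground truth (temporal modules, annotated terms, driven TFs, an
upstream cytokine-like hub), so every stage has a recoverable answer.

## Worked example

```python
from retrodyn.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))
print(res.manifest["stages"]["de"]["det_count"])    # 262
print(res.partition.module_sizes)                    # {1: 100, 2: 80, 3: 71}
sel = res.selection
print(sel.tf_group, sel.layer, sel.sensitivity_pct)  # 2 4 66.7
print(res.truth.hub_node in sel.nodes)               # True
```

On the default simulated study (2000 transcripts, 250 planted differential
ones) the run above finds 262 DETs at FDR < 0.05 (all 250 planted ones,
observed FDR 4.6%), recovers the three planted temporal modules exactly
(the 45-min transient, 24-h up and 24-h down blocks), and the selected
TF-seeded network — group 2, fourth growth layer, 67% sensitivity, 100%
specificity — contains the planted upstream hub: the retro-analysis reaches
back from transcript counts to the regulator that caused them. The
`examples/` directory walks each capability with a short narrative script
(`python examples/01_simulate_study.py`, …), and the `retrodyn` console
command exposes the same stages for shell use (`retrodyn run --out DIR`).

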