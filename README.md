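# disjunctsdm

Climatic-niche comparison and future range projection for plant species with
geographically disjunct populations.

Many mountain and relict plants persist as one large **core** population group
plus one or more small, geographically separated **disjunct** groups. Two
questions follow. First, do the disjunct populations occupy a different
climatic niche than the core, or merely a subset of the same niche? Second,
when future ranges are projected under climate change, does it matter whether
the species is modelled as a single entity or as separate population groups
whose predictions are then combined? `disjunctsdm` implements the full
analysis chain for both questions, plus a synthetic-landscape laboratory for
validating every step against known truths:

- **Synthetic landscapes and virtual species** — spatially autocorrelated,
  cross-correlated climate layers (including an explicitly low-rank,
  collinear variant mimicking real bioclimatic variables); Gaussian-niche
  virtual species with core/disjunct population bands; constructed future
  climates, including an oracle that shrinks the true range to an exact
  target fraction.
- **Occurrence preparation** — one-record-per-cell spatial thinning and
  distance-buffered background extraction (5/10/15 km around each group).
- **Environmental space** — pooled ("harmonized") PCA over all climate
  scenarios so current and future cells share one projection; gridded
  kernel-density occupancy surfaces in the two-component space.
- **Niche metrics** — Schoener's D overlap and the background-randomization
  niche similarity test in both directions, with more/less-similar verdicts.
- **SDM core** — a Maxent-style presence-background model: L1-penalized
  logistic regression on linear, quadratic, and product features of the two
  principal components, fitted by a monotone proximal-gradient optimizer;
  pseudo-absence sampling and repeated-split cross-validation.
- **Evaluation** — rank-based AUC, the true skill statistic, and three
  binarization threshold rules (Sens=Spec, MaxSens+Spec, MinROCdist).
- **Range dynamics** — species, core, disjunct, and aggregate (cellwise union
  of group predictions) model types; majority-consensus ensembles across
  cross-validation repeats, threshold rules, and climate models; the range
  change index RC = 100 × (RG − RL) / CPR.
- **I/O and CLI** — ESRI ASCII grid raster stacks, CSV occurrences, a YAML
  pipeline configuration, and a `disjunctsdm` command-line interface with a
  one-shot `run-all`.

## Worked example

A complete in-memory study: simulate a landscape and a cold-margin virtual
species with 250 core and 50 disjunct occurrences, project two GCMs under two
emissions pathways, and run the full analysis.

```python
import disjunctsdm as d
from disjunctsdm import PipelineConfig, run_species_analysis

stack = d.generate_climate_stack(6, (120, 120), autocorr_range=15, seed=7)
truth = d.make_virtual_species(stack)                 # cold-margin species
occ = d.sample_occurrences(truth, stack, n_core=250, n_disjunct=50, seed=8)
scenarios = d.generate_scenario_set(stack, gcm_ids=("GCM1", "GCM2"), seed=9)

cfg = PipelineConfig(seed=0, n_background=5000, n_cv=5, similarity_reps=99,
                     buffers_km=(10.0,))
res = run_species_analysis(scenarios, occ, cfg)

print(res.niche_table[["buffer_km", "direction", "D", "p_more", "verdict"]]
      .to_string(index=False))
```

```
 buffer_km        direction        D  p_more verdict
      10.0 core_vs_disjunct 0.196034    0.31      ns
      10.0 disjunct_vs_core 0.196034    0.30      ns
```

The two groups overlap weakly in environmental space (D ≈ 0.20) but neither
direction of the similarity test is significant — the niches are not more (or
less) similar than their backgrounds would predict by chance.

```python
print(res.eval_table[["model_type", "auc_mean", "tss_mean", "sensitivity_pct"]]
      .round(3).to_string(index=False))
```

```
model_type  auc_mean  tss_mean  sensitivity_pct
   species     0.947     0.827           92.667
      core     0.958     0.845           79.000
  disjunct     0.975     0.904           18.000
 aggregate     0.966     0.875           95.667
```

All models discriminate well on held-out data, but sensitivity against the
full occurrence set exposes the transferability gap: the disjunct-only model
covers 18 % of all records, while the aggregate model (union of the core and
disjunct predictions) covers 95.7 % — more than either component alone.

```python
print(res.range_change_table[["model_type", "rcp", "RG", "RL", "CPR", "RC"]]
      .round(1).to_string(index=False))
```

```
model_type   rcp  RG  RL  CPR    RC
   species rcp26  76 151 1824  -4.1
   species rcp85 234 320 1824  -4.7
      core rcp26  77 132 1442  -3.8
      core rcp85 272 252 1442   1.4
  disjunct rcp26   7 144  960 -14.3
  disjunct rcp85   3 325  960 -33.5
 aggregate rcp26  47 251 2354  -8.7
 aggregate rcp85 174 489 2354 -13.4
```

Projected fates diverge by model type: the whole-species and core models are
nearly stable, while the disjunct model loses a third of its range under the
high-emissions pathway — the choice of modelling unit changes the
conservation conclusion.

The same pipeline runs from the command line over rasters on disk:

```sh
disjunctsdm simulate --out-dir data --seed 3
disjunctsdm run-all --config config.yaml --out-dir results
```

`run-all` writes `niche_analysis.csv`, `evaluation.csv`, `range_change.csv`,
the thinned occurrences, consensus binary maps (`.asc`), and a `runlog.json`
with the effective configuration and derived stage seeds.

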