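# spiralsort

Process modelling for **label-free purification of manufactured red blood
cells (mRBCs)**. In vitro erythropoiesis from CD34+ progenitors ends in a
mixture of enucleated cells (the therapeutic product), residual nucleated
cells and free-floating expelled nuclei. `spiralsort` models the two-stage
downstream purification of that mixture — deformability-based inertial
sorting in a spiral microchannel followed by membrane filtration — as a
reusable, testable in-silico pipeline for bioprocess engineers and
microfluidics researchers.

## What it computes

* **Channel design numbers** for a rectangular spiral (default
  170 µm × 30 µm, six loops, four balanced outlets): hydraulic diameter
  Dh = 2HW/(H+W), mean velocity U = Q/(WH), channel Reynolds number
  Re = ρUDh/µ, Dean number De = Re·√(Dh/R), and the crowding parameter
  α = 6WH·VF/(πa²) with its α ≤ 1 single-stream focusing check.
* **Cytometry gating** of event tables (projected area, deformability,
  DNA and CD235a fluorescence): debris below 15 µm², DNA− → enucleated,
  DNA+ split by size into nucleated cells vs free nuclei, with the DNA
  threshold fitted as an upper quantile of an unstained control.
* **A phenomenological focusing model**: measured lateral equilibrium
  positions (mean ± SD, µm from the outer wall) per cell class and flow
  rate. At 1 ml/min the deformable enucleated cells shift to 36 ± 21 µm
  near the outer wall while nucleated cells (103 ± 32 µm) and rigid
  nuclei (154 ± 18 µm) stay inward — the deformability-induced lift
  effect the separation exploits.
* **ROC-based operating-point selection**: for each candidate flow rate,
  the ROC of position cut-offs (TPR = fraction of enucleated cells at or
  below the cut-off, FPR the contaminant analogue) is integrated by
  trapezoid; the flow rate maximizing the worst-case AUC wins
  (AUC = 0.96 vs nucleated and > 0.99 vs nuclei at 1 ml/min).
* **Separation metrics** per outlet: separation efficiency
  counts[c][i]/Σᵢcounts[c][i], purity counts[c][i]/Σ꜀counts[c][i]·100 %,
  and enrichment ratio [C]outlet/[C]inlet under the channel's equal
  laminar four-way volume split.
* **Membrane filtration** (3 µm pore): per-class Bernoulli passage with
  calibrated defaults that raise outlet-A purity to ≈ 99 % at a 50–70 %
  enucleated-cell loss, plus batch/dead-volume recovery accounting.
* **Threshold-based image analysis** of cytospin-like fields (detection,
  three-class calling from area and nuclear dark fraction) and lateral
  position extraction from in-channel frames, with synthetic renderers
  providing exact ground truth.

## Worked example

```python
import spiralsort as ss

model = ss.default_focusing_model()
sel = ss.select_flow_rate(model, [0.2, 0.4, 0.6, 0.8, 1.0], seed=1)
print("chosen flow rate:", sel.flow_rate_ml_min, "ml/min")
print(sel.auc_table.round(3).to_string(index=False))

report = ss.full_process(ss.donor_presets()["I"], flow_rate=1.0, n=100_000, seed=1)
print("outlet A purity (%):", report.sections["purity_pct"]["A"])
print("post-filter purity (%):", report.sections["filter"]["purity_pct"])
```

prints

```
chosen flow rate: 1.0 ml/min
 flow_rate_ml_min  auc_vs_nucleated  auc_vs_nucleus  min_auc
              0.2             0.627             NaN    0.627
              0.4             0.531           0.812    0.531
              0.6             0.546           0.835    0.546
              0.8               NaN           0.943    0.943
              1.0             0.960           1.000    0.960
outlet A purity (%): {'enucleated': 93.4, 'nucleated': 6.6, 'nucleus': 0.0}
post-filter purity (%): {'enucleated': 99.93, 'nucleated': 0.07, 'nucleus': 0.0}
```

Reading: at low flow rates enucleated and nucleated cells overlap in
lateral position (AUC ≈ 0.5–0.6, no separation), nuclei have no entry at
0.2 ml/min (`NaN`, never extrapolated), and 1 ml/min is selected because
its worst pairwise AUC (0.96) dominates. Sorting a donor-I-like synthetic
population at that rate sends most enucleated cells to outlet A (93 %
pure), and the membrane stage lifts purity above 99 % at the cost of 60 %
of the enucleated cells.

A `spiralsort` console script exposes the same stages
(`design`, `gate`, `roc`, `sort`, `filter`, `run`, `fixtures`); try
`spiralsort run --config run.yaml --out-dir out` with a YAML like
`{donor: I, seed: 5, n_events: 20000}`.

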