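# hemoflow

Automated immunophenotyping of human whole-blood multicolor flow
cytometry — as a library and command-line tool, with a synthetic-blood
simulator that makes the entire analysis chain testable without donor
samples.

## The problem

Clinical immune monitoring tracks dozens of circulating cell subsets —
T-helper and cytotoxic T cells with their naive/effector/memory
compartments, B-cell maturation stages, NK and NKT cells, the four
monocyte subsets, neutrophils, eosinophils, basophils, dendritic cells,
and rare non-leukocytes (HSC, EPC, CEC) — plus activation markers on each
of them, from small volumes of fresh whole blood stained across a modular
set of antibody panels. Doing that reproducibly requires an explicit,
automated version of the full gating strategy: morphology quality control,
hierarchical geometric gates, Boolean gate algebra, bead-based absolute
counting, and replicate quality metrics. `hemoflow` implements exactly
that pipeline:

* **12 staining panels** on a 3-laser/10-color instrument layout,
  resolving **34 immune + 3 non-immune subsets** and **27 activation
  readouts**; a standard report enumerates **208 populations** per sample.
* **Morphology QC**: a Flow-gate (event rate vs. time, median/MAD outlier
  windows), two pulse-shape doublet gates (FSC area vs. width, then area
  vs. height), and the All Cells gate excluding debris and reduced-FSC
  (dead) events.
* **Display model**: spillover compensation (`observed = true · S` solved
  per event) and the logicle (biexponential) scale — linear around zero,
  logarithmic at high intensity — with per-channel parameters
  `T, M, W, A`.
* **Absolute counts** from counting beads spiked into a fixed blood
  volume: per fluorescence channel, doublets are added twice to singlets,
  the five channels are averaged, and

  ```
  cells/µL = (cells acquired / beads acquired) × (beads per tube / blood volume µL)
  ```

  The per-µL numbers of the major cell types are then transferred onto
  every other panel's subsets.
* **Robustness**: per-population CV (%) over independent replicates
  (`sd/mean × 100`), a `<100 events` validity filter, and the CV-band
  summary (<5%, <10%, 10–15%, ≥15%).

The simulator generates acquisitions from a fully specified ground truth
(population frequencies, lognormal marker-intensity templates, scatter
classes, debris/dead/doublet artifacts, spillover, counting beads), and
every event carries a hidden label — so each gate can be scored against
what was actually generated.

## Worked example

```python
import hemoflow as hf

profile = hf.build_default_profile(seed=1)      # the synthetic donor
schemas = hf.build_diob_schema()                # all 12 panels
tables = hf.simulate_sample(profile, schemas, n_events=50_000, seed=1)
report = hf.analyze_sample(tables, schemas)

print(f"reported populations: {len(report.all_stats())}")
print("absolute counts (cells/uL):",
      {k: round(v) for k, v in report.absolute_per_ul.items()})
frame = report.frame()
rows = frame[frame.population.isin(["TH", "TREG", "NK1", "Mo1", "Neutrophils", "pDC"])]
print(rows[["panel", "population", "events", "pct_parent", "abs_per_ul"]]
      .round(2).to_string(index=False))
```

prints

```
reported populations: 208
absolute counts (cells/uL): {'Leu': 5996, 'T': 1509, 'B': 304, 'Mo': 518, 'Gr': 3217, 'NK': 241}
panel  population  events  pct_parent  abs_per_ul
  P01          TH    6832       56.97      859.64
  P02          TH    6938       57.12      861.91
  P02        TREG     352        5.07       43.73
  P06         NK1    1774       88.97      214.41
  P07         NK1    1693       90.49      218.07
  P08         Mo1    3555       85.58      442.93
  P09 Neutrophils   24253       94.40     3036.99
  P10         pDC     371       43.09       15.53
```

Reading this: the donor was simulated with 6,000 leukocytes/µL of which
25% are T cells — the pipeline recovers 5,996/µL and 1,509 T cells/µL
from the counting tube. TH is measured independently in two panels
(57.0% and 57.1% of T cells — the linked CD3 gates make panels
comparable), regulatory T cells are 5.1% of TH, NK1 is ~89–90% of NK
cells in both NK panels, Mo1 is 85.6% of monocytes, and each
population's absolute count is its within-major fraction times the
major's per-µL number.

The same run from a shell:

```sh
hemoflow report --panels P01,P02,P12 --n-events 50000 --seed 1 --out out/
hemoflow robustness --replicates 3 --n-events 50000 --seed 1
hemoflow simulate --panels P03 --n-events 20000 --out sim/   # writes FCS 3.1
hemoflow gate sim/P03.fcs --panel P03
hemoflow count sim_p12.fcs --beads-per-tube 10000 --volume-ul 50
```

## Layout

| module | contents |
| --- | --- |
| `hemoflow.synthetic` | ground-truth profiles, panel/counting-tube simulation |
| `hemoflow.fcs` | FCS 3.1 read/write, plain-text spillover matrices |
| `hemoflow.preprocess` | compensation, logicle transform, Flow/singlet/All Cells gates |
| `hemoflow.gating` | gate geometry, Boolean expressions, gate trees |
| `hemoflow.panels` | the 12-panel schema, subset definitions, 208-population enumeration |
| `hemoflow.counting` | bead enumeration, absolute-count formula, propagation |
| `hemoflow.robustness` | replicate CV, validity filter, CV summary |
| `hemoflow.pipeline` / `hemoflow.cli` | end-to-end runs, report bundle, CLI |

See `docs/methods.md` for the underlying models, the default parameter
choices and the known limitations.
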