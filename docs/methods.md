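# Methods

This note documents the models behind `hemoflow`: what the synthetic
whole-blood generator emulates, how the automated gates are defined, the
numerical choices, and what the passing tests do and do not establish
about real instrument data.

## 1. The synthetic whole-blood acquisition

The generator is the package's stand-in for donor blood. An acquisition
is a mixture of *leaf populations* — each a complete surface-marker
phenotype — plus instrument and preparation artifacts. Every event
carries a hidden ground-truth label, so downstream gates can be scored
exactly.

### 1.1 Composition

Default leukocyte composition (fractions of intact leukocytes), chosen
at the midpoints of normal adult ranges:

| compartment | fraction | internal structure |
| --- | --- | --- |
| T cells | 25% | TH 57% (16 memory x lineage leaves + TREG 5% of TH), CD8hi 26%, CD8lo 2%, DNT 5%, DPT 1%, CD4lo 3%, NKT 6% |
| B cells | 5% | naive 62%, memory 25%, pre-naive 2%, transitional 3%, plasmablasts 2%, BREG 3%, other 3% |
| NK cells | 4% | NK1 90%, NK2 6%, NK3 4% |
| monocytes | 8.5% | Mo1 85%, Mo2/Mo3/Mo4 5% each |
| neutrophils | 50% | — |
| eosinophils | 3% | — |
| basophils | 0.8% | — |
| dendritic cells | 0.6% | pDC 45%, mDC-1 45%, mDC-2 10% |
| other lymphoid | 2.1% | marker-silent CD45+ filler ("rest of PBL") |

Non-leukocytes (HSC split CD133±, EPC split CD45±, CEC) are additional
fractions of all intact cells, each below 0.01% — at desk-scale event
counts they appear as a handful of events, which is exactly the regime
the `<100 events` validity filter exists for.

Artifact defaults: debris 2% of events (8% in the unwashed counting
tube), dead cells 0.5% (always <1% in fresh blood), cell doublets 2%,
bead doublets 2% of bead events (<3%).

### 1.2 Intensity model

Marker intensities are lognormal in raw linear units on a
[0, 1,048,576] digitizer scale: `value = location · exp(σ·z)` with
σ = 0.25 by default. Canonical locations are neg = 30, lo = 800,
pos = 12,000, hi = 150,000, with per-marker overrides (e.g. CD4/CD8
hi = 50,000 and lo = 1,500; CD38/CD24 hi = 60,000 on B cells). This is a
standard approximation — real fluorescence distributions are heavier
tailed — but it yields realistic logicle displays and, importantly,
well-defined geometric midpoints for split thresholds. Activation
markers (CD38, CD25, CD69, CD80, CD86, HLA-DR, CD279, CD152, CD64hi,
CD83, CD274, ...) are Bernoulli per event with per-population positive
probabilities, so activation readouts are genuine subsamples rather
than fixed subpopulations.

Two physically motivated details:

* **Merged channels.** The combined CD19/20 stain and the lineage
  cocktail (CD3, CD14, CD16, CD19, CD20, CD56) are modelled as the *sum*
  of their component markers' intensities in one channel.
* **CD16 isoforms.** Two simulated markers distinguish the
  FcγRIIIA-specific readout (positive on NK1, Mo2/Mo3, NKT) from the
  pan-isoform readout that additionally stains neutrophils
  (FcγRIIIB). The neutrophil/eosinophil panel, the counting tube and the
  lineage cocktail use the pan form; the NK and monocyte panels the
  A-specific form. One consequence mirrors the real assay: eosinophils
  (CD16-negative) pass the lineage-negative gate but are HLA-DR⁻/CD123⁻
  and therefore land in no basophil or DC gate.

Scatter: per-class (FSC, SSC) locations — lymphoid (220k, 30k),
monocytes (330k, 80k), granulocytes (430k, 250k), with basophils and
DCs slightly above the lymphoid cloud — FSC jitter 8% (normal), SSC
12% (lognormal). Pulse shape is derived from the FSC area:
width = area/1000, height = area/8, each with 5% jitter. Doublets sum
the areas, SSC, fluorescence and widths of two random singlets and keep
the larger height; dead cells keep their markers but scale the whole FSC
pulse by 0.25. The uncentrifuged counting tube shifts all cell FSC by
x1.3. Spillover mixes the true signals through a modest within-laser
matrix (`observed = true · S`), and additive Gaussian acquisition noise
(sd 10 units) makes compensated negatives appear, as on a real
instrument.

Event times are uniform over a 60 s acquisition; an optional burst
artifact `(start, duration, rate multiplier)` produces the
rate-irregularity the Flow-gate is designed to remove. One master seed
spawns an independent substream per panel, so adding or dropping a panel
never perturbs the other panels' events.

### 1.3 Counting beads

Beads are FSC-low (60k) / SSC-high (600k), tightly distributed (4% CV),
fluorescent at 50k (10% CV) in FL1–FL4 and FL8. A bead doublet doubles
FSC at unchanged SSC. The tube holds `beads_per_tube` (default 10,000)
in `blood_volume_ul` (default 50 µL) of blood at 6,000 leukocytes/µL;
an `acquired_fraction` scales cells and beads together, which is what
makes the absolute-count formula invariant to how much of the tube is
measured.

### 1.4 What the simulator does **not** emulate

No donor-to-donor biology, cell cycle, or cytokine response; no
autofluorescence spectra, time drift, or carry-over; intensity
distributions are cleanly separated lognormals, so the shipped split
thresholds classify near-perfectly. Passing recovery tests therefore
establish the *correctness of the analysis logic* (gate algebra,
conventions, propagation, statistics), not that the default thresholds
would segment real donor data — on real data the thresholds must be
recalibrated against FMO-style controls.

## 2. Preprocessing and morphology QC

The manually drawn gates of interactive analysis are replaced by
deterministic rules (`QcConfig`, raw units):

* **Flow-gate** — events are binned into 1 s windows; windows whose
  event rate deviates from the median by more than 5x the MAD are
  excluded wholesale. A Poisson floor on the MAD keeps perfectly flat
  streams from zero-MAD artifacts; a trailing partial window is merged
  into its neighbour. Acquisitions shorter than three windows are kept
  entirely (with a warning).
* **Doublet gates** — stage one keeps events whose FSC area/width ratio
  lies within ±25% of the median; stage two applies the same ±25% band
  to area/height, anchored on the stage-one survivors' median. Doublets
  (summed area at single height) fail stage two.
* **All Cells gate** — FSC ≥ 130k (×1.3 for the counting tube) and
  SSC ≥ 1k. Excluded events are annotated `debris` (low FSC *and*
  SSC < 18k) or `low_fsc` (the dead/dying fraction). Retained events get
  informative PBL/Mo/Gr scatter classes (SSC < 55k / 55–150k / ≥150k);
  marker gating always runs on the full All Cells mask.

No dead-cell dye is modelled: in fresh blood the reduced-FSC exclusion
covers the (sub-1%) dead fraction, and the corresponding dye channel is
deliberately left free.

**Compensation** solves `observed = true · S` per event with row =
source fluorochrome and unit diagonal; a condition number above 1e12 is
treated as singular. **Logicle** display uses the standard biexponential
`S(x) = a·e^{bx} − c·e^{−dx} − f` with reflection below the
linearization point; parameters default to T = 1,048,576, M = 4.5
decades, W = 0.5, A = 0, overridable per channel. The inverse is closed
form; the forward map seeds from a cached 2^14-point grid and polishes
with three Newton steps (round-trip error ~1e-12 relative; with
W = A = 0 it agrees with pure log10 above 10^3 to <1e-3 display units).
FSC is displayed linearly and SSC on a 4.5-decade log scale.

## 3. Gating engine and conventions

Gates live in display space (where they are drawn) and are converted
from raw-unit cut points at schema build time. All boundaries are
half-open `[lo, hi)`; the four cells of a quadrant therefore partition
their parent exactly and no event can belong to two cells. Geometric
kinds: threshold, rectangle, quadrant cell, simple polygon
(matplotlib-path containment). Boolean gates are expression trees over
gate ids (`&`, `|`, `!`, parentheses) evaluated elementwise — a union
counts every event once, which is what makes the NKT definition
("CD3⁺ and any NK marker") well-defined. Trees are evaluated
topologically, each node's mask intersected with its parent's;
`%parent` is relative to the immediate parent, `%major` to the panel's
major-cell-type gate, `%all cells` to the QC-passed root. Populations
below 100 events are flagged invalid.

Split thresholds are geometric midpoints between adjacent template
levels (e.g. CD3⁺ at 600 between 30 and 12,000; CD8 hi/lo at 8,660
between 1,500 and 50,000), stored per marker with named cuts (`pos`,
`hi`, `lo`, monocyte-specific `mono_pos`/`mono_hi`) and overridable per
run. "Two-pattern" monocyte readouts (CD64, CD86, HLA-DR as `+` vs
`hi`) use two thresholds on one marker.

## 4. The 12-panel schema

Panel contents follow the standard channel assignment of a 10-color
instrument; the T-cell identification gate is *linked* across the four
T panels and the NK gates are linked between the two NK panels
(identical geometry, shared ids). Noteworthy design choices at points
where the assay definition is genuinely open:

* pDC are HLA-DR⁺ (like all DCs); basophils are the HLA-DR⁻/CD123⁺
  branch of the lineage-negative gate.
* mDC-2 is the CD1c⁻ fraction of mDC; no second mDC-2 marker is
  modelled.
* Each panel's NKT union uses exactly the NK markers that panel stains
  (CD56/CD16/CD314 in one, CD56/CD16/CD94/CD159a/CD159c in the other).
* TH lineage subsets use CD183/CD196; the TREG gate is CD25hi/CD127−lo
  inside TH.
* Transitional B requires CD24hi (not merely CD24⁺).
* The regulatory-B gate works on "Rest of B" — B cells outside the five
  classical subsets — then selects CD27⁺/CD24hi.
* DNT/DPT and the CD4lo/CD8lo edge gates are recorded (they appear in
  the report) but not sub-analyzed.
* The counting tube classifies majors strictly sequentially
  (T → B → monocytes/granulocytes by scatter → NK → rests), each step
  excluding the cells already identified, so majors + rests partition
  the CD45⁺ leukocytes by construction.

### 4.1 The 208-population report

The per-sample enumeration (what a standard report contains) totals 208:

| panel | populations | content |
| --- | --- | --- |
| P01 | 34 | T; TH/T8hi/T8lo/TC/DNT/DPT + 3 edge gates; 12 memory subsets; 12 CD38⁺ readouts |
| P02 | 7 | T; TH; TH1/TH2/TH17/TH1-17; TREG |
| P03 | 4 | T; TCRαβ; TCRγδ; CD152⁺ T |
| P04 | 15 | CD19⁺/CD20⁺/B; B-on-PBL alignment; 4 CD27xCD38 cells; 5 subsets; Rest of B; BREG |
| P05 | 13 | T; B; 6 T-activation; 5 B-activation readouts |
| P06 | 26 | CD3⁻; NK; NK1-3; 3 NK readouts; 9 subset readouts; CD314 cross-check (4); T; 3 NKT gates; NKT |
| P07 | 24 | CD3⁻; NK; NK1-3; 3 heterodimer readouts; 9 subset readouts; T; 5 NKT gates; NKT |
| P08 | 40 | Mo; Mo1-4; 7 activation readouts; 7x4 subset-level activation |
| P09 | 5 | granulocytes; Neu; Eos; CD64⁺ Neu; CD64⁺ Eos |
| P10 | 11 | LIN⁻; HLA-DR⁻; basophils; DCs; pDC/mDC/mDC-1/mDC-2; All DCs; CD83⁺/CD274⁺ DC |
| P11 | 11 | EPC gate + CD45± split; CD45−/lo; CEC; HSC + CD133± split; 2 All-Cells alignment gates; HSPC union |
| P12 | 18 | leukocytes; 5 majors; Rest 1–4; Rest of PBL/cells; CD16 splits of Gr and Mo |

The subset bookkeeping counts terminal subsets (34 immune: 14 T, 6 B,
4 NK incl. NKT, 4 monocyte, 3 granulocyte, 3 DC) plus HSC/EPC/CEC = 37;
intermediate gates (T, TH, TC, B, NK, Mo, DC, mDC) are parents, not
subsets. Activation readouts are counted as (cell type, marker)
assignments: 8 on T, 5 on B, 6 on NK, 4 on monocytes, CD64 on
neutrophils and on eosinophils, 2 on DCs = 27.

One known definitional overlap is kept deliberately: a CD133⁺ HSC also
satisfies the EPC gate (CD146⁻/CD133⁺), as the phenotype definitions of
these rare cells genuinely overlap; the HSPC Boolean union exists for
exactly this reason, and the planted-phenotype tests assert exclusivity
only within each definition family.

## 5. Absolute counting

Beads are found in a raw-scatter box (FSC < 250k, SSC > 400k — generous
on the low-FSC side so small beads are not discarded with debris) and
counted per channel as fluorescence-positive events (> 5,000 units).
Beads must be counted *before* pulse-shape doublet exclusion — that gate
would remove the very bead doublets that need to be added back twice.
The singlet/doublet split per channel is the FSC histogram valley
between 1.15x and 1.85x the singlet median, falling back to 1.5x the
median when no valley is resolvable. Effective count = singlets +
2xdoublets; the five channels are averaged. Results are per µL (a per-mL
convenience conversion exists). `beads_per_tube` is a config value, as
bead counts are lot-specific. Propagation anchors every population to
its nearest gated ancestor with a counting-tube absolute (T, B, NK, Mo,
Gr) or, for populations without one (DCs, basophils, non-leukocytes), to
the all-leukocyte count.

## 6. Robustness statistics

CV uses the sample (n−1) standard deviation — with three replicates the
population form would bias low. Validity uses the strictest reading:
a population is excluded if *any* replicate has fewer than 100 events
(`mode="mean"` is selectable). Replicate noise is a multiplicative
lognormal jitter on the profile frequencies (default σ = 0.02,
renormalized); with σ = 0 the only variation is counting noise, for
which the closed-form prediction `CV ≈ 100·sqrt((1−p)/(p·n))` holds and
is used as the oracle in tests. Note that a sample CV from three
replicates is itself very noisy (chi distribution with 2 degrees of
freedom), so per-population agreement with the prediction is asserted
as an upper bound with the two-sided check applied to the median across
populations.

## 7. Problem sizes and tolerances used in the test suite

Frequency-recovery runs use 100,000 events per standard panel (300,000
for the triple-volume rare-cell panels and the counting tube) against
3σ binomial bounds plus a 3-event slack for QC edge effects;
planted-phenotype runs use 4,000 events and require ≥98% recovery with
≤1% leakage into excluded siblings; bead recovery uses 10,000 beads with
a 1% tolerance; end-to-end absolute counts use a 5% tolerance. The
logicle round-trip is checked to 1e-6 relative (achieved: ~1e-12) and
compensation inversion to 1e-9.

## 8. Known limitations

* FCS support is deliberately narrow: FCS 3.1, single dataset, float32
  list mode. No FCS 2.0 log-amplifier scaling, no multi-dataset files.
* Split thresholds ship calibrated to the simulator; real data requires
  per-site recalibration (the package provides the override mechanism,
  not the calibration).
* The Flow-gate's median/MAD rule is an automated stand-in for visual
  inspection of the event-rate trace; there is no community-standard
  numeric criterion for it.
* Scatter-based monocyte/granulocyte separation in the counting tube
  assumes the classes' SSC distributions do not overlap at the
  configured boundaries, which holds for the simulator's geometry but is
  optimistic for degraded real samples.
* No plotting beyond what users build from the exported tables; the
  report bundle is CSV/JSON.
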