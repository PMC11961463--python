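# glycocurate

Automated curation of label-free LC–MS glycoproteomics and glycomics
quantitation output.

High-throughput bottom-up glycoproteomics quantifies hundreds of
glycopeptides — a peptide backbone identifying protein and glycosylation
site, carrying a glycan composition such as `H5N4F1S1` — across hundreds to
thousands of samples on 96-well plates. Upstream tools (LaCyTools-style
summaries, Skyline-style reports) deliver per-analyte intensities together
with three quality metrics: mass error (ppm), an isotopologue-pattern score,
and a signal measure. Before statistics, the dataset must be *curated*:
whole measurements (spectra) of insufficient quality excluded per
glycosylation site, and a defensible list of quantifiable analytes selected.
Doing this by hand is slow and irreproducible; `glycocurate` is a headless
library + CLI that automates it and records every decision.

The pipeline:

1. **Ingest** — parse either quantitation dialect into one long record
   table; link plate positions (`plate1_C10`) to sample IDs via a layout
   workbook; infer sample types (sample / pool / blank / negative control)
   from IDs; rename co-eluting isomers (`N1` → `N1a`, `N1b`); merge
   metadata by sample ID.
2. **Quality flags** — per record, pass iff mass error is inside the window
   and the pattern score and signal measure clear their thresholds
   (defaults: ±20 ppm, IPQ ≤ 0.2, S/N ≥ 9 for LaCyTools; ±2 ppm,
   idotp ≥ 0.9, area > 0 for Skyline).
3. **Spectra curation** — per (sample, site), compute the sum intensity of
   passing analytes and the fraction of the targeted list passing; exclude
   measurements below a per-site 2-D cutoff derived from negative controls
   (a percentile of the controls, default 95th), from a lower percentile of
   the samples themselves, or skip the step.
4. **Analyte curation** — per analyte × charge state, the frequency of
   surviving measurements in which it passes quality; lists built per
   biological group are merged into a consensus by AND/OR set logic
   (typical frequency cutoffs: 80% for high-, 50% for medium-quality data);
   manual overrides are tracked.
5. **Normalization and traits** — total-area normalization per site
   (relative abundances in %, summing to 100), then derived glycosylation
   traits from a formula mini-language
   (`trait := sum [ "/" sum ]`, e.g. `0.5 * IgGI1H4N4F1 + IgGI1H5N4F1`).
6. **Optional** — absolute quantitation from stable-isotope-labelled (SIL)
   spikes (median over peptides of light/heavy ratio × spiked amount), and
   intra-/inter-plate repeatability (CV = 100·sd/mean) of a pooled control.

Every run emits a wide statistics-ready table (metadata → traits →
site-prefixed analyte abundances) and a JSON report holding all settings,
input digests, cutoffs and curation outcomes, from which the run can be
replayed exactly. A seeded synthetic-data generator emulates both dialects
with planted ground truth so the whole pipeline is testable offline.

## Worked example

```python
from glycocurate import SimulationSpec, simulate, run_pipeline

sim = simulate(SimulationSpec(seed=5), outdir="demo")   # writes both dialects
result = run_pipeline({
    "inputs": {"dialect": "lacytools",
               "data": str(sim.paths["lacytools"]),
               "layout": str(sim.paths["layout"]),
               "metadata": str(sim.paths["metadata"])},
    "spectra": {"strategy": "negative_control", "percentile": 95},
    "analytes": {"grouping": "by_group", "group_column": "group", "min_freq": 0.5},
    "traits": {"formulas": "igg_example"},
}, outdir="demo_out")

print("measurements kept:", len(result.kept), "of", len(result.summaries))
print("consensus entries:", len(result.consensus.retained))
print(result.wide_abund.iloc[:2, :3].round(2))
```

prints

```
measurements kept: 148 of 192
consensus entries: 40
             IgGI1H3N4  IgGI1H3N4F1  IgGI1H3N5F1
sample_id
patient_001      16.27        16.00         9.94
patient_002      19.91        10.03        14.18
```

Of the 192 (sample, site) measurements of this 96-sample, two-site cohort,
148 survive: the planted low-quality tail, the blanks and the negative
controls themselves fall below the control-derived cutoffs (for site
`IgGI1`: sum intensity 4.3, passing fraction 0.300). The consensus keeps 40
analyte × charge entries (both groups' panels merged by OR), and the wide
table holds each analyte as a percentage of its site's summed signal. The
derived traits (e.g. `fucosylation` 69.8% for `patient_001`) and the
repeatability of the pooled control (median intra-plate CV 29.8% on this
deliberately noisy simulation) are in `demo_out/`.

The same run from a shell:

```bash
glycocurate simulate --seed 5 --outdir demo
glycocurate run --config demo.yaml --outdir demo_out      # same keys as above, YAML
glycocurate traits --example --outdir .                   # example formula workbook
```

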