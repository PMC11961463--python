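# Methods

This note documents the models, defaults and numerical choices behind
`glycocurate`, and what the synthetic-data generator does and does not
emulate.

## Scope and assumptions

The engine starts where upstream quantitation ends: glycopeptides (or
released glycans) have been identified, integrated and scored by a
LaCyTools- or Skyline-style tool. It consumes per-analyte quantities and
three quality metrics as-is — it never re-computes pattern scores or
signal-to-noise from raw spectra, performs no retention-time alignment or
mass calibration, and does not infer glycan structures. Sample handling
assumes 96-well plates (rows A–H, columns 1–12); other geometries are
rejected rather than guessed at.

Analyte names follow the `siteH5N4F1S1` convention: a site/peptide prefix
followed by monosaccharide counts over a configurable alphabet (default
H, N, F, S, G). The paper-style "split before the first number" rule breaks
on site identifiers that contain digits (e.g. `peptide1H5N4F1S1`), so the
default rule splits before the first *alphabet-letter-followed-by-digit*
token, which parses both digit-bearing and plain prefixes sensibly; a
strict first-digit mode is available for corpora whose site names are
digit-free. A single trailing lowercase letter is an isomer suffix.

## Input dialects

**Skyline-style report (CSV).** Key columns `Protein name` (the site;
released-glycan data uses a placeholder such as `AB`), `Peptide` (the
composition) and `Precursor Charge`; per sample, three columns suffixed
`Isotope Dot Product`, `Average mass error PPM`, `Total area MS1`. The
isotope dot product measures similarity to the theoretical isotopologue
pattern (1 = perfect); the MS1 area doubles as intensity and signal
measure. A `sample_regex` escape hatch restricts which column prefixes are
treated as samples when replicate naming is unusual.

**LaCyTools-style summary (tab-separated text).** Real-world summary
layouts vary by version; this package and its generator co-define one
documented form, and the parser additionally tolerates blank lines between
blocks and accepts blocks in any order. Per charge state, four blocks —
`Analyte Intensity (background subtracted)`, `Mass Accuracy [ppm]`,
`Isotopic Pattern Quality`, `S/N` — each formatted as

```
<block name>\tcharge=<z>
\t<analyte 1>\t<analyte 2>...
<measurement file>\t<value>\t<value>...
```

The four blocks of one charge must agree on measurement files and analyte
columns; disagreement is a structural error naming the block. The isotopic
pattern quality (IPQ) measures *deviation* from the theoretical pattern
(0 = perfect) — the opposite directionality from the idotp — and the signal
measure is a signal-to-noise ratio. Blank cells become explicit missing
values at ingest, never zeros; zeroing is available only as a
spectra-curation policy.

Duplicate compositions on one site are assumed to be chromatographically
separated isomers in Skyline data and are renamed with running lowercase
letters in order of file appearance (deterministic and idempotent;
consistent assignment presumes conserved retention order). In LaCyTools
input, duplicate compositions indicate upstream integration errors and are
rejected.

## Quality flags

A record passes iff all three criteria hold; a missing value in any
criterion fails the record, since a quantity without quality metrics cannot
be trusted. Defaults (configurable per run):

| dialect | mass error | pattern | signal |
|---|---|---|---|
| lacytools | −20 … +20 ppm (inclusive) | IPQ ≤ 0.2 | S/N ≥ 9 |
| skyline | −2 … +2 ppm (inclusive) | idotp ≥ 0.9 | area > 0 (strict) |

All comparisons are inclusive except the Skyline area, which is strict so
that the meaningful default threshold of 0 rejects zero-area analytes.

## Spectra curation

Each (sample, site) measurement is summarised by (a) the sum intensity of
quality-passing analytes and (b) the number of passing analyte × charge
combinations divided by the full targeted-list size for the site — the
denominator ignores how many analytes were actually detected, and counts
combinations (not compositions) so that this step and the per-charge
analyte curation use the same unit; a configurable alternative is noted
below. Sites are curated independently because data quality differs
between them.

Three cutoff strategies:

* **skip** — keep everything.
* **negative_control** — per dimension, the cutoff is a percentile
  (default 95) of the values observed in negative-control measurements;
  percentile 100 is the control maximum. Percentiles use linear
  interpolation between order statistics (the numpy default) — documented
  because control sets are small and quantile definitions diverge. An
  advanced variant assumes normality: cutoff = mean + z(p)·sd of the
  controls, with the one-sided standard-normal quantile and sample sd
  (n−1); a single control degenerates to that control's value. Controls
  without values are ignored; a site with no control values at all keeps
  everything, with a warning, since the curation would be vacuous.
* **percentile** — per dimension, a lower percentile of the real samples'
  own values; all control and blank types must be excluded from the
  computation. Because the percentile applies per dimension, the jointly
  excluded fraction can exceed it. Percentile 0 is special-cased to "no
  exclusion": the 0th percentile is the sample minimum and the strict rule
  below would otherwise always exclude one sample.

A measurement is kept iff it is **strictly above** the cutoff in *both*
dimensions. Strictness makes the rule self-consistent for the
negative-control strategy at percentile 100: every control is ≤ the control
maximum, hence excluded. An inclusive rule is available. Measurements with
no values at all are excluded by default, or compared as zeros under the
`zero` policy (and hence excluded whenever cutoffs are positive). The
exclusion log records the failing dimension(s) per measurement and is
summarised per sample type.

## Analyte curation

After spectra curation, each (site, analyte, charge) entry is judged by the
relative frequency of eligible measurements in which it passes quality.
Eligible means: survived spectra curation *and* has values for the site —
counting empty measurements would deflate frequencies. Charge states are
curated individually because their quality differs with analyte size and
acidity. Frequencies can be computed over the whole dataset, per biological
group (recommended when groups with expected qualitative differences exist;
groups below 10 eligible samples trigger a warning), or per sample.
Optionally only a subset of samples (e.g. one measurement series) informs
the frequencies while the resulting list is applied to all measurements —
the default resolution of an otherwise ambiguous scope question, and
configurable.

Per-scope lists keep entries with frequency ≥ the user cutoff (inclusive,
so 50% keeps an analyte passing in exactly half the samples); group lists
merge by OR (union, preserving group-specific analytes) or AND
(intersection). An empty consensus is an error because downstream
normalization would be undefined. Manual overrides (a keep/drop table keyed
by entry) always win and are flagged in the provenance; applying the same
overrides twice is a no-op. In consensus mode, non-retained entries are
removed from every sample (retained entries keep their values even in
samples where they failed quality — removal is list-based); in per-sample
mode each sample keeps exactly its own passing records.

## Normalization and traits

Total-area normalization: per (sample, site), retained charge states of an
analyte are summed, then each analyte is expressed as a percentage of the
site's summed signal. Sites are independent; a zero or all-missing site
total yields missing values rather than a division by zero; abundances of a
non-empty site sum to 100 within floating-point error.

Trait formulas are space-tokenized: `formula := sum [ "/" sum ]`,
`sum := term { "+" term }`, `term := [ number "*" ] analyte-name`, with
full analyte names (site prefix + composition). `/` binds last and may
occur once — a second `/` is a parse error rather than a silently chained
division; there are no parentheses. Ratio traits are reported on the same
percentage scale as the abundances (numerator/denominator × 100, the share
of the subset), so `A / A + B` with A = 50%, B = 30% gives 62.5. Formula
analytes absent from the dataset are dropped from numerator and denominator
alike — numerically identical to zeroing for sums, but matching "ignored"
semantics for ratios; a zero-as-absent policy is available. Within a
sample, missing analyte values count as zero unless every referenced
analyte is missing (an excluded measurement), which yields a missing trait.
Dataset analytes covered by no formula are reported so the formula set can
be extended. The shipped `igg_traits_example.csv` demonstrates the syntax
on human IgG Fc N-glycans (fucosylation, bisection, galactosylation and
sialylation per antenna, a ratio-type renormalization); it is illustrative
configuration, not a validated clinical trait set.

## SIL quantitation and repeatability

With a stable-isotope-labelled standard spiked at a known amount, each
quantifying peptide estimates the protein quantity as
(Σ light intensity / Σ heavy intensity) × spiked amount; the per-sample
protein quantity is the median over peptides, and pairwise Pearson
correlations of per-peptide quantities across samples serve as a quality
check. A missing or zero heavy signal skips that peptide for the sample
with a warning.

Repeatability uses repeated measurements of a pooled technical control.
CV = 100·sd/mean with the sample sd (n−1); undefined when n < 2 or the
mean is 0. Intra-plate: CV per (plate, analyte) over that plate's
replicates (plates with fewer than two replicates omitted), median over
plates and analytes. Inter-plate: per analyte, the CV of plate means,
median over analytes. The two-level aggregation is one defensible choice
among several; both intermediate tables are exported so users can
re-aggregate.

## Reporting and replay

The JSON report contains the tool version, input paths and SHA-256 digests,
the complete effective configuration, quality criteria, per-site cutoffs,
exclusion counts per sample type, the consensus list with per-group
frequencies and override flags, serialized trait formulas, and all
warnings. Apart from the timestamp it is a pure function of inputs and
settings; the pipeline has no randomness, so replaying a report reproduces
kept sets and exports byte-for-byte.

## Synthetic-data generator

The generator emulates the structure the curation steps assume: plates of
real samples, pooled positive controls, buffer blanks and negative
controls; per site a targeted panel (a curated list of typical diantennary
IgG-Fc-style compositions) in one or more charge states with a planted
relative-abundance profile (a Dirichlet draw floored at half-uniform, so no
analyte is vanishingly rare); lognormal intensities (σ = 0.4, draws clipped
at ±3 sd); and a quality structure of a dense good cluster plus a
low-quality tail. Defaults describe a mid-size cohort: 2 plates × 48
wells, 80% samples / 6% pools / 6% blanks / 8% negative controls, two
sites × 10 compositions × charges 2–3, two equal biological groups each
owning one group-specific analyte, a 10% low-quality tail and 1% blanked
cells.

Quality strata are deliberately separated so planted outcomes are
unambiguous at the default thresholds: passing records draw metrics well
inside the windows (e.g. mass error ~ N(0, 3 ppm) clipped to ±12), failing
records well outside (|mass error| ≥ 25 ppm, IPQ ≥ 0.3, S/N ≤ 5, and the
Skyline counterparts); good spectra pass ≥ 85% of the targeted list at full
intensity, negative controls pass 3–6 combinations at 10⁻⁴ of the
intensity scale, and the tail (including blanks) passes at most 2 at 10⁻⁷ —
strictly dominated below the controls in both curation dimensions, so
negative-control curation at percentile 100 excludes exactly tail + blanks
+ controls. Both dialect files are written from the same draws, so pipeline
outcomes agree across dialects at the corresponding default thresholds.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: borderline quality values near the
thresholds, correlated quality failures (e.g. a drifting spray), plate or
batch effects on intensities, retention-time or calibration artefacts,
isotopologue interference between co-eluting analytes, and realistic
missingness mechanisms (cells are blanked completely at random). Real
datasets also mix dialect quirks the co-defined layout deliberately fixes.

The SIL generator plants per-sample true quantities (uniform 5–50 units at
spike 10) and applies lognormal noise of scale σ (default 0.1) to each
peptide's light/heavy *ratio*, the two signals sharing their other
variation — the noise parameter thus directly describes the per-peptide
quantity error.

## Verification problem sizes

The acceptance script runs desk-scale cohorts chosen to exercise every code
path while completing in seconds: 208 samples × 2 sites × 20
analyte-charges for planted-spectra recovery; 10,000 randomized records per
dialect for the quality-flag oracle; 50 random group-list pairs and an
11-point cutoff sweep for consensus algebra; 100 random formula sets for
the trait engine; 50 samples × 3 peptides for SIL recovery; and the default
96-sample cohort for normalization, replay and repeatability.

## Known limitations

* The LaCyTools layout is the documented co-defined dialect; summaries from
  tool versions with different block arrangements need conversion.
* Wells are fixed to 96-well geometry.
* Trait formulas have no parentheses and at most one division; deeper
  expressions must be decomposed into intermediate traits.
* Per-sample analyte curation yields sample-specific analyte sets; the wide
  export then contains structurally missing values, and quantitative
  comparisons across samples should be made with care.
* SIL quantitation assumes the ratio source (summed intensities) matches
  how the spike behaves; no calibration curves or LLOQ estimation.
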