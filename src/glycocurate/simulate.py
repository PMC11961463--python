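"""Synthetic-data generator for both quantitation dialects, with ground truth.

The generator emulates the structure of a plate-based label-free LC-MS
glycoproteomics study: 96-well plates holding real samples, pooled positive
controls, buffer blanks and negative controls; per glycosylation site a
targeted list of glycan compositions quantified in one or more charge states;
and a quality structure consisting of a dense cluster of good measurements
plus a low-quality tail.

Quality strata are deliberately well separated so that planted curation
outcomes are unambiguous at the default cutoffs:

* *good* spectra (real samples and pools) draw per-analyte quality metrics
  well inside the default thresholds and pass a high fraction of the
  targeted list at full intensity;
* *negative controls* pass only a small fraction at strongly reduced
  intensity;
* the *low-quality tail* (a planted fraction of real samples, and all buffer
  blanks) is strictly dominated below the negative controls in both curation
  dimensions, so that negative-control curation at percentile 100 excludes
  exactly the tail, the blanks and the controls themselves.

Both dialect files are written from the same underlying draws, so pipeline
outcomes on the two files agree when thresholds are set to the corresponding
defaults.  Intensities are lognormal around a planted per-site relative
abundance profile; biological groups may carry group-specific analytes that
never pass outside their own group (emulating qualitative group differences).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import composition_catalogue
from .ingest import (
    LACY_BLOCK_INTENSITY,
    LACY_BLOCK_IPQ,
    LACY_BLOCK_MASS,
    LACY_BLOCK_SN,
    LACYTOOLS,
    RECORD_COLUMNS,
    SKYLINE,
)

WELLS_96 = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]

CLASS_GOOD = "good"
CLASS_TAIL = "low_quality_tail"
CLASS_CONTROL = "negative_control"
CLASS_EMPTY = "empty"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset.

    Defaults describe a mid-size two-plate cohort with the sample-type mix
    typical of plate-based antibody glycosylation studies (mostly real
    samples, a few pooled positive controls, buffer blanks and negative
    controls per plate), ten targeted compositions per site in two charge
    states, two equal biological groups each carrying one group-specific
    analyte, and a 10% low-quality tail.
    """

    seed: int = 0
    n_plates: int = 2
    samples_per_plate: int = 48
    sample_type_mix: tuple[tuple[str, float], ...] = (
        ("sample", 0.80),
        ("pool", 0.06),
        ("blank", 0.06),
        ("negative_control", 0.08),
    )
    sites: tuple[str, ...] = ("IgGI1", "IgGII1")
    analytes_per_site: int = 10
    charges: tuple[int, ...] = (2, 3)
    biological_groups: tuple[tuple[str, float], ...] = (("ICU", 0.5), ("nonICU", 0.5))
    group_specific_analytes: int = 1
    fraction_low_quality_spectra: float = 0.10
    fraction_empty_spectra: float = 0.0
    fraction_missing_cells: float = 0.01
    good_pass_fraction_min: float = 0.85
    control_pass_range: tuple[int, int] = (3, 6)  # passing analyte-charge counts
    tail_pass_range: tuple[int, int] = (0, 2)
    base_intensity: float = 1.0e5
    control_intensity_scale: float = 1.0e-4
    tail_intensity_scale: float = 1.0e-7
    fail_intensity_scale: float = 1.0e-2
    intensity_sigma: float = 0.4

    def validate(self) -> None:
        mix = dict(self.sample_type_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("sample_type_mix proportions must sum to 1")
        if self.analytes_per_site < 1:
            raise ValueError("need at least one analyte per site")
        if not self.sites or not self.charges:
            raise ValueError("need at least one site and one charge state")
        if self.samples_per_plate < 1 or self.samples_per_plate > 96:
            raise ValueError("samples_per_plate must be in 1..96 (96-well plates)")
        groups = dict(self.biological_groups)
        if groups and abs(sum(groups.values()) - 1.0) > 1e-9:
            raise ValueError("biological group proportions must sum to 1")
        n_targeted = self.analytes_per_site * len(self.charges)
        n_specific_other = self.group_specific_analytes * max(len(groups) - 1, 0)
        n_allowed = (self.analytes_per_site - n_specific_other) * len(self.charges)
        if math.ceil(self.good_pass_fraction_min * n_targeted) > n_allowed:
            raise ValueError(
                "good_pass_fraction_min is infeasible given the group-specific panels"
            )
        if self.control_pass_range[1] > n_targeted:
            raise ValueError("control_pass_range exceeds the targeted list size")
        if self.tail_pass_range[1] >= self.control_pass_range[0]:
            raise ValueError(
                "tail passing counts must stay strictly below control passing counts"
            )


@dataclass
class GroundTruth:
    """What the generator planted, recorded at generation time."""

    spectra: pd.DataFrame  # sample_id, site, spectrum_class, keep, reason
    frequencies: dict[str, pd.DataFrame]  # scope -> site/analyte/charge/n_pass/n_eligible/frequency
    abundance_profile: pd.DataFrame  # group, site, analyte_full, expected_pct
    n_records: int
    n_blanked: int


@dataclass
class SimulationResult:
    spec: SimulationSpec
    truth: pd.DataFrame  # one row per (sample, site, analyte, charge) cell
    annotations: pd.DataFrame  # sample_id, sample_type, plate, well, group
    layout: pd.DataFrame  # plate, well, sample_id
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)

    def expected_records(self, dialect: str) -> pd.DataFrame:
        """The record table a faithful reader of the emitted file must return."""
        t = self.truth
        frame = pd.DataFrame(
            {
                "measurement_file": t["measurement_file"],
                "sample_id": pd.NA,
                "plate": pd.NA,
                "well": pd.NA,
                "sample_type": pd.NA,
                "site": t["site"],
                "composition": t["analyte"],
                "isomer_suffix": "",
                "analyte": t["analyte"],
                "analyte_full": t["site"] + t["analyte"],
                "charge": t["charge"].astype(int),
                "intensity": t["intensity"],
                "dialect": dialect,
                "source_order": 0,
            }
        )
        if dialect == LACYTOOLS:
            frame["mass_error_ppm"] = t["mass_error_lacy"]
            frame["pattern_score"] = t["ipq"]
            frame["signal_measure"] = t["sn"]
        elif dialect == SKYLINE:
            frame["mass_error_ppm"] = t["mass_error_sky"]
            frame["pattern_score"] = t["idotp"]
            frame["signal_measure"] = t["intensity"]
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        return frame[RECORD_COLUMNS]


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: p * n for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(proportions, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def _build_plan(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Assign wells, sample types, IDs and biological groups."""
    mix = dict(spec.sample_type_mix)
    rows = []
    counters = {t: 0 for t in mix}
    for plate_idx in range(1, spec.n_plates + 1):
        counts = _largest_remainder(mix, spec.samples_per_plate)
        type_sequence = [t for t in counts for _ in range(counts[t])]
        type_sequence = list(rng.permutation(type_sequence))
        for well, stype in zip(WELLS_96, type_sequence):
            counters[stype] += 1
            prefix = {
                "sample": "patient",
                "pool": "pool",
                "blank": "blank",
                "negative_control": "negctrl",
            }.get(stype, stype)
            rows.append(
                {
                    "plate": f"plate{plate_idx}",
                    "well": well,
                    "sample_type": stype,
                    "sample_id": f"{prefix}_{counters[stype]:03d}",
                }
            )
    plan = pd.DataFrame(rows)
    plan["measurement_file"] = plan["plate"] + "_" + plan["well"]
    groups = dict(spec.biological_groups)
    plan["group"] = pd.NA
    if groups:
        idx = plan.index[plan["sample_type"] == "sample"].to_numpy()
        counts = _largest_remainder(groups, len(idx))
        labels = [g for g in counts for _ in range(counts[g])]
        labels = list(rng.permutation(labels))
        plan.loc[idx, "group"] = labels
    return plan


def simulate(spec: SimulationSpec, outdir: str | Path | None = None) -> SimulationResult:
    """Draw one dataset and optionally write all input files plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plan = _build_plan(spec, rng)

    charges = tuple(spec.charges)
    n_charges = len(charges)
    charge_weights = np.array([0.7**i for i in range(n_charges)])
    charge_weights /= charge_weights.sum()
    groups = [g for g, _ in spec.biological_groups]

    # per-site targeted compositions and panels
    site_analytes: dict[str, list[str]] = {}
    site_profile: dict[str, np.ndarray] = {}
    specific_of: dict[str, dict[str, str | None]] = {}  # site -> analyte -> owning group
    n_specific_total = spec.group_specific_analytes * len(groups)
    for site in spec.sites:
        labels = composition_catalogue(spec.analytes_per_site)
        site_analytes[site] = labels
        dirichlet = rng.dirichlet(np.full(spec.analytes_per_site, 2.0))
        site_profile[site] = 0.5 * dirichlet + 0.5 / spec.analytes_per_site
        owners: dict[str, str | None] = {a: None for a in labels}
        if groups and spec.group_specific_analytes > 0 and n_specific_total <= len(labels):
            tail = labels[-n_specific_total:]
            for gi, g in enumerate(groups):
                for a in tail[
                    gi * spec.group_specific_analytes : (gi + 1) * spec.group_specific_analytes
                ]:
                    owners[a] = g
        specific_of[site] = owners

    n_targeted = spec.analytes_per_site * n_charges
    good_lo = math.ceil(spec.good_pass_fraction_min * n_targeted)

    # spectrum classes per (sample, site)
    class_rows = []
    sample_ids_of_type = plan.groupby("sample_type")["sample_id"].apply(list).to_dict()
    for site in spec.sites:
        real = list(sample_ids_of_type.get("sample", []))
        n_tail = int(round(spec.fraction_low_quality_spectra * len(real)))
        tail_ids = set(rng.choice(real, size=n_tail, replace=False)) if n_tail else set()
        remaining = [s for s in real if s not in tail_ids]
        n_empty = int(round(spec.fraction_empty_spectra * len(real)))
        empty_ids = (
            set(rng.choice(remaining, size=n_empty, replace=False)) if n_empty else set()
        )
        for row in plan.itertuples(index=False):
            if row.sample_type in ("sample",):
                if row.sample_id in tail_ids:
                    cls = CLASS_TAIL
                elif row.sample_id in empty_ids:
                    cls = CLASS_EMPTY
                else:
                    cls = CLASS_GOOD
            elif row.sample_type == "pool":
                cls = CLASS_GOOD
            elif row.sample_type == "blank":
                cls = CLASS_TAIL
            elif row.sample_type == "negative_control":
                cls = CLASS_CONTROL
            else:
                cls = CLASS_GOOD
            class_rows.append(
                {"sample_id": row.sample_id, "site": site, "spectrum_class": cls}
            )
    classes = pd.DataFrame(class_rows)

    # draw every cell
    records: list[dict] = []
    for site in spec.sites:
        labels = site_analytes[site]
        profile = dict(zip(labels, site_profile[site]))
        owners = specific_of[site]
        pairs = [(a, z) for a in labels for z in charges]
        pair_index = {p: i for i, p in enumerate(pairs)}
        cls_of = dict(
            zip(
                classes.loc[classes["site"] == site, "sample_id"],
                classes.loc[classes["site"] == site, "spectrum_class"],
            )
        )
        for row in plan.itertuples(index=False):
            cls = cls_of[row.sample_id]
            if cls == CLASS_EMPTY:
                pass_mask = np.zeros(len(pairs), dtype=bool)
                blank_mask = np.ones(len(pairs), dtype=bool)
                scale = 0.0
            else:
                if cls == CLASS_GOOD:
                    group = None if pd.isna(row.group) else row.group
                    if group is None:
                        # pooled material contains every group's analytes
                        allowed = list(range(len(pairs)))
                    else:
                        allowed = [
                            pair_index[(a, z)]
                            for a, z in pairs
                            if owners[a] is None or owners[a] == group
                        ]
                    n_pass = int(rng.integers(good_lo, len(allowed) + 1))
                    chosen = rng.choice(allowed, size=n_pass, replace=False)
                    scale = 1.0
                elif cls == CLASS_CONTROL:
                    lo, hi = spec.control_pass_range
                    n_pass = int(rng.integers(lo, hi + 1))
                    chosen = rng.choice(len(pairs), size=n_pass, replace=False)
                    scale = spec.control_intensity_scale
                else:  # low-quality tail (incl. blanks)
                    lo, hi = spec.tail_pass_range
                    n_pass = int(rng.integers(lo, hi + 1))
                    chosen = rng.choice(len(pairs), size=n_pass, replace=False)
                    scale = spec.tail_intensity_scale
                pass_mask = np.zeros(len(pairs), dtype=bool)
                pass_mask[np.asarray(chosen, dtype=int)] = True
                blank_mask = (~pass_mask) & (
                    rng.random(len(pairs)) < spec.fraction_missing_cells
                )
            for i, (analyte, charge) in enumerate(pairs):
                passes = bool(pass_mask[i])
                blanked = bool(blank_mask[i])
                rec = {
                    "measurement_file": row.measurement_file,
                    "sample_id": row.sample_id,
                    "plate": row.plate,
                    "well": row.well,
                    "sample_type": row.sample_type,
                    "group": row.group,
                    "site": site,
                    "analyte": analyte,
                    "charge": charge,
                    "spectrum_class": cls,
                    "planted_pass": passes,
                    "blanked": blanked,
                }
                if blanked:
                    rec.update(
                        intensity=np.nan,
                        mass_error_lacy=np.nan,
                        ipq=np.nan,
                        sn=np.nan,
                        mass_error_sky=np.nan,
                        idotp=np.nan,
                    )
                else:
                    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
                    base = (
                        spec.base_intensity
                        * profile[analyte]
                        * charge_weights[charges.index(charge)]
                        * math.exp(spec.intensity_sigma * z)
                    )
                    if passes:
                        intensity = base * scale
                        rec.update(
                            intensity=intensity,
                            mass_error_lacy=float(np.clip(rng.normal(0.0, 3.0), -12.0, 12.0)),
                            ipq=float(rng.uniform(0.0, 0.15)),
                            sn=float(rng.uniform(15.0, 150.0)),
                            mass_error_sky=float(np.clip(rng.normal(0.0, 0.5), -1.6, 1.6)),
                            idotp=float(rng.uniform(0.92, 1.0)),
                        )
                    else:
                        missing = rng.random() < 0.6
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        rec.update(
                            intensity=(
                                np.nan
                                if missing
                                else base * max(scale, 1e-12) * spec.fail_intensity_scale
                            ),
                            mass_error_lacy=sign * float(rng.uniform(25.0, 60.0)),
                            ipq=float(rng.uniform(0.3, 0.9)),
                            sn=float(rng.uniform(0.0, 5.0)),
                            mass_error_sky=sign * float(rng.uniform(2.5, 8.0)),
                            idotp=float(rng.uniform(0.4, 0.85)),
                        )
                records.append(rec)
    truth = pd.DataFrame(records)

    annotations = plan[["sample_id", "sample_type", "plate", "well", "group"]].copy()
    layout = plan[["plate", "well", "sample_id"]].copy()
    meta = plan.loc[plan["sample_type"] == "sample", ["sample_id", "group"]].copy()
    meta["age"] = rng.integers(18, 90, size=len(meta))
    meta["sex"] = rng.choice(["F", "M"], size=len(meta))

    ground_truth = _ground_truth(spec, truth, classes, site_analytes, site_profile, specific_of, groups, charges)

    result = SimulationResult(
        spec=spec,
        truth=truth,
        annotations=annotations,
        layout=layout,
        metadata=meta,
        ground_truth=ground_truth,
    )
    if outdir is not None:
        result.paths = write_all(result, Path(outdir))
    return result


def _ground_truth(spec, truth, classes, site_analytes, site_profile, specific_of, groups, charges):
    spectra = classes.copy()
    spectra["keep"] = spectra["spectrum_class"] == CLASS_GOOD
    spectra["reason"] = spectra["spectrum_class"].map(
        {
            CLASS_GOOD: None,
            CLASS_TAIL: "low_quality",
            CLASS_CONTROL: "negative_control",
            CLASS_EMPTY: "no_values",
        }
    )
    types = truth[["sample_id", "sample_type", "group"]].drop_duplicates("sample_id")
    spectra = spectra.merge(types, on="sample_id", how="left")

    kept = truth.merge(
        spectra.loc[spectra["keep"], ["sample_id", "site"]],
        on=["sample_id", "site"],
        how="inner",
    )

    def freq_table(sub: pd.DataFrame) -> pd.DataFrame:
        n_eligible = sub.groupby("site")["sample_id"].nunique().rename("n_eligible")
        table = (
            sub.groupby(["site", "analyte", "charge"])["planted_pass"]
            .sum()
            .rename("n_pass")
            .reset_index()
        )
        table = table.merge(n_eligible.reset_index(), on="site")
        table["n_pass"] = table["n_pass"].astype(int)
        table["frequency"] = table["n_pass"] / table["n_eligible"]
        return table.sort_values(["site", "analyte", "charge"], kind="stable").reset_index(drop=True)

    frequencies = {"all": freq_table(kept)}
    for g in groups:
        frequencies[g] = freq_table(kept[kept["group"] == g])

    profile_rows = []
    for site in spec.sites:
        labels = site_analytes[site]
        prof = dict(zip(labels, site_profile[site]))
        owners = specific_of[site]
        for g in groups or [None]:
            allowed = [a for a in labels if owners[a] is None or owners[a] == g]
            total = sum(prof[a] for a in allowed)
            for a in allowed:
                profile_rows.append(
                    {
                        "group": g,
                        "site": site,
                        "analyte_full": f"{site}{a}",
                        "expected_pct": 100.0 * prof[a] / total,
                    }
                )
    profile = pd.DataFrame(profile_rows)
    return GroundTruth(
        spectra=spectra[
            ["sample_id", "sample_type", "group", "site", "spectrum_class", "keep", "reason"]
        ],
        frequencies=frequencies,
        abundance_profile=profile,
        n_records=len(truth),
        n_blanked=int(truth["blanked"].sum()),
    )


def _fmt(value: float) -> str:
    return "" if pd.isna(value) else repr(float(value))


def write_lacytools(truth: pd.DataFrame, path: str | Path) -> Path:
    """Emit the LaCyTools summary dialect (four blocks per charge state)."""
    path = Path(path)
    files = list(dict.fromkeys(truth["measurement_file"]))
    labels = list(dict.fromkeys(truth["site"] + truth["analyte"]))
    truth = truth.assign(label=truth["site"] + truth["analyte"])
    lines: list[str] = []
    blocks = (
        (LACY_BLOCK_INTENSITY, "intensity"),
        (LACY_BLOCK_MASS, "mass_error_lacy"),
        (LACY_BLOCK_IPQ, "ipq"),
        (LACY_BLOCK_SN, "sn"),
    )
    for charge in sorted(set(truth["charge"])):
        sub = truth[truth["charge"] == charge]
        for block_name, column in blocks:
            grid = sub.pivot(index="measurement_file", columns="label", values=column)
            grid = grid.reindex(index=files, columns=labels)
            lines.append(f"{block_name}\tcharge={charge}")
            lines.append("\t" + "\t".join(labels))
            for mfile in files:
                row = grid.loc[mfile]
                lines.append(mfile + "\t" + "\t".join(_fmt(v) for v in row))
            lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_skyline(truth: pd.DataFrame, path: str | Path) -> Path:
    """Emit the Skyline report dialect (per-sample column triplets)."""
    path = Path(path)
    files = list(dict.fromkeys(truth["measurement_file"]))
    targets = truth[["site", "analyte", "charge"]].drop_duplicates().reset_index(drop=True)
    columns: dict[str, np.ndarray | pd.Series] = {
        "Protein name": targets["site"],
        "Peptide": targets["analyte"],
        "Precursor Charge": targets["charge"],
    }
    indexed = truth.set_index(["site", "analyte", "charge", "measurement_file"])
    key = pd.MultiIndex.from_frame(targets)
    for mfile in files:
        sub = indexed.xs(mfile, level="measurement_file")
        for metric, column in (
            ("Isotope Dot Product", "idotp"),
            ("Average mass error PPM", "mass_error_sky"),
            ("Total area MS1", "intensity"),
        ):
            columns[f"{mfile} {metric}"] = sub[column].reindex(key).to_numpy()
    pd.DataFrame(columns).to_csv(path, index=False)
    return path


def write_all(result: SimulationResult, outdir: Path) -> dict[str, Path]:
    """Write both dialect files, layout, metadata and the ground-truth JSON."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lacytools": write_lacytools(result.truth, outdir / "lacytools_summary.txt"),
        "skyline": write_skyline(result.truth, outdir / "skyline_report.csv"),
        "layout": outdir / "plate_layout.xlsx",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    result.layout.to_excel(paths["layout"], index=False)
    result.metadata.to_csv(paths["metadata"], index=False)
    gt = result.ground_truth
    payload = {
        "spectra": gt.spectra.to_dict(orient="records"),
        "frequencies": {k: v.to_dict(orient="records") for k, v in gt.frequencies.items()},
        "abundance_profile": gt.abundance_profile.to_dict(orient="records"),
        "n_records": gt.n_records,
        "n_blanked": gt.n_blanked,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1, default=str))
    return paths


def simulate_sil(
    seed: int,
    n_samples: int = 50,
    peptides: tuple[str, ...] = ("pepA", "pepB", "pepC"),
    spike_amount: float = 10.0,
    sigma: float = 0.1,
    quantity_range: tuple[float, float] = (5.0, 50.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate light/heavy peptide signals around planted protein quantities.

    Per sample, the true protein quantity is drawn uniformly from
    ``quantity_range``; every quantifying peptide observes lognormal
    multiplicative noise of scale ``sigma`` on its light/heavy ratio (the
    per-peptide quantity), the two signals sharing all other variation.
    Returns ``(records, sil_map, true_quantities)`` where the record table
    matches what :func:`glycocurate.quant_repeat.sil_quantify` expects.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"patient_{i:03d}" for i in range(1, n_samples + 1)]
    true_q = pd.Series(
        rng.uniform(*quantity_range, size=n_samples), index=sample_ids, name="true_quantity"
    )
    base = 1.0e6
    rows = []
    for sid in sample_ids:
        for pep in peptides:
            # common signal-level variation cancels in the ratio
            common = math.exp(0.3 * rng.standard_normal())
            heavy = base * common
            light = (true_q[sid] / spike_amount) * base * common * math.exp(
                sigma * rng.standard_normal()
            )
            # split the light signal over two glycoforms to exercise summing
            split = rng.uniform(0.3, 0.7)
            for analyte, frac in (("H3N4", split), ("H4N4", 1.0 - split)):
                rows.append(
                    {
                        "sample_id": sid,
                        "site": pep,
                        "analyte": analyte,
                        "charge": 2,
                        "intensity": light * frac,
                    }
                )
            rows.append(
                {
                    "sample_id": sid,
                    "site": f"{pep}_SIL",
                    "analyte": "H3N4",
                    "charge": 2,
                    "intensity": heavy,
                }
            )
    records = pd.DataFrame(rows)
    sil_map = pd.DataFrame(
        {
            "peptide": list(peptides),
            "heavy_name": [f"{p}_SIL" for p in peptides],
            "spike_amount": spike_amount,
        }
    )
    return records, sil_map, true_q
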