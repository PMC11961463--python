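"""Absolute quantitation via stable-isotope-labelled standards, and
plate-based repeatability metrics.

SIL quantitation: a known amount of an isotopically heavy standard protein is
spiked into each sample; the light/heavy summed-intensity ratio of each
quantifying peptide, times the spiked amount, estimates the protein quantity.
When several peptides quantify the same protein the median is reported, and
pairwise Pearson correlations of the per-peptide quantities across samples
serve as a quality check.

Repeatability: technical variability is derived from repeated measurements of
a pooled control.  Per (plate, analyte) the mean and coefficient of variation
(CV = 100 * sd / mean, sample sd with n-1) of the replicates are computed;
the intra-plate CV is summarised as the median over plates and analytes, and
the inter-plate CV as the median over analytes of the CV of plate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SilQuantResult:
    """Per-sample, per-peptide quantities with median and peptide correlations."""

    quantities: pd.DataFrame  # samples x peptides
    median_quantity: pd.Series  # per sample
    peptide_correlations: pd.DataFrame  # peptides x peptides (Pearson)
    units: str | None = None


@dataclass
class RepeatabilityReport:
    per_plate: pd.DataFrame  # plate, analyte_full, n, mean, cv
    intra_plate_median_cv: float
    inter_plate: pd.DataFrame  # analyte_full, cv of plate means
    inter_plate_median_cv: float


def cv_percent(values: np.ndarray | pd.Series) -> float:
    """100 * sample sd / mean; missing when n < 2 or the mean is zero."""
    values = pd.Series(values).dropna().to_numpy(dtype=float)
    if values.size < 2:
        return np.nan
    mean = values.mean()
    if mean == 0:
        return np.nan
    return 100.0 * values.std(ddof=1) / mean


def sil_quantify(
    records: pd.DataFrame,
    sil_map: pd.DataFrame,
    units: str | None = None,
) -> SilQuantResult:
    """Protein quantities from light/heavy ratios of SIL-quantified peptides.

    ``sil_map`` needs columns ``peptide`` (the light site/peptide name),
    ``heavy_name`` (site name of the heavy standard's signals) and
    ``spike_amount``.  Per sample and peptide the quantity is
    (sum light intensity / sum heavy intensity) * spike_amount; a missing or
    zero heavy signal skips the peptide for that sample with a warning.
    """
    required = {"peptide", "heavy_name", "spike_amount"}
    if not required.issubset(sil_map.columns):
        raise ValueError(f"SIL map must have columns {sorted(required)}")
    sums = (
        records.groupby(["sample_id", "site"])["intensity"].sum(min_count=1).unstack("site")
    )
    quantities = {}
    for row in sil_map.itertuples(index=False):
        light = sums.get(row.peptide)
        heavy = sums.get(row.heavy_name)
        if light is None or heavy is None:
            warnings.warn(
                f"peptide {row.peptide!r}: light or heavy signals absent from the data",
                stacklevel=2,
            )
            quantities[row.peptide] = pd.Series(np.nan, index=sums.index)
            continue
        bad = heavy.isna() | (heavy == 0)
        if bad.any():
            warnings.warn(
                f"peptide {row.peptide!r}: heavy signal missing or zero in "
                f"{int(bad.sum())} sample(s); skipped there",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            quantities[row.peptide] = (light / heavy.where(~bad)) * float(row.spike_amount)
    table = pd.DataFrame(quantities)
    median = table.median(axis=1, skipna=True).rename("median_quantity")
    if table.shape[1] >= 2:
        corr = table.corr(method="pearson")
    else:
        corr = pd.DataFrame(index=table.columns, columns=table.columns, dtype=float)
    return SilQuantResult(
        quantities=table, median_quantity=median, peptide_correlations=corr, units=units
    )


def repeatability(
    rel_abund: pd.DataFrame,
    annotations: pd.DataFrame,
    control_type: str = "pool",
    plate_col: str = "plate",
) -> RepeatabilityReport:
    """Intra- and inter-plate repeatability of a repeated technical control.

    ``rel_abund`` is the long relative-abundance table; ``annotations`` must
    map sample_id to sample_type and plate.  Plates with fewer than two
    control replicates are omitted from the intra-plate CVs.
    """
    controls = annotations.loc[annotations["sample_type"] == control_type, ["sample_id", plate_col]]
    if controls.empty:
        raise ValueError(f"no samples of control type {control_type!r}")
    data = rel_abund.merge(controls, on="sample_id", how="inner")
    if data["sample_id"].nunique() < 2:
        raise ValueError(
            f"need at least two replicate measurements of {control_type!r} overall"
        )
    per_plate = (
        data.groupby([plate_col, "analyte_full"])["rel_abundance"]
        .agg(n="count", mean="mean", cv=cv_percent)
        .reset_index()
    )
    per_plate = per_plate[per_plate["n"] >= 2].reset_index(drop=True)
    intra = float(per_plate["cv"].median(skipna=True)) if len(per_plate) else np.nan

    plate_means = (
        data.groupby([plate_col, "analyte_full"])["rel_abundance"].mean().reset_index()
    )
    inter = (
        plate_means.groupby("analyte_full")["rel_abundance"]
        .agg(cv=cv_percent)
        .reset_index()
    )
    inter_median = float(inter["cv"].median(skipna=True)) if len(inter) else np.nan
    return RepeatabilityReport(
        per_plate=per_plate,
        intra_plate_median_cv=intra,
        inter_plate=inter,
        inter_plate_median_cv=inter_median,
    )
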