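"""Per-record quality evaluation and per-(sample, site) spectrum summaries.

Three quality metrics accompany every quantified analyte: the mass error in
ppm, an isotopologue-pattern score, and a signal measure.  Score
directionality differs between dialects: the LaCyTools isotopic pattern
quality (IPQ) measures *deviation* from the theoretical pattern (0 is
perfect, pass when small), whereas the Skyline isotope dot product (idotp)
measures *similarity* (1 is perfect, pass when large).  The signal measure is
a signal-to-noise ratio for LaCyTools (pass at or above the threshold) and
an absolute MS1 area for Skyline (pass strictly above the threshold, so the
default threshold of 0 rejects zero-area analytes).

Whole measurements ("spectra") are summarised per (sample, glycosylation
site) into the two curation dimensions: the sum intensity of all
quality-passing analytes, and the fraction of the targeted extraction list
that passes.  The denominator is always the full targeted list for the site,
counting analyte x charge combinations, regardless of how many were actually
detected in a given sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import LACYTOOLS, SKYLINE


@dataclass(frozen=True)
class QualityCriteria:
    """Pass/fail boundaries for the three per-analyte quality metrics."""

    dialect: str
    mass_error_window: tuple[float, float]
    pattern_threshold: float
    signal_threshold: float

    def __post_init__(self) -> None:
        low, high = self.mass_error_window
        if not (np.isfinite(low) and np.isfinite(high) and low < high):
            raise ValueError(f"mass error window must be finite with low < high, got {self.mass_error_window}")
        if not np.isfinite(self.pattern_threshold) or not np.isfinite(self.signal_threshold):
            raise ValueError("pattern and signal thresholds must be finite")
        if self.dialect not in (LACYTOOLS, SKYLINE):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @classmethod
    def defaults(cls, dialect: str) -> "QualityCriteria":
        """Empirically established defaults for each dialect."""
        if dialect == LACYTOOLS:
            return cls(LACYTOOLS, (-20.0, 20.0), 0.2, 9.0)
        if dialect == SKYLINE:
            return cls(SKYLINE, (-2.0, 2.0), 0.9, 0.0)
        raise ValueError(f"unknown dialect {dialect!r}")


def evaluate_quality(records: pd.DataFrame, criteria: QualityCriteria) -> pd.DataFrame:
    """Add boolean columns pass_mass, pass_pattern, pass_signal, pass_all.

    Missing values in any criterion fail that criterion (a measured intensity
    without quality metrics is untrustworthy).  Window and thresholds are
    inclusive, except the Skyline area threshold which is strict.
    """
    dialects = set(records["dialect"].unique())
    if dialects - {criteria.dialect}:
        raise ValueError(
            f"criteria are for dialect {criteria.dialect!r} but records contain {sorted(dialects)}"
        )
    out = records.copy()
    low, high = criteria.mass_error_window
    mass = out["mass_error_ppm"]
    pattern = out["pattern_score"]
    signal = out["signal_measure"]
    out["pass_mass"] = (mass >= low) & (mass <= high)
    if criteria.dialect == LACYTOOLS:
        out["pass_pattern"] = pattern <= criteria.pattern_threshold
        out["pass_signal"] = signal >= criteria.signal_threshold
    else:
        out["pass_pattern"] = pattern >= criteria.pattern_threshold
        out["pass_signal"] = signal > criteria.signal_threshold
    for col in ("pass_mass", "pass_pattern", "pass_signal"):
        out[col] = out[col].fillna(False).astype(bool)
    out["pass_all"] = out["pass_mass"] & out["pass_pattern"] & out["pass_signal"]
    return out


def targeted_list(records: pd.DataFrame) -> pd.DataFrame:
    """The targeted extraction list: unique (site, analyte, charge) triples."""
    return (
        records[["site", "analyte", "charge"]]
        .drop_duplicates()
        .sort_values(["site", "analyte", "charge"], kind="stable")
        .reset_index(drop=True)
    )


def summarize_spectra(
    flagged: pd.DataFrame,
    targeted: pd.DataFrame | None = None,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Summarise each (sample, site) into the two spectra-curation dimensions.

    ``flagged`` must carry a ``pass_all`` column (see :func:`evaluate_quality`).
    ``targeted`` defaults to the triples present in the data; it is
    authoritative — records referencing triples outside it are an error.
    Returns one row per (sample, site) over the full sample x site grid, with
    columns sum_intensity, passing_fraction, n_targeted, n_passing and
    has_values (False when the site yielded no values at all for the sample).
    """
    if "pass_all" not in flagged.columns:
        raise ValueError("records must be quality-flagged first (missing pass_all)")
    if targeted is None:
        targeted = targeted_list(flagged)
    targeted = targeted[["site", "analyte", "charge"]].drop_duplicates()
    known = set(map(tuple, targeted.itertuples(index=False)))
    present = set(
        map(tuple, flagged[["site", "analyte", "charge"]].drop_duplicates().itertuples(index=False))
    )
    stray = present - known
    if stray:
        raise ValueError(
            f"records reference analytes absent from the targeted extraction list: {sorted(stray)[:5]}"
        )
    n_targeted = targeted.groupby("site").size().rename("n_targeted")

    grouped = flagged.groupby([sample_col, "site"], dropna=False)
    n_passing = grouped["pass_all"].sum().rename("n_passing")
    sum_intensity = (
        flagged["intensity"].where(flagged["pass_all"], 0.0).fillna(0.0)
        .groupby([flagged[sample_col], flagged["site"]])
        .sum()
        .rename("sum_intensity")
    )
    has_values = grouped["intensity"].apply(lambda s: bool(s.notna().any())).rename("has_values")

    samples = flagged[sample_col].dropna().unique()
    sites = targeted["site"].unique()
    grid = pd.MultiIndex.from_product([samples, sites], names=[sample_col, "site"])
    summary = (
        pd.concat([n_passing, sum_intensity, has_values], axis=1)
        .reindex(grid)
        .reset_index()
    )
    summary["n_passing"] = summary["n_passing"].fillna(0).astype(int)
    summary["sum_intensity"] = summary["sum_intensity"].fillna(0.0)
    summary["has_values"] = summary["has_values"].astype("boolean").fillna(False).astype(bool)
    summary = summary.merge(n_targeted.reset_index(), on="site", how="left")
    summary["n_targeted"] = summary["n_targeted"].astype(int)
    summary["passing_fraction"] = summary["n_passing"] / summary["n_targeted"]
    return summary[
        [sample_col, "site", "sum_intensity", "passing_fraction", "n_targeted", "n_passing", "has_values"]
    ]
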