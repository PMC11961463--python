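"""Spectra (whole-measurement) curation per glycosylation site.

Each (sample, site) measurement is characterised by two quality dimensions —
sum intensity of quality-passing analytes and fraction of the targeted list
passing — and is excluded when it does not clear a per-site cutoff pair.
Three strategies are supported:

* ``skip`` — no exclusion (small, unmissable datasets).
* ``negative_control`` — cutoffs at a percentile (default 95) of the values
  observed in relevant negative-control measurements; optionally under a
  normality assumption (mean + z * sd).  The recommended strategy.
* ``percentile`` — in the absence of adequate controls, cutoffs at a fixed
  lower percentile of the real samples' own values (controls and blanks must
  be excluded from the computation).  Because the percentile applies to each
  dimension separately, the jointly excluded fraction can exceed it.

Sites are curated independently of one another.  The pass rule is strict
(``>``) in both dimensions by default, so with the negative-control strategy
at percentile 100 every control — each of which is at or below the control
maximum — is itself excluded; an inclusive rule is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STRATEGY_SKIP = "skip"
STRATEGY_NEGATIVE_CONTROL = "negative_control"
STRATEGY_PERCENTILE = "percentile"

_CUTOFF_COLUMNS = [
    "site",
    "intensity_cutoff",
    "fraction_cutoff",
    "strategy",
    "percentile",
    "normal_assumption",
    "control_type",
    "n_reference",
    "degenerate",
]


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class CurationSettings:
    """Spectra-curation configuration for one run."""

    strategy: str = STRATEGY_NEGATIVE_CONTROL
    percentile: float = 95.0
    control_type: str = "negative_control"
    normal_assumption: bool = False
    excluded_types: tuple[str, ...] = ("negative_control", "blank", "pool")
    missing_policy: str = "exclude"  # or "zero"
    rule: str = "strict"  # or "inclusive"


def _percentile_cutoff(values: np.ndarray, percentile: float, normal: bool) -> float:
    values = np.asarray(values, dtype=float)
    if normal:
        if values.size < 2:
            # variance undefined; fall back to the single observed value
            return float(values[0])
        z = stats.norm.ppf(percentile / 100.0)
        return float(values.mean() + z * values.std(ddof=1))
    # linear interpolation between order statistics; percentile 100 -> maximum
    return float(np.percentile(values, percentile))


def cutoffs_from_negative_controls(
    summaries: pd.DataFrame,
    control_type: str = "negative_control",
    percentile: float = 95.0,
    normal: bool = False,
) -> pd.DataFrame:
    """Per-site cutoff pairs from negative-control measurements.

    ``summaries`` must carry a ``sample_type`` column.  Controls without
    values are ignored; a site with no control values at all degenerates to
    no exclusion (flagged and warned about, identical to not curating).
    """
    if not 0 < percentile <= 100:
        raise CurationError(f"percentile must be in (0, 100], got {percentile}")
    rows = []
    for site, site_sum in summaries.groupby("site", sort=True):
        controls = site_sum[
            (site_sum["sample_type"] == control_type) & site_sum["has_values"]
        ]
        if controls.empty:
            warnings.warn(
                f"site {site!r}: no negative-control values; curation for this "
                "site is identical to not applying curation",
                stacklevel=2,
            )
            rows.append(
                dict(
                    site=site,
                    intensity_cutoff=-np.inf,
                    fraction_cutoff=-np.inf,
                    strategy=STRATEGY_NEGATIVE_CONTROL,
                    percentile=percentile,
                    normal_assumption=normal,
                    control_type=control_type,
                    n_reference=0,
                    degenerate=True,
                )
            )
            continue
        rows.append(
            dict(
                site=site,
                intensity_cutoff=_percentile_cutoff(
                    controls["sum_intensity"].to_numpy(), percentile, normal
                ),
                fraction_cutoff=_percentile_cutoff(
                    controls["passing_fraction"].to_numpy(), percentile, normal
                ),
                strategy=STRATEGY_NEGATIVE_CONTROL,
                percentile=percentile,
                normal_assumption=normal,
                control_type=control_type,
                n_reference=len(controls),
                degenerate=False,
            )
        )
    return pd.DataFrame(rows, columns=_CUTOFF_COLUMNS)


def cutoffs_from_percentile(
    summaries: pd.DataFrame,
    percentile: float,
    excluded_types: tuple[str, ...] = ("negative_control", "blank", "pool"),
) -> pd.DataFrame:
    """Per-site cutoffs excluding a fixed lower percentile of the samples.

    All control and blank sample types must be listed in ``excluded_types``
    so that only real samples inform the cutoffs.  ``percentile`` 0 means no
    exclusion.
    """
    if not 0 <= percentile <= 100:
        raise CurationError(f"percentile must be in [0, 100], got {percentile}")
    rows = []
    for site, site_sum in summaries.groupby("site", sort=True):
        eligible = site_sum[
            ~site_sum["sample_type"].isin(excluded_types) & site_sum["has_values"]
        ]
        if eligible.empty:
            raise CurationError(
                f"site {site!r}: all samples excluded by type; cannot place percentile cutoffs"
            )
        if percentile == 0:
            icut, fcut = -np.inf, -np.inf
        else:
            icut = _percentile_cutoff(eligible["sum_intensity"].to_numpy(), percentile, False)
            fcut = _percentile_cutoff(eligible["passing_fraction"].to_numpy(), percentile, False)
        rows.append(
            dict(
                site=site,
                intensity_cutoff=icut,
                fraction_cutoff=fcut,
                strategy=STRATEGY_PERCENTILE,
                percentile=percentile,
                normal_assumption=False,
                control_type=None,
                n_reference=len(eligible),
                degenerate=percentile == 0,
            )
        )
    return pd.DataFrame(rows, columns=_CUTOFF_COLUMNS)


def skip_cutoffs(sites) -> pd.DataFrame:
    """Cutoffs that keep everything (spectra curation skipped)."""
    rows = [
        dict(
            site=site,
            intensity_cutoff=-np.inf,
            fraction_cutoff=-np.inf,
            strategy=STRATEGY_SKIP,
            percentile=np.nan,
            normal_assumption=False,
            control_type=None,
            n_reference=0,
            degenerate=False,
        )
        for site in sites
    ]
    return pd.DataFrame(rows, columns=_CUTOFF_COLUMNS)


def apply_spectra_curation(
    summaries: pd.DataFrame,
    cutoffs: pd.DataFrame,
    missing_policy: str = "exclude",
    rule: str = "strict",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude measurements below the per-site cutoffs.

    Returns ``(kept, exclusion_log)``: ``kept`` is the subset of summary rows
    that survive; the log lists each excluded (sample, site) with the failing
    dimension(s).  Measurements without values are excluded under the default
    missing policy or compared as zeros under the ``zero`` policy.  Skipped or
    degenerate sites keep everything.
    """
    if missing_policy not in ("exclude", "zero"):
        raise CurationError(f"unknown missing policy {missing_policy!r}")
    if rule not in ("strict", "inclusive"):
        raise CurationError(f"unknown rule {rule!r}")
    cut = cutoffs.set_index("site")
    missing_sites = set(summaries["site"].unique()) - set(cut.index)
    if missing_sites:
        raise CurationError(f"no cutoffs for sites: {sorted(missing_sites)}")

    kept_mask = np.zeros(len(summaries), dtype=bool)
    reasons: list[str | None] = [None] * len(summaries)
    for i, row in enumerate(summaries.itertuples(index=False)):
        c = cut.loc[row.site]
        if c["strategy"] == STRATEGY_SKIP or c["degenerate"]:
            kept_mask[i] = True
            continue
        if not row.has_values:
            if missing_policy == "exclude":
                reasons[i] = "no_values"
                continue
            intensity, fraction = 0.0, 0.0
        else:
            intensity, fraction = row.sum_intensity, row.passing_fraction
        if rule == "strict":
            ok_i = intensity > c["intensity_cutoff"]
            ok_f = fraction > c["fraction_cutoff"]
        else:
            ok_i = intensity >= c["intensity_cutoff"]
            ok_f = fraction >= c["fraction_cutoff"]
        if ok_i and ok_f:
            kept_mask[i] = True
        else:
            failing = []
            if not ok_i:
                failing.append("low_intensity")
            if not ok_f:
                failing.append("low_fraction")
            reasons[i] = "+".join(failing)

    kept = summaries.loc[kept_mask].reset_index(drop=True)
    log = summaries.loc[~kept_mask].copy()
    log["reason"] = [r for r, m in zip(reasons, kept_mask) if not m]
    return kept, log.reset_index(drop=True)


def exclusions_by_sample_type(exclusion_log: pd.DataFrame) -> pd.DataFrame:
    """Counts of excluded measurements per (sample type, site, reason)."""
    if exclusion_log.empty:
        return pd.DataFrame(columns=["sample_type", "site", "reason", "n_excluded"])
    return (
        exclusion_log.groupby(["sample_type", "site", "reason"], dropna=False)
        .size()
        .rename("n_excluded")
        .reset_index()
    )


def plot_curation_scatter(summaries: pd.DataFrame, cutoffs: pd.DataFrame, path) -> None:
    """Static per-site scatter of the two curation dimensions with cutoff lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = list(cutoffs["site"])
    fig, axes = plt.subplots(1, len(sites), figsize=(5 * len(sites), 4), squeeze=False)
    cut = cutoffs.set_index("site")
    for ax, site in zip(axes[0], sites):
        sub = summaries[summaries["site"] == site]
        for stype, group in sub.groupby("sample_type", dropna=False):
            ax.scatter(
                group["passing_fraction"], group["sum_intensity"], s=12, alpha=0.6, label=str(stype)
            )
        c = cut.loc[site]
        if np.isfinite(c["intensity_cutoff"]):
            ax.axhline(c["intensity_cutoff"], color="red", lw=1, ls="--")
        if np.isfinite(c["fraction_cutoff"]):
            ax.axvline(c["fraction_cutoff"], color="red", lw=1, ls="--")
        ax.set_yscale("symlog")
        ax.set_xlabel("fraction of targeted analytes passing")
        ax.set_ylabel("sum intensity of passing analytes")
        ax.set_title(str(site))
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
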