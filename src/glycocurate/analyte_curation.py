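"""Analyte curation: which (site, analyte, charge) entries are quantifiable.

After spectra curation, each analyte x charge combination is judged by the
relative frequency of surviving measurements in which it passes all three
quality criteria.  Frequencies can be computed over the whole dataset, per
biological group (with the group lists merged into a consensus by AND/OR set
logic), or degenerately per sample.  Charge states of one composition are
curated individually, because their quality can differ substantially.

The eligibility denominator counts only measurements that survived spectra
curation *and* have values for the site; empty measurements would otherwise
deflate frequencies.  Frequency comparison against the user cutoff is
inclusive (an analyte passing in exactly half the samples survives a 50%
cutoff).  Typical cutoffs are 0.8 for high-quality and 0.5 for medium- to
low-quality datasets.  Automated decisions can be overridden entry by entry;
overrides are tracked in the consensus provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

ENTRY_KEY = ["site", "analyte", "charge"]

#: Minimum recommended biological-group size for per-group curation.
MIN_GROUP_SIZE = 10


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusList:
    """Retained analyte entries with per-scope frequencies and provenance."""

    entries: pd.DataFrame  # columns: site, analyte, charge, freq columns, retained, override
    min_freq: float
    logic: str
    scopes: tuple[str, ...]

    @property
    def retained(self) -> pd.DataFrame:
        return self.entries.loc[self.entries["retained"], ENTRY_KEY].reset_index(drop=True)

    def retained_set(self) -> set[tuple]:
        return set(map(tuple, self.retained.itertuples(index=False)))


def _eligible_measurements(records: pd.DataFrame, kept: pd.DataFrame) -> pd.DataFrame:
    """(sample_id, site) pairs that survived spectra curation and have values."""
    has_values = (
        records.groupby(["sample_id", "site"])["intensity"]
        .apply(lambda s: bool(s.notna().any()))
        .rename("has_values")
        .reset_index()
    )
    eligible = kept[["sample_id", "site"]].merge(has_values, on=["sample_id", "site"], how="left")
    eligible["has_values"] = eligible["has_values"].astype("boolean").fillna(False).astype(bool)
    return eligible.loc[eligible["has_values"], ["sample_id", "site"]]


def passing_frequency(
    records: pd.DataFrame,
    kept: pd.DataFrame,
    grouping: str = "all",
    annotations: pd.DataFrame | None = None,
    group_col: str | None = None,
    subset_samples: set | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> dict[str, pd.DataFrame]:
    """Per-scope passing-frequency tables.

    ``records`` must be quality-flagged; ``kept`` holds the (sample_id, site)
    pairs surviving spectra curation.  ``grouping`` is ``"all"``,
    ``"per_sample"`` or ``"by_group"`` (requires ``annotations`` with
    ``group_col``).  ``subset_samples`` optionally restricts which samples
    inform the frequencies (e.g. only one measurement series), without
    restricting what the resulting list is later applied to.

    Returns a mapping scope name -> frequency table with columns
    site, analyte, charge, n_pass, n_eligible, frequency.
    """
    if "pass_all" not in records.columns:
        raise ValueError("records must be quality-flagged first (missing pass_all)")
    eligible = _eligible_measurements(records, kept)
    if subset_samples is not None:
        eligible = eligible[eligible["sample_id"].isin(subset_samples)]

    if grouping == "all":
        scopes = {"all": set(eligible["sample_id"].unique())}
    elif grouping == "per_sample":
        scopes = {sid: {sid} for sid in sorted(eligible["sample_id"].unique())}
    elif grouping == "by_group":
        if annotations is None or group_col is None:
            raise ValueError("by_group grouping requires annotations and group_col")
        if group_col not in annotations.columns:
            raise ValueError(f"annotations lack grouping column {group_col!r}")
        membership = annotations.dropna(subset=[group_col])
        scopes = {
            str(g): set(sub["sample_id"])
            for g, sub in membership.groupby(group_col, sort=True)
        }
        if not scopes:
            raise ValueError(f"grouping column {group_col!r} assigns no samples to any group")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    entries = records[ENTRY_KEY].drop_duplicates().sort_values(ENTRY_KEY, kind="stable")
    rec = records.merge(eligible.assign(_eligible=True), on=["sample_id", "site"], how="left")
    rec = rec[rec["_eligible"].astype("boolean").fillna(False).astype(bool)]

    tables: dict[str, pd.DataFrame] = {}
    for scope, members in scopes.items():
        scope_elig = eligible[eligible["sample_id"].isin(members)]
        n_samples = scope_elig["sample_id"].nunique()
        if grouping == "by_group" and n_samples < min_group_size:
            warnings.warn(
                f"biological group {scope!r} has only {n_samples} eligible samples "
                f"(recommended absolute minimum: {min_group_size})",
                stacklevel=2,
            )
        n_eligible = scope_elig.groupby("site")["sample_id"].nunique().rename("n_eligible")
        scope_rec = rec[rec["sample_id"].isin(members)]
        n_pass = (
            scope_rec.groupby(ENTRY_KEY)["pass_all"].sum().rename("n_pass").reset_index()
        )
        table = entries.merge(n_pass, on=ENTRY_KEY, how="left")
        table["n_pass"] = table["n_pass"].fillna(0).astype(int)
        table = table.merge(n_eligible.reset_index(), on="site", how="left")
        table["n_eligible"] = table["n_eligible"].fillna(0).astype(int)
        table["frequency"] = table["n_pass"] / table["n_eligible"].where(table["n_eligible"] > 0)
        tables[str(scope)] = table.reset_index(drop=True)
    return tables


def build_consensus(
    freq_tables: dict[str, pd.DataFrame], min_freq: float, logic: str = "OR"
) -> ConsensusList:
    """Merge per-scope analyte lists into a consensus by AND/OR set logic.

    A scope's list holds entries with frequency >= ``min_freq``; OR keeps the
    union of the lists, AND their intersection.  An empty consensus leaves
    downstream normalization undefined and is an error.
    """
    logic = logic.upper()
    if logic not in ("OR", "AND"):
        raise ConsensusError(f"merge logic must be OR or AND, got {logic!r}")
    if not 0 <= min_freq <= 1:
        raise ConsensusError(f"min_freq must be in [0, 1], got {min_freq}")
    if not freq_tables:
        raise ConsensusError("no frequency tables given")
    scopes = tuple(freq_tables)
    merged: pd.DataFrame | None = None
    for scope in scopes:
        table = freq_tables[scope][ENTRY_KEY + ["frequency"]].rename(
            columns={"frequency": f"freq_{scope}"}
        )
        merged = table if merged is None else merged.merge(table, on=ENTRY_KEY, how="outer")
    in_cols = []
    for scope in scopes:
        col = f"in_{scope}"
        merged[col] = merged[f"freq_{scope}"].fillna(-1.0) >= min_freq
        in_cols.append(col)
    if logic == "OR":
        merged["retained"] = merged[in_cols].any(axis=1)
    else:
        merged["retained"] = merged[in_cols].all(axis=1)
    merged["override"] = False
    merged = merged.sort_values(ENTRY_KEY, kind="stable").reset_index(drop=True)
    consensus = ConsensusList(entries=merged, min_freq=min_freq, logic=logic, scopes=scopes)
    if not merged["retained"].any():
        raise ConsensusError(
            f"consensus list is empty at min_freq={min_freq}; downstream normalization undefined"
        )
    return consensus


def apply_overrides(consensus: ConsensusList, overrides: pd.DataFrame) -> ConsensusList:
    """Apply manual keep/drop decisions; the override always wins.

    ``overrides`` needs columns site, analyte, charge, keep.  Referencing an
    entry not in the frequency tables is an error.  Idempotent: applying the
    same overrides twice gives the same result.
    """
    entries = consensus.entries.copy()
    if overrides is None or overrides.empty:
        return ConsensusList(entries, consensus.min_freq, consensus.logic, consensus.scopes)
    needed = set(ENTRY_KEY + ["keep"])
    if not needed.issubset(overrides.columns):
        raise ConsensusError(f"override table must have columns {sorted(needed)}")
    index = entries.set_index(ENTRY_KEY).index
    for row in overrides.itertuples(index=False):
        key = (row.site, row.analyte, int(row.charge))
        pos = index.get_indexer([key])
        if pos[0] < 0:
            raise ConsensusError(f"override references unknown entry {key}")
        changed = bool(entries.at[pos[0], "retained"]) != bool(row.keep)
        entries.at[pos[0], "retained"] = bool(row.keep)
        # flag relative to the automated result only once
        if changed and not entries.at[pos[0], "override"]:
            entries.at[pos[0], "override"] = True
        elif not changed and entries.at[pos[0], "override"]:
            pass  # keep existing flag: override already recorded
    out = ConsensusList(entries, consensus.min_freq, consensus.logic, consensus.scopes)
    if not entries["retained"].any():
        raise ConsensusError("overrides emptied the consensus list")
    return out


def apply_analyte_curation(
    records: pd.DataFrame,
    consensus: ConsensusList | None = None,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Remove non-quantifiable analytes from the record table.

    Consensus mode removes entries absent from the consensus list from every
    sample; per-sample mode removes, in each sample, the records failing that
    sample's own quality check (requires quality flags).
    """
    if per_sample:
        if "pass_all" not in records.columns:
            raise ValueError("per-sample curation requires quality-flagged records")
        return records[records["pass_all"]].reset_index(drop=True)
    if consensus is None:
        raise ValueError("consensus list required unless per_sample=True")
    keyed = records.set_index(ENTRY_KEY).index
    retained = consensus.retained.set_index(ENTRY_KEY).index
    return records[keyed.isin(retained)].reset_index(drop=True)
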