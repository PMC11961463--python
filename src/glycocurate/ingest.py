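"""Readers for the two upstream quantitation dialects and sample bookkeeping.

Two long-established quantitation tools are supported as input dialects:

* **LaCyTools-style summary** — a tab-separated text file holding, per charge
  state, four aligned blocks (background-subtracted analyte intensity, mass
  accuracy in ppm, isotopic pattern quality, signal-to-noise).  Each block
  starts with a header line ``<output name>\\tcharge=<z>``, followed by a row
  of analyte labels and one row per measurement file.  Blocks are separated
  by blank lines.  The exact layout is documented in ``docs/methods.md``.

* **Skyline-style report CSV** — one row per targeted precursor with key
  columns ``Protein name``, ``Peptide`` and ``Precursor Charge``, and one
  column triplet per sample: ``<sample> Isotope Dot Product``,
  ``<sample> Average mass error PPM``, ``<sample> Total area MS1``.

Both are normalised into one long-format record table (one row per
(sample, site, analyte, charge) cell) with a shared schema; score
directionality differences between the dialects are resolved downstream by
the quality module, never by rescaling the scores themselves.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compositions import (
    DEFAULT_ALPHABET,
    AnalyteNameError,
    full_name,
    parse_composition,
    split_analyte_name,
)

LACYTOOLS = "lacytools"
SKYLINE = "skyline"

#: Block header names of the LaCyTools summary dialect.
LACY_BLOCK_INTENSITY = "Analyte Intensity (background subtracted)"
LACY_BLOCK_MASS = "Mass Accuracy [ppm]"
LACY_BLOCK_IPQ = "Isotopic Pattern Quality"
LACY_BLOCK_SN = "S/N"
LACY_BLOCKS = (LACY_BLOCK_INTENSITY, LACY_BLOCK_MASS, LACY_BLOCK_IPQ, LACY_BLOCK_SN)

SKYLINE_KEY_COLUMNS = ("Protein name", "Peptide", "Precursor Charge")
SKYLINE_METRICS = ("Isotope Dot Product", "Average mass error PPM", "Total area MS1")

#: Columns of the normalised long record table.
RECORD_COLUMNS = [
    "measurement_file",
    "sample_id",
    "plate",
    "well",
    "sample_type",
    "site",
    "composition",
    "isomer_suffix",
    "analyte",
    "analyte_full",
    "charge",
    "intensity",
    "mass_error_ppm",
    "pattern_score",
    "signal_measure",
    "dialect",
    "source_order",
]

WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
_PLATE_WELL_RE = re.compile(r"(?P<plate>plate\w*?)_(?P<well>[A-H](?:1[0-2]|[1-9]))(?!\d)")


class DialectError(ValueError):
    """Structural problem in an upstream quantitation file."""


def _float_or_nan(cell: str) -> float:
    cell = cell.strip()
    if cell == "" or cell.lower() in {"na", "nan", "none"}:
        return np.nan
    return float(cell)


def _parse_lacytools_blocks(text: str) -> dict[tuple[str, int], pd.DataFrame]:
    """Split the summary text into blocks keyed by (output name, charge)."""
    blocks: dict[tuple[str, int], pd.DataFrame] = {}
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        header = line.split("\t")
        if len(header) < 2 or not header[1].startswith("charge="):
            raise DialectError(
                f"line {i + 1}: expected block header '<output>\\tcharge=<z>', got {line!r}"
            )
        output_name = header[0].strip()
        if output_name not in LACY_BLOCKS:
            raise DialectError(
                f"line {i + 1}: unknown output block {output_name!r}; "
                f"expected one of {list(LACY_BLOCKS)}"
            )
        try:
            charge = int(header[1].split("=", 1)[1])
        except ValueError as exc:
            raise DialectError(f"line {i + 1}: bad charge in header {line!r}") from exc
        i += 1
        if i >= n:
            raise DialectError(f"block {output_name!r} charge {charge}: truncated file")
        analyte_row = lines[i].split("\t")
        if analyte_row[0].strip():
            raise DialectError(
                f"block {output_name!r} charge {charge}: analyte header row must "
                "start with an empty cell"
            )
        analytes = [a.strip() for a in analyte_row[1:]]
        seen: set[str] = set()
        for a in analytes:
            if a in seen:
                raise DialectError(
                    f"block {output_name!r} charge {charge}: duplicate composition "
                    f"{a!r}; duplicate compositions lead to integration errors upstream"
                )
            seen.add(a)
        i += 1
        rows: list[list[float]] = []
        files: list[str] = []
        while i < n and lines[i].strip():
            cells = lines[i].split("\t")
            files.append(cells[0].strip())
            values = cells[1:]
            if len(values) != len(analytes):
                raise DialectError(
                    f"block {output_name!r} charge {charge}: row {files[-1]!r} has "
                    f"{len(values)} values for {len(analytes)} analytes"
                )
            rows.append([_float_or_nan(v) for v in values])
            i += 1
        frame = pd.DataFrame(rows, index=files, columns=analytes)
        key = (output_name, charge)
        if key in blocks:
            raise DialectError(f"duplicate block {output_name!r} for charge {charge}")
        blocks[key] = frame
    if not blocks:
        raise DialectError("no blocks found in LaCyTools summary")
    return blocks


def read_lacytools(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    strict_first_digit: bool = False,
) -> pd.DataFrame:
    """Read a LaCyTools-style summary into the long record table.

    Every grid cell becomes one record; blank cells yield missing values
    (never zeros).  The four blocks of one charge state must agree on their
    measurement files and analyte labels.
    """
    text = Path(path).read_text()
    blocks = _parse_lacytools_blocks(text)
    charges = sorted({charge for _, charge in blocks})
    records: list[dict] = []
    order = 0
    for charge in charges:
        per_output: dict[str, pd.DataFrame] = {}
        for output_name in LACY_BLOCKS:
            key = (output_name, charge)
            if key not in blocks:
                raise DialectError(f"missing block {output_name!r} for charge {charge}")
            per_output[output_name] = blocks[key]
        ref = per_output[LACY_BLOCK_INTENSITY]
        for output_name, frame in per_output.items():
            if list(frame.index) != list(ref.index):
                raise DialectError(
                    f"block {output_name!r} charge {charge}: measurement files "
                    "differ from the intensity block"
                )
            if list(frame.columns) != list(ref.columns):
                raise DialectError(
                    f"block {output_name!r} charge {charge}: analyte labels "
                    "differ from the intensity block"
                )
        parsed = {}
        for label in ref.columns:
            try:
                parsed[label] = split_analyte_name(label, alphabet, strict_first_digit)
            except AnalyteNameError as exc:
                raise AnalyteNameError(f"unparsable analyte label {label!r}: {exc}") from exc
        for mfile in ref.index:
            for label in ref.columns:
                site, composition, suffix = parsed[label]
                analyte = composition.raw_label + suffix
                records.append(
                    {
                        "measurement_file": mfile,
                        "site": site,
                        "composition": composition.raw_label,
                        "isomer_suffix": suffix,
                        "analyte": analyte,
                        "analyte_full": full_name(site, analyte),
                        "charge": charge,
                        "intensity": ref.at[mfile, label],
                        "mass_error_ppm": per_output[LACY_BLOCK_MASS].at[mfile, label],
                        "pattern_score": per_output[LACY_BLOCK_IPQ].at[mfile, label],
                        "signal_measure": per_output[LACY_BLOCK_SN].at[mfile, label],
                        "source_order": order,
                    }
                )
                order += 1
    return _finalize_records(records, LACYTOOLS)


def read_skyline(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    sample_regex: str | None = None,
) -> pd.DataFrame:
    """Read a Skyline-style report CSV into the long record table.

    The glycosylation site is taken from ``Protein name`` (released-glycan
    data conventionally uses a placeholder such as ``AB``); ``Peptide`` holds
    the composition label.  ``sample_regex`` optionally restricts which
    column prefixes are treated as sample names.
    """
    table = pd.read_csv(path)
    for col in SKYLINE_KEY_COLUMNS:
        if col not in table.columns:
            raise DialectError(f"Skyline report is missing required column {col!r}")
    samples: dict[str, dict[str, str]] = {}
    for col in table.columns:
        for metric in SKYLINE_METRICS:
            suffix = " " + metric
            if col.endswith(suffix):
                sample = col[: -len(suffix)]
                if sample_regex is not None and not re.search(sample_regex, sample):
                    continue
                samples.setdefault(sample, {})[metric] = col
    if not samples:
        raise DialectError(
            "Skyline report contains no per-sample metric columns "
            f"(expected suffixes {list(SKYLINE_METRICS)})"
        )
    for sample, cols in samples.items():
        for metric in SKYLINE_METRICS:
            if metric not in cols:
                raise DialectError(
                    f"Skyline report is missing column {sample + ' ' + metric!r}"
                )
    records: list[dict] = []
    order = 0
    for row_idx, row in table.iterrows():
        site = str(row["Protein name"])
        label = str(row["Peptide"])
        composition, suffix = parse_composition(label, alphabet)
        analyte = composition.raw_label + suffix
        charge = int(row["Precursor Charge"])
        for sample, cols in samples.items():
            area = row[cols["Total area MS1"]]
            records.append(
                {
                    "measurement_file": sample,
                    "site": site,
                    "composition": composition.raw_label,
                    "isomer_suffix": suffix,
                    "analyte": analyte,
                    "analyte_full": full_name(site, analyte),
                    "charge": charge,
                    "intensity": area,
                    "mass_error_ppm": row[cols["Average mass error PPM"]],
                    "pattern_score": row[cols["Isotope Dot Product"]],
                    "signal_measure": area,
                    "source_order": int(row_idx),
                }
            )
            order += 1
    return _finalize_records(records, SKYLINE)


def _finalize_records(records: list[dict], dialect: str) -> pd.DataFrame:
    frame = pd.DataFrame(records)
    frame["sample_id"] = pd.NA
    frame["plate"] = pd.NA
    frame["well"] = pd.NA
    frame["sample_type"] = pd.NA
    frame["dialect"] = dialect
    for col in ("intensity", "mass_error_ppm", "pattern_score", "signal_measure"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame["charge"] = frame["charge"].astype(int)
    return frame[RECORD_COLUMNS]


def rename_isomers(records: pd.DataFrame) -> pd.DataFrame:
    """Suffix duplicate compositions (isomers) with running lowercase letters.

    Within each (site, composition+existing suffix, charge), distinct targets
    in file order receive suffixes ``a``, ``b``, ``c`` ...  Only the Skyline
    dialect may contain duplicates; duplicate compositions in LaCyTools input
    indicate upstream integration errors and are rejected.  The operation is
    idempotent: already-unique names are left untouched.
    """
    if (records["dialect"] == LACYTOOLS).any():
        dup_mask = records.duplicated(
            subset=["measurement_file", "site", "analyte", "charge"], keep=False
        )
        if dup_mask.any():
            dups = records.loc[dup_mask, ["site", "analyte", "charge"]].drop_duplicates()
            raise DialectError(
                "duplicate compositions in LaCyTools input will lead to integration "
                f"errors upstream; offending analytes: {dups.to_dict('records')}"
            )
        return records.copy()
    targets = (
        records[["site", "analyte", "charge", "source_order"]]
        .drop_duplicates(subset=["site", "analyte", "charge", "source_order"])
        .sort_values("source_order", kind="stable")
    )
    dup_counts = targets.groupby(["site", "analyte", "charge"])["source_order"].transform("size")
    if (dup_counts == 1).all():
        return records.copy()
    targets = targets.copy()
    targets["occurrence"] = targets.groupby(["site", "analyte", "charge"]).cumcount()
    letters = "abcdefghijklmnopqrstuvwxyz"

    def new_suffix(row) -> str:
        if dup_counts.loc[row.name] == 1:
            return ""
        if row["occurrence"] >= len(letters):
            raise DialectError(
                f"more than {len(letters)} isomers of {row['site']}{row['analyte']}"
            )
        return letters[row["occurrence"]]

    targets["extra"] = targets.apply(new_suffix, axis=1)
    out = records.merge(
        targets[["site", "analyte", "charge", "source_order", "extra"]],
        on=["site", "analyte", "charge", "source_order"],
        how="left",
    )
    out["extra"] = out["extra"].fillna("")
    out["isomer_suffix"] = out["isomer_suffix"].fillna("") + out["extra"]
    out["analyte"] = out["composition"] + out["isomer_suffix"]
    out["analyte_full"] = out["site"] + out["analyte"]
    return out.drop(columns="extra")[RECORD_COLUMNS]


def read_plate_layout(path: str | Path) -> pd.DataFrame:
    """Read a plate-layout table (XLSX or CSV) with columns plate, well, sample_id.

    Wells must match the 96-well pattern (rows A-H, columns 1-12); other
    geometries are rejected.  Duplicate well assignments within a plate are
    an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        layout = pd.read_excel(path)
    else:
        layout = pd.read_csv(path)
    layout.columns = [str(c).strip().lower() for c in layout.columns]
    required = {"plate", "well", "sample_id"}
    if not required.issubset(layout.columns):
        raise DialectError(
            f"plate layout must have columns {sorted(required)}, got {list(layout.columns)}"
        )
    layout = layout[["plate", "well", "sample_id"]].astype(str)
    layout["well"] = layout["well"].str.strip().str.upper()
    # normalise zero-padded columns, e.g. C02 -> C2
    layout["well"] = layout["well"].str.replace(
        r"^([A-H])0(\d)$", r"\1\2", regex=True
    )
    bad = layout.loc[~layout["well"].str.match(WELL_RE), "well"]
    if len(bad):
        raise DialectError(
            f"plate layout is restricted to 96-well plates (A-H x 1-12); "
            f"invalid wells: {sorted(bad.unique())}"
        )
    dup = layout.duplicated(subset=["plate", "well"], keep=False)
    if dup.any():
        pairs = layout.loc[dup, ["plate", "well"]].drop_duplicates()
        raise DialectError(f"duplicate well assignments in layout: {pairs.to_dict('records')}")
    return layout


def parse_plate_well(measurement_file: str) -> tuple[str, str] | None:
    """Extract (plate, well) from a measurement file name like ``plate1_C10``."""
    m = _PLATE_WELL_RE.search(measurement_file)
    if m is None:
        return None
    return m.group("plate"), m.group("well")


def link_plate_layout(
    records: pd.DataFrame, layout: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Resolve measurement file names to sample IDs via the plate layout.

    Returns the updated records and the list of measurement files that could
    not be resolved (these keep a missing sample_id; they are reported, not
    silently dropped).
    """
    lookup = {
        (row.plate, row.well): row.sample_id for row in layout.itertuples(index=False)
    }
    out = records.copy()
    unresolved: list[str] = []
    sample_ids, plates, wells = [], [], []
    for mfile in out["measurement_file"]:
        parsed = parse_plate_well(str(mfile))
        if parsed is None or parsed not in lookup:
            sample_ids.append(pd.NA)
            plates.append(parsed[0] if parsed else pd.NA)
            wells.append(parsed[1] if parsed else pd.NA)
            unresolved.append(str(mfile))
        else:
            sample_ids.append(lookup[parsed])
            plates.append(parsed[0])
            wells.append(parsed[1])
    out["sample_id"] = sample_ids
    out["plate"] = plates
    out["well"] = wells
    return out, sorted(set(unresolved))


DEFAULT_TYPE_RULES: tuple[tuple[str, str], ...] = (
    (r"pool|posctrl|positive", "pool"),
    (r"blank", "blank"),
    (r"neg|visucon", "negative_control"),
    (r"patient|sample|subject|donor", "sample"),
)


def infer_sample_types(
    sample_ids: Iterable[str],
    rules: Sequence[tuple[str, str]] = DEFAULT_TYPE_RULES,
    mapping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Assign a sample type to every sample ID.

    Ordered case-insensitive regex rules are applied first-match-wins; an
    explicit ``mapping`` (sample_id -> type) overrides the regex result.
    Unmatched IDs are typed ``"unknown"``.  Returns the annotation table and
    the list of mapping IDs absent from the data (a warning, not an error).
    """
    ids = [str(s) for s in dict.fromkeys(sample_ids)]
    compiled = [(re.compile(pat, re.IGNORECASE), stype) for pat, stype in rules]
    types = []
    for sid in ids:
        stype = "unknown"
        for pat, candidate in compiled:
            if pat.search(sid):
                stype = candidate
                break
        types.append(stype)
    annotations = pd.DataFrame({"sample_id": ids, "sample_type": types})
    stale: list[str] = []
    if mapping:
        stale = sorted(set(mapping) - set(ids))
        annotations["sample_type"] = [
            mapping.get(sid, stype)
            for sid, stype in zip(annotations["sample_id"], annotations["sample_type"])
        ]
    return annotations, stale


def merge_metadata(
    annotations: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Left-join metadata onto sample annotations by ``sample_id``.

    Returns ``(merged, data_only_ids, metadata_only_ids)``.  Duplicate sample
    IDs in the metadata would multiply rows and are rejected.
    """
    if metadata is None or metadata.empty:
        return annotations.copy(), [], []
    if "sample_id" not in metadata.columns:
        raise DialectError("metadata table must contain a 'sample_id' column")
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
    if len(dups):
        raise DialectError(f"duplicate sample_id in metadata: {sorted(dups.unique())}")
    merged = annotations.merge(meta, on="sample_id", how="left", suffixes=("", "_meta"))
    data_only = sorted(set(annotations["sample_id"]) - set(meta["sample_id"]))
    meta_only = sorted(set(meta["sample_id"]) - set(annotations["sample_id"]))
    return merged, data_only, meta_only


def annotate_records(records: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Fill the sample_type column of the record table from annotations."""
    mapping = dict(zip(annotations["sample_id"], annotations["sample_type"]))
    out = records.copy()
    out["sample_type"] = out["sample_id"].map(mapping)
    return out
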