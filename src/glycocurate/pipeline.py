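"""End-to-end curation pipeline: ingest -> spectra curation -> analyte
curation -> normalization -> traits, with optional SIL quantitation and
repeatability, driven by a single configuration mapping.

The configuration (usually a YAML file) fully determines a run; the JSON run
report records it together with input-file digests, derived cutoffs and all
curation outcomes, so that any run can be replayed exactly from its report.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import analyte_curation as ac
from . import ingest, normalize_traits as nt, quant_repeat as qr
from . import quality as ql
from . import spectra_curation as sc


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {
        "dialect": ingest.LACYTOOLS,
        "data": None,
        "layout": None,
        "metadata": None,
        "sample_type_rules": None,  # list of [regex, type]
        "sample_type_mapping": None,  # csv path: sample_id, sample_type
        "sample_regex": None,  # Skyline column-prefix escape hatch
    },
    "quality": {
        # null -> per-dialect defaults
        "mass_error_window": None,
        "pattern_threshold": None,
        "signal_threshold": None,
    },
    "spectra": {
        "strategy": sc.STRATEGY_NEGATIVE_CONTROL,
        "percentile": 95.0,
        "control_type": "negative_control",
        "normal_assumption": False,
        "excluded_types": ["negative_control", "blank", "pool"],
        "missing_policy": "exclude",
        "rule": "strict",
    },
    "analytes": {
        "mode": "consensus",  # or "per_sample"
        "grouping": "all",  # "all" or "by_group"
        "group_column": "group",
        "min_freq": 0.5,
        "logic": "OR",
        "min_group_size": 10,
        "subset_sample_types": None,  # e.g. ["sample"]
        "overrides": None,  # csv/xlsx path: site, analyte, charge, keep
    },
    "traits": {
        "formulas": None,  # path or "igg_example"
        "absent_policy": "drop",
    },
    "sil": {
        "map": None,  # csv path: peptide, heavy_name, spike_amount
        "units": None,
    },
    "repeatability": {
        "control_type": "pool",
    },
}


def merge_config(user: dict[str, Any] | None) -> dict[str, Any]:
    """User settings on top of the documented defaults (one level deep)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (user or {}).items():
        if section not in config:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in config[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            config[section][key] = value
    return config


def load_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    return merge_config(user)


def _criteria_from_config(config: dict[str, Any]) -> ql.QualityCriteria:
    dialect = config["inputs"]["dialect"]
    base = ql.QualityCriteria.defaults(dialect)
    q = config["quality"]
    window = q["mass_error_window"] or base.mass_error_window
    return ql.QualityCriteria(
        dialect=dialect,
        mass_error_window=tuple(window),
        pattern_threshold=(
            base.pattern_threshold if q["pattern_threshold"] is None else q["pattern_threshold"]
        ),
        signal_threshold=(
            base.signal_threshold if q["signal_threshold"] is None else q["signal_threshold"]
        ),
    )


@dataclass
class RunResult:
    """Everything one pipeline run computed, plus the machine-readable report."""

    config: dict[str, Any]
    records: pd.DataFrame
    annotations: pd.DataFrame
    criteria: ql.QualityCriteria
    summaries: pd.DataFrame
    cutoffs: pd.DataFrame
    kept: pd.DataFrame
    exclusion_log: pd.DataFrame
    freq_tables: dict[str, pd.DataFrame]
    consensus: ac.ConsensusList | None
    curated: pd.DataFrame
    rel_abund: pd.DataFrame
    wide_abund: pd.DataFrame
    traits: pd.DataFrame | None
    sil: qr.SilQuantResult | None
    repeatability: qr.RepeatabilityReport | None
    messages: list[str] = field(default_factory=list)
    report: dict[str, Any] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def example_trait_path() -> Path:
    """Path of the shipped trait table for human IgG Fc N-glycans.

    The file demonstrates the formula syntax (fucosylation, bisection,
    galactosylation/sialylation per antenna, a ratio-type renormalization);
    it is illustrative configuration, not a validated clinical trait set.
    """
    return Path(__file__).parent / "data" / "igg_traits_example.csv"


def run_pipeline(config: dict[str, Any], outdir: str | Path | None = None) -> RunResult:
    """Execute the full curation pipeline described by ``config``.

    The run is deterministic for fixed inputs and settings.  When ``outdir``
    is given, the wide export, exclusion logs, frequency tables, figures and
    the JSON report are written there.
    """
    config = merge_config(config)
    messages: list[str] = []
    inputs = config["inputs"]
    if not inputs["data"]:
        raise ConfigError("inputs.data is required")
    dialect = inputs["dialect"]
    if dialect == ingest.LACYTOOLS:
        records = ingest.read_lacytools(inputs["data"])
    elif dialect == ingest.SKYLINE:
        records = ingest.read_skyline(inputs["data"], sample_regex=inputs["sample_regex"])
    else:
        raise ConfigError(f"inputs.dialect must be lacytools or skyline, got {dialect!r}")
    records = ingest.rename_isomers(records)

    if inputs["layout"]:
        layout = ingest.read_plate_layout(inputs["layout"])
        records, unresolved = ingest.link_plate_layout(records, layout)
        if unresolved:
            messages.append(f"unresolved measurement files (no layout entry): {unresolved}")
    else:
        records = records.assign(sample_id=records["measurement_file"])

    rules = (
        tuple((p, t) for p, t in inputs["sample_type_rules"])
        if inputs["sample_type_rules"]
        else ingest.DEFAULT_TYPE_RULES
    )
    mapping = None
    if inputs["sample_type_mapping"]:
        mapping_table = pd.read_csv(inputs["sample_type_mapping"])
        mapping = dict(zip(mapping_table["sample_id"].astype(str), mapping_table["sample_type"]))
    annotations, stale = ingest.infer_sample_types(
        records["sample_id"].dropna(), rules=rules, mapping=mapping
    )
    if stale:
        messages.append(f"sample-type mapping IDs absent from the data: {stale}")
    wells = records[["sample_id", "plate", "well"]].dropna(subset=["sample_id"]).drop_duplicates(
        "sample_id"
    )
    annotations = annotations.merge(wells, on="sample_id", how="left")
    if inputs["metadata"]:
        meta_path = Path(inputs["metadata"])
        metadata = (
            pd.read_excel(meta_path)
            if meta_path.suffix.lower() in {".xlsx", ".xls"}
            else pd.read_csv(meta_path)
        )
        annotations, data_only, meta_only = ingest.merge_metadata(annotations, metadata)
        if data_only:
            messages.append(f"samples without metadata: {data_only}")
        if meta_only:
            messages.append(f"metadata rows without samples: {meta_only}")
    records = ingest.annotate_records(records, annotations)

    criteria = _criteria_from_config(config)
    flagged = ql.evaluate_quality(records, criteria)
    targeted = ql.targeted_list(flagged)
    summaries = ql.summarize_spectra(flagged, targeted)
    summaries = summaries.merge(
        annotations[["sample_id", "sample_type"]], on="sample_id", how="left"
    )

    spectra_cfg = config["spectra"]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if spectra_cfg["strategy"] == sc.STRATEGY_SKIP:
            cutoffs = sc.skip_cutoffs(sorted(summaries["site"].unique()))
        elif spectra_cfg["strategy"] == sc.STRATEGY_NEGATIVE_CONTROL:
            cutoffs = sc.cutoffs_from_negative_controls(
                summaries,
                control_type=spectra_cfg["control_type"],
                percentile=spectra_cfg["percentile"],
                normal=spectra_cfg["normal_assumption"],
            )
        elif spectra_cfg["strategy"] == sc.STRATEGY_PERCENTILE:
            cutoffs = sc.cutoffs_from_percentile(
                summaries,
                percentile=spectra_cfg["percentile"],
                excluded_types=tuple(spectra_cfg["excluded_types"]),
            )
        else:
            raise ConfigError(f"unknown spectra.strategy {spectra_cfg['strategy']!r}")
        kept, exclusion_log = sc.apply_spectra_curation(
            summaries,
            cutoffs,
            missing_policy=spectra_cfg["missing_policy"],
            rule=spectra_cfg["rule"],
        )

        analyte_cfg = config["analytes"]
        subset = None
        if analyte_cfg["subset_sample_types"]:
            subset = set(
                annotations.loc[
                    annotations["sample_type"].isin(analyte_cfg["subset_sample_types"]),
                    "sample_id",
                ]
            )
        grouping = "per_sample" if analyte_cfg["mode"] == "per_sample" else analyte_cfg["grouping"]
        if analyte_cfg["mode"] == "per_sample":
            freq_tables = {}
            consensus = None
            kept_records = flagged.merge(
                kept[["sample_id", "site"]], on=["sample_id", "site"], how="inner"
            )
            curated = ac.apply_analyte_curation(kept_records, per_sample=True)
        else:
            freq_tables = ac.passing_frequency(
                flagged,
                kept,
                grouping=grouping,
                annotations=annotations,
                group_col=analyte_cfg["group_column"],
                subset_samples=subset,
                min_group_size=analyte_cfg["min_group_size"],
            )
            consensus = ac.build_consensus(
                freq_tables, analyte_cfg["min_freq"], analyte_cfg["logic"]
            )
            if analyte_cfg["overrides"]:
                opath = Path(analyte_cfg["overrides"])
                overrides = (
                    pd.read_excel(opath)
                    if opath.suffix.lower() in {".xlsx", ".xls"}
                    else pd.read_csv(opath)
                )
                consensus = ac.apply_overrides(consensus, overrides)
            kept_records = flagged.merge(
                kept[["sample_id", "site"]], on=["sample_id", "site"], how="inner"
            )
            curated = ac.apply_analyte_curation(kept_records, consensus)
    messages.extend(str(w.message) for w in caught)

    rel_abund = nt.normalize_total_area(curated)
    wide_abund = nt.abundance_wide(rel_abund)

    traits = None
    traits_cfg = config["traits"]
    if traits_cfg["formulas"]:
        formula_path = (
            example_trait_path()
            if traits_cfg["formulas"] == "igg_example"
            else traits_cfg["formulas"]
        )
        formulas = nt.read_trait_table(formula_path)
        traits, trait_messages = nt.compute_traits(
            wide_abund, formulas, absent_policy=traits_cfg["absent_policy"]
        )
        messages.extend(trait_messages)
    else:
        formulas = []

    sil = None
    if config["sil"]["map"]:
        sil_map = pd.read_csv(config["sil"]["map"])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sil = qr.sil_quantify(curated, sil_map, units=config["sil"]["units"])
        messages.extend(str(w.message) for w in caught)

    repeat = None
    repeat_type = config["repeatability"]["control_type"]
    if repeat_type and (annotations["sample_type"] == repeat_type).sum() >= 2:
        try:
            repeat = qr.repeatability(rel_abund, annotations, control_type=repeat_type)
        except ValueError as exc:
            messages.append(f"repeatability skipped: {exc}")

    report = build_report(
        config=config,
        criteria=criteria,
        cutoffs=cutoffs,
        exclusion_log=exclusion_log,
        consensus=consensus,
        formulas=formulas,
        messages=messages,
        n_samples=annotations["sample_id"].nunique(),
        n_records=len(records),
    )

    result = RunResult(
        config=config,
        records=records,
        annotations=annotations,
        criteria=criteria,
        summaries=summaries,
        cutoffs=cutoffs,
        kept=kept,
        exclusion_log=exclusion_log,
        freq_tables=freq_tables,
        consensus=consensus,
        curated=curated,
        rel_abund=rel_abund,
        wide_abund=wide_abund,
        traits=traits,
        sil=sil,
        repeatability=repeat,
        messages=messages,
        report=report,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def build_report(
    config, criteria, cutoffs, exclusion_log, consensus, formulas, messages, n_samples, n_records
) -> dict[str, Any]:
    """Assemble the machine-readable run report.

    Apart from the timestamp the report is a pure function of inputs and
    settings, and it contains everything needed to replay the run.
    """
    inputs = config["inputs"]
    digests = {
        key: _sha256(inputs[key])
        for key in ("data", "layout", "metadata")
        if inputs.get(key)
    }
    excl_counts = sc.exclusions_by_sample_type(exclusion_log)
    return {
        "tool": "glycocurate",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {"paths": {k: str(v) for k, v in inputs.items() if v}, "sha256": digests},
        "settings": config,
        "quality_criteria": {
            "dialect": criteria.dialect,
            "mass_error_window": list(criteria.mass_error_window),
            "pattern_threshold": criteria.pattern_threshold,
            "signal_threshold": criteria.signal_threshold,
        },
        "cutoffs": json.loads(cutoffs.to_json(orient="records")),
        "exclusions_by_sample_type": excl_counts.to_dict(orient="records"),
        "consensus": (
            json.loads(consensus.entries.to_json(orient="records"))
            if consensus is not None
            else None
        ),
        "trait_formulas": {f.name: f.serialize() for f in formulas},
        "counts": {"samples": int(n_samples), "records": int(n_records)},
        "messages": messages,
    }


def write_report(report: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=str) + "\n")
    return path


def export_wide(
    wide_abund: pd.DataFrame,
    traits: pd.DataFrame | None,
    annotations: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """Statistics-ready wide table: one row per sample, columns ordered
    metadata -> traits -> site-prefixed analyte relative abundances.

    Samples excluded during curation stay as rows with missing values; they
    are never silently dropped.  Clashing column names between metadata and
    analytes are suffixed.
    """
    meta = annotations.drop_duplicates("sample_id").set_index("sample_id")
    blocks = [meta]
    if traits is not None:
        blocks.append(traits)
    analyte_block = wide_abund.copy()
    used = set(meta.columns) | (set(traits.columns) if traits is not None else set())
    clashes = [c for c in analyte_block.columns if c in used]
    if clashes:
        warnings.warn(f"analyte columns clashing with metadata/traits renamed: {clashes}")
        analyte_block = analyte_block.rename(columns={c: f"{c}_analyte" for c in clashes})
    blocks.append(analyte_block)
    wide = pd.concat(blocks, axis=1).reindex(meta.index)
    wide.index.name = "sample_id"
    wide = wide.reset_index()
    path = Path(path)
    wide.to_csv(path, index=False)
    try:
        wide.to_excel(path.with_suffix(".xlsx"), index=False)
    except ValueError:  # pragma: no cover - very wide tables
        pass
    return wide


def write_outputs(result: RunResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["records"] = outdir / "records.csv"
    result.records.to_csv(paths["records"], index=False)
    paths["spectra_kept"] = outdir / "spectra_kept.csv"
    result.kept.to_csv(paths["spectra_kept"], index=False)
    paths["exclusion_log"] = outdir / "spectra_exclusions.csv"
    result.exclusion_log.to_csv(paths["exclusion_log"], index=False)
    for scope, table in result.freq_tables.items():
        p = outdir / f"frequencies_{scope}.csv"
        table.to_csv(p, index=False)
        paths[f"frequencies_{scope}"] = p
    if result.consensus is not None:
        paths["consensus"] = outdir / "consensus.csv"
        result.consensus.entries.to_csv(paths["consensus"], index=False)
    paths["wide"] = outdir / "curated_wide.csv"
    export_wide(result.wide_abund, result.traits, result.annotations, paths["wide"])
    if result.sil is not None:
        paths["sil"] = outdir / "sil_quantities.csv"
        table = result.sil.quantities.copy()
        table["median_quantity"] = result.sil.median_quantity
        table.to_csv(paths["sil"])
    if result.repeatability is not None:
        paths["repeatability"] = outdir / "repeatability_per_plate.csv"
        result.repeatability.per_plate.to_csv(paths["repeatability"], index=False)
    paths["scatter"] = outdir / "spectra_curation_scatter.png"
    sc.plot_curation_scatter(result.summaries, result.cutoffs, paths["scatter"])
    paths["report"] = outdir / "report.json"
    write_report(result.report, paths["report"])
    return paths


def replay(report_path: str | Path, outdir: str | Path | None = None) -> RunResult:
    """Re-execute a run exactly from its recorded report settings."""
    with open(report_path) as handle:
        report = json.load(handle)
    return run_pipeline(report["settings"], outdir=outdir)
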