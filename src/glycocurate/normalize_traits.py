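"""Total-area normalization per site and derived glycosylation traits.

Normalization expresses each retained analyte as a percentage of the summed
signal of all retained analytes of its glycosylation site, per sample.
Retained charge states of one analyte are summed before normalizing, and
sites are normalized independently.

Glycosylation traits (e.g. galactosylation per antenna, fucosylation of
complex-type glycans) are computed from explicit formulas over full analyte
names rather than from structure logic.  The formula mini-language is
space-tokenized::

    formula := sum [ "/" sum ]
    sum     := term { "+" term }
    term    := [ number "*" ] analyte-name

``+`` sums analytes, ``number *`` scales a term (e.g. ``0.5 *`` for
monogalactosylated species when counting modification per antenna), and a
single ``/`` renormalizes to a subset.  Formula analytes absent from the
dataset are dropped from numerator and denominator alike; dataset analytes
covered by no formula are reported so the user can extend the formula set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd


class TraitSyntaxError(ValueError):
    pass


def normalize_total_area(curated: pd.DataFrame) -> pd.DataFrame:
    """Relative abundance (%) of each analyte within its site, per sample.

    Input is the curated record table; retained charge states are summed per
    (sample, site, analyte).  Returns a long table with columns sample_id,
    site, analyte_full, rel_abundance.  A (sample, site) whose analytes are
    all missing, or whose total is zero, yields missing values rather than a
    division by zero.
    """
    if (curated["intensity"].dropna() < 0).any():
        bad = curated.loc[curated["intensity"] < 0, "analyte_full"].unique()
        raise ValueError(f"negative intensities for {sorted(bad)[:5]}")
    summed = (
        curated.groupby(["sample_id", "site", "analyte_full"], sort=True)["intensity"]
        .sum(min_count=1)
        .rename("summed_intensity")
        .reset_index()
    )
    totals = (
        summed.groupby(["sample_id", "site"])["summed_intensity"]
        .sum(min_count=1)
        .rename("site_total")
        .reset_index()
    )
    out = summed.merge(totals, on=["sample_id", "site"], how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rel_abundance"] = 100.0 * out["summed_intensity"] / out["site_total"]
    out.loc[out["site_total"] == 0, "rel_abundance"] = np.nan
    return out[["sample_id", "site", "analyte_full", "rel_abundance"]]


def abundance_wide(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long relative-abundance table to samples x full analyte names."""
    wide = rel_abund.pivot_table(
        index="sample_id",
        columns="analyte_full",
        values="rel_abundance",
        aggfunc="first",
        dropna=False,
    )
    wide.columns.name = None
    return wide


@dataclass(frozen=True)
class TraitFormula:
    """A parsed trait: weighted sums of analyte names, optionally a ratio."""

    name: str
    numerator: tuple[tuple[float, str], ...]
    denominator: tuple[tuple[float, str], ...] | None = None

    def serialize(self) -> str:
        def side(terms: tuple[tuple[float, str], ...]) -> str:
            parts = []
            for coef, analyte in terms:
                parts.append(analyte if coef == 1 else f"{coef:g} * {analyte}")
            return " + ".join(parts)

        text = side(self.numerator)
        if self.denominator is not None:
            text += " / " + side(self.denominator)
        return text


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_sum(tokens: list[str], offset: int) -> tuple[tuple[float, str], ...]:
    terms: list[tuple[float, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        coef = 1.0
        tok = tokens[i]
        if _NUMBER_RE.match(tok):
            if i + 1 >= n or tokens[i + 1] != "*":
                raise TraitSyntaxError(
                    f"token {offset + i + 1}: number {tok!r} must be followed by '*'"
                )
            coef = float(tok)
            i += 2
            if i >= n:
                raise TraitSyntaxError(f"token {offset + i}: dangling '*'")
            tok = tokens[i]
        if tok in {"+", "*", "/"}:
            raise TraitSyntaxError(
                f"token {offset + i + 1}: expected analyte name, got operator {tok!r}"
            )
        terms.append((coef, tok))
        i += 1
        if i < n:
            if tokens[i] != "+":
                raise TraitSyntaxError(
                    f"token {offset + i + 1}: expected '+', got {tokens[i]!r}"
                )
            i += 1
            if i >= n:
                raise TraitSyntaxError(f"token {offset + i}: dangling '+'")
    if not terms:
        raise TraitSyntaxError(f"token {offset + 1}: empty expression")
    return tuple(terms)


def parse_formula(name: str, text: str) -> TraitFormula:
    """Parse one space-tokenized trait formula.

    ``/`` binds last and may occur at most once; a second ``/`` is an error
    rather than a silently chained division.  Trait names must not contain
    spaces.
    """
    if not name or re.search(r"\s", name):
        raise TraitSyntaxError(f"trait name {name!r} must be non-empty and contain no spaces")
    tokens = text.split()
    if not tokens:
        raise TraitSyntaxError(f"trait {name!r}: empty formula")
    slashes = [i for i, t in enumerate(tokens) if t == "/"]
    if len(slashes) > 1:
        raise TraitSyntaxError(
            f"trait {name!r}: more than one '/' (token {slashes[1] + 1})"
        )
    if slashes:
        cut = slashes[0]
        numerator = _parse_sum(tokens[:cut], 0)
        denominator = _parse_sum(tokens[cut + 1 :], cut + 1)
    else:
        numerator = _parse_sum(tokens, 0)
        denominator = None
    return TraitFormula(name=name, numerator=numerator, denominator=denominator)


def read_trait_table(path) -> list[TraitFormula]:
    """Read trait formulas from a workbook/CSV with columns 'trait' and 'formula'."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in table.columns}
    if "trait" not in cols or "formula" not in cols:
        raise TraitSyntaxError(
            f"trait table must have columns 'trait' and 'formula', got {list(table.columns)}"
        )
    formulas = []
    seen = set()
    for name, text in zip(
        table[cols["trait"]].astype(str), table[cols["formula"]].astype(str)
    ):
        if name in seen:
            raise TraitSyntaxError(f"duplicate trait name {name!r}")
        seen.add(name)
        formulas.append(parse_formula(name, text))
    return formulas


def _evaluate_side(
    wide: pd.DataFrame,
    terms: tuple[tuple[float, str], ...],
    absent_policy: str,
) -> tuple[pd.Series, bool]:
    """Weighted sum over samples; returns (series, any_term_present)."""
    total = pd.Series(0.0, index=wide.index)
    all_missing = pd.Series(True, index=wide.index)
    any_present = False
    for coef, analyte in terms:
        if analyte not in wide.columns:
            if absent_policy == "zero":
                any_present = True  # treated as an always-zero analyte
            continue
        any_present = True
        col = wide[analyte]
        total = total + coef * col.fillna(0.0)
        all_missing &= col.isna()
    total[all_missing] = np.nan
    return total, any_present


def compute_traits(
    wide: pd.DataFrame,
    formulas: list[TraitFormula],
    absent_policy: str = "drop",
) -> tuple[pd.DataFrame, list[str]]:
    """Evaluate trait formulas over a samples x analyte-names abundance table.

    Ratio traits are reported on the same percentage scale as the input
    abundances (numerator / denominator x 100, i.e. the share of the subset).
    Formula analytes absent from the dataset are dropped (``absent_policy
    "drop"``, matching "absent compositions are ignored") or treated as zero
    (``"zero"``; identical for sums, different for ratios).  Within a sample,
    missing analyte values count as zero unless every referenced analyte is
    missing (an excluded measurement), which yields a missing trait.  A zero
    denominator yields a missing trait value.

    Returns ``(trait table, warnings)`` where warnings name traits whose
    referenced analytes are entirely absent, and dataset analytes covered by
    no formula.
    """
    if absent_policy not in ("drop", "zero"):
        raise ValueError(f"unknown absent policy {absent_policy!r}")
    messages: list[str] = []
    values: dict[str, pd.Series] = {}
    for formula in formulas:
        num, num_present = _evaluate_side(wide, formula.numerator, absent_policy)
        if not num_present:
            messages.append(
                f"trait {formula.name!r}: no referenced analyte present in the dataset"
            )
            values[formula.name] = pd.Series(np.nan, index=wide.index)
            continue
        if formula.denominator is None:
            values[formula.name] = num
            continue
        den, den_present = _evaluate_side(wide, formula.denominator, absent_policy)
        if not den_present:
            messages.append(
                f"trait {formula.name!r}: denominator analytes all absent from the dataset"
            )
            values[formula.name] = pd.Series(np.nan, index=wide.index)
            continue
        # renormalization to a subset, reported on the same percentage scale
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = 100.0 * num / den.where(den != 0)
        values[formula.name] = ratio
    covered = {analyte for f in formulas for _, analyte in f.numerator}
    covered |= {analyte for f in formulas if f.denominator for _, analyte in f.denominator}
    uncovered = sorted(set(wide.columns) - covered)
    if uncovered:
        messages.append(
            "analytes covered by no trait formula (extend the formula set to "
            f"include them): {uncovered}"
        )
    traits = pd.DataFrame(values, index=wide.index)
    return traits, messages
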