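"""Glycan composition labels and analyte-name parsing.

Analyte names follow the widespread glycopeptide convention in which a
peptide/site identifier is immediately followed by a monosaccharide
composition, e.g. ``IgGI1H3N4F1``: the site prefix ``IgGI1`` carries the
glycosylation-site identity and ``H3N4F1`` encodes three hexoses (H), four
N-acetylhexosamines (N) and one fucose (F).  Isomers separated upstream are
distinguished by a trailing running lowercase letter (``N1a``, ``N1b``).

The default split rule places the site/composition boundary before the first
``<monosaccharide letter><digit>`` token.  A stricter "first digit" rule
(boundary before the first digit anywhere in the name) is available but
rejects site identifiers that themselves contain digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Default monosaccharide alphabet: hexose, N-acetylhexosamine, fucose,
#: N-acetylneuraminic acid, N-glycolylneuraminic acid.
DEFAULT_ALPHABET: tuple[str, ...] = ("H", "N", "F", "S", "G")

_TOKEN_RE = re.compile(r"([A-Za-z])(\d+)")


class AnalyteNameError(ValueError):
    """Raised when an analyte label cannot be parsed."""


@dataclass(frozen=True)
class GlycanComposition:
    """A monosaccharide composition in first-appearance order.

    ``counts`` is an ordered tuple of ``(letter, count)`` pairs so that
    serialisation reproduces the original label (minus any isomer suffix).
    """

    raw_label: str
    counts: tuple[tuple[str, int], ...]

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.raw_label

    @property
    def count_map(self) -> dict[str, int]:
        return dict(self.counts)

    def serialize(self) -> str:
        return "".join(f"{letter}{count}" for letter, count in self.counts)


def parse_composition(
    text: str, alphabet: Sequence[str] = DEFAULT_ALPHABET
) -> tuple[GlycanComposition, str]:
    """Parse ``text`` as ``<letter><count>`` tokens plus an optional trailing
    lowercase isomer letter.

    Returns ``(composition, isomer_suffix)`` where the suffix is ``""`` when
    absent.  Raises :class:`AnalyteNameError` when the text is not fully
    tokenizable, a letter is outside ``alphabet``, or a count is zero.
    """
    suffix = ""
    body = text
    # a single trailing lowercase letter (not part of a letter+digit token)
    if body and body[-1].islower() and body[-1].isalpha():
        suffix = body[-1]
        body = body[:-1]

    pos = 0
    counts: list[tuple[str, int]] = []
    alpha = set(alphabet)
    for m in _TOKEN_RE.finditer(body):
        if m.start() != pos:
            raise AnalyteNameError(
                f"composition {text!r}: cannot tokenize {body[pos:m.start()]!r}"
            )
        letter, digits = m.group(1), m.group(2)
        if letter not in alpha:
            raise AnalyteNameError(
                f"composition {text!r}: letter {letter!r} not in alphabet {sorted(alpha)}"
            )
        count = int(digits)
        if count < 1:
            raise AnalyteNameError(f"composition {text!r}: zero count for {letter!r}")
        counts.append((letter, count))
        pos = m.end()
    if pos != len(body) or not counts:
        raise AnalyteNameError(
            f"composition {text!r}: cannot tokenize {body[pos:]!r}"
        )
    return GlycanComposition(raw_label=body, counts=tuple(counts)), suffix


def split_analyte_name(
    label: str,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    strict_first_digit: bool = False,
) -> tuple[str, GlycanComposition, str]:
    """Split an analyte label into ``(site, composition, isomer_suffix)``.

    Default rule: the composition starts at the first position where an
    alphabet letter is directly followed by a digit.  With
    ``strict_first_digit=True`` the composition instead starts at the first
    digit's preceding letter (rejecting sites that contain digits).
    """
    if not label:
        raise AnalyteNameError("empty analyte label")
    alpha = set(alphabet)
    split_at = -1
    if strict_first_digit:
        for i, ch in enumerate(label):
            if ch.isdigit():
                split_at = i - 1
                break
        if split_at < 0 or label[split_at] not in alpha:
            raise AnalyteNameError(
                f"label {label!r}: no <letter><digit> composition start found"
            )
    else:
        for i in range(len(label) - 1):
            if label[i] in alpha and label[i + 1].isdigit():
                split_at = i
                break
        if split_at < 0:
            raise AnalyteNameError(
                f"label {label!r}: no composition token "
                f"(<letter in {sorted(alpha)}><digit>) found"
            )
    site = label[:split_at]
    composition, suffix = parse_composition(label[split_at:], alphabet)
    return site, composition, suffix


def full_name(site: str, analyte: str) -> str:
    """Reassemble the full analyte label (site prefix + composition+suffix)."""
    return f"{site}{analyte}"


#: Typical IgG-Fc-style diantennary compositions, most abundant first
#: (G0F, G1F, G2F, afucosylated, bisected, sialylated, then rarer species).
_CATALOGUE_BASE = (
    "H3N4F1", "H4N4F1", "H5N4F1", "H3N4", "H4N4", "H5N4",
    "H3N5F1", "H4N5F1", "H5N4F1S1", "H4N4F1S1",
    "H5N4S1", "H3N5", "H4N5", "H5N5F1", "H5N4S2", "H5N5F1S1",
    "H6N5F1", "H6N5", "H6N5F1S1", "H7N5F1",
    "H6N4F1", "H6N4", "H7N5", "H7N5F1S1",
)


def composition_catalogue(n: int) -> list[str]:
    """Deterministic list of ``n`` plausible N-glycan composition labels.

    Starts from a curated panel of typical diantennary IgG-Fc-style
    compositions (most abundant first) and extends it by enumeration when
    more are requested.  Used by the synthetic-data generator.
    """
    labels = list(_CATALOGUE_BASE)
    if n > len(labels):
        seen = set(labels)
        for s in (0, 1, 2):
            for f in (0, 1):
                for hexnac in (4, 5, 6):
                    for h in range(3, 9):
                        if h - 3 < s:  # at least one galactose per sialic acid
                            continue
                        label = f"H{h}N{hexnac}" + (f"F{f}" if f else "") + (f"S{s}" if s else "")
                        if label not in seen:
                            seen.add(label)
                            labels.append(label)
    if n > len(labels):
        raise ValueError(f"catalogue holds only {len(labels)} compositions")
    return labels[:n]


def validate_alphabet(alphabet: Iterable[str]) -> tuple[str, ...]:
    letters = tuple(alphabet)
    if not letters or any(len(c) != 1 or not c.isalpha() for c in letters):
        raise ValueError("alphabet must be single letters")
    return letters
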