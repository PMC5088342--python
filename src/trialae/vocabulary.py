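"""Adverse-event term normalization and MedDRA system-organ-class mapping.

Free-text event names arrive in mixed case with inconsistent punctuation and
spacing.  :func:`normalize_term` reduces them to a canonical form, and
:func:`map_to_soc` resolves the canonical form to one of the 26 MedDRA system
organ classes (SOCs) through an exact-match lookup table.  A registry-provided
SOC code on the event itself always wins over the table.  Terms that resolve
nowhere fall through to the :data:`UNCLASSIFIED` sentinel — mapping never
raises.

The mapping table is deliberately a deterministic exact-match table rather
than a concept-normalization engine; synonyms can be aliased by adding rows
that point at the same SOC.  A default table of common trial adverse events
ships with the package, alongside the 26-name SOC vocabulary.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ValidationError

__all__ = [
    "SOC_CLASSES",
    "UNCLASSIFIED",
    "normalize_term",
    "map_to_soc",
    "load_term_map",
    "default_term_map",
    "default_filter_list",
    "load_filter_list",
]

UNCLASSIFIED = "UNCLASSIFIED"

_PUNCT_RE = re.compile(r"[^\w\s]+")
_WS_RE = re.compile(r"\s+")


def _load_soc_classes() -> tuple[str, ...]:
    text = resources.files("trialae.data").joinpath("soc_classes.txt").read_text("utf-8")
    names = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(names) != 26 or len(set(names)) != 26:
        raise ValidationError("packaged SOC vocabulary must contain 26 unique names")
    return names


#: The 26 MedDRA system organ classes (top level of the hierarchy, prior to
#: the 2016 addition of "Product issues").
SOC_CLASSES: tuple[str, ...] = _load_soc_classes()
_SOC_SET = frozenset(SOC_CLASSES)
_SOC_BY_CANONICAL = {}  # filled after normalize_term is defined


def normalize_term(term: str) -> str:
    """Canonicalize a free-text adverse-event term.

    Lower-cases, strips leading/trailing whitespace, replaces punctuation
    runs with single spaces and collapses internal whitespace.  Idempotent:
    ``normalize_term(normalize_term(x)) == normalize_term(x)``.

    Raises :class:`ValidationError` if the input is empty after trimming.
    """
    if term is None or not term.strip():
        raise ValidationError("adverse-event term is empty")
    out = _PUNCT_RE.sub(" ", term.lower())
    out = _WS_RE.sub(" ", out).strip()
    if not out:
        raise ValidationError(f"term {term!r} is empty after normalization")
    return out


_SOC_BY_CANONICAL = {normalize_term(name): name for name in SOC_CLASSES}


def map_to_soc(
    term: str,
    term_map: Mapping[str, str],
    soc_hint: str | None = None,
) -> str:
    """Resolve an event term to a system organ class.

    Resolution order: a valid registry-provided ``soc_hint`` (matched
    case/punctuation-insensitively against the 26 class names) wins; then the
    canonical term is looked up in ``term_map``; anything else is
    :data:`UNCLASSIFIED`.  This function never raises.
    """
    if soc_hint:
        try:
            hinted = _SOC_BY_CANONICAL.get(normalize_term(soc_hint))
        except ValidationError:
            hinted = None
        if hinted is not None:
            return hinted
    try:
        canonical = normalize_term(term)
    except ValidationError:
        return UNCLASSIFIED
    return term_map.get(canonical, UNCLASSIFIED)


def load_term_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (term, SOC name) into a canonical lookup table.

    ``#``-prefixed lines and blank lines are ignored.  Keys are
    canonicalized with :func:`normalize_term`.  Identical duplicate rows are
    deduplicated; duplicate keys mapping to different SOCs, and rows naming
    an unknown SOC, raise :class:`ValidationError` identifying the row.
    """
    entries: dict[str, str] = {}
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            raw_term, raw_soc = parts
            soc = _SOC_BY_CANONICAL.get(normalize_term(raw_soc)) if raw_soc.strip() else None
            if soc is None:
                raise ValidationError(
                    f"{path}:{lineno}: unknown system organ class {raw_soc!r}"
                )
            key = normalize_term(raw_term)
            if key in entries and entries[key] != soc:
                raise ValidationError(
                    f"{path}:{lineno}: term {key!r} already mapped to "
                    f"{entries[key]!r}, conflicting with {soc!r}"
                )
            entries[key] = soc
    return entries


def default_term_map() -> dict[str, str]:
    """The packaged default term → SOC table (~160 common trial AE terms)."""
    with resources.as_file(
        resources.files("trialae.data").joinpath("term_soc_map.tsv")
    ) as path:
        return load_term_map(path)


def load_filter_list(path: str | Path) -> frozenset[str]:
    """Load a nonserious-event filter list: one canonical term per line,
    ``#`` comments and blank lines ignored."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        terms.add(normalize_term(stripped))
    return frozenset(terms)


def default_filter_list() -> frozenset[str]:
    """The packaged placeholder filter list of commonly shared nonserious events."""
    with resources.as_file(
        resources.files("trialae.data").joinpath("nonserious_filter.txt")
    ) as path:
        return load_filter_list(path)
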