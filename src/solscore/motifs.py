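"""PROSITE-syntax pattern engine and the built-in PTM/motif catalogue.

Consensus patterns over residue sets describe post-translational
modification sites (phosphorylation, N-glycosylation, amidation, Asx
hydroxylation, sulfation, prenylation, ...) and short sequence motifs.
The grammar supported here is the classical PROSITE pattern syntax:

* single uppercase residue literals (``N``),
* ``x`` wildcard,
* ``[ST]`` residue sets, ``{P}`` complement sets,
* ``(n)`` / ``(n,m)`` repeat counts on any element,
* ``<`` N-terminal and ``>`` C-terminal anchors (whole-pattern only),
* ``-`` element separators; a trailing ``.`` is ignored.

Matching reports, for every start position, the leftmost-shortest match
(variable repeats expand minimally).  Overlapping matches at different
start positions are all reported; the PS_SCAN skip-flag convention for
high-probability patterns is deliberately not emulated.  Coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .dataset import STANDARD_RESIDUES, AminoAcidSequence, ExpressionDataset

__all__ = [
    "PatternError",
    "PatternElement",
    "MotifPattern",
    "MotifMatch",
    "MotifCatalogue",
    "parse_pattern",
    "scan",
    "count_sites",
    "load_catalogue",
]


class PatternError(ValueError):
    """Raised for malformed PROSITE-syntax patterns."""


@dataclass(frozen=True)
class PatternElement:
    """One dash-separated pattern element with its repeat range.

    kind is ``set`` (explicit residues), ``complement`` (any residue not
    listed) or ``wildcard`` (``x``).
    """

    kind: str
    residues: Optional[frozenset[str]]
    min_repeat: int = 1
    max_repeat: int = 1

    def accepts(self, ch: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "set":
            return ch in self.residues  # type: ignore[operator]
        return ch not in self.residues  # type: ignore[operator]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    raw: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_width(self) -> int:
        return sum(e.min_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """1-based inclusive match coordinates."""

    pattern_name: str
    start: int
    end: int


_TOKEN_RE = re.compile(
    r"^(?:(?P<literal>[A-Z])|(?P<wild>x)|\[(?P<set>[A-Z]*)\]|\{(?P<comp>[A-Z]*)\})"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


def parse_pattern(raw: str, name: str = "") -> MotifPattern:
    """Parse PROSITE-syntax text into a :class:`MotifPattern`.

    Raises :class:`PatternError` with the offending token and position for
    unbalanced brackets, empty sets, malformed repeats, unknown residues,
    or bracket-embedded anchors (``[G>]`` is not supported).
    """
    text = raw.strip()
    if text.endswith("."):
        text = text[:-1].strip()
    if not text:
        raise PatternError("empty pattern")
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if "<" in text or ">" in text:
        raise PatternError(
            f"{raw!r}: anchors are supported only at the pattern ends"
        )
    if not text:
        raise PatternError(f"{raw!r}: pattern has anchors but no elements")

    elements: list[PatternElement] = []
    for idx, token in enumerate(text.split("-"), start=1):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if m is None:
            raise PatternError(f"{raw!r}: malformed token {token!r} (element {idx})")
        if m.group("wild") is not None:
            kind, residues = "wildcard", None
        elif m.group("literal") is not None:
            kind, residues = "set", frozenset(m.group("literal"))
        elif m.group("set") is not None:
            kind, residues = "set", frozenset(m.group("set"))
        else:
            kind, residues = "complement", frozenset(m.group("comp"))
        if residues is not None:
            if not residues:
                raise PatternError(f"{raw!r}: empty set in element {idx}")
            bad = residues - STANDARD_RESIDUES
            if bad:
                raise PatternError(
                    f"{raw!r}: non-standard residues {sorted(bad)} in element {idx}"
                )
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo > hi:
            raise PatternError(
                f"{raw!r}: repeat minimum exceeds maximum in element {idx}"
            )
        elements.append(PatternElement(kind, residues, lo, hi))
    return MotifPattern(
        name=name or raw,
        raw=raw,
        elements=tuple(elements),
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def _match_ends(seq: str, elements: tuple[PatternElement, ...], i: int, pos: int) -> Iterator[int]:
    """Yield candidate end offsets (exclusive), shortest expansion first."""
    if i == len(elements):
        yield pos
        return
    elem = elements[i]
    end = pos
    for _ in range(elem.min_repeat):
        if end >= len(seq) or not elem.accepts(seq[end]):
            return
        end += 1
    reps = elem.min_repeat
    while True:
        yield from _match_ends(seq, elements, i + 1, end)
        if reps == elem.max_repeat or end >= len(seq) or not elem.accepts(seq[end]):
            return
        end += 1
        reps += 1


def scan(seq: AminoAcidSequence | str, pattern: MotifPattern) -> list[MotifMatch]:
    """All matches of *pattern* in *seq*, ascending by start position.

    One match per start position (the shortest for variable repeats);
    zero-width matches are suppressed.
    """
    residues = seq.residues if isinstance(seq, AminoAcidSequence) else seq
    n = len(residues)
    starts: Iterable[int]
    if pattern.anchored_start:
        starts = (0,)
    else:
        starts = range(n - pattern.min_width + 1)
    matches: list[MotifMatch] = []
    for start in starts:
        for end in _match_ends(residues, pattern.elements, 0, start):
            if end == start:
                continue  # zero-width expansion carries no site
            if pattern.anchored_end and end != n:
                continue
            matches.append(MotifMatch(pattern.name, start + 1, end))
            break
    return matches


@dataclass
class MotifCatalogue:
    """Named, parseable pattern set with a feature kind per pattern.

    kind ``binary`` exposes the pattern as a presence/absence feature,
    ``discrete`` as a per-sequence site count.
    """

    patterns: list[MotifPattern] = field(default_factory=list)
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.patterns]
        if len(set(names)) != len(names):
            raise PatternError("duplicate pattern names in catalogue")
        for name, kind in self.kinds.items():
            if kind not in ("binary", "discrete"):
                raise PatternError(f"{name}: unknown feature kind {kind!r}")

    def __iter__(self) -> Iterator[MotifPattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.patterns)

    def get(self, name: str) -> MotifPattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise KeyError(name)


def load_catalogue(path: str | Path | None = None) -> MotifCatalogue:
    """Load a catalogue file (``name<TAB>pattern<TAB>kind`` per line).

    Without *path* the bundled catalogue of classical PROSITE consensus
    patterns is loaded.  ``#`` lines are comments.
    """
    if path is None:
        text = (
            resources.files("solscore.data").joinpath("ptm_patterns.tsv").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    patterns: list[MotifPattern] = []
    kinds: dict[str, str] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PatternError(
                f"catalogue line {line_no}: expected 3 tab-separated fields"
            )
        name, raw, kind = (p.strip() for p in parts)
        patterns.append(parse_pattern(raw, name=name))
        kinds[name] = kind
    return MotifCatalogue(patterns=patterns, kinds=kinds)


def count_sites(
    dataset: ExpressionDataset, catalogue: MotifCatalogue
) -> "pd.DataFrame":
    """Per-record site counts and presence flags for every pattern.

    Returns a DataFrame indexed by record id with two columns per pattern,
    ``<name>_count`` (int) and ``<name>_present`` (0/1).
    """
    import pandas as pd

    if len(catalogue) == 0:
        raise PatternError("catalogue is empty")
    data: dict[str, list] = {}
    for pattern in catalogue:
        counts = [len(scan(rec.sequence, pattern)) for rec in dataset]
        data[f"{pattern.name}_count"] = counts
        data[f"{pattern.name}_present"] = [int(c > 0) for c in counts]
    return pd.DataFrame(data, index=pd.Index(dataset.ids, name="id"))
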