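"""Sequence-computable structural features and the external-predictor adapter.

Four feature families are computed directly from sequence:

* PEST regions — D/E/P/S/T-rich stretches of >= 12 residues between
  positively charged flanks (K/R/H or the sequence ends), scored with the
  classical epestfind-style formula
  ``0.55 * mole%(DEPST) - 0.5 * mean rescaled hydropathy`` where the
  Kyte–Doolittle value is rescaled linearly onto a 0–90 scale.
* Coiled coils — Lupas-style sliding-window heptad scoring: per residue,
  the maximum over all 28-residue windows covering it and over the 7
  heptad registers of the geometric mean of positional propensities.
* Transmembrane segments — ``baseline:`` hydropathy stand-in: maximal
  19-residue windows with mean Kyte–Doolittle hydropathy above a cutoff,
  merged when overlapping.
* Disorder — ``baseline:`` composition stand-in: running mean of a
  per-residue disorder propensity scale (TOP-IDP), reported as the
  fraction of positions above a threshold.

The transmembrane and disorder features are transparent baselines, not
re-implementations of the trained predictors used in practice (dedicated
TM topology tools, RONN, ...).  Output of such external tools — and of
accessibility, secondary-structure, signal-peptide, disulfide and
site-specific PTM predictors — enters the analysis through the adapter
table contract of :func:`load_external_features`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .dataset import AminoAcidSequence, ExpressionDataset
from .physchem import KYTE_DOOLITTLE

__all__ = [
    "PestRegion",
    "CoiledCoilProfile",
    "StructuralFeatures",
    "StructuralConfig",
    "ExternalFeatureTable",
    "find_pest",
    "coiled_coil",
    "tm_segments",
    "disorder_profile",
    "structural_features",
    "load_external_features",
    "load_cc_propensities",
]

logger = logging.getLogger(__name__)

#: TOP-IDP composition scale; positive values are disorder-promoting.
TOP_IDP: dict[str, float] = {
    "A": 0.060, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.020,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

_PEST_FLANKS = frozenset("KRH")
_PEST_ENRICHED = frozenset("DEPST")


@dataclass(frozen=True)
class PestRegion:
    """One candidate PEST stretch, 1-based inclusive coordinates."""

    start: int
    end: int
    score: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CoiledCoilProfile:
    """Per-residue heptad scores and above-threshold segments."""

    scores: np.ndarray
    segments: tuple[tuple[int, int], ...]
    threshold: float

    @property
    def cc_fraction(self) -> float:
        if self.scores.size == 0:
            return 0.0
        covered = sum(end - start + 1 for start, end in self.segments)
        return covered / self.scores.size


@dataclass(frozen=True)
class StructuralFeatures:
    n_pest: int
    max_pest_score: float
    cc_fraction: float
    n_tm: int
    disorder_fraction: float


@dataclass(frozen=True)
class StructuralConfig:
    """Window sizes and thresholds for the structural feature family."""

    pest_min_length: int = 12
    pest_score_threshold: float = 5.0
    cc_window: int = 28
    cc_threshold: float = 1.3
    tm_window: int = 19
    tm_cutoff: float = 1.6
    disorder_window: int = 21
    disorder_threshold: float = 0.1


DEFAULT_STRUCTURAL = StructuralConfig()


def find_pest(
    seq: AminoAcidSequence, min_length: int = 12
) -> list[PestRegion]:
    """Candidate PEST regions between positively charged flanks.

    A stretch qualifies when it is at least *min_length* residues long,
    contains at least one P, one of D/E and one of S/T, and is bounded by
    K/R/H residues or the sequence ends.  The score combines D/E/P/S/T
    mole percent with mean hydropathy rescaled to 0–90; scores above +5
    are conventionally "interesting" but all candidates are returned.
    """
    residues = seq.residues
    n = len(residues)
    boundaries = [-1] + [i for i, ch in enumerate(residues) if ch in _PEST_FLANKS] + [n]
    regions: list[PestRegion] = []
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        start, stop = left + 1, right  # half-open stretch between flanks
        length = stop - start
        if length < min_length:
            continue
        stretch = residues[start:stop]
        if (
            "P" not in stretch
            or not any(c in stretch for c in "DE")
            or not any(c in stretch for c in "ST")
        ):
            continue
        depst_pct = 100.0 * sum(stretch.count(c) for c in _PEST_ENRICHED) / length
        hydro = math.fsum(10.0 * KYTE_DOOLITTLE[c] + 45.0 for c in stretch) / length
        score = 0.55 * depst_pct - 0.5 * hydro
        regions.append(PestRegion(start=start + 1, end=stop, score=score))
    return regions


_CC_TABLE_CACHE: Optional[dict[str, np.ndarray]] = None


def load_cc_propensities(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Residue -> 7 heptad-position propensities, from the bundled table."""
    global _CC_TABLE_CACHE
    if path is None and _CC_TABLE_CACHE is not None:
        return _CC_TABLE_CACHE
    if path is None:
        text = (
            resources.files("solscore.data")
            .joinpath("coiled_coil_propensities.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise ValueError("coiled-coil table rows need residue + 7 values")
        values = np.array([float(v) for v in parts[1:]])
        if np.any(values <= 0):
            raise ValueError("coiled-coil propensities must be positive")
        table[parts[0]] = values
    if path is None:
        _CC_TABLE_CACHE = table
    return table


def coiled_coil(
    seq: AminoAcidSequence,
    window: int = 28,
    threshold: float = 1.3,
    propensities: dict[str, np.ndarray] | None = None,
) -> CoiledCoilProfile:
    """Sliding-window heptad score profile.

    For a window starting at ``s`` scanned in register ``r``, residue ``i``
    occupies heptad position ``(i - s + r) mod 7``; the window score is the
    geometric mean of the positional propensities.  Each residue receives
    the maximum score over all windows covering it and all 7 registers.
    Sequences shorter than the window get an all-zero profile.
    """
    if propensities is None:
        propensities = load_cc_propensities()
    n = len(seq)
    scores = np.zeros(n)
    if n < window:
        return CoiledCoilProfile(scores=scores, segments=(), threshold=threshold)
    # For fixed c = (r - s) mod 7 the heptad position of residue i is
    # (i + c) mod 7, so only 7 distinct window phases exist.
    logp = np.empty((7, n))
    for c in range(7):
        for i, ch in enumerate(seq.residues):
            logp[c, i] = math.log(propensities[ch][(i + c) % 7])
    csum = np.concatenate([np.zeros((7, 1)), np.cumsum(logp, axis=1)], axis=1)
    win_means = (csum[:, window:] - csum[:, :-window]) / window  # (7, n-window+1)
    win_scores = np.exp(win_means)
    for s in range(n - window + 1):
        best = win_scores[:, s].max()
        span = scores[s : s + window]
        np.maximum(span, best, out=span)
    above = scores >= threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            segments.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return CoiledCoilProfile(
        scores=scores, segments=tuple(segments), threshold=threshold
    )


def tm_segments(
    seq: AminoAcidSequence, window: int = 19, cutoff: float = 1.6
) -> list[tuple[int, int]]:
    """baseline: hydrophobic stretches compatible with membrane spans.

    Maximal *window*-sized stretches whose mean Kyte–Doolittle hydropathy
    reaches *cutoff*, merged when overlapping; 1-based inclusive.
    """
    n = len(seq)
    if n < window:
        return []
    kd = np.array([KYTE_DOOLITTLE[ch] for ch in seq.residues])
    csum = np.concatenate([[0.0], np.cumsum(kd)])
    means = (csum[window:] - csum[:-window]) / window
    hits = np.flatnonzero(means >= cutoff)
    segments: list[tuple[int, int]] = []
    for s in hits:
        start, end = int(s) + 1, int(s) + window
        if segments and start <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
    return segments


def disorder_profile(
    seq: AminoAcidSequence,
    window: int = 21,
    threshold: float = 0.1,
) -> tuple[np.ndarray, float]:
    """baseline: composition-propensity disorder profile.

    Running mean (edge-shrunk, centred) of the TOP-IDP scale; returns the
    per-residue profile and the fraction of positions above *threshold*.
    """
    values = np.array([TOP_IDP[ch] for ch in seq.residues])
    n = values.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    profile = (csum[hi] - csum[lo]) / (hi - lo)
    fraction = float(np.mean(profile > threshold))
    return profile, fraction


def structural_features(
    seq: AminoAcidSequence, cfg: StructuralConfig = DEFAULT_STRUCTURAL
) -> StructuralFeatures:
    """All structural descriptors for one sequence."""
    pest = find_pest(seq, min_length=cfg.pest_min_length)
    interesting = [r for r in pest if r.score > cfg.pest_score_threshold]
    cc = coiled_coil(seq, window=cfg.cc_window, threshold=cfg.cc_threshold)
    tms = tm_segments(seq, window=cfg.tm_window, cutoff=cfg.tm_cutoff)
    _, dis_frac = disorder_profile(
        seq, window=cfg.disorder_window, threshold=cfg.disorder_threshold
    )
    return StructuralFeatures(
        n_pest=len(interesting),
        max_pest_score=max((r.score for r in pest), default=0.0),
        cc_fraction=cc.cc_fraction,
        n_tm=len(tms),
        disorder_fraction=dis_frac,
    )


VALID_FEATURE_KINDS = ("binary", "discrete", "continuous")


@dataclass
class ExternalFeatureTable:
    """Adapter-supplied feature values joined to a dataset by id.

    features maps feature name -> (kind, {id: value}); ids absent from a
    feature's rows are declared missing and excluded from correlation.
    """

    features: dict[str, tuple[str, dict[str, float]]] = field(default_factory=dict)


def load_external_features(
    path: str | Path, dataset: ExpressionDataset
) -> ExternalFeatureTable:
    """Load an adapter TSV (``id<TAB>feature<TAB>kind<TAB>value``).

    Values from external predictors (solvent accessibility, secondary
    structure content, signal peptides, S–S bonds, site-specific PTM
    predictions, ...) are joined by record id.  Unknown kinds, non-numeric
    values for numeric kinds, and non-0/1 values for binary kinds raise
    errors naming the line; ids never covered by a feature are logged and
    excluded downstream.
    """
    dataset_ids = set(dataset.ids)
    table = ExternalFeatureTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != [
            "id",
            "feature",
            "kind",
            "value",
        ]:
            raise ValueError(f"{path}: expected header 'id feature kind value'")
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"line {line_no}: expected 4 columns")
            rec_id, feature, kind, raw_value = (c.strip() for c in row)
            if kind not in VALID_FEATURE_KINDS:
                raise ValueError(f"line {line_no}: unknown kind {kind!r}")
            if rec_id not in dataset_ids:
                raise ValueError(
                    f"line {line_no}: id {rec_id!r} not in dataset"
                )
            try:
                value = float(raw_value)
            except ValueError:
                raise ValueError(
                    f"line {line_no}: non-numeric value {raw_value!r} "
                    f"for feature {feature!r}"
                ) from None
            if kind == "binary" and value not in (0.0, 1.0):
                raise ValueError(
                    f"line {line_no}: binary feature {feature!r} has value {value}"
                )
            declared_kind, values = table.features.setdefault(feature, (kind, {}))
            if declared_kind != kind:
                raise ValueError(
                    f"line {line_no}: feature {feature!r} redeclared as {kind!r}"
                )
            values[rec_id] = value
    for feature, (kind, values) in table.features.items():
        missing = len(dataset_ids) - len(values)
        if missing:
            logger.warning(
                "external feature %s: %d dataset ids without a value "
                "(excluded from correlation)",
                feature,
                missing,
            )
    return table
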