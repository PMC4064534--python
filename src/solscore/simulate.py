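"""Seeded synthetic expression datasets with planted feature effects.

The generator emulates the statistical shape of a large cell-free
expression screen: a few thousand independent sequences with background
residue composition, category base rates near the observed soluble rate
(A defaults to 25.7%), and configurable monotone feature-category
associations planted through a multinomial-logit category model

    logit weights:  log(base_rate_k) + sum_e beta_e * z(feature_e),

where z is the feature standardised over the generated batch and each
effect e targets one category k.  Outcome records (expressed flag, soluble
yield, full-length flag) are back-filled per category so the categorical
assessment path is exercised end to end rather than bypassed.

Motif plants overwrite a pattern instance into a configurable fraction of
sequences (at the terminus for anchored patterns), letting binary
presence features carry planted effects.

Determinism: a dataset is reproducible bit for bit from (config, seed);
one seed sequence per generate call is split per record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    AminoAcidSequence,
    CategorizationConfig,
    ExpressionDataset,
    ExpressionOutcome,
    ExpressionRecord,
    assign_category,
    write_dataset,
)
from .motifs import MotifCatalogue, MotifPattern, load_catalogue, scan
from .physchem import (
    DEFAULT_PHYSCHEM,
    gravy,
    isoelectric_point,
    molecular_weight,
    net_charge,
)

__all__ = [
    "NATURAL_FREQUENCIES",
    "Effect",
    "MotifPlant",
    "SynthConfig",
    "SynthDataset",
    "realize_pattern",
    "sample_sequence",
    "generate",
]

#: Approximate background amino-acid frequencies of vertebrate proteomes.
NATURAL_FREQUENCIES: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.025,
    "Q": 0.040, "E": 0.063, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


@dataclass(frozen=True)
class Effect:
    """One planted association: beta log-odds per SD of *feature* on *category*."""

    feature: str
    category: str
    beta: float

    def __post_init__(self) -> None:
        if self.category not in ("A", "C", "N"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def expected_sign(self) -> str:
        return "+" if self.beta > 0 else "-" if self.beta < 0 else "ND"


@dataclass(frozen=True)
class MotifPlant:
    """Insert an instance of catalogue pattern into a fraction of sequences."""

    pattern: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("plant fraction must be in [0, 1]")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the scale and base rates of a large uniform-condition
    cell-free screen: n = 3000 records of 50-300 residues with background
    composition, soluble rate 25.7%, remainder split near-evenly between
    insoluble and non-expressed.
    """

    n: int = 3000
    length_range: tuple[int, int] = (50, 300)
    composition: dict[str, float] = field(
        default_factory=lambda: dict(NATURAL_FREQUENCIES)
    )
    base_rates: dict[str, float] = field(
        default_factory=lambda: {"A": 0.257, "C": 0.370, "N": 0.373}
    )
    effects: list[Effect] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    seed: int = 0
    yield_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range minimum must be >= 30 and <= maximum")
        rates = self.base_rates
        if set(rates) != {"A", "C", "N"} or any(v <= 0 for v in rates.values()):
            raise ValueError("base_rates must cover A, C, N with positive values")
        if abs(sum(rates.values()) - 1.0) > 1e-9:
            raise ValueError("base_rates must sum to 1")
        self.effects = [e if isinstance(e, Effect) else Effect(**e) for e in self.effects]
        self.motif_plants = [
            m if isinstance(m, MotifPlant) else MotifPlant(**m)
            for m in self.motif_plants
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)


@dataclass
class SynthDataset:
    """Generated dataset plus its ground-truth effect ledger."""

    dataset: ExpressionDataset
    truth: pd.DataFrame  # feature, category, beta, expected_sign
    config: SynthConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Export FASTA + outcome TSV + ground-truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fasta",
            "outcomes": outdir / "outcomes.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_dataset(self.dataset, paths["fasta"], paths["outcomes"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def realize_pattern(pattern: MotifPattern) -> str:
    """A concrete residue string matching *pattern* (minimal expansion)."""
    out: list[str] = []
    for elem in pattern.elements:
        if elem.kind == "wildcard":
            ch = "A"
        elif elem.kind == "set":
            ch = min(elem.residues)  # type: ignore[arg-type]
        else:
            for cand in "AGLSVTEKIDR":
                if cand not in elem.residues:  # type: ignore[operator]
                    ch = cand
                    break
            else:  # pragma: no cover - complements never cover the alphabet
                raise ValueError(f"{pattern.raw}: complement covers alphabet")
        out.append(ch * elem.min_repeat)
    return "".join(out)


def sample_sequence(
    cfg: SynthConfig,
    rng: np.random.Generator,
    index: int = 0,
    plants: Sequence[tuple[MotifPattern, str]] = (),
) -> AminoAcidSequence:
    """Draw one sequence: uniform length, i.i.d. residues, optional plants."""
    letters = sorted(cfg.composition)
    weights = np.array([cfg.composition[ch] for ch in letters], dtype=float)
    weights = weights / weights.sum()
    lo, hi = cfg.length_range
    length = int(rng.integers(lo, hi + 1))
    residues = list(rng.choice(list(letters), size=length, p=weights))
    for pattern, instance in plants:
        width = len(instance)
        if width > length:
            continue
        if pattern.anchored_start:
            pos = 0
        elif pattern.anchored_end:
            pos = length - width
        else:
            pos = int(rng.integers(0, length - width + 1))
        residues[pos : pos + width] = list(instance)
    return AminoAcidSequence(id=f"syn{index:05d}", residues="".join(residues))


def _feature_values(
    name: str,
    sequences: list[AminoAcidSequence],
    catalogue: MotifCatalogue,
) -> np.ndarray:
    """Resolve an effect's feature name to per-sequence values."""
    if name == "length":
        return np.array([float(len(s)) for s in sequences])
    if name == "molecular_weight":
        return np.array([molecular_weight(s) for s in sequences])
    if name == "gravy":
        return np.array([gravy(s) for s in sequences])
    if name == "pi":
        return np.array([isoelectric_point(s) for s in sequences])
    if name == "net_charge":
        return np.array([net_charge(s, DEFAULT_PHYSCHEM.charge_pH) for s in sequences])
    base = name[: -len("_present")] if name.endswith("_present") else name
    if base in catalogue:
        pattern = catalogue.get(base)
        counts = np.array([float(len(scan(s, pattern))) for s in sequences])
        return (counts > 0).astype(float) if name.endswith("_present") else counts
    raise KeyError(f"effect references unknown feature {name!r}")


def _backfill_outcome(
    category: str, rng: np.random.Generator, threshold: float
) -> ExpressionOutcome:
    if category == "A":
        return ExpressionOutcome(
            expressed=True,
            soluble_yield=threshold + float(rng.exponential(0.4)),
            full_length=True,
        )
    if category == "C":
        return ExpressionOutcome(
            expressed=True,
            soluble_yield=float(rng.uniform(0.0, threshold)),
            full_length=True,
        )
    if rng.random() < 0.8:  # non-expressed vs truncated product
        return ExpressionOutcome(expressed=False, soluble_yield=0.0, full_length=True)
    return ExpressionOutcome(
        expressed=True,
        soluble_yield=float(rng.uniform(0.0, threshold)),
        full_length=False,
    )


def generate(
    cfg: SynthConfig, catalogue: MotifCatalogue | None = None
) -> SynthDataset:
    """Generate a full synthetic dataset with its ground-truth ledger."""
    if catalogue is None:
        catalogue = load_catalogue()
    root = np.random.SeedSequence(cfg.seed)
    record_seeds = root.spawn(cfg.n)
    cat_rng = np.random.default_rng(root.spawn(1)[0])
    outcome_rng = np.random.default_rng(root.spawn(1)[0])

    plant_instances = [
        (catalogue.get(p.pattern), realize_pattern(catalogue.get(p.pattern)))
        for p in cfg.motif_plants
    ]
    sequences: list[AminoAcidSequence] = []
    for i in range(cfg.n):
        rng = np.random.default_rng(record_seeds[i])
        chosen = [
            plant_instances[j]
            for j, plant in enumerate(cfg.motif_plants)
            if rng.random() < plant.fraction
        ]
        sequences.append(sample_sequence(cfg, rng, index=i, plants=chosen))

    order = ["A", "C", "N"]
    logits = np.tile(
        np.log(np.array([cfg.base_rates[c] for c in order])), (cfg.n, 1)
    )
    for effect in cfg.effects:
        values = _feature_values(effect.feature, sequences, catalogue)
        sd = values.std()
        z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
        logits[:, order.index(effect.category)] += effect.beta * z
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    draws = cat_rng.random(cfg.n)
    cum = np.cumsum(probs, axis=1)
    cat_idx = (draws[:, None] > cum).sum(axis=1)
    categories = [order[i] for i in cat_idx]

    categorization = CategorizationConfig(yield_threshold=cfg.yield_threshold)
    records = []
    for seq, category in zip(sequences, categories):
        outcome = _backfill_outcome(category, outcome_rng, cfg.yield_threshold)
        assigned = assign_category(outcome, categorization)
        assert assigned.value == category
        records.append(
            ExpressionRecord(sequence=seq, outcome=outcome, category=assigned)
        )
    truth = pd.DataFrame(
        [
            {
                "feature": e.feature,
                "category": e.category,
                "beta": e.beta,
                "expected_sign": e.expected_sign,
            }
            for e in cfg.effects
        ]
        + [
            {
                "feature": f"{p.pattern}_planted",
                "category": "",
                "beta": p.fraction,
                "expected_sign": "",
            }
            for p in cfg.motif_plants
        ],
        columns=["feature", "category", "beta", "expected_sign"],
    )
    return SynthDataset(
        dataset=ExpressionDataset(records=records), truth=truth, config=cfg
    )
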