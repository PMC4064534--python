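"""Model/results surface tying features to expression categories.

:class:`ExpressionAssociationModel` is built from an
:class:`~solscore.dataset.ExpressionDataset` plus a feature table (computed
by :func:`featurize` when not supplied); ``fit()`` runs the per-category
association analysis for every feature — Fisher exact tests for yes/no
features, binned percentage-curve correlations for discrete and continuous
ones — and returns an :class:`ExpressionAssociationResults` carrying the
estimates, p-values, sign calls and profiles, with a ``summary()`` table
mirroring the Soluble/Insoluble/Undetectable sign-matrix layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .association import (
    CATEGORIES,
    BinaryAssociation,
    CategoryProfile,
    CorrelationResult,
)
from .dataset import CategorizationConfig, ExpressionDataset, read_dataset
from .motifs import MotifCatalogue, count_sites, load_catalogue
from .physchem import DEFAULT_PHYSCHEM, PhyschemConfig, physchem_features
from .structural import (
    DEFAULT_STRUCTURAL,
    ExternalFeatureTable,
    StructuralConfig,
    load_external_features,
    structural_features,
)

__all__ = [
    "AssociationConfig",
    "featurize",
    "ExpressionAssociationModel",
    "ExpressionAssociationResults",
]

CATEGORY_LABELS = {"A": "Soluble", "C": "Insoluble", "N": "Undetectable"}


@dataclass(frozen=True)
class AssociationConfig:
    """Correlation-analysis parameters.

    alpha is the per-feature significance level (no multiple-testing
    correction by default; Benjamini–Hochberg adjusted p-values are
    reported alongside and drive significance when ``use_bh`` is set).
    Smoothing is presentation-only unless ``correlate_smoothed``.
    """

    alpha: float = 0.05
    n_bins: int = 10
    min_bin: int = 20
    smooth_window: int = 3
    correlate_smoothed: bool = False
    use_bh: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


DEFAULT_ASSOCIATION = AssociationConfig()


def featurize(
    dataset: ExpressionDataset,
    catalogue: MotifCatalogue | None = None,
    physchem_cfg: PhyschemConfig = DEFAULT_PHYSCHEM,
    structural_cfg: StructuralConfig = DEFAULT_STRUCTURAL,
    external: ExternalFeatureTable | None = None,
    include: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Compute the default feature table for a dataset.

    Returns a DataFrame indexed by record id together with a mapping
    feature name -> kind (binary | discrete | continuous).  Transparent
    stand-in features carry a ``baseline:`` prefix so they are never
    mistaken for external-predictor output.  *include* restricts the
    built-in selection (motif features are selected by pattern name).
    """
    if catalogue is None:
        catalogue = load_catalogue()
    ids = dataset.ids
    columns: dict[str, list[float]] = {}
    kinds: dict[str, str] = {}

    phys = [physchem_features(rec.sequence, physchem_cfg) for rec in dataset]
    struct = [structural_features(rec.sequence, structural_cfg) for rec in dataset]

    def add(name: str, kind: str, values: list[float]) -> None:
        columns[name] = values
        kinds[name] = kind

    add("length", "continuous", [float(p.length) for p in phys])
    add("molecular_weight", "continuous", [p.molecular_weight for p in phys])
    add("pi", "continuous", [p.pI for p in phys])
    add("gravy", "continuous", [p.gravy for p in phys])
    add("net_charge", "continuous", [p.net_charge for p in phys])
    add("positive_density", "continuous", [p.positive_density for p in phys])
    add("negative_density", "continuous", [p.negative_density for p in phys])
    add("n_pest", "discrete", [float(s.n_pest) for s in struct])
    add("max_pest_score", "continuous", [s.max_pest_score for s in struct])
    add("cc_fraction", "continuous", [s.cc_fraction for s in struct])
    add("baseline:n_tm", "discrete", [float(s.n_tm) for s in struct])
    add(
        "baseline:disorder_fraction",
        "continuous",
        [s.disorder_fraction for s in struct],
    )

    motif_table = count_sites(dataset, catalogue)
    for pattern in catalogue:
        kind = catalogue.kinds.get(pattern.name, "discrete")
        if kind == "binary":
            add(
                f"{pattern.name}_present",
                "binary",
                motif_table[f"{pattern.name}_present"].astype(float).tolist(),
            )
        else:
            add(
                f"{pattern.name}_count",
                "discrete",
                motif_table[f"{pattern.name}_count"].astype(float).tolist(),
            )

    if include is not None:
        include_set = set(include)
        unknown = include_set - set(columns)
        if unknown:
            raise KeyError(f"unknown features requested: {sorted(unknown)}")
        columns = {k: v for k, v in columns.items() if k in include_set}
        kinds = {k: v for k, v in kinds.items() if k in include_set}

    frame = pd.DataFrame(columns, index=pd.Index(ids, name="id"))

    if external is not None:
        for name, (kind, values) in external.features.items():
            frame[name] = [values.get(i, math.nan) for i in ids]
            kinds[name] = kind
    if frame.shape[1] == 0:
        raise ValueError("no features selected")
    return frame, kinds


@dataclass
class ExpressionAssociationModel:
    """Association of sequence features with A/C/N expression categories.

    Build from a dataset (features computed on demand) or pass a
    pre-computed feature table with its kind map.  ``fit()`` returns an
    :class:`ExpressionAssociationResults`.
    """

    dataset: ExpressionDataset
    features: Optional[pd.DataFrame] = None
    kinds: Optional[Mapping[str, str]] = None
    catalogue: Optional[MotifCatalogue] = None
    config: AssociationConfig = field(default_factory=AssociationConfig)
    external: Optional[ExternalFeatureTable] = None

    def __post_init__(self) -> None:
        if self.catalogue is None:
            self.catalogue = load_catalogue()
        if self.features is None:
            self.features, kinds = featurize(
                self.dataset, self.catalogue, external=self.external
            )
            self.kinds = kinds
        elif self.kinds is None:
            raise ValueError("a feature table requires its kind map")
        missing = set(self.features.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"features without a declared kind: {sorted(missing)}")
        if self.features.shape[1] == 0:
            raise ValueError("no features selected")

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        outcomes_path: str | Path,
        categorization: CategorizationConfig | None = None,
        catalogue_path: str | Path | None = None,
        external_path: str | Path | None = None,
        config: AssociationConfig | None = None,
        drop_invalid: bool = False,
    ) -> "ExpressionAssociationModel":
        dataset = read_dataset(
            fasta_path,
            outcomes_path,
            categorization or CategorizationConfig(),
            drop_invalid=drop_invalid,
        )
        catalogue = load_catalogue(catalogue_path)
        external = (
            load_external_features(external_path, dataset)
            if external_path is not None
            else None
        )
        return cls(
            dataset=dataset,
            catalogue=catalogue,
            config=config or AssociationConfig(),
            external=external,
        )

    def fit(self) -> "ExpressionAssociationResults":
        cfg = self.config
        cats = np.asarray(self.dataset.categories())
        rows: list[dict] = []
        profiles: dict[str, CategoryProfile] = {}
        smoothed: dict[str, CategoryProfile] = {}
        binaries: dict[str, dict[str, BinaryAssociation]] = {}
        correlations: dict[str, dict[str, CorrelationResult]] = {}

        for name in self.features.columns:
            kind = self.kinds[name]
            values = self.features[name].to_numpy(dtype=float)
            if kind == "binary":
                keep = ~np.isnan(values)
                results = assoc.binary_association(
                    cats[keep], values[keep].astype(bool), alpha=cfg.alpha
                )
                binaries[name] = results
                signs = assoc.sign_from_binary(results)
                for cat in CATEGORIES:
                    res = results[cat]
                    rows.append(
                        {
                            "feature": name,
                            "kind": kind,
                            "category": cat,
                            "n": res.n,
                            "estimate": res.odds_ratio,
                            "p": res.p,
                            "sign": signs[cat],
                            "significant": res.significant,
                        }
                    )
            else:
                profile = assoc.profile_feature(
                    cats,
                    values,
                    kind,
                    feature=name,
                    n_bins=cfg.n_bins,
                    min_bin=cfg.min_bin,
                )
                profiles[name] = profile
                smooth = assoc.smooth_profile(profile, cfg.smooth_window)
                smoothed[name] = smooth
                target = smooth if cfg.correlate_smoothed else profile
                results = assoc.correlate_profile(target, alpha=cfg.alpha)
                correlations[name] = results
                signs = assoc.sign_from_profile(target, results, alpha=cfg.alpha)
                for cat in CATEGORIES:
                    res = results[cat]
                    rows.append(
                        {
                            "feature": name,
                            "kind": kind,
                            "category": cat,
                            "n": res.n,
                            "estimate": res.r,
                            "p": res.p_one_tailed,
                            "sign": signs[cat],
                            "significant": res.significant,
                        }
                    )

        frame = pd.DataFrame(rows)
        frame["p_bh"] = _bh_adjust(frame["p"].to_numpy())
        if cfg.use_bh:
            significant = frame["p_bh"] < cfg.alpha
            frame["significant"] = significant.where(~frame["p"].isna(), False)
            frame.loc[
                frame["sign"].isin(["+", "-"]) & ~frame["significant"], "sign"
            ] = "ND"
        return ExpressionAssociationResults(
            model=self,
            frame=frame,
            profiles=profiles,
            smoothed_profiles=smoothed,
            binary_results=binaries,
            correlation_results=correlations,
        )


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    from scipy.stats import false_discovery_control

    adjusted = np.full(pvalues.shape, np.nan)
    mask = ~np.isnan(pvalues)
    if mask.any():
        adjusted[mask] = false_discovery_control(pvalues[mask], method="bh")
    return adjusted


@dataclass
class ExpressionAssociationResults:
    """Fitted per-feature, per-category association results.

    ``frame`` is the tidy results table (feature, kind, category, n,
    estimate, p, p_bh, sign, significant) where the estimate is an odds
    ratio for binary features and Pearson's r otherwise.
    """

    model: ExpressionAssociationModel
    frame: pd.DataFrame
    profiles: dict[str, CategoryProfile]
    smoothed_profiles: dict[str, CategoryProfile]
    binary_results: dict[str, dict[str, BinaryAssociation]]
    correlation_results: dict[str, dict[str, CorrelationResult]]

    @property
    def sign_matrix(self) -> pd.DataFrame:
        """Feature x {Soluble, Insoluble, Undetectable} sign table."""
        pivot = self.frame.pivot(index="feature", columns="category", values="sign")
        pivot = pivot.reindex(self.frame["feature"].unique())
        pivot = pivot[list(CATEGORIES)]
        pivot.columns = [CATEGORY_LABELS[c] for c in pivot.columns]
        pivot.columns.name = None
        return pivot

    def summary(self) -> str:
        """Human-readable sign-matrix summary (Unicode ± rendering)."""
        ds = self.model.dataset
        counts = ds.category_counts()
        n = len(ds)
        header = "Cell-free expression association summary"
        lines = [
            header,
            "=" * 74,
            (
                f"Records: {n}    "
                f"A (soluble): {100 * counts['A'] / n:.1f}%   "
                f"C (insoluble): {100 * counts['C'] / n:.1f}%   "
                f"N (non-expressed): {100 * counts['N'] / n:.1f}%"
            ),
            f"alpha: {self.model.config.alpha:g} (one-tailed for r; Fisher exact for yes/no)",
            "-" * 74,
            f"{'feature':<34}{'kind':<12}{'Soluble':>9}{'Insoluble':>10}{'Undetectable':>13}",
            "-" * 74,
        ]
        pretty = {"+/-": "±"}
        matrix = self.sign_matrix
        kinds = self.frame.drop_duplicates("feature").set_index("feature")["kind"]
        for feature, row in matrix.iterrows():
            lines.append(
                f"{feature:<34}{kinds[feature]:<12}"
                f"{pretty.get(row['Soluble'], row['Soluble']):>9}"
                f"{pretty.get(row['Insoluble'], row['Insoluble']):>10}"
                f"{pretty.get(row['Undetectable'], row['Undetectable']):>13}"
            )
        lines.append("=" * 74)
        return "\n".join(lines)

    def profile_frame(self, feature: str) -> pd.DataFrame:
        """Tidy per-bin profile (raw and smoothed percentages)."""
        profile = self.profiles[feature]
        smooth = self.smoothed_profiles[feature]
        rows = []
        for raw_bin, smooth_bin in zip(profile.bins, smooth.bins):
            row = {
                "bin": raw_bin.label,
                "value": raw_bin.representative,
                "count": raw_bin.count,
            }
            for cat in CATEGORIES:
                row[f"pct_{cat}"] = raw_bin.percentages[cat]
            for cat in CATEGORIES:
                row[f"pct_{cat}_smooth"] = smooth_bin.percentages[cat]
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_profile(self, feature: str, path: str | Path | None = None):
        """Percentage curves + bin distribution (or bars for binary)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if feature in self.binary_results:
            fig, ax = plt.subplots(figsize=(5, 4))
            results = self.binary_results[feature]
            width = 0.35
            xs = np.arange(3)
            with_f, without_f = [], []
            for cat in CATEGORIES:
                a, b, c, d = results[cat].table
                n_with, n_without = a + b, c + d
                with_f.append(100 * a / n_with if n_with else 0.0)
                without_f.append(100 * c / n_without if n_without else 0.0)
            ax.bar(xs - width / 2, with_f, width, label="feature present")
            ax.bar(xs + width / 2, without_f, width, label="feature absent")
            ax.set_xticks(xs, [CATEGORY_LABELS[c] for c in CATEGORIES])
            ax.set_ylabel("% of subset")
            ax.set_title(feature)
            ax.legend()
        else:
            profile = self.profiles[feature]
            smooth = self.smoothed_profiles[feature]
            fig, (ax, ax2) = plt.subplots(
                2, 1, figsize=(6, 6), sharex=True,
                gridspec_kw={"height_ratios": [2, 1]},
            )
            x = profile.representatives
            for cat in CATEGORIES:
                ax.plot(x, smooth.percentages(cat), marker="o",
                        label=CATEGORY_LABELS[cat])
            ax.set_ylabel("% of bin")
            ax.set_title(feature)
            ax.legend()
            ax2.bar(x, profile.counts, width=np.ptp(x) / (2 * len(x)) if len(x) > 1 else 0.5)
            ax2.set_ylabel("records")
            ax2.set_xlabel(feature)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
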