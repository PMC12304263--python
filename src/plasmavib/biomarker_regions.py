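"""Spectral biomarker selection: RF wavenumber ranking, binning, ANOVA.

For every train/test iteration a seeded Random Forest is fitted on the
pre-processed training spectra (original wavenumber features, not PCA
scores) and the ten wavenumbers with the highest mean-impurity-decrease
importance form that iteration's classifying panel. Panel members from all
iterations are histogrammed into fixed 12.6 cm⁻¹ bins anchored at the
truncation lower edge; a per-wavenumber one-way ANOVA (cancer vs control)
screens members at α = 0.05, and each occupied bin whose members survive the
screen is reported as a region of interest with its occurrence count and
p-value range. For fused datasets every region is attributed to its source
modality block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .classify_eval import SplitPlan
from .fuse import FusedDataset
from .spectral_io import SpectralDataset

__all__ = [
    "RankingConfig",
    "BiomarkerPanel",
    "RegionOfInterest",
    "rank_wavenumbers",
    "anova_pvalues",
    "bin_panels",
    "select_regions",
    "run_biomarker_study",
]


@dataclass
class RankingConfig:
    panel_size: int = 10
    bin_width: float = 12.6
    alpha: float = 0.05
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BiomarkerPanel:
    """Top-ranked classifying wavenumbers of one iteration."""

    iteration: int
    members: list[tuple[float, float]]  # (wavenumber, importance), score-desc
    #: parallel modality tags (None for single-modality data)
    modalities: list[str | None] = field(default_factory=list)

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([w for w, _ in self.members])


@dataclass
class RegionOfInterest:
    """A 12.6 cm⁻¹ bin of recurrent significant classifying wavenumbers."""

    center: float
    count: int
    members: list[float]
    p_min: float
    p_max: float
    p_mean: float
    modality: str | None = None


def rank_wavenumbers(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray,
    cfg: RankingConfig,
    iteration: int = 0,
    modalities: Sequence[str] | None = None,
) -> BiomarkerPanel:
    """Seeded RF importance ranking; top ``panel_size`` wavenumbers.

    Importance is the forest's mean impurity decrease per feature. Ties are
    broken toward the lower wavenumber so panels are deterministic.
    """
    X = np.asarray(X, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if cfg.panel_size > wavenumbers.size:
        raise ValueError("panel_size exceeds the number of wavenumber features")
    if len(set(np.asarray(y))) < 2:
        raise ValueError("need both classes to rank wavenumbers")

    rf = RandomForestClassifier(
        n_estimators=cfg.rf_trees, max_features="sqrt", random_state=cfg.seed
    )
    rf.fit(X, y)
    imp = rf.feature_importances_
    # sort by descending importance, then ascending wavenumber
    order = np.lexsort((wavenumbers, -imp))[: cfg.panel_size]
    members = [(float(wavenumbers[i]), float(imp[i])) for i in order]
    mods = [modalities[i] if modalities is not None else None for i in order]
    return BiomarkerPanel(iteration=iteration, members=members, modalities=mods)


def anova_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray,
    subset: Sequence[float] | None = None,
) -> dict[float, float]:
    """One-way ANOVA F-test p-value per wavenumber across the class groups.

    Degenerate columns (zero variance in every group) get p = 1 when the
    group means agree and p = 0 otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    classes = sorted(set(y))
    if any(np.sum(y == c) < 2 for c in classes):
        raise ValueError("need >= 2 samples per class for ANOVA")

    if subset is None:
        cols = np.arange(wavenumbers.size)
    else:
        cols = np.array(
            [int(np.argmin(np.abs(wavenumbers - w))) for w in subset], dtype=int
        )
    out: dict[float, float] = {}
    for j in cols:
        groups = [X[y == c, j] for c in classes]
        if all(np.ptp(g) == 0 for g in groups):
            means = [g[0] for g in groups]
            out[float(wavenumbers[j])] = 1.0 if np.ptp(means) == 0 else 0.0
            continue
        _, p = stats.f_oneway(*groups)
        out[float(wavenumbers[j])] = float(p) if np.isfinite(p) else 1.0
    return out


def bin_panels(
    panels: Sequence[BiomarkerPanel],
    cfg: RankingConfig,
    anchor: float,
) -> dict[float, list[float]]:
    """Histogram panel wavenumbers into fixed ``bin_width`` bins.

    Bins are anchored at ``anchor`` (the truncation lower edge); wavenumber w
    falls in bin ⌊(w − anchor)/width⌋ and the bin is keyed by its arithmetic
    centre. Returns {bin centre: list of member wavenumbers (with repeats)}.
    """
    if not panels:
        raise ValueError("need at least one panel")
    bins: dict[float, list[float]] = {}
    for panel in panels:
        for w, _ in panel.members:
            i = int(np.floor((w - anchor) / cfg.bin_width))
            center = anchor + (i + 0.5) * cfg.bin_width
            bins.setdefault(round(center, 6), []).append(w)
    return bins


def select_regions(
    bins: Mapping[float, list[float]],
    pvals: Mapping[float, float],
    cfg: RankingConfig,
    modality_of: Mapping[float, str] | None = None,
) -> list[RegionOfInterest]:
    """Regions of interest: occupied bins restricted to significant members.

    Members without p < alpha are dropped; bins left empty are not reported.
    ``modality_of`` (wavenumber -> modality) attributes fused-analysis regions
    to their source instrument block.
    """
    regions = []
    for center in sorted(bins):
        members = [w for w in bins[center] if pvals.get(w, 1.0) < cfg.alpha]
        if not members:
            continue
        ps = [pvals[w] for w in members]
        mods = (
            {modality_of[w] for w in members} if modality_of is not None else {None}
        )
        modality = mods.pop() if len(mods) == 1 else "mixed"
        regions.append(
            RegionOfInterest(
                center=float(center),
                count=len(members),
                members=sorted(set(members)),
                p_min=float(min(ps)),
                p_max=float(max(ps)),
                p_mean=float(np.mean(ps)),
                modality=modality,
            )
        )
    return regions


def run_biomarker_study(
    ds: SpectralDataset | FusedDataset,
    plan: SplitPlan,
    cfg: RankingConfig,
) -> tuple[list[BiomarkerPanel], list[RegionOfInterest]]:
    """Per-iteration RF ranking on training rows, then binning + ANOVA.

    The ranking sees only each iteration's training spectra (the same
    patient partitions as the supervised study); the ANOVA screen is
    computed once on the full pre-processed dataset, cancer vs control.
    """
    if isinstance(ds, FusedDataset):
        wn = ds.wavenumbers
        modalities: Sequence[str] | None = ds.modalities
        # bins anchored per modality block at its own truncation lower edge
        block_anchor = {
            m: float(wn[ds.modalities == m].min()) for m in ("ATR-FTIR", "Raman")
        }
    else:
        wn = ds.grid
        modalities = None
        block_anchor = None

    seed_base = np.random.SeedSequence((cfg.seed, 303))
    seeds = [int(s % 2**31) for s in seed_base.generate_state(len(plan.iterations))]

    panels = []
    for it, (train_pids, _) in enumerate(plan):
        rows = ds.rows_for_patients(train_pids)
        it_cfg = RankingConfig(
            panel_size=cfg.panel_size, bin_width=cfg.bin_width,
            alpha=cfg.alpha, rf_trees=cfg.rf_trees, seed=seeds[it],
        )
        panels.append(
            rank_wavenumbers(
                ds.matrix[rows], ds.class_labels[rows], wn, it_cfg,
                iteration=it, modalities=modalities,
            )
        )

    selected = sorted({w for p in panels for w, _ in p.members})
    pvals = anova_pvalues(ds.matrix, ds.class_labels, wn, subset=selected)

    if isinstance(ds, FusedDataset):
        mod_of = {}
        for p in panels:
            for (w, _), m in zip(p.members, p.modalities):
                mod_of[w] = m
        regions: list[RegionOfInterest] = []
        for m in ("ATR-FTIR", "Raman"):
            sub = [
                BiomarkerPanel(
                    iteration=p.iteration,
                    members=[
                        (w, s) for (w, s), pm in zip(p.members, p.modalities) if pm == m
                    ],
                )
                for p in panels
            ]
            sub = [p for p in sub if p.members]
            if not sub:
                continue
            bins = bin_panels(sub, cfg, anchor=block_anchor[m])
            regions.extend(select_regions(bins, pvals, cfg, modality_of=mod_of))
        regions.sort(key=lambda r: (r.modality or "", r.center))
    else:
        bins = bin_panels(panels, cfg, anchor=float(wn.min()))
        regions = select_regions(bins, pvals, cfg)
    return panels, regions
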