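"""Synthetic blood-plasma spectrum generator.

Emulates the statistical structure of a dual-modality (ATR-FTIR + Raman)
plasma study of endometrial cancer: a 54-patient cohort (22 cancer, 18 PCOS,
14 healthy), two acquisitions per wet sample per modality, twenty site spectra
per dry ATR-FTIR sample with coffee-ring heterogeneity, a broad water
absorption band in wet ATR-FTIR, dehydration drift across wet acquisitions,
baseline drift and additive noise.

Each patient carries a latent disease score d ∈ [0, 1]: cancer patients d = 1,
healthy d = 0, PCOS patients draw d from a mixing distribution (default
Uniform(0, 1)), placing their spectra between the healthy and cancer groups —
the mechanism behind the unsupervised-overlap behaviour of real PCOS plasma.
Band amplitudes respond linearly to d; patient-level biological variability
perturbs every band amplitude so that classes overlap and patient-level
classification is imperfect, as in real cohorts.

Gaussian line shapes are used throughout: the downstream methods are
shape-agnostic, so Voigt profiles would add parameters without adding
testable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .spectral_io import (
    GROUPS,
    SampleRecord,
    SpectralDataset,
    Spectrum,
)

__all__ = [
    "SyntheticConfig",
    "BandTemplate",
    "CohortMember",
    "FTIR_BANDS",
    "RAMAN_BANDS",
    "build_cohort",
    "synth_spectrum",
    "synth_study",
    "template_spectrum",
]


@dataclass(frozen=True)
class BandTemplate:
    """One Gaussian band: centre/width in cm⁻¹, amplitudes in intensity a.u.

    ``class_effect`` is the signed amplitude shift per unit latent disease
    score; its sign encodes whether the band rises or falls with disease.
    """

    center: float
    width: float  # Gaussian SD, cm⁻¹
    base_amplitude: float
    class_effect: float
    modality: str

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")


# ATR-FTIR bio-fingerprint bands. Centres follow the canonical plasma
# assignments (lipid ester C=O 1733; Amide I 1635–1695; Amide II 1545;
# CH₂/CH₃ deformations 1400–1456; Amide III 1240–1340; PO₂⁻ 1080).
# The 1733 cm⁻¹ lipid band carries the strongest planted class effect.
FTIR_BANDS: tuple[BandTemplate, ...] = tuple(
    BandTemplate(c, w, a, e, "ATR-FTIR")
    for c, w, a, e in [
        (1733.0, 8.0, 0.10, +0.055),
        (1695.0, 12.0, 0.25, 0.0),
        (1658.0, 18.0, 1.00, -0.060),
        (1635.0, 16.0, 0.55, +0.030),
        (1545.0, 16.0, 0.60, +0.040),
        (1515.0, 8.0, 0.12, 0.0),
        (1500.0, 10.0, 0.10, +0.020),
        (1450.0, 10.0, 0.28, 0.0),
        (1400.0, 10.0, 0.30, -0.030),
        (1340.0, 10.0, 0.15, +0.020),
        (1240.0, 14.0, 0.30, +0.030),
        (1170.0, 10.0, 0.12, +0.020),
        (1080.0, 12.0, 0.25, +0.030),
    ]
)

# Raman bands: Amide I 1655, carotenoids 1525, CH₂ deformation 1450 (the
# normalisation anchor, deliberately class-free), Amide III 1250–1317,
# nucleic-acid PO₂ 807/1071/1090, phenylalanine 1004.
RAMAN_BANDS: tuple[BandTemplate, ...] = tuple(
    BandTemplate(c, w, a, e, "Raman")
    for c, w, a, e in [
        (1655.0, 14.0, 0.70, -0.040),
        (1617.0, 8.0, 0.20, 0.0),
        (1525.0, 8.0, 0.15, -0.050),
        (1450.0, 10.0, 0.80, 0.0),
        (1317.0, 9.0, 0.25, +0.030),
        (1279.0, 9.0, 0.20, +0.030),
        (1250.0, 10.0, 0.30, +0.020),
        (1128.0, 8.0, 0.20, +0.020),
        (1090.0, 9.0, 0.18, +0.030),
        (1071.0, 8.0, 0.15, +0.020),
        (1004.0, 5.0, 0.60, -0.020),
        (940.0, 10.0, 0.15, 0.0),
        (855.0, 9.0, 0.20, 0.0),
        (807.0, 8.0, 0.10, +0.025),
    ]
)

#: the three acquisition settings the study analyses
SUPPORTED_SETTINGS = (("ATR-FTIR", "wet"), ("ATR-FTIR", "dry"), ("Raman", "wet"))


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Defaults are the study conditions: cohort sizes 22/18/14, two wet
    acquisitions per modality, twenty dry ATR-FTIR site spectra. Noise and
    effect magnitudes are calibrated once so the downstream pipeline operates
    in the realistic ~0.75–0.90 patient-level accuracy regime rather than at
    a trivially separable ceiling.
    """

    n_cancer: int = 22
    n_pcos: int = 18
    n_healthy: int = 14
    replicates_wet: int = 2
    replicates_dry: int = 20
    effect_scale: float = 1.0
    #: PCOS latent-score distribution: float = point mass, (lo, hi) = uniform,
    #: or a callable (rng, n) -> array with support in [0, 1]
    pcos_mixing: float | tuple[float, float] | Callable = (0.0, 1.0)
    #: relative per-patient, per-band amplitude SD (biological heterogeneity)
    biological_sd: float = 0.055
    #: relative per-acquisition, per-band amplitude SD (contact/focus drift);
    #: replicate averaging suppresses it, patient-level noise it does not
    acquisition_sd: float = 0.07
    noise_sd: float = 0.01
    baseline_amplitude: float = 0.08
    water_band_amplitude: float = 1.2
    water_band_center: float = 1637.0
    water_band_width: float = 60.0
    #: relative per-acquisition jitter of the water band amplitude
    water_jitter_sd: float = 0.30
    coffee_ring_sd: float = 0.15
    dehydration_drift: float = 0.02
    raw_grid_ftir: tuple[float, float, float] = (800.0, 2000.0, 2.0)
    raw_grid_raman: tuple[float, float, float] = (600.0, 2000.0, 2.0)
    #: optional band-list overrides (None = the module's default templates)
    bands_ftir: tuple[BandTemplate, ...] | None = None
    bands_raman: tuple[BandTemplate, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer, self.n_pcos, self.n_healthy) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.n_cancer + self.n_pcos + self.n_healthy == 0:
            raise ValueError("cohort is empty: all three counts are zero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lo, hi, step in (self.raw_grid_ftir, self.raw_grid_raman):
            if not (lo < hi and step > 0):
                raise ValueError("raw grids must be ascending with step > 0")

    def grid(self, modality: str) -> np.ndarray:
        lo, hi, step = (
            self.raw_grid_ftir if modality == "ATR-FTIR" else self.raw_grid_raman
        )
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def bands(self, modality: str) -> tuple[BandTemplate, ...]:
        if modality == "ATR-FTIR":
            return self.bands_ftir if self.bands_ftir is not None else FTIR_BANDS
        return self.bands_raman if self.bands_raman is not None else RAMAN_BANDS


@dataclass(frozen=True)
class CohortMember:
    """A patient with latent disease score and frozen biological perturbations."""

    record: SampleRecord
    disease_score: float
    #: per-band relative amplitude perturbation, keyed by modality
    band_perturbation: dict[str, np.ndarray]


def _draw_pcos_scores(mixing, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(mixing):
        d = np.asarray(mixing(rng, n), dtype=float)
    elif isinstance(mixing, tuple):
        lo, hi = mixing
        d = rng.uniform(lo, hi, n)
    else:
        d = np.full(n, float(mixing))
    if d.size and (d.min() < 0 or d.max() > 1):
        raise ValueError("PCOS latent scores must lie in [0, 1]")
    return d


_BMI_CATS = ("normal", "overweight", "obese", "severely_obese")
# category frequencies loosely mirroring a surgical EC cohort vs controls
_BMI_P = {
    "cancer": (1 / 22, 8 / 22, 11 / 22, 2 / 22),
    "control": (1 / 32, 17 / 32, 14 / 32, 0.0),
}
_HYPERTENSION_P = {"cancer": 16 / 22, "control": 13 / 32}
_AGE = {"cancer": (63.0, 10.0), "pcos": (32.0, 6.0), "healthy": (48.0, 15.0)}


def build_cohort(config: SyntheticConfig) -> list[CohortMember]:
    """Create the patient cohort with latent scores and demographics.

    Cancer patients get d = 1, healthy d = 0 and PCOS patients draw d from
    ``config.pcos_mixing``, so PCOS plasma sits between the two poles.
    Demographics (age, BMI category, blood-pressure status) are sampled to
    loosely mirror a typical surgical cohort (cancer mean age 63 SD 10,
    controls mean 39 SD 13).
    """
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = config.n_cancer + config.n_pcos + config.n_healthy
    pert_rngs = [np.random.default_rng(s) for s in ss.spawn(n_total + 1)[1:]]

    plan: list[tuple[str, str, float]] = []
    for i in range(config.n_cancer):
        plan.append((f"EC{i + 1:02d}", "cancer", 1.0))
    pcos_scores = _draw_pcos_scores(config.pcos_mixing, cohort_rng, config.n_pcos)
    for i in range(config.n_pcos):
        plan.append((f"PC{i + 1:02d}", "pcos", float(pcos_scores[i])))
    for i in range(config.n_healthy):
        plan.append((f"HC{i + 1:02d}", "healthy", 0.0))

    members: list[CohortMember] = []
    for (pid, group, d), prng in zip(plan, pert_rngs):
        cls = "cancer" if group == "cancer" else "control"
        mu, sd = _AGE[group]
        age = float(np.clip(cohort_rng.normal(mu, sd), 18.0, 95.0))
        bmi = cohort_rng.choice(_BMI_CATS, p=np.array(_BMI_P[cls]) / sum(_BMI_P[cls]))
        bp = (
            "hypertension"
            if cohort_rng.random() < _HYPERTENSION_P[cls]
            else "normotension"
        )
        pert = {
            m: prng.normal(0.0, config.biological_sd, len(config.bands(m)))
            for m in ("ATR-FTIR", "Raman")
        }
        members.append(
            CohortMember(
                record=SampleRecord(
                    patient_id=pid,
                    group=group,
                    age_years=round(age, 1),
                    bmi_category=str(bmi),
                    bp_status=bp,
                ),
                disease_score=d,
                band_perturbation=pert,
            )
        )
    return members


def _gaussian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def template_spectrum(
    disease_score: float, modality: str, hydration: str, config: SyntheticConfig
) -> np.ndarray:
    """Noiseless expected spectrum for a latent score (no baseline, no water).

    Closed-form: Σ_bands G(center, width) × (base + d × effect × scale).
    Useful as the analytic reference for class-difference checks.
    """
    grid = config.grid(modality)
    y = np.zeros_like(grid)
    for b in config.bands(modality):
        amp = b.base_amplitude + disease_score * b.class_effect * config.effect_scale
        y += amp * _gaussian(grid, b.center, b.width)
    return y


def synth_spectrum(
    member: CohortMember,
    modality: str,
    hydration: str,
    replicate: int,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Generate one acquisition for a cohort member.

    Intensity model: per-band Gaussian with amplitude
    ``(base × (1 + biological perturbation) + d × class_effect × effect_scale)``
    plus a random quadratic baseline, a broad ~1637 cm⁻¹ water band (wet
    ATR-FTIR only, decaying with replicate index through dehydration), a
    multiplicative site factor for dry replicates (coffee-ring heterogeneity)
    and additive Gaussian noise; the result is clipped to be non-negative.
    """
    if (modality, hydration) not in SUPPORTED_SETTINGS:
        raise ValueError(f"unsupported modality/hydration pair ({modality}, {hydration})")
    if rng is None:
        rng = np.random.default_rng(0)

    grid = config.grid(modality)
    bands = config.bands(modality)
    pert = member.band_perturbation[modality]
    d = member.disease_score

    acq_eps = (
        rng.normal(0.0, config.acquisition_sd, len(bands))
        if config.acquisition_sd > 0
        else np.zeros(len(bands))
    )
    y = np.zeros_like(grid)
    for b, eps, aeps in zip(bands, pert, acq_eps):
        amp = b.base_amplitude * (1.0 + eps) + d * b.class_effect * config.effect_scale
        y += amp * (1.0 + aeps) * _gaussian(grid, b.center, b.width)

    if modality == "ATR-FTIR" and hydration == "wet":
        jitter = 1.0 + config.water_jitter_sd * rng.standard_normal()
        w_amp = (
            config.water_band_amplitude
            * max(jitter, 0.0)
            * (1.0 - config.dehydration_drift * replicate)
        )
        y += w_amp * _gaussian(grid, config.water_band_center, config.water_band_width)

    # slowly varying instrumental baseline, random per acquisition
    x = (grid - grid.mean()) / (grid[-1] - grid[0])
    c0, c1, c2 = rng.normal(0.0, config.baseline_amplitude, 3)
    y += np.abs(c0) + 0.05 + c1 * x + c2 * x**2

    if hydration == "dry":
        y *= max(rng.normal(1.0, config.coffee_ring_sd), 0.05)

    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, y.size)

    y = np.clip(y, 0.0, None)
    return Spectrum(
        grid=grid,
        intensities=y,
        modality=modality,
        hydration=hydration,
        sample_ref=member.record.patient_id,
    )


def _acquisition_record(member: CohortMember, modality, hydration, replicate):
    r = member.record
    return SampleRecord(
        patient_id=r.patient_id,
        group=r.group,
        modality=modality,
        hydration=hydration,
        replicate=replicate,
        age_years=r.age_years,
        bmi_category=r.bmi_category,
        bp_status=r.bp_status,
    )


def synth_study(
    config: SyntheticConfig, cohort: list[CohortMember] | None = None
) -> dict[str, SpectralDataset]:
    """Generate the three study datasets on fixed keys.

    Returns ``{"ftir_wet": ..., "ftir_dry": ..., "raman_wet": ...}`` with
    ``replicates_wet`` rows per patient for each wet modality and
    ``replicates_dry`` rows per patient for dry ATR-FTIR. Fully determined
    by ``config.seed``.
    """
    if cohort is None:
        cohort = build_cohort(config)

    settings = [
        ("ftir_wet", "ATR-FTIR", "wet", config.replicates_wet),
        ("ftir_dry", "ATR-FTIR", "dry", config.replicates_dry),
        ("raman_wet", "Raman", "wet", config.replicates_wet),
    ]
    # one child seed per acquisition, in a fixed (setting, patient, replicate) order
    ss = np.random.SeedSequence((config.seed, 1))
    n_acq = sum(len(cohort) * n_rep for _, _, _, n_rep in settings)
    acq_seeds = iter(ss.spawn(n_acq))

    out: dict[str, SpectralDataset] = {}
    for key, modality, hydration, n_rep in settings:
        rows, records = [], []
        for member in cohort:
            for rep in range(1, n_rep + 1):
                rng = np.random.default_rng(next(acq_seeds))
                spec = synth_spectrum(member, modality, hydration, rep, config, rng)
                rows.append(spec.intensities)
                records.append(_acquisition_record(member, modality, hydration, rep))
        out[key] = SpectralDataset(
            grid=config.grid(modality), matrix=np.array(rows), samples=records
        )
    return out
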