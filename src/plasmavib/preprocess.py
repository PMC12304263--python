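"""Spectral pre-processing operator stack.

Each modality gets the pipeline used in clinical biospectroscopy practice:

* ATR-FTIR: truncation to the 1800–900 cm⁻¹ bio-fingerprint region →
  optional atmospheric-gas correction → asymmetric-least-squares (AsLS)
  baseline correction (λ = 1000, p = 0.05, ≤ 10 iterations) → vector
  normalisation.
* Raman: truncation to 1800–750 cm⁻¹ → rubber-band (lower convex hull)
  baseline correction → CH₂-band area normalisation (integration window
  1378.1–1490.1 cm⁻¹) for single-modality analysis, or vector normalisation
  when the spectra are destined for cross-modality concatenation.

The AsLS baseline is the Eilers–Boelens scheme: minimise
Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σ (Δ²z)² with asymmetric weights wᵢ = p where yᵢ > zᵢ
and 1 − p elsewhere, iterating from w ≡ 1. The pentadiagonal normal
equations are solved with a banded Cholesky factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import solveh_banded
from scipy.optimize import nnls

from .spectral_io import IntegrityError, SampleRecord, SpectralDataset, Spectrum

__all__ = [
    "PreprocessParams",
    "truncate",
    "truncate_grid",
    "atmospheric_correction",
    "asls_baseline",
    "rubberband_baseline",
    "lower_hull_indices",
    "vector_normalize",
    "band_integral",
    "band_area_normalize",
    "resample_to_grid",
    "average_replicates",
    "preprocess_modality",
]


@dataclass
class PreprocessParams:
    """Pre-processing constants; defaults are the analysis settings."""

    ftir_range: tuple[float, float] = (900.0, 1800.0)
    raman_range: tuple[float, float] = (750.0, 1800.0)
    asls_lambda: float = 1000.0
    asls_p: float = 0.05
    asls_max_iter: int = 10
    raman_band: tuple[float, float] = (1378.1, 1490.1)
    raman_band_target: float = 1.0
    #: optional (vapor, co2) reference Spectrum pair for gas correction
    atmospheric_refs: tuple[Spectrum, Spectrum] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.ftir_range, self.raman_range, self.raman_band):
            if not lo < hi:
                raise ValueError("ranges must be ascending")
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be > 0")
        if not 0 < self.asls_p < 1:
            raise ValueError("asls_p must be in (0, 1)")
        if self.asls_max_iter < 1:
            raise ValueError("asls_max_iter must be >= 1")


# ---------------------------------------------------------------------------
# truncation / resampling


def truncate_grid(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of grid points inside the closed interval [lo, hi]."""
    if not lo < hi:
        raise ValueError("truncation range must be ascending")
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"truncation to [{lo}, {hi}] leaves {int(mask.sum())} point(s)"
        )
    return mask


def truncate(s: Spectrum, rng: tuple[float, float]) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval ``rng``."""
    mask = truncate_grid(s.grid, *rng)
    return Spectrum(
        grid=s.grid[mask],
        intensities=s.intensities[mask],
        modality=s.modality,
        hydration=s.hydration,
        sample_ref=s.sample_ref,
    )


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; exact at coincident points."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.grid[0] or grid[-1] > s.grid[-1]:
        raise ValueError("target grid extends beyond the source span (extrapolation)")
    y = np.interp(grid, s.grid, s.intensities)
    return Spectrum(
        grid=grid,
        intensities=y,
        modality=s.modality,
        hydration=s.hydration,
        sample_ref=s.sample_ref,
    )


# ---------------------------------------------------------------------------
# atmospheric-gas correction


def atmospheric_correction(
    s: Spectrum, vapor_ref: Spectrum, co2_ref: Spectrum
) -> Spectrum:
    """Subtract non-negative multiples of vapor/CO₂ reference spectra.

    Coefficients (a, b) ≥ 0 minimise the first-difference roughness of the
    corrected spectrum ``s − a·vapor − b·co2`` (non-negative least squares on
    the difference vectors). References on a different grid are resampled
    first.
    """
    refs = []
    for ref in (vapor_ref, co2_ref):
        if ref.grid.shape != s.grid.shape or not np.allclose(ref.grid, s.grid):
            ref = resample_to_grid(ref, s.grid)
        if not np.any(ref.intensities):
            raise ValueError("degenerate all-zero atmospheric reference")
        refs.append(ref.intensities)

    A = np.column_stack([np.diff(r) for r in refs])
    coeffs, _ = nnls(A, np.diff(s.intensities))
    y = s.intensities - coeffs[0] * refs[0] - coeffs[1] * refs[1]
    return Spectrum(
        grid=s.grid,
        intensities=y,
        modality=s.modality,
        hydration=s.hydration,
        sample_ref=s.sample_ref,
    )


# ---------------------------------------------------------------------------
# AsLS baseline


@lru_cache(maxsize=32)
def _d2td2_diagonals(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals of DᵀD for the (n−2)×n second-difference operator D."""
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    return main, off1, off2


def asls_baseline(
    y: np.ndarray,
    lam: float = 1000.0,
    p: float = 0.05,
    max_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric-least-squares baseline; returns (baseline, corrected).

    Solves (W + λ DᵀD) z = W y with the banded symmetric solver, refreshing
    the asymmetric weights each iteration starting from w ≡ 1, and stops
    early once the weight set reaches a fixed point.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D intensity vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input intensities")

    n = y.size
    main, off1, off2 = _d2td2_diagonals(n)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1

    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab[2] = lam * main + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z, y - z


# ---------------------------------------------------------------------------
# rubber-band baseline


def lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Vertex indices of the lower convex hull of (x, y), x strictly ascending."""
    hull: list[int] = []
    for k in range(len(x)):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            # pop j unless the chain turns strictly left (convex from below)
            cross = (x[j] - x[i]) * (y[k] - y[i]) - (y[j] - y[i]) * (x[k] - x[i])
            if cross < 0:
                hull.pop()
            else:
                break
        hull.append(k)
    return hull


def rubberband_baseline(
    y: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rubber-band baseline: lower convex hull, linearly interpolated.

    Returns (baseline, corrected); the corrected spectrum is ≥ 0 everywhere
    and exactly 0 at every hull vertex including both endpoints.
    """
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D intensity vector of length >= 3")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(grid))):
        raise ValueError("non-finite input")
    idx = lower_hull_indices(grid, y)
    baseline = np.interp(grid, grid[idx], y[idx])
    return baseline, y - baseline


# ---------------------------------------------------------------------------
# normalisation


def vector_normalize(y: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm."""
    y = np.asarray(y, dtype=float)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("cannot vector-normalise a zero spectrum")
    return y / norm


def band_integral(
    grid: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral over [lo, hi], band edges linearly interpolated."""
    if not lo < hi:
        raise ValueError("band must be ascending")
    if lo < grid[0] or hi > grid[-1]:
        raise ValueError("band extends beyond the grid")
    inside = (grid > lo) & (grid < hi)
    xs = np.concatenate(([lo], grid[inside], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, grid, y)], y[inside], [np.interp(hi, grid, y)])
    )
    return float(np.trapezoid(ys, xs))


def band_area_normalize(
    s: Spectrum, band: tuple[float, float], target: float = 1.0
) -> Spectrum:
    """Scale so the band's trapezoidal integral equals ``target``."""
    integral = band_integral(s.grid, s.intensities, *band)
    if integral <= 0:
        raise ValueError(
            f"non-positive band integral {integral:.3g}: baseline correction "
            "upstream likely failed"
        )
    return Spectrum(
        grid=s.grid,
        intensities=s.intensities * (target / integral),
        modality=s.modality,
        hydration=s.hydration,
        sample_ref=s.sample_ref,
    )


# ---------------------------------------------------------------------------
# replicate averaging and the per-modality pipeline

_DEFAULT_KEY = ("patient_id", "modality", "hydration")


def average_replicates(
    ds: SpectralDataset, key: tuple[str, ...] = _DEFAULT_KEY
) -> SpectralDataset:
    """Average rows sharing the grouping key (arithmetic mean per wavenumber).

    Replicate indices collapse to 1; the group label must be constant within
    each key group (conflicting labels raise :class:`IntegrityError`).
    """
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(ds.samples):
        groups.setdefault(tuple(getattr(s, f) for f in key), []).append(i)

    rows, records = [], []
    for k, idx in groups.items():
        labels = {ds.samples[i].group for i in idx}
        if len(labels) > 1:
            raise IntegrityError(
                f"conflicting group labels {sorted(labels)} within key {k}"
            )
        rows.append(ds.matrix[idx].mean(axis=0))
        first = ds.samples[idx[0]]
        records.append(
            SampleRecord(
                patient_id=first.patient_id,
                group=first.group,
                modality=first.modality,
                hydration=first.hydration,
                replicate=1,
                age_years=first.age_years,
                bmi_category=first.bmi_category,
                bp_status=first.bp_status,
            )
        )
    return SpectralDataset(grid=ds.grid.copy(), matrix=np.array(rows), samples=records)


def preprocess_modality(
    ds: SpectralDataset,
    params: PreprocessParams,
    modality: str,
    purpose: str = "single",
) -> SpectralDataset:
    """Run the full per-modality pre-processing stack on every row.

    ``purpose`` selects the final normalisation: ``"single"`` applies each
    modality's own convention (FTIR: vector norm; Raman: CH₂-band area),
    ``"fused"`` applies vector normalisation to both so that blocks can be
    concatenated on a common intensity scale.
    """
    if purpose not in ("single", "fused"):
        raise ValueError("purpose must be 'single' or 'fused'")
    wrong = [s.modality for s in ds.samples if s.modality != modality]
    if wrong:
        raise IntegrityError(
            f"dataset contains rows of modality {wrong[0]!r}, expected {modality!r}"
        )

    rng = params.ftir_range if modality == "ATR-FTIR" else params.raman_range
    mask = truncate_grid(ds.grid, *rng)
    grid = ds.grid[mask]
    X = ds.matrix[:, mask]

    out = np.empty_like(X)
    for i in range(X.shape[0]):
        y = X[i]
        if modality == "ATR-FTIR":
            if params.atmospheric_refs is not None:
                spec = Spectrum(grid, y, modality, ds.samples[i].hydration or "wet",
                                ds.samples[i].patient_id)
                y = atmospheric_correction(spec, *params.atmospheric_refs).intensities
            _, y = asls_baseline(
                y, params.asls_lambda, params.asls_p, params.asls_max_iter
            )
            y = vector_normalize(y)
        else:
            _, y = rubberband_baseline(y, grid)
            if purpose == "fused":
                y = vector_normalize(y)
            else:
                integral = band_integral(grid, y, *params.raman_band)
                if integral <= 0:
                    raise ValueError(
                        f"row {i}: non-positive CH2 band integral after baseline"
                    )
                y = y * (params.raman_band_target / integral)
        out[i] = y
    return SpectralDataset(grid=grid, matrix=out, samples=list(ds.samples))
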